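"""Synthetic-data generator: plasma, uptake, rendering, motion, dataset layout."""

import json

import numpy as np
import pandas as pd
import pytest

from fpetconn import (
    AcquisitionSpec,
    DynamicImage,
    NetworkSpec,
    block_parcellation,
    fit_plasma_curve,
    integrate_cumulative,
    plasma_model,
    read_par,
    render_volumes,
    simulate_cohort,
    simulate_motion,
    simulate_plasma_input,
    simulate_roi_uptake,
    write_motion_par,
    write_synthetic_dataset,
)
from fpetconn.connectome import RoiTimeseries, subject_connectivity


class TestPlasmaInput:
    def test_noiseless_curve_strictly_increases_to_peak(self, small_acq):
        samples = simulate_plasma_input(small_acq, peak_time_s=5400, noise_cv=0)
        vals = [s.activity for s in samples if s.draw_time_s <= 5400]
        assert np.all(np.diff(vals) > 0)

    def test_decay_correction_roundtrip(self, small_acq):
        # raw counts were back-computed so the decay correction recovers activity
        samples = simulate_plasma_input(small_acq, noise_cv=0.05, seed=7)
        for s in samples:
            assert s.decay_corrected() == pytest.approx(s.activity, rel=1e-12)

    def test_exact_quadratic_recovered_downstream(self, small_acq):
        samples = simulate_plasma_input(small_acq, noise_cv=0)
        curve = fit_plasma_curve(samples)
        t = np.array([s.draw_time_s for s in samples])
        expected = plasma_model(t, small_acq.plasma_peak_time_s, small_acq.plasma_peak_value)
        assert curve(t) == pytest.approx(expected, abs=1e-9)

    def test_seed_contract(self, small_acq):
        a = simulate_plasma_input(small_acq, seed=1)
        b = simulate_plasma_input(small_acq, seed=2)
        noiseless = simulate_plasma_input(small_acq, noise_cv=0)
        assert [s.activity for s in a] != [s.activity for s in b]
        # identical noiseless curve underneath
        for sa, s0 in zip(a, noiseless):
            assert sa.draw_time_s == s0.draw_time_s

    def test_peak_before_first_draw_rejected(self, small_acq):
        with pytest.raises(ValueError):
            simulate_plasma_input(small_acq, peak_time_s=300)


class TestRoiUptake:
    def test_deterministic_given_seed(self, small_acq):
        net = NetworkSpec(seed=5)
        a = simulate_roi_uptake(net, small_acq)
        b = simulate_roi_uptake(net, small_acq)
        assert np.array_equal(a.values, b.values)

    def test_independent_rois_nearly_uncorrelated(self, small_acq):
        net = NetworkSpec(rho_within=0.0, rho_between=0.0, seed=11)
        ts = simulate_roi_uptake(net, small_acq)
        r = np.corrcoef(ts.values)
        off = r[np.triu_indices(net.n_roi, 1)]
        assert np.max(np.abs(off)) < 0.3  # single realization, 225 frames
        assert np.mean(np.abs(off)) < 0.15

    def test_planted_correlation_converges_over_seeds(self, small_acq):
        # Monte-Carlo mean of the within-community sample correlation
        net0 = NetworkSpec(rho_within=0.6, rho_between=0.1)
        lab = np.array(net0.block_assignment)
        same = lab[:, None] == lab[None, :]
        iu = np.triu_indices(net0.n_roi, 1)
        within, between = [], []
        for seed in range(200):
            net = NetworkSpec(rho_within=0.6, rho_between=0.1, seed=seed)
            r = np.corrcoef(simulate_roi_uptake(net, small_acq).values)
            within.append(r[iu][same[iu]].mean())
            between.append(r[iu][~same[iu]].mean())
        assert np.mean(within) == pytest.approx(0.6, abs=0.02)
        assert np.mean(between) == pytest.approx(0.1, abs=0.02)

    def test_rates_nonnegative(self, small_acq):
        net = NetworkSpec(seed=3)
        assert simulate_roi_uptake(net, small_acq).values.min() >= 0

    def test_invalid_network_rejected(self):
        with pytest.raises(ValueError):
            NetworkSpec(rho_within=0.1, rho_between=0.5)


class TestIntegrateCumulative:
    def test_constant_rate_gives_arithmetic_series(self):
        rates = RoiTimeseries(np.full((2, 5), 3.0), [1, 2], frame_duration_s=16.0)
        cum = integrate_cumulative(rates)
        for k in range(5):
            assert cum.values[0, k] == pytest.approx(3.0 * (k + 1) * 16.0)

    def test_zero_rates_give_zero(self):
        rates = RoiTimeseries(np.zeros((3, 4)), [1, 2, 3])
        assert np.all(integrate_cumulative(rates).values == 0)

    def test_first_differences_invert_integration(self, rng):
        vals = rng.uniform(0, 5, size=(4, 30))
        rates = RoiTimeseries(vals, [1, 2, 3, 4], frame_duration_s=16.0)
        cum = integrate_cumulative(rates).values
        recovered = np.diff(np.concatenate([np.zeros((4, 1)), cum], axis=1)) / 16.0
        assert recovered == pytest.approx(vals, rel=1e-12)

    def test_monotone_nondecreasing_every_roi(self, small_acq):
        net = NetworkSpec(seed=9)
        cum = integrate_cumulative(simulate_roi_uptake(net, small_acq))
        assert np.all(np.diff(cum.values, axis=1) >= 0)

    def test_negative_rates_rejected(self):
        rates = RoiTimeseries(np.full((1, 4), 1.0), [1])
        rates.values[0, 2] = -0.5
        with pytest.raises(ValueError):
            integrate_cumulative(rates)


class TestRenderVolumes:
    def _tiny(self):
        acq = AcquisitionSpec(grid_shape=(12, 12, 12), noise_sd=0, psf_fwhm_mm=0)
        parc = block_parcellation(acq.grid_shape, 8, acq.voxel_size_mm)
        vals = np.cumsum(np.ones((8, 10)), axis=1) * np.arange(1, 9)[:, None]
        cum = RoiTimeseries(vals, list(range(1, 9)), frame_duration_s=16.0)
        return acq, parc, cum

    def test_noiseless_unblurred_voxels_equal_their_tac(self):
        acq, parc, cum = self._tiny()
        img = render_volumes(cum, parc, acq, seed=0)
        for r_idx, roi in enumerate(parc.roi_ids):
            mask = parc.labels == roi
            vox = img.data[mask]
            assert np.allclose(vox, cum.values[r_idx][None, :])

    def test_blur_preserves_roi_mean_monotonicity(self):
        acq, parc, cum = self._tiny()
        img = render_volumes(cum, parc, acq, seed=0, psf_fwhm_mm=5.0)
        for roi in parc.roi_ids:
            series = img.data[parc.labels == roi].mean(axis=0)
            assert np.all(np.diff(series) >= -1e-12)

    def test_background_noise_sd_matches(self):
        from fpetconn import Parcellation

        acq = AcquisitionSpec(grid_shape=(20, 20, 20), psf_fwhm_mm=0, noise_sd=2.0)
        # ROIs fill only the lower 16 z-slices; the rest is background
        inner = block_parcellation((20, 20, 16), 8, acq.voxel_size_mm)
        labels = np.zeros((20, 20, 20), dtype=np.int64)
        labels[:, :, :16] = inner.labels
        parc = Parcellation(labels=labels, voxel_size_mm=acq.voxel_size_mm)
        cum = RoiTimeseries(
            np.ones((8, 40)).cumsum(axis=1), list(range(1, 9)), frame_duration_s=16.0
        )
        img = render_volumes(cum, parc, acq, seed=4)
        bg = img.data[parc.labels == 0]
        assert bg.shape[0] > 100
        sd = bg.std(axis=1).mean()
        assert sd == pytest.approx(2.0, rel=0.1)

    def test_shape_mismatch_rejected(self):
        acq, parc, cum = self._tiny()
        bad_acq = AcquisitionSpec(grid_shape=(10, 10, 10))
        with pytest.raises(ValueError):
            render_volumes(cum, parc, bad_acq, seed=0)


class TestMotionSim:
    def test_zero_steps_give_zero_trace(self, small_acq):
        tr = simulate_motion(small_acq, step_sd_mm=0, step_sd_rad=0, seed=0)
        assert np.all(tr.params == 0)
        assert tr.params[0] @ tr.params[0] == 0

    def test_first_frame_is_reference(self, small_acq):
        tr = simulate_motion(small_acq, seed=3)
        assert np.all(tr.params[0] == 0)
        assert tr.n_frames == 225

    def test_par_roundtrip_bit_exact_at_written_precision(self, small_acq, tmp_path):
        tr = simulate_motion(small_acq, seed=8)
        path = tmp_path / "trace.par"
        write_motion_par(tr, path)
        back = read_par(path)
        rewritten = tmp_path / "trace2.par"
        write_motion_par(back, rewritten)
        assert path.read_text() == rewritten.read_text()
        assert back.params == pytest.approx(tr.params, abs=1e-8)


class TestDatasetWriter:
    @pytest.fixture(scope="class")
    @staticmethod
    def dataset(tmp_path_factory):
        acq = AcquisitionSpec(
            grid_shape=(10, 10, 10),
            scan_duration_s=480.0,
            analysis_onset_s=96.0,
            n_blocks=2,
            block_duration_s=160.0,
            plasma_peak_time_s=460.0,
            noise_sd=1.0,
        )
        net = NetworkSpec(n_roi=8, n_communities=2)
        subs, parc = simulate_cohort(2, net=net, acq=acq, seed=42)
        root = write_synthetic_dataset(subs, parc, tmp_path_factory.mktemp("ds"))
        return root, subs

    def test_layout_and_participants(self, dataset):
        root, _ = dataset
        assert (root / "sub-01" / "pet").is_dir()
        assert (root / "sub-02" / "func").is_dir()
        table = pd.read_csv(root / "participants.tsv", sep="\t")
        assert len(table) == 2
        assert list(table["participant_id"]) == ["sub-01", "sub-02"]

    def test_pet_sidecar_records_frame_duration(self, dataset):
        root, _ = dataset
        with open(root / "sub-01" / "pet" / "sub-01_task-rest_pet.json") as fh:
            meta = json.load(fh)
        assert meta["FrameDuration"] == 16.0

    def test_nifti_roundtrip(self, dataset):
        root, subs = dataset
        img = DynamicImage.load(root / "sub-01" / "pet" / "sub-01_task-rest_pet.nii.gz")
        assert img.data.shape == subs[0].pet.data.shape
        # stored as float32
        assert img.data == pytest.approx(
            subs[0].pet.data.astype(np.float32), rel=1e-6, abs=1e-4
        )

    def test_motion_par_present_with_one_row_per_frame(self, dataset):
        root, subs = dataset
        par = (
            root / "derivatives" / "mcflirt" / "sub-01" / "pet"
            / "sub-01_task_rest_pet_moco.par"
        )
        assert read_par(par).n_frames == subs[0].motion.n_frames


def test_cohort_bit_reproducible():
    net = NetworkSpec(n_roi=8, n_communities=2)
    acq = AcquisitionSpec(grid_shape=(10, 10, 10), noise_sd=1.0)
    a, _ = simulate_cohort(2, net=net, acq=acq, seed=77, include_bold=False)
    b, _ = simulate_cohort(2, net=net, acq=acq, seed=77, include_bold=False)
    for sa, sb in zip(a, b):
        assert np.array_equal(sa.pet.data, sb.pet.data)
        assert np.array_equal(sa.motion.params, sb.motion.params)
        assert [s.activity for s in sa.plasma] == [s.activity for s in sb.plasma]
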