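"""Synthetic constant-infusion fPET/fMRI subjects with planted connectivity.

The generator emulates the statistical structure the analysis pipeline
assumes, at desk scale:

* a 95-min (5700 s) scan binned into 16-s frames, analysed over six 10-min
  blocks starting at 30 min (225 frames);
* a plasma input function that rises concavely to a peak near 90 min;
* regional instantaneous uptake rates = a plasma-tied baseline plus
  correlated Gaussian fluctuations whose population correlation matrix has a
  planted community (block) structure;
* cumulative voxel time-activity curves (running integral of the rates),
  rendered onto a voxel grid through a region parcellation, blurred with a
  Gaussian point-spread and degraded with white noise;
* rigid-motion random-walk traces in the 6-parameter realignment format;
* a BIDS-like on-disk layout (sub-*/pet, sub-*/func, derivatives/mcflirt,
  participants.tsv, JSON sidecars).

Everything is deterministic given a seed.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .connectome import RoiTimeseries
from .core import DynamicImage, Parcellation, block_parcellation
from .timing import FrameGrid, PlasmaSample, build_frame_grid, analysis_window

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class NetworkSpec:
    """Planted inter-regional correlation structure on the uptake signal.

    The implied n_roi x n_roi population correlation matrix is 1 on the
    diagonal, ``rho_within`` for pairs sharing a community and ``rho_between``
    otherwise. With equal-ish blocks and rho_within > rho_between >= 0 this
    matrix is positive semi-definite.

    ``baseline_rate`` is the mean uptake rate (activity units/s) around which
    the correlated fluctuations (SD ``signal_sd``) ride; ``plasma_coupling``
    is the fraction of the baseline that follows the plasma input's shape
    (the rest is steady-state), kept small so the shared infusion trend does
    not swamp the planted correlations.
    """

    n_roi: int = 82
    n_communities: int = 4
    rho_within: float = 0.5
    rho_between: float = 0.1
    signal_sd: float = 1.0
    baseline_rate: float = 6.0
    plasma_coupling: float = 0.15
    seed: int = 0
    block_assignment: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.rho_between <= self.rho_within < 1):
            raise ValueError("require 0 <= rho_between <= rho_within < 1")
        if self.n_roi < 1:
            raise ValueError("need at least one ROI")
        if self.block_assignment:
            if len(self.block_assignment) != self.n_roi:
                raise ValueError("block_assignment length must equal n_roi")
        else:
            assign = tuple(
                int(i * self.n_communities // self.n_roi) for i in range(self.n_roi)
            )
            object.__setattr__(self, "block_assignment", assign)

    @property
    def roi_ids(self) -> list[int]:
        return list(range(1, self.n_roi + 1))

    def correlation_matrix(self) -> np.ndarray:
        """The implied population correlation matrix."""
        labels = np.asarray(self.block_assignment)
        same = labels[:, None] == labels[None, :]
        c = np.where(same, self.rho_within, self.rho_between)
        np.fill_diagonal(c, 1.0)
        return c


@dataclass(frozen=True)
class AcquisitionSpec:
    """Scanner/protocol geometry and noise for the synthetic acquisition."""

    scan_duration_s: float = 5700.0
    frame_duration_s: float = 16.0
    analysis_onset_s: float = 1800.0
    n_blocks: int = 6
    block_duration_s: float = 600.0
    voxel_size_mm: tuple[float, float, float] = (2.09, 2.09, 2.03)
    grid_shape: tuple[int, int, int] = (40, 40, 40)
    psf_fwhm_mm: float = 5.0
    noise_sd: float = 20.0
    plasma_peak_time_s: float = 5400.0
    plasma_peak_value: float = 100.0
    bold_tr_s: float = 2.45

    def __post_init__(self) -> None:
        if min(self.scan_duration_s, self.frame_duration_s, self.block_duration_s) <= 0:
            raise ValueError("durations must be positive")
        if self.analysis_onset_s + self.n_blocks * self.block_duration_s > self.scan_duration_s:
            raise ValueError("analysis window does not fit inside the scan")

    def frame_grid(self) -> FrameGrid:
        return build_frame_grid(
            self.scan_duration_s, self.frame_duration_s, self.analysis_onset_s
        )

    def analysis_frames(self) -> np.ndarray:
        return analysis_window(self.frame_grid(), self.n_blocks, self.block_duration_s)

    def psf_sigma_vox(self) -> tuple[float, float, float]:
        return tuple(
            self.psf_fwhm_mm * FWHM_TO_SIGMA / v for v in self.voxel_size_mm
        )


def plasma_model(t_s: np.ndarray | float, peak_time_s: float, peak_value: float):
    """Noiseless plasma concentration: concave quadratic through the origin.

    ``p(t) = peak_value * (2 u - u^2)`` with ``u = t / peak_time_s`` —
    strictly increasing up to the peak, mirroring the constant-infusion rise.
    """
    u = np.asarray(t_s, dtype=float) / peak_time_s
    out = peak_value * (2.0 * u - u * u)
    return out if out.ndim else float(out)


def simulate_plasma_input(
    acq: AcquisitionSpec,
    peak_time_s: float | None = None,
    peak_value: float | None = None,
    noise_cv: float = 0.03,
    first_draw_s: float | None = None,
    draw_interval_s: float | None = None,
    count_duration_s: float = 240.0,
    half_life_s: float = 6586.2,
    seed: int = 0,
) -> list[PlasmaSample]:
    """Blood draws from the noiseless plasma curve with multiplicative noise.

    Samples are drawn every ``draw_interval_s`` starting at ``first_draw_s``;
    by default draws happen every 10 min for the full-length scan and the
    schedule scales down proportionally for shorter (test-size) scans. Raw
    well-counter counts are back-computed so that decay correction by the
    F-18 half-life recovers the (noisy) concentration exactly.
    """
    peak_time_s = acq.plasma_peak_time_s if peak_time_s is None else peak_time_s
    peak_value = acq.plasma_peak_value if peak_value is None else peak_value
    if draw_interval_s is None:
        draw_interval_s = 600.0 if acq.scan_duration_s >= 5700 else acq.scan_duration_s / 9.5
    if first_draw_s is None:
        first_draw_s = draw_interval_s
    if not (0 < peak_time_s <= acq.scan_duration_s):
        raise ValueError("plasma peak must lie within the scan")
    if first_draw_s > peak_time_s:
        raise ValueError("peak precedes the first blood draw")
    rng = np.random.default_rng(seed)
    times = np.arange(first_draw_s, acq.scan_duration_s + 1e-9, draw_interval_s)
    samples = []
    for t in times:
        conc = plasma_model(t, peak_time_s, peak_value)
        conc *= 1.0 + noise_cv * rng.standard_normal()
        conc = max(conc, 0.0)
        raw = conc * count_duration_s / 2.0 ** (t / half_life_s)
        samples.append(
            PlasmaSample(
                draw_time_s=float(t),
                raw_counts=float(raw),
                count_duration_s=count_duration_s,
                plasma_volume_ml=1.0,
                activity=float(conc),
            )
        )
    return samples


def simulate_roi_uptake(net: NetworkSpec, acq: AcquisitionSpec) -> RoiTimeseries:
    """Instantaneous regional uptake rates over the analysis window.

    rate_i(t) = baseline(t) + signal_sd * e_i(t), where e has the planted
    population correlation (realized via the symmetric matrix square root)
    and baseline follows the plasma shape through ``plasma_coupling``. Rates
    are floored at zero; with the defaults the floor is ~6 SD below the mean
    so clipping is negligible.
    """
    corr = net.correlation_matrix()
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() < -1e-8:
        raise ValueError("implied correlation matrix is not positive semi-definite")
    root = vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None))) @ vecs.T
    grid = acq.frame_grid()
    idx = acq.analysis_frames()
    mids = grid.frame_mid_s[idx]
    p = plasma_model(mids, acq.plasma_peak_time_s, acq.plasma_peak_value)
    p_peak = plasma_model(acq.plasma_peak_time_s, acq.plasma_peak_time_s, acq.plasma_peak_value)
    baseline = net.baseline_rate * (
        (1.0 - net.plasma_coupling) + net.plasma_coupling * p / p_peak
    )
    rng = np.random.default_rng(net.seed)
    z = rng.standard_normal((net.n_roi, mids.size))
    rates = baseline[None, :] + net.signal_sd * (root @ z)
    rates = np.maximum(rates, 0.0)
    return RoiTimeseries(
        values=rates,
        roi_ids=net.roi_ids,
        frame_duration_s=acq.frame_duration_s,
        start_time_s=float(grid.frame_start_s[idx[0]]),
        units="activity/s",
    )


def integrate_cumulative(rates: RoiTimeseries) -> RoiTimeseries:
    """Cumulative uptake: running sum of rates scaled by the frame duration.

    Inverse of first-differencing: diff(cumulative)/frame_duration == rates.
    """
    if np.any(rates.values < 0):
        raise ValueError("uptake rates must be nonnegative")
    cum = np.cumsum(rates.values, axis=1) * rates.frame_duration_s
    return RoiTimeseries(
        values=cum,
        roi_ids=list(rates.roi_ids),
        frame_duration_s=rates.frame_duration_s,
        start_time_s=rates.start_time_s,
        units="activity",
    )


def render_volumes(
    cum: RoiTimeseries,
    parc: Parcellation,
    acq: AcquisitionSpec,
    seed: int = 0,
    noise_sd: float | None = None,
    psf_fwhm_mm: float | None = None,
) -> DynamicImage:
    """Paint regional TACs onto the voxel grid, blur with the PSF, add noise.

    Every voxel of a region carries that region's cumulative TAC; background
    (label 0) carries noise only.
    """
    if parc.labels.shape != tuple(acq.grid_shape):
        raise ValueError(
            f"parcellation grid {parc.labels.shape} != acquisition grid {acq.grid_shape}"
        )
    missing = set(cum.roi_ids) - set(parc.roi_ids)
    if missing:
        raise ValueError(f"parcellation lacks labels for ROIs {sorted(missing)[:5]}")
    noise_sd = acq.noise_sd if noise_sd is None else noise_sd
    psf = acq.psf_fwhm_mm if psf_fwhm_mm is None else psf_fwhm_mm
    lookup = np.zeros(max(parc.roi_ids) + 1)
    n_frames = cum.n_frames
    data = np.zeros((*acq.grid_shape, n_frames))
    sigma = tuple(psf * FWHM_TO_SIGMA / v for v in acq.voxel_size_mm)
    rng = np.random.default_rng(seed)
    for f in range(n_frames):
        lookup[cum.roi_ids] = cum.values[:, f]
        frame = lookup[parc.labels]
        if psf > 0:
            frame = gaussian_filter(frame, sigma=sigma, mode="nearest")
        data[..., f] = frame
    if noise_sd > 0:
        data += noise_sd * rng.standard_normal(data.shape)
    return DynamicImage(
        data=data,
        voxel_size_mm=acq.voxel_size_mm,
        frame_duration_s=acq.frame_duration_s,
        start_time_s=cum.start_time_s,
    )


def simulate_bold(
    net: NetworkSpec, acq: AcquisitionSpec, seed: int = 0, mean_level: float = 100.0
) -> RoiTimeseries:
    """Regional BOLD series with the same planted correlation structure.

    Sampled at the EPI TR over the six-block window; amplitude 1% of the
    mean level, the typical resting-state BOLD fluctuation scale.
    """
    corr = net.correlation_matrix()
    vals, vecs = np.linalg.eigh(corr)
    root = vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None))) @ vecs.T
    n_frames = int(acq.n_blocks * acq.block_duration_s // acq.bold_tr_s)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((net.n_roi, n_frames))
    values = mean_level * (1.0 + 0.01 * (root @ z))
    return RoiTimeseries(
        values=values,
        roi_ids=net.roi_ids,
        frame_duration_s=acq.bold_tr_s,
        start_time_s=acq.analysis_onset_s,
        units="a.u.",
    )


@dataclass
class MotionTrace:
    """Per-frame rigid-body parameters: pitch, roll, yaw (rad), x, y, z (mm)."""

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("motion trace must be n_frames x 6")
        if not np.all(np.isfinite(self.params)):
            raise ValueError("motion parameters must be finite")

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]

    @property
    def rotations_rad(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def translations_mm(self) -> np.ndarray:
        return self.params[:, 3:]


def simulate_motion(
    acq: AcquisitionSpec,
    step_sd_mm: float = 0.26,
    step_sd_rad: float = 0.0005,
    seed: int = 0,
    n_frames: int | None = None,
) -> MotionTrace:
    """Random-walk 6-parameter head-motion trace; frame 0 is the reference.

    The default translational step SD of 0.26 mm is calibrated so the
    expected framewise displacement, ``step_sd * E[chi_3] ~= 1.6 * step_sd``,
    matches the ~0.41 mm group-mean head motion typical of compliant young
    adults over a 95-min scan.
    """
    if step_sd_mm < 0 or step_sd_rad < 0:
        raise ValueError("step SDs must be nonnegative")
    if n_frames is None:
        n_frames = int(acq.analysis_frames().size)
    rng = np.random.default_rng(seed)
    steps = np.zeros((n_frames, 6))
    steps[1:, :3] = step_sd_rad * rng.standard_normal((n_frames - 1, 3))
    steps[1:, 3:] = step_sd_mm * rng.standard_normal((n_frames - 1, 3))
    return MotionTrace(params=np.cumsum(steps, axis=0))


@dataclass
class SyntheticSubject:
    """One simulated participant: images, plasma samples and motion."""

    subject_id: str
    pet: DynamicImage
    bold: RoiTimeseries
    bold_image: DynamicImage | None
    motion: MotionTrace
    plasma: list[PlasmaSample]
    rates: RoiTimeseries
    network: NetworkSpec
    acquisition: AcquisitionSpec


def simulate_subject(
    net: NetworkSpec,
    acq: AcquisitionSpec,
    parc: Parcellation,
    seed: int = 0,
    subject_id: str = "sub-01",
    include_bold: bool = True,
) -> SyntheticSubject:
    """Full single-subject simulation: rates → cumulative → rendered volumes,
    plus BOLD, motion and plasma samples, all seeded from ``seed``.

    ``include_bold=False`` skips rendering the (large) BOLD volume for
    PET-only analyses; the regional BOLD series is still generated.
    """
    ss = np.random.SeedSequence(seed)
    s_net, s_render, s_bold, s_bold_noise, s_motion, s_plasma = [
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(6)
    ]
    net = NetworkSpec(**{**_asdict(net), "seed": s_net})
    rates = simulate_roi_uptake(net, acq)
    cum = integrate_cumulative(rates)
    pet = render_volumes(cum, parc, acq, seed=s_render)
    bold_ts = simulate_bold(net, acq, seed=s_bold)
    bold_img = (
        render_bold_volumes(bold_ts, parc, acq, seed=s_bold_noise)
        if include_bold
        else None
    )
    motion = simulate_motion(acq, seed=s_motion)
    plasma = simulate_plasma_input(acq, seed=s_plasma)
    return SyntheticSubject(
        subject_id=subject_id,
        pet=pet,
        bold=bold_ts,
        bold_image=bold_img,
        motion=motion,
        plasma=plasma,
        rates=rates,
        network=net,
        acquisition=acq,
    )


def render_bold_volumes(
    bold: RoiTimeseries, parc: Parcellation, acq: AcquisitionSpec, seed: int = 0,
    noise_sd: float = 0.5,
) -> DynamicImage:
    """Paint BOLD regional series onto the grid with white noise (no PSF)."""
    lookup = np.zeros(max(parc.roi_ids) + 1)
    data = np.zeros((*parc.labels.shape, bold.n_frames))
    for f in range(bold.n_frames):
        lookup[bold.roi_ids] = bold.values[:, f]
        data[..., f] = lookup[parc.labels]
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        data += noise_sd * rng.standard_normal(data.shape)
    return DynamicImage(
        data=data,
        voxel_size_mm=acq.voxel_size_mm,
        frame_duration_s=acq.bold_tr_s,
        start_time_s=acq.analysis_onset_s,
    )


def _asdict(net: NetworkSpec) -> dict:
    return {
        "n_roi": net.n_roi,
        "n_communities": net.n_communities,
        "rho_within": net.rho_within,
        "rho_between": net.rho_between,
        "signal_sd": net.signal_sd,
        "baseline_rate": net.baseline_rate,
        "plasma_coupling": net.plasma_coupling,
        "seed": net.seed,
        "block_assignment": net.block_assignment,
    }


def simulate_cohort(
    n_subjects: int,
    net: NetworkSpec | None = None,
    acq: AcquisitionSpec | None = None,
    seed: int = 0,
    include_bold: bool = True,
) -> tuple[list[SyntheticSubject], Parcellation]:
    """Simulate ``n_subjects`` participants sharing a parcellation and network."""
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    net = net or NetworkSpec()
    acq = acq or AcquisitionSpec()
    parc = block_parcellation(acq.grid_shape, net.n_roi, acq.voxel_size_mm)
    ss = np.random.SeedSequence(seed)
    subjects = [
        simulate_subject(
            net, acq, parc,
            seed=int(c.generate_state(1)[0] % (2**31)),
            subject_id=f"sub-{i + 1:02d}",
            include_bold=include_bold,
        )
        for i, c in enumerate(ss.spawn(n_subjects))
    ]
    return subjects, parc


def write_motion_par(trace: MotionTrace, path: str | Path) -> None:
    """MCFLIRT-style .par: 6 space-delimited columns, one row per frame."""
    np.savetxt(str(path), trace.params, fmt="%0.8f", delimiter="  ")


def write_synthetic_dataset(
    subjects: list[SyntheticSubject], parc: Parcellation, out_dir: str | Path
) -> Path:
    """Emit a BIDS-like dataset: sub-*/pet, sub-*/func, derivatives, sidecars."""
    if not subjects:
        raise ValueError("need at least one subject")
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    rows = []
    id_hash = zlib.crc32("".join(s.subject_id for s in subjects).encode())
    rng = np.random.default_rng(id_hash % (2**31))
    for sub in subjects:
        sid = sub.subject_id
        pet_dir = root / sid / "pet"
        func_dir = root / sid / "func"
        moco_dir = root / "derivatives" / "mcflirt" / sid / "pet"
        for d in (pet_dir, func_dir, moco_dir):
            d.mkdir(parents=True, exist_ok=True)
        sub.pet.save(pet_dir / f"{sid}_task-rest_pet.nii.gz")
        with open(pet_dir / f"{sid}_task-rest_pet.json", "w") as fh:
            json.dump(
                {
                    "Modality": "PT",
                    "Radiopharmaceutical": "[18F]FDG",
                    "FrameDuration": sub.acquisition.frame_duration_s,
                    "ScanDuration": sub.acquisition.scan_duration_s,
                    "FrameTimesStart": float(sub.pet.start_time_s),
                    "Units": "arbitrary",
                },
                fh,
                indent=2,
            )
        blood = pd.DataFrame(
            {
                "draw_time_s": [s.draw_time_s for s in sub.plasma],
                "raw_counts": [s.raw_counts for s in sub.plasma],
                "count_duration_s": [s.count_duration_s for s in sub.plasma],
                "plasma_volume_mL": [s.plasma_volume_ml for s in sub.plasma],
            }
        )
        blood.to_csv(pet_dir / f"{sid}_recording-blood.tsv", sep="\t", index=False)
        if sub.bold_image is not None:
            sub.bold_image.save(func_dir / f"{sid}_task-rest_bold.nii.gz")
            with open(func_dir / f"{sid}_task-rest_bold.json", "w") as fh:
                json.dump(
                    {"RepetitionTime": sub.acquisition.bold_tr_s, "TaskName": "rest"},
                    fh,
                    indent=2,
                )
        write_motion_par(sub.motion, moco_dir / f"{sid}_task_rest_pet_moco.par")
        rows.append(
            {
                "participant_id": sid,
                "age": int(rng.integers(18, 24)),
                "sex": str(rng.choice(["F", "M"], p=[0.78, 0.22])),
                "handedness": "R",
            }
        )
    pd.DataFrame(rows).to_csv(root / "participants.tsv", sep="\t", index=False)
    parc_dir = root / "derivatives" / "parcellation"
    parc_dir.mkdir(parents=True, exist_ok=True)
    parc.save(parc_dir / "atlas_dseg.nii.gz")
    with open(root / "dataset_description.json", "w") as fh:
        json.dump(
            {"Name": "fpetconn synthetic rsPET-MR", "BIDSVersion": "1.4.0"},
            fh,
            indent=2,
        )
    return root
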