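"""End-to-end orchestration of the fPET/fMRI/static-PET analysis.

Per subject: select the analysis window, gradient-filter the dynamic PET,
extract regional series, correlate (metabolic connectivity); high-pass and
correlate the BOLD series (haemodynamic connectivity); sum the PET frames for
the static image feeding the across-subject metabolic covariance. Motion QC
and plasma fits are computed from the derivatives. Outputs are TSV matrices
with a JSON provenance sidecar sufficient to replay the run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectome as cn
from . import motion as mqc
from .core import DynamicImage, Parcellation
from .dataset import DatasetLayout, PipelineConfig
from .gradient import apply_gradient_filter, build_gradient_kernel
from .timing import (
    PlasmaSample,
    analysis_window,
    build_frame_grid,
    fit_plasma_curve,
)

logger = logging.getLogger(__name__)


def describe_variability(img: DynamicImage) -> dict[str, np.ndarray]:
    """Voxelwise temporal mean, SD and coefficient of variation maps.

    CoV at zero-mean voxels is emitted as NaN (flagged missing), never
    infinite.
    """
    if img.n_frames < 2:
        raise ValueError("variability maps need at least 2 frames")
    mean = img.data.mean(axis=3)
    sd = img.data.std(axis=3, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = np.where(mean != 0, sd / np.where(mean != 0, mean, 1.0), np.nan)
    return {"mean": mean, "sd": sd, "cov": cov}


def write_matrix_tsv(mat: cn.ConnectivityMatrix, path: str | Path) -> None:
    """Connectivity matrix as TSV with roi_id header row/column + JSON sidecar."""
    df = pd.DataFrame(mat.values, index=mat.roi_ids, columns=mat.roi_ids)
    df.index.name = "roi_id"
    df.to_csv(path, sep="\t", float_format="%.10g")
    sidecar = Path(str(path)).with_suffix(".json")
    with open(sidecar, "w") as fh:
        json.dump(
            {
                "modality": mat.modality,
                "aggregation": mat.aggregation,
                "block_index": mat.block_index,
                "n_roi": mat.n_roi,
                **mat.extra,
            },
            fh,
            indent=2,
        )


def read_matrix_tsv(path: str | Path) -> cn.ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta = {}
    sidecar = Path(str(path)).with_suffix(".json")
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
    return cn.ConnectivityMatrix(
        values=df.to_numpy(),
        roi_ids=[int(c) for c in df.columns],
        modality=meta.get("modality", "fpet"),
        block_index=meta.get("block_index"),
        aggregation=meta.get("aggregation", "subject"),
    )


@dataclass
class PipelineResult:
    """Bundle of everything a pipeline run produced."""

    fpet_subject: dict[str, cn.ConnectivityMatrix] = field(default_factory=dict)
    fpet_group: cn.ConnectivityMatrix | None = None
    fmri_subject: dict[str, cn.ConnectivityMatrix] = field(default_factory=dict)
    fmri_group: cn.ConnectivityMatrix | None = None
    static_covariance: cn.ConnectivityMatrix | None = None
    block_similarity: dict[str, np.ndarray] = field(default_factory=dict)
    motion_summary: dict | None = None
    plasma_curves: dict[str, object] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)
    out_dir: Path | None = None


def _read_blood_tsv(path: Path) -> list[PlasmaSample]:
    df = pd.read_csv(path, sep="\t")
    return [
        PlasmaSample(
            draw_time_s=float(r["draw_time_s"]),
            raw_counts=float(r["raw_counts"]),
            count_duration_s=float(r["count_duration_s"]),
            plasma_volume_ml=float(r.get("plasma_volume_mL", 1.0)),
        )
        for _, r in df.iterrows()
    ]


def run_pipeline(
    config: PipelineConfig, layout: DatasetLayout, out_dir: str | Path | None = None
) -> PipelineResult:
    """Execute the full multi-modal analysis over every subject in a layout.

    One failing subject is logged and skipped unless ``config.strict`` is
    set, in which case the run aborts naming the subject. Outputs (if
    ``out_dir`` given) land under ``<out_dir>/derivatives/fpetconn/``.
    """
    if layout.parcellation is None:
        raise ValueError("layout has no parcellation volume")
    parc = Parcellation.load(layout.parcellation)
    result = PipelineResult()
    grid = build_frame_grid(
        config.scan_duration_s, config.frame_duration_s, config.analysis_onset_s
    )
    win = analysis_window(grid, config.n_blocks, config.block_duration_s)
    kernel = build_gradient_kernel(
        config.sigma_spatial_vox, config.sigma_temporal_frames, config.window_extent
    )
    # "valid" filtering trims kernel.half voxels per spatial face
    parc_grad = parc.crop(kernel.half) if config.edge_policy == "valid" else parc

    static_rows: list[np.ndarray] = []
    static_sids: list[str] = []
    traces = []
    for sub in layout.subjects:
        sid = sub.subject_id
        try:
            if sub.has_pet:
                img = DynamicImage.load(
                    sub.pet, frame_duration_s=config.frame_duration_s
                )
                if img.n_frames == grid.n_frames:
                    img = img.select_frames(win)
                    img.start_time_s = float(grid.frame_start_s[win[0]])
                elif img.n_frames != win.size:
                    raise ValueError(
                        f"{sid}: PET has {img.n_frames} frames; expected "
                        f"{grid.n_frames} (full scan) or {win.size} (window)"
                    )
                else:
                    img.start_time_s = float(grid.frame_start_s[win[0]])
                grad = apply_gradient_filter(img, kernel, config.edge_policy)
                ts = cn.extract_roi_timeseries(grad, parc_grad)
                result.fpet_subject[sid] = cn.subject_connectivity(ts, modality="fpet")
                if config.run_block_stability:
                    _, sims = cn.block_stability(
                        ts,
                        config.n_blocks,
                        config.block_duration_s,
                        window_onset_s=float(grid.frame_start_s[win[0]]),
                    )
                    result.block_similarity[sid] = sims
                static = cn.static_image(img)
                s_ts = cn.extract_roi_timeseries(
                    DynamicImage(
                        static[..., None],
                        img.voxel_size_mm,
                        img.frame_duration_s,
                    ),
                    parc,
                )
                static_rows.append(s_ts.values[:, 0])
                static_sids.append(sid)
            if sub.has_func:
                bold = DynamicImage.load(sub.func, frame_duration_s=config.fmri_tr_s)
                bts = cn.extract_roi_timeseries(bold, parc)
                bts = cn.highpass_fmri(bts, config.fmri_highpass_hz, config.fmri_tr_s)
                result.fmri_subject[sid] = cn.subject_connectivity(bts, modality="fmri")
            if sub.blood is not None:
                samples = _read_blood_tsv(sub.blood)
                result.plasma_curves[sid] = fit_plasma_curve(
                    samples, half_life_s=config.half_life_s
                )
            if sub.motion_par is not None:
                traces.append(mqc.read_par(sub.motion_par))
        except Exception as exc:  # noqa: BLE001 - aggregate per-subject failures
            if config.strict:
                raise RuntimeError(f"subject {sid} failed: {exc}") from exc
            logger.error("subject %s failed: %s", sid, exc)
            result.errors[sid] = str(exc)

    if result.fpet_subject:
        result.fpet_group = cn.group_average(list(result.fpet_subject.values()))
    if result.fmri_subject:
        result.fmri_group = cn.group_average(list(result.fmri_subject.values()))
    if len(static_rows) >= 3:
        result.static_covariance = cn.metabolic_covariance(
            np.array(static_rows), roi_ids=list(parc.roi_ids)
        )
    if traces:
        result.motion_summary = mqc.group_motion_summary(traces)

    if out_dir is not None:
        result.out_dir = _write_outputs(result, config, layout, Path(out_dir))
    return result


def _write_outputs(
    result: PipelineResult,
    config: PipelineConfig,
    layout: DatasetLayout,
    out_dir: Path,
) -> Path:
    deriv = out_dir / "derivatives" / "fpetconn"
    deriv.mkdir(parents=True, exist_ok=True)
    for sid, mat in result.fpet_subject.items():
        write_matrix_tsv(mat, deriv / f"{sid}_fpet_connectivity.tsv")
    for sid, mat in result.fmri_subject.items():
        write_matrix_tsv(mat, deriv / f"{sid}_fmri_connectivity.tsv")
    if result.fpet_group is not None:
        write_matrix_tsv(result.fpet_group, deriv / "group_fpet_connectivity.tsv")
    if result.fmri_group is not None:
        write_matrix_tsv(result.fmri_group, deriv / "group_fmri_connectivity.tsv")
    if result.static_covariance is not None:
        write_matrix_tsv(result.static_covariance, deriv / "group_static_covariance.tsv")
    if result.block_similarity:
        rows = [
            {"subject": sid, **{f"block_{b + 1}": v for b, v in enumerate(sims)}}
            for sid, sims in result.block_similarity.items()
        ]
        pd.DataFrame(rows).to_csv(
            deriv / "block_stability.tsv", sep="\t", index=False, float_format="%.10g"
        )
    if result.motion_summary is not None:
        with open(deriv / "motion_qc.json", "w") as fh:
            json.dump(result.motion_summary, fh, indent=2)
    if result.plasma_curves:
        rows = [
            {
                "subject": sid,
                "c0": c.c0,
                "c1": c.c1,
                "c2": c.c2,
                "n_samples": c.n_samples_used,
            }
            for sid, c in result.plasma_curves.items()
        ]
        pd.DataFrame(rows).to_csv(
            deriv / "plasma_fits.tsv", sep="\t", index=False, float_format="%.10g"
        )
    provenance = {
        "config": asdict(config),
        "dataset_root": str(layout.root),
        "subjects": layout.subject_ids,
        "errors": result.errors,
    }
    with open(deriv / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    return deriv
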