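"""ROI time-series extraction and connectivity estimation.

Three connectivity products are supported, mirroring how a simultaneous
fPET/fMRI resting-state study is analysed:

* **metabolic connectivity** — within-subject Pearson correlation between
  regional gradient-filtered fPET time series;
* **haemodynamic connectivity** — the same statistic on high-pass-filtered
  BOLD fMRI regional series;
* **metabolic covariance** — across-subject correlation of static (summed)
  regional FDG uptake, after removing each subject's global mean.

Subject matrices are aggregated on the Fisher-z scale. Block-stability
utilities split the analysis window into consecutive blocks and compare each
block's connectome with the full-window one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .core import DynamicImage, Parcellation

logger = logging.getLogger(__name__)


@dataclass
class RoiTimeseries:
    """n_roi x n_frames matrix of regional values with frame timing."""

    values: np.ndarray
    roi_ids: list[int]
    frame_duration_s: float = 16.0
    start_time_s: float = 0.0
    units: str = "a.u."

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be n_roi x n_frames")
        if self.values.shape[0] != len(self.roi_ids):
            raise ValueError("row count must equal number of ROI ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ROI time series contain non-finite values")

    @property
    def n_roi(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def frame_mid_s(self) -> np.ndarray:
        return (
            self.start_time_s
            + np.arange(self.n_frames) * self.frame_duration_s
            + self.frame_duration_s / 2.0
        )


@dataclass
class ConnectivityMatrix:
    """Symmetric ROI x ROI correlation matrix with provenance metadata.

    By convention the diagonal is zero (self-correlation carries no
    information and would otherwise dominate summaries).
    """

    values: np.ndarray
    roi_ids: list[int]
    modality: str = "fpet"  # fpet | fmri | static_covariance
    block_index: int | None = None
    aggregation: str = "subject"  # subject | group
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.roi_ids)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} ROIs")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        off = v[~np.eye(n, dtype=bool)]
        if off.size and (np.nanmax(np.abs(off)) > 1.0 + 1e-12):
            raise ValueError("off-diagonal correlations must lie in [-1, 1]")
        np.fill_diagonal(v, 0.0)
        self.values = v

    @property
    def n_roi(self) -> int:
        return len(self.roi_ids)

    def upper_triangle(self) -> np.ndarray:
        """Strict upper-triangle entries as a flat vector."""
        n = self.n_roi
        return self.values[np.triu_indices(n, k=1)]


def extract_roi_timeseries(
    img: DynamicImage, parc: Parcellation, on_empty: str = "drop"
) -> RoiTimeseries:
    """Per-frame mean over the voxels of each parcellation label.

    ``on_empty`` controls labels with no voxels (possible after masking or
    edge trimming): ``"drop"`` removes the row with a warning, ``"error"``
    raises.
    """
    if img.data.shape[:3] != parc.labels.shape:
        raise ValueError(
            f"image grid {img.data.shape[:3]} != parcellation grid {parc.labels.shape}"
        )
    flat_labels = parc.labels.reshape(-1)
    flat = img.data.reshape(-1, img.n_frames)
    rows = []
    kept: list[int] = []
    dropped: list[int] = []
    for roi in parc.roi_ids:
        mask = flat_labels == roi
        if not mask.any():
            if on_empty == "error":
                raise ValueError(f"ROI {roi} has no voxels")
            dropped.append(roi)
            continue
        rows.append(flat[mask].mean(axis=0))
        kept.append(roi)
    if dropped:
        warnings.warn(f"dropped empty ROIs: {dropped}", stacklevel=2)
        logger.warning("dropped empty ROIs: %s", dropped)
    return RoiTimeseries(
        values=np.array(rows),
        roi_ids=kept,
        frame_duration_s=img.frame_duration_s,
        start_time_s=img.start_time_s,
    )


def highpass_fmri(
    ts: RoiTimeseries, cutoff_hz: float = 0.01, tr_s: float = 2.45
) -> RoiTimeseries:
    """High-pass a regional BOLD series by projecting out a slow cosine basis.

    Discrete-cosine regressors with frequency below ``cutoff_hz`` (plus the
    constant) are removed by least squares, the standard drift model for
    resting-state BOLD. Output rows have zero mean.
    """
    if tr_s <= 0:
        raise ValueError("TR must be positive")
    nyquist = 0.5 / tr_s
    if cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz is at/above Nyquist {nyquist} Hz")
    n = ts.n_frames
    # DCT-II basis: frequency of order k is k / (2 * n * TR).
    n_reg = int(np.floor(2.0 * n * tr_s * cutoff_hz)) + 1
    t = np.arange(n)
    basis = np.cos(
        np.pi * np.outer(t + 0.5, np.arange(n_reg)) / n
    )  # includes the constant (k=0)
    coef, *_ = np.linalg.lstsq(basis, ts.values.T, rcond=None)
    resid = ts.values.T - basis @ coef
    return replace(ts, values=resid.T, units=ts.units)


def subject_connectivity(
    ts: RoiTimeseries, modality: str = "fpet", block_index: int | None = None
) -> ConnectivityMatrix:
    """Pearson correlation across frames for every ROI pair, diagonal zeroed."""
    if ts.n_frames < 3:
        raise ValueError("need at least 3 frames to correlate")
    sds = ts.values.std(axis=1)
    zero_var = np.nonzero(sds == 0)[0]
    if zero_var.size:
        bad = [ts.roi_ids[i] for i in zero_var]
        raise ValueError(f"zero-variance ROI time series: {bad}")
    r = np.corrcoef(ts.values)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix(
        values=r, roi_ids=list(ts.roi_ids), modality=modality, block_index=block_index
    )


def group_average(mats: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Fisher-z average of subject matrices.

    Each off-diagonal entry is atanh-transformed, averaged across subjects,
    and mapped back with tanh — the standard aggregation for correlation
    coefficients.
    """
    if not mats:
        raise ValueError("need at least one matrix")
    first = mats[0]
    for m in mats[1:]:
        if m.roi_ids != first.roi_ids:
            raise ValueError("matrices have mismatched ROI ids")
        if m.modality != first.modality:
            raise ValueError("cannot average across modalities")
    stack = np.array([m.values for m in mats])
    with np.errstate(divide="ignore"):
        z = np.arctanh(np.clip(stack, -1.0, 1.0))
    avg = np.tanh(z.mean(axis=0))
    np.fill_diagonal(avg, 0.0)
    return ConnectivityMatrix(
        values=avg,
        roi_ids=list(first.roi_ids),
        modality=first.modality,
        aggregation="group",
    )


def static_image(img: DynamicImage) -> np.ndarray:
    """Static PET: voxelwise sum of the dynamic frames."""
    if img.n_frames < 1:
        raise ValueError("need at least one frame")
    return img.data.sum(axis=3)


def metabolic_covariance(static_roi_values: np.ndarray, roi_ids: list[int]) -> ConnectivityMatrix:
    """Across-subject correlation of demeaned static regional uptake.

    ``static_roi_values`` is subjects x ROIs. Each subject's global mean over
    ROIs is subtracted first, so the statistic reflects the regional pattern
    rather than global dose/uptake differences.
    """
    x = np.asarray(static_roi_values, dtype=float)
    if x.ndim != 2 or x.shape[1] != len(roi_ids):
        raise ValueError("expected subjects x ROIs matrix matching roi_ids")
    if x.shape[0] < 3:
        raise ValueError("metabolic covariance needs at least 3 subjects")
    x = x - x.mean(axis=1, keepdims=True)
    sds = x.std(axis=0)
    if np.any(sds == 0):
        bad = [roi_ids[i] for i in np.nonzero(sds == 0)[0]]
        raise ValueError(f"zero-variance ROI columns: {bad}")
    r = np.corrcoef(x.T)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix(
        values=r, roi_ids=list(roi_ids), modality="static_covariance",
        aggregation="group",
    )


def matrix_similarity(a: ConnectivityMatrix, b: ConnectivityMatrix) -> float:
    """Pearson correlation of the strict upper triangles of two matrices."""
    if a.roi_ids != b.roi_ids:
        raise ValueError("matrices have mismatched ROI ids")
    return float(np.corrcoef(a.upper_triangle(), b.upper_triangle())[0, 1])


def assign_blocks(
    ts: RoiTimeseries, n_blocks: int = 6, block_duration_s: float = 600.0,
    window_onset_s: float | None = None,
) -> np.ndarray:
    """Block index for every frame, by the block containing the frame midpoint.

    With 225 16-s frames over six 10-min blocks this yields the deterministic
    37/38 alternation. Frames whose midpoint falls outside the block span get
    index -1.
    """
    onset = ts.start_time_s if window_onset_s is None else window_onset_s
    rel = ts.frame_mid_s - onset
    idx = np.floor(rel / block_duration_s).astype(int)
    idx[(rel < 0) | (idx >= n_blocks)] = -1
    return idx


def block_stability(
    ts: RoiTimeseries,
    n_blocks: int = 6,
    block_duration_s: float = 600.0,
    window_onset_s: float | None = None,
    modality: str = "fpet",
) -> tuple[list[ConnectivityMatrix], np.ndarray]:
    """Per-block connectomes and their similarity to the full-window connectome.

    Returns ``(matrices, similarity)``: one subject-level matrix per block and
    the upper-triangle correlation of each with the matrix computed from the
    whole window.
    """
    idx = assign_blocks(ts, n_blocks, block_duration_s, window_onset_s)
    full = subject_connectivity(ts, modality=modality)
    mats: list[ConnectivityMatrix] = []
    sims = np.empty(n_blocks)
    for b in range(n_blocks):
        sel = idx == b
        if sel.sum() < 3:
            raise ValueError(f"block {b} has {int(sel.sum())} frames (<3)")
        sub = replace(ts, values=ts.values[:, sel])
        mat = subject_connectivity(sub, modality=modality, block_index=b)
        mats.append(mat)
        sims[b] = matrix_similarity(mat, full)
    return mats, sims
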