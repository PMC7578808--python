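"""Spatio-temporal gradient filter for constant-infusion fPET.

Constant-infusion FDG produces a cumulative uptake signal: what the scanner
measures at each voxel is (noisy) accumulated glucose uptake, while the
quantity of neuroscientific interest is the short-term *change* in uptake.
The filter built here estimates that change: it is the outer product of a
3D spatial Gaussian (denoising) and an odd, derivative-of-step temporal
profile — negative Gaussian weights on past frames, zero weight on the
current frame, positive Gaussian weights on future frames — truncated to a
7x7x7x7 window so spatial smoothing cannot manufacture correlation between
adjacent regions.

Sign convention: the kernel is *correlated* (not flip-convolved) with the
image, so positive temporal offsets address later frames and a rising signal
yields a positive response. The kernel is normalized so that a unit-slope
temporal ramp maps to exactly 1; output units are therefore activity change
per frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.ndimage import correlate1d

from .core import DynamicImage


def _gaussian_lobe(sigma: float, half: int) -> np.ndarray:
    """Discrete Gaussian on offsets -half..half, normalized to unit sum."""
    x = np.arange(-half, half + 1, dtype=float)
    g = np.exp(-0.5 * (x / sigma) ** 2)
    return g / g.sum()


@dataclass(frozen=True)
class GradientKernel:
    """Separable 4D gradient-estimation kernel.

    ``weights`` has shape (w, w, w, w) ordered (x, y, z, t). The temporal
    profile is antisymmetric (w(-t) = -w(t)) with a zero central slice; the
    spatial part is an isotropic Gaussian in voxel units.
    """

    weights: np.ndarray
    sigma_spatial_vox: float
    sigma_temporal_frames: float
    window_extent: int

    @property
    def half(self) -> int:
        return (self.window_extent - 1) // 2

    @property
    def spatial_lobe(self) -> np.ndarray:
        """Unit-sum 1D spatial factor (same along x, y and z)."""
        return _gaussian_lobe(self.sigma_spatial_vox, self.half)

    @property
    def temporal_profile(self) -> np.ndarray:
        """Signed, ramp-normalized 1D temporal factor."""
        return _temporal_profile(self.sigma_temporal_frames, self.half)

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.weights.astype(np.float32), np.eye(4))

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))


def _temporal_profile(sigma_t: float, half: int) -> np.ndarray:
    t = np.arange(-half, half + 1, dtype=float)
    prof = np.sign(t) * np.exp(-0.5 * (t / sigma_t) ** 2)
    # Unit response to a unit-slope ramp: sum_t prof(t)*t == 1.
    ramp_response = float(np.sum(prof * t))
    return prof / ramp_response


def build_gradient_kernel(
    sigma_spatial_vox: float = 1.0,
    sigma_temporal_frames: float = 2.0,
    window_extent: int = 7,
) -> GradientKernel:
    """Build the truncated separable spatio-temporal gradient kernel.

    Parameters
    ----------
    sigma_spatial_vox:
        Standard deviation of the 3D spatial Gaussian, in voxels (default 1).
    sigma_temporal_frames:
        Standard deviation of the temporal Gaussian, in frames (default 2).
    window_extent:
        Odd extent of the truncation window along every axis (default 7,
        i.e. offsets -3..3).
    """
    if sigma_spatial_vox <= 0 or sigma_temporal_frames <= 0:
        raise ValueError("Gaussian widths must be positive")
    if window_extent < 3 or window_extent % 2 == 0:
        raise ValueError("window_extent must be odd and >= 3")
    half = (window_extent - 1) // 2
    lobe = _gaussian_lobe(sigma_spatial_vox, half)
    spatial = lobe[:, None, None] * lobe[None, :, None] * lobe[None, None, :]
    temporal = _temporal_profile(sigma_temporal_frames, half)
    weights = spatial[..., None] * temporal[None, None, None, :]
    return GradientKernel(
        weights=weights,
        sigma_spatial_vox=float(sigma_spatial_vox),
        sigma_temporal_frames=float(sigma_temporal_frames),
        window_extent=int(window_extent),
    )


def apply_gradient_filter(
    img: DynamicImage,
    kernel: GradientKernel | None = None,
    edge_policy: str = "valid",
) -> DynamicImage:
    """Sliding correlation of the gradient kernel with a 4D image.

    Because the kernel is separable the correlation is applied as three 1D
    spatial passes followed by one signed temporal pass; the result is
    identical (to round-off) to the full 4D correlation.

    edge_policy:
        ``"valid"`` (default) trims ``(window_extent-1)/2`` frames at each
        temporal end and the same number of voxels at each spatial face, so
        every output sample saw a complete kernel.
        ``"renormalized"`` keeps the full grid: near the boundaries the
        visible part of each 1D lobe is renormalized (spatial lobes to unit
        sum; the temporal lobe re-zeroed via the current-frame tap and
        rescaled to unit ramp response), so constants still map to zero and
        ramps to their slope everywhere.

    Output frame timing: with ``"valid"``, frame 0 of the output corresponds
    to input frame ``half``, and units are activity per frame.
    """
    if kernel is None:
        kernel = build_gradient_kernel()
    half = kernel.half
    data = np.asarray(img.data, dtype=float)
    if data.shape[3] < kernel.window_extent:
        raise ValueError(
            f"image has {data.shape[3]} frames; kernel needs >= {kernel.window_extent}"
        )
    if min(data.shape[:3]) < kernel.window_extent and edge_policy == "valid":
        raise ValueError("spatial grid smaller than the kernel window")
    if edge_policy not in ("valid", "renormalized"):
        raise ValueError(f"unknown edge policy: {edge_policy!r}")

    lobe = kernel.spatial_lobe
    temporal = kernel.temporal_profile

    if edge_policy == "valid":
        out = data
        for axis in range(3):
            # constant padding then trim == valid correlation
            out = correlate1d(out, lobe, axis=axis, mode="constant", cval=0.0)
            sl = [slice(None)] * 4
            sl[axis] = slice(half, out.shape[axis] - half)
            out = out[tuple(sl)]
        out = correlate1d(out, temporal, axis=3, mode="constant", cval=0.0)
        out = out[..., half : out.shape[3] - half]
        start = img.start_time_s + half * img.frame_duration_s
    else:
        out = data
        for axis in range(3):
            num = correlate1d(out, lobe, axis=axis, mode="constant", cval=0.0)
            shape = [1, 1, 1, 1]
            shape[axis] = out.shape[axis]
            ones = np.ones(shape)
            norm = correlate1d(ones, lobe, axis=axis, mode="constant", cval=0.0)
            out = num / norm
        out = _temporal_pass_renormalized(out, temporal, half)
        start = img.start_time_s

    return DynamicImage(
        data=out,
        voxel_size_mm=img.voxel_size_mm,
        frame_duration_s=img.frame_duration_s,
        start_time_s=start,
    )


def _temporal_pass_renormalized(
    data: np.ndarray, temporal: np.ndarray, half: int
) -> np.ndarray:
    """Temporal correlation with the truncated lobe renormalized at the edges.

    Near a temporal boundary the visible part of the odd lobe no longer sums
    to zero nor has unit ramp response. Both properties are restored by (a)
    moving the zero-sum correction onto the current-frame tap and (b)
    rescaling by the visible ramp response — so constants still map to zero
    and a ramp to its slope at every frame.
    """
    n_t = data.shape[3]
    offsets = np.arange(-half, half + 1)
    out = np.zeros_like(data)
    for t in range(n_t):
        visible = (t + offsets >= 0) & (t + offsets < n_t)
        w = temporal[visible].copy()
        offs = offsets[visible]
        ramp = float(np.sum(w * offs))
        if ramp == 0.0:
            continue
        w[offs == 0] = -float(np.sum(w[offs != 0]))
        w = w / ramp
        acc = np.zeros(data.shape[:3])
        for wi, dt in zip(w, offs):
            acc += wi * data[..., t + dt]
        out[..., t] = acc
    return out


def sweep_filter_parameters(
    img: DynamicImage,
    parcellation,
    sigma_s_list=(1.0, 2.0, 3.0),
    sigma_t_list=(1.0, 2.0, 3.0),
    window_extent: int = 7,
    edge_policy: str = "valid",
    default_sigma_s: float = 1.0,
    default_sigma_t: float = 2.0,
):
    """Connectivity consistency across a grid of filter widths.

    For each (sigma_s, sigma_t) pair the full per-subject chain runs —
    gradient filter, ROI extraction, Pearson connectivity — and the resulting
    matrix is compared with the default-parameter matrix by correlating the
    strict-upper-triangle entries. Returns ``(matrices, summary)`` where
    ``matrices`` maps (sigma_s, sigma_t) to a ConnectivityMatrix and
    ``summary`` is a pandas DataFrame with similarity-to-default and mean
    off-diagonal connectivity per pair.
    """
    import pandas as pd

    from .connectome import (
        extract_roi_timeseries,
        matrix_similarity,
        subject_connectivity,
    )

    sigma_s_list = list(sigma_s_list)
    sigma_t_list = list(sigma_t_list)
    if not sigma_s_list or not sigma_t_list:
        raise ValueError("parameter lists must be nonempty")

    def run(ss: float, st: float):
        k = build_gradient_kernel(ss, st, window_extent)
        grad = apply_gradient_filter(img, k, edge_policy)
        parc = parcellation.crop(k.half) if edge_policy == "valid" else parcellation
        ts = extract_roi_timeseries(grad, parc)
        return subject_connectivity(ts)

    reference = run(default_sigma_s, default_sigma_t)
    matrices = {}
    rows = []
    for ss in sigma_s_list:
        for st in sigma_t_list:
            mat = run(ss, st)
            matrices[(ss, st)] = mat
            n = mat.values.shape[0]
            off = mat.values[np.triu_indices(n, k=1)]
            rows.append(
                {
                    "sigma_s": ss,
                    "sigma_t": st,
                    "similarity_to_default": matrix_similarity(mat, reference),
                    "mean_connectivity": float(np.mean(off)),
                }
            )
    return matrices, pd.DataFrame(rows)
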