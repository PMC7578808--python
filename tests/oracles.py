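"""Independent brute-force oracles used to cross-check the optimized paths.

Each oracle is a direct transcription of the operation's definition (explicit
loops / closed forms), deliberately ignorant of how the package implements it.
"""

from __future__ import annotations

import numpy as np


def brute_force_correlate4d(data: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Valid sliding correlation of a 4D kernel with a 4D image, by loops."""
    wx, wy, wz, wt = weights.shape
    nx, ny, nz, nt = data.shape
    ox, oy, oz, ot = nx - wx + 1, ny - wy + 1, nz - wz + 1, nt - wt + 1
    out = np.empty((ox, oy, oz, ot))
    for i in range(ox):
        for j in range(oy):
            for k in range(oz):
                for t in range(ot):
                    patch = data[i : i + wx, j : j + wy, k : k + wz, t : t + wt]
                    out[i, j, k, t] = float(np.sum(patch * weights))
    return out


def roi_means_by_loop(data4d: np.ndarray, labels: np.ndarray, roi_ids) -> np.ndarray:
    """Per-ROI per-frame voxel average via explicit voxel loops."""
    n_frames = data4d.shape[3]
    out = np.zeros((len(roi_ids), n_frames))
    for r, roi in enumerate(roi_ids):
        coords = np.argwhere(labels == roi)
        for f in range(n_frames):
            total = 0.0
            for (i, j, k) in coords:
                total += data4d[i, j, k, f]
            out[r, f] = total / len(coords)
    return out


def quadratic_fit_normal_equations(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Closed-form normal-equations solution for y = c0 + c1 t + c2 t^2."""
    x = np.stack([np.ones_like(t), t, t * t], axis=1)
    return np.linalg.solve(x.T @ x, x.T @ y)


def mean_relative_displacement_by_loop(params: np.ndarray) -> float:
    """Mean Euclidean norm of framewise translation differences, by loops."""
    total = 0.0
    n = params.shape[0]
    for i in range(1, n):
        dx = params[i, 3] - params[i - 1, 3]
        dy = params[i, 4] - params[i - 1, 4]
        dz = params[i, 5] - params[i - 1, 5]
        total += (dx * dx + dy * dy + dz * dz) ** 0.5
    return total / (n - 1)


def static_sum_by_loop(data4d: np.ndarray) -> np.ndarray:
    """Voxelwise frame sum via an explicit frame loop."""
    out = np.zeros(data4d.shape[:3])
    for f in range(data4d.shape[3]):
        out += data4d[..., f]
    return out
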