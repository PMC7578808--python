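"""Shared in-memory containers: dynamic 4D images and integer parcellations."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np


@dataclass
class DynamicImage:
    """A 4D intensity grid (x, y, z, t) with frame timing.

    The central object for both the fPET and fMRI paths. ``frame_duration_s``
    is the uniform frame length; ``start_time_s`` is the onset of frame 0
    relative to infusion/scan start.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (2.09, 2.09, 2.03)
    frame_duration_s: float = 16.0
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D data, got {self.data.ndim}D")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def frame_mid_s(self) -> np.ndarray:
        return (
            self.start_time_s
            + np.arange(self.n_frames) * self.frame_duration_s
            + self.frame_duration_s / 2.0
        )

    def select_frames(self, indices: np.ndarray) -> "DynamicImage":
        """Contiguous frame subset; timing metadata follows the first frame."""
        idx = np.asarray(indices)
        if idx.size and np.any(np.diff(idx) != 1):
            raise ValueError("frame selection must be contiguous")
        return DynamicImage(
            data=self.data[..., idx],
            voxel_size_mm=self.voxel_size_mm,
            frame_duration_s=self.frame_duration_s,
            start_time_s=self.start_time_s + float(idx[0]) * self.frame_duration_s,
        )

    def affine(self) -> np.ndarray:
        aff = np.diag([*self.voxel_size_mm, 1.0])
        return aff

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine())
        img.header.set_zooms((*self.voxel_size_mm, self.frame_duration_s))
        img.header.set_xyzt_units(xyz="mm", t="sec")
        return img

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(
        cls,
        path: str | Path,
        frame_duration_s: float | None = None,
        start_time_s: float = 0.0,
    ) -> "DynamicImage":
        img = nib.load(str(path))
        zooms = img.header.get_zooms()
        if frame_duration_s is None:
            frame_duration_s = float(zooms[3]) if len(zooms) > 3 else 1.0
        return cls(
            data=np.asanyarray(img.dataobj, dtype=np.float64),
            voxel_size_mm=tuple(float(z) for z in zooms[:3]),
            frame_duration_s=frame_duration_s,
            start_time_s=start_time_s,
        )


@dataclass
class Parcellation:
    """Integer-labelled 3D volume assigning voxels to regions; 0 = background."""

    labels: np.ndarray
    roi_ids: list[int] = field(default_factory=list)
    voxel_size_mm: tuple[float, float, float] = (2.09, 2.09, 2.03)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("parcellation must be a 3D label grid")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("parcellation labels must be integers")
        present = set(np.unique(self.labels)) - {0}
        if not self.roi_ids:
            self.roi_ids = sorted(int(v) for v in present)
        if len(set(self.roi_ids)) != len(self.roi_ids):
            raise ValueError("roi_ids must be distinct")
        stray = present - set(self.roi_ids)
        if stray:
            raise ValueError(f"labels not in roi_ids: {sorted(stray)[:5]}")

    @property
    def n_roi(self) -> int:
        return len(self.roi_ids)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    def crop(self, margin: int) -> "Parcellation":
        """Trim ``margin`` voxels from every face (to match a valid-filtered grid).

        ROIs that lose all their voxels are dropped from ``roi_ids``.
        """
        if margin == 0:
            return self
        if margin < 0 or min(self.labels.shape) <= 2 * margin:
            raise ValueError(f"cannot crop {margin} voxels from {self.labels.shape}")
        sub = self.labels[margin:-margin, margin:-margin, margin:-margin]
        present = set(np.unique(sub)) - {0}
        kept = [r for r in self.roi_ids if r in present]
        return Parcellation(labels=sub, roi_ids=kept, voxel_size_mm=self.voxel_size_mm)

    def save(self, path: str | Path) -> None:
        aff = np.diag([*self.voxel_size_mm, 1.0])
        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), aff), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "Parcellation":
        img = nib.load(str(path))
        zooms = img.header.get_zooms()
        return cls(
            labels=np.asanyarray(img.dataobj).astype(np.int64),
            voxel_size_mm=tuple(float(z) for z in zooms[:3]),
        )


def block_parcellation(
    grid_shape: tuple[int, int, int],
    n_roi: int = 82,
    voxel_size_mm: tuple[float, float, float] = (2.09, 2.09, 2.03),
) -> Parcellation:
    """Tile a grid into contiguous rectangular ROIs labelled 1..n_roi.

    The grid is partitioned into the smallest near-cubic lattice of boxes with
    at least ``n_roi`` cells; the first ``n_roi`` boxes (lexicographic order)
    become ROIs and any leftover boxes stay background. A stand-in for an
    anatomical atlas at desk scale.
    """
    if n_roi < 1:
        raise ValueError("need at least one ROI")
    # Near-cubic lattice of a*b*c >= n_roi boxes; leftover boxes stay background.
    best = None
    hi = int(np.ceil(n_roi ** (1 / 3))) + 3
    for a in range(1, min(hi, grid_shape[0]) + 1):
        for b in range(1, min(hi, grid_shape[1]) + 1):
            c = int(np.ceil(n_roi / (a * b)))
            if c > grid_shape[2] or a * b * c < n_roi:
                continue
            spread = max(a, b, c) - min(a, b, c)
            waste = a * b * c - n_roi
            key = (waste, spread, a * b * c)
            if best is None or key < best[0]:
                best = (key, (a, b, c))
    if best is None:
        raise ValueError(f"grid {grid_shape} too small to tile {n_roi} ROIs")
    nx, ny, nz = best[1]
    labels = np.zeros(grid_shape, dtype=np.int64)
    xs = np.array_split(np.arange(grid_shape[0]), nx)
    ys = np.array_split(np.arange(grid_shape[1]), ny)
    zs = np.array_split(np.arange(grid_shape[2]), nz)
    label = 1
    for xi in xs:
        for yi in ys:
            for zi in zs:
                if label > n_roi:
                    break
                labels[np.ix_(xi, yi, zi)] = label
                label += 1
    return Parcellation(
        labels=labels, roi_ids=list(range(1, n_roi + 1)), voxel_size_mm=voxel_size_mm
    )
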