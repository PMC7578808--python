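"""Motion QC from rigid-body realignment parameters.

Dynamic PET frames are realigned before analysis; the realignment parameters
(pitch, roll, yaw in radians, then x, y, z translations in mm — the MCFLIRT
``.par`` column order) summarise how much the head moved. The QC statistic is
the mean relative (frame-to-frame) translational displacement per subject,
plus its across-subject mean and maximum.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .synth import MotionTrace


def read_par(path: str | Path) -> MotionTrace:
    """Parse a 6-column whitespace-delimited realignment file.

    Tolerant of repeated whitespace and blank lines; a line with the wrong
    column count raises an error naming the line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6:
                raise ValueError(
                    f"{path}: line {lineno} has {len(parts)} columns, expected 6"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
    if not rows:
        raise ValueError(f"{path}: no parameter rows found")
    return MotionTrace(params=np.array(rows))


def relative_displacements(trace: MotionTrace) -> np.ndarray:
    """Euclidean norm of the frame-to-frame translation difference, per step."""
    if trace.n_frames < 2:
        raise ValueError("need at least 2 frames for relative displacement")
    diffs = np.diff(trace.translations_mm, axis=0)
    return np.linalg.norm(diffs, axis=1)


def mean_relative_displacement(trace: MotionTrace) -> float:
    """Mean framewise translational displacement (mm) over the scan."""
    return float(relative_displacements(trace).mean())


def mean_axis_displacement(trace: MotionTrace) -> np.ndarray:
    """Per-axis variant: mean |Δ| of each translation axis separately (mm)."""
    if trace.n_frames < 2:
        raise ValueError("need at least 2 frames for relative displacement")
    return np.abs(np.diff(trace.translations_mm, axis=0)).mean(axis=0)


def group_motion_summary(traces: list[MotionTrace]) -> dict:
    """Across-subject summary of per-subject mean relative displacements."""
    if not traces:
        raise ValueError("need at least one motion trace")
    per_subject = [mean_relative_displacement(t) for t in traces]
    return {
        "per_subject": per_subject,
        "mean_mm": float(np.mean(per_subject)),
        "max_mm": float(np.max(per_subject)),
    }
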