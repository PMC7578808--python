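"""Frame-grid arithmetic and plasma-sample handling for constant-infusion FDG.

A constant-infusion acquisition runs the tracer pump for the whole scan, so
plasma radioactivity rises throughout and the tissue signal is a cumulative
uptake curve. Everything downstream needs a common clock: frames are binned at
a fixed duration from infusion onset (which coincides with PET start), and
blood samples drawn during the scan are decay-corrected back to that onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: F-18 physical half-life in seconds (109.77 min).
HALF_LIFE_F18_S = 6586.2


@dataclass(frozen=True)
class FrameGrid:
    """Uniform frame binning of a dynamic scan.

    Frames are 0-indexed half-open intervals ``[i*dt, (i+1)*dt)`` measured
    from infusion onset; a partial trailing frame is discarded.
    """

    frame_duration_s: float
    scan_duration_s: float
    analysis_onset_s: float = 0.0
    n_frames: int = field(init=False)

    def __post_init__(self) -> None:
        if self.frame_duration_s <= 0 or self.scan_duration_s <= 0:
            raise ValueError("durations must be positive")
        if self.frame_duration_s > self.scan_duration_s:
            raise ValueError("frame longer than scan")
        if not (0 <= self.analysis_onset_s < self.scan_duration_s):
            raise ValueError("analysis onset outside scan")
        object.__setattr__(
            self, "n_frames", int(self.scan_duration_s // self.frame_duration_s)
        )

    @property
    def frame_start_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_duration_s

    @property
    def frame_mid_s(self) -> np.ndarray:
        return self.frame_start_s + self.frame_duration_s / 2.0

    def frame_index_at(self, t_s: float) -> int:
        """Index of the frame whose half-open interval contains ``t_s``."""
        if not (0 <= t_s < self.n_frames * self.frame_duration_s):
            raise ValueError(f"time {t_s} s outside the binned scan")
        return int(t_s // self.frame_duration_s)


def build_frame_grid(
    scan_duration_s: float,
    frame_duration_s: float,
    analysis_onset_s: float = 0.0,
) -> FrameGrid:
    """Bin a scan of ``scan_duration_s`` into complete frames.

    The study default (5700 s at 16 s) yields 356 frames.
    """
    return FrameGrid(
        frame_duration_s=frame_duration_s,
        scan_duration_s=scan_duration_s,
        analysis_onset_s=analysis_onset_s,
    )


def analysis_window(
    grid: FrameGrid, n_blocks: int = 6, block_duration_s: float = 600.0
) -> np.ndarray:
    """Frame indices of the analysis window.

    The window commences at the frame containing ``analysis_onset_s`` (index
    ``floor(onset / frame_duration)``) and spans ``n_blocks *
    block_duration_s`` of frames from that frame's start. With the defaults
    (onset 30 min, six 10-min blocks, 16-s frames) this selects exactly 225
    frames starting at index 112; block boundaries downstream are measured
    from the first retained frame.
    """
    if n_blocks < 1 or block_duration_s <= 0:
        raise ValueError("need at least one block of positive duration")
    start = int(grid.analysis_onset_s // grid.frame_duration_s)
    duration = n_blocks * block_duration_s
    n_window = int(np.ceil(duration / grid.frame_duration_s - 1e-9))
    if start + n_window > grid.n_frames:
        raise ValueError("analysis window exceeds scan duration")
    return np.arange(start, start + n_window)


@dataclass(frozen=True)
class PlasmaSample:
    """One venous blood draw, well-counted and decay-correctable.

    ``activity`` is the decay-corrected plasma concentration referenced back
    to infusion onset, on the arbitrary well-counter counts/min scale.
    """

    draw_time_s: float
    raw_counts: float
    count_duration_s: float
    plasma_volume_ml: float = 1.0
    activity: float = float("nan")

    def decay_corrected(self, half_life_s: float = HALF_LIFE_F18_S) -> float:
        return decay_correct(
            self.raw_counts, self.count_duration_s, self.draw_time_s, half_life_s
        )


@dataclass(frozen=True)
class PlasmaCurve:
    """Second-order polynomial fit ``c0 + c1*t + c2*t**2`` to plasma activity."""

    c0: float
    c1: float
    c2: float
    fit_window_s: tuple[float, float]
    n_samples_used: int

    def __post_init__(self) -> None:
        if self.n_samples_used < 3:
            raise ValueError("a quadratic fit needs at least 3 samples")

    def __call__(self, t_s: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t_s, dtype=float)
        out = self.c0 + self.c1 * t + self.c2 * t * t
        return out if out.ndim else float(out)

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.c0, self.c1, self.c2])


def decay_correct(
    raw_counts: float,
    count_duration_s: float,
    elapsed_s: float,
    half_life_s: float = HALF_LIFE_F18_S,
) -> float:
    """Decay-correct a count rate back to the common reference time.

    Returns ``(raw_counts / count_duration_s) * 2**(elapsed_s / half_life_s)``
    — the count rate the sample would have shown at infusion onset. One
    half-life of elapsed time doubles the rate.
    """
    if half_life_s <= 0:
        raise ValueError("half-life must be positive")
    if count_duration_s <= 0:
        raise ValueError("count duration must be positive")
    if raw_counts < 0 or elapsed_s < 0:
        raise ValueError("counts and elapsed time must be nonnegative")
    return (raw_counts / count_duration_s) * 2.0 ** (elapsed_s / half_life_s)


def fit_plasma_curve(
    samples: list[PlasmaSample], half_life_s: float = HALF_LIFE_F18_S
) -> PlasmaCurve:
    """Least-squares quadratic fit of decay-corrected activity vs draw time.

    Samples carrying a finite ``activity`` are used as-is; otherwise activity
    is derived from the raw counts via :func:`decay_correct`.
    """
    if len(samples) < 3:
        raise ValueError("need at least 3 plasma samples for a quadratic fit")
    t = np.array([s.draw_time_s for s in samples], dtype=float)
    if len(np.unique(t)) < 3:
        raise ValueError("need at least 3 distinct draw times")
    y = np.array(
        [
            s.activity
            if np.isfinite(s.activity)
            else s.decay_corrected(half_life_s)
            for s in samples
        ],
        dtype=float,
    )
    # Fit on scaled time (t/t_max) to keep the Vandermonde well conditioned,
    # then map the coefficients back to the seconds scale.
    scale = max(float(np.abs(t).max()), 1.0)
    design = np.vander(t / scale, 3, increasing=True)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    coef = coef / scale ** np.arange(3)
    return PlasmaCurve(
        c0=float(coef[0]),
        c1=float(coef[1]),
        c2=float(coef[2]),
        fit_window_s=(float(t.min()), float(t.max())),
        n_samples_used=len(samples),
    )


def group_average_curve(
    curves: list[PlasmaCurve], grid_s: np.ndarray
) -> np.ndarray:
    """Pointwise mean of fitted plasma polynomials on a common time grid."""
    if not curves:
        raise ValueError("need at least one fitted curve")
    grid = np.asarray(grid_s, dtype=float)
    return np.mean([c(grid) for c in curves], axis=0)
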