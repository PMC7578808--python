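"""Plasma-curve fitting with decay correction, and motion QC.

Blood samples drawn every 10 min are decay-corrected back to infusion onset
(F-18 half-life 109.77 min) and fit with a 2nd-order polynomial; the group
average curve is evaluated on a common grid. Motion is summarised as the
mean framewise translational displacement per subject.
"""

import numpy as np

from fpetconn import (
    AcquisitionSpec,
    fit_plasma_curve,
    group_average_curve,
    group_motion_summary,
    simulate_motion,
    simulate_plasma_input,
)

acq = AcquisitionSpec()

curves = []
for seed in range(3):
    samples = simulate_plasma_input(acq, seed=seed)
    print(f"subject {seed + 1}: {len(samples)} draws, "
          f"last at {samples[-1].draw_time_s / 60:.0f} min, "
          f"decay-corrected peak {max(s.activity for s in samples):.1f}")
    curves.append(fit_plasma_curve(samples))

grid = np.arange(600.0, 5401.0, 600.0)
avg = group_average_curve(curves, grid)
print("group-average plasma curve (activity, a.u.):")
print("  t(min):", " ".join(f"{t / 60:5.0f}" for t in grid))
print("  value :", " ".join(f"{v:5.1f}" for v in avg))
print("The curve rises concavely toward its peak near 90 min, the expected")
print("constant-infusion behaviour.")

traces = [simulate_motion(acq, seed=s) for s in range(5)]
summary = group_motion_summary(traces)
print("\nmotion QC over 5 subjects (225 frames each):")
print("  per-subject mean relative displacement (mm):",
      " ".join(f"{v:.3f}" for v in summary["per_subject"]))
print(f"  group mean {summary['mean_mm']:.3f} mm, max {summary['max_mm']:.3f} mm")
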