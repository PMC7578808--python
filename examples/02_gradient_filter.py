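"""Build the spatio-temporal gradient kernel and verify its defining algebra.

The kernel estimates the short-term change in glucose uptake from the
cumulative signal: negative Gaussian weights on past frames, zero on the
current frame, positive on future frames, times a 3D spatial Gaussian.
"""

import numpy as np

from fpetconn import DynamicImage, apply_gradient_filter, build_gradient_kernel

k = build_gradient_kernel(sigma_spatial_vox=1.0, sigma_temporal_frames=2.0)
offsets = np.arange(-k.half, k.half + 1)

print("kernel extent:", k.weights.shape)
print("temporal profile (spatial centre):",
      np.round(k.weights[3, 3, 3, :], 5))
print("sum of all weights (zero response to constants):", f"{k.weights.sum():.2e}")
print("ramp response (unit slope -> 1):",
      f"{np.sum(k.weights * offsets[None, None, None, :]):.12f}")

# a cumulative signal rising 0.7 activity-units per frame maps to 0.7
ramp = np.broadcast_to(0.7 * np.arange(20.0), (10, 10, 10, 20)).copy()
out = apply_gradient_filter(DynamicImage(ramp), k)
print("filter output on a 0.7/frame ramp:",
      f"{out.data.mean():.6f} (uptake change per frame)")
print("output frames:", out.n_frames, "(3 trimmed at each temporal end)")
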