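"""Stability of the connectome across the six 10-minute blocks.

With constant-infusion FDG the signal-to-noise rises as plasma activity
approaches its peak near 90 min, so connectivity structure becomes clearer
in the late blocks. Here a network appears only in blocks 5-6 and the
block-wise similarity to the full-window connectome shows it.
"""

import numpy as np

from fpetconn import RoiTimeseries, assign_blocks, block_stability

lab = np.repeat([0, 1, 2, 3], 3)
c = np.where(lab[:, None] == lab[None, :], 0.6, 0.1).astype(float)
np.fill_diagonal(c, 1.0)
root = np.linalg.cholesky(c)
rng = np.random.default_rng(4)
noise = rng.standard_normal((12, 225))
signal = root @ rng.standard_normal((12, 225))
onset = np.zeros(225)
onset[150:] = 1.0  # structure only in blocks 5 and 6

ts = RoiTimeseries(noise * (1 - onset) + signal * onset, list(range(12)),
                   frame_duration_s=16.0, start_time_s=1792.0)
idx = assign_blocks(ts)
print("frames per block:", [int((idx == b).sum()) for b in range(6)])

_, sims = block_stability(ts)
for b, s in enumerate(sims, start=1):
    bar = "#" * max(0, int(40 * s))
    print(f"block {b}: similarity to full-window connectome {s:+.3f} {bar}")
print("Late blocks carry the planted structure, so they resemble the")
print("full-window connectome far more than the early, noise-only blocks.")
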