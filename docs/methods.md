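# Methods

This note records the models, conventions and numerical choices behind
`fpetconn`, in the spirit of a package methods appendix: what is assumed,
what is tunable, and what the synthetic tests do and do not demonstrate.

## Acquisition model and frame arithmetic

A constant-infusion scan of duration `T` (default 5700 s) is binned into
complete frames of duration `Δ` (default 16 s); a partial trailing frame is
discarded, so `n_frames = ⌊T/Δ⌋` (356 for the defaults). Frames are 0-indexed
half-open intervals `[iΔ, (i+1)Δ)` on a clock starting at infusion onset,
which coincides with PET start.

The analysis window covers `n_blocks` × `block_duration` (default 6 × 600 s)
commencing at the 30-min point. Because 1800 s is not a multiple of 16 s,
a convention is required: **the window commences at the frame containing the
onset** (index `⌊1800/16⌋ = 112`) and spans the window duration of frames
from that frame's start. This retains exactly 225 frames, and block
boundaries are measured from the first retained frame's start, which makes
the midpoint block assignment deterministic: 225 frames partition into
blocks of 37/38/37/38/37/38.

## Plasma model, decay correction and curve fitting

Blood draws (default every 600 s, configurable; proportionally scaled for
shortened test scans) are decay-corrected back to infusion onset:

```
activity = (raw_counts / count_duration) · 2^(elapsed / T½),   T½ = 6586.2 s
```

The F-18 half-life (109.77 min) is a physical constant exposed as
`timing.HALF_LIFE_F18_S`. Activity units are the arbitrary well-counter
counts/min scale; no cross-calibration is modelled. Curves are fit to
**decay-corrected** concentrations (recorded in provenance; fitting raw
concentrations is the other defensible choice) with a least-squares
quadratic. The fit uses a scaled time variable `t/t_max` internally to keep
the Vandermonde system well conditioned, then maps coefficients back to the
seconds scale; on exactly quadratic data the coefficients are recovered to
~1e-11 absolute.

The synthetic plasma input is the concave quadratic
`p(t) = peak · (2u − u²)`, `u = t/t_peak` (default peak at 5400 s = 90 min),
strictly increasing to its peak — the same polynomial family the analysis
fits, and the canonical constant-infusion shape. Measurement noise is
multiplicative (default CV 3%); raw counts are back-computed so the decay
correction chain is exercised end to end.

## Synthetic uptake model

Regional instantaneous uptake rates over the analysis window are

```
rate_i(t) = b(t) + σ · e_i(t),
b(t)      = r₀ · [(1 − c) + c · p(t)/p_peak]
```

with `r₀ = baseline_rate = 6` (activity/s), `σ = signal_sd = 1`,
`c = plasma_coupling = 0.15`, and `e` zero-mean unit-variance Gaussian noise
with population correlation given by the planted community structure
(within-community ρ = 0.5, between ρ = 0.1, four equal-ish communities of 82
ROIs by default), realized through the symmetric eigendecomposition square
root of the correlation matrix. Rates are floored at zero; with the defaults
the floor sits ≈ 5.7 SD below the mean, so clipping is negligible and the
sample correlations converge to the planted matrix (bias < 0.01).

The coupling constant deserves a note. A baseline fully proportional to the
rising plasma curve would add a *shared* temporal trend whose variance over
the 60-min window rivals the fluctuation variance, inflating every pairwise
Pearson correlation by ≈ v/(v + σ²) and destroying the planted-correlation
contract of the generator. Physiologically, tissue at this stage of a
constant infusion is near steady uptake; the generator therefore treats the
baseline as mostly flat with a small plasma-coupled modulation (c = 0.15).
The residual shared trend still inflates absolute correlations slightly —
visible in the worked example — while the within/between *gap* is preserved.

Cumulative uptake is the running sum of rates scaled by the frame duration
(`diff(cumulative)/Δ` recovers the rates exactly). Volumes are rendered by
painting each region's cumulative TAC onto a synthetic parcellation (82
contiguous rectangular blocks tiling a 40³ default grid; leftover lattice
boxes remain background), blurring each frame with a Gaussian point-spread
(default FWHM 5 mm at 2.09 × 2.09 × 2.03 mm voxels) and adding white noise
(default SD 20 activity units ≈ 20% of the per-frame uptake increment).
Background carries noise only. BOLD volumes use the same planted network
sampled at TR 2.45 s with 1% fluctuation amplitude around a mean of 100.

What the generator does **not** emulate: anatomy (the parcellation is a
rectangular tiling, not an atlas), scanner physics (attenuation, scatter,
randoms, reconstruction artefacts), physiological confounds (cardiac and
respiratory cycles, global signal fluctuations), motion-induced intensity
artefacts (motion traces are generated but the rendered volumes are not
resampled through them), and temporally autocorrelated noise. Passing tests
therefore demonstrate correctness of the *computations* under the assumed
signal model, not robustness to every property of real data.

## The gradient filter

Weights: `w(x,y,z,t) = G₃(x,y,z; σ_s) · sgn(t) · G₁(t; σ_t)` over integer
offsets in `[−3, 3]⁴` (window extent 7), with σ_s = 1 voxel and σ_t = 2
frames by default. The spatial lobes are renormalized to unit sum after
truncation. The temporal profile is antisymmetric with a zero central tap,
and the whole kernel is scaled so that a unit-slope temporal ramp yields
exactly 1 — making the output interpretable as uptake change per frame and
forcing zero response to constants. σ_s is specified in voxels; anisotropic
voxel sizes are ignored by the kernel (the study's voxels are near-isotropic).

The filter is applied as a sliding **correlation** (positive offsets address
later frames), implemented as three 1D spatial passes and one temporal pass
— identical to the full 4D correlation by separability, and verified against
a four-deep loop oracle to 1e-10 in the tests.

Edge policies:

- `valid` (default): trim `(w−1)/2 = 3` frames per temporal end and 3 voxels
  per spatial face (225 → 219 frames); no edge bias, and the parcellation is
  cropped to match (`Parcellation.crop`).
- `renormalized`: full-grid output. Near boundaries the visible spatial
  lobes are rescaled to unit sum (normalized convolution); for the temporal
  lobe, rescaling alone cannot preserve the ramp response because the
  visible odd lobe acquires a nonzero sum, so the zero-sum correction is
  placed on the current-frame tap before rescaling by the visible ramp
  response. This keeps constants → 0 and ramps → slope at every frame, at
  the cost of a nonzero current-frame weight at the edges.

Whether the original pipeline filtered before or after ROI averaging is
implemented as filter-first (moco → filter → parcellate), the order that
lets the spatial lobe act on voxel data.

## Connectivity estimation

ROI series are voxel **means** per label. Metabolic and haemodynamic
connectivity use Pearson correlation across frames; matrices are symmetric
with zero diagonal by convention. Group aggregation applies the Fisher z
transform entrywise, averages, and back-transforms (recorded in provenance;
plain averaging is the comparable variant). Static PET is the frame sum;
metabolic covariance demeans each subject's ROI vector (removing global
dose/uptake level) before correlating ROI columns across subjects — hence
its invariance to per-subject additive offsets, and an induced −1/(n_roi−1)
offset under the null that is negligible at 82 ROIs.

Empty ROIs after masking or cropping are dropped with a warning rather than
propagated as NaN; zero-variance series are rejected naming the ROI.

fMRI high-pass filtering projects out a discrete-cosine drift basis
(frequencies below 0.01 Hz at TR 2.45 s, plus the constant) by least
squares — the standard resting-state drift model. Output rows have zero
mean; a 0.1-Hz sinusoid passes with < 5% amplitude loss.

Block stability assigns frames to the block containing their midpoint,
computes a per-block connectome, and reports its similarity to the
full-window connectome as the Pearson correlation of strict upper-triangle
entries — the same similarity statistic used by the filter-width sweep.

## Problem sizes and defaults

The synthetic defaults mirror the study acquisition (5700 s, 16-s frames,
30-min onset, six 10-min blocks, 82 ROIs, 5-mm PSF, plasma peak at 90 min)
on a 40³ rendering grid — large enough for the 7×7×7×7 kernel and the
82-region tiling to coexist with an interior, small enough that the
10-subject recovery analysis completes in about a minute. Full-size grids
are available through `AcquisitionSpec.grid_shape`. Monte-Carlo checks use
200 seeds (correlation-bias bounds of ±0.02 correspond to ≈ 3 standard
errors at 225 frames × 200 seeds).

## Known limitations

- The synthetic parcellation is a rectangular tiling; adjacency-driven blur
  leakage between anatomically meaningful neighbours is not represented.
- Motion traces feed QC only; rendered images are motion-free.
- No compartmental kinetic modelling (Patlak slopes etc.); the uptake model
  is phenomenological.
- The renormalized edge policy preserves first-order (constant + ramp)
  response at edges but not the full interior transfer function.
- Correlation inflation from the shared infusion trend is intrinsic to the
  constant-infusion design; the package reports raw Pearson correlations and
  leaves trend-removal strategies to the user.
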