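# Methods

## Model

The unit of analysis is one stimulus frame.  All maps live on the stimulus
pixel grid (w × h, image orientation: x rightward, y downward; pixel (i, j)
has center (j + 0.5, i + 0.5) in continuous coordinates) and are flattened
to vectors in row-major order, so one pixel is one regression observation.

**Response.**  The eye-position density map Y of a group is the bivariate
kernel density estimate of the group's pooled fixation coordinates on that
frame, f̂(x; H) = N⁻¹ Σᵢ K_H(x − Xᵢ) with the scaled Gaussian kernel
K_H(x) = (2π)⁻¹|H|^(−1/2) exp(−½ xᵀH⁻¹x), evaluated at pixel centers and
renormalized to sum 1 over the grid (see *Numerical choices*).

**Predictors.**  Feature maps, each normalized to a discrete density:

| map | construction | default parameters |
|---|---|---|
| uniform | constant 1/(w·h) | — |
| center bias | Gaussian, diagonal covariance, at the stimulus center | σₓ = w/12, σ_y = h/12 (pixels) |
| static saliency | Gabor bank on mean-subtracted luminance, channel-max normalized, summed | 4 orientations × 2 frequencies (0.10, 0.20 cycles/px) |
| dynamic saliency | blur(σ=2 px) → abs frame difference → blur(σ=3 px) | undefined on frame 0 |
| AoI | boundary-inclusive point-in-polygon rasterization at pixel centers | — |
| external | any per-frame grid loaded from CSV (clipped at 0, normalized) | — |

The built-in saliency operators are deliberately simple, deterministic
stand-ins for full video-saliency models (which are exchangeable in this
framework); outputs of any such model can be substituted through the
external-map loader and enter the regression identically.

**Estimation.**  Per frame, weights minimize ‖Y − Σ βₖMₖ‖² + λ Σ|βₖ| along
a descending λ path (100 log-spaced values from the all-zero KKT threshold
2·max|XᵀY| down to 10⁻⁴ of it, plus the λ = 0 least-squares endpoint).  The
reported fit minimizes BIC = −2 log L + K log n with Gaussian likelihood
(variance RSS/n) and K = number of nonzero weights, ties broken toward the
sparser (larger-λ) solution.  Adjusted R² uses K as the parameter count.

**Multi-group extension.**  For two groups the response stacks the
treatment and control density maps (treatment block first, n = w·h rows
each); a 0/1 group dummy is interacted with every feature column, giving
K main-effect plus K interaction columns.  On the control block the model
reduces to the main effects; on the treatment block each effective weight is
βₖ + β_{k,G}.  At λ = 0 this reproduces both separate single-group
least-squares fits exactly (verified to 1e−8 in the tests); with more than
two groups, G − 1 dummies generalize the construction with the last group in
the stacking order as reference.

**Standardization.**  Maps and response are centered and scaled to unit
SD *within each group block* (population SD); interaction columns are built
from the standardized main columns.  Per-group standardization prevents a
group with an overall stronger density peak from masquerading as a feature
effect.  The scaling record maps standardized weights back to the raw scale
(raw βₖ = std βₖ · sd(Y)/sd(Mₖ) per block), and both scales are reported.

**The uniform map.**  After centering, a constant column is identically
zero, so in standardized fits the uniform map is absorbed by the (zero)
intercept of the centered model and reported with weight 0 — consistent with
its role as the catch-all that should carry no weight when the other
features explain the fixations.  Raw-scale fits retain it; its raw weight is
the implied intercept divided by the constant map value.

**Inference.**  Group differences are tested by permuting participant-level
group labels (sizes preserved, within-participant data untouched — the
participant is the exchangeable unit), re-running the full pipeline per
permutation, and recording the interaction weights.  Two-sided p-values use
the standard +1 smoothing: p = (1 + #{|β*| ≥ |β̂|})/(P + 1).  Permutations
are drawn with replacement (standard Monte Carlo practice); a single seed
controls the whole test.  No multiple-testing correction across frames or
features is applied — p-values are raw, as reported.

## Bandwidth selection

H is selected per frame and per group by minimizing
LSCV(H) = ∫f̂² − (2/N) Σᵢ f̂₋ᵢ(Xᵢ), with the exact leave-one-out estimator in
the second term.  The ∫f̂² term is a Riemann sum over the pixel grid extended
by three marginal standard deviations beyond the stimulus box (pixel area 1),
so boundary mass is not lost; for diagonal H it is computed through a
separable Gram-matrix identity that is algebraically equal to the per-pixel
sum (verified to 1e−10 against a naive double loop).

The search family is diagonal H: a log-spaced grid of 15 candidates per axis
spanning [0.25, 4] × the plug-in pilot bandwidth (σ̂ · N^(−1/6) per axis),
refined by Nelder–Mead in log-σ space.  Full unconstrained LSCV is
ill-conditioned at the few dozen points available per frame and group.  The
procedure is deterministic.  Cells with fewer than two usable points are
skipped by default (an explicit skip record, not a silent absence); a
fixed-bandwidth mode both serves as fallback and reproduces the older
fixed-kernel approach.

Because the KDE smooths, the response is the *smoothed* mixture: recovered
AoI weights are attenuated relative to the generating weights and the lost
mass surfaces in the intercept-derived uniform weight.  Weight *rankings*
among the penalized features are preserved, which is what the recovery
battery checks.

## Synthetic data generator

The generator emulates a letterboxed dynamic-stimulus experiment: a bright
square (dynamic AoI) moving linearly toward a static dark target (static
AoI) over a seeded textured background; fixations drawn per participant and
frame from Σₖ wₖ(t)·Mₖ(t) with smoothly time-varying weights; tracker
samples at 60 Hz against a 25 Hz stimulus (2.4 samples/frame, so the
alignment rule selects samples 1, 4, 6, 9, 11, 13, …); (0,0) dropout
(default 5%), black-bar samples (2%), and ragged per-participant record
counts (up to 12 extra trailing samples).  The default grid is 90 × 72 — 1/8
scale of a PAL stimulus, with the monitor geometry scaled accordingly — so
the full pipeline runs in seconds.  A group difference is injected by
shifting weight δ onto one feature in the treatment group, the other
features shrinking proportionally.

What the generator does *not* emulate: saccade dynamics, smooth pursuit,
scanpath autocorrelation (fixations are i.i.d. across frames given the
weight curves — matching the frame-marginal model under test), oculomotor
noise, and calibration drift.  Passing recovery tests therefore demonstrate
correctness of the estimation machinery, not robustness to violations of
frame-marginal sampling in real data.

## Data cleaning rules

Fixed order: (1) truncate every participant's stream to the minimum
per-participant count (trailing samples only — the time points of lost
samples are unknown); (2) drop (0,0) samples (tracking loss) and samples
outside the video area [side_bar, mon_w − side_bar) × [0, mon_h) (half-open);
(3) per frame and participant select the first sample whose tracker interval
[(s−1)/tracker, s/tracker) lies entirely within the frame interval
[(f−1)/refresh, f/refresh) — computed in exact rational arithmetic; (4) map
monitor to stimulus coordinates by x_stim = (x_mon − side_bar)/scale,
y_stim = y_mon/scale with scale = mon_h/stim_h.  The letterbox rule (full
monitor height, width proportional, centered) fixes all derived constants;
for a 720×576 stimulus on a 1920×1080 monitor the video area is 1350×1080
and each side bar is (1920 − 1350)/2 = 285 px.  Missing (participant, frame)
cells are tolerated downstream.

## Numerical choices

- Normalization tolerance for all density maps: 1e−9; weights with
  |β| ≤ 1e−10 count as exact zeros (least-squares returns O(1e−16) noise on
  truly-zero coefficients).
- KDE renormalization: no boundary correction is applied to the estimate
  itself; mass falling off-grid is handled by renormalizing the map to sum 1,
  a deliberate deviation needed for the regression's density interpretation.
- Positive-λ solutions come from coordinate descent (penalty mapped as
  α = λ/(2n)); λ = 0 from a least-squares solve.  BIC guards RSS = 0 by
  clamping the variance at 1e−300.
- Degenerate inputs raise typed errors naming the map and frame: all-zero
  maps, identical frames for the dynamic map (policy-switchable to a uniform
  fallback with a logged warning), AoIs covering no pixel center, gaze
  points degenerate along an axis (with guidance to the fixed-bandwidth
  fallback).
- Boundary pixels count as inside AoI polygons (closed polygons,
  `shapely.covers`); pixel-center evaluation throughout; the center-bias
  Gaussian is evaluated at pixel centers and normalized over the grid
  (no truncation correction).
- First stimulus frame: the dynamic map is undefined there, so the frame is
  skipped by default (`first_frame="reduce"` keeps it with the dynamic map
  dropped).

## Simulation conditions of the verification batteries

- **Recovery**: 30 frames, 90×72 grid, 1000 fixations/frame; bandwidth
  search 9×9 candidates without refinement (the refinement changes selected
  bandwidths by a few percent and no ranking); pass criterion: mean
  per-frame Spearman correlation ≥ 0.9 between generating and recovered
  weights over the penalized features.
- **Power**: δ = 0.3 on the static AoI, 500 fixations/group/frame, 45×36
  grid, P = 19 permutations (the minimum resolving p ≤ 0.05), 25
  replicates; detection = p ≤ 0.05 for the target interaction.
- **Null calibration**: 100 replicate null experiments, 30×24 grid, 16
  participants/group, P = 199.  The battery fits the λ = 0 endpoint so the
  null statistic is continuous (the BIC-selected statistic produces exact
  zeros, making the permutation test strictly conservative — valid but with
  a discrete p-value atom at 1), and uses pooled-bandwidth reuse: one LSCV
  bandwidth per frame selected from the label-pooled points, applied to the
  observed fit and every permutation alike.  Pooling keeps the statistic
  label-invariant, so permutation exactness is preserved — reusing
  *observed per-group* bandwidths would not be label-symmetric.

## Known limitations

- Residuals ignore spatial dependence between pixels; BIC's n is the raw
  pixel count.  Absolute fit statistics should be read comparatively, not
  as calibrated likelihood quantities.
- The KDE attenuation bias above means raw-scale weights under-estimate
  sharp-feature (AoI) weights; between-group *differences* of a feature are
  affected symmetrically and the permutation test is unaffected under the
  null.
- Only raw p-values are reported; with ten frames and several features,
  analysts should apply their own multiplicity control.
- Confidence intervals for the weights are out of scope; uncertainty is
  addressed through the permutation test only.
- The built-in saliency operators are not substitutes for a tuned video
  saliency model on real footage; use the external-map loader for that.
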