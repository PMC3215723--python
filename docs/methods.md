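# Methods

`rtattn` re-implements, end to end and at desk scale, a real-time decoding
pipeline for covert visuospatial attention: a subject attends left, right or
center while fixating centrally; lateralized BOLD changes in visual cortex
are located with an incremental GLM during a localizer period, and a scalar
control signal derived from two regions of interest then drives per-scan
classification and feedback.  A companion classifier decodes the same
three-way task from high-gamma ECoG band power.  Because no raw recordings
are distributed with the original study, every stage runs on synthetic data
with planted ground truth; this note states the models, the defaults and
what they do and do not establish.

## Experimental design constants

One continuous run at TR = 1.62 s: a localizer of 25 trials x 8 scans
(8 per condition plus one initial center trial; 200 scans, 13.0 s per
trial) followed by a feedback phase of 30 trials x 10 scans (10 per
condition; 300 scans, 16.2 s per trial).  Trial order is pseudo-random under
the constraint that no two adjacent attention trials share a direction; the
scheduler is rejection sampling over seeded shuffles (any
constraint-satisfying sampler is acceptable — the constraint, not the
sampler, is what matters), and the constraint is also enforced across the
localizer/feedback junction since the run is continuous.  All constants live
in `RunConfig` and are configurable.

## Synthetic BOLD model

Each voxel follows

    y(t) = B · (1 + drift(t) + a · x_c(t) + sigma · eps(t))

with baseline B = 1000 inside an ellipsoidal "head" (2% of that outside),
`x_c` the unit-peak HRF-convolved boxcar of the condition driving the voxel,
`a` the planted effect (default +2% in the contralateral activation blobs,
−1% in small ipsilateral posterior-pole blobs responding to opposite-side
attention), and white Gaussian noise with sigma = 1.5% of baseline
(temporal SNR ≈ 67, typical of high-field EPI, where a 2% effect is
single-trial detectable).  Drift is linear (0.3%/min) plus a slow cosine
(0.1%, 300 s period), with a per-voxel slope jitter so the per-voxel
detrender has a spatially varying target.  The HRF is a double-gamma with a
5 s peak and 15 s undershoot (1:6 amplitude); the 5 s peak is consistent
with the pipeline's 3-TR (4.86 s) delay compensation.  Optional per-scan
rigid motion can be injected through the same resampler the corrector uses.

What the phantom does *not* emulate: physiological (cardiac/respiratory)
noise, spatial autocorrelation of noise, susceptibility dropout, partial
voluming, and between-subject variability of map topography.  Passing tests
therefore demonstrate correctness of the algorithms under the stated
statistical model, not expected performance on human data.

## Motion correction

Each volume is aligned to the first by minimizing the mean squared intensity
difference after Gaussian blurring (sigma = 1 voxel).  Parameters are three
Euler angles about the grid axes (rotation center = grid center; the
original work fixes neither convention) and three voxel translations, in a
pull-back convention: `resampled(v) = image(R(v−c) + c + t)`.  The default
optimizer is stochastic gradient descent — 50 iterations, a fresh random
subsample of 2000 interior voxels per iteration, normalized steps decaying
as 1/(1 + k/10) in a preconditioned space where rotations are scaled by the
mean lever arm; a deterministic full-gradient mode with backtracking line
search exists for reproducible tests.  Numerical choices that matter: the
SSD is evaluated on interior voxels only (2-voxel margin) with
nearest-neighbour extension beyond the field of view, because a constant
fill makes the objective discontinuous exactly at integer alignments;
linear interpolation is used during optimization and cubic B-spline for the
final resample.  If no parameter set improves on the identity the identity
is returned with a warning.  Round-trip accuracy on smooth phantoms is
within 0.1 voxel for sub-voxel translations and 0.2 degrees for small
rotations (deterministic mode).

## Incremental GLM

The mass-univariate model has four regressors per scan: HRF-convolved right-
and left-attention boxcars, a centered linear drift term, and an intercept.
(The original lists three regressors with the mean term implicit and does
not state whether convolution was applied; both toggles are exposed, and an
explicit intercept is required for valid t statistics.)  Streaming updates
accumulate the sufficient statistics X'X, X'y and y'y — algebraically exact,
constant cost per scan — rather than an orthogonalization recursion; a
full-data reference (`batch_fit`, stacked `lstsq` with explicit residuals)
serves as the independent oracle, and the two agree to |Δt| < 1e-8 with ROI
Dice ≈ 1.0 on every seeded run.  t-maps use the differential contrasts
right−left and left−right.  Degenerate voxels are kept orderable: a zero
contrast gives t = 0 and a zero-residual voxel gives a sign-preserving
capped t (1e6), because downstream top-K selection needs a total ranking.

## ROI selection and baselines

The brain mask is the smoothed mean volume thresholded at 30% of its 98th
percentile (no number is stated in the original; this tracks the head
reliably across phantom intensities), hole-filled, with the two most
anterior coronal slices removed.  Per contrast, the 500 highest t-values
inside the mask are taken (ties broken by ascending linear voxel index) and
face-adjacent (6-connectivity) clusters smaller than 5 voxels are removed.
Baselines average the raw motion-corrected signal over ROI voxels and
center-condition scans, excluding the first 3 scans (4.86 s) of center
trials that follow an attention trial; an initial center trial keeps all
scans.  Whether the original computed baselines on detrended signal is not
stated; raw is the default (a detrended option exists) and the feedback-time
detrending makes the difference small by construction.

## Feedback decoding

At each feedback scan the full available series of every ROI voxel
(localizer + feedback so far) is re-detrended with a smoothness-priors
filter: trend = (I + λ²·D₂'D₂)⁻¹ z, D₂ the second-difference operator,
λ = 500 by default (the original's value is not recoverable; at TR 1.62 s
this λ passes the 13–16 s task frequencies nearly untouched while removing
scanner drift).  The affine component of z lies exactly in the penalty's
null space and is split off before the banded solve, so constants and ramps
detrend to zero identically; one step of iterative refinement handles the
stiffness of the system at large λ.  A sliding-window mode bounds per-scan
cost but is not the reference path.

The control signal is the differential percent change

    CS = 100 (S_R − B_R)/B_R − 100 (S_L − B_L)/B_L

with an optional variant dividing each term by its localizer-derived
standard deviation (more laterally symmetric when the two ROIs respond with
unequal strength).  CS is classified against three positive and three
negative thresholds — beyond the second level is "strong", between first
and second "weak", inside the first pair "off" — and colored green when the
state matches the instruction (near-baseline counts as correct during
center), red otherwise.

Thresholds are either the fixed ladder ±1.5/±2.5/±4 (percent units) or
estimated adaptively from the retrospective localizer CS: with instruction
labels shifted 3 TRs, θ₁ is the smallest observed CS value whose training
false-positive rate over non-right scans is ≤ 0.2, mirrored for the left
side.  The empirical FPR is a step function with steps only at observed
values, so this search over observed values (plus +∞) is exact — a
brute-force sweep oracle confirms it.  Higher rungs scale from θ₁ by the
fixed-scheme ratios 2.5/1.5 and 4/1.5.  Two degeneracies are handled
explicitly: an adaptive θ on a biased CS can cross zero (observed in
practice), so only strict ordering — not sign — is enforced; and near-1
targets can invert the pair, in which case the negative side is clamped to
the positive one.  The same detrender is applied to the localizer CS as to
the feedback CS, for internal consistency.

## Scoring

Per-scan TPR/FPR are computed after shifting instruction labels 3 TRs later
than the CS (scans whose shifted label precedes the run are dropped from
numerator and denominator alike).  The FPR is reported both with and
without center scans in the denominator: the BOLD undershoot after an
attention block rebounds CS across baseline, a hemodynamic artifact that an
electrophysiological implementation would not show.  ROC curves sweep
thresholds from −1 to 5 (right) and 1 to −5 (left).  Trials are also
classified three-way from a single within-trial time point (right if
CS > θ₁, left if CS < θ₋₁, center otherwise; with θ₁ ≥ θ₋₁ both side rules
cannot fire at once), unshifted, which makes the HRF lag directly visible
as low accuracy at early time points.  The Wolpaw information transfer rate
is log₂N + P·log₂P + (1−P)·log₂((1−P)/(N−1)) bits per decision (P∈{0,1} by
continuity), scaled to bits/min; ROI overlap uses the Dice coefficient,
defined as 1.0 when both sets are empty.

## ECoG classifier

Features are high-gamma (65–95 Hz) band power per channel over the first
4 s of each trial at 512 Hz, after common-average referencing; the spectral
estimate is Welch's method with 1 s Hann segments at 50% overlap (the
original names only the band and window).  Evaluation is leave-one-out over
79 trials (20 left / 20 right / 39 center): per fold, all trials are
normalized with the training trials' mean and SD (the held-out trial never
enters these statistics — a leakage check re-derives them from training
rows only); per direction, a channel is selected if its training mean is
beyond both other class means by more than a margin and its magnitude
exceeds half the channel's SD ("SD over all three directions" is read as
the pooled SD of all training values; the SD-of-class-means reading is an
option).  A channel can carry a positive sign for one direction and a
negative one for another.  The margin is chosen per fold by nested
optimization — 50 candidates from 0 to the 95th percentile of observed
between-class mean gaps, scored by training-set accuracy, ties to the
smallest margin — and the held-out trial goes to the direction whose set
has the highest sign-adjusted mean ("average magnitude" is read
sign-adjusted to preserve deactivation information; an absolute-value mode
is a flag).  Ties follow the fixed precedence center > right > left; if all
sets are empty the training-majority class is predicted.  Selection is
monotone in the margin by construction.  The synthetic feature sets place
unit-variance Gaussian features with ±1 mean shifts on a few known channels
per class; raw-waveform synthesis is out of scope (band power is the
feature the method consumes).

A note on the permutation null: leave-one-out predictions within one
permutation share training sets, so pooled correct counts are overdispersed
relative to a binomial; the null check therefore treats per-permutation
accuracies as the i.i.d. unit and compares their mean to the
independence-agreement level computed from the prediction marginals.

## Problem sizes and determinism

Default desk-scale grids are 32×32×16 (the full 96×96×35 acquisition matrix
is supported by configuration); equivalence and recovery suites use 20–50
seeded replicates and the ECoG null 100 permutations.  Every random draw
flows through an explicit seed argument, stage outputs are byte-identical
across repeat invocations of a fixed configuration, and each pipeline stage
logs its config hash and seed to `provenance.json`.

## Known limitations

- The noise model is white; autocorrelated noise would widen t-statistics
  (the original uses no prewhitening either).
- The stochastic registration mode trades accuracy for speed and is not
  used where sub-voxel guarantees are asserted.
- Published per-subject performance tables were measured on undeposited
  human recordings; this package reproduces the pipeline and its internal
  consistency properties, not those numbers.
- No anatomically restricted ROIs, nonrigid registration, slice-timing
  correction, or group-level mapping.
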