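# Methods

This note documents the models, the synthetic-data conventions, the
numerical choices and the known limitations of the package. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Stimulus model

A Glass pattern is a field of dot dipoles in a square aperture
(default 7.7°). The spiral angle of a dipole is the angle between its
orientation and the radius from its centre to the aperture centre: 0° gives
a radial pattern, 90° a concentric one; anticlockwise handedness negates the
angle. Signal level is the percentage of dipoles oriented by this rule
(`round(n · signal/100)` exactly); the rest draw orientations uniformly on
[0°, 180°). Dipole count follows from dot density: `n = round(density ·
aperture_area / (2 · dot_area))` — 605 dipoles (1210 dots) at the default
3% density, 2.3′ dots. The Glass shift (dipole dot separation) defaults to
16.2′ and is exposed as a parameter because the training protocol uses 25′
and testing/scanning 30′; the generator takes whatever the design asks for.

Jitter: a per-trial condition jitter (±1.5°, uniform) and a per-exemplar
jitter (±5°, uniform) are each drawn once per generated pattern and added
to the template angle, so all signal dipoles of one exemplar share one
jittered template. Dipole centres are drawn uniformly with rejection so
both dots fall inside the aperture; overlap between dots is allowed (at 3%
density it is rare, and no exclusion zone is specified by the protocol).
A consequence of edge rejection worth knowing: near the aperture border the
accepted orientation distribution of noise dipoles is slightly anisotropic
(an edge-parallel dipole fits where a perpendicular one does not); interior
dipoles are exactly uniform, and the uniformity test in the suite checks
those.

## Psychometric model

Proportion-correct data are fit with
`P(s) = γ + (1−γ) Φ((s−μ)/σ)`, γ fixed at 0.5 (a signed-axis
proportion-concentric mode with γ = 0 is provided), lapse rate fixed at 0.
Estimation maximizes the binomial log-likelihood with an analytic gradient,
L-BFGS-B from a 3×4 grid of starts (μ at the level quartiles, σ
log-spaced); ties break by likelihood then smaller σ. Bounds express the
*plausible range* given the sampling grid: μ within the level range ±2
spans; σ between half the minimum level spacing (narrower transitions are
unresolvable by the grid) and 3× the span.

Derived quantities: threshold at criterion p is
`μ + σ Φ⁻¹((p−γ)/(1−γ))` (78% by convention); slope is the derivative of
the percent-correct curve at μ, `100(1−γ)/(σ√(2π))`, which puts group
values on a 2–3 scale; the slope index is post minus pre. The printed group
summaries used to parameterize the built-in observers (young pre/post
71.2/40.6% threshold, 2.1/3.2 slope; older 81.1/43.6%, 1.8/3.0) are
inverted through exactly these formulas, so generator and estimator share
one convention.

Goodness of fit is the significance of the Pearson correlation between
observed and fitted per-level proportions; non-significant fits are flagged
and excluded from slope indices rather than raised. Confidence intervals
are percentile bootstrap (default 2000 iterations) resampling trials within
level, refitting from the point estimate.

**Estimator behaviour at session scale.** With 240 trials over a 5%-step
grid, a steep curve (σ ≈ 6% signal) puts only ~3 levels on the transition.
The ML spread estimate is then noisy (CV ≈ 30%) and occasionally collapses
toward a step, and because the slope is convex in σ, the *mean* recovered
slope across sessions overshoots the generating slope even though the
median is close and the recovered threshold is essentially unbiased. The
bootstrap slope interval is mildly anti-conservative in that regime for the
same reason; at ~60 trials/level coverage is near nominal (the suite pins
both regimes). Threshold estimates do not share this pathology — they are
nearly linear in the data.

## Designs

Scanner runs are history-balanced one trial back: each ordered pair of
conditions (including repeats) occurs equally often as a transition. The
sequence is a randomized Eulerian circuit (Hierholzer with shuffled edge
lists) over the complete transition digraph with self-loops, plus one
initial trial that balances the second trial's history: `n·r + 1` trials
for `n` conditions × `r` repetitions (129 for 8 conditions × 16, 97 for 6
× 16). When `n ∤ r`, extra transitions are laid out as disjoint circulant
permutation layers so ordered-pair counts differ by at most one (flagged in
the run metadata); a coprime shift guarantees connectivity when there is no
uniform layer.

Behavioral sessions: pre-test 240 trials (15 levels × 16, 8 radial + 8
concentric each); post-test 240 trials over 16 levels (15/level, odd counts
category-balanced by alternating 8/7 splits so the session is exactly
120/120); training runs 256 trials over 15 levels (middle level 18, others
17, alternating 9/8 splits; per-level counts are recorded in the log since
256 does not divide by 15). Stimulus duration (300 ms) is metadata.
Control-task letter streams show one letter per 500 ms slot for 80 ms; one
target letter per run, 15% target probability per slot, non-targets uniform
over the remaining alphabet.

## Synthetic data

The behavioral generator is the exact inverse of the psychometric model.
The pattern generator produces trial-wise voxel patterns
`c · κ · (s/100) · w + stimulus_response + noise`, with `c = ±1` the
category, `w` a unit-norm weight vector on an informative voxel subset
whose signs alternate (so the category code carries no univariate offset —
the mean-signal contrast is null by construction while decoding succeeds),
κ a session gain with κ_post ≥ κ_pre under learning, and iid Gaussian
noise. Every stimulus trial additionally evokes a category-independent
response (default 0.5 noise-sd in all voxels), which is what
stimulus-vs-fixation voxel selection detects; fixation trials are pure
noise. The linear-in-s ramp is the default (discriminability grows
monotonically with signal); a saturating `Φ((s−μ)/σ)` ramp is available.
Default gains (κ_pre 1, κ_post 2, noise sd 1) were chosen so decoding
curves span roughly 50–100% accuracy over the scanned signal levels —
a synthetic convention, not an empirical claim.

Volume mode writes NIfTI-1 runs at 2.5 × 2.5 × 4 mm, TR 1.5 s: baseline
100, HRF-convolved stimulus boxcars in all gray-matter voxels, category
contrast confined to spherical informative blobs with sign-balanced
weights, iid Gaussian noise (temporal autocorrelation deliberately
omitted: decoding operates on trial-averaged patterns). The HRF is a
double-gamma parameterized so the positive lobe's mode sits exactly at
`peak_delay_s` (default 6 s) with a 1/6-amplitude undershoot at 16 s.
Calibration runs: 10-s breath-hold blocks whose per-voxel amplitude is 2%
× a vascular-reactivity factor (1.0 young, 0.5 older by default), and a
reversing-checkerboard run with known peak latency and amplitude; the
generator also emits a task %BOLD map scaled by the same reactivity, since
reactivity multiplies all evoked BOLD — that shared scaling is exactly what
normalization divides out.

What the generators do *not* emulate: physiological and motion artifacts,
temporal autocorrelation (optional AR structure is off by default),
between-subject anatomical variability, and nonstationary learning within
a session. Tests passing on these data show the estimators and their
contracts are correct, not that real fMRI effect sizes are attainable.

## Decoding chain

Patterns: per-voxel z-scoring within run (flat voxels are a hard error),
a 3-volume (4.5 s) shift for hemodynamic delay, then the mean of each
trial's 2 volumes. Voxel selection: two-sample t-test of stimulus vs
fixation trials computed on the training folds only, p < 0.05 uncorrected,
ranked by t, up to 100 voxels; if nothing passes, the top-N by t are used
with a warning. Classification: linear SVM with fixed C = 1 (no
hyperparameter search), leave-one-run-out; training pools all signal levels
(`all_levels`) or only 100%-signal trials (`train_100_only`). Accuracy is
pooled over folds per signal level; per-category accuracies are retained.
Motion-flagged trials (upstream >1 mm / >1° rule; the synthetic generator
sets the flag) never enter training or testing.

Searchlight: a 9-mm-radius sphere on the voxel grid (98-voxel apertures on
a full grid at the default voxel size — a diagnostic, not a contract),
leave-one-run-out decoding per aperture with no top-N selection, and a
per-voxel map value equal to the mean over all apertures containing the
voxel (order-independent by construction). Group maps: one-sided one-sample
t-test vs 0.5 per voxel at α = 0.05, then a cluster-extent threshold with
6-connectivity. The extent threshold is *estimated* by sign-flip
permutation of the subject maps about chance (all 2^S flips when feasible,
else 500 random ones), taking the smallest extent whose family-wise null
rate is ≤ α. A fixed integer `cluster_min` is accepted for the classical
behaviour, but a fixed 2-voxel extent does not control the family-wise rate
on searchlight maps — aperture averaging correlates neighbours, so null
t-maps produce contiguous supra-threshold voxels far more often than
independent-voxel intuition suggests; the permutation default restores the
intended ~5% null survival rate.

fMR-metric functions reuse the behavioral fitting path verbatim on
per-level (correct, total) classifier counts with γ = 0.5. Group curves
average per-subject accuracies, but slope indices are computed per subject
before averaging. The permutation control shuffles pattern–label
correspondence within run (preserving run structure and label counts),
re-runs the full decode and refits; the fraction of significant fits is
reported against the nominal α.

## Calibration controls

Percent signal change is referenced to the mean of the two pre-stimulus
time points per trial and trial-averaged. Breath-hold normalization fits a
per-voxel GLM (10-s boxcar convolved with the double-gamma HRF) to the
hypercapnia run, keeps voxels with a significant positive response
(p < 0.05 uncorrected, selected fraction reported), and divides task %BOLD
by breath-hold %BOLD with a guard excluding near-zero denominators. The
operation is scale-equivariant: common multiplicative factors (vascular
reactivity) cancel. HR characterization takes peak amplitude and latency
from the trial-averaged response; fSNR is the mean task-evoked % signal
change across ROI voxels.

## Numerical conventions and degenerate inputs

Orientations are degrees mod 180 (dipoles are unoriented). A dipole exactly
at the aperture centre is rejected (radial direction undefined). All-correct
or all-wrong psychometric data are fit but flagged as boundary cases; flat
accuracy curves yield non-significant fits, not exceptions. Decoding folds
whose training set lacks a category are skipped and logged; an all-skipped
decode is an error. SVM tie-breaking follows the underlying library's
deterministic rule. Every randomized operation takes an explicit seed; there
is no hidden global RNG state, and identical seeds are bit-reproducible.

## Problem sizes

The test suite uses reduced replicate counts (e.g. 300 simulated sessions
for recovery checks, 10–30 replicates for null and ordering checks, small
voxel grids for searchlight) chosen so the whole suite runs in a few
minutes; `scripts/acceptance.py` uses 2000 sessions per group, 100 label
permutations and 100 letter-stream runs.

## Known limitations

* The mean-of-ML-slopes statistic at single-session trial counts is biased
  upward for steep curves (see the estimator note above); threshold-based
  comparisons are the robust alternative at that scale.
* The searchlight is exhaustive rather than optimized (no incremental
  aperture updates); whole-brain grids at full resolution are outside the
  intended desk scale.
* Eye-movement analysis, scanner preprocessing (slice timing, motion
  correction, anatomical normalization) and retinotopic mapping are out of
  scope; inputs are assumed preprocessed and aligned.
* Group repeated-measures ANOVAs are left to standard statistical routines
  on the exported tidy CSVs.
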