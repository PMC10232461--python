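# Methods

This note documents the models, default parameters, numerical choices and
known limitations of `taskspike`. All empirical statements below are the
ones the test suite itself computes.

## Behavioral model

A session is a sequence of self-paced trials. Holding time is
1 s + Exp(mean 0.8 s) truncated at 2 s, so completed holds span 1–3 s —
the spread the Hold/Go intersection-slope analysis needs. Trials are
immature (holding period abandoned before 1 s; default rate 0.05) or
completed; completed trials are errors (wrong pedal; default rate 0.10) or
correct, and correct trials are rewarded after a delay drawn uniformly
from {0.3, 0.4, 0.5, 0.6, 0.7} s. The block side alternates when the
animal has more than 30 rewards in the block and ≥ 80% correct over the
last 10 completed trials, or unconditionally at 100 rewards; the
performance clause can be disabled to force fixed-length blocks.

Pedal traces are synthesized at 1 kHz (configurable): both pedals rest at
70%, descend into the holding area over 200 ms ending at hold onset, sit
at 10% with 0.4% Gaussian wobble while holding, and rise back over a
smoothstep of 80 ms starting at the release onset (the unreleased pedal,
and both pedals on immature trials, rise 300 ms later). The 80 ms rise
exercises the two-stage release detector: task progression is the first
30% crossing; the release onset for neural analysis is the first sample
exceeding a 5% excursion above the within-trial holding baseline (median
position before the 30% crossing), scanning backward from that crossing.
An absolute-5% mode is available; which reading of the 5% criterion is
intended is ambiguous in the source description, so both are implemented
and the excursion-relative one is the default.

## Spike model

Spike trains are inhomogeneous Poisson: a constant baseline plus
archetype kernels, all nonnegative by construction.

- **Hold**: linear ramp at fixed rise rate `effect × baseline / 1.5 s`
  from hold onset to release. Because the rise rate (not the peak) is
  fixed, the time at which the rate crosses any fixed level shifts
  one-for-one with holding time, so the planted intersection slope is −1.
- **Go**: Gaussian bump (σ = 50 ms) at release onset plus a per-neuron
  offset; cohorts split Go-type neurons 50/50 between a preparatory
  (−225 ms) and a feedback (+62 ms) offset, mirroring the pre- and
  post-movement subpopulations the latency clustering should find.
- **Reward**: Gaussian bump (σ = 60 ms) centered 300 ms after reward
  delivery on correct trials only — inside the reward-aligned [0, 1] s
  analysis window and outside the release-aligned ±500 ms window, so the
  archetypes do not leak across alignments.
- Combined archetypes sum kernels; `none` is baseline only. Kernels on the
  non-preferred side are scaled by `side_bias` (default 0.3).

Defaults for task neurons are baseline 4 Hz and kernel peak 6× baseline
(~28 Hz peaks, the tens-of-Hz scale typical of task-related PETHs).
Recovery-cohort sessions target 320 trials — a multi-hour self-paced
session — giving ~150 completed trials per side and ~35 trials per
holding-time range; the intersection-slope estimator needs this many
trials per range for a stable 75%-criterion crossing.

Stimulation epochs implement collision physics. A projection neuron
responds to a control stimulus with an antidromic spike at its conduction
latency (Gaussian jitter, sd 0.03 ms) unless a spontaneous spike occurred
within one conduction round-trip (2 × latency) before the stimulus; test
stimuli are triggered 2 ms after a spontaneous spike and therefore always
collide. Non-projection neurons never produce antidromic spikes.
Window-trough amplitudes come from two Gaussians — spike present:
N(−60, 5); absent: N(−5, 3) arbitrary filtered units — for ROC
thresholding. Frequency-following pairs are simulated with reliability
0.95 at 100 Hz and 0.7 at 200 Hz; the pass levels (≥ 0.8 and ≥ 0.5) are
package choices, as only the existence of the test is specified upstream.

## Analysis choices

**Task relevance.** One-sample KS against the uniform CDF on the window,
rather than a two-sample comparison with a single random uniform draw:
this removes test-side Monte-Carlo noise and is asymptotically equivalent;
the two-sample variant is available (`two_sample=True`). Zero pooled
spikes return p = 1. Preferred side is the smaller release-aligned
p-value, ties broken toward contra (arbitrary but fixed). Contra/ipsi is
derived from a per-session `recorded_hemisphere` metadata field, never
inferred.

**Hold/Go slope.** The four holding-time ranges are count-balanced
quantile groups of the preferred-side holding times. The criterion level
is 75% of the peak of the all-trials PETH (20 ms bins). Range PETHs are
lightly smoothed (σ = 40 ms) before the backward scan from the range peak
to the interpolated criterion crossing; a range whose PETH never reaches
the criterion is omitted, and fewer than two valid ranges yields
`indeterminate`. The regression is intersection time (s, relative to
release) on mean holding time (s), so a slope of −1 means the onset shifts
one second earlier per second of extra holding. The signed slope is
compared with −0.5 (boundary → Hold); an absolute-value mode exists. The
Hold component additionally requires the fit (not only the smoothed-peak
sign): release-significant neurons without a Hold-class fit — including
post-movement peaks — are Go-type.

**Indices.** The peak bin is located on the preferred-side unsmoothed
20 ms PETH and the same absolute peak period is reused on the
non-preferred side. Neurons with both normalized activities ≤ 0 have an
undefined laterality index and are excluded from laterality summaries
(the piecewise definition does not cover that case). Reward modulation on
unrewarded trials uses a surrogate alignment of release + 500 ms (the mean
reward delay), because error trials have no reward event; this is a
package choice.

**GLM.** Gaussian-identity least squares on the σ = 150 ms smoothed rate,
sampled on a 20 ms grid restricted to within-trial spans (hold onset to
next hold onset); partial F-tests implement the add/remove deviance tests
(p = 0.05 / 0.10), and term significance for classification uses a
Bonferroni factor of 3 (three candidates). Smoothed-rate samples are
serially correlated; p-values are reported uncorrected, as in the source
procedure, and a `decimate` option subsamples the grid when approximate
independence is wanted. Constant (rank-deficient) predictors are dropped
and flagged.

**GMM/BIC.** The 1D EM is vectorized across repeats so the full
1000-repeat × k = 1..5 protocol is cheap; BIC = −2 ln L + (3k − 1) ln n
(free means, variances, weights). Each repeat is initialized by a short
k-means pass (10 Lloyd iterations from random distinct data points) — the
initialization standard EM implementations default to. Pure
random-responsibility initialization was tried and rejected: it parks EM
at the symmetric saddle where all components coincide, or in degenerate
single-point components, and both failure modes corrupt the mean-BIC
profile. Stopping is |Δ ln L| < 10⁻³ with a 100-iteration cap and a
variance floor of 10⁻⁴ ms² (floored repeats are counted and reported).
The reported fit at the chosen k is the single best-likelihood repeat.
The x-means cross-check is implemented in-package as BIC-driven 2-means
splitting on scikit-learn KMeans. The 2D bootstrap-flow GMM uses
scikit-learn's `GaussianMixture` with full covariances; k is chosen by the
minimum mean BIC over repeated random initializations (default 20). Order
labels follow the signs of (CA1−LECs, CA1−LECd) and their difference;
exact-zero ties break toward the earlier-listed region in the order CA1,
LECs, LECd.

With small samples (a few dozen latencies) the mean-BIC rule can still
prefer k = 4–5 because narrow components on a handful of points inflate
the likelihood; selection is reliable from n ≈ 200, the regime the
consistency checks use.

**Collision test.** Without ground-truth labels the trough threshold comes
from a 2-means split: pseudo-labels feed a Youden-J ROC cut. The split is
flagged low-confidence (and the pre-screen fails) when the 2-means centers
are separated by less than 2.5× the summed within-cluster spreads — the
unimodal signature. The composed decision requires: ≥ 10 supra-threshold
control responses with a confident threshold, control spike probability
strictly above 0.5, test probability below half the control, Pearson χ²
(no Yates correction by default) p < 0.05, jitter (IQR of trough times)
below 0.5 ms, and the frequency-following levels when paired-pulse events
exist.

## Pipeline

Per-stage seeds fan out from the global seed via `SeedSequence`, so a
fixed configuration yields byte-identical report tables. The default
cohort is 36 task neurons (6 per archetype across CA1/LECs/LECd) plus 8
stimulation-tested LEC neurons (4 projecting) over a 120-trial session;
the report includes per-region type fractions, index summaries, GLM
classes, GMM selections, flow order-label frequencies, collision
decisions, and confusion matrices against ground truth. Cohort-level
tests (signed-rank on indices, Kruskal–Wallis plus Holm-corrected pairwise
rank tests on latencies) are included for report completeness; the
pairwise procedure is a documented stand-in for a joint-ranking multiple
comparison. Failure of one neuron's analysis is logged and skipped.

## What the synthetic data does and does not show

The generator reproduces the *structure* real sessions impose on the
analysis — event timing and windows, holding-time spread, side preference,
reward contingency, collision physics, waveform bimodality — with known
labels, so passing tests demonstrate that each estimator recovers what was
planted under realistic rates and trial counts. It does not emulate
bursting or refractoriness, rate drift, spike-sorting contamination,
correlated noise across neurons, learning within a session, or LFP;
population fractions measured on recorded animals are therefore not
reproduction targets, and agreement rates reported here bound estimator
error, not biological variability.

## Known limitations

- The intersection-slope estimator degrades below ~20 trials per
  holding-time range; with the default 120-trial session it still
  classifies but with wider slope scatter (the recovery conditions use
  320-trial sessions).
- GLM p-values ignore serial correlation of the smoothed response (see
  above); between-candidate collinearity (left and right pedals move
  together during holds) means the selected pedal side is not meaningful,
  only the Pedal/Time distinction.
- Mixture-order selection on very small latency samples overfits (noted
  above); the report records the full mean-BIC curve so this is visible.
- Session containers are directories of TSVs with a checksum manifest; no
  NWB or vendor formats.
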