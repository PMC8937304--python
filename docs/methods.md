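# Methods

## Signal model and conventions

A trial is an ROI × frame matrix at 30 frames/s: 400 frames with the
final-valve (stimulus) onset at frame 200, so there are 200 baseline frames
(~6.7 s) before and ~6.7 s after onset.  Frames are 0-based; times are
seconds relative to onset; analysis windows `(start_s, end_s)` are half-open
in frames, `[onset + round(start·rate), onset + round(end·rate))`.  ΔF/F is
computed per ROI against the mean fluorescence of the 2 s preceding onset;
a non-positive baseline raises an error naming the ROI.  Response
amplitudes are window means of ΔF/F; the default response window is the
first post-onset second (exactly 30 frames).  Time-resolved analyses slide
a 30-frame window in 0.25-s steps and label each point by the window
centre; centre labelling keeps sub-second latencies expressible while every
window still has the same length.

## Synthetic sessions

The generator starts at ROI time series (no pixel-level synthesis, no sniff
waveforms) and emulates the statistical structure the analyses assume:

* **Odour panel.** 11 odours; each non-target tuning vector is built in
  standardised space as `ρ·z_target + √(1−ρ²)·z_⊥` with the residual
  empirically orthogonalised, so the realised Pearson correlation with the
  target tuning equals the requested overlap exactly.  Default overlaps
  grade from 0.9 (the masker, MB) down to 0.  Tuning amplitudes are
  Gaussian with mean 2.5 and SD 2.0 ΔF/F for somatic fields; glomerular
  fields use a sparser 0.5 ± 1.5 so that a distinct target-responsive set
  exists.  These scales are order-of-magnitude choices — per-ROI amplitude
  distributions for this preparation are not published — set so that
  two-component sums reach the bend of the saturation curve (≈ 1/s = 5
  ΔF/F) under the high-gain preset.
* **Trials.** Sessions are blocks of 10 trials; every block contains the
  target, the masker, and their mixture, plus one target+other mixture,
  four other singles and two non-target mixtures, shuffled within the
  block.  Mixtures have exactly two components.
* **Transients.** Difference of exponentials (0.1-s rise, state-dependent
  decay) starting after a state-dependent onset lag, scaled so the mean
  over the first post-onset second equals the target amplitude.  The
  waveform shape is a modelling choice; only window means enter the
  analyses.
* **Noise.** Per-trial, per-ROI Gaussian amplitude noise (`trial_noise_sd`)
  plus small per-frame imaging noise (0.02 ΔF/F); an optional per-trial
  shared gain jitter is off by default.
* **Summation.** Single-odour amplitudes are `gain × tuning`.  Mixture
  amplitudes are either the linear sum of the component tunings or that sum
  passed through the saturating sigmoid (below), times the gain.  Under the
  saturating rule, each ROI's deviation from the linear sum is additionally
  scaled by a frozen per-ROI factor `1 + h`, `h ~ N(0, 0.5)`
  (`summation_heterogeneity`): real populations show a broad spread of
  mixture interactions around the typical suppression (interquartile range
  of fractional deviations ≈ 0.3–0.4, with a small supralinear tail), and
  without this diversity the deviation distribution collapses to a
  ~0.1-wide spike whose median is artificially sensitive to added noise.
* **State presets.** `anaesthetised`: gain 1.0, trial SD 0.2 ΔF/F,
  saturating summation, slow sustained transients (τ = 6 s), full pattern
  overlap.  `behaving`: gain 0.4, trial SD 2.0 ΔF/F, linear summation,
  faster decay, overlap spectrum halved (decorrelated patterns).
  `naive_engaged` / `naive_disengaged` interpolate.  The two SDs are the
  stated baseline noise levels of the simulation (0.2 anaesthetised,
  2 awake); gains express that awake early-phase responses are dampened.
* **Determinism.** All randomness flows through explicit integer seeds
  (`numpy` `default_rng` / `SeedSequence.spawn`); identical inputs give
  bit-identical sessions.

Behavioural trials: per trial a background odour cycles through the panel,
the reward flag is Bernoulli (1/3 rewarded), and a per-class probability
decides whether the choice is correct.  Hits produce
`max(2, Poisson(rate_rewarded))` anticipatory licks, misses and correct
rejections `min(1, Poisson(rate_unrewarded))`, false alarms
`2 + Poisson(rate_unrewarded)` — so with a zero unrewarded rate and perfect
performance the lick preference index is exactly 1.

## Summation statistics

`linear_sum_pairs` averages the mixture trials (`R_obs`) and sums the
trial-averaged component responses (`R_lin`); the joint SEM is the **sum**
of the component SEMs, taken literally from the printed formula (pooling
variances instead would be slightly smaller).  Fractional deviation
`(R_obs − R_lin)/|R_lin|` excludes ROIs with `|R_lin| < 0.05` ΔF/F
(configurable): the ratio is unstable near zero and the floor is logged in
the summaries.  The joint-SEM deviation classifies ROIs at ±2; with a zero
joint SEM (noise-free data) a numerically-zero numerator counts as exactly
linear.  Per-field medians are pooled as the median of field medians with
25th/75th percentiles.  The noise-robustness analysis adds zero-mean
Gaussian noise to every trial amplitude *before* averaging, 200 Monte-Carlo
repeats per SD, and reports per-repeat medians and IQRs.

The masking index z-scores the trial-averaged target responses **across
glomeruli within a field**, takes glomeruli with z > 2 as the
target-responsive set, and averages the clipped ratio
`clip(R_bg/R_target, 0, 1)` over that set (negative responses clip to 0, so
each glomerulus contributes at most 1).  The ratio definition is an
interpretation of "average overlap"; the alternative
`min(R_bg, R_target)/R_target` is available behind the `overlap="min"`
switch and coincides with it for non-negative responses.

## Similarity and decoding

Population similarity is the Pearson correlation between trial vectors
(one amplitude per ROI); zero-variance vectors are excluded with a log
entry.  Class means run over off-diagonal pairs counted once.  The
discriminability index compares, per S+ trial, its mean correlation to the
other S+ trials against its mean correlation to all S− trials; ties count
as non-discriminated (strict inequality), and the per-trial granularity
(means of correlations, not correlation of means) is deliberate.

Decoders are linear SVMs with the intercept constrained to 0 and an L2
penalty of fixed strength C = 1 (a one-decade sweep is covered by a test);
no kernels, no hyperparameter search.  Accuracy is **balanced** (mean of
per-class correct rates) because session compositions are class-imbalanced
(~30% S+); chance is then 0.5 regardless of composition.  Random 80/20
partitions are drawn once and reused across time points by default, so time
courses reflect coding dynamics rather than split noise; single-class
partitions are redrawn (logged, capped at 20).  Cross-generalization trains
on a random 80% of the single-odour trials (target vs other singles) and
tests on all mixtures.  The number of splits defaults to 50 (unstated in
the motivating analyses).  Significance onsets use a one-sample, one-sided
t-test of field-level mean accuracies against 0.5 per time point, with no
multiple-comparison correction (deliberately matching the original
procedure).  The rank-sum comparison reports the tie-corrected
normal-approximation z of the Wilcoxon rank-sum statistic.

Held-out decoding of information-free (pre-onset or label-shuffled)
features is slightly pessimistic at small trial counts — the held-out
trials anti-correlate with the training class means — so decoder-sanity
analyses use 120-trial sessions, where the effect is within ±0.05.

## Normalising-sublinearity simulation

The saturating transform is `R* = Rmax(2/(1+e^{−sR}) − 1)`: odd, strictly
increasing, bounded by ±Rmax, slope `Rmax·s/2` at 0.  Reference parameters
(Rmax = 6 ΔF/F, s = 0.2 /ΔF/F) correspond to fits to observed mixture
responses of behaving animals at 2 s after onset; `fit_normalisation`
recovers them from ≥10 (linear sum, observed) pairs by unweighted least
squares (pooled across ROIs) and flags the fit as unidentifiable when the
data carry no curvature (relative parameter SE ≥ 1).  Trial noise is
modelled as SD = `sigma0 + slope·|amplitude|`, with `sigma0` supplied by
the state preset (0.2 / 2) and the slope from an OLS regression of per-ROI
across-trial SDs on mean amplitudes (clipped at 0).  The in-silico
experiment trains a decoder per time window on single-odour responses,
builds every pairwise sum of trial-averaged single-odour responses, adds
fresh per-repetition Gaussian noise (drawn before the sigmoid; 20
repetitions by default), optionally applies the sigmoid with the same
parameters at every time point, and reports balanced accuracy.  The
accuracy ratio (sublinear / linear) is summarised over the early (0–1.5 s]
and late (1.5–3 s] phases; sublinear vs linear phase means are compared by
a paired t-test across fields within a state, and ratios between states by
a Welch test (the two state groups have different field counts, so a
cross-state pairing does not exist).

Why the contrast works: with the intercept fixed at 0 a uniform rescaling
of all amplitudes cannot change any decision, so the sigmoid hurts only
through *differential* compression — ROIs whose summed response sits past
the bend are flattened relative to the rest, rotating the population
pattern away from the decoder's weight vector.  High-gain correlated
populations place many sums past the bend and their informative (target
minus masker) component is small, so the rotation flips borderline
mixtures; dampened populations live in the near-linear part of the curve
and are essentially unaffected.

## Behavioural metrics

Anticipatory licks are counted in the 3 s after the final-valve onset with
the threshold at 2: a rewarded trial is correct with ≥2 licks, an
unrewarded one with ≤1.  Learning curves are proportions of correct trials
in consecutive non-overlapping 50-trial blocks (trailing partial block
reported separately); "trials to criterion" is the end index of the first
block at ≥80% (the convention is unstated in the source procedure; the
block-end index is used).  The lick preference index per background is
`(L_rew − L_unrew)/(L_rew + L_unrew)` of the mean anticipatory-lick counts,
in [−1, 1], undefined when both means are 0.

## Problem sizes and what the tests show

The test suite and the acceptance script run entirely on synthetic data at
study-like sizes: 8 fields × 13 ROIs (high-gain state) and 13 × 16
(dampened state) for the pooled summation medians, a 150-ROI field with 8
core-trial repeats for the noise-robustness analysis, 120-trial sessions
for decoder sanity, 8 fields per state × 11 time windows × 20 noise
repetitions for the sublinearity experiment, and 200 pairs for parameter
recovery.  Passing these shows that the estimators recover the generating
rules (summation sign and parameters, overlap ordering, chance levels,
directional state contrast) under the generator's assumptions — Gaussian
tuning and noise, a single global sigmoid with lognormal-free per-ROI
scaling of suppression, exact trial alignment.  It does not show anything
about features the generator lacks: sniff-locked dynamics, slow drift,
correlated (shared) noise across ROIs, non-Gaussian amplitude
distributions, adaptation across the session, or motion artefacts.

## Known limitations

* The deposited-data checks (two-column linear-sum/observed tables) have a
  loader and tests on synthetic stand-ins, but the deposited tables
  themselves must be downloaded separately; the corresponding acceptance
  test fails in their absence rather than silently skipping.
* The masking index needs sparse (glomerular-like) patterns to rank
  background odours by tuning overlap; on dense somatic-like tuning the
  target-responsive set is tiny and the index saturates.
* Cross-generalization accuracy is structurally below within-design
  accuracy here: with a zero-intercept decoder, target+masker mixtures sit
  near the single-odour boundary (`w·(target+x) ≈ margin⁺ − margin⁻`).
* The joint-SEM "sum of SEMs" convention and the clipped-ratio overlap are
  literal readings of the printed formulas; both have alternatives noted
  above.
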