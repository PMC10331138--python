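# Methods

## Study design emulated by the generator

A 14-day EMA protocol: six signal-contingent prompts per day at fixed
anchors 09:00, 11:30, 14:00, 16:30, 19:00, 21:30 (exactly 150 min apart),
each jittered uniformly by ±15 min and answerable for 60 min; 84 prompts
per participant in total. One item per prompt — momentary food craving on a
0–100 visual-analog scale — is the dependent variable. Passive streams run
for the whole period: acceleration-change summaries every 5 min, audio dB
and light (mean, min, max) triplets every 15 min, notification events, and
screen on/off intervals.

Compliance is Bernoulli per prompt with a per-person answer probability
drawn from Beta(6.40, 1.28), giving a mean of 70 answered prompts per
person with an across-person SD of ≈11. The answer delay is uniform on
[0, 60] min — the protocol fixes only the window, not the delay law.

## Generative craving model

For person *i* at answered prompt *t* the latent predictor is

    z_it = σ_p·u_i + σ_s·S_it + σ_d·D_it + σ_n·ε_it

with u_i ~ N(0,1) a person intercept, S a standardized weighted sensor
signal (below), D a standardized evening-peaking diurnal rhythm, and ε an
AR(1) process across successive prompts (coefficient φ = 0.5, stationary
variance 1). Default variance shares are person 0.30, sensor 0.385,
diurnal 0.07, noise 0.245 (total 1). The rating is

    craving = clip(c0 + c1·expm1(b·z)/b, 0, 100)

with (c0, c1, b) = (10.5059, 45.7479, −0.15371). These constants were
frozen by least squares on latents simulated from the generator itself
(the latents do not depend on the transform, so common random numbers make
the fit exact), targeting the observed descriptives of the emulated study:
pooled mean 21.9, pooled SD 26.7, mean per-person (bias-corrected)
skewness 1.28. Verified over 30 replicate cohorts of 56, all three land
within 3 Monte-Carlo SEs of their targets. The transform produces the
characteristic zero-inflation of craving scales (≈40% exact zeros) and a
per-person skewness range spanning negative to strongly positive values,
driven by the person intercept.

**Sensor signal.** The true drivers are per-prompt aggregates over the full
lagged span [T0−150, T0−30): mean acceleration change, mean audio dB, mean
lux, notification count, and total screen-on seconds — computed with the
same windowing code the feature pipeline uses, on the *full* pre-dropout
streams, so downstream models see a noisy, partially missing view of the
truth. Each driver is standardized within person and residualized against
a diurnal sin/cos basis before being weighted (default weights SCREEN 1.0,
AUDIO 0.6, ACC 0.5, LIGHT 0.3, NOTIF 0.2, per-person log-normal jitter
SD 0.25). Without residualization the diurnal factor common to all five
streams accumulates in the weighted sum and the per-group weights are
unrecoverable in principle; with it, driver cross-correlations are ≈0 and
the stored per-person truth (weights, latents, sensor scores) supports
recovery testing. Craving keeps its own, separate diurnal component.

**Null mode** zeroes the sensor weights and reallocates the sensor variance
share to the AR(1) noise, preserving the latent variance (and hence
approximately the marginal calibration — exactly guaranteed only for the
default signal preset, since component shapes differ slightly). Null and
signal cohorts generated from the same seed share every stream and
compliance draw and differ only in ratings: exact counterfactuals.

**Missingness.** Sensor dropout is block-wise, not record-wise: alternating
keep/drop runs with geometric lengths (mean drop run 12 records), the keep
run scaled so the expected retained fraction equals the per-person target,
which is drawn from Beta(3.1210, 0.5600) truncated to [0.15, 0.998]. The
Beta mean parameter was solved numerically so the *truncated* mean is
0.848, matching the observed mean availability of 84.8% (SD ≈ 16.6).

**Seeds.** One master seed; per-participant child generators come from
`numpy.random.SeedSequence.spawn`, and every stage draws a
parameter-independent number of variates, so cohorts are bit-reproducible
and effect settings are exactly counterfactual.

## Feature pipeline

Four half-open 30-min windows tile [T0−150, T0−30); data after T0−30 are
never used (30-min prediction horizon). Per window: ACC mean change; AUDIO
mean of dB means, min of minima, max of maxima; LIGHT the analogous lux
triplet; NOTIF event count; SCREEN on-seconds and on-transition count —
plus prompt slot and hour-of-day sine/cosine: 43 columns. T0 is the answer
time by default (the windows are defined relative to when the questionnaire
was answered); prompt-time anchoring is a flag. Empty windows yield NaN for
mean/min/max (imputed later from training rows only) and 0 for counts and
durations. The acceleration-change summary for raw triaxial blocks projects
successive differences onto their first principal axis (re-identified per
5-min block — whether the original on-device PCA was per-block or
continuously updated is not recoverable, so per-block is implemented) and
is rotation-invariant.

## Labeling, splitting, outlier handling

Thresholds are linear-interpolation empirical quantiles of the
participant's own ratings; *high* means strictly above the threshold, so a
zero-inflated majority at the 25% quantile stays low. The greedy day-wise
split selects 4 test days, each step adding the day that minimizes the
absolute difference between the growing test set's high fraction and the
full-data fraction, ties to the earliest day. It can be suboptimal relative
to exhaustive search over all C(14,4) subsets (property-tested bound) but
beats the last-4-days and random splits for the large majority of synthetic
participants. Isolation-forest outlier removal (contamination 0.05, fixed
seed) operates on mean-imputed training feature vectors only — never on
test rows; a craving-univariate mode exists behind a flag. If removal would
empty a class it reverts with a warning.

## Model grids and selection

36 sensor-arm configurations (3 quantiles × outlier on/off × 6 learners)
and 12 baseline configurations (median split only). Learners use library
defaults with fixed seeds, except LogisticRegression `max_iter=1000` and
MLPClassifier `max_iter=500` (the stock limits do not converge on ~50-row
standardized matrices). Each candidate is a Pipeline of training-mean
imputation, standardization, and the classifier, so no test-day statistic
reaches fitting (leakage-tested). The baseline predicts the current
rating's class from the four immediately preceding answered ratings
(crossing day boundaries; unanswered prompts do not break the sequence).

`paper` mode selects the candidate with the highest test-set AUC (ties:
lower Brier, then enumeration order). This reproduces the original
procedure and its optimism: the selected score is an upper bound, which the
null-mode acceptance check demonstrates mechanically (honest ≈ 0.50,
best-of-36 ≈ 0.79 on null data). `honest` mode carves an inner greedy
validation split (3 of the 10 training days, mirroring the 4/14 outer
proportion), selects on validation AUC, refits the single winner on all
training days, and reports its test AUC.

## Evaluation

AUC is computed in rank-sum form (ties 0.5), tested against a brute-force
pair-counting oracle and scikit-learn. Hanley–McNeil 90% intervals use
SE² = [A(1−A) + (n₊−1)(Q1−A²) + (n₋−1)(Q2−A²)]/(n₊n₋), Q1 = A/(2−A),
Q2 = 2A²/(1+A), z = 1.6449; simulated coverage at A ∈ {0.6, 0.75, 0.9} and
10–25 per class is mildly below nominal (≥0.82 asserted), a known property
of the closed form at small n. The Mann–Whitney U reported is the first
sample's (#{x>y} + ½ ties), exact for tie-free n ≤ 8 per group, otherwise
tie-corrected normal. Grouped permutation importance shuffles all columns
of a sensor group jointly (fresh permutation per repetition, 50
repetitions), reporting the mean AUC drop; negative drops are kept as-is.
Cohort "average 90% CI" is the mean of lower and of upper bounds,
labelled as such since the aggregation rule is otherwise undefined.

## What the synthetic cohorts do and do not show

Passing tests demonstrate that the *pipeline* recovers injected
sensor-craving dependence, that its selection procedure is optimistic by
the expected amount under the null, and that its statistics match their
oracles. They do not validate that real smartphone streams carry craving
information; the generator's effect sizes are a modeling choice (sensor
share 0.385 of within-person variance), its streams lack hardware noise
floors, app semantics, and geolocation (excluded by design), and the AR(1)
coefficient (0.5) is uncalibrated because no autocorrelation value is
reported for the emulated study.

A further inherent limit: with ~70 observations, 43 features, and the
sensor signal split across five near-orthogonal groups, per-participant
identification of the *single* top-weighted sensor group from permutation
importance is noisy — an oracle logistic model fit and scored on all rows
recovers it for only ~50% of synthetic participants (top-2: ~85%), and the
faithful pipeline (selected-of-36 model, ~19 test rows) for ~35%. Grouped
importance is therefore most meaningful cohort-averaged, where the
top-weighted group does rank first.

## Problem sizes used in checks

Calibration checks use 30 replicate cohorts of 56 participants; recovery
and null/optimism checks use 20-participant cohorts, which keeps the full
grid (36 + 12 configurations per participant and mode) tractable while the
cohort-level proportions remain interpretable.
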