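# Methods

## Cosinor regression

All rhythm fits are ordinary least squares on the trigonometric regressors
`{1, cos(2πit/24), sin(2πit/24)}` for harmonics `i = 1..N` (period fixed at
24 h; no period estimation). Writing each component as
`β_i cos + γ_i sin`, the derived parameters are `A_i = √(β_i² + γ_i²)` and
`φ_i = atan2(−γ_i, β_i)`. The package fixes one sign convention in a single
place (`circarhythm.cosinor`): acrophases live on the principal branch
`(−π, π]` of `cos(ωt + φ)`, so the curve peaks at clock hour
`−φ·24/2π (mod 24)` and a *later* peak corresponds to a *smaller* (more
negative, modulo wrapping) acrophase. Published cosinor software differs in
this sign; every clock-hour quantity in this package goes through
`acrophase_to_peak_hour`, and correlations reported "in radians" follow
this convention (an age-related phase delay therefore appears as a negative
age–acrophase correlation here).

Fits are closed-form (`numpy.linalg.lstsq`), not iterative; rank-deficient
designs and under-determined sample sizes (`n < 2N + 2`) raise errors
rather than returning unstable coefficients.

**Rhythm detection.** The zero-amplitude test compares the full fit to the
intercept-only model, `F = ((RSS₀ − RSS)/2N) / (RSS/(n − 2N − 1))` on
`F(2N, n − 2N − 1)`. Degenerate inputs are handled explicitly: a constant
series (RSS₀ = 0) returns p = 1 (no variance is no rhythm), while a
numerically perfect rhythmic fit (RSS ≈ 0 with real variance) returns p = 0
and is flagged `degenerate`. Under the null the p value is Uniform(0,1);
the test suite checks the 5% rejection rate and Kolmogorov–Smirnov
uniformity on 2,000 simulated null series.

**Harmonic-count selection** steps from N to N+1 only when the
extra-sum-of-squares F-test (ΔRSS/2 over the larger model's residual mean
square) is significant at α = 0.05, resolving ties toward the smaller
model. Because the step-up test is exactly sized, the probability of
keeping the generating N on single-harmonic data is exactly 1 − α = 95% —
a seeded selection-accuracy estimate over a couple of hundred replicates
therefore fluctuates around 95% by binomial noise, which is the expected
behaviour of a correctly calibrated procedure, not a defect.

**Multi-component summaries.** For N > 1 the reported "amplitude" is half
the peak-to-trough range of the fitted curve on a 1-minute grid and the
"acrophase"/peak hour is its argmax; for N = 1 these reduce to the exact
closed-form parameters.

## Data model and quality filtering

Samples live on a 2-h slot grid (12 slots/day), timestamps are local civil
time with no DST arithmetic (the analysis concerns clock-time rhythms in
free-living conditions), and values carry physical units (HR bpm, RMSSD
ms, HF ms², pNN50 %). Repeated values from the same recording segment
(identical participant/timestamp/slot/metric) are averaged at ingestion;
the same key with distinct timestamps is a validation error.

A day enters the analysis only if it has values in at least 7 of its 12
distinct slot hours, which caps per-day missingness at 5 slots. By default
the rule is evaluated jointly (a slot counts only when every metric in the
table is observed there); a per-metric mode exists because metric-specific
missingness can differ. Missingness accounting is always against the full
grid of included days (`expected = 12 × days`), with rates rounded half-up
to 2 decimals. Note that applying the day rule to a cohort with uniform
random dropout *lowers* the realized missing rate on included days below
the raw dropout rate (the worst days are excluded): at 36.12% uniform
dropout the included-day missing rate is ≈ 30%.

## Synthetic cohorts

The generator emulates the study conditions the analysis is designed for:
30 participants, gestational weeks 14–40, 12 slots/day on 5 recorded days
per week, and 36.12% missing-completely-at-random slot dropout. Per-metric
piecewise-linear trends give the population MESOR, amplitude and peak hour
by week — HR: MESOR 74 bpm (wk 14) → 80 (wk 34) → 74 (wk 40), amplitude
3.5 → 2 (wk 27) → 3 bpm; RMSSD: MESOR 46 ms (wk 14) → 36 (wk 34) → 43
(wk 37) → 39 (wk 40), amplitude 2 → 1 ms. Each participant draws one
MESOR offset (SD 7 bpm HR / 12 ms RMSSD), one amplitude offset (SD 1.5
bpm / 0.8 ms) and one wrapped-normal acrophase offset (SD 7 h HR / 5 h
RMSSD, optionally shifted by an age slope in h/decade); slot values add
iid Gaussian noise (SD 5 bpm / 8 ms, chosen as plausible residual spread
for 12-min-averaged free-living vitals at 2-h spacing). Draws that would
produce non-positive amplitudes, troughs or values are rejected and
resampled rather than clipped, keeping noise symmetric near the mean.
Ground-truth per-participant-week parameters are returned for recovery
tests.

What the generator does **not** emulate: residual autocorrelation from
activity and sleep bouts, device- and behaviour-driven (non-random)
missingness, seasonality/daylight effects, and week-to-week within-person
phase wobble (each participant's phase offset is constant across
gestation). Consequences worth knowing:

- Passing recovery tests show the estimation hierarchy is unbiased and
  correctly calibrated under the stated structure; they do not certify
  behaviour under structured missingness or autocorrelated noise.
- With iid slot noise, a participant's own slot-hour mean is statistically
  close to the optimal imputer, so a 6-lag univariate sequence model
  cannot beat it (the window carries ~σ²/6 estimation variance plus
  unknown-clock-phase variance). On such cohorts the LSTM matches the
  optimal linear 6-lag predictor but trails the slot-mean baseline; its
  advantage materialises exactly when residuals are autocorrelated or the
  level drifts (on noiseless drifting-cosine cohorts it beats slot-mean by
  a wide margin, as the tests verify).
- The amplitude of the population-mean curve is attenuated relative to
  individual amplitudes by `exp(−σ_φ²/2)` for phase dispersion σ_φ
  (verified to within 5% at n = 500): at the default 7 h HR dispersion the
  factor is ≈ 0.19, so aggregate-level rhythm detection is intrinsically
  weak even when every individual is strongly rhythmic. Both quantities
  (population-curve amplitude and mean individual amplitude) are therefore
  computed and labelled distinctly.

## Imputation

The sequence imputer is a numpy LSTM regressor: one 50-unit LSTM layer
over a univariate window of 6 consecutive observed slots, two dense layers
(25-unit ReLU, linear output), MSE loss, Adam (lr 5e-3, gradient-norm clip
5), mini-batches of 5, at most 100 epochs. Inputs are min-max scaled to
[0, 1] with bounds learned from training data only. Early stopping
monitors a validation slice — 10% of training *participants* when there
are enough, otherwise a 10% pair slice — with patience 10 and best-weight
restoration. Train/test splitting is at the participant level
(round-half-up 80%, clamped so both sides are non-empty), eliminating
user-level leakage; separate models are trained per metric. All training
is seeded and bit-reproducible.

At inference, missing slots are filled chronologically and
autoregressively: a slot is imputed when its 6 preceding grid-consecutive
slots are observed or already imputed; observed values are never altered,
imputed values are flagged, and slots with insufficient history remain
missing and are counted in the report. This forward-only rule has a known
cost at high missingness: the expected wait for the first run of 6
consecutive observed slots at ~36% dropout is ≈ 38 slots (renewal
argument), comparable to a 5-day recording block (60 slots), so roughly
half of missing slots never accumulate enough history and remain missing;
the day-inclusion rule bounds how much this matters for the weekly fits,
and deterministic baselines (`slot_mean`, `linear_interp`) are available —
and are the default for fully deterministic pipeline runs (`--no-nn`).

## Population hierarchy and inference

Daily fits default to N = 1 (12 points per day keep a single harmonic
well-posed; per-day selection is available via `components="auto"`, with
coefficient vectors zero-padded to a common basis before averaging).
Averaging daily fits and aggregating participants both happen in linear
coefficient space, never on (A, φ) directly — angle averaging is
ill-defined across the wrap-around, and coefficient averaging is the
standard population-mean construction; by linearity the jackknife identity
(mean of leave-one-out vectors = full-sample vector) holds exactly and is
asserted in the tests.

Two weekly rhythm-detection p values are reported: the default pooled
zero-amplitude F-test on the stacked participant-mean slot series (which
treats between-participant MESOR spread as noise and is therefore
conservative under large inter-individual differences) and a
population-mean Hotelling T² test on the per-participant first-harmonic
(β, γ) vectors. Confidence bands are pointwise
`mean ± t₀.₉₇₅,k₋₁ · SD/√k` across participant curves. Between-participant
SDs use sample SD (n−1) for MESOR and amplitude and the circular SD
`√(−2 ln R)` (converted to hours) for acrophase. Leave-one-out summaries
perform exactly k refits per week and report mean and SD per parameter
(circular statistics for the peak hour).

Early/late comparisons default to participant-level window means (one
value per participant per window, circular mean for acrophase) so the
compared observations are independent; pooled participant-weeks are
available as a mode. Cohen's d uses the pooled-SD (n₁+n₂−2) formula with
the (early − late) sign convention; p values come from Welch's t-test.
Age correlations are Pearson's r on participant-level means across all
weeks, with acrophase treated linearly in radians on the principal branch.
No multiple-testing correction is applied.

## Problem sizes and tolerances

The test suite and the acceptance script run everything at the study's
native scale: 30-participant cohorts over 27 weeks for recovery and
benchmarking, 2,000 replicates for test calibration, 200 for selection
accuracy, 500 participants for the attenuation law. Exact identities
(coefficient recovery on noiseless data, jackknife identity, scaling
round-trips) are asserted at 1e-9 to 1e-12; noiseless RSS at 1e-18;
Monte-Carlo quantities at their binomial/analytic tolerances. Recovery is
judged against the realized cohort truth (the coefficient-space mean of
the drawn participant curves) within two jackknife standard errors — the
realized mean, not the configured trend, is the estimand of the population
hierarchy once random effects are drawn.

## Known limitations

- Period is fixed at 24 h; no period estimation, non-sinusoidal shapes, or
  robust/weighted regression.
- No mixed-effects or state-space rhythm model; the hierarchy is the
  classical two-stage average, so weeks with very few fittable days per
  participant get no shrinkage.
- The imputer is univariate per metric; no joint HR/HRV modelling, no
  hyperparameter search, and the forward-only filling rule leaves early-
  block gaps unfilled (see above).
- MCAR is the only built-in missingness mechanism (plus optional
  per-participant rate heterogeneity at generation time); structured
  dropout must be supplied by the user's own data.
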