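# circarhythm

Population-mean cosinor analysis of longitudinal wearable heart-rate (HR) and
heart-rate-variability (HRV) data, built for studies that sample vitals on a
sparse clock grid in free-living conditions — the motivating use case is
tracking circadian rhythms of HR and RMSSD across gestational weeks 14–40 of
pregnancy from smartwatch photoplethysmography, where each participant
contributes 12-minute recordings every 2 hours, many slots are missing, and
the scientific questions concern how the rhythm's baseline, strength and
timing evolve week by week.

The package is aimed at biostatisticians and physiological-data researchers
who need the whole chain as tested, reusable code: day-level quality
filtering, missing-slot imputation, cosinor rhythmometry, hierarchical
population aggregation, and cohort-level inference — plus a seeded synthetic
cohort generator so every stage can be validated against known ground truth.

## The model

A single-component cosinor fits a fixed 24-h cosine by least squares:

    Y(t) = M + A cos(2πt/24 + φ) + e(t)

where `M` is the MESOR (rhythm-adjusted mean), `A` the amplitude (half the
peak-to-trough range) and `φ` the acrophase in radians; the fitted curve
peaks at clock time `−φ·24/2π (mod 24)`. Multi-component fits add harmonics
`A_i cos(2πit/24 + φ_i)`, with the harmonic count chosen by the nested
extra-sum-of-squares F-test, and rhythm presence tested by the
zero-amplitude F-test against the intercept-only model.

The population hierarchy follows the population-mean cosinor construction:
a cosinor is fitted to each participant's daily 24-h series; each
participant's daily fits are averaged **in linear coefficient space**
`(M, β_i, γ_i)` into a weekly rhythm; the weekly population rhythm is the
arithmetic mean of the participant vectors, with between-participant SDs
(circular SD for phase), 95% t-based confidence bands, and leave-one-out
jackknife stability estimates. Downstream inference compares early
(weeks 14–20) vs late (weeks 34–40) pregnancy with Welch's t-test and
Cohen's d, and correlates participant age with rhythm parameters
(Pearson's r).

Missing slots are imputed with a small LSTM sequence regressor (one
50-unit recurrent layer and two dense layers, implemented in numpy with
full backpropagation-through-time) that predicts each slot from the six
preceding consecutive observed slots, trained with user-level train/test
splits so evaluation reflects unseen individuals; deterministic slot-mean
and linear-interpolation baselines are included.

## Worked example

```python
from circarhythm import (apply_missingness, default_config, filter_days,
                         generate_cohort, missingness_report, analyze_cohort)
from circarhythm.imputation import baseline_impute

cfg = default_config("HR", seed=1).with_(
    n_participants=10, week_end=20, acrophase_sd_hours=2.0)
samples, truth = generate_cohort(cfg)
sparse = apply_missingness(samples, cfg.missing_rate, seed=2)
filtered, profiles = filter_days(sparse)           # >=7 distinct hours/day
qc = missingness_report(filtered, profiles)
print(f"included days: {qc.n_days}, expected samples: {qc.expected_samples}, "
      f"missing: {qc.missing_rate_pct}%")

filled = baseline_impute(filtered, "linear_interp")
analysis = analyze_cohort(filled)
for week in (14, 17, 20):
    pop = analysis["population"][("HR", week)]
    loo = analysis["loocv"][("HR", week)]
    print(f"week {week}: k={pop.k}  MESOR {pop.mesor:5.2f} bpm  "
          f"amplitude {pop.amplitude:4.2f} bpm  peak {pop.peak_hour:5.2f} h  "
          f"p={pop.p_population:.1e}  LOOCV MESOR sd {loo.sd['mesor']:.2f}")
```

prints

```
included days: 254, expected samples: 3048, missing: 29.63%
week 14: k=10  MESOR 73.15 bpm  amplitude 3.98 bpm  peak 16.27 h  p=1.6e-05  LOOCV MESOR sd 0.87
week 17: k=10  MESOR 72.72 bpm  amplitude 3.35 bpm  peak 14.87 h  p=7.2e-05  LOOCV MESOR sd 0.90
week 20: k=10  MESOR 74.72 bpm  amplitude 3.03 bpm  peak 14.32 h  p=1.1e-03  LOOCV MESOR sd 0.92
```

Reading the output: after the day-inclusion rule, 254 participant-days
remain and ~30% of their 2-h slots are missing. Each week's population
MESOR sits near the configured 73–75 bpm trend, the fitted curve peaks in
mid-afternoon, the rhythm-detection p value (here the population-mean
Hotelling test on per-participant cosine coefficients) is strongly
significant, and removing any single participant moves the weekly MESOR by
less than 1 bpm. Note this demo narrows the between-participant phase
dispersion to 2 h; at the default 7 h the population-mean curve's amplitude
is attenuated by `exp(−σ_φ²/2)` (≈ 0.19 at 7 h) and the aggregate rhythm
becomes hard to detect — see `docs/methods.md`.

A command-line interface mirrors the library
(`circarhythm simulate|impute|fit|population|compare|correlate|loocv|run`);
`circarhythm run --no-nn --out-dir out --seed 1` executes the whole pipeline
deterministically and writes CSV artifacts plus a content-hashed
`manifest.json`.

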