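"""Seeded synthetic cohorts with the longitudinal circadian structure the
analysis assumes: gestational-week trend curves for MESOR, amplitude and peak
hour, between-participant random effects, within-day cosine structure plus
Gaussian noise, and missing-completely-at-random slot dropout.

The generator stands in for wearable HR/HRV data that cannot be shared: 30
pregnant participants followed from gestational week 14 to 40, sampled on a
2-hour grid (12 slots/day) on several days per week, with roughly 36% of
slots missing.  Each participant draws a constant MESOR offset, amplitude
offset and (wrapped-normal) acrophase offset; weekly true parameters are the
population trend plus those offsets, and slot values are

    Y(t) = M_pw + A_pw * cos(2*pi*t/24 + phi_pw) + eps,  eps ~ N(0, sigma).

Negative value draws are rejected and resampled rather than clipped, keeping
the noise symmetric around the mean.  Ground-truth per-participant-week
parameters are returned alongside the samples for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .cosinor import OMEGA, peak_hour_to_acrophase
from .io_model import CSV_COLUMNS, SLOT_HOURS

__all__ = [
    "TrendCurve",
    "SyntheticCohortConfig",
    "default_config",
    "generate_cohort",
    "apply_missingness",
]

_EPOCH = date(2023, 1, 2)  # arbitrary Monday anchoring week 0 of the calendar


@dataclass(frozen=True)
class TrendCurve:
    """Piecewise-linear gestational trend: anchors (week, value), interpolated
    linearly and held constant outside the anchor range."""

    anchors: tuple[tuple[float, float], ...]

    def __post_init__(self):
        weeks = [w for w, _ in self.anchors]
        if len(weeks) == 0 or sorted(weeks) != weeks:
            raise ValueError("anchors must be non-empty and sorted by week")

    def __call__(self, week) -> np.ndarray | float:
        weeks = np.array([w for w, _ in self.anchors], dtype=float)
        values = np.array([v for _, v in self.anchors], dtype=float)
        out = np.interp(np.asarray(week, dtype=float), weeks, values)
        return float(out) if np.ndim(week) == 0 else out


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Full generative specification of a one-metric synthetic cohort."""

    metric: str
    mesor_trend: TrendCurve
    amplitude_trend: TrendCurve
    peak_hour_trend: TrendCurve
    n_participants: int = 30
    week_start: int = 14
    week_end: int = 40
    days_per_week: int = 5
    mesor_sd: float = 0.0          # between-participant, metric units
    amplitude_sd: float = 0.0      # between-participant, metric units
    acrophase_sd_hours: float = 0.0  # between-participant circular SD, hours
    noise_sd: float = 0.0          # within-slot, metric units
    age_range: tuple[int, int] = (23, 39)
    acrophase_delay_h_per_decade: float = 0.0
    missing_rate: float = 0.3612
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if not (1 <= self.week_start <= self.week_end <= 42):
            raise ValueError("week range must satisfy 1 <= start <= end <= 42")
        if self.days_per_week < 1:
            raise ValueError("days_per_week must be >= 1")
        for name in ("mesor_sd", "amplitude_sd", "acrophase_sd_hours", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")

    @property
    def weeks(self) -> np.ndarray:
        return np.arange(self.week_start, self.week_end + 1)

    def with_(self, **kwargs) -> "SyntheticCohortConfig":
        return replace(self, **kwargs)


def default_config(metric: str, seed: int = 0) -> SyntheticCohortConfig:
    """Study-condition defaults for a metric.

    HR (bpm): MESOR rises from ~74 at week 14 to ~80 at week 34, then falls
    back to ~74 by week 40; population amplitude 3.5 -> <2 by week 27 -> ~3 by
    week 40; between-participant MESOR SD ~7 bpm and acrophase SD ~7 h.

    RMSSD (ms): MESOR declines from ~46 at week 14 to below 36 at week 34,
    transiently recovers to ~43 around week 37 and ends near 39; amplitude
    declines from ~2 to ~1; MESOR SD ~12 ms (observed range 8-16), acrophase
    SD ~5 h, with a mild age-related acrophase delay (~1.2 h per decade).
    """
    if metric == "HR":
        return SyntheticCohortConfig(
            metric="HR",
            mesor_trend=TrendCurve(((14, 74.0), (34, 80.0), (40, 74.0))),
            amplitude_trend=TrendCurve(((14, 3.5), (27, 2.0), (40, 3.0))),
            peak_hour_trend=TrendCurve(((14, 16.0), (22, 14.0), (27, 16.0), (34, 15.0), (37, 17.0), (40, 14.0))),
            mesor_sd=7.0,
            amplitude_sd=1.5,
            acrophase_sd_hours=7.0,
            noise_sd=5.0,
            acrophase_delay_h_per_decade=0.0,
            seed=seed,
        )
    if metric == "RMSSD":
        return SyntheticCohortConfig(
            metric="RMSSD",
            mesor_trend=TrendCurve(((14, 46.0), (34, 36.0), (37, 43.0), (40, 39.0))),
            amplitude_trend=TrendCurve(((14, 2.0), (40, 1.0))),
            peak_hour_trend=TrendCurve(((14, 20.0), (40, 21.0))),
            mesor_sd=12.0,
            amplitude_sd=0.8,
            acrophase_sd_hours=5.0,
            noise_sd=8.0,
            acrophase_delay_h_per_decade=1.2,
            seed=seed,
        )
    raise ValueError(f"no default configuration for metric {metric!r}")


def _participant_dates(config: SyntheticCohortConfig, week: int) -> list[date]:
    base = _EPOCH + timedelta(weeks=int(week) - config.week_start)
    return [base + timedelta(days=d) for d in range(config.days_per_week)]


def generate_cohort(config: SyntheticCohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (samples, truth) tables; fully reproducible from ``config.seed``.

    ``samples`` follows the package CSV schema with no missing values (apply
    :func:`apply_missingness` for dropout).  ``truth`` has one row per
    participant-week with the realized true MESOR, amplitude, acrophase
    (radians, principal branch), peak hour, and the participant's age.
    """
    rng = np.random.default_rng(config.seed)
    weeks = config.weeks
    slots = np.array(SLOT_HOURS, dtype=float)
    mean_age = np.mean(config.age_range)

    sample_rows = []
    truth_rows = []
    for p in range(config.n_participants):
        pid = f"P{p + 1:02d}"
        age = int(rng.integers(config.age_range[0], config.age_range[1] + 1))
        amp_trend = config.amplitude_trend(weeks)
        mesor_trend = config.mesor_trend(weeks)
        # resample offsets until the true curve stays positive everywhere:
        # amplitudes must be > 0 and the trough M - A must clear zero
        for _ in range(1000):
            amp_off = rng.normal(0.0, config.amplitude_sd) if config.amplitude_sd else 0.0
            if np.all(amp_trend + amp_off > 0):
                break
        else:
            raise RuntimeError("could not draw a positive amplitude offset")
        for _ in range(1000):
            mesor_off = rng.normal(0.0, config.mesor_sd) if config.mesor_sd else 0.0
            if np.all(mesor_trend + mesor_off - (amp_trend + amp_off) > 0):
                break
        else:
            raise RuntimeError("could not draw a positive-trough MESOR offset")
        phase_off_h = (
            rng.normal(0.0, config.acrophase_sd_hours)
            + config.acrophase_delay_h_per_decade * (age - mean_age) / 10.0
        )

        for wi, week in enumerate(weeks):
            m_true = float(mesor_trend[wi] + mesor_off)
            a_true = float(amp_trend[wi] + amp_off)
            peak_true = float((config.peak_hour_trend(float(week)) + phase_off_h) % 24.0)
            phi_true = peak_hour_to_acrophase(peak_true)
            truth_rows.append(
                {
                    "participant_id": pid,
                    "age": age,
                    "gestational_week": int(week),
                    "mesor": m_true,
                    "amplitude": a_true,
                    "acrophase": phi_true,
                    "peak_hour": peak_true,
                }
            )
            mean_curve = m_true + a_true * np.cos(OMEGA * slots + phi_true)
            for day in _participant_dates(config, int(week)):
                values = mean_curve + (
                    rng.normal(0.0, config.noise_sd, size=slots.size)
                    if config.noise_sd
                    else 0.0
                )
                if config.noise_sd:
                    bad = values <= 0
                    tries = 0
                    while np.any(bad):
                        values[bad] = mean_curve[bad] + rng.normal(0.0, config.noise_sd, size=int(bad.sum()))
                        bad = values <= 0
                        tries += 1
                        if tries > 1000:
                            raise RuntimeError("value resampling did not converge")
                for slot, value in zip(SLOT_HOURS, values):
                    sample_rows.append(
                        (
                            pid,
                            pd.Timestamp(day.year, day.month, day.day, slot),
                            int(week),
                            slot,
                            config.metric,
                            float(value),
                        )
                    )
    samples = pd.DataFrame(sample_rows, columns=CSV_COLUMNS)
    truth = pd.DataFrame(truth_rows)
    return samples, truth


def apply_missingness(
    samples: pd.DataFrame,
    rate: float,
    seed: int,
    participant_concentration: float | None = None,
) -> pd.DataFrame:
    """Flag each slot value MISSING independently with probability ``rate``
    (MCAR).  Returns a new table; the input is not modified.

    With ``participant_concentration`` set, per-participant rates are drawn
    from a Beta distribution with mean ``rate`` and the given concentration
    (``alpha + beta``), emulating lifestyle-driven differences in wear
    compliance; smaller concentrations give more heterogeneity.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    out = samples.copy()
    if rate == 0.0 or not len(out):
        return out
    rng = np.random.default_rng(seed)
    if participant_concentration is None:
        drop = rng.random(len(out)) < rate
    else:
        if participant_concentration <= 0:
            raise ValueError("participant_concentration must be > 0")
        pids = sorted(out["participant_id"].unique())
        rates = {
            pid: rng.beta(rate * participant_concentration,
                          (1.0 - rate) * participant_concentration)
            for pid in pids
        }
        per_row = out["participant_id"].map(rates).to_numpy()
        drop = rng.random(len(out)) < per_row
    out.loc[drop, "value"] = np.nan
    return out
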