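"""Population-mean cosinor hierarchy.

Per gestational week the estimation ladder is:

1. a cosinor model is fitted to every participant's daily 24-h series;
2. each participant's daily fits are averaged *in linear coefficient space*
   (M, beta_i, gamma_i) to a weekly participant rhythm — averaging (A, phi)
   directly is ill-defined across the phase wrap-around;
3. the population rhythm for the week is the arithmetic mean of the
   participants' weekly coefficient vectors, with between-participant SDs
   (circular SD for the acrophase), a 95% t-based confidence band around the
   mean curve, and rhythm-detection p values.

Two rhythmicity p values are reported per week: a pooled zero-amplitude
F-test on the stacked weekly participant-mean slot series (default), and a
population-mean (Hotelling T^2 on the per-participant (beta, gamma) vectors)
test as an alternative.  A leave-one-out jackknife over participants
quantifies the stability of the weekly estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import cosinor
from .cosinor import CosinorFit, FitError, fit_cosinor, select_components

__all__ = [
    "ParticipantWeekRhythm",
    "PopulationWeekRhythm",
    "LoocvWeekSummary",
    "circular_mean",
    "circular_sd_hours",
    "weekly_participant_rhythm",
    "population_week_rhythm",
    "interindividual_sd",
    "loocv_week",
    "analyze_cohort",
]

CURVE_GRID_HOURS = np.arange(24.0)


def circular_mean(angles) -> float:
    """Circular mean of angles in radians, on the principal branch."""
    angles = np.asarray(angles, dtype=float)
    return float(cosinor.wrap_angle(np.angle(np.mean(np.exp(1j * angles)))))


def circular_sd_hours(angles) -> float:
    """Circular SD sqrt(-2 ln R) of angles (radians), converted to hours."""
    angles = np.asarray(angles, dtype=float)
    r = float(np.abs(np.mean(np.exp(1j * angles))))
    r = min(max(r, 1e-300), 1.0)
    return float(np.sqrt(-2.0 * np.log(r)) * 24.0 / (2.0 * np.pi))


def _pad_coefficients(vectors: list[np.ndarray]) -> np.ndarray:
    """Stack coefficient vectors, zero-padding to the largest harmonic count."""
    width = max(v.size for v in vectors)
    out = np.zeros((len(vectors), width))
    for i, v in enumerate(vectors):
        out[i, : v.size] = v
    return out


@dataclass
class ParticipantWeekRhythm:
    """One participant's weekly rhythm: daily cosinor fits averaged in
    coefficient space, plus the weekly mean value per slot hour."""

    participant_id: str
    metric: str
    gestational_week: int
    coefficients: np.ndarray
    n_days: int
    mean_rss: float
    slot_hours: np.ndarray = field(repr=False)
    slot_means: np.ndarray = field(repr=False)

    @property
    def mesor(self) -> float:
        return float(self.coefficients[0])

    @property
    def amplitude(self) -> float:
        return cosinor.params_from_coefficients(self.coefficients)[1]

    @property
    def acrophase(self) -> float:
        return cosinor.params_from_coefficients(self.coefficients)[2]

    @property
    def peak_hour(self) -> float:
        return cosinor.params_from_coefficients(self.coefficients)[3]

    def curve(self, t=CURVE_GRID_HOURS) -> np.ndarray:
        return cosinor.evaluate_curve(self.coefficients, t)


@dataclass
class PopulationWeekRhythm:
    """Population-mean rhythm for one gestational week."""

    metric: str
    gestational_week: int
    k: int
    coefficients: np.ndarray
    mesor_sd: float
    amplitude_sd: float
    acrophase_sd_hours: float
    p_pooled: float
    p_population: float
    residual_se: float
    grid_hours: np.ndarray = field(repr=False)
    mean_curve: np.ndarray = field(repr=False)
    ci_low: np.ndarray = field(repr=False)
    ci_high: np.ndarray = field(repr=False)

    @property
    def mesor(self) -> float:
        return float(self.coefficients[0])

    @property
    def amplitude(self) -> float:
        return cosinor.params_from_coefficients(self.coefficients)[1]

    @property
    def acrophase(self) -> float:
        return cosinor.params_from_coefficients(self.coefficients)[2]

    @property
    def peak_hour(self) -> float:
        return cosinor.params_from_coefficients(self.coefficients)[3]


@dataclass
class LoocvWeekSummary:
    """Leave-one-out stability of one week's population parameters.

    ``estimates`` holds the k leave-one-out values per parameter; means and
    SDs use circular statistics for the peak hour (hours) and plain sample
    statistics otherwise.
    """

    metric: str
    gestational_week: int
    k: int
    estimates: dict[str, np.ndarray]
    mean: dict[str, float]
    sd: dict[str, float]


def weekly_participant_rhythm(
    samples: pd.DataFrame,
    n_components: int | str = 1,
    alpha: float = 0.05,
    min_points_per_day: int = 4,
) -> ParticipantWeekRhythm:
    """Fit daily cosinor models for one participant-week and average them.

    ``samples`` must contain one participant, one metric and one gestational
    week.  ``n_components`` is a fixed harmonic count or ``"auto"`` for
    per-day extra-sum-of-squares selection (vectors from different days are
    zero-padded to a common harmonic basis before averaging).  Days with
    fewer than ``min_points_per_day`` observed slots are skipped.
    """
    pids = samples["participant_id"].unique()
    metrics = samples["metric"].unique()
    weeks = samples["gestational_week"].unique()
    if len(pids) != 1 or len(metrics) != 1 or len(weeks) != 1:
        raise ValueError("expected samples for exactly one participant-week-metric")
    observed = samples[samples["value"].notna()]
    fits: list[CosinorFit] = []
    for _, day_df in observed.groupby(observed["timestamp"].dt.date):
        t = day_df["timestamp"].dt.hour + day_df["timestamp"].dt.minute / 60.0
        if len(day_df) < max(min_points_per_day, 4):
            continue
        try:
            if n_components == "auto":
                fits.append(select_components(t, day_df["value"], alpha=alpha))
            else:
                fits.append(fit_cosinor(t, day_df["value"], int(n_components)))
        except FitError:
            continue
    if not fits:
        raise FitError(f"no fittable days for participant {pids[0]} week {weeks[0]}")
    coeffs = _pad_coefficients([f.coefficients for f in fits]).mean(axis=0)
    slot_means = observed.groupby("slot_hour")["value"].mean()
    return ParticipantWeekRhythm(
        participant_id=str(pids[0]),
        metric=str(metrics[0]),
        gestational_week=int(weeks[0]),
        coefficients=coeffs,
        n_days=len(fits),
        mean_rss=float(np.mean([f.rss for f in fits])),
        slot_hours=slot_means.index.to_numpy(dtype=float),
        slot_means=slot_means.to_numpy(dtype=float),
    )


def population_week_rhythm(
    rhythms: list[ParticipantWeekRhythm],
    conf_level: float = 0.95,
) -> PopulationWeekRhythm:
    """Aggregate participants' weekly rhythms into the population rhythm.

    The population coefficient vector is the arithmetic mean of participant
    vectors.  The CI band at each grid hour is mean +/- t_{(1+conf)/2, k-1} *
    SD(participant curves) / sqrt(k); with one participant the band collapses
    onto the curve.
    """
    if not rhythms:
        raise ValueError("need at least one participant rhythm")
    k = len(rhythms)
    metric = rhythms[0].metric
    week = rhythms[0].gestational_week
    stacked = _pad_coefficients([r.coefficients for r in rhythms])
    pop_coeffs = stacked.mean(axis=0)

    mesors = np.array([r.mesor for r in rhythms])
    amplitudes = np.array([r.amplitude for r in rhythms])
    acrophases = np.array([r.acrophase for r in rhythms])
    mesor_sd = float(np.std(mesors, ddof=1)) if k >= 2 else float("nan")
    amplitude_sd = float(np.std(amplitudes, ddof=1)) if k >= 2 else float("nan")
    acro_sd = circular_sd_hours(acrophases) if k >= 2 else float("nan")

    # pooled rhythmicity test on the stacked participant-mean slot series
    t_pool = np.concatenate([r.slot_hours for r in rhythms])
    y_pool = np.concatenate([r.slot_means for r in rhythms])
    n_comp = (pop_coeffs.size - 1) // 2
    try:
        pooled_fit = fit_cosinor(t_pool, y_pool, n_comp)
        p_pooled = pooled_fit.p_zero_amplitude
        residual_se = pooled_fit.residual_se
    except FitError:
        p_pooled = float("nan")
        residual_se = float("nan")

    p_population = _hotelling_rhythm_test(stacked) if k >= 3 else float("nan")

    grid = CURVE_GRID_HOURS
    curves = np.vstack([cosinor.evaluate_curve(v, grid) for v in stacked])
    mean_curve = cosinor.evaluate_curve(pop_coeffs, grid)
    if k >= 2:
        t_crit = stats.t.ppf(0.5 + conf_level / 2.0, k - 1)
        half = t_crit * curves.std(axis=0, ddof=1) / np.sqrt(k)
    else:
        half = np.zeros_like(mean_curve)
    return PopulationWeekRhythm(
        metric=metric,
        gestational_week=week,
        k=k,
        coefficients=pop_coeffs,
        mesor_sd=mesor_sd,
        amplitude_sd=amplitude_sd,
        acrophase_sd_hours=acro_sd,
        p_pooled=p_pooled,
        p_population=p_population,
        residual_se=residual_se,
        grid_hours=grid,
        mean_curve=mean_curve,
        ci_low=mean_curve - half,
        ci_high=mean_curve + half,
    )


def _hotelling_rhythm_test(stacked: np.ndarray) -> float:
    """Population-mean cosinor zero-amplitude test: Hotelling T^2 on the
    first-harmonic (beta, gamma) vectors across participants."""
    bg = stacked[:, 1:3]
    k = bg.shape[0]
    mean = bg.mean(axis=0)
    cov = np.cov(bg, rowvar=False, ddof=1)
    try:
        t2 = k * mean @ np.linalg.solve(cov, mean)
    except np.linalg.LinAlgError:
        return float("nan")
    f_stat = (k - 2) / (2.0 * (k - 1)) * t2
    return float(stats.f.sf(f_stat, 2, k - 2))


def interindividual_sd(rhythms: list[ParticipantWeekRhythm]) -> dict[str, float]:
    """Between-participant SDs of MESOR, amplitude (sample SD, n-1) and
    acrophase (circular SD from the mean resultant length, in hours)."""
    if len(rhythms) < 2:
        raise ValueError("between-participant SD requires k >= 2")
    return {
        "mesor_sd": float(np.std([r.mesor for r in rhythms], ddof=1)),
        "amplitude_sd": float(np.std([r.amplitude for r in rhythms], ddof=1)),
        "acrophase_sd_hours": circular_sd_hours([r.acrophase for r in rhythms]),
    }


def loocv_week(rhythms: list[ParticipantWeekRhythm]) -> LoocvWeekSummary:
    """Leave-one-participant-out stability: exactly k refits of the
    population rhythm, summarised as mean and SD per parameter (circular for
    the peak hour)."""
    k = len(rhythms)
    if k < 2:
        raise ValueError("LOOCV requires k >= 2")
    est = {"mesor": [], "amplitude": [], "peak_hour": [], "acrophase": []}
    for i in range(k):
        subset = rhythms[:i] + rhythms[i + 1:]
        pop = population_week_rhythm(subset)
        est["mesor"].append(pop.mesor)
        est["amplitude"].append(pop.amplitude)
        est["peak_hour"].append(pop.peak_hour)
        est["acrophase"].append(pop.acrophase)
    est = {name: np.asarray(v) for name, v in est.items()}
    omega = 2.0 * np.pi / 24.0
    mean = {
        "mesor": float(est["mesor"].mean()),
        "amplitude": float(est["amplitude"].mean()),
        "peak_hour": float((circular_mean(-est["peak_hour"] * omega) / -omega) % 24.0),
        "acrophase": circular_mean(est["acrophase"]),
    }
    sd = {
        "mesor": float(est["mesor"].std(ddof=1)),
        "amplitude": float(est["amplitude"].std(ddof=1)),
        "peak_hour": circular_sd_hours(est["peak_hour"] * omega),
        "acrophase": circular_sd_hours(est["acrophase"]) * omega,  # back to radians
    }
    return LoocvWeekSummary(
        metric=rhythms[0].metric,
        gestational_week=rhythms[0].gestational_week,
        k=k,
        estimates=est,
        mean=mean,
        sd=sd,
    )


def analyze_cohort(
    samples: pd.DataFrame,
    n_components: int | str = 1,
    alpha: float = 0.05,
    run_loocv: bool = True,
) -> dict:
    """Run the full weekly hierarchy for every metric and gestational week.

    Returns a dict with ``participant_rhythms`` (per metric-week lists of
    :class:`ParticipantWeekRhythm`), ``population`` (per metric-week
    :class:`PopulationWeekRhythm`) and optional ``loocv`` summaries.
    Participant-weeks with no fittable day are skipped.
    """
    participant_rhythms: dict[tuple[str, int], list[ParticipantWeekRhythm]] = {}
    for (metric, week, _pid), sub in samples.groupby(
        ["metric", "gestational_week", "participant_id"], sort=True
    ):
        try:
            rhythm = weekly_participant_rhythm(sub, n_components=n_components, alpha=alpha)
        except FitError:
            continue
        participant_rhythms.setdefault((metric, int(week)), []).append(rhythm)
    population = {
        key: population_week_rhythm(rhythms)
        for key, rhythms in participant_rhythms.items()
    }
    result = {"participant_rhythms": participant_rhythms, "population": population}
    if run_loocv:
        result["loocv"] = {
            key: loocv_week(rhythms)
            for key, rhythms in participant_rhythms.items()
            if len(rhythms) >= 2
        }
    return result


def participant_rhythms_frame(rhythms_by_week: dict) -> pd.DataFrame:
    """Tidy per-participant-week parameter table from analyze_cohort output."""
    rows = []
    for (metric, week), rhythms in rhythms_by_week.items():
        for r in rhythms:
            rows.append(
                {
                    "participant_id": r.participant_id,
                    "metric": metric,
                    "gestational_week": week,
                    "mesor": r.mesor,
                    "amplitude": r.amplitude,
                    "acrophase": r.acrophase,
                    "peak_hour": r.peak_hour,
                    "n_days": r.n_days,
                }
            )
    return pd.DataFrame(rows)
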