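"""Cross-week cohort inference: early-vs-late pregnancy comparison with
Cohen's d, and Pearson correlation between age and rhythm parameters.

Group comparisons default to participant-level window means (one value per
participant per window, averaging that participant's weeks inside the
window) so the compared observations are independent; pooling all
participant-weeks is available as an alternative mode.  Cohen's d uses the
classic pooled SD with (n1 + n2 - 2) weights and the (early - late) sign
convention: an early mean below the late mean yields a negative d.  P values
come from Welch's two-sample t-test.  Acrophases are compared linearly in
radians on the principal branch (circular means are used when collapsing a
participant's weeks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .population import circular_mean

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "cohens_d",
    "early_late_comparison",
    "age_rhythm_correlation",
]

PARAMETERS = ("mesor", "amplitude", "acrophase")


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    parameter: str
    early_mean: float
    late_mean: float
    p_value: float
    effect_size_d: float
    n_early: int
    n_late: int


@dataclass(frozen=True)
class CorrelationResult:
    covariate: str
    metric: str
    parameter: str
    r: float
    p_value: float
    n: int


def cohens_d(a, b) -> float:
    """Cohen's d of (mean(a) - mean(b)) with pooled-SD (n1 + n2 - 2) weights.

    Zero pooled SD yields 0 for identical means and signed infinity
    otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    diff = a.mean() - b.mean()
    if n1 + n2 <= 2:
        return float("nan")
    pooled_var = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if pooled_var == 0.0:
        return 0.0 if diff == 0.0 else float(np.sign(diff)) * float("inf")
    return float(diff / np.sqrt(pooled_var))


def _welch_p(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.array_equal(a, b) or (a.var(ddof=1) == 0 and b.var(ddof=1) == 0):
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def _participant_window_means(rhythms: pd.DataFrame, weeks: tuple[int, int]) -> pd.DataFrame:
    lo, hi = weeks
    sub = rhythms[(rhythms["gestational_week"] >= lo) & (rhythms["gestational_week"] <= hi)]
    if sub.empty:
        raise ValueError(f"no participant-weeks inside window {lo}-{hi}")
    rows = []
    for pid, g in sub.groupby("participant_id"):
        rows.append(
            {
                "participant_id": pid,
                "mesor": g["mesor"].mean(),
                "amplitude": g["amplitude"].mean(),
                "acrophase": circular_mean(g["acrophase"]),
            }
        )
    return pd.DataFrame(rows)


def early_late_comparison(
    rhythms: pd.DataFrame,
    early_weeks: tuple[int, int] = (14, 20),
    late_weeks: tuple[int, int] = (34, 40),
    mode: str = "participant_means",
) -> list[GroupComparison]:
    """Compare rhythm parameters between two gestational windows.

    ``rhythms`` is the tidy participant-week parameter table (columns
    ``participant_id, metric, gestational_week, mesor, amplitude,
    acrophase``).  ``mode='participant_means'`` (default) averages each
    participant's weeks within a window before testing;
    ``mode='pooled_weeks'`` treats every participant-week as an observation.
    """
    if mode not in ("participant_means", "pooled_weeks"):
        raise ValueError(f"unknown mode {mode!r}")
    results = []
    for metric, sub in rhythms.groupby("metric", sort=True):
        if mode == "participant_means":
            early = _participant_window_means(sub, early_weeks)
            late = _participant_window_means(sub, late_weeks)
        else:
            lo, hi = early_weeks
            early = sub[(sub["gestational_week"] >= lo) & (sub["gestational_week"] <= hi)]
            lo, hi = late_weeks
            late = sub[(sub["gestational_week"] >= lo) & (sub["gestational_week"] <= hi)]
            if early.empty or late.empty:
                raise ValueError("empty comparison window")
        for parameter in PARAMETERS:
            a = early[parameter].to_numpy(dtype=float)
            b = late[parameter].to_numpy(dtype=float)
            results.append(
                GroupComparison(
                    metric=str(metric),
                    parameter=parameter,
                    early_mean=float(a.mean()),
                    late_mean=float(b.mean()),
                    p_value=_welch_p(a, b),
                    effect_size_d=cohens_d(a, b),
                    n_early=a.size,
                    n_late=b.size,
                )
            )
    return results


def age_rhythm_correlation(
    ages: pd.Series,
    rhythms: pd.DataFrame,
    covariate_name: str = "age",
) -> list[CorrelationResult]:
    """Pearson correlation between a per-participant covariate (age in
    years) and participant-level mean rhythm parameters across all weeks.

    ``ages`` is indexed by participant_id.  Acrophases are collapsed per
    participant with a circular mean and then correlated linearly in radians.
    Requires n >= 3 participants; zero variance in either variable raises.
    """
    results = []
    for metric, sub in rhythms.groupby("metric", sort=True):
        means = _participant_window_means(
            sub, (int(sub["gestational_week"].min()), int(sub["gestational_week"].max()))
        ).set_index("participant_id")
        common = means.index.intersection(ages.index)
        if len(common) < 3:
            raise ValueError("correlation requires at least 3 participants")
        x = ages.loc[common].to_numpy(dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError("ages must be finite")
        if np.std(x) == 0:
            raise ValueError("zero variance in the covariate")
        for parameter in PARAMETERS:
            y = means.loc[common, parameter].to_numpy(dtype=float)
            if np.std(y) == 0:
                raise ValueError(f"zero variance in {parameter}")
            r, p = stats.pearsonr(x, y)
            results.append(
                CorrelationResult(
                    covariate=covariate_name,
                    metric=str(metric),
                    parameter=parameter,
                    r=float(r),
                    p_value=float(p),
                    n=len(common),
                )
            )
    return results
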