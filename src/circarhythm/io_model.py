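"""Data model, CSV I/O, day-level quality filtering and missingness accounting.

Sample tables are tidy pandas DataFrames with one row per
(participant, timestamp, metric) observation on a 2-hour slot grid:

    participant_id,timestamp,gestational_week,slot_hour,metric,value

Timestamps are local civil time (``YYYY-MM-DDTHH:MM``, no timezone
arithmetic) because the analysis concerns clock-time rhythms in free-living
conditions.  A missing measurement is a row whose ``value`` is NaN (empty
string on disk); a slot with no row at all also counts as missing when
accounting against the 12-slot daily grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

CSV_COLUMNS = ["participant_id", "timestamp", "gestational_week", "slot_hour", "metric", "value"]
TIMESTAMP_FORMAT = "%Y-%m-%dT%H:%M"
METRICS = ("HR", "RMSSD", "HF", "PNN50")
SLOTS_PER_DAY = 12
SLOT_HOURS = tuple(range(0, 24, 2))

__all__ = [
    "CSV_COLUMNS",
    "METRICS",
    "SLOTS_PER_DAY",
    "SLOT_HOURS",
    "ValidationError",
    "EmptyCohortError",
    "MissingnessStats",
    "read_samples",
    "write_samples",
    "validate_samples",
    "filter_days",
    "missingness_report",
]


class ValidationError(ValueError):
    """Input rows violate the sample-table schema; message names the rows."""


class EmptyCohortError(ValueError):
    """No included days remain, so rates are undefined."""


@dataclass(frozen=True)
class MissingnessStats:
    """Cohort-level missing-sample accounting over included days.

    ``expected_samples`` is always ``12 * n_days`` (the full 2-h grid);
    rates are percentages rounded half-up to 2 decimals.
    """

    n_days: int
    expected_samples: int
    missing_samples: int
    missing_rate_pct: float
    valid_rate_pct: float


def _round_pct(numerator: int, denominator: int) -> float:
    frac = Decimal(100 * numerator) / Decimal(denominator)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _value_ok(metric: pd.Series, value: pd.Series) -> pd.Series:
    ok = pd.Series(True, index=value.index)
    present = value.notna()
    pos_metrics = metric.isin(["HR", "RMSSD", "HF"])
    ok &= ~(present & pos_metrics & (value <= 0))
    ok &= ~(present & (metric == "PNN50") & ((value < 0) | (value > 100)))
    return ok


def validate_samples(samples: pd.DataFrame) -> None:
    """Check SampleRecord invariants; raise :class:`ValidationError` naming rows."""
    problems = []
    slot = samples["slot_hour"]
    bad_slot = samples.index[(slot % 2 != 0) | (slot < 0) | (slot > 22)]
    for i in bad_slot:
        problems.append(f"row {i}: slot_hour {slot[i]} not on the 2-h grid")
    hour_mismatch = samples.index[
        (samples["timestamp"].dt.hour // 2) * 2 != slot
    ]
    for i in hour_mismatch:
        problems.append(f"row {i}: slot_hour inconsistent with timestamp hour")
    bad_metric = samples.index[~samples["metric"].isin(METRICS)]
    for i in bad_metric:
        problems.append(f"row {i}: unknown metric {samples['metric'][i]!r}")
    bad_value = samples.index[~_value_ok(samples["metric"], samples["value"])]
    for i in bad_value:
        problems.append(f"row {i}: value {samples['value'][i]} out of range")
    key = [samples["participant_id"], samples["timestamp"].dt.date, samples["slot_hour"], samples["metric"]]
    dup = samples.index[pd.Series(list(zip(*key)), index=samples.index).duplicated(keep=False)]
    # duplicates sharing the exact timestamp are legitimately averaged at
    # ingestion (one 12-min segment); distinct timestamps in one slot are not
    full_key = key + [samples["timestamp"]]
    same_segment = pd.Series(list(zip(*full_key)), index=samples.index).duplicated(keep=False)
    for i in dup:
        if not same_segment[i]:
            problems.append(f"row {i}: duplicate (participant, date, slot_hour, metric) key")
    if problems:
        raise ValidationError("; ".join(problems[:20]))


def read_samples(path, metric: str | None = None) -> pd.DataFrame:
    """Read a sample CSV, validate it, and collapse same-segment duplicates.

    Multiple rows for the same (participant, timestamp, slot, metric) — i.e.
    repeated values derived from one 12-min recording segment — are averaged.
    Rows failing validation raise :class:`ValidationError` with row numbers.
    """
    raw = pd.read_csv(path, dtype={"participant_id": str, "metric": str})
    if list(raw.columns) != CSV_COLUMNS:
        raise ValidationError(
            f"unexpected header {list(raw.columns)}; expected {CSV_COLUMNS}"
        )
    if raw.empty:
        return _empty_table()
    try:
        raw["timestamp"] = pd.to_datetime(raw["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"malformed timestamp: {exc}") from exc
    raw["gestational_week"] = raw["gestational_week"].astype(int)
    raw["slot_hour"] = raw["slot_hour"].astype(int)
    raw["value"] = pd.to_numeric(raw["value"], errors="coerce").astype(float)
    validate_samples(raw)
    grouped = (
        raw.groupby(["participant_id", "timestamp", "gestational_week", "slot_hour", "metric"],
                    as_index=False, dropna=False, sort=False)["value"]
        .mean()
    )
    out = grouped[CSV_COLUMNS].sort_values(
        ["participant_id", "timestamp", "metric"], kind="stable"
    ).reset_index(drop=True)
    if metric is not None:
        if metric not in METRICS:
            raise ValueError(f"unknown metric {metric!r}")
        out = out[out["metric"] == metric].reset_index(drop=True)
    return out


def write_samples(samples: pd.DataFrame, path) -> None:
    """Write a sample table to CSV (empty string for missing values)."""
    out = samples.loc[:, CSV_COLUMNS].copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime(TIMESTAMP_FORMAT)
    out.to_csv(path, index=False, na_rep="")


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": pd.Series(dtype=str),
            "timestamp": pd.Series(dtype="datetime64[ns]"),
            "gestational_week": pd.Series(dtype=int),
            "slot_hour": pd.Series(dtype=int),
            "metric": pd.Series(dtype=str),
            "value": pd.Series(dtype=float),
        }
    )


def _observed_slot_mask(samples: pd.DataFrame, mode: str) -> pd.Series:
    """Boolean per-(participant, date, slot) qualification of an observed slot.

    Returns a Series indexed by (participant_id, date, slot_hour) that is True
    when the slot counts as observed: in ``per_metric`` mode any metric group
    is handled separately upstream; in ``joint`` mode a slot qualifies only if
    every metric present in the table has a non-missing value there.
    """
    df = samples.assign(date=samples["timestamp"].dt.date, present=samples["value"].notna())
    if mode == "joint":
        n_metrics = df["metric"].nunique()
        per_slot = df.groupby(["participant_id", "date", "slot_hour"])["present"].agg(["sum", "count"])
        # all metrics present in the table must be observed at the slot
        return (per_slot["sum"] >= n_metrics) & (per_slot["count"] >= n_metrics)
    raise ValueError(f"unknown mode {mode!r}")


def filter_days(
    samples: pd.DataFrame,
    min_distinct_hours: int = 7,
    mode: str = "joint",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the day-inclusion rule: keep days with >= ``min_distinct_hours``
    distinct observed slot hours (of 12 on the 2-h grid).

    With the default threshold of 7 an included day can miss at most 5 of its
    12 slots.  ``mode='joint'`` requires a slot to be observed for every metric
    in the table (HR and RMSSD observed together); ``mode='per_metric'``
    evaluates the rule independently per metric and returns day profiles with
    a ``metric`` column.

    Returns ``(filtered samples, day profiles)``; filtering is idempotent.
    """
    if not 1 <= min_distinct_hours <= SLOTS_PER_DAY:
        raise ValueError("min_distinct_hours must be between 1 and 12")
    if samples.empty:
        profiles = pd.DataFrame(
            columns=["participant_id", "date", "expected_slots", "observed_distinct_hours", "included"]
        )
        return samples.copy(), profiles
    df = samples.assign(date=samples["timestamp"].dt.date)
    if mode == "per_metric":
        parts = []
        prof_parts = []
        for metric, sub in df.groupby("metric", sort=False):
            filt, prof = filter_days(sub.drop(columns="date"), min_distinct_hours, mode="joint")
            prof["metric"] = metric
            parts.append(filt)
            prof_parts.append(prof)
        filtered = pd.concat(parts).sort_index() if parts else samples.iloc[0:0].copy()
        return filtered.reset_index(drop=True), pd.concat(prof_parts, ignore_index=True)
    observed = _observed_slot_mask(samples, mode)
    distinct = observed.groupby(level=["participant_id", "date"]).sum().astype(int)
    all_days = df.groupby(["participant_id", "date"]).size().index
    distinct = distinct.reindex(all_days, fill_value=0)
    profiles = pd.DataFrame(
        {
            "participant_id": [k[0] for k in distinct.index],
            "date": [k[1] for k in distinct.index],
            "expected_slots": SLOTS_PER_DAY,
            "observed_distinct_hours": distinct.values,
            "included": distinct.values >= min_distinct_hours,
        }
    )
    included = set(
        zip(profiles.loc[profiles["included"], "participant_id"], profiles.loc[profiles["included"], "date"])
    )
    keep = [
        (pid, d) in included
        for pid, d in zip(df["participant_id"], df["date"])
    ]
    filtered = samples.loc[keep].reset_index(drop=True)
    return filtered, profiles


def missingness_report(
    samples: pd.DataFrame,
    day_profiles: pd.DataFrame,
    mode: str = "joint",
) -> MissingnessStats:
    """Missing-sample accounting over included days.

    ``expected = 12 * included days``; a sample is observed when its slot
    qualifies under ``mode`` (see :func:`filter_days`); rates are percentages
    rounded half-up to 2 decimals.
    """
    included = day_profiles[day_profiles["included"]]
    n_days = len(included)
    if n_days == 0:
        raise EmptyCohortError("no included days; missingness rates undefined")
    expected = SLOTS_PER_DAY * n_days
    if samples.empty:
        observed_n = 0
    else:
        observed = _observed_slot_mask(samples, mode)
        included_keys = set(zip(included["participant_id"], included["date"]))
        keys = [(k[0], k[1]) in included_keys for k in observed.index]
        observed_n = int(observed[keys].sum())
    missing = expected - observed_n
    return MissingnessStats(
        n_days=n_days,
        expected_samples=expected,
        missing_samples=missing,
        missing_rate_pct=_round_pct(missing, expected),
        valid_rate_pct=_round_pct(observed_n, expected),
    )
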