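import numpy as np
import pandas as pd
import pytest

from circarhythm import apply_missingness, default_config, filter_days, generate_cohort

SLOT_GRID = np.arange(0.0, 24.0, 2.0)


def make_samples(rows):
    """Build a sample table from (pid, iso_timestamp, week, slot, metric, value)."""
    df = pd.DataFrame(
        rows,
        columns=["participant_id", "timestamp", "gestational_week", "slot_hour", "metric", "value"],
    )
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["value"] = df["value"].astype(float)
    return df


def day_rows(pid, day, metric, values, week=14, slots=SLOT_GRID):
    """Rows for one participant-day; values aligned with slots, NaN = missing."""
    return [
        (pid, f"{day}T{int(s):02d}:00", week, int(s), metric, v)
        for s, v in zip(slots, values)
    ]


@pytest.fixture(scope="session")
def slot_grid():
    return SLOT_GRID.copy()


@pytest.fixture(scope="session")
def small_hr_cohort():
    """Six-participant HR cohort, weeks 14-18, realistic missingness, day-filtered."""
    cfg = default_config("HR", seed=11).with_(n_participants=6, week_end=18)
    samples, truth = generate_cohort(cfg)
    sparse = apply_missingness(samples, cfg.missing_rate, seed=12)
    filtered, profiles = filter_days(sparse)
    return {"samples": samples, "sparse": sparse, "filtered": filtered,
            "profiles": profiles, "truth": truth, "config": cfg}


@pytest.fixture(scope="session")
def default_hr_cohort():
    """The full default HR study cohort: 30 participants, weeks 14-40, 36.12% MCAR."""
    cfg = default_config("HR", seed=1)
    samples, truth = generate_cohort(cfg)
    sparse = apply_missingness(samples, cfg.missing_rate, seed=1001)
    filtered, profiles = filter_days(sparse)
    return {"sparse": sparse, "filtered": filtered, "profiles": profiles,
            "truth": truth, "config": cfg}
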