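import numpy as np
import pandas as pd
import pytest

from circarhythm import imputation as imp
from circarhythm.imputation import (
    ImputerHyperparams,
    baseline_impute,
    build_sequences,
    impute,
    pair_matrix,
    train_imputer,
    user_level_split,
)
from circarhythm.synthetic import default_config, generate_cohort

from conftest import day_rows, make_samples


def _series(pid, values, start_slot=0, day="2023-01-02"):
    """A single participant-day run starting at start_slot (values may be NaN)."""
    slots = [start_slot + 2 * i for i in range(len(values))]
    rows = [
        (pid, f"{day}T{s:02d}:00", 14, s, "HR", v)
        for s, v in zip(slots, values)
    ]
    return make_samples(rows)


class TestBuildSequences:
    def test_six_observed_slots_give_no_pairs(self):
        pairs = build_sequences(_series("P01", [70.0] * 6))
        assert pairs.empty

    def test_ten_consecutive_slots_give_four_pairs(self):
        pairs = build_sequences(_series("P01", list(range(70, 80))))
        assert len(pairs) == 4  # 10 - (6+1) + 1
        x, y = pair_matrix(pairs)
        np.testing.assert_allclose(x[0], np.arange(70, 76))
        np.testing.assert_allclose(y, np.arange(76, 80))

    def test_missing_slot_breaks_runs(self):
        values = [70.0, 71, 72, 73, np.nan, 75, 76, 77, 78, 79]
        pairs = build_sequences(_series("P01", values))
        assert pairs.empty  # runs of length 4 and 5 are both too short

    def test_windows_cross_midnight_on_consecutive_days(self):
        rows = day_rows("P01", "2023-01-02", "HR", list(np.arange(70.0, 82.0))) + day_rows(
            "P01", "2023-01-03", "HR", list(np.arange(82.0, 94.0))
        )
        pairs = build_sequences(make_samples(rows))
        assert len(pairs) == 24 - 6  # one unbroken 24-slot run

    def test_gap_in_grid_breaks_runs(self):
        rows = day_rows("P01", "2023-01-02", "HR", [70.0] * 12) + day_rows(
            "P01", "2023-01-04", "HR", [70.0] * 12
        )
        pairs = build_sequences(make_samples(rows))
        assert len(pairs) == 2 * (12 - 6)

    def test_seq_len_validation(self):
        with pytest.raises(ValueError):
            build_sequences(_series("P01", [70.0] * 8), seq_len=0)


class TestSplit:
    def _pairs(self, n_participants):
        frames = [
            build_sequences(_series(f"P{i:02d}", list(np.arange(70.0, 80.0))))
            for i in range(n_participants)
        ]
        return pd.concat(frames, ignore_index=True)

    def test_eighty_twenty_participant_count(self):
        train, test = user_level_split(self._pairs(10), seed=0)
        assert train["participant_id"].nunique() == 8
        assert test["participant_id"].nunique() == 2

    def test_no_participant_overlap(self):
        train, test = user_level_split(self._pairs(7), seed=4)
        assert not set(train["participant_id"]) & set(test["participant_id"])

    def test_same_seed_same_partition(self):
        pairs = self._pairs(9)
        t1, _ = user_level_split(pairs, seed=2)
        t2, _ = user_level_split(pairs, seed=2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_single_participant_rejected(self):
        with pytest.raises(ValueError):
            user_level_split(self._pairs(1))


class TestTraining:
    def test_default_hyperparams_follow_study_protocol(self):
        hp = ImputerHyperparams()
        assert (hp.units, hp.seq_len, hp.epochs, hp.batch_size, hp.train_fraction) == (
            50, 6, 100, 5, 0.8,
        )

    def test_scaling_round_trip(self):
        from circarhythm.imputation import ImputerModel
        from circarhythm.lstm import LSTMRegressor

        model = ImputerModel(
            net=LSTMRegressor(4, 3, rng=0), metric="HR", seq_len=6,
            x_min=40.0, x_max=110.0,
        )
        values = np.linspace(40, 110, 31)
        np.testing.assert_allclose(model.unscale(model.scale(values)), values, atol=1e-9)

    def test_constant_series_learnability(self):
        c = 70.0
        frames = [
            build_sequences(_series(f"P{i:02d}", [c] * 12)) for i in range(4)
        ]
        pairs = pd.concat(frames, ignore_index=True)
        hp = ImputerHyperparams(epochs=30, patience=30)
        model = train_imputer(pairs, hp, seed=0)
        preds = model.predict(np.full((3, 6), c))
        assert np.all(np.abs(preds - c) <= 0.05 * c)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_imputer(build_sequences(_series("P01", [70.0] * 6)))

    def test_training_is_seeded(self):
        frames = [
            build_sequences(_series(f"P{i:02d}", list(np.arange(70.0 + i, 82.0 + i))))
            for i in range(5)
        ]
        pairs = pd.concat(frames, ignore_index=True)
        hp = ImputerHyperparams(epochs=3, patience=3)
        m1 = train_imputer(pairs, hp, seed=3)
        m2 = train_imputer(pairs, hp, seed=3)
        window = np.linspace(70, 80, 6)[None, :]
        assert m1.predict(window)[0] == m2.predict(window)[0]


@pytest.fixture(scope="module")
def trained():
    cfg = default_config("HR", seed=21).with_(
        n_participants=6, week_end=16, noise_sd=1.0, missing_rate=0.0
    )
    samples, _ = generate_cohort(cfg)
    pairs = build_sequences(samples)
    hp = ImputerHyperparams(epochs=15, patience=15)
    return train_imputer(pairs, hp, seed=21), samples


class TestImpute:
    def test_complete_table_unchanged(self, trained):
        model, samples = trained
        out, report = impute(model, samples)
        pd.testing.assert_frame_equal(out.drop(columns="imputed"), samples)
        assert report.n_missing_before == 0
        assert report.fraction_unimputed == 0.0

    def test_single_gap_filled_others_bitwise_identical(self, trained):
        model, samples = trained
        holed = samples.copy()
        target = holed.index[20]  # inside a long observed run
        holed.loc[target, "value"] = np.nan
        out, report = impute(model, holed)
        assert report.n_imputed == 1
        assert out.loc[target, "imputed"]
        assert np.isfinite(out.loc[target, "value"])
        others = out.index != target
        np.testing.assert_array_equal(
            out.loc[others, "value"].to_numpy(), samples.loc[others, "value"].to_numpy()
        )

    def test_insufficient_history_left_missing(self, trained):
        model, samples = trained
        holed = samples.copy()
        first_day = holed[holed["participant_id"] == "P01"].index[:12]
        holed.loc[first_day[2], "value"] = np.nan  # only 2 slots of history
        out, report = impute(model, holed)
        assert np.isnan(out.loc[first_day[2], "value"])
        assert report.n_unimputable >= 1

    def test_report_consistency_on_sparse_cohort(self, trained, default_hr_cohort):
        model, _ = trained
        filtered = default_hr_cohort["filtered"]
        sub = filtered[filtered["participant_id"].isin(["P01", "P02", "P03"])]
        out, report = impute(model, sub)
        assert report.n_missing_before == int(sub["value"].isna().sum())
        assert report.n_imputed + report.n_unimputable == report.n_missing_before
        assert report.n_imputed == int(out["imputed"].sum())
        assert 0.0 <= report.fraction_unimputed <= 1.0


class TestBaselines:
    def test_linear_interp_hand_example(self):
        samples = _series("P01", [70.0, np.nan, 74.0, 75.0, 76.0, 77.0, 78.0])
        out = baseline_impute(samples, "linear_interp")
        assert out.loc[1, "value"] == pytest.approx(72.0)
        assert out.loc[1, "imputed"]

    def test_constant_series_filled_exactly(self):
        values = [70.0, 70, np.nan, 70, 70, np.nan, 70, 70]
        for method in ("slot_mean", "linear_interp"):
            out = baseline_impute(_series("P01", values), method)
            np.testing.assert_allclose(out["value"], 70.0)

    def test_slot_mean_uses_participant_slot_history(self):
        rows = (
            day_rows("P01", "2023-01-02", "HR", [60 + s for s in range(12)])
            + day_rows("P01", "2023-01-03", "HR", [64 + s for s in range(12)])
        )
        samples = make_samples(rows)
        samples.loc[14, "value"] = np.nan  # day 2, slot_hour 4
        out = baseline_impute(samples, "slot_mean")
        # only day 1 still observes slot 4, so the fill is that value (62)
        assert out.loc[14, "value"] == pytest.approx(62.0)

    def test_observed_values_untouched(self, default_hr_cohort):
        filtered = default_hr_cohort["filtered"]
        sub = filtered[filtered["participant_id"] == "P04"]
        observed = sub["value"].notna()
        for method in ("slot_mean", "linear_interp"):
            out = baseline_impute(sub, method)
            np.testing.assert_array_equal(
                out.loc[observed, "value"].to_numpy(), sub.loc[observed, "value"].to_numpy()
            )
            assert not out.loc[observed, "imputed"].any()

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            baseline_impute(_series("P01", [70.0] * 8), "cubic")
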