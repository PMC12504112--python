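import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circarhythm.cosinor import OMEGA, fit_cosinor, peak_hour_to_acrophase
from circarhythm.population import (
    ParticipantWeekRhythm,
    circular_sd_hours,
    interindividual_sd,
    loocv_week,
    population_week_rhythm,
    weekly_participant_rhythm,
)

from conftest import day_rows, make_samples

GRID = np.arange(0.0, 24.0, 2.0)


def cosine_day(mesor, beta, gamma):
    return mesor + beta * np.cos(OMEGA * GRID) + gamma * np.sin(OMEGA * GRID)


def rhythm_from(mesor, amplitude, acrophase, pid="P01", week=14):
    """Construct a ParticipantWeekRhythm with exact coefficients."""
    beta = amplitude * np.cos(acrophase)
    gamma = -amplitude * np.sin(acrophase)
    coeffs = np.array([mesor, beta, gamma])
    values = mesor + amplitude * np.cos(OMEGA * GRID + acrophase)
    return ParticipantWeekRhythm(
        participant_id=pid,
        metric="HR",
        gestational_week=week,
        coefficients=coeffs,
        n_days=1,
        mean_rss=0.0,
        slot_hours=GRID.copy(),
        slot_means=values,
    )


def samples_for(days, pid="P01", week=14):
    rows = []
    for i, values in enumerate(days):
        rows += day_rows(pid, f"2023-01-{i + 2:02d}", "HR", values, week=week)
    return make_samples(rows)


class TestWeeklyParticipantRhythm:
    def test_single_day_equals_daily_fit(self):
        y = cosine_day(70.0, 3.0, 0.0)
        rhythm = weekly_participant_rhythm(samples_for([y]))
        fit = fit_cosinor(GRID, y, 1)
        np.testing.assert_allclose(rhythm.coefficients, fit.coefficients, atol=1e-12)
        assert rhythm.n_days == 1

    def test_identical_days_average_is_idempotent(self):
        y = cosine_day(70.0, 3.0, 1.0)
        one = weekly_participant_rhythm(samples_for([y]))
        two = weekly_participant_rhythm(samples_for([y, y]))
        np.testing.assert_allclose(one.coefficients, two.coefficients, atol=1e-12)
        assert two.n_days == 2

    def test_hand_coefficient_average(self):
        # days with beta {3, 5}, gamma 0, MESOR {70, 74} -> (72, 4, 0)
        days = [cosine_day(70.0, 3.0, 0.0), cosine_day(74.0, 5.0, 0.0)]
        rhythm = weekly_participant_rhythm(samples_for(days))
        np.testing.assert_allclose(rhythm.coefficients, [72.0, 4.0, 0.0], atol=1e-9)
        assert rhythm.amplitude == pytest.approx(4.0)
        assert rhythm.acrophase == pytest.approx(0.0, abs=1e-9)

    def test_mixed_participants_rejected(self):
        bad = samples_for([cosine_day(70, 3, 0)])
        bad2 = samples_for([cosine_day(70, 3, 0)], pid="P02")
        import pandas as pd

        with pytest.raises(ValueError):
            weekly_participant_rhythm(pd.concat([bad, bad2]))


class TestPopulationWeekRhythm:
    def test_identical_participants_collapse(self):
        rhythms = [rhythm_from(75.0, 3.0, -1.0, pid=f"P{i}") for i in range(4)]
        pop = population_week_rhythm(rhythms)
        assert pop.k == 4
        assert pop.mesor == pytest.approx(75.0)
        assert pop.amplitude == pytest.approx(3.0)
        assert pop.mesor_sd == pytest.approx(0.0, abs=1e-12)
        assert pop.amplitude_sd == pytest.approx(0.0, abs=1e-12)
        assert pop.acrophase_sd_hours == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(pop.ci_low, pop.mean_curve, atol=1e-9)
        np.testing.assert_allclose(pop.ci_high, pop.mean_curve, atol=1e-9)

    def test_mesor_mean_amplitude_preserved(self):
        rhythms = [rhythm_from(70.0, 3.0, 0.5), rhythm_from(80.0, 3.0, 0.5, pid="P02")]
        pop = population_week_rhythm(rhythms)
        assert pop.mesor == pytest.approx(75.0)
        assert pop.amplitude == pytest.approx(3.0)
        assert pop.acrophase == pytest.approx(0.5)

    def test_symmetric_acrophases_attenuate(self):
        delta_hours = 3.0
        delta = delta_hours * OMEGA
        rhythms = [
            rhythm_from(70.0, 4.0, -delta),
            rhythm_from(70.0, 4.0, +delta, pid="P02"),
        ]
        pop = population_week_rhythm(rhythms)
        assert pop.acrophase == pytest.approx(0.0, abs=1e-9)
        assert pop.amplitude == pytest.approx(4.0 * np.cos(delta), abs=1e-9)

    def test_hierarchy_collapses_to_plain_fit(self):
        # one participant, one day: population == weekly == fit_cosinor
        y = cosine_day(75.0, 2.0, -1.5)
        rhythm = weekly_participant_rhythm(samples_for([y]))
        pop = population_week_rhythm([rhythm])
        fit = fit_cosinor(GRID, y, 1)
        np.testing.assert_allclose(pop.coefficients, fit.coefficients, atol=1e-12)
        assert pop.p_pooled == pytest.approx(fit.p_zero_amplitude)

    def test_ci_band_contains_mean_curve(self, small_hr_cohort):
        from circarhythm.imputation import baseline_impute
        from circarhythm.population import analyze_cohort

        filled = baseline_impute(small_hr_cohort["filtered"], "linear_interp")
        analysis = analyze_cohort(filled, run_loocv=False)
        for pop in analysis["population"].values():
            assert (pop.ci_low <= pop.mean_curve + 1e-12).all()
            assert (pop.ci_high >= pop.mean_curve - 1e-12).all()
            assert 0.0 <= pop.p_pooled <= 1.0


class TestInterindividualSD:
    def test_identical_participants_zero_sd(self):
        rhythms = [rhythm_from(70.0, 3.0, 1.0, pid=f"P{i}") for i in range(3)]
        sds = interindividual_sd(rhythms)
        assert sds["mesor_sd"] == pytest.approx(0.0, abs=1e-12)
        assert sds["acrophase_sd_hours"] == pytest.approx(0.0, abs=1e-6)

    def test_hand_mesor_sd(self):
        rhythms = [rhythm_from(70.0, 3.0, 0.0), rhythm_from(80.0, 3.0, 0.0, pid="P02")]
        assert interindividual_sd(rhythms)["mesor_sd"] == pytest.approx(np.sqrt(50.0))

    def test_hand_circular_sd(self):
        # acrophases +-pi/6: R = cos(pi/6), sd = sqrt(-2 ln R) = 0.5363 rad = 2.049 h
        rhythms = [
            rhythm_from(70.0, 3.0, -np.pi / 6),
            rhythm_from(70.0, 3.0, +np.pi / 6, pid="P02"),
        ]
        sd_hours = interindividual_sd(rhythms)["acrophase_sd_hours"]
        assert sd_hours == pytest.approx(np.sqrt(-2 * np.log(np.cos(np.pi / 6))) * 24 / (2 * np.pi))
        assert sd_hours == pytest.approx(2.049, abs=2e-3)

    def test_requires_two_participants(self):
        with pytest.raises(ValueError):
            interindividual_sd([rhythm_from(70.0, 3.0, 0.0)])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(rotation=st.floats(-np.pi, np.pi, allow_nan=False))
    def test_circular_sd_rotation_invariant(self, rotation):
        angles = np.array([-0.4, 0.1, 0.9, 2.2])
        assert circular_sd_hours(angles + rotation) == pytest.approx(
            circular_sd_hours(angles), abs=1e-9
        )


class TestLoocv:
    def test_identical_participants_zero_sd(self):
        rhythms = [rhythm_from(70.0, 3.0, 1.0, pid=f"P{i}") for i in range(4)]
        summary = loocv_week(rhythms)
        assert summary.k == 4
        for parameter in ("mesor", "amplitude", "peak_hour"):
            assert summary.sd[parameter] == pytest.approx(0.0, abs=1e-6)
            assert len(summary.estimates[parameter]) == 4

    def test_exactly_k_refits_and_jackknife_consistency(self):
        rng = np.random.default_rng(17)
        rhythms = [
            rhythm_from(72.0 + rng.normal(0, 3), 3.0, 0.3, pid=f"P{i}")
            for i in range(5)
        ]
        full = population_week_rhythm(rhythms)
        summary = loocv_week(rhythms)
        assert summary.k == 5
        between_sd = np.std([r.mesor for r in rhythms], ddof=1)
        assert abs(summary.mean["mesor"] - full.mesor) <= between_sd / np.sqrt(5)

    def test_jackknife_identity_exact(self):
        rng = np.random.default_rng(8)
        rhythms = [
            rhythm_from(70 + rng.normal(0, 5), 2 + rng.normal(0, 0.5), rng.normal(0, 1), pid=f"P{i}")
            for i in range(6)
        ]
        full = population_week_rhythm(rhythms).coefficients
        loo_vectors = [
            population_week_rhythm(rhythms[:i] + rhythms[i + 1:]).coefficients
            for i in range(6)
        ]
        np.testing.assert_allclose(np.mean(loo_vectors, axis=0), full, atol=1e-12)

    def test_removing_mean_participant_changes_nothing(self):
        others = [rhythm_from(70.0, 3.0, 0.0), rhythm_from(80.0, 5.0, 0.0, pid="P02")]
        neutral = rhythm_from(75.0, 4.0, 0.0, pid="P03")  # equals the others' mean
        with_neutral = population_week_rhythm(others + [neutral])
        without = population_week_rhythm(others)
        np.testing.assert_allclose(with_neutral.coefficients, without.coefficients, atol=1e-12)

    def test_requires_two_participants(self):
        with pytest.raises(ValueError):
            loocv_week([rhythm_from(70.0, 3.0, 0.0)])
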