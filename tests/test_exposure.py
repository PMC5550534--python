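"""Intake arithmetic, risk metrics, and cohort-level exposure."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from hgintake.exposure import (MealEvent, MealSchedule, Subject, ThresholdSet,
                               cohort_exposure, daily_intake, edi, ewi,
                               exceedance_fraction, hazard_index, meal_intake,
                               mehg_from_thg, percent_ptwi,
                               schedule_total_intake, subject_exposure,
                               weekly_intake, weekly_mass_equivalent)

# -- canonical intervention numbers, fixed by the fried reference means ------
TOTAL_UG = 105.212
DAILY_UG = 10.5212
WEEKLY_UG = 52.606


class TestMealIntake:
    @pytest.mark.parametrize("conc,mass,expected", [
        (0.109, 0.150, 16.35),   # one hoki portion
        (0.0, 0.5, 0.0),
        (0.055, 0.166, 9.13),    # one coalfish portion
    ])
    def test_known_products(self, conc, mass, expected):
        assert meal_intake(conc, mass) == pytest.approx(expected)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            meal_intake(-0.1, 0.1)
        with pytest.raises(ValueError):
            meal_intake(0.1, -0.1)


class TestScheduleIntake:
    def test_intervention_total_daily_weekly(self, intervention_schedule,
                                             conc_lookup):
        total = schedule_total_intake(intervention_schedule, conc_lookup)
        assert total == pytest.approx(TOTAL_UG)
        assert round(total) == 105
        assert daily_intake(total, intervention_schedule) == pytest.approx(DAILY_UG)
        assert weekly_intake(total, intervention_schedule) == pytest.approx(WEEKLY_UG)

    def test_empty_schedule_total_is_zero(self, conc_lookup):
        sched = MealSchedule([], 1)
        assert schedule_total_intake(sched, conc_lookup) == 0.0
        with pytest.raises(ValueError):
            daily_intake(0.0, sched)

    def test_single_event_equals_meal_intake(self, conc_lookup):
        sched = MealSchedule([MealEvent(3, "g_morhua", "fried", 0.173)], 1)
        assert schedule_total_intake(sched, conc_lookup) == pytest.approx(
            meal_intake(conc_lookup[("g_morhua", "fried")], 0.173))

    def test_unknown_species_named_in_error(self, intervention_schedule):
        with pytest.raises(KeyError, match="m_magellanicus"):
            schedule_total_intake(intervention_schedule,
                                  {("g_morhua", "fried"): 0.06})

    def test_calendar_day_division_flag(self, intervention_schedule,
                                        conc_lookup):
        total = schedule_total_intake(intervention_schedule, conc_lookup)
        assert daily_intake(total, intervention_schedule,
                            calendar_days=True) == pytest.approx(total / 14)

    @given(st.lists(
        st.tuples(st.integers(1, 14), st.floats(0.0, 1.0), st.floats(0.0, 0.3)),
        min_size=1, max_size=30))
    def test_conservation_and_linearity(self, raw_events):
        conc = {("sp", "fried"): 0.0}
        events, lookup = [], {}
        for i, (day, c, m) in enumerate(raw_events):
            sid = f"sp{i}"
            lookup[(sid, "fried")] = c
            events.append(MealEvent(day, sid, "fried", m))
        sched = MealSchedule(events, 2)
        total = schedule_total_intake(sched, lookup)
        assert total == pytest.approx(
            sum(meal_intake(lookup[(e.species_id, e.state)], e.mass)
                for e in events))
        doubled = MealSchedule(
            [MealEvent(e.day, e.species_id, e.state, 2 * e.mass)
             for e in events], 2)
        assert schedule_total_intake(doubled, lookup) == pytest.approx(
            2 * total, rel=1e-12, abs=1e-9)


class TestNormalization:
    def test_ptwi_mass_equivalence_at_70kg(self):
        assert ewi(112.0, 70.0) == pytest.approx(1.6)
        assert weekly_mass_equivalent(1.6, 70.0) == pytest.approx(0.112)

    def test_inferred_mean_body_weight_reproduces_cohort_ewi(self):
        assert ewi(WEEKLY_UG, 85.0) == pytest.approx(0.619, abs=5e-4)

    @given(st.floats(0.0, 1e4), st.floats(1.0, 300.0))
    def test_ewi_round_trip(self, weekly, bw):
        assert ewi(weekly, bw) * bw == pytest.approx(weekly, rel=1e-12,
                                                     abs=1e-9)

    def test_nonpositive_body_weight_rejected(self):
        for fn in (lambda: ewi(1.0, 0.0), lambda: edi(1.0, -5.0),
                   lambda: weekly_mass_equivalent(1.0, 0.0)):
            with pytest.raises(ValueError):
                fn()


class TestRiskMetrics:
    def test_reported_hazard_and_risk_indices(self):
        assert round(hazard_index(0.62, 1.6), 2) == 0.39
        assert round(percent_ptwi(1.34, 1.6)) == 84

    def test_limit_attained_is_exactly_100pct(self):
        assert percent_ptwi(1.6, 1.6) == pytest.approx(100.0)
        assert hazard_index(1.6, 1.6) == pytest.approx(1.0)

    @given(st.floats(0.0, 100.0), st.floats(0.01, 10.0))
    def test_percent_is_100_times_hazard(self, ewi_value, ptwi):
        assert percent_ptwi(ewi_value, ptwi) == pytest.approx(
            100 * hazard_index(ewi_value, ptwi))

    def test_nonpositive_ptwi_rejected(self):
        with pytest.raises(ValueError):
            hazard_index(0.5, 0.0)

    @pytest.mark.parametrize("thg,fraction,expected", [
        (100.0, 1.0, 100.0), (100.0, 0.9, 90.0)])
    def test_mehg_fraction(self, thg, fraction, expected):
        assert mehg_from_thg(thg, fraction) == pytest.approx(expected)

    @given(st.floats(0.0, 100.0), st.floats(0.0, 100.0),
           st.floats(0.01, 1.0))
    def test_mehg_fraction_linearity(self, a, b, fraction):
        assert mehg_from_thg(a + b, fraction) == pytest.approx(
            mehg_from_thg(a, fraction) + mehg_from_thg(b, fraction),
            rel=1e-12, abs=1e-9)

    def test_fraction_outside_unit_interval_rejected(self):
        for bad in (0.0, 1.5, -0.1):
            with pytest.raises(ValueError):
                mehg_from_thg(1.0, bad)


class TestSubject:
    def test_body_weight_derived_from_bmi_and_height(self):
        s = Subject("a", bmi=26.9, height=1.77)
        assert s.body_weight == pytest.approx(26.9 * 1.77**2)

    def test_inconsistent_routes_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            Subject("a", body_weight=70.0, bmi=26.9, height=1.77)

    def test_consistent_routes_accepted(self):
        Subject("a", body_weight=84.3, bmi=26.9, height=1.77)


class TestCohortExposure:
    def test_uniform_cohort_is_degenerate(self, intervention_schedule,
                                          conc_lookup):
        cohort = [Subject(f"s{i}", body_weight=80.0) for i in range(5)]
        results, summary = cohort_exposure(cohort, intervention_schedule,
                                           conc_lookup)
        ewis = {r.ewi for r in results}
        assert len(ewis) == 1
        assert summary["ewi"]["mean"] == pytest.approx(results[0].ewi)

    def test_body_weight_extremes_bracket_reported_ewi_range(
            self, intervention_schedule, conc_lookup):
        # inverting the published EWI range 0.36-0.96 against 52.6 μg/week
        cohort = [Subject("light", body_weight=54.8),
                  Subject("heavy", body_weight=146.1)]
        results, _ = cohort_exposure(cohort, intervention_schedule,
                                     conc_lookup)
        assert round(results[0].ewi, 2) == 0.96
        assert round(results[1].ewi, 2) == 0.36

    def test_summary_matches_per_subject_loop_oracle(
            self, intervention_schedule, conc_lookup):
        from hgintake.simulate import GeneratorConfig, generate_cohort
        cohort = generate_cohort(GeneratorConfig(seed=5, n_subjects=40))
        results, summary = cohort_exposure(cohort, intervention_schedule,
                                           conc_lookup)
        # independent loop: recompute every subject from scratch
        total = schedule_total_intake(intervention_schedule, conc_lookup)
        expected = sorted(total / 2 / s.body_weight for s in cohort)
        got = sorted(r.ewi for r in results)
        assert got == pytest.approx(expected)
        assert summary["ewi"]["mean"] == pytest.approx(
            sum(expected) / len(expected))

    def test_result_invariants(self, intervention_schedule, conc_lookup):
        res = subject_exposure(Subject("x", body_weight=70.0),
                               intervention_schedule, conc_lookup)
        assert res.pct_ptwi == pytest.approx(100 * res.hazard_index)
        assert res.ewi == pytest.approx(res.weekly_intake / 70.0)
        assert res.exceeds_nrc == (res.ewi > 0.7)
        assert not res.exceeds_ptwi

    def test_mehg_fraction_scales_risk_not_intake(self, intervention_schedule,
                                                  conc_lookup):
        full = subject_exposure(Subject("x", body_weight=70.0),
                                intervention_schedule, conc_lookup,
                                ThresholdSet())
        scaled = subject_exposure(Subject("x", body_weight=70.0),
                                  intervention_schedule, conc_lookup,
                                  ThresholdSet(mehg_fraction=0.9))
        assert scaled.total_intake == pytest.approx(full.total_intake)
        assert scaled.ewi == pytest.approx(0.9 * full.ewi)

    def test_empty_cohort_rejected(self, intervention_schedule, conc_lookup):
        with pytest.raises(ValueError, match="empty"):
            cohort_exposure([], intervention_schedule, conc_lookup)


class TestExceedance:
    def _results(self, ewis, intervention_schedule, conc_lookup):
        total = schedule_total_intake(intervention_schedule, conc_lookup)
        weekly = weekly_intake(total, intervention_schedule)
        cohort = [Subject(f"s{i}", body_weight=weekly / e)
                  for i, e in enumerate(ewis)]
        results, _ = cohort_exposure(cohort, intervention_schedule,
                                     conc_lookup)
        return results

    def test_bounds(self, intervention_schedule, conc_lookup):
        results = self._results([0.4, 0.6, 0.8], intervention_schedule,
                                conc_lookup)
        assert exceedance_fraction(results, 0.1) == 1.0
        assert exceedance_fraction(results, 5.0) == 0.0

    def test_strict_boundary_and_inclusive_flag(self, intervention_schedule,
                                                conc_lookup):
        results = self._results([0.7], intervention_schedule, conc_lookup)
        limit = results[0].ewi
        assert exceedance_fraction(results, limit) == 0.0
        assert exceedance_fraction(results, limit, inclusive=True) == 1.0

    def test_monotone_nonincreasing_in_limit(self, intervention_schedule,
                                             conc_lookup):
        results = self._results([0.3, 0.5, 0.7, 0.9, 1.1],
                                intervention_schedule, conc_lookup)
        limits = [0.0, 0.4, 0.6, 0.8, 1.0, 2.0]
        fracs = [exceedance_fraction(results, L) for L in limits]
        assert all(0.0 <= f <= 1.0 for f in fracs)
        assert fracs == sorted(fracs, reverse=True)

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            exceedance_fraction([], 0.7)
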