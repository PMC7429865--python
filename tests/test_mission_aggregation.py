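"""Daily budgets, mission totals, deltas and the concurrent-heat scenario."""

import pytest
from hypothesis import given, strategies as st

from crewmet import (
    CrewMember,
    ExercisePrescription,
    MissionScenario,
    concurrent_exercise_heat,
    daily_budget,
    mission_totals,
    scenario_delta,
)
from crewmet.resting_metabolism import resting_profile

from .reference_values import (
    CONCURRENT_HEAT_LARGE_CREW_J_S,
    DAY_REST_CO2_L,
    DAY_REST_HEAT_MJ,
    DAY_REST_O2_L,
    DAY_REST_TEE_MJ,
    GAS_HEAT_RATIO_PCT,
    STATURES,
    SWEAT_RATE_ML_MIN,
    TEE_RATIO_PCT,
)


def crew(stature: float, n: int = 4) -> tuple[CrewMember, ...]:
    return tuple(CrewMember(stature=stature) for _ in range(n))


def test_no_exercise_day_reference_rows(five_members):
    """Resting-day TEE/O2/CO2/heat match the published 24-h table: TEE,
    O2 and CO2 carry the PAL factor, heat is basal Mprod alone."""
    for m, tee, o2, co2, heat in zip(
        five_members, DAY_REST_TEE_MJ, DAY_REST_O2_L, DAY_REST_CO2_L,
        DAY_REST_HEAT_MJ,
    ):
        day = daily_budget(m)
        assert day.tee == pytest.approx(tee, abs=0.06)
        assert day.o2 == pytest.approx(o2, abs=0.6)
        assert day.co2 == pytest.approx(co2, abs=0.6)
        assert day.heat == pytest.approx(heat, abs=0.06)
        assert not day.exercising
        assert day.co2 < day.o2  # RER < 1 throughout


def test_exercise_day_dominates_rest_day(five_members, prescription):
    for m in five_members:
        rest = daily_budget(m)
        ex = daily_budget(m, prescription=prescription)
        for field in ("tee", "o2", "co2", "heat", "water"):
            assert getattr(ex, field) > getattr(rest, field)


def test_zero_bout_prescription_equals_rest_day(five_members):
    rx = ExercisePrescription(bouts_per_day=0)
    for m in five_members[:2]:
        assert daily_budget(m, prescription=rx) == daily_budget(m)


def test_consistent_heat_variant_applies_pal():
    m = CrewMember(stature=1.70)
    prof = resting_profile(m)
    paper = daily_budget(m, prof, heat_variant="paper")
    consistent = daily_budget(m, prof, heat_variant="consistent")
    assert consistent.heat == pytest.approx(paper.heat * prof.pal, rel=1e-12)
    with pytest.raises(ValueError, match="heat_variant"):
        daily_budget(m, heat_variant="bogus")


def test_mission_totals_linear_in_duration_and_crew(prescription):
    base = mission_totals(MissionScenario(crew(1.70), 30, prescription))
    double_t = mission_totals(MissionScenario(crew(1.70), 60, prescription))
    double_n = mission_totals(MissionScenario(crew(1.70, 8), 30, prescription))
    for field in ("energy", "o2", "co2", "heat", "water"):
        assert getattr(double_t, field) == pytest.approx(
            2 * getattr(base, field), rel=1e-12)
        assert getattr(double_n, field) == pytest.approx(
            2 * getattr(base, field), rel=1e-12)


def test_unit_duration_equals_crew_sum_of_daily_budgets():
    scenario = MissionScenario(crew(1.60), 1)
    totals = mission_totals(scenario)
    day = daily_budget(scenario.roster[0])
    assert totals.energy == pytest.approx(4 * day.tee, rel=1e-12)
    assert totals.o2 == pytest.approx(4 * day.o2, rel=1e-12)
    assert totals.water == pytest.approx(4 * day.water, rel=1e-12)


def test_strict_schedule_scales_exercise_increment(prescription):
    """6 d/week pro rata: the exercise increment shrinks by 6/7."""
    rest = mission_totals(MissionScenario(crew(1.70), 30))
    daily = mission_totals(MissionScenario(crew(1.70), 30, prescription))
    strict = mission_totals(MissionScenario(crew(1.70), 30, prescription),
                            strict_schedule=True)
    assert strict.energy == pytest.approx(
        rest.energy + (6 / 7) * (daily.energy - rest.energy), rel=1e-12)
    assert rest.energy < strict.energy < daily.energy


def test_scenario_delta_antisymmetry(prescription):
    a = mission_totals(MissionScenario(crew(1.50), 30))
    b = mission_totals(MissionScenario(crew(1.90), 30, prescription))
    d = scenario_delta(a, b)
    assert d.energy == pytest.approx(b.energy - a.energy, rel=1e-12)
    zero = scenario_delta(a, a)
    assert (zero.energy, zero.o2, zero.co2, zero.heat, zero.water) == (
        0.0, 0.0, 0.0, 0.0, 0.0)


def test_body_size_ratios_match_abstract_levels():
    """Stature 1.50 -> 1.90 m alone raises daily TEE by ~44% and O2, CO2
    and heat by ~60% (within one percentage point)."""
    small = daily_budget(CrewMember(stature=1.50))
    large = daily_budget(CrewMember(stature=1.90))
    assert 100 * (large.tee / small.tee - 1) == pytest.approx(TEE_RATIO_PCT, abs=1.0)
    for field in ("o2", "co2", "heat"):
        pct = 100 * (getattr(large, field) / getattr(small, field) - 1)
        assert pct == pytest.approx(GAS_HEAT_RATIO_PCT, abs=1.0)


def test_per_person_quantities_monotone_in_stature(five_members, prescription):
    for budget_kw in ({}, {"prescription": prescription}):
        budgets = [daily_budget(m, **budget_kw) for m in five_members]
        for field in ("tee", "o2", "co2", "heat", "water"):
            vals = [getattr(b, field) for b in budgets]
            assert vals == sorted(vals) and len(set(vals)) == len(vals)


def test_concurrent_exercise_heat_worst_case():
    """One 1.90 m member exercising plus three resting: ~1,388 J/s (the
    published figure uses inputs rounded to table precision)."""
    total = concurrent_exercise_heat(crew(1.90))
    assert total == pytest.approx(CONCURRENT_HEAT_LARGE_CREW_J_S, abs=2.5)


def test_concurrent_exercise_heat_edge_cases():
    one = (CrewMember(stature=1.70),)
    resting_only = concurrent_exercise_heat(one, n_exercising=0)
    assert resting_only == pytest.approx(
        resting_profile(one[0]).mprod_basal, rel=1e-12)
    # 4 x 1.50 m by hand: exercise Mprod + 3 x basal Mprod
    small = crew(1.50)
    expected = 666.89 + 3 * 65.743
    assert concurrent_exercise_heat(small) == pytest.approx(expected, abs=0.1)
    with pytest.raises(ValueError, match="roster"):
        concurrent_exercise_heat(())
    with pytest.raises(ValueError, match="n_exercising"):
        concurrent_exercise_heat(small, n_exercising=5)


@given(duration=st.integers(1, 2000))
def test_mission_totals_scale_exactly_with_duration(duration):
    unit = mission_totals(MissionScenario(crew(1.80, 2), 1))
    scaled = mission_totals(MissionScenario(crew(1.80, 2), duration))
    assert scaled.energy == pytest.approx(duration * unit.energy, rel=1e-9)
    assert scaled.water == pytest.approx(duration * unit.water, rel=1e-9)


def test_scenario_validation():
    with pytest.raises(ValueError, match="roster"):
        MissionScenario(roster=(), duration=30)
    with pytest.raises(ValueError, match="duration"):
        MissionScenario(roster=crew(1.70), duration=0)
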