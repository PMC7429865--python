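"""Per-day and mission-level resource budgets.

A no-exercise person-day is

    TEE  = RMR x PAL + TEM                       (MJ)
    O2   = resting VO2  x PAL x 1440             (L)
    CO2  = resting VCO2 x PAL x 1440             (L)
    heat = basal Mprod x 86,400 / 1e6            (MJ)   [no PAL factor]
    water = basal hydration need                 (L)

and a countermeasure-exercise day adds ``bouts_per_day`` bout totals on
top of the full resting day (resting metabolism during the exercise
minutes is not deducted).  The asymmetry on heat — TEE/O2/CO2 carry the
PAL multiplier while 24-h heat is basal Mprod alone — reproduces the
reference tables; a self-consistent variant that applies PAL to heat as
well is available via ``heat_variant="consistent"``.

Mission totals are linear: sum over crew of the daily budget times
duration, with exercise applied every day by default (the reference
aggregates require 7 d/week despite the nominal 6 d/week prescription;
``strict_schedule=True`` honours days_per_week pro rata).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .anthropometrics import CrewMember
from .exercise_metabolism import (
    BoutTotals,
    ExercisePrescription,
    bout_totals,
    exercise_rates,
)
from .constants import MINUTES_PER_DAY, SECONDS_PER_DAY
from .resting_metabolism import RestingProfile, resting_profile
from .thermoregulation import (
    DEFAULT_EXTERNAL_WORK_FRACTION,
    Environment,
    heat_balance,
)
from .water_requirements import Intake, water_budget

__all__ = [
    "DailyBudget",
    "MissionScenario",
    "MissionTotals",
    "daily_budget",
    "mission_totals",
    "scenario_delta",
    "concurrent_exercise_heat",
]


@dataclass(frozen=True)
class DailyBudget:
    """One person-day of resource use."""

    tee: float      # MJ
    o2: float       # L
    co2: float      # L
    heat: float     # MJ
    water: float    # L
    exercising: bool


@dataclass(frozen=True)
class MissionScenario:
    """A crew roster flown for a duration under one exercise/environment
    regime.  ``prescription=None`` means no countermeasure exercise."""

    roster: tuple[CrewMember, ...]
    duration: float  # days
    prescription: ExercisePrescription | None = None
    environment: Environment = Environment()
    intake: Intake = Intake()

    def __post_init__(self) -> None:
        if not self.roster:
            raise ValueError("roster must be non-empty")
        if not self.duration > 0:
            raise ValueError(f"duration must be positive, got {self.duration!r}")
        object.__setattr__(self, "roster", tuple(self.roster))


@dataclass(frozen=True)
class MissionTotals:
    """Crew totals over a whole mission."""

    energy: float  # MJ
    o2: float      # L
    co2: float     # L
    heat: float    # MJ
    water: float   # L

    def __sub__(self, other: "MissionTotals") -> "MissionTotals":
        return MissionTotals(
            energy=self.energy - other.energy,
            o2=self.o2 - other.o2,
            co2=self.co2 - other.co2,
            heat=self.heat - other.heat,
            water=self.water - other.water,
        )


def member_bout(
    member: CrewMember,
    prescription: ExercisePrescription,
    env: Environment | None = None,
) -> BoutTotals:
    """Totals for one of this member's exercise bouts, with the sweat
    rate predicted by the heat-balance model."""
    rates = exercise_rates(member, prescription.intensity_fraction)
    hb = heat_balance(rates.mprod, member.bsa, env,
                      external_work_fraction=DEFAULT_EXTERNAL_WORK_FRACTION)
    return bout_totals(
        rates, prescription.bout_duration, prescription.epoc_fraction,
        hb.sweat_rate,
    )


def daily_budget(
    member: CrewMember,
    profile: RestingProfile | None = None,
    prescription: ExercisePrescription | None = None,
    env: Environment | None = None,
    *,
    intake: Intake | None = None,
    heat_variant: str = "paper",
    water_energy_route: str = "gas_exchange",
    sweat_rate_ml_min: float | None = None,
) -> DailyBudget:
    """One person-day budget, without or with countermeasure exercise.

    ``sweat_rate_ml_min`` overrides the model-predicted whole-body sweat
    rate during exercise (useful for feeding externally tabulated rates).
    ``heat_variant``: "paper" reproduces the reference tables (24-h heat
    = basal Mprod x 86,400 without the PAL factor); "consistent" applies
    PAL to heat as it is applied to TEE/O2/CO2.
    """
    if heat_variant not in ("paper", "consistent"):
        raise ValueError(f"unknown heat_variant {heat_variant!r}")
    profile = profile if profile is not None else resting_profile(member)
    pal = profile.pal
    tee = profile.rmr * pal + profile.tem
    o2 = profile.vo2_rest * pal * MINUTES_PER_DAY
    co2 = profile.vco2_rest * pal * MINUTES_PER_DAY
    heat_pal = pal if heat_variant == "consistent" else 1.0
    heat = profile.mprod_basal * heat_pal * SECONDS_PER_DAY / 1e6

    n_bouts = prescription.bouts_per_day if prescription is not None else 0
    sweat_l = 0.0
    if n_bouts > 0:
        assert prescription is not None
        if sweat_rate_ml_min is not None:
            rates = exercise_rates(member, prescription.intensity_fraction)
            bout = bout_totals(rates, prescription.bout_duration,
                               prescription.epoc_fraction, sweat_rate_ml_min)
        else:
            bout = member_bout(member, prescription, env)
        tee += n_bouts * bout.energy
        o2 += n_bouts * bout.o2
        co2 += n_bouts * bout.co2
        heat += n_bouts * bout.heat / 1000.0
        sweat_l = n_bouts * bout.sweat / 1000.0

    water = water_budget(profile, intake, sweat_l, water_energy_route)
    return DailyBudget(tee=tee, o2=o2, co2=co2, heat=heat,
                       water=water.total_water, exercising=n_bouts > 0)


def mission_totals(
    scenario: MissionScenario,
    *,
    strict_schedule: bool = False,
    heat_variant: str = "paper",
    water_energy_route: str = "gas_exchange",
) -> MissionTotals:
    """Crew x duration aggregate of daily budgets.

    By default exercise is applied every mission day; with
    ``strict_schedule`` the exercise increment is scaled by
    days_per_week/7 (pro rata, fractional days allowed).
    """
    energy = o2 = co2 = heat = water = 0.0
    for member in scenario.roster:
        profile = resting_profile(member)
        rest = daily_budget(member, profile, None, scenario.environment,
                            intake=scenario.intake, heat_variant=heat_variant,
                            water_energy_route=water_energy_route)
        day = rest
        if scenario.prescription is not None and scenario.prescription.bouts_per_day:
            ex = daily_budget(member, profile, scenario.prescription,
                              scenario.environment, intake=scenario.intake,
                              heat_variant=heat_variant,
                              water_energy_route=water_energy_route)
            if strict_schedule:
                f = scenario.prescription.days_per_week / 7.0
                day = DailyBudget(
                    tee=rest.tee + f * (ex.tee - rest.tee),
                    o2=rest.o2 + f * (ex.o2 - rest.o2),
                    co2=rest.co2 + f * (ex.co2 - rest.co2),
                    heat=rest.heat + f * (ex.heat - rest.heat),
                    water=rest.water + f * (ex.water - rest.water),
                    exercising=True,
                )
            else:
                day = ex
        energy += day.tee * scenario.duration
        o2 += day.o2 * scenario.duration
        co2 += day.co2 * scenario.duration
        heat += day.heat * scenario.duration
        water += day.water * scenario.duration
    return MissionTotals(energy=energy, o2=o2, co2=co2, heat=heat, water=water)


def scenario_delta(a: MissionTotals, b: MissionTotals) -> MissionTotals:
    """Elementwise b - a: the resource cost of moving from scenario a to b."""
    return b - a


def concurrent_exercise_heat(
    roster: Sequence[CrewMember],
    prescription: ExercisePrescription | None = None,
    n_exercising: int = 1,
) -> float:
    """Crew heat output (J/s) when ``n_exercising`` members exercise and
    the rest are at rest — the worst-case instantaneous load if sessions
    are performed back-to-back.

    Resting members contribute basal Mprod (no PAL factor: the scenario
    is quiet rest while a crewmate exercises).
    """
    if not roster:
        raise ValueError("roster must be non-empty")
    members = list(roster)
    if not 0 <= n_exercising <= len(members):
        raise ValueError(
            f"n_exercising must lie in [0, {len(members)}], got {n_exercising!r}")
    prescription = prescription if prescription is not None else ExercisePrescription()
    total = 0.0
    for member in members[:n_exercising]:
        total += exercise_rates(member, prescription.intensity_fraction).mprod
    for member in members[n_exercising:]:
        total += resting_profile(member).mprod_basal
    return total
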