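"""Countermeasure-exercise metabolism.

In-flight countermeasure (CM) exercise is modelled as steady-state
aerobic work at a fixed fraction of VO2max (default 75%, 30 min, twice a
day, 6 d/week).  Energy expenditure uses the Weir indirect-calorimetry
equation; heat production uses the thermal equivalent of O2 at the
exercise RER.  Excess post-exercise oxygen consumption (EPOC) adds a
fixed fraction (default 6%) to per-bout energy, O2 and CO2 — but not to
heat or sweat, which are in-bout steady-state quantities.
"""

from __future__ import annotations

from dataclasses import dataclass

from .anthropometrics import CrewMember
from .constants import (
    KCAL_TO_KJ,
    THERMAL_EQUIV_EXERCISE_KCAL_PER_L,
)
from .resting_metabolism import mprod

__all__ = [
    "ExercisePrescription",
    "ExerciseRates",
    "BoutTotals",
    "weir_energy_expenditure",
    "exercise_rates",
    "bout_totals",
]


@dataclass(frozen=True)
class ExercisePrescription:
    """A countermeasure exercise schedule.

    The default mirrors current ISS practice collapsed to its aerobic
    equivalent: two 30-min bouts/day at 75% VO2max, 6 d/week, with EPOC
    worth 6% of in-bout consumption.  Resistance exercise is represented
    as the second identical aerobic bout.
    """

    intensity_fraction: float = 0.75
    bout_duration: float = 30.0   # min
    bouts_per_day: int = 2
    days_per_week: int = 6
    epoc_fraction: float = 0.06

    def __post_init__(self) -> None:
        if not 0 < self.intensity_fraction <= 1:
            raise ValueError(
                "intensity_fraction must lie in (0, 1]; supramaximal exercise "
                f"is not modelled (got {self.intensity_fraction!r})")
        if not self.bout_duration > 0:
            raise ValueError(f"bout_duration must be positive, got {self.bout_duration!r}")
        if self.bouts_per_day < 0:
            raise ValueError(f"bouts_per_day must be >= 0, got {self.bouts_per_day!r}")
        if not 1 <= self.days_per_week <= 7:
            raise ValueError(f"days_per_week must lie in [1, 7], got {self.days_per_week!r}")
        if not 0 <= self.epoc_fraction < 1:
            raise ValueError(f"epoc_fraction must lie in [0, 1), got {self.epoc_fraction!r}")


@dataclass(frozen=True)
class ExerciseRates:
    """Steady-state rates during a bout."""

    vo2: float       # L/min
    vco2: float      # L/min
    ee: float        # kcal/min
    mprod: float     # J/s


@dataclass(frozen=True)
class BoutTotals:
    """Totals for one exercise bout (EPOC included in energy/O2/CO2)."""

    energy: float   # MJ
    o2: float       # L
    co2: float      # L
    heat: float     # kJ
    sweat: float    # mL

    def __post_init__(self) -> None:
        for name in ("energy", "o2", "co2", "heat", "sweat"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def weir_energy_expenditure(vo2: float, vco2: float) -> float:
    """Weir equation: EE (kcal/min) = 3.94*VO2 + 1.11*VCO2, both L/min."""
    if vo2 < 0 or vco2 < 0:
        raise ValueError("vo2 and vco2 must be non-negative")
    return 3.94 * vo2 + 1.11 * vco2


def exercise_rates(member: CrewMember, intensity_fraction: float) -> ExerciseRates:
    """Steady-state gas exchange, energy and heat rates at a fraction of
    the member's VO2max.

    VO2 = fraction x absolute VO2max; VCO2 = exercise RER x VO2; EE via
    Weir; heat via the thermal equivalent of O2 at the exercise RER.
    """
    if not 0 < intensity_fraction <= 1:
        raise ValueError(
            "intensity_fraction must lie in (0, 1]; supramaximal exercise "
            f"is not modelled (got {intensity_fraction!r})")
    vo2 = intensity_fraction * member.vo2max_abs
    vco2 = member.rer_exercise * vo2
    return ExerciseRates(
        vo2=vo2,
        vco2=vco2,
        ee=weir_energy_expenditure(vo2, vco2),
        mprod=mprod(vo2, THERMAL_EQUIV_EXERCISE_KCAL_PER_L),
    )


def bout_totals(
    rates: ExerciseRates,
    bout_duration: float,
    epoc_fraction: float,
    sweat_rate: float,
) -> BoutTotals:
    """Totals for a single bout of given duration (min).

    Energy, O2 and CO2 carry the EPOC multiplier (1 + epoc_fraction);
    heat and sweat are the in-bout steady-state rate x duration only,
    since EPOC heat is dissipated at rest and sweating decays after the
    bout.  ``sweat_rate`` is the whole-body rate in mL/min.
    """
    if bout_duration < 0:
        raise ValueError(f"bout_duration must be non-negative, got {bout_duration!r}")
    if sweat_rate < 0:
        raise ValueError(f"sweat_rate must be non-negative, got {sweat_rate!r}")
    scale = bout_duration * (1.0 + epoc_fraction)
    return BoutTotals(
        energy=rates.ee * scale * KCAL_TO_KJ / 1000.0,
        o2=rates.vo2 * scale,
        co2=rates.vco2 * scale,
        heat=rates.mprod * bout_duration * 60.0 / 1000.0,
        sweat=sweat_rate * bout_duration,
    )
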