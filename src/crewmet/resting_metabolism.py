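"""Resting metabolism: RMR, NEAT, TEM, resting gas exchange, basal heat.

Resting metabolic rate comes from the revised Harris-Benedict equation
for males.  Non-exercise activity thermogenesis is expressed through a
physical activity level (PAL) multiplier: NEAT = (PAL - 1) x RMR.  The
thermic effect of meals (TEM) is a flat daily energy cost independent of
body size.  Resting gas exchange scales with body mass at a fixed
relative resting VO2, with VCO2 set by the resting RER.
"""

from __future__ import annotations

from dataclasses import dataclass

from .anthropometrics import CrewMember
from .constants import (
    KCAL_TO_KJ,
    MPROD_DIVISOR,
    THERMAL_EQUIV_REST_KCAL_PER_L,
)

__all__ = [
    "RestingProfile",
    "rmr_harris_benedict",
    "neat_from_pal",
    "resting_gas_exchange",
    "mprod",
    "resting_profile",
]

#: Default daily thermic effect of meals, kcal/d (three meals a day).
TEM_KCAL_PER_DAY = 206.0

#: Default physical activity level for confined in-flight living
#: (sedentary but not immobile), excluding countermeasure exercise.
DEFAULT_PAL = 1.4


def rmr_harris_benedict(body_mass: float, stature: float, age: float) -> float:
    """Resting metabolic rate (MJ/d), revised Harris-Benedict, males.

    RMR[kcal/d] = 88.362 + 13.397*mass[kg] + 4.799*height[cm]
                  - 5.677*age[y], converted to MJ/d at 4.1868 kJ/kcal.
    """
    if not body_mass > 0:
        raise ValueError(f"body_mass must be strictly positive, got {body_mass!r}")
    if not stature > 0:
        raise ValueError(f"stature must be strictly positive, got {stature!r}")
    if not 0 < age < 120:
        raise ValueError(f"age must lie in (0, 120) years, got {age!r}")
    kcal = 88.362 + 13.397 * body_mass + 4.799 * (stature * 100.0) - 5.677 * age
    return kcal * KCAL_TO_KJ / 1000.0


def neat_from_pal(rmr: float, pal: float) -> float:
    """Non-exercise activity thermogenesis (MJ/d) as (PAL - 1) x RMR."""
    if pal < 1:
        raise ValueError(f"pal must be >= 1, got {pal!r}")
    return (pal - 1.0) * rmr


def resting_gas_exchange(
    body_mass: float, vo2_rest_rel: float, rer_rest: float
) -> tuple[float, float]:
    """Resting (VO2, VCO2) in L/min from mass, relative VO2 and RER."""
    if not body_mass > 0 or not vo2_rest_rel > 0 or not rer_rest > 0:
        raise ValueError("body_mass, vo2_rest_rel and rer_rest must be positive")
    vo2 = body_mass * vo2_rest_rel / 1000.0
    return vo2, rer_rest * vo2


def mprod(vo2: float, thermal_equiv: float) -> float:
    """Metabolic heat production (J/s) from VO2 (L/min) and the thermal
    equivalent of O2 at the prevailing RER (kcal/L).

    Mprod = VO2 x thermal_equiv / 0.01433, i.e. kcal/min x 69.78 J/s.
    """
    if vo2 < 0 or thermal_equiv <= 0:
        raise ValueError("vo2 must be non-negative, thermal_equiv positive")
    return vo2 * thermal_equiv / MPROD_DIVISOR


@dataclass(frozen=True)
class RestingProfile:
    """One crew member's resting energy/gas/heat state (per day or per
    minute as indicated by units)."""

    rmr: float          # MJ/d
    neat: float         # MJ/d
    tem: float          # MJ/d
    pal: float
    vo2_rest: float     # L/min
    vco2_rest: float    # L/min
    mprod_basal: float  # J/s

    def __post_init__(self) -> None:
        for name in ("rmr", "neat", "tem", "pal", "vo2_rest", "vco2_rest",
                     "mprod_basal"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def resting_profile(
    member: CrewMember,
    pal: float = DEFAULT_PAL,
    tem_kcal: float = TEM_KCAL_PER_DAY,
) -> RestingProfile:
    """Derive the full resting profile for one crew member."""
    rmr = rmr_harris_benedict(member.body_mass, member.stature, member.age)
    vo2, vco2 = resting_gas_exchange(
        member.body_mass, member.vo2_rest_rel, member.rer_rest
    )
    return RestingProfile(
        rmr=rmr,
        neat=neat_from_pal(rmr, pal),
        tem=tem_kcal * KCAL_TO_KJ / 1000.0,
        pal=pal,
        vo2_rest=vo2,
        vco2_rest=vco2,
        mprod_basal=mprod(vo2, THERMAL_EQUIV_REST_KCAL_PER_L),
    )
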