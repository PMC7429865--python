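"""Daily hydration water needs.

Basal (non-exercise) water need is the sum of insensible water needs,
IWN = 0.4 x energy needs [kcal] / 1000 (L/d), and the urine volume
required to excrete the dietary solute load at a urine concentration of
600 mmol/kg, UV600 = DSL / 600, where

    DSL [mmol/d] = protein[g]/0.175 + 2 * (Na[mg]/23 + K[mg]/39).

Respiratory water loss is assumed balanced by metabolic water production
and is not modelled; transcutaneous loss has no explicit term (see the
methods note).  Exercise adds sweat replacement on top of the basal need.

"Energy needs" for IWN defaults to the gas-exchange route: resting Weir
energy expenditure x 1440 min x PAL plus the thermic effect of meals.
The Harris-Benedict route (RMR x PAL + TEM) is available as an option;
the two differ by ~3% but the gas-exchange route matches the reference
basal-fluid column far more closely.
"""

from __future__ import annotations

from dataclasses import dataclass

from .constants import KCAL_TO_KJ, MINUTES_PER_DAY
from .exercise_metabolism import weir_energy_expenditure
from .resting_metabolism import RestingProfile

__all__ = [
    "Intake",
    "WaterBudget",
    "insensible_water",
    "dietary_solute_load",
    "daily_water",
    "resting_energy_needs_kcal",
    "water_budget",
]


@dataclass(frozen=True)
class Intake:
    """Daily dietary intakes relevant to renal solute load (ISS menu)."""

    protein_g: float = 95.0
    sodium_mg: float = 4320.0
    potassium_mg: float = 3062.0

    def __post_init__(self) -> None:
        for name in ("protein_g", "sodium_mg", "potassium_mg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class WaterBudget:
    """One person-day of hydration water needs (litres except DSL)."""

    iwn: float             # L/d
    dsl: float             # mmol/d
    uv600: float           # L/d
    basal_water: float     # L/d
    exercise_sweat: float  # L/d
    total_water: float     # L/d


def insensible_water(energy_needs_kcal: float) -> float:
    """Insensible water needs (L/d) from daily energy needs (kcal/d)."""
    if energy_needs_kcal < 0:
        raise ValueError(f"energy_needs_kcal must be non-negative, got {energy_needs_kcal!r}")
    return 0.4 * energy_needs_kcal / 1000.0


def dietary_solute_load(protein_g: float, sodium_mg: float, potassium_mg: float) -> float:
    """Dietary solute load (mmol/d) from protein, sodium and potassium."""
    if protein_g < 0 or sodium_mg < 0 or potassium_mg < 0:
        raise ValueError("intakes must be non-negative")
    return protein_g / 0.175 + 2.0 * (sodium_mg / 23.0 + potassium_mg / 39.0)


def resting_energy_needs_kcal(
    profile: RestingProfile, route: str = "gas_exchange"
) -> float:
    """Daily resting energy needs (kcal) feeding the IWN term.

    "gas_exchange": Weir EE from resting VO2/VCO2 x 1440 x PAL + TEM.
    "harris_benedict": RMR x PAL + TEM, converted from MJ.
    """
    tem_kcal = profile.tem * 1000.0 / KCAL_TO_KJ
    if route == "gas_exchange":
        ee = weir_energy_expenditure(profile.vo2_rest, profile.vco2_rest)
        return ee * MINUTES_PER_DAY * profile.pal + tem_kcal
    if route == "harris_benedict":
        return profile.rmr * profile.pal * 1000.0 / KCAL_TO_KJ + tem_kcal
    raise ValueError(f"unknown energy-needs route {route!r}")


def daily_water(iwn: float, uv600: float, exercise_sweat: float) -> WaterBudget:
    """Assemble a water budget from its components (all L/d).

    DSL is back-derived from uv600 (uv600 = DSL/600 exactly).
    """
    if iwn < 0 or uv600 < 0 or exercise_sweat < 0:
        raise ValueError("water components must be non-negative")
    basal = iwn + uv600
    return WaterBudget(
        iwn=iwn,
        dsl=uv600 * 600.0,
        uv600=uv600,
        basal_water=basal,
        exercise_sweat=exercise_sweat,
        total_water=basal + exercise_sweat,
    )


def water_budget(
    profile: RestingProfile,
    intake: Intake | None = None,
    exercise_sweat_l: float = 0.0,
    energy_route: str = "gas_exchange",
) -> WaterBudget:
    """Full daily water budget for one crew member.

    The basal term uses resting-day energy needs regardless of exercise;
    exercise enters only through sweat replacement.
    """
    intake = intake if intake is not None else Intake()
    iwn = insensible_water(resting_energy_needs_kcal(profile, energy_route))
    dsl = dietary_solute_load(intake.protein_g, intake.sodium_mg, intake.potassium_mg)
    return daily_water(iwn, dsl / 600.0, exercise_sweat_l)
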