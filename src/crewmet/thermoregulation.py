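"""Partitional-calorimetry heat balance during exercise.

Steady-state heat balance in the cabin environment determines the
required evaporative cooling

    Ereq = Mnet - (dry heat loss),    Mnet = Mprod x (1 - work fraction) / BSA

and the maximal evaporative capacity of the environment

    Emax = (Psk,sat - Pa) / (Re,cl + 1 / (fcl * hc * LR))

with all area-specific quantities in W/m^2.  Whole-body steady-state
sweat rate then follows the Gonzalez et al. regression

    SR [g/m^2/h] = 147 + 1.527 * Ereq - 0.87 * Emax

scaled by body surface area.  Coefficient choices that the heat-balance
literature leaves open (convective/radiative coefficients, clothing area
factor, Lewis relation, mean skin temperature) are this implementation's
documented defaults, exposed on :class:`Environment`.

Saturation vapour pressure uses the Antoine equation for water,
log10(P[mmHg]) = 8.07131 - 1730.63/(233.426 + T[degC]), valid 1-100 degC
and accurate to <0.1% over the 0-45 degC range used here.
"""

from __future__ import annotations

from dataclasses import dataclass

from .constants import MMHG_TO_KPA

__all__ = [
    "Environment",
    "HeatBalance",
    "saturation_vapour_pressure",
    "net_metabolic_heat",
    "dry_heat_loss",
    "emax",
    "sweat_rate",
    "heat_balance",
]

#: Fraction of metabolic power converted to external mechanical work on
#: a cycle ergometer by non-cyclists.
DEFAULT_EXTERNAL_WORK_FRACTION = 0.20


@dataclass(frozen=True)
class Environment:
    """Cabin thermal/atmospheric state, clothing biophysics and the
    heat-transfer coefficient set.

    Defaults are the ISS-like cabin (22 degC, 55% RH, 760 mmHg, 0.5 m/s
    fan-driven airflow) with light sports clothing (Icl = 0.06 m^2.degC/W,
    Re,cl = 0.01 m^2.kPa/W).  Mean skin temperature defaults to 35 degC, a
    conventional exercising value.  hc = 8.3 v^0.6 is a standard forced-
    convection correlation; hr = 4.7 W/m^2/degC a standard radiative
    coefficient; fcl = 1.1 the clothing area factor; the Lewis relation
    16.5 degC/kPa converts hc to an evaporative coefficient.
    """

    air_temp: float = 22.0                      # degC
    relative_humidity: float = 0.55             # fraction
    barometric_pressure: float = 760.0          # mmHg
    air_velocity: float = 0.5                   # m/s
    core_temp: float = 37.0                     # degC
    skin_temp: float = 35.0                     # degC
    clothing_thermal_resistance: float = 0.06   # m^2.degC/W
    clothing_evaporative_resistance: float = 0.01  # m^2.kPa/W
    conv_coeff_scale: float = 8.3               # hc = scale * v^exponent
    conv_coeff_exponent: float = 0.6
    radiative_coeff: float = 4.7                # W/m^2/degC
    clothing_area_factor: float = 1.1
    lewis_relation: float = 16.5                # degC/kPa

    def __post_init__(self) -> None:
        if not 0 < self.relative_humidity <= 1:
            raise ValueError(
                f"relative_humidity must lie in (0, 1], got {self.relative_humidity!r}")
        if self.air_velocity < 0:
            raise ValueError(f"air_velocity must be >= 0, got {self.air_velocity!r}")
        if not self.skin_temp < self.core_temp:
            raise ValueError(
                f"skin_temp ({self.skin_temp!r}) must be below core_temp "
                f"({self.core_temp!r})")

    @property
    def hc(self) -> float:
        """Convective heat-transfer coefficient, W/m^2/degC."""
        return self.conv_coeff_scale * self.air_velocity**self.conv_coeff_exponent


@dataclass(frozen=True)
class HeatBalance:
    """Area-specific heat-balance terms plus whole-body sweat rate."""

    mnet: float        # W/m^2
    dry_loss: float    # W/m^2
    ereq: float        # W/m^2
    emax: float        # W/m^2
    sweat_rate: float  # mL/min, whole body

    @property
    def wettedness(self) -> float:
        """Required skin wettedness proxy Ereq/Emax (dimensionless)."""
        return self.ereq / self.emax


def saturation_vapour_pressure(temp_c: float) -> float:
    """Saturated water-vapour pressure (kPa) at temp_c (degC), Antoine form."""
    p_mmhg = 10.0 ** (8.07131 - 1730.63 / (233.426 + temp_c))
    return p_mmhg * MMHG_TO_KPA


def net_metabolic_heat(mprod: float, external_work_fraction: float, bsa: float) -> float:
    """Area-specific net metabolic heat Mnet (W/m^2).

    Subtracts the external mechanical work fraction from gross metabolic
    power and normalises by body surface area.
    """
    if not 0 <= external_work_fraction < 1:
        raise ValueError(
            f"external_work_fraction must lie in [0, 1), got {external_work_fraction!r}")
    if not bsa > 0:
        raise ValueError(f"bsa must be positive, got {bsa!r}")
    return mprod * (1.0 - external_work_fraction) / bsa


def dry_heat_loss(env: Environment) -> float:
    """Convective + radiative (dry) heat loss through clothing, W/m^2.

    (Tsk - To) over the series resistance of clothing plus the boundary
    air layer, 1/(fcl*(hc+hr)).  Operative temperature equals air
    temperature here (mean radiant temperature is taken equal to air
    temperature in the cabin).  Returns <= 0 (heat gain) without error
    when the air is at or above skin temperature.
    """
    h = env.hc + env.radiative_coeff
    total_resistance = env.clothing_thermal_resistance + 1.0 / (
        env.clothing_area_factor * h
    )
    return (env.skin_temp - env.air_temp) / total_resistance


def emax(env: Environment) -> float:
    """Maximal evaporative capacity of the environment, W/m^2.

    Vapour-pressure gradient from saturated skin to ambient air over the
    series evaporative resistance of clothing plus the boundary layer
    via the Lewis relation.
    """
    gradient = saturation_vapour_pressure(env.skin_temp) - (
        env.relative_humidity * saturation_vapour_pressure(env.air_temp)
    )
    total_resistance = env.clothing_evaporative_resistance + 1.0 / (
        env.clothing_area_factor * env.hc * env.lewis_relation
    )
    return gradient / total_resistance


def sweat_rate(ereq: float, emax_: float, bsa: float) -> float:
    """Whole-body steady-state sweat rate (mL/min), Gonzalez regression.

    Area-specific rate 147 + 1.527*Ereq - 0.87*Emax (g/m^2/h), clamped at
    zero, scaled by BSA and converted to mL/min (1 g sweat = 1 mL).  No
    allowance is made for the thermal inertia of sweating onset; it is
    assumed balanced by post-exercise decay.
    """
    if emax_ <= 0:
        raise ValueError(
            "emax must be positive: an environment with no evaporative "
            "capacity is outside the model's scope")
    if not bsa > 0:
        raise ValueError(f"bsa must be positive, got {bsa!r}")
    area_rate = 147.0 + 1.527 * ereq - 0.87 * emax_
    return max(area_rate, 0.0) * bsa / 60.0


def heat_balance(
    mprod: float,
    bsa: float,
    env: Environment | None = None,
    external_work_fraction: float = DEFAULT_EXTERNAL_WORK_FRACTION,
) -> HeatBalance:
    """Full heat balance for one exercising crew member.

    ``mprod`` is gross metabolic heat production in J/s (= W) and ``bsa``
    body surface area in m^2.
    """
    env = env if env is not None else Environment()
    mnet = net_metabolic_heat(mprod, external_work_fraction, bsa)
    dry = dry_heat_loss(env)
    ereq = mnet - dry
    e_max = emax(env)
    return HeatBalance(
        mnet=mnet,
        dry_loss=dry,
        ereq=ereq,
        emax=e_max,
        sweat_rate=sweat_rate(ereq, e_max, bsa),
    )
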