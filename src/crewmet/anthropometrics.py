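"""Body-size scaling for a theoretical astronaut population.

Crew are assumed geometrically similar across the stature band, so at a
fixed body-mass index (BMI) body mass scales exactly with stature squared.
Body surface area follows the Du Bois & Du Bois formula and absolute
aerobic capacity (VO2max, L/min) scales linearly with body mass at a
fixed relative VO2max (mL/kg/min).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "CrewMember",
    "body_mass_from_bmi",
    "bsa_dubois",
    "vo2max_absolute",
]


def _require_positive(**fields: float) -> None:
    for name, value in fields.items():
        if not value > 0:
            raise ValueError(f"{name} must be strictly positive, got {value!r}")


def body_mass_from_bmi(stature: float, bmi: float) -> float:
    """Body mass (kg) from stature (m) and BMI (kg/m^2).

    Inverts BMI = mass / stature^2; under geometric similarity the whole
    population shares one BMI, so mass is proportional to stature^2.
    """
    _require_positive(stature=stature, bmi=bmi)
    return bmi * stature**2


def bsa_dubois(stature: float, body_mass: float) -> float:
    """Du Bois body surface area (m^2) from stature (m) and mass (kg).

    BSA = 0.007184 * height(cm)^0.725 * mass(kg)^0.425.  The classical
    Du Bois coefficients take height in centimetres; stature is converted
    internally.
    """
    _require_positive(stature=stature, body_mass=body_mass)
    return 0.007184 * (stature * 100.0) ** 0.725 * body_mass**0.425


def vo2max_absolute(body_mass: float, vo2max_rel: float) -> float:
    """Absolute aerobic capacity (L O2/min) from mass (kg) and relative
    VO2max (mL O2/kg/min)."""
    _require_positive(body_mass=body_mass, vo2max_rel=vo2max_rel)
    return body_mass * vo2max_rel / 1000.0


@dataclass(frozen=True)
class CrewMember:
    """One astronaut's anthropometric and physiological parameter set.

    Only stature varies across the default population; the shared
    parameters (age 40 y, BMI 26.5 kg/m^2, VO2max 43.4 mL/kg/min, resting
    VO2 3.3 mL/kg/min, RER 0.788 at rest and 0.898 at 75% VO2max) encode
    a male astronaut reference population.  Derived fields (body mass,
    body surface area, absolute VO2max) are computed on construction and
    carried unrounded.
    """

    stature: float
    age: float = 40.0
    bmi: float = 26.5
    vo2max_rel: float = 43.4
    vo2_rest_rel: float = 3.3
    rer_rest: float = 0.788
    rer_exercise: float = 0.898
    body_mass: float = field(init=False, repr=False)
    bsa: float = field(init=False, repr=False)
    vo2max_abs: float = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not 1.0 < self.stature < 2.5:
            raise ValueError(f"stature must lie in (1.0, 2.5) m, got {self.stature!r}")
        _require_positive(bmi=self.bmi, vo2max_rel=self.vo2max_rel,
                          vo2_rest_rel=self.vo2_rest_rel)
        if not 0 < self.age < 120:
            raise ValueError(f"age must lie in (0, 120) years, got {self.age!r}")
        if not 0.6 <= self.rer_rest <= 1.0:
            raise ValueError(f"rer_rest must lie in [0.6, 1.0], got {self.rer_rest!r}")
        if not 0.6 <= self.rer_exercise <= 1.2:
            raise ValueError(
                f"rer_exercise must lie in [0.6, 1.2], got {self.rer_exercise!r}")
        mass = body_mass_from_bmi(self.stature, self.bmi)
        object.__setattr__(self, "body_mass", mass)
        object.__setattr__(self, "bsa", bsa_dubois(self.stature, mass))
        object.__setattr__(self, "vo2max_abs", vo2max_absolute(mass, self.vo2max_rel))
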