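"""Shared physical constants and unit conversions.

Everything here is a fixed scalar; model parameters with a physiological
interpretation (PAL, RERs, intakes, environment) live on the domain types
instead, where they can be overridden per scenario.
"""

#: Thermochemical-calorie convention used throughout (kJ per kcal).
#: 4.1868 (the international table calorie) reproduces the reference
#: energy tables at printed precision; 4.184 does not.
KCAL_TO_KJ = 4.1868

#: J/s produced per (kcal/min): 1 kcal/min = 69.78 J/s, so heat production
#: in J/s is (VO2 [L/min] x thermal equivalent [kcal/L]) / 0.01433.
MPROD_DIVISOR = 0.01433

#: Thermal equivalent of oxygen (kcal per litre O2) at the resting
#: respiratory exchange ratio of 0.788.
THERMAL_EQUIV_REST_KCAL_PER_L = 4.788

#: Thermal equivalent of oxygen at the heavy-exercise RER of 0.898.
THERMAL_EQUIV_EXERCISE_KCAL_PER_L = 4.924

MMHG_TO_KPA = 0.133322

MINUTES_PER_DAY = 1440.0
SECONDS_PER_DAY = 86400.0
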