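"""Partitional-calorimetry heat balance and sweat-rate prediction."""

import dataclasses

import pytest

from crewmet.exercise_metabolism import exercise_rates
from crewmet.thermoregulation import (
    Environment,
    dry_heat_loss,
    emax,
    heat_balance,
    net_metabolic_heat,
    saturation_vapour_pressure,
    sweat_rate,
)

from .reference_values import SWEAT_RATE_ML_MIN

# Regression constants for the default cabin and coefficient set, pinned
# from a hand evaluation of the documented resistance network:
#   Rt   = 0.06 + 1/(1.1*(8.3*0.5^0.6 + 4.7))          = 0.149337 m2.degC/W
#   dry  = (35-22)/Rt                                  = 87.05 W/m2
#   Re   = 0.01 + 1/(1.1 * 8.3*0.5^0.6 * 16.5)         = 0.020062 m2.kPa/W
#   emax = (psat(35) - 0.55*psat(22))/Re               = 207.36 W/m2
PINNED_DRY_LOSS = 87.05
PINNED_EMAX = 207.36


def test_saturation_vapour_pressure_anchor_points():
    """Antoine curve: ~2.64 kPa at 22 degC, ~5.62 kPa at 35 degC, and
    101.3 kPa at the boiling point."""
    assert saturation_vapour_pressure(22.0) == pytest.approx(2.64, abs=0.02)
    assert saturation_vapour_pressure(35.0) == pytest.approx(5.62, abs=0.02)
    assert saturation_vapour_pressure(100.0) == pytest.approx(101.3, rel=0.01)


@pytest.mark.parametrize(
    "mprod, frac, bsa, expected",
    [
        (857.0, 0.20, 1.88, 364.68),   # arithmetic from the 1.70 m inputs
        (500.0, 0.0, 2.0, 250.0),      # no external work
        (1070.0, 0.20, 2.24, 382.14),  # arithmetic oracle, 1.90 m
    ],
)
def test_net_metabolic_heat(mprod, frac, bsa, expected):
    assert net_metabolic_heat(mprod, frac, bsa) == pytest.approx(expected, abs=0.01)


def test_net_metabolic_heat_rejects_full_external_work():
    with pytest.raises(ValueError, match="external_work_fraction"):
        net_metabolic_heat(857.0, 1.0, 1.88)


def test_dry_heat_loss_pinned_default():
    assert dry_heat_loss(Environment()) == pytest.approx(PINNED_DRY_LOSS, abs=0.02)


def test_dry_heat_loss_vanishes_without_gradient():
    env = dataclasses.replace(Environment(), air_temp=35.0)
    assert dry_heat_loss(env) == pytest.approx(0.0, abs=1e-12)


def test_dry_heat_loss_sign_flips_in_hot_air():
    env = dataclasses.replace(Environment(), air_temp=36.5)
    assert dry_heat_loss(env) < 0  # heat gain, not an error


def test_dry_heat_loss_halves_when_resistance_doubles():
    env = Environment()
    base = dry_heat_loss(env)
    h = env.hc + env.radiative_coeff
    rt = env.clothing_thermal_resistance + 1.0 / (env.clothing_area_factor * h)
    # double the total resistance by padding the clothing term
    doubled = dataclasses.replace(
        env, clothing_thermal_resistance=env.clothing_thermal_resistance + rt)
    assert dry_heat_loss(doubled) == pytest.approx(base / 2.0, rel=1e-12)


def test_emax_pinned_default():
    assert emax(Environment()) == pytest.approx(PINNED_EMAX, abs=0.02)


def test_emax_vanishes_with_saturated_air_at_skin_temp():
    env = dataclasses.replace(Environment(), air_temp=35.0,
                              relative_humidity=1.0, skin_temp=35.0,
                              core_temp=37.0)
    assert emax(env) == pytest.approx(0.0, abs=1e-12)


def test_emax_increases_as_humidity_drops():
    base = emax(Environment())
    drier = emax(dataclasses.replace(Environment(), relative_humidity=0.30))
    assert drier > base


def test_sweat_rate_requires_evaporative_capacity():
    with pytest.raises(ValueError, match="emax"):
        sweat_rate(200.0, 0.0, 1.88)


def test_sweat_rate_floor_is_non_negative():
    """With no required cooling the regression intercept may go negative;
    the predicted rate is clamped at zero."""
    assert sweat_rate(0.0, PINNED_EMAX, 1.88) >= 0.0


def test_predicted_sweat_rates_match_reference_within_15pct(five_members):
    """Whole-body sweat rates for the five statures fall within +-15% of
    the published 10.1-17.1 mL/min row and increase strictly with size.
    (The regression coefficients behind the published row are not fully
    specified, hence a tolerance band rather than printed equality.)"""
    rates = []
    for m, printed in zip(five_members, SWEAT_RATE_ML_MIN):
        r = exercise_rates(m, 0.75)
        hb = heat_balance(r.mprod, m.bsa)
        assert hb.sweat_rate == pytest.approx(printed, rel=0.15)
        rates.append(hb.sweat_rate)
    assert rates == sorted(rates)


def test_heat_balance_structure(five_members):
    """Ereq = Mnet - dry loss; wettedness proxy positive and bounded by
    the model's documented worst case (<1.5 in this cabin)."""
    for m in five_members:
        r = exercise_rates(m, 0.75)
        hb = heat_balance(r.mprod, m.bsa)
        assert hb.ereq == pytest.approx(hb.mnet - hb.dry_loss, rel=1e-12)
        assert hb.ereq <= hb.mnet
        assert 0.0 < hb.wettedness < 1.5


def test_sweat_rate_monotone_in_metabolic_heat():
    m_low = heat_balance(700.0, 1.88)
    m_high = heat_balance(900.0, 1.88)
    assert m_high.sweat_rate > m_low.sweat_rate


def test_environment_validation():
    with pytest.raises(ValueError, match="relative_humidity"):
        Environment(relative_humidity=0.0)
    with pytest.raises(ValueError, match="skin_temp"):
        Environment(skin_temp=38.0, core_temp=37.0)
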