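"""Tidy report tables for the reference analysis.

Builders return pandas DataFrames mirroring the reference tables
("table1" crew characteristics, "table2" single-bout totals, "table3"
24-h budgets, "table4" mission-level deltas) plus the mission-duration
series behind the figures.  Internal accumulation is unrounded; pass
``rounded=True`` to round to each table's printed precision.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .anthropometrics import CrewMember
from .exercise_metabolism import ExercisePrescription, exercise_rates
from .mission_aggregation import (
    MissionScenario,
    daily_budget,
    member_bout,
    mission_totals,
)
from .resting_metabolism import resting_profile
from .synthetic_crew import GRID_DURATIONS, GRID_STATURES
from .thermoregulation import (
    DEFAULT_EXTERNAL_WORK_FRACTION,
    Environment,
    heat_balance,
)
from .water_requirements import water_budget

__all__ = ["TABLE_IDS", "crew_for", "table1", "table2", "table3", "table4",
           "figure_series", "build_all"]

TABLE_IDS = ("table1", "table2", "table3", "table4", "figure_series")


def crew_for(statures: Sequence[float] = GRID_STATURES, **shared) -> list[CrewMember]:
    return [CrewMember(stature=s, **shared) for s in statures]


def _round(df: pd.DataFrame, digits: dict[str, int], rounded: bool) -> pd.DataFrame:
    if not rounded:
        return df
    out = df.copy()
    for row, nd in digits.items():
        if row in out.index:
            out.loc[row] = out.loc[row].round(nd)
    return out


def table1(
    members: Sequence[CrewMember] | None = None,
    prescription: ExercisePrescription | None = None,
    env: Environment | None = None,
    rounded: bool = True,
) -> pd.DataFrame:
    """Crew characteristics: anthropometrics, resting and exercise rates."""
    members = members if members is not None else crew_for()
    rx = prescription if prescription is not None else ExercisePrescription()
    env = env if env is not None else Environment()
    cols = {}
    for m in members:
        prof = resting_profile(m)
        rates = exercise_rates(m, rx.intensity_fraction)
        hb = heat_balance(rates.mprod, m.bsa, env, DEFAULT_EXTERNAL_WORK_FRACTION)
        wb = water_budget(prof)
        cols[f"{m.stature:.2f}"] = {
            "body_mass_kg": m.body_mass,
            "bsa_m2": m.bsa,
            "vo2max_l_min": m.vo2max_abs,
            "rmr_mj_d": prof.rmr,
            "neat_mj_d": prof.neat,
            "rest_vo2_l_min": prof.vo2_rest,
            "rest_vco2_l_min": prof.vco2_rest,
            "basal_mprod_j_s": prof.mprod_basal,
            "basal_fluid_l_d": wb.basal_water,
            "ex_vo2_l_min": rates.vo2,
            "ex_vco2_l_min": rates.vco2,
            "ex_ee_kcal_min": rates.ee,
            "ex_mprod_j_s": rates.mprod,
            "sweat_rate_ml_min": hb.sweat_rate,
        }
    df = pd.DataFrame(cols)
    digits = {"body_mass_kg": 1, "bsa_m2": 2, "vo2max_l_min": 2, "rmr_mj_d": 2,
              "neat_mj_d": 2, "rest_vo2_l_min": 3, "rest_vco2_l_min": 3,
              "basal_mprod_j_s": 1, "basal_fluid_l_d": 2, "ex_vo2_l_min": 2,
              "ex_vco2_l_min": 2, "ex_ee_kcal_min": 1, "ex_mprod_j_s": 0,
              "sweat_rate_ml_min": 1}
    return _round(df, digits, rounded)


def table2(
    members: Sequence[CrewMember] | None = None,
    prescription: ExercisePrescription | None = None,
    env: Environment | None = None,
    rounded: bool = True,
) -> pd.DataFrame:
    """Single-bout totals of energy, O2, CO2, heat and sweat."""
    members = members if members is not None else crew_for()
    rx = prescription if prescription is not None else ExercisePrescription()
    cols = {}
    for m in members:
        bout = member_bout(m, rx, env)
        cols[f"{m.stature:.2f}"] = {
            "energy_mj": bout.energy,
            "o2_l": bout.o2,
            "co2_l": bout.co2,
            "heat_kj": bout.heat,
            "sweat_ml": bout.sweat,
        }
    df = pd.DataFrame(cols)
    digits = {"energy_mj": 2, "o2_l": 1, "co2_l": 1, "heat_kj": 0, "sweat_ml": 0}
    return _round(df, digits, rounded)


def table3(
    members: Sequence[CrewMember] | None = None,
    prescription: ExercisePrescription | None = None,
    env: Environment | None = None,
    rounded: bool = True,
    heat_variant: str = "paper",
) -> pd.DataFrame:
    """24-h per-person budgets without and with countermeasure exercise."""
    members = members if members is not None else crew_for()
    rx = prescription if prescription is not None else ExercisePrescription()
    cols = {}
    for m in members:
        prof = resting_profile(m)
        rest = daily_budget(m, prof, None, env, heat_variant=heat_variant)
        ex = daily_budget(m, prof, rx, env, heat_variant=heat_variant)
        ex_rates = exercise_rates(m, rx.intensity_fraction)
        cols[f"{m.stature:.2f}"] = {
            "rest_tee_mj": rest.tee,
            "rest_o2_l": rest.o2,
            "rest_co2_l": rest.co2,
            "rest_heat_mj": rest.heat,
            "rest_water_l": rest.water,
            "ex_tee_mj": ex.tee,
            "ex_o2_l": ex.o2,
            "ex_co2_l": ex.co2,
            "ex_heat_mj": ex.heat,
            "ex_water_l": ex.water,
        }
    df = pd.DataFrame(cols)
    digits = {"rest_tee_mj": 1, "rest_o2_l": 0, "rest_co2_l": 0, "rest_heat_mj": 1,
              "rest_water_l": 2, "ex_tee_mj": 1, "ex_o2_l": 0, "ex_co2_l": 0,
              "ex_heat_mj": 1, "ex_water_l": 2}
    return _round(df, digits, rounded)


def _totals(stature: float, duration: float, rx: ExercisePrescription | None,
            env: Environment | None, n_crew: int = 4, **kw):
    members = tuple(CrewMember(stature=stature) for _ in range(n_crew))
    scenario = MissionScenario(
        roster=members, duration=duration, prescription=rx,
        environment=env if env is not None else Environment())
    return mission_totals(scenario, **kw)


def table4(
    prescription: ExercisePrescription | None = None,
    env: Environment | None = None,
    durations: Sequence[float] = (30, 1080),
    small: float = 1.50,
    large: float = 1.90,
    rounded: bool = True,
) -> pd.DataFrame:
    """Mission-level absolute increases from body size alone and from
    countermeasure exercise, for a four-person crew."""
    rx = prescription if prescription is not None else ExercisePrescription()
    rows = {}
    for d in durations:
        small_rest = _totals(small, d, None, env)
        large_rest = _totals(large, d, None, env)
        small_ex = _totals(small, d, rx, env)
        large_ex = _totals(large, d, rx, env)
        size = large_rest - small_rest
        ex_small = small_ex - small_rest
        ex_large = large_ex - large_rest
        rows[f"size_{d:g}d"] = size
        rows[f"exercise_small_{d:g}d"] = ex_small
        rows[f"exercise_large_{d:g}d"] = ex_large
        rows[f"combined_{d:g}d"] = large_ex - small_rest
    df = pd.DataFrame(
        {k: {"energy_mj": v.energy, "o2_kl": v.o2 / 1000.0,
             "co2_kl": v.co2 / 1000.0, "heat_mj": v.heat, "water_l": v.water}
         for k, v in rows.items()})
    if rounded:
        df = df.round(1)
    return df


def figure_series(
    prescription: ExercisePrescription | None = None,
    env: Environment | None = None,
    statures: Sequence[float] = GRID_STATURES,
    durations: Sequence[float] = GRID_DURATIONS,
    rounded: bool = True,
) -> pd.DataFrame:
    """Long-format crew totals over the full scenario grid (the series
    plotted in the reference figures)."""
    rx = prescription if prescription is not None else ExercisePrescription()
    records = []
    for stature in statures:
        for d in durations:
            for label, rx_i in (("none", None), ("cm", rx)):
                t = _totals(stature, d, rx_i, env)
                records.append({
                    "stature_m": stature, "duration_d": d, "exercise": label,
                    "energy_mj": t.energy, "o2_kl": t.o2 / 1000.0,
                    "co2_kl": t.co2 / 1000.0, "heat_mj": t.heat,
                    "water_l": t.water,
                })
    df = pd.DataFrame.from_records(records)
    if rounded:
        for col in ("energy_mj", "o2_kl", "co2_kl", "heat_mj", "water_l"):
            df[col] = df[col].round(1)
    return df


def build_all(
    prescription: ExercisePrescription | None = None,
    env: Environment | None = None,
    rounded: bool = True,
    heat_variant: str = "paper",
) -> dict[str, pd.DataFrame]:
    """All report tables keyed by their identifiers."""
    members = crew_for()
    return {
        "table1": table1(members, prescription, env, rounded),
        "table2": table2(members, prescription, env, rounded),
        "table3": table3(members, prescription, env, rounded, heat_variant),
        "table4": table4(prescription, env, rounded=rounded),
        "figure_series": figure_series(prescription, env, rounded=rounded),
    }
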