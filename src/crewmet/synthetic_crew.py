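"""Roster generation for the hypothetical astronaut populations.

The study conditions are five homogeneous four-person male crews at
statures 1.50-1.90 m in 0.10 m steps, flown for 30-1,080 days without
and with ISS-like countermeasure exercise.  ``paper_grid`` builds that
5 x 6 x 2 scenario grid.  Stochastic samplers (uniform and truncated
normal over the agency stature band) exist for sensitivity studies; the
deterministic fixed-list sampler is the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .anthropometrics import CrewMember
from .exercise_metabolism import ExercisePrescription
from .mission_aggregation import MissionScenario
from .thermoregulation import Environment

__all__ = [
    "RosterSpec",
    "generate_roster",
    "paper_grid",
    "GRID_STATURES",
    "GRID_DURATIONS",
    "AGENCY_STATURE_BAND",
]

#: Reference statures (m) spanning the space-agency band.
GRID_STATURES: tuple[float, ...] = (1.50, 1.60, 1.70, 1.80, 1.90)

#: Reference mission durations (days): Lunar-orbit transit up to a
#: prolonged Martian-orbit mission.
GRID_DURATIONS: tuple[int, ...] = (30, 90, 180, 360, 720, 1080)

#: Historical/current stature admissibility band (m) shared by the major
#: space agencies.
AGENCY_STATURE_BAND: tuple[float, float] = (1.495, 1.905)

DEFAULT_CREW_SIZE = 4


@dataclass(frozen=True)
class RosterSpec:
    """Specification of a crew roster.

    ``sampler`` is one of:

    - ``("fixed", [statures...])`` — explicit stature list (n_crew must
      match its length);
    - ``("uniform", lo, hi)`` — i.i.d. uniform statures;
    - ``("truncnorm", mean, sd, lo, hi)`` — normal statures truncated by
      rejection to [lo, hi].

    ``shared_params`` are keyword overrides applied to every member
    (age, bmi, vo2max_rel, vo2_rest_rel, rer_rest, rer_exercise).
    """

    n_crew: int = DEFAULT_CREW_SIZE
    sampler: tuple = ("fixed", (1.70,) * DEFAULT_CREW_SIZE)
    seed: int = 0
    shared_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_crew < 1:
            raise ValueError(f"n_crew must be >= 1, got {self.n_crew!r}")
        kind = self.sampler[0]
        if kind not in ("fixed", "uniform", "truncnorm"):
            raise ValueError(f"unknown sampler kind {kind!r}")
        if kind == "fixed" and len(self.sampler[1]) != self.n_crew:
            raise ValueError(
                f"fixed sampler lists {len(self.sampler[1])} statures for "
                f"n_crew={self.n_crew}")


def _check_band(lo: float, hi: float) -> None:
    band_lo, band_hi = AGENCY_STATURE_BAND
    if lo < band_lo or hi > band_hi:
        warnings.warn(
            f"sampler bounds [{lo}, {hi}] extend outside the agency "
            f"stature band [{band_lo}, {band_hi}] m",
            stacklevel=3,
        )


def generate_roster(spec: RosterSpec) -> tuple[CrewMember, ...]:
    """Generate a fully derived crew roster; deterministic under a fixed
    seed."""
    kind = spec.sampler[0]
    if kind == "fixed":
        statures = np.asarray(spec.sampler[1], dtype=float)
    else:
        rng = np.random.default_rng(spec.seed)
        if kind == "uniform":
            lo, hi = spec.sampler[1], spec.sampler[2]
            _check_band(lo, hi)
            statures = rng.uniform(lo, hi, size=spec.n_crew)
        else:  # truncnorm, by rejection
            mean, sd, lo, hi = spec.sampler[1:5]
            _check_band(lo, hi)
            out: list[float] = []
            while len(out) < spec.n_crew:
                draw = rng.normal(mean, sd, size=max(spec.n_crew, 8))
                out.extend(d for d in draw if lo <= d <= hi)
            statures = np.asarray(out[: spec.n_crew])
    return tuple(CrewMember(stature=s, **spec.shared_params) for s in statures)


def paper_grid(
    prescription: ExercisePrescription | None = None,
    environment: Environment | None = None,
    statures: Sequence[float] = GRID_STATURES,
    durations: Sequence[float] = GRID_DURATIONS,
    n_crew: int = DEFAULT_CREW_SIZE,
) -> list[MissionScenario]:
    """The reference scenario grid: homogeneous four-person crews at each
    stature x each duration x {no exercise, countermeasure exercise}."""
    prescription = prescription if prescription is not None else ExercisePrescription()
    environment = environment if environment is not None else Environment()
    grid: list[MissionScenario] = []
    for stature in statures:
        spec = RosterSpec(n_crew=n_crew, sampler=("fixed", (stature,) * n_crew))
        roster = generate_roster(spec)
        for duration in durations:
            for rx in (None, prescription):
                grid.append(
                    MissionScenario(
                        roster=roster,
                        duration=duration,
                        prescription=rx,
                        environment=environment,
                    )
                )
    return grid
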