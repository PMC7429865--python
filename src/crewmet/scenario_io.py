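"""Scenario configuration, pipeline driver and CLI.

A scenario is described by a YAML file whose schema is validated by
pydantic (unknown keys are rejected, constraint violations name the
offending field).  An empty file yields the reference defaults: a
four-person male crew grid (BMI 26.5 kg/m^2, age 40 y, VO2max
43.4 mL/kg/min), the ISS-like cabin, ISS-like countermeasure exercise
and the reference mission durations.  ``run_pipeline`` writes the report
tables as CSV (with a provenance header), a JSON summary and a run log.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Literal, Optional

import click
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .exercise_metabolism import ExercisePrescription
from .synthetic_crew import (
    GRID_DURATIONS,
    GRID_STATURES,
    RosterSpec,
)
from .tables import TABLE_IDS, build_all
from .thermoregulation import Environment
from .water_requirements import Intake

__all__ = ["ScenarioConfig", "load_config", "save_config", "config_hash",
           "run_pipeline", "main"]

log = logging.getLogger("crewmet")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CrewParams(_Strict):
    """Shared per-member physiology (defaults: reference male crew)."""

    age: float = Field(40.0, gt=0, lt=120)
    bmi: float = Field(26.5, gt=0)
    vo2max_rel: float = Field(43.4, gt=0)
    vo2_rest_rel: float = Field(3.3, gt=0)
    rer_rest: float = Field(0.788, ge=0.6, le=1.0)
    rer_exercise: float = Field(0.898, ge=0.6, le=1.2)


class RosterConfig(_Strict):
    n_crew: int = Field(4, ge=1)
    statures: list[float] = Field(default_factory=lambda: list(GRID_STATURES))
    seed: int = 0
    params: CrewParams = CrewParams()


class EnvironmentConfig(_Strict):
    air_temp: float = 22.0
    relative_humidity: float = Field(0.55, gt=0, le=1)
    barometric_pressure: float = Field(760.0, gt=0)
    air_velocity: float = Field(0.5, ge=0)
    core_temp: float = 37.0
    skin_temp: float = 35.0
    clothing_thermal_resistance: float = Field(0.06, gt=0)
    clothing_evaporative_resistance: float = Field(0.01, gt=0)

    def to_domain(self) -> Environment:
        return Environment(**self.model_dump())


class PrescriptionConfig(_Strict):
    intensity_fraction: float = Field(0.75, gt=0, le=1)
    bout_duration: float = Field(30.0, gt=0)
    bouts_per_day: int = Field(2, ge=0)
    days_per_week: int = Field(6, ge=1, le=7)
    epoc_fraction: float = Field(0.06, ge=0, lt=1)

    def to_domain(self) -> ExercisePrescription:
        return ExercisePrescription(**self.model_dump())


class IntakeConfig(_Strict):
    protein_g: float = Field(95.0, ge=0)
    sodium_mg: float = Field(4320.0, ge=0)
    potassium_mg: float = Field(3062.0, ge=0)

    def to_domain(self) -> Intake:
        return Intake(**self.model_dump())


class ScenarioConfig(_Strict):
    """Top-level scenario: roster, environment, exercise, intakes,
    durations and reporting variants."""

    roster: RosterConfig = RosterConfig()
    environment: EnvironmentConfig = EnvironmentConfig()
    prescription: PrescriptionConfig = PrescriptionConfig()
    intake: IntakeConfig = IntakeConfig()
    durations: list[float] = Field(
        default_factory=lambda: [float(d) for d in GRID_DURATIONS])
    variant: Literal["paper", "consistent"] = "paper"
    strict_schedule: bool = False
    rounded: bool = True


def load_config(path: str | Path) -> ScenarioConfig:
    """Load and validate a YAML scenario file; empty file means defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return ScenarioConfig.model_validate(raw)


def save_config(config: ScenarioConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=True))


def config_hash(config: ScenarioConfig) -> str:
    """Stable sha256 over the canonical JSON form of the config."""
    blob = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _members(config: ScenarioConfig):
    from .synthetic_crew import generate_roster

    spec = RosterSpec(
        n_crew=len(config.roster.statures),
        sampler=("fixed", tuple(config.roster.statures)),
        seed=config.roster.seed,
        shared_params=config.roster.params.model_dump(),
    )
    return generate_roster(spec)


def run_pipeline(config: ScenarioConfig, outdir: str | Path) -> dict[str, Path]:
    """Run the full analysis for one scenario config.

    Writes table1..table4 and the figure series as CSV, a summary.json
    and run.log into ``outdir``; returns the written paths by table id.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    header = (f"# crewmet {__version__} config_sha256={chash} "
              f"seed={config.roster.seed} variant={config.variant}\n")

    members = _members(config)
    t0 = time.perf_counter()
    tables = build_all(
        prescription=config.prescription.to_domain(),
        env=config.environment.to_domain(),
        rounded=config.rounded,
        heat_variant=config.variant,
    )
    written: dict[str, Path] = {}
    logpath = outdir / "run.log"
    with logpath.open("w") as fh:
        for name in TABLE_IDS:
            stage_t = time.perf_counter()
            df = tables[name]
            path = outdir / f"{name}.csv"
            with path.open("w", newline="") as out:
                out.write(header)
                df.to_csv(out)
            written[name] = path
            fh.write(
                f"stage={name} rows={len(df)} "
                f"wall_s={time.perf_counter() - stage_t:.4f}\n")
        summary = {
            "version": __version__,
            "config_sha256": chash,
            "seed": config.roster.seed,
            "variant": config.variant,
            "strict_schedule": config.strict_schedule,
            "n_crew": len(members),
            "statures_m": [m.stature for m in members],
            "durations_d": list(config.durations),
            "tables": {k: str(v) for k, v in written.items()},
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
        fh.write(f"stage=summary rows=1 wall_s={time.perf_counter() - t0:.4f}\n")
    written["summary"] = outdir / "summary.json"
    return written


def _print_table_ids(ctx, param, value):
    if not value or ctx.resilient_parsing:
        return
    for name in TABLE_IDS:
        click.echo(name)
    ctx.exit(0)


@click.group()
@click.version_option(__version__, prog_name="crewmet")
@click.option("--list-tables", is_flag=True, callback=_print_table_ids,
              expose_value=False, is_eager=True,
              help="List the table identifiers the pipeline emits and exit.")
def main() -> None:
    """Crew metabolic-resource budgets for exploration missions."""


@main.command()
@click.option("-c", "--config", "config_path", type=click.Path(exists=True),
              default=None, help="Scenario YAML (defaults when omitted).")
@click.option("-o", "--outdir", type=click.Path(), required=True)
@click.option("--variant", type=click.Choice(["paper", "consistent"]),
              default=None, help="Override the 24-h heat accounting variant.")
@click.option("--strict-schedule", is_flag=True, default=None,
              help="Honour days_per_week pro rata instead of daily exercise.")
def run(config_path, outdir, variant, strict_schedule) -> None:
    """Run the pipeline and write report tables."""
    try:
        config = load_config(config_path) if config_path else ScenarioConfig()
    except ValidationError as err:
        raise click.ClickException(str(err)) from err
    updates = {}
    if variant is not None:
        updates["variant"] = variant
    if strict_schedule:
        updates["strict_schedule"] = True
    if updates:
        config = config.model_copy(update=updates)
    written = run_pipeline(config, outdir)
    for name, path in written.items():
        click.echo(f"{name}: {path}")


@main.command()
@click.option("-o", "--outdir", type=click.Path(), required=True)
def tables(outdir) -> None:
    """Emit the reference scenario grid tables with all defaults."""
    written = run_pipeline(ScenarioConfig(), outdir)
    for name, path in written.items():
        click.echo(f"{name}: {path}")


@main.command()
@click.option("-c", "--config", "config_path", type=click.Path(exists=True),
              required=True)
def validate(config_path) -> None:
    """Validate a scenario YAML file."""
    try:
        config = load_config(config_path)
    except ValidationError as err:
        raise click.ClickException(str(err)) from err
    click.echo(f"valid (config_sha256={config_hash(config)})")
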