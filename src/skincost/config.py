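"""Run configuration: loading, validation and the end-to-end pipeline.

``run_pipeline`` ties the modules together for one country/cancer: resolve
the parameter set (a supplied CSV/YAML file or the calibrated headline
fixture), validate the pathway models, run the Monte Carlo and tornado
analyses, extrapolate the national burden and build the 5-year projection,
and write the result tables plus a run log (seed, config echo, config hash)
to the output directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .burden import (
    ProjectionAssumptions,
    build_projection_table,
    national_cost,
    round_millions,
    scenario_incidence_uplift,
    scenario_nnb,
)
from .kc import build_kc_model
from .melanoma import STAGES, StageDistribution, build_melanoma_model, stage_weighted_mean
from .model_graph import validate_model
from .parameters import Cancer, Country, ParameterSet
from .reference_inputs import (
    DEATH_SCHEDULES,
    INCREMENTAL_COST_SCHEDULES,
    KC_INCIDENT_PERSONS,
    MELANOMA_INCIDENT_PERSONS,
)
from .synthetic import headline_fixture
from .uncertainty import ModelCost, StageWeightedCost, one_way_sensitivity, run_psa

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config", "run_pipeline"]


class ConfigError(ValueError):
    """Invalid or unresolvable run configuration."""


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    country: str = "AU"
    cancer: str = "melanoma"
    parameter_file: str | None = None
    n_iterations: int = 10_000
    seed: int = 0
    margin: float = 0.15
    nnb_specialist: float = 3.5
    nnb_gp: float = 14.6
    nnb_gp_fraction: float = 0.5
    kc_incidence_uplift: float = 0.20
    output_dir: str = "results"

    def __post_init__(self) -> None:
        Country(self.country)
        cancer = Cancer(self.cancer)
        if cancer is Cancer.SHARED:
            raise ConfigError("cancer must be 'melanoma' or 'KC'")
        if self.n_iterations < 1:
            raise ConfigError("n_iterations must be >= 1")
        if not 0.05 <= self.margin <= 0.5:
            raise ConfigError("margin must be within [0.05, 0.5]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Parse, default and validate a YAML run configuration (strict keys)."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ConfigError(f"config root must be a mapping, got {type(doc).__name__}")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(doc) - known)
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(unknown)}")
    try:
        return RunConfig(**doc)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def _resolve_params(config: RunConfig) -> ParameterSet:
    if config.parameter_file is None:
        params, _ = headline_fixture(config.country)
        return params
    path = Path(config.parameter_file)
    if not path.exists():
        raise ConfigError(f"parameter file not found: {path}")
    if path.suffix.lower() in (".yaml", ".yml"):
        return ParameterSet.from_yaml(path)
    return ParameterSet.from_csv(path)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full pipeline for one country/cancer; returns written paths.

    Outputs (CSV unless noted): per-model cost summaries with 95% UIs, the
    tornado table, the national burden table and the 5-year projection
    table, plus ``run_log.json``.  Currency columns are 2021 AU$/NZ$.
    """
    country = Country(config.country)
    cancer = Cancer(config.cancer)
    params = _resolve_params(config)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    currency = f"{country.value}$2021"

    if cancer is Cancer.MELANOMA:
        models = {s: build_melanoma_model(country, s) for s in STAGES}
        for stage, model in models.items():
            validate_model(model, params).raise_if_invalid()
        summaries = []
        stage_means = {}
        for i, stage in enumerate(STAGES):
            summary = run_psa(
                models[stage], params, n=config.n_iterations, seed=config.seed + i
            )
            stage_means[stage] = ModelCost(models[stage]).evaluate(params.point_values())
            summaries.append(
                {
                    "group": stage,
                    f"deterministic_mean ({currency})": stage_means[stage],
                    f"psa_mean ({currency})": summary.mean,
                    f"ui_low ({currency})": summary.ui_low,
                    f"ui_high ({currency})": summary.ui_high,
                    "n_iterations": summary.n_iterations,
                    "seed": summary.seed,
                }
            )
        dist = StageDistribution.default()
        mean_cost = stage_weighted_mean(dist, stage_means)
        evaluator = StageWeightedCost(models)
        tornado = one_way_sensitivity(evaluator, params, margin=config.margin)
        persons = MELANOMA_INCIDENT_PERSONS[country.value]
    else:
        model = build_kc_model(country)
        validate_model(model, params).raise_if_invalid()
        summary = run_psa(model, params, n=config.n_iterations, seed=config.seed)
        mean_cost = ModelCost(model).evaluate(params.point_values())
        summaries = [
            {
                "group": "KC",
                f"deterministic_mean ({currency})": mean_cost,
                f"psa_mean ({currency})": summary.mean,
                f"ui_low ({currency})": summary.ui_low,
                f"ui_high ({currency})": summary.ui_high,
                "n_iterations": summary.n_iterations,
                "seed": summary.seed,
            }
        ]
        tornado = one_way_sensitivity(model, params, margin=config.margin)
        persons = KC_INCIDENT_PERSONS[country.value]

    total_millions = national_cost(mean_cost, persons)
    burden_rows = [
        {
            "region": country.value,
            "cancer": cancer.value,
            f"mean_cost_per_person ({currency})": mean_cost,
            "incident_persons": persons,
            f"total_cost_millions ({currency})": round_millions(total_millions),
        }
    ]
    key = (country.value, cancer.value)
    assumptions = ProjectionAssumptions(
        deaths=DEATH_SCHEDULES[key],
        incremental_cost_per_person=INCREMENTAL_COST_SCHEDULES[key],
    )
    projection = build_projection_table(persons, total_millions, assumptions)

    # scenario block
    scenarios = []
    if cancer is Cancer.MELANOMA:
        biopsy_component = params["cost_pathology"].point_estimate
        nnb = scenario_nnb(
            mean_cost,
            biopsy_component,
            persons,
            config.nnb_specialist,
            config.nnb_gp,
            config.nnb_gp_fraction,
        )
        scenarios.append(
            {
                "scenario": "number_needed_to_biopsy",
                f"per_patient_cost ({currency})": nnb.adjusted_per_patient_cost,
                f"national_cost_millions ({currency})": round_millions(
                    nnb.national_cost_millions
                ),
            }
        )
    else:
        uplifted = scenario_incidence_uplift(total_millions, config.kc_incidence_uplift)
        scenarios.append(
            {
                "scenario": f"incidence_uplift_{config.kc_incidence_uplift:+.0%}",
                f"per_patient_cost ({currency})": mean_cost,
                f"national_cost_millions ({currency})": round_millions(uplifted),
            }
        )

    paths = {}
    frames = {
        "cost_summaries": pd.DataFrame(summaries),
        "tornado": tornado.to_frame(),
        "burden": pd.DataFrame(burden_rows),
        "projection": projection,
        "scenarios": pd.DataFrame(scenarios),
    }
    tag = f"{country.value}_{cancer.value}"
    for name, frame in frames.items():
        path = outdir / f"{name}_{tag}.csv"
        frame.to_csv(path, index=False, float_format="%.6f")
        paths[name] = path

    log = {
        "package_version": __version__,
        "seed": config.seed,
        "config": self_config(config),
        "config_hash": config.config_hash(),
        "outputs": {k: str(v) for k, v in paths.items()},
    }
    log_path = outdir / f"run_log_{tag}.json"
    with open(log_path, "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    paths["run_log"] = log_path
    return paths


def self_config(config: RunConfig) -> dict:
    return config.to_dict()
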