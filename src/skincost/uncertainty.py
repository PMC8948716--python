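"""Probabilistic (Monte Carlo) and one-way (tornado) sensitivity analysis.

PSA draws every non-fixed parameter from its fitted beta/gamma distribution
once per iteration and evaluates the full model, yielding a mean cost and a
95% uncertainty interval from the 2.5th/97.5th percentiles of the ranked
draws.  One-way analysis moves one parameter at a time to a low/high setting
(a +/- margin around the point estimate, or its 25th/75th percentiles) and
ranks parameters by the induced output range.

Both analyses accept a :class:`~skincost.model_graph.PathwayModel` directly
or any "cost evaluator" object exposing ``evaluate(values)`` and
``referenced_names()``; :class:`StageWeightedCost` combines the per-stage
melanoma models into the all-stage mean through the stage-proportion
parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .melanoma import STAGES
from .model_graph import PathwayModel, expected_cost, referenced_parameters
from .parameters import Distribution, Kind, ParameterSet

__all__ = [
    "CostSummary",
    "TornadoEntry",
    "TornadoResult",
    "ModelCost",
    "StageWeightedCost",
    "run_psa",
    "percentile_interval",
    "one_way_sensitivity",
]

#: Per-model calibration scales are internal knobs, never varied in analyses.
_SCALE_PREFIX = "cost_scale_"


@dataclass
class ModelCost:
    """Adapter evaluating one pathway model to a scalar cost.

    ``metric`` is ``"year1"`` (first-year mean, the headline per-patient
    figure) or ``"total"`` (cumulative cost over the horizon).
    """

    model: PathwayModel
    metric: str = "year1"
    horizon: int | None = None

    def __post_init__(self) -> None:
        if self.metric not in ("year1", "total"):
            raise ValueError(f"metric must be 'year1' or 'total', got {self.metric!r}")

    def evaluate(self, values: Mapping[str, float]) -> float:
        result = expected_cost(self.model, values, self.horizon)
        return result.year1 if self.metric == "year1" else result.total

    def referenced_names(self) -> set[str]:
        return referenced_parameters(self.model)


@dataclass
class StageWeightedCost:
    """All-stage melanoma cost: stage-proportion-weighted per-stage means.

    Stage proportions are parameters (``p_stage_<stage>``) with the last
    stage's share as the complement, so sampled proportions always sum to one.
    """

    models: Mapping[str, PathwayModel]
    metric: str = "year1"

    def __post_init__(self) -> None:
        missing = set(STAGES) - set(self.models)
        if missing:
            raise ValueError(f"missing stage models for {sorted(missing)}")

    def stage_proportions(self, values: Mapping[str, float]) -> dict[str, float]:
        props = {s: values[f"p_stage_{s}"] for s in STAGES[:-1]}
        props[STAGES[-1]] = max(1.0 - sum(props.values()), 0.0)
        return props

    def evaluate(self, values: Mapping[str, float]) -> float:
        props = self.stage_proportions(values)
        total = 0.0
        for stage in STAGES:
            adapter = ModelCost(self.models[stage], self.metric)
            total += props[stage] * adapter.evaluate(values)
        return total

    def referenced_names(self) -> set[str]:
        names: set[str] = {f"p_stage_{s}" for s in STAGES[:-1]}
        for model in self.models.values():
            names |= referenced_parameters(model)
        return names


def _as_evaluator(model_or_eval, metric: str = "year1"):
    if isinstance(model_or_eval, PathwayModel):
        return ModelCost(model_or_eval, metric)
    return model_or_eval


@dataclass
class CostSummary:
    """Mean cost with its 95% uncertainty interval from Monte Carlo draws."""

    mean: float
    ui_low: float
    ui_high: float
    n_iterations: int
    seed: int
    metric: str = "year1"
    samples: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.ui_low > self.ui_high:
            raise ValueError("ui_low must not exceed ui_high")


def percentile_interval(
    samples: Sequence[float], lower_pct: float = 2.5, upper_pct: float = 97.5
) -> tuple[float, float]:
    """Empirical percentile interval, rank-based with linear interpolation."""
    arr = np.asarray(samples, dtype=float)
    if arr.size == 0:
        raise ValueError("percentile_interval needs at least one sample")
    low, high = np.percentile(arr, [lower_pct, upper_pct])
    return float(low), float(high)


def run_psa(
    model_or_evaluator,
    params: ParameterSet,
    n: int = 10_000,
    seed: int = 0,
    metric: str = "year1",
    keep_samples: bool = False,
) -> CostSummary:
    """Monte Carlo parameter-uncertainty analysis.

    Each of the ``n`` iterations draws one value per parameter (fixed specs
    stay at their point estimate) and evaluates the full model; the summary is
    the sample mean and 2.5th/97.5th percentile interval.  Bit-reproducible
    given the seed.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n!r}")
    evaluator = _as_evaluator(model_or_evaluator, metric)
    rng = np.random.default_rng(seed)
    costs = np.empty(n)
    for i in range(n):
        values = params.sample_values(rng)
        costs[i] = evaluator.evaluate(values)
    low, high = percentile_interval(costs)
    return CostSummary(
        mean=float(costs.mean()),
        ui_low=low,
        ui_high=high,
        n_iterations=n,
        seed=seed,
        metric=getattr(evaluator, "metric", metric),
        samples=costs if keep_samples else None,
    )


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low_setting: float
    high_setting: float
    low_cost: float
    high_cost: float

    @property
    def range(self) -> float:
        return abs(self.high_cost - self.low_cost)


@dataclass
class TornadoResult:
    """One-way sensitivity results, ranked by descending output range."""

    base_cost: float
    entries: list[TornadoEntry]

    def ranking(self) -> list[str]:
        return [e.parameter for e in self.entries]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "parameter": e.parameter,
                "low_setting": e.low_setting,
                "high_setting": e.high_setting,
                "low_cost": e.low_cost,
                "high_cost": e.high_cost,
                "range": e.range,
                "rank": i + 1,
            }
            for i, e in enumerate(self.entries)
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "parameter",
                "low_setting",
                "high_setting",
                "low_cost",
                "high_cost",
                "range",
                "rank",
            ],
        )


def _settings_for(spec, margin: float, mode: str) -> tuple[float, float]:
    point = spec.point_estimate
    if mode == "quartiles" and spec.distribution is not Distribution.FIXED:
        return spec.quantile(0.25), spec.quantile(0.75)
    low = point * (1.0 - margin)
    high = point * (1.0 + margin)
    if spec.kind is Kind.PROBABILITY:
        if high > 1.0:
            warnings.warn(
                f"{spec.name}: high setting {high:.4g} clamped to 1", stacklevel=3
            )
            high = 1.0
        low = max(low, 0.0)
    return low, high


def one_way_sensitivity(
    model_or_evaluator,
    params: ParameterSet,
    margin: float = 0.15,
    mode: str = "margin",
    parameters: Sequence[str] | None = None,
    metric: str = "year1",
) -> TornadoResult:
    """Tornado analysis: vary each parameter alone between low/high settings.

    ``mode="margin"`` sets low/high to the point estimate times (1 -/+ margin)
    with probabilities clamped to [0, 1]; ``mode="quartiles"`` uses each
    non-fixed parameter's fitted 25th/75th percentiles.  All other parameters
    stay at their point estimates.
    """
    if mode not in ("margin", "quartiles"):
        raise ValueError(f"mode must be 'margin' or 'quartiles', got {mode!r}")
    if mode == "margin" and not 0.05 <= margin <= 0.5:
        raise ValueError(f"margin must be within [0.05, 0.5], got {margin!r}")
    evaluator = _as_evaluator(model_or_evaluator, metric)
    base_values = params.point_values()
    base_cost = evaluator.evaluate(base_values)

    if parameters is None:
        # vary the uncertain inputs: published anchors (fixed specs) and
        # internal calibration scales stay put
        parameters = sorted(
            name
            for name in evaluator.referenced_names()
            if name in params.names
            and not name.startswith(_SCALE_PREFIX)
            and params[name].distribution is not Distribution.FIXED
        )

    entries = []
    for name in parameters:
        spec = params[name]
        low_setting, high_setting = _settings_for(spec, margin, mode)
        values = dict(base_values)
        values[name] = low_setting
        low_cost = evaluator.evaluate(values)
        values[name] = high_setting
        high_cost = evaluator.evaluate(values)
        entries.append(
            TornadoEntry(name, low_setting, high_setting, low_cost, high_cost)
        )
    entries.sort(key=lambda e: (-e.range, e.parameter))
    return TornadoResult(base_cost=base_cost, entries=entries)
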