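"""National burden extrapolation, 5-year projections and scenario analyses.

The national figure is per-patient mean cost times incident persons.  The
5-year projection compounds incident cases at the registry growth factor
(1.0091/yr), accumulates the continuing cohort net of deaths, and prices
first-incident and subsequent-episode costs separately; health inflation
(2.02%/yr average) is applied once at the first projected year, which is the
schedule consistent with the published cost rows.  Scenario analyses cover
the number-needed-to-biopsy (NNB) case-finding multiplier and a KC incidence
uplift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .reference_inputs import (
    CASE_GROWTH,
    HEALTH_INFLATION,
    NNB_GP,
    NNB_SPECIALIST,
)

__all__ = [
    "IncidenceRecord",
    "ProjectionAssumptions",
    "NNBScenario",
    "national_cost",
    "estimate_cases",
    "project_incident_cases",
    "project_first_incident_cost",
    "accumulate_continuing_cohort",
    "build_projection_table",
    "scenario_nnb",
    "scenario_incidence_uplift",
    "round_millions",
]


def round_millions(value: float) -> float:
    """Display rounding for cost columns: 0.1 million."""
    return round(value, 1)


@dataclass(frozen=True)
class IncidenceRecord:
    """Region-level incidence inputs and estimated case counts."""

    region: str
    population: float
    incidence_rate: float  # per 100,000
    est_invasive_cases: float
    est_in_situ_cases: float
    est_kc_cases: float = 0.0

    def __post_init__(self) -> None:
        for fname in (
            "population",
            "incidence_rate",
            "est_invasive_cases",
            "est_in_situ_cases",
            "est_kc_cases",
        ):
            if getattr(self, fname) < 0:
                raise ValueError(f"{fname} must be >= 0")

    @property
    def est_melanoma_persons(self) -> float:
        return self.est_invasive_cases + self.est_in_situ_cases


def national_cost(mean_cost_per_person: float, persons: float) -> float:
    """Total national cost in millions: per-person mean times incident persons."""
    if mean_cost_per_person < 0 or persons < 0:
        raise ValueError("mean cost and persons must be >= 0")
    return mean_cost_per_person * persons / 1e6


def estimate_cases(
    rate_per_100k: float,
    population: float,
    in_situ_ratio: float = 1.0,
    region: str = "",
    invasive_cases: float | None = None,
) -> IncidenceRecord:
    """Crude-rate case estimate: invasive = rate x population / 100,000.

    Published registry-projected counts can be supplied via ``invasive_cases``
    and take precedence over the crude product (registry projections are
    age-structured; the crude product is not).
    """
    if rate_per_100k < 0 or population < 0 or in_situ_ratio < 0:
        raise ValueError("inputs must be >= 0")
    invasive = (
        rate_per_100k * population / 1e5 if invasive_cases is None else invasive_cases
    )
    return IncidenceRecord(
        region=region,
        population=population,
        incidence_rate=rate_per_100k,
        est_invasive_cases=invasive,
        est_in_situ_cases=invasive * in_situ_ratio,
    )


def project_incident_cases(
    base_cases: float, growth: float = CASE_GROWTH, years: int = 4
) -> np.ndarray:
    """Compound incident cases over ``years`` projected years (unrounded)."""
    if base_cases < 0:
        raise ValueError("base_cases must be >= 0")
    if years < 1:
        raise ValueError("years must be >= 1")
    t = np.arange(1, years + 1)
    return base_cases * growth**t


@dataclass(frozen=True)
class ProjectionAssumptions:
    """Assumptions driving the 5-year national projection.

    ``inflation_years`` lists the projected years (1-based) in which health
    inflation applies; the default single application at year 1 is the
    schedule that reproduces the published cost rows.  ``deaths`` and
    ``incremental_cost_per_person`` run over projected years 1..n.
    """

    case_growth: float = CASE_GROWTH
    health_inflation: float = HEALTH_INFLATION
    inflation_years: tuple[int, ...] = (1,)
    deaths: Sequence[float] = (0.0, 0.0, 0.0, 0.0)
    incremental_cost_per_person: Sequence[float] = (0.0, 0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.case_growth <= 0:
            raise ValueError("case_growth must be positive")


def project_first_incident_cost(
    base_cost_millions: float,
    assumptions: ProjectionAssumptions = ProjectionAssumptions(),
    years: int = 4,
    round_each_year: bool = True,
) -> list[float]:
    """Project the first-incident national cost over the coming years.

    Each projected year multiplies the previous year's cost by the case
    growth factor, plus the inflation factor in the scheduled years.  With
    ``round_each_year`` each value is display-rounded (0.1m) before
    compounding the next, matching how the published rows chain.
    """
    if base_cost_millions < 0:
        raise ValueError("base cost must be >= 0")
    out: list[float] = []
    current = base_cost_millions
    for year in range(1, years + 1):
        factor = assumptions.case_growth
        if year in assumptions.inflation_years:
            factor *= 1.0 + assumptions.health_inflation
        current = current * factor
        if round_each_year:
            current = round_millions(current)
        out.append(current)
    return out


def accumulate_continuing_cohort(
    prior_continuing: float, prior_incident: float, deaths: float
) -> float:
    """Next year's continuing cohort: prior pool plus prior incidents, minus deaths."""
    if prior_continuing < 0 or prior_incident < 0 or deaths < 0:
        raise ValueError("inputs must be >= 0")
    pool = prior_continuing + prior_incident
    if deaths > pool:
        warnings.warn(
            f"deaths ({deaths:.0f}) exceed the cohort pool ({pool:.0f}); floored at 0",
            stacklevel=2,
        )
        return 0.0
    return pool - deaths


def build_projection_table(
    base_cases: float,
    base_cost_millions: float,
    assumptions: ProjectionAssumptions,
    years: int = 5,
    start_year: int = 2021,
) -> pd.DataFrame:
    """Five-year projection: incident cases, continuing cohort, costs, totals.

    Row conventions follow the published table: case counts are rounded to
    integers for display, costs to 0.1 million, and each year's total is the
    sum of the (displayed) first-incident and subsequent-episode costs.
    """
    n_proj = years - 1
    incident_unrounded = [float(base_cases)] + list(
        project_incident_cases(base_cases, assumptions.case_growth, n_proj)
    )
    incident = [int(round(c)) for c in incident_unrounded]
    first_cost = [round_millions(base_cost_millions)] + project_first_incident_cost(
        base_cost_millions, assumptions, n_proj
    )

    deaths = list(assumptions.deaths)[:n_proj] + [0.0] * max(
        0, n_proj - len(assumptions.deaths)
    )
    increments = list(assumptions.incremental_cost_per_person)[:n_proj] + [0.0] * max(
        0, n_proj - len(assumptions.incremental_cost_per_person)
    )

    continuing = [0]
    for t in range(n_proj):
        continuing.append(
            int(round(accumulate_continuing_cohort(continuing[-1], incident[t], deaths[t])))
        )

    subsequent = [0.0] + [
        round_millions(continuing[t + 1] * increments[t] / 1e6) for t in range(n_proj)
    ]
    total = [round_millions(f + s) for f, s in zip(first_cost, subsequent)]

    return pd.DataFrame(
        {
            "year": [start_year + t for t in range(years)],
            "first_incident_cases": incident,
            "continuing_cohort": continuing,
            "cost_first_incident_millions": first_cost,
            "cost_subsequent_millions": subsequent,
            "total_cost_millions": total,
        }
    )


@dataclass(frozen=True)
class NNBScenario:
    """Outcome of the number-needed-to-biopsy case-finding scenario."""

    weighted_nnb: float
    adjusted_per_patient_cost: float
    national_cost_millions: float


def scenario_nnb(
    per_patient_cost: float,
    biopsy_cost_component: float,
    persons: float,
    nnb_specialist: float = NNB_SPECIALIST,
    nnb_gp: float = NNB_GP,
    gp_fraction: float = 0.5,
) -> NNBScenario:
    """Scale diagnostic biopsy costs by the provider-weighted NNB multiplier.

    To find one melanoma, specialists biopsy 3.5 lesions and GPs 14.6; the
    per-patient cost gains ``biopsy_cost_component x (weighted_nnb - 1)`` and
    the national figure follows linearly.
    """
    if nnb_specialist < 1 or nnb_gp < 1:
        raise ValueError("NNB multipliers must be >= 1")
    if not 0.0 <= gp_fraction <= 1.0:
        raise ValueError("gp_fraction must be in [0, 1]")
    if per_patient_cost < 0 or biopsy_cost_component < 0:
        raise ValueError("costs must be >= 0")
    weighted = gp_fraction * nnb_gp + (1.0 - gp_fraction) * nnb_specialist
    adjusted = per_patient_cost + biopsy_cost_component * (weighted - 1.0)
    return NNBScenario(
        weighted_nnb=weighted,
        adjusted_per_patient_cost=adjusted,
        national_cost_millions=national_cost(adjusted, persons),
    )


def scenario_incidence_uplift(base_total_millions: float, uplift: float) -> float:
    """Total national cost when incidence is ``uplift`` higher (e.g. +20% KC)."""
    if uplift < -1.0:
        raise ValueError("uplift must be >= -1")
    return base_total_millions * (1.0 + uplift)
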