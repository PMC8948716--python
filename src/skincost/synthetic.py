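"""Synthetic parameter sets and the calibrated headline fixture.

The patient-level sources behind the pathway probabilities and unit costs
(linked claims data, national prescription records, hospital costing reports)
are restricted, so this module generates complete, internally consistent
parameter sets with the published statistical structure: beta-distributed
probabilities, gamma-distributed costs, a default SE of 10% of the point
estimate, and the published anchors held fixed (SLNB uptake 60.4%, excision
after biopsy 90.5%, hospitalisation 44/10,000, annualised 5-year multiplicity
50.9%, year-1 script share 89%, adverse events within 15-28%).

Unit-cost levels are then calibrated: a per-model scale factor is solved so
each stage model's deterministic first-year mean matches the published
headline figure (e.g. AU$644 for melanoma in situ, AU$100,725 for
unresectable III/IV, AU$525 per KC).  The calibrated fixture claims only to
reproduce those aggregate means, never to recover true unit costs; every
value carries a provenance flag (printed-in-paper / assumption / calibrated)
in the accompanying manifest.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .kc import KC_SCALE_PARAM, annual_multiplicity, build_kc_model
from .melanoma import STAGES, build_melanoma_model
from .model_graph import PathwayModel
from .parameters import (
    Cancer,
    Country,
    Distribution,
    Kind,
    NZ_AU_PRICE_RATIO,
    ParameterError,
    ParameterSet,
    ParameterSpec,
    impute_nz_unit_cost,
    survival_to_annual_transition,
)
from .reference_inputs import KC_MEAN_COST, STAGE_COST_TARGETS
from .uncertainty import ModelCost

__all__ = [
    "FixtureManifest",
    "ManifestEntry",
    "generate_parameter_set",
    "calibrate_costs",
    "headline_fixture",
    "write_fixture",
]

PRINTED = "printed-in-paper"
ASSUMPTION = "assumption"
CALIBRATED = "calibrated"


@dataclass(frozen=True)
class ManifestEntry:
    name: str
    value: float
    provenance: str
    citation: str = ""


@dataclass
class FixtureManifest:
    """Per-parameter provenance record for a packaged fixture."""

    entries: list[ManifestEntry]

    def __post_init__(self) -> None:
        for e in self.entries:
            if e.provenance == PRINTED and not e.citation:
                raise ValueError(f"{e.name}: printed value without a citation")

    def provenance_of(self, name: str) -> str:
        for e in self.entries:
            if e.name == name:
                return e.provenance
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "name": e.name,
                    "value": e.value,
                    "provenance": e.provenance,
                    "citation": e.citation,
                }
                for e in sorted(self.entries, key=lambda e: e.name)
            ],
            columns=["name", "value", "provenance", "citation"],
        )


# ---------------------------------------------------------------------------
# templates
#
# Each row: (name, kind, point, distribution, provenance, citation, jitter).
# jitter is the relative half-width of the uniform range generate_parameter_set
# draws assumption values from; anchors have jitter 0.

_SE_FRACTION = 0.10  # default dispersion: SE = 10% of the point estimate

# annual palliative-care transition probabilities from 5-year trial survival
_SURVIVAL_5Y = {
    "ipilimumab": 0.20,
    "nivolumab": 0.44,
    "pembrolizumab": 0.43,
    "dabrafenib_trametinib": 0.34,
    "interferon": 0.30,
}
_P_PALLIATIVE = {
    tx: survival_to_annual_transition(s, 5) for tx, s in _SURVIVAL_5Y.items()
}

_AE_PROBS = {
    "ipilimumab": 0.28,
    "nivolumab": 0.16,
    "pembrolizumab": 0.17,
    "dabrafenib_trametinib": 0.24,
    "interferon": 0.20,
}

_AE_CITATION = "grade 3/4 adverse-event rates within the published 15-28% range"

# AU unit costs (2021 AU$); NZ service costs are imputed at the 1.91 price
# ratio, NZ pharmaceutical courses carry their own schedule prices.
_AU_SERVICE_COSTS = {
    "cost_gp_consult": 40.0,
    "cost_skin_exam": 82.0,
    "cost_pathology": 97.0,
    "cost_biopsy_shave": 50.0,
    "cost_biopsy_punch": 62.0,
    "cost_excision_in_situ": 420.0,
    "cost_excision_invasive": 650.0,
    "cost_wide_excision": 1_200.0,
    "cost_slnb": 4_500.0,
    "cost_clnd": 11_000.0,
    "cost_radiotherapy_course": 8_000.0,
    "cost_ae_hospitalisation": 9_500.0,
    "cost_palliative_care": 11_000.0,
    "cost_kc_excision": 250.0,
    "cost_cautery": 55.0,
    "cost_cryotherapy": 45.0,
    "cost_topical_course": 120.0,
    "cost_specialist_consult": 90.0,
    "cost_reexcision": 220.0,
    "cost_hospital_wide_excision": 2_500.0,
    "cost_hospital_radiotherapy": 6_000.0,
    "cost_hospital_mohs": 3_000.0,
}

_COURSE_COSTS = {
    "AU": {
        "ipilimumab": 130_000.0,
        "nivolumab": 95_000.0,
        "pembrolizumab": 105_000.0,
        "dabrafenib_trametinib": 140_000.0,
    },
    "NZ": {
        "nivolumab": 85_000.0,
        "pembrolizumab": 95_000.0,
        "interferon": 28_000.0,
    },
}

_MELANOMA_KC_SHARED = ("cost_skin_exam", "cost_pathology", "p_background_mortality")


def _rows_melanoma(country: Country) -> list[tuple]:
    imputed = country is Country.NZ

    def cost(name: str) -> float:
        au = _AU_SERVICE_COSTS[name]
        return impute_nz_unit_cost(au) if imputed else au

    cost_cite = (
        f"AU unit cost x {NZ_AU_PRICE_RATIO} AU->NZ relative price ratio"
        if imputed
        else ""
    )
    rows = [
        ("p_slnb_uptake", Kind.PROBABILITY, 0.604, Distribution.FIXED, PRINTED,
         "SLNB uptake 60.4% in melanomas meeting thickness criteria", 0.0),
        ("p_slnb_positive", Kind.PROBABILITY, 0.12, Distribution.BETA, ASSUMPTION, "", 0.15),
        ("p_clnd", Kind.PROBABILITY, 0.40, Distribution.BETA, ASSUMPTION, "", 0.15),
        ("p_radiotherapy_iii", Kind.PROBABILITY, 0.20, Distribution.BETA, ASSUMPTION, "", 0.15),
        ("p_palliative_adjuvant", Kind.PROBABILITY,
         survival_to_annual_transition(0.60, 5), Distribution.BETA, ASSUMPTION, "", 0.10),
        ("p_palliative_iii", Kind.PROBABILITY,
         survival_to_annual_transition(0.55, 5), Distribution.BETA, ASSUMPTION, "", 0.10),
        ("p_background_mortality", Kind.PROBABILITY, 0.01, Distribution.BETA,
         ASSUMPTION, "", 0.15),
        ("therapy_year1_share", Kind.PROBABILITY, 0.89, Distribution.FIXED, PRINTED,
         "89% of systemic-therapy scripts claimed within 12 months of diagnosis", 0.0),
        ("p_stage_in_situ", Kind.PROBABILITY, 0.50, Distribution.FIXED, PRINTED,
         "1:1 incidence rate ratio of in situ to invasive melanoma", 0.0),
        ("p_stage_IA", Kind.PROBABILITY, 0.22, Distribution.BETA, ASSUMPTION, "", 0.10),
        ("p_stage_IB_II", Kind.PROBABILITY, 0.14, Distribution.BETA, ASSUMPTION, "", 0.10),
        ("p_stage_III_resectable", Kind.PROBABILITY, 0.09, Distribution.BETA,
         ASSUMPTION, "", 0.10),
    ]
    if country is Country.AU:
        rows += [
            ("p_adjuvant_uptake", Kind.PROBABILITY, 0.60, Distribution.BETA,
             ASSUMPTION, "", 0.15),
            ("p_tx_adjuvant_nivolumab", Kind.PROBABILITY, 0.45, Distribution.BETA,
             ASSUMPTION, "", 0.10),
            ("p_tx_adjuvant_pembrolizumab", Kind.PROBABILITY, 0.35, Distribution.BETA,
             ASSUMPTION, "", 0.10),
            ("p_tx_advanced_ipilimumab", Kind.PROBABILITY, 0.10, Distribution.BETA,
             ASSUMPTION, "", 0.10),
            ("p_tx_advanced_nivolumab", Kind.PROBABILITY, 0.40, Distribution.BETA,
             ASSUMPTION, "", 0.10),
            ("p_tx_advanced_pembrolizumab", Kind.PROBABILITY, 0.30, Distribution.BETA,
             ASSUMPTION, "", 0.10),
        ]
        therapies = ("ipilimumab", "nivolumab", "pembrolizumab", "dabrafenib_trametinib")
    else:
        rows += [
            ("p_interferon_uptake", Kind.PROBABILITY, 0.50, Distribution.BETA,
             ASSUMPTION, "", 0.15),
            ("p_tx_advanced_nivolumab", Kind.PROBABILITY, 0.55, Distribution.BETA,
             ASSUMPTION, "", 0.10),
        ]
        therapies = ("nivolumab", "pembrolizumab", "interferon")

    for tx in therapies:
        rows += [
            (f"p_ae_{tx}", Kind.PROBABILITY, _AE_PROBS[tx], Distribution.BETA,
             ASSUMPTION, _AE_CITATION, 0.0),
            (f"p_palliative_{tx}", Kind.PROBABILITY, _P_PALLIATIVE[tx],
             Distribution.BETA, ASSUMPTION,
             "annualised from 4/5-year overall survival in pivotal trials", 0.10),
            (f"cost_course_{tx}", Kind.COST, _COURSE_COSTS[country.value][tx],
             Distribution.GAMMA, ASSUMPTION, "", 0.20),
        ]

    for name in (
        "cost_skin_exam",
        "cost_pathology",
        "cost_excision_in_situ",
        "cost_excision_invasive",
        "cost_wide_excision",
        "cost_slnb",
        "cost_clnd",
        "cost_radiotherapy_course",
        "cost_ae_hospitalisation",
        "cost_palliative_care",
    ):
        rows.append(
            (name, Kind.COST, cost(name), Distribution.GAMMA, ASSUMPTION, cost_cite, 0.20)
        )
    for stage in STAGES:
        rows.append(
            (f"cost_scale_{stage}", Kind.COST, 1.0, Distribution.FIXED, CALIBRATED,
             "", 0.0)
        )
    return rows


def _rows_kc(country: Country) -> list[tuple]:
    imputed = country is Country.NZ

    def cost(name: str) -> float:
        au = _AU_SERVICE_COSTS[name]
        return impute_nz_unit_cost(au) if imputed else au

    cost_cite = (
        f"AU unit cost x {NZ_AU_PRICE_RATIO} AU->NZ relative price ratio"
        if imputed
        else ""
    )
    rows = [
        ("p_kc_biopsy", Kind.PROBABILITY, 0.60, Distribution.BETA, ASSUMPTION, "", 0.15),
        ("p_kc_shave", Kind.PROBABILITY, 0.50, Distribution.BETA, ASSUMPTION, "", 0.15),
        ("p_kc_excision", Kind.PROBABILITY, 0.905, Distribution.FIXED, PRINTED,
         "surgical excision in 90.5% of KCs after biopsy", 0.0),
        ("p_kc_cautery", Kind.PROBABILITY, 0.04, Distribution.BETA, ASSUMPTION,
         "non-excision modality shares leave <3% topical/radiotherapy", 0.10),
        ("p_kc_cryotherapy", Kind.PROBABILITY, 0.03, Distribution.BETA, ASSUMPTION,
         "non-excision modality shares leave <3% topical/radiotherapy", 0.10),
        ("p_kc_referral_specialist", Kind.PROBABILITY, 0.30, Distribution.BETA,
         ASSUMPTION, "", 0.15),
        ("p_kc_hospitalisation", Kind.PROBABILITY, 0.0044, Distribution.FIXED, PRINTED,
         "hospitalisation rate of 44 per 10,000 patients with KC", 0.0),
        ("p_kc_hospital_wide_excision", Kind.PROBABILITY, 0.50, Distribution.BETA,
         ASSUMPTION, "", 0.15),
        ("p_kc_hospital_radiotherapy", Kind.PROBABILITY, 0.25, Distribution.BETA,
         ASSUMPTION, "", 0.15),
        ("p_kc_reexcision", Kind.PROBABILITY, 0.10, Distribution.BETA, ASSUMPTION, "", 0.15),
        ("p_kc_benign", Kind.PROBABILITY, 0.30, Distribution.BETA, ASSUMPTION, "", 0.15),
        ("p_kc_multiplicity_annual", Kind.PROBABILITY,
         annual_multiplicity(0.509), Distribution.FIXED, PRINTED,
         "constant-hazard annualisation of 50.9% 5-year KC multiplicity", 0.0),
        ("p_background_mortality", Kind.PROBABILITY, 0.01, Distribution.BETA,
         ASSUMPTION, "", 0.15),
        (KC_SCALE_PARAM, Kind.COST, 1.0, Distribution.FIXED, CALIBRATED, "", 0.0),
    ]
    for name in (
        "cost_gp_consult",
        "cost_skin_exam",
        "cost_pathology",
        "cost_biopsy_shave",
        "cost_biopsy_punch",
        "cost_kc_excision",
        "cost_cautery",
        "cost_cryotherapy",
        "cost_topical_course",
        "cost_specialist_consult",
        "cost_reexcision",
        "cost_hospital_wide_excision",
        "cost_hospital_radiotherapy",
        "cost_hospital_mohs",
    ):
        rows.append(
            (name, Kind.COST, cost(name), Distribution.GAMMA, ASSUMPTION, cost_cite, 0.20)
        )
    return rows


def _template_rows(country: Country, cancer: Cancer) -> list[tuple]:
    if cancer is Cancer.MELANOMA:
        return _rows_melanoma(country)
    if cancer is Cancer.KC:
        return _rows_kc(country)
    raise ValueError(f"no template for cancer {cancer!r}")


def _spec_from_row(row: tuple, country: Country, cancer: Cancer, point: float
                   ) -> ParameterSpec:
    name, kind, _, dist, provenance, citation, _ = row
    se = None
    if dist is not Distribution.FIXED:
        se = _SE_FRACTION * point
    return ParameterSpec(
        name=name,
        kind=kind,
        point_estimate=point,
        distribution=dist,
        se=se,
        country=country,
        cancer=cancer,
        source_tag=provenance if not citation else f"{provenance}: {citation}",
    )


def generate_parameter_set(
    seed: int, country: Country | str, cancer: Cancer | str
) -> ParameterSet:
    """Draw a complete, valid parameter set for one country and cancer.

    Published anchors stay at their printed values; assumption-flagged points
    are drawn uniformly within a relative band around the template value
    (clipped to valid probability ranges, adverse events clipped to the
    published 15-28% band).  Reproducible given the seed.
    """
    country, cancer = Country(country), Cancer(cancer)
    rng = np.random.default_rng(seed)
    out = ParameterSet(country=country)
    for row in sorted(_template_rows(country, cancer)):
        name, kind, point, dist, provenance, _, jitter = row
        value = point
        if jitter > 0.0 and provenance == ASSUMPTION:
            value = point * float(rng.uniform(1.0 - jitter, 1.0 + jitter))
            if kind is Kind.PROBABILITY:
                value = min(max(value, 1e-6), 1.0 - 1e-6)
            if name.startswith("p_ae_"):
                value = min(max(value, 0.15), 0.28)
        out.add(_spec_from_row(row, country, cancer, value))
    return out


def _template_set(country: Country, cancer: Cancer) -> ParameterSet:
    out = ParameterSet(country=country)
    for row in sorted(_template_rows(country, cancer)):
        out.add(_spec_from_row(row, country, cancer, row[2]))
    return out


def _merge(a: ParameterSet, b: ParameterSet) -> ParameterSet:
    out = ParameterSet(country=a.country, currency_year=a.currency_year)
    for spec in a:
        out.add(spec)
    for spec in b:
        if spec.name in out:
            existing = out[spec.name]
            if abs(existing.point_estimate - spec.point_estimate) > 1e-9:
                raise ParameterError(
                    f"conflicting values for shared parameter {spec.name!r}"
                )
            continue
        out.add(spec)
    return out


# ---------------------------------------------------------------------------
# calibration


def _deterministic_cost(model: PathwayModel, params: ParameterSet, metric: str) -> float:
    return ModelCost(model, metric).evaluate(params.point_values())


def calibrate_costs(
    params: ParameterSet,
    model: PathwayModel,
    target_mean: float,
    tolerance: float = 0.005,
    metric: str = "year1",
) -> ParameterSet:
    """Scale all cost parameters by one factor so the model hits a target mean.

    The factor is found by bisection on the deterministic expected cost,
    which is monotone (linear) in a global cost scale; the calibrated model's
    mean lies within ``tolerance`` (relative) of ``target_mean``.
    """
    if target_mean <= 0.0:
        raise ParameterError(f"target mean must be positive, got {target_mean!r}")

    def objective(factor: float) -> float:
        return _deterministic_cost(model, params.scaled_costs(factor), metric) - target_mean

    lo, hi = 1e-6, 1e6
    f_lo, f_hi = objective(lo), objective(hi)
    if f_lo > 0.0 or f_hi < 0.0:
        raise ParameterError(
            f"calibration cannot bracket target {target_mean} within scale "
            f"range [{lo}, {hi}]"
        )
    factor = float(optimize.brentq(objective, lo, hi, xtol=1e-12, rtol=1e-12))
    calibrated = params.scaled_costs(factor)
    achieved = _deterministic_cost(model, calibrated, metric)
    if abs(achieved - target_mean) > tolerance * target_mean:
        raise ParameterError(
            f"calibration missed target: {achieved:.4f} vs {target_mean:.4f}"
        )
    return calibrated


def _solve_scale(
    params: ParameterSet,
    model: PathwayModel,
    scale_name: str,
    target: float,
    metric: str = "year1",
) -> float:
    """Value of one scale parameter that puts the model mean on target."""

    def objective(scale: float) -> float:
        return (
            ModelCost(model, metric).evaluate(
                params.replace_value(scale_name, scale).point_values()
            )
            - target
        )

    lo, hi = 1e-6, 1e6
    if objective(lo) > 0.0 or objective(hi) < 0.0:
        raise ParameterError(
            f"cannot bracket target {target} by varying {scale_name!r}"
        )
    return float(optimize.brentq(objective, lo, hi, xtol=1e-12, rtol=1e-12))


def headline_fixture(
    country: Country | str,
) -> tuple[ParameterSet, FixtureManifest]:
    """Deterministic packaged fixture calibrated to the published means.

    Returns the merged melanoma + KC parameter set for the country, with the
    per-stage cost scales solved so every melanoma stage model and the KC
    model reproduce their published (or assumption-target) first-year means,
    and the manifest flagging each value's provenance.
    """
    country = Country(country)
    params = _merge(
        _template_set(country, Cancer.MELANOMA), _template_set(country, Cancer.KC)
    )

    for stage in STAGES:
        model = build_melanoma_model(country, stage)
        target = STAGE_COST_TARGETS[country.value][stage]
        scale = _solve_scale(params, model, f"cost_scale_{stage}", target)
        params = params.replace_value(f"cost_scale_{stage}", scale)

    kc_model = build_kc_model(country)
    kc_scale = _solve_scale(params, kc_model, KC_SCALE_PARAM, KC_MEAN_COST[country.value])
    params = params.replace_value(KC_SCALE_PARAM, kc_scale)

    entries = []
    rows = {
        row[0]: row
        for row in _template_rows(country, Cancer.MELANOMA)
        + _template_rows(country, Cancer.KC)
    }
    for name in sorted(params.names):
        _, _, _, _, provenance, citation, _ = rows[name]
        entries.append(
            ManifestEntry(
                name=name,
                value=params[name].point_estimate,
                provenance=provenance,
                citation=citation,
            )
        )
    return params, FixtureManifest(entries)


def write_fixture(directory, country: Country | str) -> tuple[Path, Path]:
    """Write the headline fixture's parameter and manifest CSVs to a directory."""
    country = Country(country)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    params, manifest = headline_fixture(country)
    param_path = directory / f"parameters_{country.value}.csv"
    manifest_path = directory / f"manifest_{country.value}.csv"
    params.to_csv(param_path)
    manifest.to_frame().to_csv(manifest_path, index=False)
    return param_path, manifest_path
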