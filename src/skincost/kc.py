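"""Keratinocyte cancer (BCC/SCC) treatment-pathway model.

One lesion class covers BCC and SCC, which the universal schedules subsidise
jointly.  A suspected-KC episode starts with a GP consultation and skin
examination; a proportion receive a biopsy (shave with curative intent or
punch), treatment is delivered by the GP or a referred specialist, and the
modality mix is dominated by surgical excision (90.5% after biopsy) with
cautery/curettage, cryotherapy and topical treatment making up the rest.
A share of excisions prove benign on histopathology (costed, but they do not
feed the multiplicity loop); a small share need re-excision for unclear
margins, and 44 per 10,000 patients are treated in hospital (wide excision,
radiotherapy for perineural invasion, or Mohs surgery).

Multiplicity — 50.9% of treated patients have further KC treatments within
five years — enters as an annual self-renewing loop: each cycle a fraction of
the surviving cohort re-enters a full new-lesion episode, charged at the
rolled-back expected episode cost.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

from .model_graph import (
    COMPLEMENT,
    Branch,
    Chance,
    MarkovState,
    PathwayModel,
    Product,
    Scaled,
    Subtree,
    Terminal,
    Transition,
)
from .parameters import Country, multi_period_to_annual_probability

__all__ = [
    "KCMix",
    "build_kc_model",
    "annual_multiplicity",
    "set_followup_schedule",
    "KC_SCALE_PARAM",
]

KC_SCALE_PARAM = "cost_scale_kc"

#: Five-year probability of multiple KC treatments per person.
FIVE_YEAR_MULTIPLICITY = 0.509


def annual_multiplicity(p_5yr: float) -> float:
    """Annual probability of a further KC episode from the 5-year probability."""
    return multi_period_to_annual_probability(p_5yr, years=5)


@dataclass(frozen=True)
class KCMix:
    """Treatment-mix probabilities for the KC pathway.

    Modality probabilities (excision, cautery/curettage, cryotherapy, topical)
    must sum to one; topical is stored as the residual.  Defaults carry the
    published anchors (excision after biopsy 0.905, hospitalisation 0.0044,
    5-year multiplicity 0.509); the rest are assumptions surfaced in the
    fixture manifest.
    """

    biopsy: float = 0.60
    shave_vs_punch: float = 0.50
    excision_after_biopsy: float = 0.905
    cautery: float = 0.04
    cryotherapy: float = 0.03
    referral_specialist: float = 0.30
    hospitalisation: float = 0.0044
    hospital_wide_excision: float = 0.50
    hospital_radiotherapy: float = 0.25
    reexcision: float = 0.10
    benign_share: float = 0.30
    multiplicity_5yr: float = FIVE_YEAR_MULTIPLICITY

    def __post_init__(self) -> None:
        for fname, value in dataclasses.asdict(self).items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{fname}={value!r} outside [0, 1]")
        if self.excision_after_biopsy + self.cautery + self.cryotherapy > 1.0 + 1e-9:
            raise ValueError("modality probabilities exceed 1")
        if self.hospital_wide_excision + self.hospital_radiotherapy > 1.0 + 1e-9:
            raise ValueError("hospital modality probabilities exceed 1")
        if self.multiplicity_5yr >= 1.0:
            raise ValueError("5-year multiplicity must be < 1")

    @property
    def topical(self) -> float:
        return 1.0 - self.excision_after_biopsy - self.cautery - self.cryotherapy

    @property
    def multiplicity_annual(self) -> float:
        return annual_multiplicity(self.multiplicity_5yr)


def _C(name: str) -> Product:
    return Product(name, KC_SCALE_PARAM)


def build_kc_model(
    country: Country | str,
    mix: KCMix | None = None,
    followup: str = "annual",
    horizon_years: int = 5,
) -> PathwayModel:
    """Build the KC pathway model for one country.

    ``mix`` is validated but the model references canonical parameter names
    (``p_kc_*``), so Monte Carlo re-sampling flows through the same graph.
    ``followup`` is ``"annual"`` (primary analysis, one visit a year) or
    ``"biannual"`` (sensitivity analysis, two visits a year).
    """
    country = Country(country)
    mix = mix if mix is not None else KCMix()
    if followup not in ("annual", "biannual"):
        raise ValueError(f"followup must be 'annual' or 'biannual', got {followup!r}")
    visits = 1 if followup == "annual" else 2
    fu_cost = Scaled(_C("cost_skin_exam"), float(visits))

    def surveillance_terminal(name: str) -> Terminal:
        return Terminal(name, state="at_risk")

    hospital_modality = Chance(
        "kc_hospital_modality",
        branches=[
            Branch(
                "p_kc_hospital_wide_excision",
                surveillance_terminal("kc_hosp_wide"),
                costs=[_C("cost_hospital_wide_excision")],
            ),
            Branch(
                "p_kc_hospital_radiotherapy",
                surveillance_terminal("kc_hosp_rt"),
                costs=[_C("cost_hospital_radiotherapy")],
            ),
            Branch(
                COMPLEMENT,
                surveillance_terminal("kc_hosp_mohs"),
                costs=[_C("cost_hospital_mohs")],
            ),
        ],
    )
    hospital = Chance(
        "kc_hospital",
        branches=[
            Branch("p_kc_hospitalisation", hospital_modality),
            Branch(COMPLEMENT, surveillance_terminal("kc_community_managed")),
        ],
    )
    reexcision = Chance(
        "kc_reexcision",
        branches=[
            Branch("p_kc_reexcision", hospital, costs=[_C("cost_reexcision")]),
            Branch(COMPLEMENT, hospital),
        ],
    )
    excision_outcome = Chance(
        "kc_excision_outcome",
        branches=[
            Branch("p_kc_benign", Terminal("kc_benign", state="benign_exit")),
            Branch(COMPLEMENT, reexcision),
        ],
    )
    modality = Chance(
        "kc_modality",
        branches=[
            Branch(
                "p_kc_excision",
                excision_outcome,
                costs=[_C("cost_kc_excision"), _C("cost_pathology")],
            ),
            Branch(
                "p_kc_cautery",
                surveillance_terminal("kc_cautery_done"),
                costs=[_C("cost_cautery")],
            ),
            Branch(
                "p_kc_cryotherapy",
                surveillance_terminal("kc_cryo_done"),
                costs=[_C("cost_cryotherapy")],
            ),
            Branch(
                COMPLEMENT,
                surveillance_terminal("kc_topical_done"),
                costs=[_C("cost_topical_course")],
            ),
        ],
    )
    setting = Chance(
        "kc_treatment_setting",
        branches=[
            Branch(
                "p_kc_referral_specialist",
                modality,
                costs=[_C("cost_specialist_consult")],
            ),
            Branch(COMPLEMENT, modality),
        ],
    )
    biopsy = Chance(
        "kc_biopsy",
        costs=[_C("cost_pathology")],
        branches=[
            Branch("p_kc_shave", setting, costs=[_C("cost_biopsy_shave")]),
            Branch(COMPLEMENT, setting, costs=[_C("cost_biopsy_punch")]),
        ],
    )
    root = Chance(
        "kc_presentation",
        costs=[_C("cost_gp_consult"), _C("cost_skin_exam")],
        branches=[
            Branch("p_kc_biopsy", biopsy),
            Branch(COMPLEMENT, setting),
        ],
    )

    # Multiplicity loop: new-lesion episodes are charged the rolled-back cost
    # of a full presentation.  Initial placement into "at_risk" carries no
    # entry cost; flagged edges into "new_episode" do.
    multiplicity = [
        Transition("new_episode", "p_kc_multiplicity_annual", counts_as_entry=True),
        Transition("death", "p_background_mortality", counts_as_entry=False),
    ]
    states = {
        "at_risk": MarkovState(
            "at_risk", annual_costs=[fu_cost], transitions=multiplicity
        ),
        "new_episode": MarkovState(
            "new_episode",
            annual_costs=[fu_cost],
            entry_costs=[Subtree("kc_presentation")],
            transitions=multiplicity,
        ),
        "benign_exit": MarkovState("benign_exit"),
        "death": MarkovState("death"),
    }

    return PathwayModel(
        name=f"kc_{country.value}",
        root=root,
        states=states,
        horizon_years=horizon_years,
        metadata={
            "cancer": "KC",
            "country": country.value,
            "scale_param": KC_SCALE_PARAM,
            "followup": followup,
            "followup_visits_per_year": visits,
            "mix": mix,
        },
    )


def set_followup_schedule(model: PathwayModel, frequency: str) -> PathwayModel:
    """Return the KC model rebuilt with the given follow-up frequency."""
    if model.metadata.get("cancer") != "KC":
        raise ValueError("follow-up schedule applies to KC models only")
    return build_kc_model(
        model.metadata["country"],
        mix=model.metadata.get("mix"),
        followup=frequency,
        horizon_years=model.horizon_years,
    )
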