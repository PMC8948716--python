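"""Melanoma treatment-pathway models by country and stage.

Five stage groups are modelled: ``in_situ``, ``IA``, ``IB_II``,
``III_resectable`` and ``III_IV_unresectable``.  In situ and stage IA disease
follow an excision-only pathway; IB/II adds sentinel lymph node biopsy (SLNB,
60.4% uptake) with node-positive patients upstaged into the resectable stage
III pathway; resectable III adds complete lymph node dissection, radiotherapy
and (in Australia) adjuvant systemic therapy; unresectable III/IV is treated
with systemic therapies that carry adverse-event costs and an annual
transition to palliative care derived from trial survival.  New Zealand does
not subsidise adjuvant therapies, ipilimumab or dabrafenib/trametinib; its
model omits those branches and adds interferon for resectable stage III.
Follow-up skin examinations are bi-annual (two visits a year) for the 5-year
horizon in every stage.

All cost references are multiplied by a per-stage calibration scale parameter
(``cost_scale_<stage>``), which the synthetic fixture sets so each stage's
deterministic first-year mean matches the published headline figure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .model_graph import (
    COMPLEMENT,
    Branch,
    Chance,
    MarkovState,
    OneMinus,
    PathwayModel,
    Product,
    Scaled,
    Terminal,
    Transition,
)
from .parameters import Country

__all__ = [
    "STAGES",
    "ADJUVANT_THERAPIES_AU",
    "ADVANCED_THERAPIES",
    "StageDistribution",
    "TherapyCourse",
    "build_melanoma_model",
    "stage_weighted_mean",
    "therapy_year_split",
    "adverse_event_cost",
]

#: Stage keys, in severity order; these appear in config and outputs.
STAGES = ("in_situ", "IA", "IB_II", "III_resectable", "III_IV_unresectable")

ADJUVANT_THERAPIES_AU = ("nivolumab", "pembrolizumab", "dabrafenib_trametinib")
ADVANCED_THERAPIES = {
    "AU": ("ipilimumab", "nivolumab", "pembrolizumab", "dabrafenib_trametinib"),
    "NZ": ("nivolumab", "pembrolizumab"),
}

#: Default share of systemic-therapy scripts claimed within 12 months.
YEAR1_SCRIPT_SHARE = 0.89

#: Default grade 3/4 adverse-event probability range for systemic therapies.
ADVERSE_EVENT_RANGE = (0.15, 0.28)


@dataclass(frozen=True)
class StageDistribution:
    """Proportion of incident melanoma in each stage group (sums to one).

    The default puts half of all melanoma in situ (1:1 in situ to invasive
    incidence ratio) with the invasive remainder split across IA, IB/II,
    resectable III and unresectable III/IV.
    """

    proportions: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.proportions) != set(STAGES):
            missing = set(STAGES) - set(self.proportions)
            extra = set(self.proportions) - set(STAGES)
            raise ValueError(f"stage keys mismatch: missing {missing}, extra {extra}")
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"stage proportions sum to {total:.9g}, not 1")
        if any(p < 0.0 for p in self.proportions.values()):
            raise ValueError("stage proportions must be non-negative")

    @classmethod
    def default(cls) -> "StageDistribution":
        return cls(
            {
                "in_situ": 0.50,
                "IA": 0.22,
                "IB_II": 0.14,
                "III_resectable": 0.09,
                "III_IV_unresectable": 0.05,
            }
        )

    def __getitem__(self, stage: str) -> float:
        return self.proportions[stage]


@dataclass(frozen=True)
class TherapyCourse:
    """A systemic therapy course and the quantities hung off it."""

    name: str
    year1_share: float = YEAR1_SCRIPT_SHARE
    adverse_event_probability: float = 0.20
    survival_fraction: float = 0.40
    survival_horizon_years: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.year1_share <= 1.0:
            raise ValueError(f"year1_share {self.year1_share!r} outside [0, 1]")
        lo, hi = ADVERSE_EVENT_RANGE
        if not lo <= self.adverse_event_probability <= hi:
            raise ValueError(
                f"{self.name}: adverse-event probability "
                f"{self.adverse_event_probability!r} outside [{lo}, {hi}]"
            )


def therapy_year_split(
    course: TherapyCourse | None, total_course_cost: float
) -> tuple[float, float]:
    """Split a therapy course cost into year-1 and year-2 components.

    By default 89% of scripts fall in the first 12 months and the remainder
    carries to year 2.
    """
    if total_course_cost < 0.0:
        raise ValueError(f"course cost must be >= 0, got {total_course_cost!r}")
    share = YEAR1_SCRIPT_SHARE if course is None else course.year1_share
    year1 = share * total_course_cost
    return year1, total_course_cost - year1


def adverse_event_cost(course: TherapyCourse, episode_cost: float) -> float:
    """Expected adverse-event cost: probability times hospital episode cost."""
    if episode_cost < 0.0:
        raise ValueError(f"episode cost must be >= 0, got {episode_cost!r}")
    return course.adverse_event_probability * episode_cost


def stage_weighted_mean(
    dist: StageDistribution, stage_costs: Mapping[str, float]
) -> float:
    """Probability-weighted all-stage mean of per-stage mean costs."""
    missing = set(STAGES) - set(stage_costs)
    if missing:
        raise ValueError(f"missing stage costs for {sorted(missing)}")
    return sum(dist[stage] * stage_costs[stage] for stage in STAGES)


# ---------------------------------------------------------------------------
# model construction


def _mix_branches(context: str, therapies, node_for):
    """Categorical therapy-mix branches; the last share is the complement."""
    branches = []
    for i, tx in enumerate(therapies):
        prob = COMPLEMENT if i == len(therapies) - 1 else f"p_tx_{context}_{tx}"
        branches.append(Branch(prob, node_for(tx)))
    return branches


def build_melanoma_model(
    country: Country | str,
    stage: str,
    followup_visits_per_year: int = 2,
    horizon_years: int = 5,
    interferon_stage: str = "III_resectable",
) -> PathwayModel:
    """Build the melanoma pathway model for one country and stage group."""
    country = Country(country)
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")

    scale = f"cost_scale_{stage}"

    def C(name: str):
        return Product(name, scale)

    fu_cost = Scaled(C("cost_skin_exam"), float(followup_visits_per_year))

    def course_node(tx: str, context: str, dest_state: str) -> Chance:
        year1 = Product(C(f"cost_course_{tx}"), "therapy_year1_share")
        return Chance(
            f"{context}_course_{tx}",
            costs=[year1],
            branches=[
                Branch(
                    f"p_ae_{tx}",
                    Terminal(
                        f"{context}_ae_{tx}",
                        costs=[C("cost_ae_hospitalisation")],
                        state=dest_state,
                    ),
                ),
                Branch(COMPLEMENT, Terminal(f"{context}_no_ae_{tx}", state=dest_state)),
            ],
        )

    def post_state(tx: str, context: str, palliative_ref: str) -> MarkovState:
        tail = Product(C(f"cost_course_{tx}"), OneMinus("therapy_year1_share"))
        return MarkovState(
            f"post_{context}_{tx}",
            annual_costs={2: [fu_cost, tail], "*": [fu_cost]},
            transitions=[Transition("palliative", palliative_ref)],
        )

    palliative = MarkovState("palliative", entry_costs=[C("cost_palliative_care")])
    death = MarkovState("death")
    surveillance = MarkovState(
        "surveillance",
        annual_costs=[fu_cost],
        transitions=[Transition("death", "p_background_mortality", counts_as_entry=False)],
    )

    def iii_resectable_parts() -> tuple[Chance, dict[str, MarkovState]]:
        states: dict[str, MarkovState] = {
            "surveillance_iii": MarkovState(
                "surveillance_iii",
                annual_costs=[fu_cost],
                transitions=[Transition("palliative", "p_palliative_iii")],
            ),
            "palliative": palliative,
        }
        no_therapy = Terminal("no_adjuvant", state="surveillance_iii")
        if country is Country.AU:
            for tx in ADJUVANT_THERAPIES_AU:
                states[f"post_adjuvant_{tx}"] = post_state(
                    tx, "adjuvant", "p_palliative_adjuvant"
                )
            mix = Chance(
                "adjuvant_mix",
                branches=_mix_branches(
                    "adjuvant",
                    ADJUVANT_THERAPIES_AU,
                    lambda tx: course_node(tx, "adjuvant", f"post_adjuvant_{tx}"),
                ),
            )
            therapy = Chance(
                "adjuvant_uptake",
                branches=[
                    Branch("p_adjuvant_uptake", mix),
                    Branch(COMPLEMENT, no_therapy),
                ],
            )
        elif interferon_stage == "III_resectable":
            states["post_adjuvant_interferon"] = post_state(
                "interferon", "adjuvant", "p_palliative_adjuvant"
            )
            therapy = Chance(
                "interferon_uptake",
                branches=[
                    Branch(
                        "p_interferon_uptake",
                        course_node(
                            "interferon", "adjuvant", "post_adjuvant_interferon"
                        ),
                    ),
                    Branch(COMPLEMENT, no_therapy),
                ],
            )
        else:
            therapy = Chance(
                "no_adjuvant_node", branches=[Branch(1.0, no_therapy)]
            )
        rt = Chance(
            "radiotherapy_iii",
            branches=[
                Branch(
                    "p_radiotherapy_iii", therapy, costs=[C("cost_radiotherapy_course")]
                ),
                Branch(COMPLEMENT, therapy),
            ],
        )
        clnd = Chance(
            "clnd",
            branches=[
                Branch("p_clnd", rt, costs=[C("cost_clnd")]),
                Branch(COMPLEMENT, rt),
            ],
        )
        sub = Chance(
            "iii_resectable_treatment",
            costs=[C("cost_wide_excision"), C("cost_pathology")],
            branches=[Branch(1.0, clnd)],
        )
        return sub, states

    if stage in ("in_situ", "IA"):
        excision = "cost_excision_in_situ" if stage == "in_situ" else "cost_excision_invasive"
        root: Chance | Terminal = Terminal(
            "diagnosis",
            costs=[C("cost_skin_exam"), C(excision), C("cost_pathology")],
            state="surveillance",
        )
        states = {"surveillance": surveillance, "death": death}

    elif stage == "IB_II":
        iii_sub, iii_states = iii_resectable_parts()
        slnb_result = Chance(
            "slnb_result",
            branches=[
                Branch("p_slnb_positive", iii_sub),
                Branch(COMPLEMENT, Terminal("node_negative", state="surveillance")),
            ],
        )
        root = Chance(
            "diagnosis",
            costs=[C("cost_skin_exam"), C("cost_excision_invasive"), C("cost_pathology")],
            branches=[
                Branch("p_slnb_uptake", slnb_result, costs=[C("cost_slnb")]),
                Branch(COMPLEMENT, Terminal("no_slnb", state="surveillance")),
            ],
        )
        states = {"surveillance": surveillance, "death": death, **iii_states}

    elif stage == "III_resectable":
        iii_sub, iii_states = iii_resectable_parts()
        root = Chance(
            "diagnosis",
            costs=[C("cost_skin_exam")],
            branches=[Branch(1.0, iii_sub)],
        )
        states = dict(iii_states)

    else:  # III_IV_unresectable
        therapies = ADVANCED_THERAPIES[country.value]
        states = {"palliative": palliative}
        for tx in therapies:
            states[f"post_advanced_{tx}"] = post_state(
                tx, "advanced", f"p_palliative_{tx}"
            )
        root = Chance(
            "systemic_therapy",
            costs=[C("cost_skin_exam")],
            branches=_mix_branches(
                "advanced",
                therapies,
                lambda tx: course_node(tx, "advanced", f"post_advanced_{tx}"),
            ),
        )

    return PathwayModel(
        name=f"melanoma_{stage}_{country.value}",
        root=root,
        states=states,
        horizon_years=horizon_years,
        metadata={
            "cancer": "melanoma",
            "country": country.value,
            "stage": stage,
            "scale_param": scale,
            "followup_visits_per_year": followup_visits_per_year,
        },
    )
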