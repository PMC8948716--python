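"""Published national inputs: incidence, per-patient means, projection rows.

These are the printed inputs the burden extrapolation and 5-year projection
consume: 2021 incidence and case counts by state/country, the modelled
per-patient mean costs, and the projection assumptions (case growth 1.0091/yr
from registry projections, health inflation 2.02%/yr applied once at the
first projected year, death decrements and per-person incremental costs for
continuing cohorts).  Death and incremental-cost schedules are not published
directly; they are recovered from the published projection rows (cohort and
cost differences) and are flagged as calibrated in the fixture manifest.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "MELANOMA_MEAN_COST",
    "KC_MEAN_COST",
    "MELANOMA_INCIDENT_PERSONS",
    "KC_INCIDENT_PERSONS",
    "MELANOMA_INVASIVE_CASES",
    "MELANOMA_INCIDENCE_RATE",
    "POPULATION_MILLIONS",
    "STATE_TABLE",
    "STAGE_COST_TARGETS",
    "STAGE_COST_TARGET_PROVENANCE",
    "ALL_STAGE_MEAN_TARGET",
    "CASE_GROWTH",
    "HEALTH_INFLATION",
    "POPULATION_GROWTH",
    "DEATH_SCHEDULES",
    "INCREMENTAL_COST_SCHEDULES",
    "NNB_SPECIALIST",
    "NNB_GP",
    "state_incidence_frame",
]

#: Annual mean cost per patient, all stages (2021 AU$/NZ$).
MELANOMA_MEAN_COST = {"AU": 11_787.0, "NZ": 8_001.0}
KC_MEAN_COST = {"AU": 525.0, "NZ": 1_167.0}

#: Invasive melanoma cases, 2021 (registry projections).
MELANOMA_INVASIVE_CASES = {"AU": 16_878, "NZ": 3_197}

#: Incident persons entering the models: invasive + in situ (1:1 ratio) for
#: melanoma; lesion-based person counts for KC.
MELANOMA_INCIDENT_PERSONS = {"AU": 33_756, "NZ": 6_393}
KC_INCIDENT_PERSONS = {"AU": 812_103, "NZ": 110_884}

MELANOMA_INCIDENCE_RATE = {"AU": 62.4, "NZ": 62.4}  # per 100,000
POPULATION_MILLIONS = {"AU": 25.7, "NZ": 5.1}

#: Per-state 2021 inputs (population in millions, melanoma rate per 100,000,
#: invasive melanoma cases, KC persons in thousands).
STATE_TABLE = {
    "NSW": (8.2, 61.1, 5_000, 229.2),
    "VIC": (6.7, 51.0, 3_404, 109.3),
    "QLD": (5.2, 81.1, 4_222, 321.4),
    "WA": (1.8, 62.0, 1_100, 36.5),
    "SA": (2.7, 46.4, 1_242, 70.1),
    "TAS": (0.5, 58.5, 317, 0.722),
    "NT": (0.2, 54.7, 135, 0.429),
    "ACT": (0.4, 56.5, 244, 0.639),
}

#: First-year per-patient mean-cost targets by melanoma stage (and KC).
#: In situ and unresectable III/IV are published headline figures; the
#: intermediate stages are assumption targets chosen so the stage-weighted
#: all-stage mean lands on the published all-stage figure.
STAGE_COST_TARGETS = {
    "AU": {
        "in_situ": 644.0,
        "IA": 1_500.0,
        "IB_II": 11_400.0,
        "III_resectable": 50_000.0,
        "III_IV_unresectable": 100_725.0,
    },
    "NZ": {
        "in_situ": 1_450.0,
        "IA": 2_000.0,
        "IB_II": 4_960.0,
        "III_resectable": 25_000.0,
        "III_IV_unresectable": 77_828.0,
    },
}
STAGE_COST_TARGET_PROVENANCE = {
    "in_situ": "printed-in-paper",
    "IA": "assumption",
    "IB_II": "assumption",
    "III_resectable": "assumption",
    "III_IV_unresectable": "printed-in-paper",
}
ALL_STAGE_MEAN_TARGET = MELANOMA_MEAN_COST

#: Projection assumptions: annual case growth (registry projection) and
#: average health inflation, applied once at the first projected year.
CASE_GROWTH = 1.0091
HEALTH_INFLATION = 0.0202
POPULATION_GROWTH = {"AU": 0.003, "NZ": 0.0064}

#: Deaths removed from the accumulated cohort each projected year
#: (2022..2025), recovered from the published continuing-cohort rows.
DEATH_SCHEDULES = {
    ("AU", "melanoma"): [1_315, 2_620, 3_862, 5_014],
    ("AU", "KC"): [760, 1_550, 2_372, 3_225],
    ("NZ", "melanoma"): [362, 724, 1_086, 1_448],
    ("NZ", "KC"): [157, 315, 471, 628],
}

#: Incremental cost per continuing person for projection years 2022..2025
#: (surveillance plus repeat lesions), recovered from the published
#: subsequent-episode cost rows.
INCREMENTAL_COST_SCHEDULES = {
    ("AU", "melanoma"): [496.28, 441.43, 401.50, 369.96],
    ("AU", "KC"): [82.09, 80.40, 78.24, 76.10],
    ("NZ", "melanoma"): [862.21, 824.97, 808.99, 789.13],
    ("NZ", "KC"): [217.65, 213.22, 207.62, 202.21],
}

#: Number needed to biopsy per confirmed melanoma, by provider.
NNB_SPECIALIST = 3.5
NNB_GP = 14.6


def state_incidence_frame() -> pd.DataFrame:
    """Per-state 2021 inputs as a tidy frame (Australian states only)."""
    rows = [
        {
            "region": state,
            "population_millions": pop,
            "melanoma_rate_per_100k": rate,
            "invasive_melanoma_cases": mel,
            "kc_persons_thousands": kc,
        }
        for state, (pop, rate, mel, kc) in STATE_TABLE.items()
    ]
    return pd.DataFrame(rows)
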