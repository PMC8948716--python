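# skincost

Markov decision-analytic cost-of-illness models for melanoma and keratinocyte
cancer (KC: basal and squamous cell carcinoma) in Australia and Aotearoa New
Zealand, for health economists and epidemiologists estimating the direct
healthcare burden of skin cancer and the savings potential of prevention.

Skin cancer care in both countries runs through universal subsidy schedules
(Medicare MBS/PBS in Australia; PHARMAC and public hospitals in New Zealand).
The package reconstructs the clinical pathways — GP and specialist
consultations, biopsies, excisions, sentinel lymph node biopsy and lymph node
dissection, systemic immunotherapies and targeted therapies, radiotherapy,
hospitalisation, palliative care and follow-up surveillance — as decision
trees feeding Markov cohort models run in annual cycles over a five-year
horizon, and scales the per-patient means to national burden and five-year
projections.

## The model

For each country and cancer, a pathway model couples

* a **decision tree**: chance nodes with branch probabilities $p_i$ (sibling
  branches stored as $k-1$ free probabilities with the last as complement, so
  they always sum to 1) and one-off costs $c_i$, rolled back as
  $E[C] = \sum_{\text{paths}} \left(\prod_i p_i\right) \sum_i c_i$; with
* a **Markov cohort**: states $s$ with annual costs $c_s$ and transition
  probabilities $P_{s\to s'}$, run as $\pi_{t+1} = \pi_t P$ from the tree's
  entry distribution. Costs attach at cycle start and transitions at cycle
  end, so year 1 equals diagnosis/treatment cost plus first-cycle state costs.
  No discounting or half-cycle correction is applied over the 5-year horizon.

Multi-period probabilities are annualised under a constant hazard,
$p_{\text{annual}} = 1-(1-P)^{1/n}$ (e.g. the 50.9% five-year KC multiplicity
gives 0.1326/year), and trial survival $S$ over $n$ years converts to an
annual palliative-care transition $1-S^{1/n}$.

Uncertainty follows standard health-economic practice: beta distributions on
probabilities and gamma distributions on costs, fitted by the method of
moments; **probabilistic sensitivity analysis** re-samples all parameters for
10,000 iterations and reports the mean with a 95% uncertainty interval
(2.5th/97.5th percentiles of the ranked costs); **one-way (tornado) analysis**
moves each parameter to ±10–20% margins or its 25th/75th percentiles and
ranks parameters by output range.

The restricted patient-level sources behind the unit costs and treatment
probabilities are not redistributable, so the package ships a synthetic
parameter generator whose published anchors are fixed (SLNB uptake 60.4%,
excision after biopsy 90.5%, hospitalisation 44/10,000, year-1 script share
89%, adverse events 15–28%) and whose cost level is calibrated — one scale
factor per model, solved by bisection — to the published per-patient means
(AU\$644 in situ … AU\$100,725 unresectable III/IV; NZ\$1,450 … NZ\$77,828;
KC AU\$525 and NZ\$1,167). See `docs/methods.md` for what that calibration
does and does not claim.

## Worked example

National burden is per-patient mean cost × incident persons:

```sh
$ skincost burden --country NZ --cancer KC
KC (NZ): 110,884 persons x 1,167 = 129.4 million NZ$2021
```

Monte Carlo uncertainty on the calibrated fixture (10,000 iterations):

```sh
$ skincost psa --country AU --cancer melanoma --stage III_IV_unresectable --n 10000 --seed 1
melanoma_III_IV_unresectable_AU: mean 100,792 (95% UI 90,177, 111,968) [AU$2021, n=10000, seed=1]
```

The PSA mean sits on the deterministic calibrated mean of AU\$100,725 for
unresectable stage III/IV melanoma to within Monte Carlo error; the interval
reflects the 10%-of-point standard errors the fixture assigns.

Five-year projection (cases compound at 1.0091/yr; health inflation of
2.02% applies once at the first projected year; continuing cohorts accrue
surveillance and repeat-lesion costs):

```sh
$ skincost project --country AU --cancer melanoma
 year  first_incident_cases  continuing_cohort  cost_first_incident_millions  cost_subsequent_millions  total_cost_millions
 2021                 33756                  0                         397.9                       0.0                397.9
 2022                 34063              32441                         409.6                      16.1                425.7
 2023                 34373              63884                         413.3                      28.2                441.5
 2024                 34686              94395                         417.1                      37.9                455.0
 2025                 35002             124067                         420.9                      45.9                466.8
```

From the library, the same pieces compose directly:

```python
from skincost import build_kc_model, headline_fixture, run_psa

params, manifest = headline_fixture("AU")   # calibrated, provenance-flagged
summary = run_psa(build_kc_model("AU"), params, n=10_000, seed=1)
print(summary.mean, summary.ui_low, summary.ui_high)
```

`skincost all --country AU --cancer melanoma --out results` runs the whole
pipeline (validation, per-stage PSA, tornado, burden, projection, scenarios)
and writes CSV tables plus a run log with the seed and config hash.

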