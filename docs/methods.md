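# Methods

## Model structure and assumptions

Four pathway models are built — melanoma and keratinocyte cancer (KC), each
for Australia (AU) and New Zealand (NZ). Each is a decision tree whose
terminals place a cohort of 1.0 into Markov health states, analysed in annual
cycles over a five-year horizon (when most skin-cancer resource use occurs).
Conventions:

* **Costs at cycle start, transitions at cycle end.** Year-1 cost therefore
  equals the tree-rollback (diagnosis and treatment) cost plus the first
  cycle's state costs, matching the "mean first-year cost" interpretation of
  the headline per-patient figures. Follow-up visits falling in year 1 are
  included.
* **No discounting, no half-cycle correction.** Inflation enters only the
  national projections.
* **Absorbing terminal care.** Palliative/death states charge the palliative
  care cost once on entry and nothing thereafter, so terminal care is never
  double-counted. Early-stage surveillance states carry a background
  all-cause mortality transition (default 0.01/yr, appropriate for a cohort
  mostly aged 60+), which also guarantees an absorbing state is reachable
  from every state.
* **Complement branch scheme.** Sibling branch probabilities are stored as
  k−1 free parameters with the last branch as the complement, so sampled
  branches always sum to one without renormalisation bias. If an extreme
  joint tail draw pushes the free shares above one, the evaluator projects
  back onto the simplex (clamps the complement to zero and renormalises);
  with the default 10% standard errors this affects roughly one draw in
  10⁵.

**Melanoma** is modelled in five stage groups (`in_situ`, `IA`, `IB_II`,
`III_resectable`, `III_IV_unresectable`). In situ/IA: excision plus pathology
only. IB/II: excision with sentinel lymph node biopsy at 60.4% uptake;
node-positive patients (share a named parameter, default 0.12) are upstaged
into the resectable-III pathway. Resectable III: wide excision, optional
complete lymph node dissection and radiotherapy, and — in Australia only —
adjuvant systemic therapy (nivolumab, pembrolizumab, dabrafenib/trametinib);
New Zealand substitutes interferon (applied to resectable III; configurable).
Unresectable III/IV: a categorical mix of systemic therapies (AU adds
ipilimumab and dabrafenib/trametinib, which NZ does not subsidise), each with
89% of course cost in year 1 and 11% in year 2, a grade-3/4 adverse-event
branch (15–28%) costed at a hospital episode, and an annual palliative
transition derived from each therapy's trial survival. Follow-up skin
examinations are bi-annual for five years in every stage.

**KC** treats BCC and SCC as one lesion class (they are subsidised jointly).
An episode: GP consultation and skin examination → probabilistic biopsy
(shave vs punch) → GP or specialist treatment → modality mix (excision 90.5%
after biopsy; cautery/curettage, cryotherapy, topical as the remainder, with
topical below 3%) → benign-histology exit (default 30% of excisions, costed
but outside the multiplicity loop) → re-excision for unclear margins (default
10%) → hospitalisation at 44/10,000 (wide excision, radiotherapy or Mohs).
Multiplicity: the published 50.9% five-year probability of further KC
treatments annualises to 0.1326; each cycle that fraction of the surviving
cohort re-enters a full new-lesion episode, charged at the rolled-back
episode cost. Primary analysis uses annual follow-up; bi-annual is the
sensitivity setting.

## Parameters

Probabilities carry beta distributions, costs gamma distributions, both
fitted by the method of moments; fixed parameters are not sampled. Where no
dispersion is published the default standard error is 10% of the point
estimate (the middle of the 10–20% one-way margins), overridable per
parameter; a 25th/75th-percentile pair may be given instead and the SE is
recovered by numeric inversion (bisection to 1e-9). NZ unit costs without an
NZ source are imputed from the Australian cost via the mean relative price
ratio 1.91.

## Synthetic generator and calibration

The patient-level claims analyses behind the treatment probabilities and
unit costs are restricted, so the generator emulates a complete input set:

* **Anchors fixed:** SLNB uptake 0.604, excision-after-biopsy 0.905,
  hospitalisation 0.0044, annualised multiplicity 0.1326, year-1 script
  share 0.89, in situ:invasive ratio 1:1. These are never sampled or
  jittered.
* **Assumptions drawn:** all other probabilities and unit costs are drawn
  uniformly within ±10–20% of field-plausible template values (consultation
  ~AU$40–80, excisions AU$250–1,200, SLNB AU$4,500, therapy courses
  AU$95,000–140,000, adverse events clipped to 15–28%, and so on), seeded
  and reproducible.
* **Calibration:** unit-cost *levels* for the restricted inputs are
  unknowable, so each stage model (and each KC model) carries one cost-scale
  parameter solved by bisection so that its deterministic first-year mean
  equals the headline target. The calibrated fixture claims only to
  reproduce those aggregate means — never to recover true unit costs. Every
  value in the fixture manifest is flagged `printed-in-paper` (with a
  citation), `assumption`, or `calibrated`.

Headline per-stage targets exist only for melanoma in situ and unresectable
III/IV (and the all-stage and KC means); the intermediate stage targets
(IA, IB/II, resectable III) are assumptions chosen so that the default stage
distribution (0.50 / 0.22 / 0.14 / 0.09 / 0.05 — half in situ by the 1:1
ratio, ~3.6–5% advanced) reproduces the published all-stage means (AU$11,787,
NZ$8,001) as a *check*, not a calibration target; the achieved values are
AU$11,784 and NZ$8,001.

What passing tests therefore show about real data: the arithmetic of the
pipeline (conversions, rollback, cohort algebra, percentiles, burden and
projection arithmetic) and the published aggregate anchors are reproduced
exactly; the synthetic fixture does **not** reproduce the published
uncertainty intervals (those depend on the unpublished per-parameter
dispersions) nor the underlying unit-cost structure.

## Uncertainty analyses

PSA samples every non-fixed parameter once per iteration (parameter
uncertainty, not patient-level microsimulation) and evaluates the full model;
10,000 iterations by default, means and 2.5th/97.5th rank percentiles with
linear interpolation between order statistics (so results are bit-for-bit
reproducible given a seed). The first-year metric is multilinear in
independently sampled parameters, so the PSA mean is an unbiased estimate of
the deterministic mean; tests check agreement within three Monte Carlo
standard errors.

One-way (tornado) analysis varies each uncertain (non-fixed, non-scale)
parameter alone to point×(1±margin) — default margin 0.15, probabilities
clamped to [0, 1] with a warning — or to its fitted 25th/75th percentiles,
ranking by the induced range. On the calibrated fixtures the leading drivers
are the stage-distribution probabilities and high-cost therapy courses for
melanoma, and excision/pathology/consultation costs for KC, in line with the
published sensitivity findings.

## Burden extrapolation and projection

National totals are per-patient mean × incident persons (2021: melanoma
33,756 AU / 6,393 NZ incident persons including in situ at 1:1; KC 812,103 /
110,884 lesion-based persons), displayed to 0.1 million with unrounded
internal arithmetic. Published registry case counts take precedence over
crude rate×population products. Projections compound incident cases at
1.0091/yr; the first-incident cost row multiplies by growth each year and by
health inflation (2.02%) once at the first projected year — the only
schedule consistent with the published cost chain — with each year's value
display-rounded before compounding the next, matching how the published rows
chain. Continuing cohorts accumulate prior incident cases net of an explicit
per-year death schedule, and subsequent-episode costs are continuing cohort ×
per-person incremental cost; both schedules are recovered from the published
projection rows and flagged `calibrated`. Scenario analyses scale diagnostic
biopsy costs by the provider-weighted number needed to biopsy (3.5
specialist, 14.6 GP; provider mix configurable, no published default) and
apply a ±20% KC incidence uplift.

## Numerical choices and degenerate inputs

* Rate conversions reject probabilities ≥1 (infinite hazard) and survival 0.
* Beta fits reject infeasible dispersions (se² ≥ mean(1−mean)).
* Calibration brackets the cost scale in [1e-6, 1e6] and fails loudly if the
  target cannot be bracketed; model cost is linear in the scale, so the
  bisection root is exact to the solver tolerance (1e-12).
* Deaths exceeding a projection cohort floor it at zero with a warning;
  empty sample sets are rejected by the percentile routine.
* Validation reports (rather than raises) unresolved references,
  probability-sum violations beyond 1e-9, out-of-range transition rows and
  states that cannot reach an absorbing state.

## Problem sizes used in the shipped checks

The test suite runs PSA at up to 10,000 iterations on single models and
smaller iteration counts (25–4,000) where only reproducibility or
convergence direction is asserted; the brute-force path-enumeration oracle
covers all models up to 4 states and 4 cycles; the closed-pipeline property
is exercised over 25 generator seeds. These sizes give the oracle checks
exact agreement and the stochastic checks three-sigma headroom.

## Known limitations

* Unit-cost structure within a calibrated model is synthetic; only aggregate
  means are anchored. Published uncertainty intervals are not reproduced.
* Indirect and out-of-pocket costs, Merkel cell carcinoma, metastatic KC and
  rare skin cancers are out of scope, as in the source analysis.
* The published projection tables contain internal rounding inconsistencies
  (one melanoma case count truncated rather than rounded; the NZ cost rows
  compound without the stated inflation; the NZ KC subsequent-episode row
  disagrees with its own total row). The package computes each row from its
  stated rule and reports totals as the sum of components rather than
  reproducing those discrepancies.
* A 1:1 in situ:invasive split of the published all-stage melanoma total is
  inconsistent with the published per-stage in situ mean; per-stage totals
  are reported from per-stage costs instead.
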