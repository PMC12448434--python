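# Methods

This note documents the model implemented in `mnhcea`: its structure and
assumptions, the parameters that matter, the calibrated inputs, the numerical
choices, and what the synthetic data generators do and do not emulate.

## Scope and structure

The package is a decision-analytic cost-effectiveness model of aerial
logistics (centralized storage + drone last-mile delivery, LMD) for maternal
and newborn health, evaluated against a counterfactual without the
intervention. It is organised as a model object
(`AerialLogisticsCEA`) whose `fit()` evaluates the deterministic base case
and returns a results object, with the stochastic analyses (ANC
microsimulation, tornado, PSA) as model methods. The deterministic chain is
pure arithmetic on the parameter set; every stochastic stage takes an
explicit seed and is reproducible bit-for-bit.

## Utilization model

Observed ANC visits at served facilities were 44 384 (2021) and 42 095
(2022). Two conventions for the 19.9% visit effect coexist in the source
tables and both are implemented as separate operations:

- `counterfactual_total`: multiplicative removal, `observed × (1 − e)`,
  which reproduces the published counterfactual totals (35 533 / 33 703 to
  within 0.05%);
- `additional_visits`: the effect read as a relative increase over the
  counterfactual, `observed × e / (1 + e)`, which reproduces the published
  additional-visit count (14 353.06) used by the costing and the
  microsimulation budget.

The discrepancy between the two (≈ 2 900 visits) is inherited from the
source material and documented here rather than resolved.

**Microsimulation.** The baseline cohort is 11 249 women distributed over
visit categories 0..13 (top category pooled). Each replicate allocates the
additional-visit budget one visit at a time: the source category of each
increment is drawn with probability proportional to
`count[k] · P(visits ≥ k+1 | visits ≥ k)`, the baseline conditional
continuation probability. Rejection steps (a sampled woman failing the
acceptance draw) do not change the state, so this categorical form is
equivalent to the sample-then-accept description while running on category
counts. Increments are applied in capped batches (≤ n/50 moves per batch,
clipped to category occupancy) for speed; population size and total visits
are conserved exactly and no woman's count ever decreases. When the
acceptance weights all vanish while below-cap women remain (possible only
when the baseline has no mass above an occupied category), remaining visits
go to the lowest occupied category first — the women furthest behind.
Replicate summaries use the mean and the 2.5/97.5 percentile interval over
1000 replicates by default.

## Outcome pathways

**Two reconstruction routes** convert (overall incidence, group share, odds
ratio) into group risks:

- *Exact mixture solve* (`solve_two_group_risks`): the unique pair
  (p, q) ∈ (0,1)² with `s·p + (1−s)·q = m` and `odds(p) = OR·odds(q)`;
  substituting the odds relation gives a quadratic in q solved with the
  numerically stable root formula. This is the default for PPH and sepsis.
- *Odds-multiplication approximation* (`odds_shift_prevalence`): multiply the
  overall odds by the OR and convert back. This ignores the mixture weighting
  (it equals the exact solve only as the exposed share → 0) but it is the
  convention behind the published LBW chain, so it is the default on that
  pathway; the exact route is available via `lbw_route="exact"` and differs
  by ≈ 13% in averted LBW cases under base-case inputs.

**LBW.** Overall prevalence 0.1073, OR 0.24 for ≥ 8 ANC visits, baseline
share of high attenders 0.3389 (calibrated; see below). Averted cases =
2252 threshold crossers × (prev<8 − prev≥8) ≈ 270, split
0.7777/0.1416/0.0807 into moderate/very/extremely LBW. Mortality follows
`cases_s · rate_p · (HR_sp − 1)` over neonatal/early-infancy/late-infancy
periods with reference rates 0.007453/0.008182/0.006936.

**PPH.** Incidence 0.199, OR 3.43 for 0 vs ≥ 1 visits, zero-visit share
0.0363; the exact solve gives risks ≈ (0.445, 0.190). Averted cases =
363.56 movers × risk difference ≈ 93, of which 24.82% severe.

**Facility-delivery neonatal mortality.** 14 619.63 shifted births ×
(17/1000) × (1 − 0.71) ≈ 72.07 deaths averted. RR values above 1 are
rejected unless explicitly overridden, since the pathway assumes facility
delivery is protective.

**Maternal mortality.** 28 observed deaths, 56.4% observed reduction →
counterfactual 64.22, averted 36.22.

**Sepsis.** The published group risks (0.0048 facility / 0.0203 home), the
overall incidence (0.01412), the OR (3.6) and the published savings are
mutually inconsistent: no single risk pair reproduces all of them. The base
case therefore uses the averted-case count implied by the published savings
(278.27 = 112 590.60 / 404.60) as a calibrated input; the model route
(exact mixture solve with the 0.86/0.13 facility/home shares renormalized to
sum to 1) is available via `sepsis_basis="model"` and is property-tested.

## Burden of disease

DALYs are mortality-only (no years lived with disability, matching the
intervention's evaluated scope). Discounting is the discrete annual annuity
`(1 − (1+r)^−L)/r`, the convention in burden-of-disease practice; a
continuous-exponential form is selectable. No age weighting. The default
rate is 3% (the value used for the reported DALYs), with 5% — which appears
as a "discount rate" input in the source tables — covered by the tornado
range [0.03, 0.05].

**Calibrated life expectancies.** The life table behind the published
totals (7 554 undiscounted LYS; 3 754.99 discounted DALYs) is not public.
The remaining life expectancy at birth is set to 62.5 years (≈ Ghana's life
expectancy at birth) and the maternal remaining life expectancy is solved so
the undiscounted LYS total is 7 554 exactly (45.8812 years at age 30).
The two published totals are *jointly* unreachable at a 3% annual annuity:
their ratio (0.497) exceeds the maximum achievable (0.472) for any per-cause
age assignment with the implied mean LYS per death of 57.9 years, because
the annuity is concave in L. A single calibration factor (1.0597189, frozen
in the defaults) therefore maps the model's discounted years onto the
published DALY total; it scales the DALY denominator without suppressing the
discount-rate response in sensitivity analyses. Both calibrations are
labelled `calibrated` in the parameter registry.

**Calibrated hazard ratios.** The severity×period hazard ratios for LBW
mortality are cited to an external cohort study but not printed in the
source; the shipped grid uses plausible magnitudes (moderate 4.0/2.2/1.6,
very 10/4.5/2.8, extreme HR rising to ~49 in the neonatal period, the last
solved so total LBW deaths equal the published 22.20). They are a labelled
validation fixture, not a derivation.

## Costs

All flows are 2024 USD `CostLine`s (payer ∈ {NHIS, HOUSEHOLD, PROGRAM},
direction ∈ {INCURRED, AVERTED}); perspectives are assembled at aggregation
time. Unit costs: PPH $72.90/$344.35 (NHIS mild/severe) and $99.50/$668.00
(OOP); sepsis $404.60/$107.80 (system/household); LBW $1 721 hospital +
$52 + $133 household per hospitalized case, with hospitalization rates 100%
(extremely LBW) and 2.66% (moderate + very, jointly); G-DRG tariffs $2.56
per ANC visit and $24.08/$49.41 per vaginal/C-section delivery (85%
vaginal), with OOP analogues $6.85/$4.42/$20.60.

Three cost inputs enter as printed totals rather than derivations, because
their primary data (the private flight ledger; the basis of the societal
out-of-pocket increase) are unavailable: the LMD category totals
($32 160.43 ANC / $45 053.48 +PPH-prevention / $131 130.20 +treatment) and
the household OOP increase ($1 075 300.83). The computed OOP analogue of
the incremental services (≈ $198 000) is reported in the results metadata
but kept out of the ledger to avoid double counting. `lmd_costing`
implements the occupancy-based allocation (cost/flight × occupancy share ×
units, aggregated over the nested product categories) for any manifest, and
is exercised on synthetic manifests. All LMD cost is treated as fully
incremental, the conservative choice.

**ICER numerator conventions** (implicit in the published ratios and
reverse-engineered from them): per-ANC-user and per-ANC-visit use the
ANC-product LMD cost alone; per-death/LYS/DALY use the perspective net cost;
per-facility-birth uses ANC+PPH-prevention LMD plus the incremental NHIS ANC
cost, a best-fit convention ($5.60) whose published basis is not stated.
The published "$5275 per PPH case averted" has no recoverable numerator and
is not reproduced.

## Sensitivity analysis

Tornado: each parameter with a registered range is set to its low/high end
with all others at base, the pipeline re-evaluated, and entries sorted by
descending ICER span (ties alphabetical). Ranges are published 95% CIs where
available (facility RR 0.54–0.87, sepsis OR 1.83–7.05, sepsis incidence
0.00946–0.02097), the 3–5% span for the discount rate, and ±25% otherwise
(±10% for the microsimulation-derived counts).

PSA: beta for probabilities/fractions, log-normal for ratios (anchored at
the CI where printed), gamma for unit costs, uniform for the discount rate;
moments are matched so the base value is the mean and the range the 95%
interval. Sampled values are clipped to hard parameter domains. 1000 draws
by default; each draw re-runs the full deterministic pipeline. The CEAC uses
net monetary benefit (`WTP × DALYs − cost ≥ 0`), which is robust to
near-zero-effect draws. The exact distribution choices of the original
analysis are unpublished, so the 95%-confidence WTP values reported there
are qualitative benchmarks only, not targets.

## Synthetic data

The generators stand in for inputs drawn from non-distributable sources:

- `generate_anc_distribution`: a negative binomial pooled at the 13+
  category, with the untruncated mean re-solved so the pooled mean hits the
  target exactly; dispersion 2.6 gives a ~3.6% zero-visit share at the
  cohort mean of ≈ 6.2 visits, matching the aggregate moments the analysis
  assumes. It does not reproduce the true survey's category-level shape,
  sampling weights, or year-to-year structure — the published category
  distribution is not printed, so the baseline shape is calibrated, not
  copied. Consequently the cohort-scale threshold-crosser counts are
  order-of-magnitude checks (the 0→≥1 count lands within ~5% of the
  published 363; the ≥8 count is the same order as the published 2252 but
  sensitive to the unprinted mass just below 8).
- `generate_flight_manifest`: product records with occupancy fractions and
  the nested category tags ANC ⊆ PPH-prevention ⊆ PPH-treatment enforced at
  generation (blood products occupy full payloads).
- `generate_cohort_truth`: per-woman exposure/outcome draws from known group
  risks, used to verify that the risk-reconstruction solver recovers the
  truth within binomial sampling error.

## Numerical choices and degenerate inputs

- The two-group quadratic uses the stable root formula; |OR − 1| < 1e-12
  short-circuits to the overall incidence. Round-trip accuracy is 1e-9.
- Discounting uses `expm1/log1p`, keeping the rate→0 limit exact.
- Severity splits renormalize shares (tolerance 0.01 on their sum) so counts
  sum to the total exactly.
- Zero redistribution budget returns the baseline unchanged; a budget
  exceeding total remaining capacity raises `CapacityError` rather than
  silently truncating.
- Monetary values are full-precision floats internally; tables round to 2
  decimals for display, and exports write `repr` precision so round trips
  are bit-exact.

## Problem sizes

Default run sizes are the study conditions: 11 249 women, 1000
microsimulation replicates, 1000 PSA draws; the full pipeline including both
stochastic stages completes in a few seconds on one CPU.

## Known limitations

- Morbidity (years lived with disability) is out of scope, as in the
  evaluated analysis.
- The sepsis pathway's published algebra is internally inconsistent; the
  base case pins it to the published savings (see above).
- The DALY calibration factor compensates for an unpublishable life table;
  absolute DALY levels inherit that uncertainty even though ratios and
  sensitivity responses are well-defined.
- Costs assume no economies of scale and fully incremental logistics costs;
  both choices bias against the intervention.
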