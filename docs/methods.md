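# Methods

## Decision problem and model structure

The model compares two first-line strategies for advanced or metastatic
G/GEJ adenocarcinoma with PD-L1 CPS ≥ 5 (and a CPS ≥ 10 subgroup):
sugemalimab (1200 mg IV every 3 weeks) added to CAPOX chemotherapy, versus
CAPOX alone, from the payer perspective of Taiwan's National Health
Insurance. It is a cohort-level, three-state partitioned survival model
(PSM): state occupancy is derived directly from the two marginal survival
curves rather than from transition probabilities, which is the standard
construction when only published Kaplan–Meier curves — not patient-level
data — are available. PF occupancy is capped at overall survival
(`PF = min(S_PFS, S_OS)`); the few cycles where fitted PFS exceeds fitted OS
(a known artifact of independently fitted curves) are counted in a
diagnostics tally. For the bundled inputs the excess is ≤ 1e-4 in occupancy
and ~1e-6 months of integrated time, i.e. immaterial.

Health states are assumed independent and mutually exhaustive: PF + PD +
dead = 1 at every cycle (the engine enforces this to 1e-12). Death collects
all-cause mortality; post-progression treatment is summarized by flat PD
cost rates rather than modelled as treatment lines.

## Time grid and numerical conventions

* **Cycle**: 21 days — one dosing cycle of the q3w regimen. Months are
  365.25/12 days; the 40-year horizon gives 695 whole cycles. The final
  sub-cycle remainder is dropped; residual survival there is ~0.2% and its
  contribution is below the discretization error.
* **Midpoint rule**: occupancy (and the discount factor) is evaluated at
  cycle midpoints, a midpoint-quadrature stand-in for half-cycle
  correction. Incident deaths per cycle come from S_OS at cycle bounds.
  Halving the cycle length moves total cost and QALYs by well under 0.5%
  (grid-convergence test), so discretization is not a material error
  source.
* **Discounting**: 3%/year, continuous-in-time factor (1+r)^(−t_years)
  applied to each cycle's flow at its midpoint.
* **Treatment exposure in whole cycles**: drugs are dispensed per 3-week
  cycle, so every duration cap (median treatment duration, median PFS,
  protocol maximum) is realized as the number of *complete* cycles fitting
  under the cap: 6.3 months → 9 cycles, 24 months → 34 cycles. A
  continuous (fractional last cycle) mode exists for validation against
  closed-form treated-time integrals.
* **Degenerate inputs**: a horizon shorter than one cycle is an error; an
  all-censored sample fits nothing (no events → error); tornado bounds that
  collapse to the base value yield exactly zero range; utilities whose DSA
  bound touches 1.0 are clamped to the valid [0, 1] interval.

## Survival models

Seven parametric families (exponential, Weibull, gamma, log-normal,
log-logistic, Gompertz, generalized gamma) with the parameterizations under
which the published inputs reproduce the trial's medians: log-logistic
S(t) = 1/(1+(t/scale)^shape) with scale in months (median = scale);
log-normal on the natural log of months (median = exp(μ)). Gompertz allows
negative shape, giving an improper distribution (a surviving fraction);
such models are flagged rather than rejected. The generalized gamma uses
the Prentice (μ, σ, Q) log-location form, with Q → 0 reducing to the
log-normal.

Fitting maximizes the right-censored log-likelihood
Σ_events ln f(t) + Σ_censored ln S(t) with L-BFGS-B on log-transformed
positive parameters, three starts (moment-based heuristic ± perturbations)
to guard against local optima, and standard errors from the numerical
observed information. Fits are ranked by AIC ascending (ties: BIC, then
family name). The base case uses the published log-logistic (CPS ≥ 5) and
log-normal (CPS ≥ 10) parameters directly; refitted models can be injected
into any scenario.

KM reconstruction follows the Guyot-type allocation: within each interval
between number-at-risk times, censorings are spread uniformly and their
count adjusted until the implied at-risk count matches the published one,
with events at each digitized step from the product-limit ratio; a
published total event count, when supplied, is matched exactly by flipping
the latest-time records. Digitized survival readings are clipped to [0, 1]
and monotonized (cumulative minimum) before allocation, absorbing
plot-extraction noise. Reconstruction is deterministic.

## Cost and QALY accrual

Annual rates (2024 USD, TWD 32.11/USD at authoring) accrue per cycle on the
relevant occupancy:

| Component | Accrues on | Rate (USD/yr) |
|---|---|---|
| Sugemalimab acquisition | on-treatment PF, ≤ cap | 59,814 (= 1,720/600 mg × 2 vials q3w) |
| CAPOX acquisition | on-treatment PF, ≤ 6 dosing cycles | 8,959 |
| Chemo administration | CAPOX exposure | 1,226 |
| PF non-medication services | PF occupancy | 25,925 |
| Supportive care | PD occupancy | 63,077 |
| PD drug | PD occupancy | 4,682 |
| PD administration | PD occupancy | 2,018 |
| Terminal care | 1 month per incident death | 54,893/12 per death |
| AE management | first cycle, one-off | prob × (769 neutropenia / 1,494 anemia) |

Design choices made where the construction was genuinely open:

* **Point conversion.** Taiwan's NHI pays non-medication services at a
  conversion factor (0.9198 TWD per fee-schedule point); medications are
  point-for-point. All non-drug rates above are point values and are
  multiplied by the conversion factor at accrual; drug acquisition costs are
  not. The scenario "one point = TWD 1" sets the factor to 1.
* **Administration follows chemotherapy.** The administration fee is the
  chemotherapy administration fee, so it tracks CAPOX exposure (6 dosing
  cycles), not the longer sugemalimab exposure; checkpoint-inhibitor
  infusion is treated as part of the bundled PF services rate.
* **Protocol caps.** CAPOX is capped at its 6-cycle protocol maximum in
  every duration rule (oxaliplatin is not given indefinitely); the
  sugemalimab 24-month cap is a reimbursement cap and is lifted under the
  "until progression" rule, where sugemalimab follows full PF occupancy.
* **Terminal care** is a per-death one-off of one month's rate, added on
  top of supportive care rather than substituted for the final supportive
  month.
* **Adverse events** (grade ≥ 3, incidence > 5%, grouped into neutropenia
  and anemia with the higher rate per group) occur in the first cycle only:
  a one-off management cost and a utility decrement lasting one full cycle.

QALYs weight PF/PD occupancy by arm-specific utilities (0.812/0.746
intervention, 0.798/0.721 comparator) minus the first-cycle AE decrement.
Life-years are the discounted occupancy integral. The equal-value-of-
life-years (evLYG) scenario values effectiveness in unweighted discounted
life-years.

## Uncertainty analysis

* **DSA**: every parameter with published bounds (95% CI, else ±25%) is set
  to each bound in turn — shared cost rates move in both arms together —
  and the tornado ranks parameters by INMB range.
* **PSA** (default 5000 draws, seeded NumPy Generator): survival parameters
  ~ normal(mean, SE) with redraw on non-positive draws for
  positivity-constrained parameters; cost rates ~ gamma with
  shape = (mean/sd)², scale = sd²/mean; utilities and disutilities ~ beta;
  conversion factor ~ uniform(0.853, 0.9913). Treatment durations, AE
  probabilities, the discount rate and the sugemalimab price are fixed in
  the PSA (they vary in DSA/scenarios). Survival parameters are sampled
  independently (no covariance is published) — a simplification that
  ignores the usual shape/scale correlation. Cost-rate draws are taken
  independently for each strategy arm, so each arm's realized accrual
  carries its own uncertainty; utilities are per-arm quantities already,
  and disutilities and the conversion factor are shared draws.
* **CEAC** on a λ grid of 0–150,000 USD in 1,000-USD steps; EVPI at λ* as
  the mean per-draw best net benefit minus the net benefit of the
  on-average best strategy. The empirical CEAC can step down by one draw
  where a cost-saving, QALY-losing draw exits the acceptance set as λ
  rises; this is estimator granularity, not model error.
* **Price threshold**: bisection on the sugemalimab price multiplier
  m ∈ [0, 1] to |INMB| < 0.5 USD; INMB is exactly linear in m, so the
  bisection is a safeguarded linear solve. Already-cost-effective (m = 1)
  is flagged; INMB < 0 at m = 0 is an error.

## Synthetic data

The trial's patient-level data are not public. The `synthetic` module
generates what the reconstruction/fitting pipeline needs: inverse-CDF event
times from any supported family, administrative censoring at a follow-up
cutoff plus optional uniform dropout, and digitized-curve fixtures (KM step
values on a reporting grid, exact at-risk counts, optional Gaussian
digitization noise). Defaults mirror a two-arm phase-3 trial at ~250
patients/arm. These fixtures reproduce the *statistical structure* the
pipeline assumes — independent right-censoring from stated parametric
families — but not real-data features such as delayed treatment effects,
non-proportional hazards beyond the fitted family, informative censoring,
or digitization bias correlated along the curve. Pipeline tests passing on
them validate the algorithms, not the clinical inputs.

## Known limitations

* Arm-level absolute totals are sensitive at the 1–3% level to accrual
  conventions (cycle placement, cap quantization, component bookkeeping)
  that no published table pins down exactly; incremental quantities are
  robust to these choices.
* No correlation between sampled survival parameters, and independent
  per-arm cost draws, are modelling choices about the joint distribution
  that the marginal inputs do not determine.
* Time-to-treatment-discontinuation is summarized by fixed duration caps,
  not modelled as its own distribution.
* The PSM structure cannot express state-transition dependence (e.g.
  post-progression survival conditional on progression time); a Markov
  reformulation is out of scope.
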