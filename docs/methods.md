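# Methods

`hifucea` is an early health-economic decision model comparing two
palliative strategies for painful, uncomplicated, non-vertebral bone
metastases from breast, prostate or lung cancer, from the perspective of
the German statutory health insurance (SHI):

* **Strategy A** — MR-guided high-intensity focused ultrasound (MR-HIFU)
  as first-line treatment for a share of patients (60% in the base case),
  with the remainder receiving external-beam radiotherapy (EBRT) first and
  MR-HIFU as the retreatment option in case of persistent pain or only
  partial pain relief.
* **Strategy B** — EBRT alone (90% multi-fraction 20 Gy/5, 10%
  single-fraction 8 Gy), with same-modality re-irradiation for persistent
  pain.

Outcomes are expected discounted lifetime cost (EUR), quality-adjusted
life years (QALYs), and months spent in complete or partial pain response
("pain-response months"); strategies are compared by incremental
cost-effectiveness ratios (EUR/QALY and EUR/pain-response month), net
monetary benefit, probabilistic sensitivity analysis and expected value of
(partial) perfect information.

## State-transition model

Patients enter the model in the month of their first-line treatment and
are followed in monthly cycles to a 600-month horizon (residual alive mass
triggers a warning, never silent truncation). The pain state is one of
*complete response*, *partial response*, *persistent after relapse*, or
*persistent, never responded*; additional flags record one-time events
(retreatment used, pathological fracture) and death is absorbing. Within
every cycle events apply in a fixed, documented order:

1. **Death** — cancer-specific monthly probability, tabulated per year
   since diagnosis for years 1–5 and held constant at the year-5 value
   beyond (constant extrapolation; the source gives no later hazard).
   Mortality is identical across strategies and states.
2. **Pain relapse** — complete/partial responders move to persistent pain
   with probability 0.022/month.
3. **Retreatment** — at most one per lifetime, never MR-HIFU after
   MR-HIFU. Eligibility in strategy A is persistent pain or partial
   response; in strategy B persistent pain only. Uptake is rate-based:
   0.018/month for every strategy-A retreat (the single-fraction EBRT
   annual rate of 20%, compounded monthly), 0.007 and 0.018/month for
   multi-/single-fraction re-irradiation in strategy B. Persistent
   patients redraw the full response profile of the retreat modality
   (MR-HIFU retreats behave like first-line MR-HIFU; re-irradiation is
   inferior: 42% no response, the rest split in the first-line
   complete:partial ratio). Retreated *partial* responders keep the better
   of their current and redrawn states (a floored redraw): only a
   complete-response draw changes anything, and a failed attempt never
   worsens existing relief. The retreatment cost and treatment disutility
   fall in the event cycle.
4. **Pathological fracture** — 0.003/month in every alive state, at most
   once per patient; one-off cost (EUR 21,430) and disutility (−0.009) in
   the event cycle.
5. **Accrual** — utility = base state (0.039/month) + response gain
   (+0.019 complete, +0.008 partial) + event decrements; cost = monthly
   opioid (EUR 210) except while in complete response. Response onset is
   treatment-specific: MR-HIFU palliates within seven days, so responders
   accrue gains and pain-response time for 23/30 of the treatment cycle;
   EBRT palliates within four weeks, so its responders accrue nothing in
   the treatment cycle and fully from the next.

Costs and QALYs (and, by default, pain-response months, so that EUR-per-
response ratios are well formed) are discounted at 3% per year as
`(1+r)^(−cycle/12)`; an undiscounted pain-month total is also reported.
No half-cycle correction is applied — at monthly cycles its effect is far
below the result precision. Death accrues nothing.

Entry costs: first-line MR-HIFU = out-patient diagnostic MRI (118) +
in-patient gDRG lump sum (3,430); multi-fraction EBRT = 70%/30% blend of
out-/in-patient tariffs (2,411/6,410); single-fraction EBRT = 1,486. A
HIFU *retreat* omits the pre-treatment MRI. HIFU-first patients may still
receive an EBRT retreatment (toggle, default on) at the strategy-A rate,
priced and weighted as the radiation-naive 90/10 EBRT mix.

## Two engines

The **cohort engine** propagates the full joint state distribution and
returns exact expectations; it checks probability-mass conservation to
1e-9 every cycle and is natively batched over parameter sets (one 600-cycle
sweep evaluates thousands of PSA draws simultaneously). The
**microsimulation** simulates individual patients under identical rules;
its means converge to the cohort expectations, which is property-tested
(20 randomized parameter sets, 3.5 Monte-Carlo SEs). Each patient owns
substreams derived from `(seed, patient index)`, so results are bit-
reproducible and enlarging the cohort never reshuffles earlier patients.
With common random numbers, both arms share the event stream (cancer,
allocation, death, relapse, retreat uptake, fracture) while response draws
stay strategy-specific; since mortality is strategy-independent, a patient
dies in the same cycle in both arms, which markedly shrinks the variance
of incremental outcomes. The default run size is 200,000 patients
(Monte-Carlo SE on ΔQALY well below the 0.02 signal); tests use a few
thousand per set.

## Sensitivity and uncertainty analyses

**One-way DSA** varies every parameter carrying a standard deviation
(cancer-specific mortality is excluded by design) between mean ± 1 SD,
clipped to its domain; response triplets are varied by shifting one
component and renormalising the complement. The source states no DSA
ranges, so ±1 SD is this package's choice. The tornado ranks by the spread
of incremental net monetary benefit at WTP €20,000/QALY — ICER spreads are
reported alongside but not used for ranking, to avoid sign-flip
pathologies. Under these ranges the dominant inputs are the MR-HIFU
fracture rate (SD larger than its mean), MR-HIFU procedure cost, the
out-patient EBRT share and MR-HIFU complete-response effectiveness,
consistent with the value-of-information ranking.

**Structural scenarios** (six named): strategy-A retreat rate at the
multi-fraction level (0.007/month) and at 32%/year (1−0.68^(1/12)); 100%
MR-HIFU first line; a cost-covering lump sum (5,147) replacing the gDRG
procedure cost (MRI logic unchanged); 100% single-fraction EBRT; 100%
out-patient EBRT.

**PSA** samples every SD-carrying parameter from a moment-matched
distribution: beta for probabilities and shares, Dirichlet for response
triplets (concentration matched to the complete-response SD), gamma for
costs (the fracture total scales its five audit components with it), and
sign-preserving truncated normals for utility values. Utility draws are
additionally truncated at the monthly-scale sanity bound (|u| < 0.09) so
that every draw satisfies the full parameter validation; for the base
utility (mean 0.039, SD 0.035) the truncation makes the moment match
approximate. The families are this package's choice — the source does not
state its PSA distributions — and are configurable. The inner evaluator is
the deterministic cohort engine, so the sample table carries parameter
uncertainty only, which is exactly what the regression-based EVPPI
estimator assumes.

**VOI.** Per-person EVPI is `E[max(INB,0)] − max(E[INB],0)` over PSA
iterations at the reference WTP of €20,000/QALY (the source does not state
the WTP behind its EVPI figure; an EVPI-vs-WTP curve is always available).
EVPPI uses the conditional-expectation regression estimator: penalised
B-spline regression of the incremental NMB on a single parameter, or
Gaussian-process regression on standardised inputs for parameter sets
(fitted on ≤750 subsampled points; predictions on all), with
nonparametric-bootstrap standard errors. Estimators are validated against
Gaussian closed forms on synthetic tables with known truth. Population
EVPI multiplies the per-person value by user-supplied discounted annual
counts of affected persons — no registry counts are built in.

## Synthetic fixtures

`fixtures.perturbed_params` jitters every input (including mortality,
unlike PSA) multiplicatively within valid domains — it emulates "some
other plausible disease/cost configuration" for engine-equivalence sweeps,
not sampling uncertainty. `gaussian_nb_psa` and `linear_theta_psa` build
two-strategy PSA tables whose incremental net benefit is exactly Gaussian
or exactly linear in standard-normal parameters, with EVPI/EVPPI ground
truths from the closed form `m·Φ(m/σ)+σ·φ(m/σ)−max(0,m)` — computed
independently of the estimators under test. What passing these fixtures
shows is estimator calibration under the assumed statistical structure;
none of them emulates real patient-level trial data.

## Numerical and design notes

* The MR-HIFU response triplet is stored as (0.23, 0.41, 0.36): the
  published no-response figure 0.350 makes the triplet sum to 0.99, and
  the source trial's 64% overall response rate identifies 0.36 as the
  intended complement. All triplets are validated onto the simplex to
  1e-9.
* Treatment disutilities live only in `UtilitySet` (one source of truth);
  annual retreatment rates are converted by compounding
  `1−(1−p)^(1/12)`, matching the tabulated monthly values.
* The floored redraw for retreated partial responders is a deliberate
  deviation from a plain redraw: a plain redraw sends 36–42% of retreated
  partial responders *back to persistent pain*, making palliative
  retreatment net-harmful for them, which is clinically implausible and
  inconsistent with the published incremental results.
* ICERs are always computed from unrounded deltas; dominance labels
  replace ratios on mixed-sign deltas, and effect deltas below 1e-9 yield
  "undefined" rather than an unbounded ratio.
* Ties on the CEAC count one half; CE-plane quadrant fractions always sum
  to one.

## Known limitations

* Event ordering within a cycle, onset operationalisation, retreatment
  eligibility pools and the partial-retreat outcome rule are not fully
  identifiable from the published description; the choices above are fixed
  and documented, and alternates are exposed as settings
  (`retreat_pool`, `retreat_eligibility_*`, `hifu_first_ebrt_retreat`,
  `ebrt_first_retreat_rate`).
* The model reproduces the published base-case incremental cost and QALYs
  and the PSA/VOI surface, but yields a flatter cost gradient and a more
  back-loaded benefit across cancer subgroups than the published subgroup
  table (whose internal arithmetic is partly inconsistent); the
  per-subgroup ICER ordering therefore differs.
* No repeat MR-HIFU, no bone-targeting-agent costs, no transportation or
  rehabilitation costs, no adverse-event treatment costs, and no
  between-patient heterogeneity beyond the primary cancer — matching the
  modelled decision problem's scope.
* Mortality implied by the tabulated monthly probabilities is more
  optimistic than the one-year survival reported by the source cohorts for
  prostate and lung cancer; the package uses the tabulated values verbatim
  and surfaces the inconsistency as a validation warning.
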