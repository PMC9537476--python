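# hifucea

An early cost-effectiveness model of **MR-guided high-intensity focused
ultrasound (MR-HIFU)** versus **external-beam radiotherapy (EBRT)** for
pain palliation of bone metastases, from the perspective of the German
statutory health insurance. It is written for health-economic modellers
and HTA analysts who want a fully inspectable, scriptable re-implementation
of the decision problem: every input is a printed tariff, trial
probability or utility, and every result can be traced through a
deterministic engine.

Two strategies are compared for patients with painful bone metastases
from breast, prostate or lung cancer:

* **Strategy A** — MR-HIFU as first-line treatment for 60% of patients, or
  as retreatment after EBRT for persistent pain or partial relief;
* **Strategy B** — EBRT alone (90% multi-fraction 20 Gy/5, 10%
  single-fraction 8 Gy) with re-irradiation for persistent pain.

The model is a discrete-time state-transition / patient-level simulation
with one-month cycles and a lifetime horizon. Each month applies death,
pain relapse, retreatment, pathological fracture, then accrual; per-cycle
rewards are discounted at 3% p.a.:

```
QALYs  = Σ_t δ(t) · [ u_base + g(state_t) − decrements_t ],   δ(t) = 1.03^(−t/12)
cost   = entry + Σ_t δ(t) · [ c_opioid·1{not complete} + event costs_t ]
ICER   = ΔC / ΔE   (strategy A − strategy B, unrounded means)
NMB(λ) = λ·E − C,  CEAC(λ) = P(NMB_A > NMB_B),  EVPI = E[max(INB,0)] − max(E[INB],0)
```

Two engines share identical mechanics: an exact **cohort engine**
(expectation propagation, natively batched over parameter sets — the PSA
inner loop) and a **microsimulation** with common random numbers across
arms, property-tested to agree with the cohort expectations. On top sit
incremental analysis, one-way deterministic sensitivity analysis with
tornado ranking, six structural scenarios, a 10,000-iteration
probabilistic sensitivity analysis and regression-based EVPI/EVPPI.

## Worked example

```python
from hifucea import builtin_basecase, expected_outcomes, incremental_analysis

params = builtin_basecase()            # every tabulated input, validated
arm_a = expected_outcomes("A", params)  # exact expectations, no sampling
arm_b = expected_outcomes("B", params)
inc = incremental_analysis(arm_a, arm_b)

print(f"strategy A: cost EUR {arm_a.mean_cost:8.0f}  QALY {arm_a.mean_qaly:.3f}  pain months {arm_a.mean_pain_months:5.2f}")
print(f"strategy B: cost EUR {arm_b.mean_cost:8.0f}  QALY {arm_b.mean_qaly:.3f}  pain months {arm_b.mean_pain_months:5.2f}")
print(f"increment : cost EUR {inc.delta_cost:8.0f}  QALY {inc.delta_qaly:.3f}  pain months {inc.delta_pain_months:5.2f}")
print(f"ICER: EUR {inc.icer_qaly:,.0f}/QALY, EUR {inc.icer_pain:,.0f}/pain-response month")
```

prints

```
strategy A: cost EUR     9742  QALY 1.053  pain months 10.67
strategy B: cost EUR     9278  QALY 1.035  pain months  9.44
increment : cost EUR      464  QALY 0.018  pain months  1.23
ICER: EUR 26,300/QALY, EUR 376/pain-response month
```

Offering MR-HIFU (strategy A) costs about EUR 464 more per patient over a
lifetime — mostly the pricier first-line procedure and the extra
retreatments — and buys 0.018 QALYs and 1.2 additional months in pain
response, driven by the faster onset of palliation (days rather than
weeks) and by retreating partial responders. At a willingness-to-pay of
EUR 20,000 per QALY the decision is close to the threshold, which is why
the probabilistic analysis matters:

```python
from hifucea import run_psa, ceac, evpi_per_person
table = run_psa(params, n_iter=10_000, seed=1)     # cohort-engine inner loop
print(ceac(table, [20_000, 40_000]))               # P(A cost-effective): ~0.57, ~0.69
print(evpi_per_person(table, 20_000))              # ~EUR 423 per person
```

The same analyses are available from the shell:

```bash
hifucea base --out results/          # base case + subgroups (CSV)
hifucea dsa --wtp 20000              # tornado-ready one-way DSA
hifucea scenarios                    # six structural scenarios
hifucea psa --n-iter 10000 --seed 1  # sample table, quadrants, CEAC
hifucea voi --seed 1                 # EVPI + per-parameter EVPPI
```

Every command writes a `manifest.json` (seed, engine, parameter hash) so
runs are reproducible; parameter sets round-trip through a strict YAML
config (`save_parameters` / `load_parameters`).

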