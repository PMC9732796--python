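# dfu-heor

Cost-utility modelling and feasibility-cohort statistics for the prevention
of **recurrent diabetic foot ulcers (DFUs)**.

People whose foot ulcer has recently healed face a high risk of recurrence,
amputation and death. Digital self-management tools (mHealth apps that
prompt daily foot checks and fast self-referral) are cheap, but their
comparative effectiveness is unknown — so the natural health-economic
question is inverted: *how small an effect on recurrence would such a tool
need to be cost-effective?* This package answers that question with a
Markov cohort cost-utility model and threshold analysis, and provides the
descriptive statistics used in small feasibility cohorts of this
population. It is written for health-economics and outcomes-research
(HEOR) analysts and methods-minded clinical researchers, as an importable
Python library with a thin `dfu-heor` command-line wrapper.

## The model

A closed cohort (baseline age 67, 70% male, all with a recently healed
DFU) moves in monthly cycles between six states:

```
post-DFU ─→ non-severe DFU (SINBAD < 3) ─→ severe DFU (SINBAD ≥ 3) ─→ amputation
   │  ↖────────────┘          ↖──────────────┘    │                      │
   └─→ death (absorbing) ←────────────────────────┘     post-amputation ←┘
                          ↖──────────────────────────────────┘
```

Occupancy evolves as `x_{c+1} = x_c P` with structural zeros on all moves
not listed above; self-transitions absorb residual row mass, and
amputation is a one-cycle tunnel into post-amputation. Each cycle accrues

- QALYs: `Σ_s x_c[s]·u_s/12 · (1+r_out)^(−c/12)`, with base-case utilities
  u = 0.64 (post-DFU), 0.61 (non-severe), 0.47 (severe), 0.34
  (amputation), 0.47 (post-amputation), 0 (death);
- costs (GBP, 2017/18): monthly state costs £180.70 / £453.83 / £972.30 /
  £1106.19 / £311.96, plus the app price (£0.00, £4.17 or £4.99 per month)
  charged to the alive fraction in the intervention arm,

with half-cycle correction and annual discount rates of 3.5% for both
streams by default. The app multiplies both recurrence transitions
(post-DFU → non-severe/severe DFU) by the compliance-adjusted relative
risk `rr_eff = γ·rr + (1−γ)` (compliance γ = 0.9 base case). The headline
output is the **threshold relative reduction** `1 − rr*` at which

`ICER(rr*) = ΔCost/ΔQALY = λ` (λ = £20,000/QALY),

found by bisection on the incremental net monetary benefit
`NMB(rr) = λ·ΔQALY(rr) − ΔCost(rr)`. One-way sensitivity analysis
re-evaluates NMB at the ends of each parameter's range and reports
tornado-ordered bars.

The package ships **no authoritative transition probabilities** — the
published inputs for this disease area come from audit data and
literature that are not reproduced here. A clearly labelled placeholder
set with plausible magnitudes (monthly recurrence 0.02, split 70/30
non-severe/severe) supports tests and demos; real analyses must load a
parameter file (see `dfu_heor.io.load_parameters`).

The feasibility side implements SINBAD scoring (six binary components;
severe ≥ 3), mean/SD and count summaries matching the published
15-patient baseline table (packaged as a CSV fixture), and a
Kaplan–Meier restricted-mean estimate of ulcer-free time with a bootstrap
percentile CI for recurrence times censored at 52 weeks.

## Worked example

```python
from dfu_heor import base_case_economics, placeholder_transition_parameters
from dfu_heor.economics import run_scenarios

params = placeholder_transition_parameters()
econ = base_case_economics("monthly")
print(run_scenarios(params, econ, pricings=("free", "annual", "monthly"))[
    ["scenario", "app_price_monthly", "threshold_rr", "relative_reduction_pct"]
])
```

prints

```
 scenario  app_price_monthly  threshold_rr  relative_reduction_pct
     free               0.00      1.000000                0.000000
   annual               4.17      0.972665                2.733469
  monthly               4.99      0.967322                3.267813
```

i.e. under the illustrative transition values a free app dominates with
any effect at all, while at £4.17 and £4.99 per month the app must cut
recurrences by about 2.7% and 3.3% respectively to hit £20,000/QALY —
note how little effect a low-priced intervention needs in a disease this
costly. The `examples/` directory has one short script per capability
(cohort trace, threshold, tornado, cohort statistics, synthetic data);
each prints its results with a line on what they mean. The same
functionality is available from the shell:

```bash
dfu-heor threshold --params my_params.yaml --price monthly --wtp 20000
dfu-heor cohort-summary
```

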