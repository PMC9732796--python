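# Methods

## Cohort model

The engine is a discrete-time Markov cohort model with six health states
(post-DFU, non-severe DFU, severe DFU, amputation, post-amputation,
death) and a fixed one-month cycle. The whole cohort starts in post-DFU.
Allowed moves are the structural edges listed in the README; anything
else is a structural zero and supplying probability mass there is a
validation error, not a warning. Self-transitions are implicit: a
validated row's diagonal is `1 − Σ outflows`, and death is absorbing.

**Amputation tunnel.** Amputation is modelled as a one-cycle tunnel:
unless the user specifies otherwise, the full mass moves to
post-amputation after one cycle (the state represents the procedure and
perioperative care, whose utility and cost are charged for exactly one
month). The constructor distinguishes *unspecified* from *explicitly
zero*: leaving the amputation outflow unset yields the tunnel default of
1.0, while an explicit 0.0 keeps the mass on the self-loop — this is what
makes "all outflows zero" produce a pure identity chain, which the test
suite uses as a degenerate oracle. Perioperative death
(amputation → death) is not part of the base structure; it can be enabled
explicitly via `allow_amputation_death=True`, which widens the structural
mask.

**Mortality is state-constant.** Death hazards attach to states
(post-DFU, severe DFU, post-amputation), not to age or sex; baseline age
67 and 70% male are cohort metadata used for the horizon and reporting.
This mirrors how state-aligned mortality inputs are published for this
population and keeps the trace a pure linear recursion. The consequence —
survival tails that are too heavy at very old ages — is bounded by the
age cap below.

**Horizon.** Lifetime, implemented as: run to `max_age_years` (default
100, i.e. 396 cycles from 67) or until the alive fraction falls below
`residual_alive_tolerance` (default 1e-6). Strategy comparisons disable
the early stop so both arms share an identical cycle grid; otherwise the
two arms could stop one cycle apart and the ICER round-trip identity
(NMB at the recomputed ICER = 0) would only hold to the size of the
discarded tail rather than to machine precision.

## Outcomes and discounting

Per cycle, QALYs accrue as occupancy · utility / 12 and costs as
occupancy · monthly cost; the app subscription is charged only to the
alive fraction of the intervention arm (charging the dead would be an
accounting artefact; the choice matters little because the price is small
relative to state costs). Half-cycle correction — using the mean of the
occupancy rows bounding each cycle — is on by default, the standard
correction for transitions happening mid-cycle; it is toggleable for
comparison with uncorrected traces.

Discounting uses the per-cycle factor `(1+r)^(−c/12)` with annual rate r
(default 0.035 for both costs and outcomes, separately configurable
because the outcome rate is a recognised sensitivity driver). A config
switch provides annual step discounting `(1+r)^(−⌊c/12⌋)` for
cross-checking against spreadsheet-style models that discount once per
model year.

## Intervention effect and threshold analysis

The app is assumed to act only on recurrence: both post-DFU → ulcer
transitions are multiplied by `rr_eff = compliance·rr + (1−compliance)`,
the simplest reading of a single scalar compliance (a fraction
`1−compliance` of the cohort receives no effect). The freed mass returns
to the post-DFU self-loop. Applying one scalar to both recurrence edges
leaves the severe/non-severe split unchanged — a deliberate neutrality
assumption in the absence of effect data.

`threshold_rr` bisects the incremental NMB at the target willingness to
pay over rr ∈ (0, 1], with tolerance 1e-6 on rr and a 200-iteration cap;
NMB is affine-decreasing in recurrence benefit forgone, so a bracketing
sign change identifies the unique crossing. Edge cases are explicit
results, not numbers: if the app is cost-saving with zero effect the
status is `dominant_at_rr1` (boundary rr → 1); if NMB never changes sign
(e.g. compliance 0) a `NoThresholdError` carries diagnostics. Southwest-
quadrant ICERs (cheaper and less effective) are flagged and never
silently compared with a willingness-to-pay threshold.

## One-way sensitivity analysis

Each parameter range is evaluated by two *independent full model runs*
(both arms re-traced at the low and high values); no incremental caching,
so bars are exactly reproducible from the public API. Bars sort by
descending width with name as the deterministic tie-break, making the
output invariant to input order. Default ranges are the conventional
deterministic-sensitivity choices — ±20% of base for probabilities,
utilities and costs, clipped to their domains, and an absolute 1.5%–6%
band for discount rates — because no published ranges exist for this
model; all are overridable per parameter. On the placeholder set the
widest bars are the post-DFU utility, the outcome discount rate, post-DFU
mortality and the severe-recurrence probability, consistent with the
qualitative ranking reported for this model class; this is a demo
observation, not a test assertion, because it depends on the illustrative
transition values.

## Feasibility statistics

SINBAD is the sum of six binary components; severity is the ≥3 cutoff.
Summaries use the arithmetic mean and *sample* (n−1) standard deviation —
the convention verified to reproduce every published baseline value of
the packaged 15-patient table at printed precision (age 60.8/9.3, BMI
32.94/6.13, SINBAD 2.1/1.0, 12/15 T2DM, 3/15 female, 9/15 previous
smokers, 2/15 completed, 6/15 reulcerated). Rounding happens only at
presentation.

Ulcer-free time uses the Kaplan–Meier restricted mean (lifelines), with
the restriction at the largest observed time, because recurrence times
are administratively censored at 52 weeks and the naive mean of observed
times would be biased low. The 95% CI is a bootstrap percentile interval
over patient resamples (default 2000, seeded, `n_boot=0` to skip): the
published interval for this quantity is asymmetric, which a normal
approximation cannot produce, and the bootstrap is the natural
nonparametric choice at n = 15. The per-patient recurrence times behind
the published 273.0-day mean are not available, so that number is treated
as non-reproducible; the estimator is validated on synthetic data instead
(uncensored KM restricted mean = arithmetic mean to 1e-9; hand-computed
censored examples).

## Synthetic data

The generator emulates the feasibility cohort's *marginal* structure:
age ~ N(60.8, 9.3²) truncated to [18, 95] by redraw (trial eligibility
starts at 18), BMI ~ N(32.94, 6.13²) on [15, 60], 20% female, 80% type 2,
smoking and employment at the observed 15-patient frequencies, diabetes
duration ~ N(17.9, 10.1²) truncated ≥1. SINBAD components are independent
Bernoulli draws with probabilities (0.20, 0.25, 0.75, 0.15, 0.40, 0.32)
— neuropathy high, as in this population — summing to 2.07, the observed
mean total; the total score and severity are always *derived* from the
components, never sampled separately. Recurrence is a constant-hazard
(geometric) waiting time at the day level, calibrated so the monthly
hazard 0.0417 yields the observed 40% (6/15) one-year reulceration
probability, censored administratively at 364 days. One integer seed
drives three spawned, independent substreams (demographics, SINBAD,
recurrence) via `numpy.random.SeedSequence`, so each piece is separately
reproducible.

What the generator does **not** emulate: correlations between covariates
(age–BMI, severity–recurrence), covariate-dependent hazards,
non-recurrence dropout, or the recruitment funnel; passing tests on
synthetic data therefore demonstrate the estimators' correctness under
the stated marginals, not robustness to real-world dependence structure.
The individual-level microsimulator shares only the transition *rules*
with the cohort engine (sampling paths rather than propagating
proportions) and serves as its stochastic oracle: empirical state
frequencies of 100,000 paths must match the deterministic trace within
three binomial standard errors.

## Numerical choices and problem sizes

- Trace mass conservation is asserted to 1e-9; the linear recursion keeps
  errors near machine epsilon over ~400 cycles.
- Bisection: tol 1e-6 on rr, ≤200 iterations, deterministic; the grid
  oracle in the tests uses 1,000 points (step 0.001) and requires
  agreement within one step.
- The test suite uses a 240-cycle horizon (to age 87) for the repeated
  grid-oracle comparisons and the full 396-cycle horizon elsewhere;
  microsimulation oracles use 40,000–100,000 paths. These sizes keep the
  full suite under half a minute while leaving Monte-Carlo bounds tight.
- Degenerate inputs are errors, not silent fixes: empty transition
  sections in parameter files, zero-cycle horizons, non-binary SINBAD
  components, empty summaries. The one deliberate clip is OWSA probability
  endpoints, clipped to [0, 1] with a warning, since ±20% ranges around
  large probabilities can leave the domain.

## Known limitations

- No probabilistic sensitivity analysis (CEAC) and no two-way analysis.
- Mortality does not age; very long horizons lean on the age-100 cap.
- The placeholder transition set is illustrative; every quantitative
  statement derived from it (e.g. the 2.7%/3.3% demo thresholds) is a
  property of those placeholder magnitudes, not an estimate for any real
  intervention.
- Costs are 2017/18 GBP with no inflation machinery; the app price is
  discounted on the same monthly grid as state costs.
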