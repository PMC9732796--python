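"""Run the six-state cohort model and accumulate discounted outcomes.

Uses the packaged PLACEHOLDER transition probabilities (illustrative
magnitudes only) with the base-case utilities and monthly costs, over a
lifetime horizon from age 67.
"""

from dfu_heor import (
    accumulate_outcomes,
    base_case_economics,
    placeholder_transition_parameters,
    run_cohort_trace,
)

params = placeholder_transition_parameters()
econ = base_case_economics("monthly")

trace = run_cohort_trace(params)
qalys, costs = accumulate_outcomes(trace, econ, include_app_cost=False)

print(f"cycles run: {trace.n_cycles} (age {trace.ages[-1]:.1f} at stop)")
print(f"share dead at horizon: {trace.occupancy[-1, -1]:.4f}")
print(f"discounted QALYs per patient: {qalys:.4f}")
print(f"discounted costs per patient: GBP {costs:,.2f}")
print()
print("Each patient starts post-ulcer; the totals are lifetime expected")
print("quality-adjusted life-years and care costs, discounted at 3.5%/yr.")
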