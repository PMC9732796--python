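"""Threshold analysis: how much recurrence reduction must the app deliver?

Finds, for each app-pricing scenario, the smallest relative reduction in
ulcer recurrence at which the app arm's ICER equals GBP 20,000/QALY.
Transition probabilities are the packaged PLACEHOLDER set, so the printed
thresholds illustrate the method rather than reproduce any published value.
"""

from dfu_heor import base_case_economics, placeholder_transition_parameters
from dfu_heor.economics import run_scenarios
from dfu_heor.io import format_threshold_report

params = placeholder_transition_parameters()
econ = base_case_economics("monthly")

table = run_scenarios(params, econ, pricings=("free", "annual", "monthly"),
                      target_icer=20_000.0)
print(format_threshold_report(table)[
    ["scenario", "app_price_monthly", "rr_print", "relative_reduction_print",
     "status"]
].to_string(index=False))
print()
print("A cheaper subscription needs a smaller effect: the free app is")
print("dominant with any effect at all, and the required relative reduction")
print("grows with the monthly price.")
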