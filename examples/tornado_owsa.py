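"""One-way sensitivity analysis with tornado ordering.

Every model parameter is pushed to the ends of a conventional range
(+/-20%, discount rates 1.5%-6%) and the incremental net monetary benefit
at rr = 0.95 and GBP 20,000/QALY is fully re-evaluated at each endpoint.
"""

from dfu_heor import base_case_economics, placeholder_transition_parameters
from dfu_heor.sensitivity import owsa, tornado_frame

params = placeholder_transition_parameters()
econ = base_case_economics("monthly")

bars = owsa(params, econ, rr=0.95, wtp=20_000.0)
frame = tornado_frame(bars)
print(frame.head(8).to_string(index=False, float_format=lambda v: f"{v:,.2f}"))
print()
print("Bars are sorted by width (impact on NMB); the widest parameters are")
print("the ones whose uncertainty matters most for the cost-effectiveness")
print("conclusion under these illustrative transition values.")
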