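"""Decompose resting fluorescence and correct measured dF/F for background.

In whole-heart voltage imaging, tissue autofluorescence and blebbistatin
contribute voltage-insensitive resting fluorescence, so the measured dF/F
underestimates the reporter's true response by (total / reporter).  The two
worked cases below use a bright and a dim GFP-based reporter on a common
absolute intensity scale.
"""
from panomap import FluorescenceBudget, correct_dff, correction_factor

cases = {
    "bright reporter (measured dF/F 3.41%)": (FluorescenceBudget(47.9, 44.0, 8.1), 3.41),
    "dim reporter    (measured dF/F 0.41%)": (FluorescenceBudget(11.8, 44.0, 8.1), 0.41),
}

for name, (budget, measured) in cases.items():
    f = correction_factor(budget)
    norm = budget.normalized()
    print(name)
    print(f"  components (% of this heart's total): reporter {norm.reporter:.1f}, "
          f"tissue {norm.tissue_autofluorescence:.1f}, blebbistatin {norm.blebbistatin:.1f}")
    print(f"  underestimation factor: {f:.2f}  -> corrected dF/F "
          f"{correct_dff(measured, f):.1f}%")
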