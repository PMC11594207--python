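"""Classify geographic origin (domestic vs imported) from spectra.

Compares PLS-DA and random forest on 2nd-derivative absorbance, with and
without random-frog wavelength screening.
"""

from bananachem import (
    ExperimentConfig, FrogConfig, SyntheticConfig, make_report,
    run_discrimination,
)

D2 = ["to_absorbance", {"sg_filter": {"window": 5, "polyorder": 2, "deriv": 2}}]
reports = []
for model, selector in [("plsda", "none"), ("rft", "none"), ("plsda", "frog")]:
    cfg = ExperimentConfig(
        target="origin", model=model, selector=selector, pretreatments=D2,
        synthetic=SyntheticConfig(seed=9, n_bands=60, n_samples=99),
        frog=FrogConfig(n_iterations=1000, q_init=2, n_lv=15, seed=9),
        seed=9)
    reports.append(run_discrimination(cfg))

table = make_report(reports)["classification"]
print(table.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
print("\n-> accuracies are percentages on the calibration and held-out")
print("   prediction sets; the class signal lives in the 800-850 nm")
print("   absorbance offset the generator gives imported fruit.")
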