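"""Compare the classical pretreatments on a quantitative PLS model.

Reproduces the structure of a preprocessing-selection table: one row per
pretreatment, columns R2c / RMSEC on the calibration set and R2p / RMSEP
on the held-out prediction set.
"""

from bananachem import ExperimentConfig, SyntheticConfig, make_report, run_quantitative

SWEEP = [
    (["to_absorbance"], "Raw"),
    (["to_absorbance", "msc"], "MSC"),
    (["to_absorbance", "snv"], "SNV"),
    (["to_absorbance", {"sg_filter": {"window": 5, "polyorder": 2, "deriv": 1}}], "1st"),
    (["to_absorbance", {"sg_filter": {"window": 5, "polyorder": 2, "deriv": 2}}], "2nd"),
    (["to_absorbance", "center"], "Center"),
]

reports = []
for steps, label in SWEEP:
    cfg = ExperimentConfig(
        target="ssc", model="pls", selector="none", pretreatments=steps,
        synthetic=SyntheticConfig(seed=3, n_bands=60, n_samples=99), seed=3)
    reports.append(run_quantitative(cfg))

table = make_report(reports)["regression"]
print(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print("\n-> R2 close to 1 and low RMSE mark the better pretreatment;")
print("   the scatter-corrective transforms (MSC, SNV, derivatives) beat")
print("   the raw absorbance because the generator plants exactly the")
print("   multiplicative-scatter and baseline structure they remove.")
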