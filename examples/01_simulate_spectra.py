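"""Generate a synthetic banana spectra dataset and inspect its structure.

The generator plants analyte-linked absorption features (soluble solids
near 840.3 nm, potassium near 641.51 nm) on a chlorophyll/water background
with scatter, baseline and noise, and records exactly which bands carry
each signal.
"""

import numpy as np

from bananachem import SyntheticConfig, generate_spectra_dataset, to_absorbance

cfg = SyntheticConfig(seed=42, n_samples=99, n_bands=225)
dataset, truth = generate_spectra_dataset(cfg)

print(f"samples x bands : {dataset.n_samples} x {dataset.n_bands}")
print(f"wavelengths     : {dataset.wavelengths[0]:.1f}..{dataset.wavelengths[-1]:.1f} nm")
print(f"SSC range       : {dataset.y_ssc.min():.2f}..{dataset.y_ssc.max():.2f} %")
print(f"K range         : {dataset.y_k.min():.1f}..{dataset.y_k.max():.1f} mg/100 g")
print(f"class balance   : {np.mean(dataset.labels == 'imported'):.2f} imported")

absorbance = to_absorbance(dataset)
band = dataset.band_nearest(840.3)
r = np.corrcoef(dataset.y_ssc, absorbance.X[:, band])[0, 1]
print(f"\ncorr(SSC, A at {dataset.wavelengths[band]:.1f} nm) = {r:.3f}")
print("-> the planted sugar feature dominates the variance at its own band,")
print("   which is what makes wavelength selection recoverable by design.")
print(f"planted SSC bands: {truth.informative_indices_ssc}")
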