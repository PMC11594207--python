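"""From a raw hyperspectral cube to a calibrated mean spectrum.

Builds a small synthetic push-broom cube with dark/white reference frames,
applies black/white reflectance calibration, averages the fruit pixels and
trims the axis to 400-1000 nm — the standard imaging workflow.
"""

import numpy as np

from bananachem import (
    ROI, SyntheticConfig, calibrate, generate_cube, roi_mean_spectrum,
    trim_wavelengths,
)

cfg = SyntheticConfig(seed=7, n_bands=50)
raw, dark, white, mask = generate_cube(cfg, shape=(32, 40))
print(f"raw cube  : {raw.shape} ({raw.kind}), counts {raw.data.min():.0f}..{raw.data.max():.0f}")

reflectance = calibrate(raw, dark, white)
print(f"calibrated: kind={reflectance.kind}, "
      f"R {reflectance.data.min():.3f}..{reflectance.data.max():.3f}")

spectrum = roi_mean_spectrum(reflectance, ROI(mask=mask), sample_id="banana-001")
spectrum = trim_wavelengths(spectrum, 400, 1000)
print(f"ROI pixels: {mask.sum()}, spectrum length {spectrum.values.size}")
print(f"mean reflectance over the fruit: {spectrum.values.mean():.3f}")
print("-> R = (I - dark) / (white - dark) per pixel and band; the ROI mean")
print("   is the per-sample spectrum every downstream model consumes.")
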