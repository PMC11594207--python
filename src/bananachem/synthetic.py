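"""Seeded generator of banana-like VIS/NIR spectra with known ground truth.

No public spectral library of bananas with matched soluble-solids (SSC) and
potassium (K) assays exists, so validation of the selection and calibration
machinery runs on synthetic spectra whose informative bands are planted and
therefore recoverable by construction.

The generative model is Beer-Lambert-flavoured: each sample's ideal
absorbance is a sum of Gaussian absorption features — an SSC-linked feature
near 840.3 nm, a K-linked feature near 641.51 nm, chlorophyll near 680 nm
and water near 960 nm — on a fixed linear baseline, plus a constant
offset added over 800-850 nm for the imported class. The observed spectrum
applies a multiplicative scatter factor and additive band noise, and is
stored as reflectance R = 10**(-A). This is exactly the distortion family
that MSC/SNV/derivative pretreatments are designed to remove, which makes
every pretreatment and both wavelength selectors testable against ground
truth.

Noise is drawn from a dedicated child stream of the seed and scaled by
``noise_sd``, so raising the noise level under a fixed seed rescales one
fixed noise realization instead of redrawing it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .dataset import SpectraDataset
from .exceptions import ConfigurationError
from .hypercube import HyperCube

__all__ = ["SyntheticConfig", "GroundTruth", "generate_spectra_dataset", "generate_cube"]

#: component order used for peak bookkeeping
_COMPONENTS = ("ssc", "k", "chlorophyll", "water")


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic spectra generator.

    Defaults emulate the study conditions: 99 samples, a 225-band axis over
    400-1000 nm, SSC in 15.23-23.23 %, K in 80-200 mg/100 g, and an
    imported-class absorbance offset over 800-850 nm.
    """

    n_samples: int = 99
    wavelength_start: float = 400.0
    wavelength_stop: float = 1000.0
    n_bands: int = 225
    #: absorption feature centers in nm, one per component
    peak_centers: dict = field(default_factory=lambda: {
        "ssc": 840.3, "k": 641.51, "chlorophyll": 680.0, "water": 960.0})
    #: Gaussian sd of each feature in nm
    peak_widths: dict = field(default_factory=lambda: {
        "ssc": 15.0, "k": 15.0, "chlorophyll": 25.0, "water": 40.0})
    #: absorbance amplitude of each feature at unit scaled concentration;
    #: analyte features are subtle against the chlorophyll/water background,
    #: as for sugar/mineral signatures in VIS-NIR fruit spectra
    peak_amplitudes: dict = field(default_factory=lambda: {
        "ssc": 0.025, "k": 0.025, "chlorophyll": 0.35, "water": 0.25})
    ssc_range: tuple = (15.23, 23.23)       # %
    k_range: tuple = (80.0, 200.0)          # mg/100 g
    #: absorbance offset added over class_band for the imported class
    class_effect: float = 0.007
    class_band: tuple = (800.0, 850.0)      # nm
    scatter_sd: float = 0.01                # sd of the multiplicative factor
    #: fixed baseline offset + slope (in absorbance over the full axis);
    #: per-sample baseline variation arises through the scatter factor
    baseline_coeffs: tuple = (0.05, 0.10)
    base_absorbance: float = 0.10           # constant pedestal, keeps R < 1
    noise_sd: float = 0.002                 # additive absorbance noise per band
    class_proportion: float = 0.6           # fraction labelled imported
    seed: int = 0

    def validate(self) -> None:
        if self.n_bands < 2:
            raise ConfigurationError("n_bands: must be >= 2")
        if not self.wavelength_start < self.wavelength_stop:
            raise ConfigurationError("wavelength_start/stop: start must be < stop")
        if self.n_samples < 1:
            raise ConfigurationError("n_samples: must be >= 1")
        for name, rng in (("ssc_range", self.ssc_range), ("k_range", self.k_range)):
            if not rng[0] < rng[1]:
                raise ConfigurationError(f"{name}: must be a nonempty interval")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd: must be >= 0")
        if self.scatter_sd < 0:
            raise ConfigurationError("scatter_sd: must be >= 0")
        if not 0.0 <= self.class_proportion <= 1.0:
            raise ConfigurationError("class_proportion: must lie in [0, 1]")
        for comp in _COMPONENTS:
            if comp not in self.peak_centers:
                raise ConfigurationError(f"peak_centers: missing component '{comp}'")
            c = self.peak_centers[comp]
            if not self.wavelength_start <= c <= self.wavelength_stop:
                raise ConfigurationError(
                    f"peak_centers: '{comp}' center {c} nm outside the wavelength range")
            if self.peak_widths.get(comp, 0) <= 0:
                raise ConfigurationError(f"peak_widths: '{comp}' must be > 0")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.wavelength_start, self.wavelength_stop, self.n_bands)


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests."""

    informative_indices_ssc: np.ndarray
    informative_indices_k: np.ndarray
    informative_indices_class: np.ndarray
    true_ssc: np.ndarray
    true_k: np.ndarray
    true_labels: np.ndarray

    def to_json(self, path: str | Path) -> None:
        payload = {k: np.asarray(v).tolist() for k, v in asdict(self).items()}
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(**{k: np.asarray(v) for k, v in payload.items()})


def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def _scaled(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    # min-max scaling against the configured range, so amplitudes are
    # comparable across analytes with different units
    return (values - lo) / (hi - lo)


def generate_spectra_dataset(
    config: SyntheticConfig,
    *,
    ssc: np.ndarray | None = None,
    k: np.ndarray | None = None,
    labels: np.ndarray | None = None,
) -> tuple[SpectraDataset, GroundTruth]:
    """Draw a seeded synthetic dataset and its ground truth.

    Optional ``ssc`` / ``k`` / ``labels`` arrays override the random draws
    (e.g. to force duplicate concentrations); everything else — baselines,
    scatter, noise — is still drawn from the seeded streams.

    Returns
    -------
    (SpectraDataset, GroundTruth)
        Reflectance spectra with targets and labels, plus the planted
        informative band indices.
    """
    config.validate()
    n, wl = config.n_samples, config.wavelengths
    ss = np.random.SeedSequence(config.seed)
    s_struct, s_noise = ss.spawn(2)
    rng = np.random.default_rng(s_struct)
    rng_noise = np.random.default_rng(s_noise)

    c_ssc = rng.uniform(*config.ssc_range, n) if ssc is None else np.asarray(ssc, float)
    c_k = rng.uniform(*config.k_range, n) if k is None else np.asarray(k, float)
    if labels is None:
        n_imported = int(round(n * config.class_proportion))
        order = rng.permutation(n)
        lab = np.where(np.argsort(order) < n_imported, "imported", "domestic")
    else:
        lab = np.asarray(labels)
    if c_ssc.shape != (n,) or c_k.shape != (n,) or lab.shape != (n,):
        raise ConfigurationError("ssc/k/labels overrides: length mismatch with n_samples")

    # chlorophyll and water carry fixed unit strength: their bands shape the
    # spectrum but only scatter/noise make them vary between samples
    strengths = {
        "ssc": _scaled(c_ssc, *config.ssc_range),
        "k": _scaled(c_k, *config.k_range),
        "chlorophyll": np.ones(n),
        "water": np.ones(n),
    }

    ideal = np.full((n, config.n_bands), config.base_absorbance)
    for comp in _COMPONENTS:
        profile = _gauss(wl, config.peak_centers[comp], config.peak_widths[comp])
        ideal += config.peak_amplitudes[comp] * strengths[comp][:, None] * profile[None, :]

    lo, hi = config.class_band
    in_band = (wl >= lo) & (wl <= hi)
    ideal += config.class_effect * np.outer(lab == "imported", in_band)

    t = (wl - config.wavelength_start) / (config.wavelength_stop - config.wavelength_start)
    ideal += config.baseline_coeffs[0] + config.baseline_coeffs[1] * t[None, :]

    m = rng.normal(1.0, config.scatter_sd, n)
    noise = config.noise_sd * rng_noise.standard_normal((n, config.n_bands))
    absorbance = m[:, None] * ideal + noise
    reflectance = 10.0 ** (-absorbance)

    dataset = SpectraDataset(
        X=reflectance,
        wavelengths=wl,
        y_ssc=c_ssc,
        y_k=c_k,
        labels=lab,
        space="reflectance",
        provenance=[f"synthetic(seed={config.seed})"],
    )

    def _near(comp: str) -> np.ndarray:
        d = np.abs(wl - config.peak_centers[comp])
        return np.flatnonzero(d <= config.peak_widths[comp])

    truth = GroundTruth(
        informative_indices_ssc=_near("ssc"),
        informative_indices_k=_near("k"),
        informative_indices_class=np.flatnonzero(in_band),
        true_ssc=c_ssc,
        true_k=c_k,
        true_labels=lab,
    )
    return dataset, truth


def generate_cube(
    config: SyntheticConfig, shape: tuple[int, int]
) -> tuple[HyperCube, np.ndarray, np.ndarray, np.ndarray]:
    """Build a small raw push-broom cube with known planted reflectance.

    An elliptical foreground carries one generated banana spectrum (plus
    per-pixel noise); the background is flat low reflectance. The returned
    single-line dark and white reference frames (cols x bands) are built so
    that black/white calibration recovers the planted reflectance in
    expectation — exactly, when ``noise_sd`` is zero.

    Returns
    -------
    (HyperCube, dark_frame, white_frame, mask)
    """
    rows, cols = shape
    if rows < 8 or cols < 8:
        raise ConfigurationError("shape: rows and cols must both be >= 8")
    one = SyntheticConfig(**{**asdict(config), "n_samples": 1})
    # dataclass asdict round-trip keeps dict/tuple fields intact
    ds, _ = generate_spectra_dataset(one)
    spectrum = ds.X[0]
    p = one.n_bands

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7341]))
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    mask = (((rr - (rows - 1) / 2) / (0.38 * rows)) ** 2
            + ((cc - (cols - 1) / 2) / (0.38 * cols)) ** 2) <= 1.0

    reflectance = np.full((rows, cols, p), 0.05)
    reflectance[mask] = spectrum
    reflectance += config.noise_sd * rng.standard_normal(reflectance.shape)

    dark_level, white_level = 100.0, 4000.0
    raw = dark_level + reflectance * (white_level - dark_level)
    frame_noise = config.noise_sd * (white_level - dark_level)
    dark = dark_level + frame_noise * rng.standard_normal((cols, p))
    white = white_level + frame_noise * rng.standard_normal((cols, p))

    cube = HyperCube(data=raw, wavelengths=one.wavelengths, kind="raw")
    return cube, dark, white, mask
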