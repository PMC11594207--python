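"""Row-wise spectral pretreatments.

The six classical treatments — multiplicative scatter correction (MSC),
standard normal variate (SNV), first and second Savitzky-Golay derivatives,
mean centering, and SG smoothing — plus reflectance-to-absorbance
conversion. Each function takes and returns a :class:`SpectraDataset`,
preserving (n, p) and the wavelength axis and appending to provenance.

Pipelines are declared as ordered step lists, e.g.::

    ["to_absorbance", {"sg_filter": {"window": 15, "polyorder": 3, "deriv": 2}}]
"""

from __future__ import annotations

import numpy as np
from scipy.signal import savgol_filter

from .dataset import SpectraDataset
from .exceptions import ConfigurationError, DegenerateDataError

__all__ = [
    "to_absorbance", "snv", "msc", "sg_filter", "mean_center", "apply_steps",
]

#: reflectance floor guarding log10(1/R)
REFLECTANCE_FLOOR = 1e-6


def to_absorbance(ds: SpectraDataset, floor: float = REFLECTANCE_FLOOR) -> SpectraDataset:
    """Convert reflectance to absorbance, A = log10(1/R).

    Reflectance is clipped from below at ``floor`` before the log; samples
    with nonpositive values even before clipping are reported by id.
    """
    if ds.space != "reflectance":
        raise ConfigurationError("to_absorbance: dataset is not in reflectance space")
    nonpos = np.any(ds.X <= 0, axis=1)
    if nonpos.any():
        bad = [ds.sample_ids[i] for i in np.flatnonzero(nonpos)]
        raise DegenerateDataError(
            f"to_absorbance: nonpositive reflectance in samples {bad}")
    A = -np.log10(np.clip(ds.X, floor, None))
    return ds.with_X(A, space="absorbance", note="to_absorbance")


def snv(ds: SpectraDataset, ddof: int = 1) -> SpectraDataset:
    """Standard normal variate: each row to mean 0, spread 1.

    ``ddof=1`` (sample sd) is the chemometrics convention; ``ddof=0`` gives
    the population sd. Constant rows are rejected by sample id.
    """
    if ds.n_bands < 2:
        raise ConfigurationError("snv: needs at least 2 bands")
    mu = ds.X.mean(axis=1, keepdims=True)
    sd = ds.X.std(axis=1, ddof=ddof, keepdims=True)
    flat = sd[:, 0] == 0
    if flat.any():
        bad = [ds.sample_ids[i] for i in np.flatnonzero(flat)]
        raise DegenerateDataError(f"snv: constant rows for samples {bad}")
    return ds.with_X((ds.X - mu) / sd, note=f"snv(ddof={ddof})")


def msc(ds: SpectraDataset, reference: np.ndarray | None = None) -> SpectraDataset:
    """Multiplicative scatter correction.

    Each row x is regressed on the reference spectrum by ordinary least
    squares, x ~ a + b*ref, and corrected to (x - a) / b. The reference
    defaults to the column-mean spectrum of the dataset.
    """
    if reference is None:
        if ds.n_samples < 2:
            raise ConfigurationError("msc: needs >= 2 samples when no reference is given")
        reference = ds.X.mean(axis=0)
    ref = np.asarray(reference, dtype=float)
    if ref.shape != (ds.n_bands,):
        raise ConfigurationError("msc: reference length mismatch with band count")
    ref_c = ref - ref.mean()
    denom = ref_c @ ref_c
    if denom == 0:
        raise DegenerateDataError("msc: reference spectrum is constant")
    b = (ds.X - ds.X.mean(axis=1, keepdims=True)) @ ref_c / denom
    tiny = np.abs(b) < 1e-12
    if tiny.any():
        bad = [ds.sample_ids[i] for i in np.flatnonzero(tiny)]
        raise DegenerateDataError(f"msc: slope |b| < 1e-12 for samples {bad}")
    a = ds.X.mean(axis=1) - b * ref.mean()
    corrected = (ds.X - a[:, None]) / b[:, None]
    return ds.with_X(corrected, note="msc")


def sg_filter(ds: SpectraDataset, window: int = 15, polyorder: int = 3,
              deriv: int = 0) -> SpectraDataset:
    """Savitzky-Golay smoothing (deriv=0) or derivative (deriv=1 or 2).

    The derivative scale is per band-index step, not per nm. Edges use the
    fitted local polynomial (scipy's ``mode="interp"``) so p is preserved.
    """
    if window % 2 == 0 or window <= polyorder:
        raise ConfigurationError(
            f"sg_filter: window ({window}) must be odd and > polyorder ({polyorder})")
    if deriv not in (0, 1, 2) or deriv > polyorder:
        raise ConfigurationError("sg_filter: deriv must be in {0,1,2} and <= polyorder")
    if ds.n_bands < window:
        raise ConfigurationError(
            f"sg_filter: window ({window}) exceeds band count ({ds.n_bands})")
    out = savgol_filter(ds.X, window_length=window, polyorder=polyorder,
                        deriv=deriv, delta=1.0, axis=1, mode="interp")
    return ds.with_X(out, note=f"sg_filter(window={window},polyorder={polyorder},deriv={deriv})")


def mean_center(ds: SpectraDataset, means: np.ndarray | None = None
                ) -> tuple[SpectraDataset, np.ndarray]:
    """Column mean centering.

    Without ``means``, centers on the dataset's own column means (requires
    n >= 2) and returns them for later application to new data; with
    ``means``, subtracts the supplied vector.
    """
    if means is None:
        if ds.n_samples < 2:
            raise ConfigurationError("mean_center: needs >= 2 samples to fit means")
        means = ds.X.mean(axis=0)
    means = np.asarray(means, dtype=float)
    if means.shape != (ds.n_bands,):
        raise ConfigurationError("mean_center: means length mismatch with band count")
    return ds.with_X(ds.X - means[None, :], note="mean_center"), means


# ---------------------------------------------------------------------------
# Declarative pipelines

_STEPS = {
    "to_absorbance": to_absorbance,
    "snv": snv,
    "msc": msc,
    "sg_filter": sg_filter,
}


def apply_steps(ds: SpectraDataset, steps: list) -> SpectraDataset:
    """Apply an ordered pretreatment pipeline declared as strings/dicts."""
    for step in steps:
        if isinstance(step, str):
            name, kwargs = step, {}
        elif isinstance(step, dict) and len(step) == 1:
            name, kwargs = next(iter(step.items()))
            kwargs = dict(kwargs or {})
        else:
            raise ConfigurationError(f"pipeline step not understood: {step!r}")
        if name in ("center", "mean_center"):
            ds, _ = mean_center(ds, **kwargs)
        elif name in _STEPS:
            ds = _STEPS[name](ds, **kwargs)
        elif name in ("1st", "d1"):
            ds = sg_filter(ds, deriv=1, **kwargs)
        elif name in ("2nd", "d2"):
            ds = sg_filter(ds, deriv=2, **kwargs)
        elif name in ("sg", "smooth"):
            ds = sg_filter(ds, deriv=0, **kwargs)
        elif name in ("raw", "none"):
            continue
        else:
            raise ConfigurationError(f"unknown pretreatment '{name}'")
    return ds
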