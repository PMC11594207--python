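"""Hyperspectral cubes: ENVI I/O, black/white reflectance calibration,
ROI mean spectra, and wavelength-range trimming.

An ENVI image is a plain binary array plus a small text header declaring its
shape, data type, byte order, band interleave (BSQ/BIL/BIP) and wavelength
list. Push-broom instruments record a dark frame (lens capped) and a white
frame (reference board) alongside each scan; reflectance is recovered per
pixel and band as R = (I_raw - I_dark) / (I_white - I_dark).

Conventions: 0-based (row, col), row-major; rectangle ROIs are half-open at
their upper bounds; wavelength trimming keeps a closed interval.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .exceptions import CalibrationError, ConfigurationError, EnviFormatError

__all__ = [
    "HyperCube", "ROI", "Spectrum",
    "read_envi", "write_envi", "calibrate", "roi_mean_spectrum", "trim_wavelengths",
]

# ENVI numeric data-type codes
_DTYPE_BY_CODE = {
    1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32,
    5: np.float64, 12: np.uint16, 13: np.uint32,
}
_CODE_BY_DTYPE = {np.dtype(v): k for k, v in _DTYPE_BY_CODE.items()}


@dataclass
class HyperCube:
    """rows x cols x bands image with a wavelength axis.

    ``kind`` is ``"raw"`` (detector counts) or ``"reflectance"``; calibrated
    values are expected to lie in [-0.5, 2.0] (noise tolerance around [0, 1]).
    """

    data: np.ndarray
    wavelengths: np.ndarray
    kind: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ConfigurationError("data: expected rows x cols x bands")
        if self.wavelengths.shape != (self.data.shape[2],):
            raise ConfigurationError("wavelengths: length must equal band count")
        if not np.all(np.isfinite(self.wavelengths)):
            raise ConfigurationError("wavelengths: non-finite entries")
        if self.wavelengths.size >= 2 and not np.all(np.diff(self.wavelengths) > 0):
            raise ConfigurationError("wavelengths: must be strictly increasing")
        if self.kind not in ("raw", "reflectance"):
            raise ConfigurationError(f"kind: unknown value {self.kind!r}")
        if self.kind == "reflectance":
            lo, hi = float(self.data.min()), float(self.data.max())
            if lo < -0.5 or hi > 2.0:
                raise ConfigurationError(
                    f"data: reflectance values outside [-0.5, 2.0] (range {lo:.3g}..{hi:.3g})")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class ROI:
    """Region of interest: a half-open rectangle or an explicit pixel mask."""

    rect: tuple[int, int, int, int] | None = None   # (row0, col0, row1, col1)
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.rect is None) == (self.mask is None):
            raise ConfigurationError("ROI: exactly one of rect or mask is required")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)

    def pixel_mask(self, shape: tuple[int, int]) -> np.ndarray:
        rows, cols = shape
        if self.mask is not None:
            if self.mask.shape != (rows, cols):
                raise ConfigurationError("ROI mask: shape mismatch with cube extent")
            m = self.mask
        else:
            r0, c0, r1, c1 = self.rect
            if not (0 <= r0 < r1 <= rows and 0 <= c0 < c1 <= cols):
                raise ConfigurationError("ROI rect: outside the cube extent or empty")
            m = np.zeros((rows, cols), dtype=bool)
            m[r0:r1, c0:c1] = True
        if not m.any():
            raise ConfigurationError("ROI: empty (no pixels)")
        return m

    def to_json(self, path: str | Path) -> None:
        if self.rect is not None:
            payload = {"type": "rect", "rect": list(self.rect)}
        else:
            payload = {"type": "mask", "mask": self.mask.astype(int).tolist()}
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ROI":
        payload = json.loads(Path(path).read_text())
        if payload.get("type") == "rect":
            return cls(rect=tuple(payload["rect"]))
        if payload.get("type") == "mask":
            return cls(mask=np.asarray(payload["mask"], dtype=bool))
        raise ConfigurationError("ROI JSON: type must be 'rect' or 'mask'")


@dataclass
class Spectrum:
    """A single mean spectrum with its wavelength axis."""

    wavelengths: np.ndarray
    values: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.shape != self.values.shape:
            raise ConfigurationError("Spectrum: wavelengths/values length mismatch")
        if self.wavelengths.size >= 2 and not np.all(np.diff(self.wavelengths) > 0):
            raise ConfigurationError("Spectrum: wavelengths must be strictly increasing")


# ---------------------------------------------------------------------------
# ENVI I/O

def _data_path_for(header_path: Path) -> Path:
    stem = header_path.with_suffix("")
    for candidate in (stem.with_suffix(".img"), stem.with_suffix(".raw"),
                      stem.with_suffix(".dat"), stem):
        if candidate.exists() and candidate != header_path:
            return candidate
    raise EnviFormatError(f"no data file found next to header {header_path}")


def _parse_header(text: str) -> dict:
    if not text.lstrip().upper().startswith("ENVI"):
        raise EnviFormatError("not an ENVI header (missing leading 'ENVI')")
    # collapse brace-delimited multi-line values, then split on '='
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict = {}
    for line in text.splitlines()[1:]:
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def _parse_list(value: str) -> list[float]:
    inner = value.strip().lstrip("{").rstrip("}")
    return [float(tok) for tok in inner.replace(",", " ").split()]


def read_envi(header_path: str | Path) -> HyperCube:
    """Read an ENVI header/data pair into a :class:`HyperCube`.

    Supports BSQ, BIL and BIP interleaves and the common numeric dtypes.
    Raises :class:`EnviFormatError` on missing wavelengths, an unsupported
    interleave, or a data file whose size disagrees with the header.
    """
    header_path = Path(header_path)
    fields = _parse_header(header_path.read_text())
    try:
        rows = int(fields["lines"])
        cols = int(fields["samples"])
        bands = int(fields["bands"])
        code = int(fields["data type"])
    except KeyError as exc:
        raise EnviFormatError(f"header missing required field {exc}") from exc
    if "wavelength" not in fields:
        raise EnviFormatError("header has no wavelength list")
    wavelengths = np.array(_parse_list(fields["wavelength"]))
    if wavelengths.size != bands:
        raise EnviFormatError(
            f"header declares {bands} bands but lists {wavelengths.size} wavelengths")
    interleave = fields.get("interleave", "bsq").lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise EnviFormatError(f"unsupported interleave '{interleave}'")
    if code not in _DTYPE_BY_CODE:
        raise EnviFormatError(f"unsupported data type code {code}")
    dtype = np.dtype(_DTYPE_BY_CODE[code])
    if int(fields.get("byte order", 0)) == 1:
        dtype = dtype.newbyteorder(">")
    offset = int(fields.get("header offset", 0))

    data_path = _data_path_for(header_path)
    flat = np.fromfile(data_path, dtype=dtype, offset=offset)
    if flat.size != rows * cols * bands:
        raise EnviFormatError(
            f"data size {flat.size} != lines*samples*bands = {rows * cols * bands}")
    if interleave == "bsq":
        data = flat.reshape(bands, rows, cols).transpose(1, 2, 0)
    elif interleave == "bil":
        data = flat.reshape(rows, bands, cols).transpose(0, 2, 1)
    else:  # bip
        data = flat.reshape(rows, cols, bands)
    kind = fields.get("bananachem kind", "raw")
    return HyperCube(data=np.ascontiguousarray(data), wavelengths=wavelengths, kind=kind)


def write_envi(cube: HyperCube, base_path: str | Path, interleave: str = "bsq") -> Path:
    """Write ``base.img`` + ``base.hdr``; returns the header path."""
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise EnviFormatError(f"unsupported interleave '{interleave}'")
    base = Path(base_path).with_suffix("")
    dtype = np.dtype(cube.data.dtype)
    if dtype not in _CODE_BY_DTYPE:
        raise EnviFormatError(f"unsupported dtype {dtype} for ENVI output")
    rows, cols, bands = cube.shape
    if interleave == "bsq":
        out = cube.data.transpose(2, 0, 1)
    elif interleave == "bil":
        out = cube.data.transpose(0, 2, 1)
    else:
        out = cube.data
    data_path = base.with_suffix(".img")
    np.ascontiguousarray(out).tofile(data_path)

    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
    header = "\n".join([
        "ENVI",
        "description = {bananachem export}",
        f"samples = {cols}",
        f"lines = {rows}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_CODE_BY_DTYPE[dtype]}",
        f"interleave = {interleave}",
        "byte order = 0",
        f"bananachem kind = {cube.kind}",
        "wavelength units = Nanometers",
        "wavelength = { " + wl + " }",
        "",
    ])
    header_path = base.with_suffix(".hdr")
    header_path.write_text(header)
    return header_path


# ---------------------------------------------------------------------------
# Calibration and spectra extraction

def _as_reference(frame: np.ndarray, shape: tuple[int, int, int], name: str) -> np.ndarray:
    """Reduce a reference frame to a single scan line (cols x bands).

    Full-cube references are averaged over scan rows first — standard
    push-broom practice, one reference spectrum per detector column/band.
    """
    frame = np.asarray(frame, dtype=float)
    rows, cols, bands = shape
    if frame.shape == (rows, cols, bands):
        return frame.mean(axis=0)
    if frame.shape == (cols, bands):
        return frame
    raise CalibrationError(
        f"{name} frame shape {frame.shape} matches neither the cube nor a single line")


def calibrate(raw: HyperCube, dark: np.ndarray, white: np.ndarray) -> HyperCube:
    """Black/white reflectance calibration: R = (I - D) / (W - D).

    ``dark`` and ``white`` may be full cubes (averaged over scan rows) or
    single-line (cols x bands) references broadcast along rows. Raises
    :class:`CalibrationError` if any averaged (white - dark) is <= 0,
    reporting the first offending column/band.
    """
    d = _as_reference(dark, raw.shape, "dark")
    w = _as_reference(white, raw.shape, "white")
    span = w - d
    bad = span <= 0
    if bad.any():
        col, band = np.argwhere(bad)[0]
        raise CalibrationError(
            f"white - dark <= 0 at column {col}, band {band} "
            f"(wavelength {raw.wavelengths[band]:.2f} nm)")
    reflectance = (raw.data.astype(float) - d[None, :, :]) / span[None, :, :]
    return HyperCube(data=reflectance, wavelengths=raw.wavelengths, kind="reflectance")


def roi_mean_spectrum(cube: HyperCube, roi: ROI, sample_id: str = "") -> Spectrum:
    """Per-band arithmetic mean over the ROI pixels of a reflectance cube."""
    if cube.kind != "reflectance":
        raise ConfigurationError("roi_mean_spectrum: cube must be calibrated reflectance")
    m = roi.pixel_mask(cube.shape[:2])
    values = cube.data[m].mean(axis=0)
    return Spectrum(wavelengths=cube.wavelengths.copy(), values=values, sample_id=sample_id)


def trim_wavelengths(obj, lo: float, hi: float):
    """Keep exactly the bands with lo <= lambda <= hi (closed interval).

    Works on :class:`Spectrum`, :class:`HyperCube` and
    :class:`~bananachem.dataset.SpectraDataset`. Raises if no band survives.
    """
    if not lo < hi:
        raise ConfigurationError("trim_wavelengths: lo must be < hi")
    wl = obj.wavelengths
    keep = (wl >= lo) & (wl <= hi)
    if not keep.any():
        raise ConfigurationError(
            f"trim_wavelengths: no bands inside [{lo}, {hi}] nm")
    if isinstance(obj, Spectrum):
        return Spectrum(wl[keep], obj.values[keep], obj.sample_id)
    if isinstance(obj, HyperCube):
        return HyperCube(obj.data[:, :, keep], wl[keep], obj.kind)
    # SpectraDataset (duck-typed to avoid an import cycle)
    ds = replace(obj, X=obj.X[:, keep], wavelengths=wl[keep],
                 provenance=list(obj.provenance) + [f"trim({lo},{hi})"],
                 sample_ids=list(obj.sample_ids))
    return ds
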