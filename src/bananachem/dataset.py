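"""The central exchange object: an n-by-p spectra matrix on a shared
wavelength axis, with optional per-sample targets and class labels.

A :class:`SpectraDataset` is immutable in spirit: every transform returns a
new instance and appends a human-readable tag to ``provenance``, so any
report can state exactly which pretreatments produced its inputs.

The on-disk form is a wide CSV: ``sample_id``, ``ssc``, ``k``,
``origin_class``, then one column per wavelength named with 2-decimal
precision in nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

__all__ = ["SpectraDataset"]

#: column order of the CSV dialect ahead of the wavelength block
_META_COLUMNS = ("sample_id", "ssc", "k", "origin_class")


@dataclass
class SpectraDataset:
    """Spectra matrix plus targets and labels on a shared wavelength axis.

    Parameters
    ----------
    X : ndarray, shape (n_samples, n_bands)
        Reflectance or absorbance values; must be finite.
    wavelengths : ndarray, shape (n_bands,)
        Strictly increasing wavelength axis in nm.
    sample_ids : sequence of str
    y_ssc, y_k : ndarray or None
        Soluble-solids content (%) and potassium (mg/100 g) targets.
    labels : ndarray of str or None
        Class labels (e.g. ``"domestic"`` / ``"imported"``).
    space : {"reflectance", "absorbance"}
    provenance : list of str
        Append-only record of applied transforms.
    """

    X: np.ndarray
    wavelengths: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    y_ssc: np.ndarray | None = None
    y_k: np.ndarray | None = None
    labels: np.ndarray | None = None
    space: str = "reflectance"
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.X.ndim != 2:
            raise ConfigurationError("X: expected a 2-D (samples x bands) matrix")
        n, p = self.X.shape
        if self.wavelengths.shape != (p,):
            raise ConfigurationError(
                f"wavelengths: length {self.wavelengths.size} != {p} bands in X"
            )
        if not np.all(np.isfinite(self.X)):
            raise ConfigurationError("X: non-finite entries present")
        if not np.all(np.isfinite(self.wavelengths)):
            raise ConfigurationError("wavelengths: non-finite entries present")
        if p >= 2 and not np.all(np.diff(self.wavelengths) > 0):
            raise ConfigurationError("wavelengths: must be strictly increasing")
        if self.space not in ("reflectance", "absorbance"):
            raise ConfigurationError(f"space: unknown value {self.space!r}")
        if not self.sample_ids:
            self.sample_ids = [f"S{i:03d}" for i in range(n)]
        if len(self.sample_ids) != n:
            raise ConfigurationError("sample_ids: length mismatch with X rows")
        for name in ("y_ssc", "y_k", "labels"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v)
                if v.shape != (n,):
                    raise ConfigurationError(f"{name}: length mismatch with X rows")
                setattr(self, name, v)

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_bands(self) -> int:
        return self.X.shape[1]

    def band_nearest(self, nm: float) -> int:
        """Index of the band whose wavelength is closest to ``nm``."""
        return int(np.argmin(np.abs(self.wavelengths - nm)))

    def target(self, name: str) -> np.ndarray:
        """Return the named target vector (``ssc`` or ``k``)."""
        vec = {"ssc": self.y_ssc, "k": self.y_k}.get(name)
        if vec is None:
            raise ConfigurationError(f"target: dataset has no '{name}' values")
        return vec

    # -- functional updates ----------------------------------------------
    def with_X(self, X: np.ndarray, *, space: str | None = None,
               note: str | None = None) -> "SpectraDataset":
        """New dataset with replaced spectra (shape preserved) and an
        appended provenance note."""
        prov = list(self.provenance)
        if note:
            prov.append(note)
        return replace(
            self,
            X=np.asarray(X, dtype=float),
            space=self.space if space is None else space,
            provenance=prov,
            sample_ids=list(self.sample_ids),
        )

    def take(self, rows: np.ndarray) -> "SpectraDataset":
        """Row subset (e.g. a calibration split), provenance untouched."""
        rows = np.asarray(rows, dtype=int)
        return replace(
            self,
            X=self.X[rows],
            sample_ids=[self.sample_ids[i] for i in rows],
            y_ssc=None if self.y_ssc is None else self.y_ssc[rows],
            y_k=None if self.y_k is None else self.y_k[rows],
            labels=None if self.labels is None else self.labels[rows],
            provenance=list(self.provenance),
        )

    # -- CSV dialect -----------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        cols = {
            "sample_id": self.sample_ids,
            "ssc": self.y_ssc if self.y_ssc is not None else np.full(self.n_samples, np.nan),
            "k": self.y_k if self.y_k is not None else np.full(self.n_samples, np.nan),
            "origin_class": self.labels if self.labels is not None else [""] * self.n_samples,
        }
        frame = pd.DataFrame(cols)
        spec = pd.DataFrame(self.X, columns=[f"{w:.2f}" for w in self.wavelengths])
        return pd.concat([frame, spec], axis=1)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, space: str = "reflectance") -> "SpectraDataset":
        frame = pd.read_csv(path)
        missing = [c for c in _META_COLUMNS if c not in frame.columns]
        if missing:
            raise ConfigurationError(f"CSV is missing columns: {missing}")
        wl_cols = [c for c in frame.columns if c not in _META_COLUMNS]
        wavelengths = np.array([float(c) for c in wl_cols])
        y_ssc = frame["ssc"].to_numpy(dtype=float)
        y_k = frame["k"].to_numpy(dtype=float)
        labels = frame["origin_class"].astype(str).to_numpy()
        return cls(
            X=frame[wl_cols].to_numpy(dtype=float),
            wavelengths=wavelengths,
            sample_ids=[str(s) for s in frame["sample_id"]],
            y_ssc=None if np.all(np.isnan(y_ssc)) else y_ssc,
            y_k=None if np.all(np.isnan(y_k)) else y_k,
            labels=None if np.all(labels == "") or np.all(labels == "nan") else labels,
            space=space,
        )
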