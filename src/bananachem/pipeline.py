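"""End-to-end experiments: quantitative calibration (SSC / K) and
geographic-origin discrimination, in the layout of the study's results
tables (pretreatment x selector x model, with calibration- and
prediction-set metrics).

A run is: pretreat -> SPXY split -> (optional wavelength selector, fitted
on the calibration rows only) -> model with cross-validated complexity ->
metrics on both sets. Every report embeds its provenance and seeds and is
exactly reproducible from its config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chemometrics import (
    EvaluationReport, evaluate_classification, evaluate_regression,
    fit_pls, fit_plsda, fit_rft, predict_pls, predict_plsda, predict_rft,
    spxy_split,
)
from .dataset import SpectraDataset
from .exceptions import ConfigurationError, DegenerateDataError
from .preprocess import apply_steps
from .synthetic import SyntheticConfig, generate_spectra_dataset
from .varselect import CarsConfig, FrogConfig, cars_select, frog_select, restrict_dataset

__all__ = ["ExperimentConfig", "run_quantitative", "run_discrimination", "make_report"]

_REGRESSION_TARGETS = ("ssc", "k")


@dataclass
class ExperimentConfig:
    """One experiment cell: input source, pretreatments, selector, model."""

    target: str = "ssc"                       # ssc | k | origin
    model: str = "pls"                        # pls | plsda | rft
    selector: str = "none"                    # none | cars | frog
    pretreatments: list = field(default_factory=lambda: ["to_absorbance"])
    synthetic: SyntheticConfig | None = None
    spectra_csv: str | None = None
    calibration_fraction: float = 2 / 3
    max_lv: int = 10
    cv_folds: int = 10
    cars: CarsConfig | None = None
    frog: FrogConfig | None = None
    n_trees: int = 500
    seed: int = 0
    output_dir: str | None = None

    def validate(self) -> None:
        if self.target in _REGRESSION_TARGETS:
            if self.model != "pls":
                raise ConfigurationError(
                    f"model: regression target '{self.target}' requires model 'pls'")
        elif self.target == "origin":
            if self.model not in ("plsda", "rft"):
                raise ConfigurationError(
                    "model: origin discrimination requires 'plsda' or 'rft'")
        else:
            raise ConfigurationError(f"target: unknown value {self.target!r}")
        if self.selector not in ("none", "cars", "frog"):
            raise ConfigurationError(f"selector: unknown value {self.selector!r}")
        if self.spectra_csv is not None and not Path(self.spectra_csv).exists():
            raise ConfigurationError(f"spectra_csv: file not found: {self.spectra_csv}")

    @classmethod
    def from_dict(cls, payload: dict) -> "ExperimentConfig":
        payload = dict(payload)
        if isinstance(payload.get("synthetic"), dict):
            syn = dict(payload["synthetic"])
            for key in ("ssc_range", "k_range", "class_band", "baseline_coeffs"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            payload["synthetic"] = SyntheticConfig(**syn)
        if isinstance(payload.get("cars"), dict):
            payload["cars"] = CarsConfig(**payload["cars"])
        if isinstance(payload.get("frog"), dict):
            payload["frog"] = FrogConfig(**payload["frog"])
        return cls(**payload)


def _pretreat_label(steps: list) -> str:
    parts = []
    for step in steps:
        name, kwargs = (step, {}) if isinstance(step, str) else next(iter(step.items()))
        kwargs = kwargs or {}
        if name == "to_absorbance":
            continue
        if name in ("sg_filter", "sg", "smooth", "1st", "2nd", "d1", "d2"):
            deriv = kwargs.get("deriv", {"1st": 1, "d1": 1, "2nd": 2, "d2": 2}.get(name, 0))
            parts.append({0: "SG", 1: "1st", 2: "2nd"}[deriv])
        elif name in ("center", "mean_center"):
            parts.append("Center")
        elif name in ("raw", "none"):
            continue
        else:
            parts.append(name.upper())
    return "-".join(parts) if parts else "Raw"


def _load(cfg: ExperimentConfig) -> SpectraDataset:
    if cfg.spectra_csv is not None:
        return SpectraDataset.from_csv(cfg.spectra_csv)
    syn = cfg.synthetic if cfg.synthetic is not None else SyntheticConfig(seed=cfg.seed)
    ds, _ = generate_spectra_dataset(syn)
    return ds


def _select(cfg: ExperimentConfig, X_cal: np.ndarray, y_cal, task: str):
    """Fit the configured selector on calibration rows only."""
    if cfg.selector == "cars":
        ccfg = cfg.cars if cfg.cars is not None else CarsConfig(seed=cfg.seed)
        trace = cars_select(X_cal, y_cal, ccfg, task=task)
        return trace.selected_indices, trace
    fcfg = cfg.frog if cfg.frog is not None else FrogConfig(seed=cfg.seed)
    trace = frog_select(X_cal, y_cal, fcfg, task=task)
    if trace.selected_indices.size == 0:
        # fall back to the most probable bands rather than an empty model
        k = max(2, fcfg.q_init)
        trace.selected_indices = np.sort(
            np.argsort(-trace.selection_probability, kind="stable")[:k])
    return trace.selected_indices, trace


def run_quantitative(cfg: ExperimentConfig) -> EvaluationReport:
    """Pretreat -> SPXY -> optional selector -> PLS with CV -> R2/RMSE on
    calibration and prediction sets."""
    cfg.validate()
    if cfg.target not in _REGRESSION_TARGETS:
        raise ConfigurationError("run_quantitative: target must be 'ssc' or 'k'")
    ds = apply_steps(_load(cfg), cfg.pretreatments)
    y = np.asarray(ds.target(cfg.target), dtype=float)
    split = spxy_split(ds.X, y, cfg.calibration_fraction)
    cal, pred = split.calibration_indices, split.prediction_indices
    X_cal, y_cal = ds.X[cal], y[cal]
    X_pred, y_pred = ds.X[pred], y[pred]

    selected: list = []
    if cfg.selector != "none":
        indices, _ = _select(cfg, X_cal, y_cal, "regression")
        selected = np.asarray(indices).tolist()
        X_cal, X_pred = X_cal[:, indices], X_pred[:, indices]

    model, rmsecv = fit_pls(X_cal, y_cal, cfg.max_lv, cfg.cv_folds)
    r2c, rmsec = evaluate_regression(y_cal, predict_pls(model, X_cal))
    r2p, rmsep = evaluate_regression(y_pred, predict_pls(model, X_pred))
    name = "-".join(filter(None, [
        _pretreat_label(cfg.pretreatments),
        cfg.selector.upper() if cfg.selector != "none" else "",
        "PLS"]))
    report = EvaluationReport(
        name=name, r2_cal=r2c, rmse_cal=rmsec, r2_pred=r2p, rmse_pred=rmsep,
        n_lv=model.n_lv,
        hyperparameters={"target": cfg.target, "selector": cfg.selector,
                         "max_lv": cfg.max_lv, "cv_folds": cfg.cv_folds,
                         "seed": cfg.seed,
                         "n_cal": int(cal.size), "n_pred": int(pred.size)},
        provenance=list(ds.provenance),
        selected_bands=selected,
    )
    _maybe_write(cfg, report)
    return report


def run_discrimination(cfg: ExperimentConfig) -> EvaluationReport:
    """Pretreat -> SPXY (integer-coded class distance) -> optional selector
    -> PLS-DA or random forest -> accuracies on both sets."""
    cfg.validate()
    if cfg.target != "origin":
        raise ConfigurationError("run_discrimination: target must be 'origin'")
    ds = apply_steps(_load(cfg), cfg.pretreatments)
    if ds.labels is None:
        raise ConfigurationError("run_discrimination: dataset has no class labels")
    labels = np.asarray(ds.labels)
    classes, y_int = np.unique(labels, return_inverse=True)
    split = spxy_split(ds.X, y_int.astype(float), cfg.calibration_fraction)
    cal, pred = split.calibration_indices, split.prediction_indices
    if np.unique(labels[cal]).size < 2:
        raise DegenerateDataError(
            "run_discrimination: calibration set is single-class after the split; "
            "check class balance / stratification of the input")
    X_cal, lab_cal = ds.X[cal], labels[cal]
    X_pred, lab_pred = ds.X[pred], labels[pred]

    selected: list = []
    if cfg.selector != "none":
        indices, _ = _select(cfg, X_cal, lab_cal, "classification")
        selected = np.asarray(indices).tolist()
        X_cal, X_pred = X_cal[:, indices], X_pred[:, indices]

    if cfg.model == "plsda":
        model, _ = fit_plsda(X_cal, lab_cal, cfg.max_lv, cfg.cv_folds)
        hat_cal, hat_pred = predict_plsda(model, X_cal), predict_plsda(model, X_pred)
        n_lv = model.n_lv
        extra = {}
    else:
        model = fit_rft(X_cal, lab_cal, cfg.n_trees, seed=cfg.seed)
        hat_cal, hat_pred = predict_rft(model, X_cal), predict_rft(model, X_pred)
        n_lv = None
        extra = {"n_trees": cfg.n_trees}
    name = "-".join(filter(None, [
        _pretreat_label(cfg.pretreatments),
        cfg.selector.upper() if cfg.selector != "none" else "",
        "PLS-DA" if cfg.model == "plsda" else "RFT"]))
    report = EvaluationReport(
        name=name,
        accuracy_cal=evaluate_classification(lab_cal, hat_cal),
        accuracy_pred=evaluate_classification(lab_pred, hat_pred),
        n_lv=n_lv,
        hyperparameters={"target": "origin", "selector": cfg.selector,
                         "model": cfg.model, "seed": cfg.seed,
                         "n_cal": int(cal.size), "n_pred": int(pred.size), **extra},
        provenance=list(ds.provenance),
        selected_bands=selected,
    )
    _maybe_write(cfg, report)
    return report


def _maybe_write(cfg: ExperimentConfig, report: EvaluationReport) -> None:
    if cfg.output_dir:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        safe = report.name.replace("/", "_")
        report.to_json(out / f"{safe}.json")


def make_report(reports: list[EvaluationReport]) -> dict[str, pd.DataFrame]:
    """Align reports into results tables.

    Regression and classification rows are separated into two tables keyed
    ``"regression"`` and ``"classification"`` (either may be absent).
    """
    if not reports:
        raise ConfigurationError("make_report: need at least one report")
    reg_rows, cls_rows = [], []
    for r in reports:
        if r.r2_cal is not None:
            reg_rows.append({"Method": r.name, "R2c": r.r2_cal, "RMSEC": r.rmse_cal,
                             "R2p": r.r2_pred, "RMSEP": r.rmse_pred, "LV": r.n_lv})
        else:
            cls_rows.append({"Method": r.name,
                             "Calibration accuracy (%)": r.accuracy_cal,
                             "Prediction accuracy (%)": r.accuracy_pred})
    out: dict[str, pd.DataFrame] = {}
    if reg_rows:
        out["regression"] = pd.DataFrame(reg_rows)
    if cls_rows:
        out["classification"] = pd.DataFrame(cls_rows)
    return out
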