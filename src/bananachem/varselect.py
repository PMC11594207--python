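"""Wavelength selection: CARS and random frog.

CARS (competitive adaptive reweighted sampling) runs N sampling rounds.
Each round fits a PLS model on a Monte-Carlo row subset of the current
variable pool, force-retains the top variables by |regression coefficient|
according to an exponentially decreasing schedule, resamples the retained
set with coefficient-proportional weights (adaptive reweighted sampling,
keeping the unique draws), and scores the surviving subset by k-fold
RMSECV. The subset with the smallest criterion across rounds is selected.

Random frog walks a Markov chain over variable subsets: each iteration
proposes a subset whose size is a normal perturbation of the current one
(grown from a random candidate pool or shrunk by dropping the weakest
coefficients), accepts improvements always and deteriorations with
probability eta * (score_old / score_new), and finally scores every band
by the fraction of iterations whose accepted subset contained it. Bands
with selection probability above a threshold (0.1 by default) are kept.

For classification tasks both selectors score subsets by 1 - CV accuracy
so "minimize RMSECV" generalizes; this is recorded in the trace.

Random frog runs internally in a canonical column order derived from the
data (columns sorted lexicographically by their values), so its random
index draws are tied to band content rather than band position: permuting
the columns of X permutes the selection probabilities identically.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import _pls
from .chemometrics import venetian_folds, _one_hot
from .dataset import SpectraDataset
from .exceptions import ConfigurationError, DegenerateDataError

__all__ = [
    "CarsConfig", "CarsTrace", "FrogConfig", "FrogTrace",
    "edf_keep_count", "cars_select", "frog_select", "restrict_dataset",
    "cars_select_repeated", "frog_select_averaged",
]


# ---------------------------------------------------------------------------
# Configs and traces

@dataclass
class CarsConfig:
    """CARS settings. The study used n_runs=100 (SSC) / 50 (K, origin) with
    10- / 15- / 8-fold cross-validation respectively."""

    n_runs: int = 50
    cv_folds: int = 10
    mc_sample_fraction: float = 0.8
    max_lv: int = 10
    seed: int = 0
    #: accepted for forward compatibility with "Monte Carlo simulations"
    #: phrasing; the run loop is governed by n_runs and this field is unused
    n_monte_carlo: int | None = None

    def validate(self) -> None:
        if self.n_runs < 2:
            raise ConfigurationError("n_runs: must be >= 2")
        if self.cv_folds < 2:
            raise ConfigurationError("cv_folds: must be >= 2")
        if not 0 < self.mc_sample_fraction <= 1:
            raise ConfigurationError("mc_sample_fraction: must be in (0, 1]")
        if self.max_lv < 1:
            raise ConfigurationError("max_lv: must be >= 1")


@dataclass
class CarsTrace:
    kept_count_per_run: np.ndarray
    rmsecv_per_run: np.ndarray
    subset_per_run: list
    best_run: int
    selected_indices: np.ndarray
    criterion: str = "rmsecv"
    truncated: bool = False

    def to_json(self, path: str | Path) -> None:
        payload = {
            "kept_count_per_run": self.kept_count_per_run.tolist(),
            "rmsecv_per_run": self.rmsecv_per_run.tolist(),
            "subset_per_run": [np.asarray(s).tolist() for s in self.subset_per_run],
            "best_run": int(self.best_run),
            "selected_indices": self.selected_indices.tolist(),
            "criterion": self.criterion,
            "truncated": self.truncated,
        }
        Path(path).write_text(json.dumps(payload))


@dataclass
class FrogConfig:
    """Random-frog settings. The study initialized with Q=3 variables and 10
    components for the quantitative task (5000 iterations) and Q=2 / 15
    components for discrimination (10000 iterations), threshold 0.1."""

    n_iterations: int = 5000
    q_init: int = 3
    n_lv: int = 10
    variance_factor: float = 0.3
    accept_factor: float = 0.1
    threshold: float = 0.1
    #: few, large venetian folds: small-fold CV under-penalizes oversized
    #: subsets in the walk's scoring and the chain drifts toward bloated sets
    cv_folds: int = 3
    seed: int = 0

    def validate(self, p: int) -> None:
        if not 1 <= self.q_init <= p:
            raise ConfigurationError(f"q_init: must be in 1..{p}")
        if not 0 < self.threshold <= 1:
            raise ConfigurationError("threshold: must be in (0, 1]")
        if not 0 < self.accept_factor <= 1:
            raise ConfigurationError("accept_factor: must be in (0, 1]")
        if self.variance_factor <= 0:
            raise ConfigurationError("variance_factor: must be > 0")
        if self.cv_folds < 2:
            raise ConfigurationError("cv_folds: must be >= 2")
        if self.n_iterations < 1:
            raise ConfigurationError("n_iterations: must be >= 1")


@dataclass
class FrogTrace:
    selection_probability: np.ndarray
    subset_size_per_iteration: np.ndarray
    selected_indices: np.ndarray
    threshold: float
    criterion: str = "rmsecv"
    warnings: list = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "selection_probability": self.selection_probability.tolist(),
            "subset_size_per_iteration": self.subset_size_per_iteration.tolist(),
            "selected_indices": self.selected_indices.tolist(),
            "threshold": self.threshold,
            "criterion": self.criterion,
            "warnings": self.warnings,
        }
        Path(path).write_text(json.dumps(payload))


# ---------------------------------------------------------------------------
# Shared internals

def _encode(y, task: str) -> np.ndarray:
    """Regression: the response as-is. Classification: one-hot columns."""
    if task == "regression":
        return np.asarray(y, dtype=float)[:, None]
    if task == "classification":
        _, Y = _one_hot(np.asarray(y))
        if Y.shape[1] < 2:
            raise DegenerateDataError("classification task needs >= 2 classes")
        return Y
    raise ConfigurationError(f"task: unknown value {task!r}")


def _coef_magnitude(X: np.ndarray, Y: np.ndarray, n_lv: int) -> np.ndarray:
    """|PLS regression coefficient| per band (L2 norm across responses)."""
    xm, ym = X.mean(axis=0), Y.mean(axis=0)
    lv = max(1, min(n_lv, X.shape[1], X.shape[0] - 1))
    W, P, Q, a = _pls.nipals(X - xm, Y - ym, lv)
    B = _pls.coefficients(W, P, Q, a)
    return np.linalg.norm(B, axis=1)


def _cv_score(X: np.ndarray, Y: np.ndarray, labels, task: str,
              cv_folds: int, n_lv: int) -> float:
    """RMSECV (regression) or 1 - CV accuracy (classification) on subset X."""
    n = X.shape[0]
    folds = venetian_folds(n, min(cv_folds, n))
    sq_err = 0.0
    hits = 0
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        Xt, Yt = X[train_idx], Y[train_idx]
        xm, ym = Xt.mean(axis=0), Yt.mean(axis=0)
        lv = max(1, min(n_lv, Xt.shape[1], Xt.shape[0] - 1))
        W, P, Q, a = _pls.nipals(Xt - xm, Yt - ym, lv)
        B = _pls.coefficients(W, P, Q, a)
        pred = (X[test_idx] - xm) @ B + ym
        if task == "regression":
            sq_err += np.sum((Y[test_idx, 0] - pred[:, 0]) ** 2)
        else:
            hits += np.sum(np.argmax(pred, axis=1) == np.argmax(Y[test_idx], axis=1))
    if task == "regression":
        return float(np.sqrt(sq_err / n))
    return float(1.0 - hits / n)


# ---------------------------------------------------------------------------
# CARS

def edf_keep_count(run_index: int, n_runs: int, p: int) -> int:
    """Forced-retention count at run i of N over p variables.

    The exponential decline r_i = a*exp(-k*i) is pinned by r_1 = 1 (keep all
    p variables at the first run) and a final keep count of 2 at run N:
    a = (p/2)**(1/(N-1)), k = ln(p/2)/(N-1). Returns round(r_i * p), floored
    at 2.
    """
    if n_runs < 2:
        raise ConfigurationError("n_runs: must be >= 2")
    if p < 2:
        raise ConfigurationError("p: must be >= 2")
    if not 1 <= run_index <= n_runs:
        raise ConfigurationError(f"run_index: must be in 1..{n_runs}")
    a = (p / 2.0) ** (1.0 / (n_runs - 1))
    k = math.log(p / 2.0) / (n_runs - 1)
    r = a * math.exp(-k * run_index)
    return max(2, int(round(r * p)))


def cars_select(X: np.ndarray, y: np.ndarray, cfg: CarsConfig,
                task: str = "regression") -> CarsTrace:
    """Run CARS on calibration data and return the full diagnostic trace.

    Fully reproducible from ``cfg.seed``. ``selected_indices`` is the
    subset whose criterion (RMSECV, or 1 - CV accuracy for classification)
    is minimal across runs.
    """
    cfg.validate()
    X = np.asarray(X, dtype=float)
    Y = _encode(y, task)
    n, p = X.shape
    if p < 2:
        raise ConfigurationError("cars_select: need at least 2 bands")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x0CA5]))
    n_mc = max(2, int(round(cfg.mc_sample_fraction * n)))

    pool = np.arange(p)
    kept_counts, scores, subsets = [], [], []
    truncated = False
    for i in range(1, cfg.n_runs + 1):
        rows = np.sort(rng.choice(n, size=n_mc, replace=False))
        mag = _coef_magnitude(X[np.ix_(rows, pool)], Y[rows], cfg.max_lv)
        keep = min(edf_keep_count(i, cfg.n_runs, p), pool.size)
        order = np.argsort(-mag, kind="stable")
        kept = pool[order[:keep]]
        w = mag[order[:keep]]
        # adaptive reweighted sampling: weighted draws with replacement,
        # retain the unique draws
        w_sum = w.sum()
        prob = w / w_sum if w_sum > 0 else np.full(keep, 1.0 / keep)
        draws = rng.choice(keep, size=keep, replace=True, p=prob)
        retained = np.unique(kept[draws])
        if retained.size < 2:
            retained = np.sort(kept[:2])
        score = _cv_score(X[:, retained], Y, y, task, cfg.cv_folds,
                          min(cfg.max_lv, retained.size))
        kept_counts.append(keep)
        scores.append(score)
        subsets.append(retained)
        pool = retained
        if pool.size < 2:
            truncated = True
            break
    best = int(np.argmin(scores))
    return CarsTrace(
        kept_count_per_run=np.asarray(kept_counts),
        rmsecv_per_run=np.asarray(scores),
        subset_per_run=subsets,
        best_run=best,
        selected_indices=np.asarray(subsets[best]),
        criterion="rmsecv" if task == "regression" else "1-accuracy",
        truncated=truncated,
    )


# ---------------------------------------------------------------------------
# Random frog

def frog_select(X: np.ndarray, y: np.ndarray, cfg: FrogConfig,
                task: str = "regression") -> FrogTrace:
    """Run random frog and return per-band selection probabilities.

    A band's importance is the fraction of iterations whose accepted subset
    contained it; bands with probability strictly above ``cfg.threshold``
    form ``selected_indices``.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    cfg.validate(p)
    Y = _encode(y, task)
    warnings = []
    if cfg.n_iterations < 100:
        warnings.append(f"n_iterations={cfg.n_iterations} < 100: probabilities are noisy")

    # canonical column order: ties the walker's index draws to band content,
    # making selection probabilities equivariant under column permutation
    canon = np.lexsort(X[::-1])
    Xc = X[:, canon]

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xF706]))
    current = np.sort(rng.choice(p, size=cfg.q_init, replace=False))
    score_cache: dict = {}

    def score_of(subset: np.ndarray) -> float:
        key = subset.tobytes()
        if key not in score_cache:
            score_cache[key] = _cv_score(
                Xc[:, subset], Y, y, task, cfg.cv_folds,
                min(cfg.n_lv, subset.size))
        return score_cache[key]

    counts = np.zeros(p)
    sizes = np.empty(cfg.n_iterations, dtype=int)
    for it in range(cfg.n_iterations):
        q_cur = current.size
        q_star = int(round(rng.normal(q_cur, cfg.variance_factor * q_cur)))
        q_star = max(1, min(p, q_star))
        if q_star < q_cur:
            mag = _coef_magnitude(Xc[:, current], Y, min(cfg.n_lv, q_cur))
            order = np.argsort(-mag, kind="stable")
            candidate = np.sort(current[order[:q_star]])
        elif q_star > q_cur:
            outside = np.setdiff1d(np.arange(p), current)
            n_extra = min(outside.size, 2 * (q_star - q_cur))
            extras = rng.choice(outside, size=n_extra, replace=False)
            superset = np.sort(np.concatenate([current, extras]))
            mag = _coef_magnitude(Xc[:, superset], Y, min(cfg.n_lv, superset.size))
            order = np.argsort(-mag, kind="stable")
            candidate = np.sort(superset[order[:q_star]])
        else:
            candidate = current
        if candidate is not current:
            s_cur = score_of(current)
            s_new = score_of(candidate)
            if s_new <= s_cur:
                current = candidate
            elif s_new > 0 and rng.random() < cfg.accept_factor * (s_cur / s_new):
                current = candidate
        counts[current] += 1
        sizes[it] = current.size

    prob_canon = counts / cfg.n_iterations
    probability = np.empty(p)
    probability[canon] = prob_canon
    selected = np.flatnonzero(probability > cfg.threshold)
    return FrogTrace(
        selection_probability=probability,
        subset_size_per_iteration=sizes,
        selected_indices=selected,
        threshold=cfg.threshold,
        criterion="rmsecv" if task == "regression" else "1-accuracy",
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# Repeat-stabilized selection

def cars_select_repeated(X: np.ndarray, y: np.ndarray, cfg: CarsConfig,
                         n_repeats: int = 5, task: str = "regression") -> CarsTrace:
    """Run CARS ``n_repeats`` times (seeds cfg.seed*100 + r) and return the
    trace whose best subset attains the globally smallest criterion.

    A single CARS chain is stochastic in its Monte-Carlo row draws and ARS
    resampling; repeated runs with the winner kept by RMSECV are the usual
    stabilization.
    """
    if n_repeats < 1:
        raise ConfigurationError("n_repeats: must be >= 1")
    best: CarsTrace | None = None
    for r in range(n_repeats):
        rcfg = CarsConfig(**{**asdict(cfg), "seed": cfg.seed * 100 + r})
        trace = cars_select(X, y, rcfg, task=task)
        if best is None or (trace.rmsecv_per_run[trace.best_run]
                            < best.rmsecv_per_run[best.best_run]):
            best = trace
    return best


def frog_select_averaged(X: np.ndarray, y: np.ndarray, cfg: FrogConfig,
                         n_repeats: int = 5, task: str = "regression") -> FrogTrace:
    """Average random-frog selection probabilities over ``n_repeats``
    independent chains (seeds cfg.seed*100 + r), then threshold.

    Mirrors the practice of running the frog repeatedly and pooling the
    per-band probabilities before applying the selection cutoff.
    """
    if n_repeats < 1:
        raise ConfigurationError("n_repeats: must be >= 1")
    prob = None
    sizes = []
    warnings: list = []
    for r in range(n_repeats):
        rcfg = FrogConfig(**{**asdict(cfg), "seed": cfg.seed * 100 + r})
        trace = frog_select(X, y, rcfg, task=task)
        prob = trace.selection_probability if prob is None else prob + trace.selection_probability
        sizes.append(trace.subset_size_per_iteration)
        warnings.extend(trace.warnings)
    prob = prob / n_repeats
    return FrogTrace(
        selection_probability=prob,
        subset_size_per_iteration=np.concatenate(sizes),
        selected_indices=np.flatnonzero(prob > cfg.threshold),
        threshold=cfg.threshold,
        criterion="rmsecv" if task == "regression" else "1-accuracy",
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# Applying a selection

def restrict_dataset(ds: SpectraDataset, indices, method: str = "manual"
                     ) -> SpectraDataset:
    """Column-subset a dataset to the selected bands (order-preserving).

    Provenance records the method, the count, and the retained fraction in
    percent (e.g. 69 of 225 bands -> 30.67%).
    """
    indices = np.asarray(indices, dtype=int)
    if indices.size == 0:
        raise ConfigurationError("restrict_dataset: empty index list")
    if np.unique(indices).size != indices.size:
        raise ConfigurationError("restrict_dataset: duplicate indices")
    if indices.min() < 0 or indices.max() >= ds.n_bands:
        raise ConfigurationError(
            f"restrict_dataset: index out of range 0..{ds.n_bands - 1}")
    indices = np.sort(indices)
    frac = 100.0 * indices.size / ds.n_bands
    note = f"select({method}: {indices.size}/{ds.n_bands} bands, {frac:.2f}% retained)"
    from dataclasses import replace
    return replace(ds, X=ds.X[:, indices], wavelengths=ds.wavelengths[indices],
                   provenance=list(ds.provenance) + [note],
                   sample_ids=list(ds.sample_ids))
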