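"""NIPALS partial least squares core.

Deflation-based NIPALS on centered data. For a single response the
per-component weight is closed-form; for multi-response (PLS2, used by
PLS-DA) the weight/score pair is iterated to convergence. Components are
nested, so one decomposition at ``max_lv`` yields the regression vector at
every smaller component count — the cross-validation loops rely on this.
"""

from __future__ import annotations

import numpy as np

from .exceptions import DegenerateDataError

_EPS = 1e-14


def nipals(Xc: np.ndarray, Yc: np.ndarray, n_components: int,
           max_iter: int = 500, tol: float = 1e-10):
    """Decompose centered Xc (n x p) against centered Yc (n x m).

    Returns ``(W, P, Q, a)`` — x-weights (p x a), x-loadings (p x a),
    y-loadings (a x m) and the achieved component count ``a`` (may be below
    ``n_components`` when X deflates to numerical zero).
    """
    X = np.array(Xc, dtype=float)
    Y = np.array(Yc, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    m = Y.shape[1]
    a_max = min(n_components, p, max(n - 1, 1))
    W = np.zeros((p, a_max))
    P = np.zeros((p, a_max))
    Q = np.zeros((a_max, m))
    achieved = 0
    x_scale = np.linalg.norm(Xc) + _EPS
    for a in range(a_max):
        if np.linalg.norm(X) < 1e-12 * x_scale or np.linalg.norm(Y) < _EPS:
            break
        if m == 1:
            w = X.T @ Y[:, 0]
            nw = np.linalg.norm(w)
            if nw < _EPS:
                break
            w /= nw
            t = X @ w
        else:
            # iterate u -> w -> t -> q -> u
            u = Y[:, int(np.argmax(Y.var(axis=0)))].copy()
            t = np.zeros(n)
            for it in range(max_iter):
                w = X.T @ u
                nw = np.linalg.norm(w)
                if nw < _EPS:
                    break
                w /= nw
                t_new = X @ w
                q = Y.T @ t_new / max(t_new @ t_new, _EPS)
                u = Y @ q / max(q @ q, _EPS)
                if np.linalg.norm(t_new - t) < tol * max(np.linalg.norm(t_new), 1.0):
                    t = t_new
                    break
                t = t_new
            else:
                raise DegenerateDataError(
                    f"NIPALS did not converge in {max_iter} iterations at tol {tol}")
            if np.linalg.norm(w) < _EPS:
                break
        tt = t @ t
        if tt < _EPS:
            break
        p_load = X.T @ t / tt
        q_load = Y.T @ t / tt
        X -= np.outer(t, p_load)
        Y -= np.outer(t, q_load)
        W[:, a] = w
        P[:, a] = p_load
        Q[a, :] = q_load
        achieved = a + 1
    if achieved == 0:
        raise DegenerateDataError("NIPALS extracted no components (degenerate input)")
    return W[:, :achieved], P[:, :achieved], Q[:achieved], achieved


def coefficients(W: np.ndarray, P: np.ndarray, Q: np.ndarray, k: int) -> np.ndarray:
    """Regression matrix B (p x m) using the first k components:
    B = W_k (P_k' W_k)^{-1} Q_k."""
    Wk, Pk, Qk = W[:, :k], P[:, :k], Q[:k]
    return Wk @ np.linalg.solve(Pk.T @ Wk, Qk)


def coefficient_path(W: np.ndarray, P: np.ndarray, Q: np.ndarray) -> list[np.ndarray]:
    """B at every nested component count 1..a."""
    return [coefficients(W, P, Q, k) for k in range(1, W.shape[1] + 1)]
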