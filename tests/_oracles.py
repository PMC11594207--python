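"""Independent loop-explicit oracles used by the test suite.

These deliberately share no code with the package: plain Python loops and
textbook formulas, kept slow and obvious.
"""

import numpy as np


def spxy_oracle(X, y, n_cal):
    """SPXY/Kennard-Stone selection with explicit loops."""
    n = len(X)
    dx = np.zeros((n, n))
    dy = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            dx[i, j] = np.sqrt(np.sum((X[i] - X[j]) ** 2))
            dy[i, j] = abs(y[i] - y[j])
    d = dx / dx.max() + dy / dy.max()
    best, pair = -1.0, None
    for i in range(n):
        for j in range(n):
            if d[i, j] > best:
                best, pair = d[i, j], (min(i, j), max(i, j))
    selected = list(pair)
    while len(selected) < n_cal:
        cand_best, cand = -1.0, None
        for i in range(n):
            if i in selected:
                continue
            mind = min(d[i, j] for j in selected)
            if mind > cand_best:
                cand_best, cand = mind, i
        selected.append(cand)
    return sorted(selected)


def nipals_oracle(X, y, n_comp):
    """Textbook PLS1 NIPALS with scalar loops; returns the regression
    vector on centered data."""
    X = np.array(X, dtype=float)
    y = np.array(y, dtype=float)
    X = X - X.mean(axis=0)
    y = y - y.mean()
    n, p = X.shape
    W = np.zeros((p, n_comp))
    P = np.zeros((p, n_comp))
    q = np.zeros(n_comp)
    for a in range(n_comp):
        w = np.zeros(p)
        for j in range(p):
            for i in range(n):
                w[j] += X[i, j] * y[i]
        w = w / np.sqrt(np.sum(w ** 2))
        t = np.zeros(n)
        for i in range(n):
            for j in range(p):
                t[i] += X[i, j] * w[j]
        tt = np.sum(t ** 2)
        pl = np.zeros(p)
        for j in range(p):
            for i in range(n):
                pl[j] += X[i, j] * t[i]
            pl[j] /= tt
        qa = np.sum(y * t) / tt
        for i in range(n):
            for j in range(p):
                X[i, j] -= t[i] * pl[j]
            y[i] -= qa * t[i]
        W[:, a], P[:, a], q[a] = w, pl, qa
    return W @ np.linalg.inv(P.T @ W) @ q
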