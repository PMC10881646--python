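"""Independent reference computations used only by the tests.

These deliberately avoid the package's own algorithms: the L1 solution is
found by exhaustive sign-pattern enumeration over KKT stationarity systems,
and the AUROC by O(n^2) pair counting.
"""

from __future__ import annotations

import itertools

import numpy as np


def lasso_bruteforce(X_std: np.ndarray, y_centered: np.ndarray,
                     lam: float) -> np.ndarray:
    """Exact minimizer of (1/(2n))||yc - Xs b||^2 + lam*||b||_1, p <= ~8.

    Enumerates all sign patterns s in {-1,0,+1}^p; for each, solves the
    stationarity system on the active set and keeps the candidate satisfying
    the full KKT conditions; returns the one with the lowest objective.
    """
    n, p = X_std.shape
    G = X_std.T @ X_std / n
    c = X_std.T @ y_centered / n

    def objective(b):
        r = y_centered - X_std @ b
        return r @ r / (2 * n) + lam * np.abs(b).sum()

    best, best_val = np.zeros(p), objective(np.zeros(p))
    for signs in itertools.product((-1, 0, 1), repeat=p):
        s = np.array(signs, dtype=float)
        active = s != 0
        b = np.zeros(p)
        if active.any():
            try:
                b[active] = np.linalg.solve(G[np.ix_(active, active)],
                                            c[active] - lam * s[active])
            except np.linalg.LinAlgError:
                continue
            if not (np.sign(b[active]) == s[active]).all():
                continue
        grad = c - G @ b
        if (~active).any() and (np.abs(grad[~active]) > lam + 1e-9).any():
            continue
        val = objective(b)
        if val < best_val - 1e-15:
            best, best_val = b, val
    return best


def auroc_paircount(scores, labels) -> float:
    """O(n^2) Mann-Whitney probability with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))
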