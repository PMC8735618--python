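"""Independent reference implementations used only to cross-check results.

Each oracle is deliberately written from the textbook definition, not by
calling the code under test: a plain multi-component NIPALS PLS1 regressor,
an ECDF-based two-sample KS statistic with the exact lattice-path p-value,
rank-statistic AUC, and exhaustive Youden search.
"""

from __future__ import annotations

from math import comb

import numpy as np


def pls1_predict(
    Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray, n_components: int
) -> np.ndarray:
    """Numeric predictions of an A-component NIPALS PLS1 regression.

    Standard algorithm: w_a ∝ X_a' y, t_a = X_a w_a, p_a = X_a' t_a / t_a't_a,
    c_a = y' t_a / t_a't_a, deflate X. Test scores are pushed through the
    same deflation chain.
    """
    Xa = Xtr.astype(float).copy()
    Za = np.atleast_2d(Xte).astype(float).copy()
    yhat = np.zeros(Za.shape[0])
    for _ in range(n_components):
        w = Xa.T @ ytr
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            break
        w /= norm
        t = Xa @ w
        tt = float(t @ t)
        if tt < 1e-12:
            break
        p = Xa.T @ t / tt
        c = float(ytr @ t) / tt
        t_new = Za @ w
        yhat += c * t_new
        Xa -= np.outer(t, p)
        Za -= np.outer(t_new, p)
    return yhat


def ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Max absolute ECDF distance, evaluated on the pooled support."""
    grid = np.unique(np.concatenate([a, b]))
    fa = np.searchsorted(np.sort(a), grid, side="right") / a.size
    fb = np.searchsorted(np.sort(b), grid, side="right") / b.size
    return float(np.max(np.abs(fa - fb)))


def ks_exact_pvalue(n: int, m: int, d: float) -> float:
    """Exact P(D >= d) for two samples without ties.

    Counts monotone lattice paths from (0,0) to (n,m) that stay strictly
    inside the band |i/n - j/m| < d; each path is one interleaving of the
    two samples, all equally likely under H0.
    """
    d_scaled = d * n * m - 1e-9  # compare i*m - j*n against d*n*m
    counts = np.zeros((n + 1, m + 1))
    counts[0, 0] = 1.0
    for i in range(n + 1):
        for j in range(m + 1):
            if i == 0 and j == 0:
                continue
            if abs(i * m - j * n) > d_scaled:
                counts[i, j] = 0.0
                continue
            c = 0.0
            if i > 0:
                c += counts[i - 1, j]
            if j > 0:
                c += counts[i, j - 1]
            counts[i, j] = c
    return 1.0 - counts[n, m] / comb(n + m, n)


def auc_mann_whitney(scores: np.ndarray, is_pos: np.ndarray) -> float:
    """AUC as the Mann-Whitney U statistic divided by n1*n0."""
    pos = scores[is_pos]
    neg = scores[~is_pos]
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (greater + 0.5 * ties) / (pos.size * neg.size)


def youden_brute_force(scores: np.ndarray, is_pos: np.ndarray):
    """Exhaustive search over every candidate threshold (rule: >= thr).

    Ties in J broken by accuracy, then by the smaller threshold. Returns
    (threshold, J, accuracy_pct).
    """
    candidates = np.concatenate([[np.inf], np.unique(scores)])
    n1 = int(is_pos.sum())
    n0 = is_pos.size - n1
    best = None
    for thr in candidates:
        pred = scores >= thr
        tpr = (pred & is_pos).sum() / n1
        fpr = (pred & ~is_pos).sum() / n0
        j = tpr - fpr
        acc = 100.0 * ((pred == is_pos).sum()) / is_pos.size
        key = (round(j, 15), round(acc, 12), -thr if np.isfinite(thr) else -np.inf)
        if best is None or key > best[0]:
            best = (key, thr, j, acc)
    return best[1], best[2], best[3]
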