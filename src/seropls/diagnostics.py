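"""Diagnostic statistics: ROC with DeLong CI, Youden threshold, and the
univariate tests used for the clinical table and key-metabolite comparisons.

The ROC operates on the OPLS-DA predictive score axis (or any per-subject
decision score): higher score means more likely positive. The Youden index
J = sensitivity + specificity - 1 picks the operating threshold; accuracy is
then recomputed on all data at that threshold (an in-sample figure by
construction).

Univariate machinery: Welch's unequal-variance t-test with Bonferroni
correction for the a-priori metabolite set, one-way ANOVA with Tukey HSD
pairwise comparisons for the three-group clinical table, Pearson's
chi-squared test for categorical variables, and ROUT outlier removal
(robust location fit with Lorentzian loss, FDR-controlled t-type test on
residuals) before post-hoc testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "RocCurve",
    "roc",
    "youden_threshold",
    "welch_t",
    "welch_bonferroni",
    "anova_tukey",
    "chi_squared",
    "rout_outliers",
    "table_one",
    "welch_report",
]

_Z975 = float(stats.norm.ppf(0.975))


# ---------------------------------------------------------------------------
# ROC / AUC / Youden


@dataclass
class RocCurve:
    """Empirical ROC over all distinct score thresholds.

    The decision rule at threshold ``thr`` is ``score >= thr -> positive``;
    ``thresholds`` are sorted descending and start at +inf, so the curve
    runs from (0, 0) to (1, 1). Ties in the scores are handled by grouping,
    which is equivalent to trapezoidal interpolation across the tie.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    ci_method: str
    scores: np.ndarray
    labels: np.ndarray          # boolean, True = positive


def _delong_ci(pos: np.ndarray, neg: np.ndarray, auc: float) -> tuple[float, float]:
    """DeLong variance of the AUC from placement values."""
    # placement of each positive among negatives and vice versa
    v10 = (
        (pos[:, None] > neg[None, :]).mean(axis=1)
        + 0.5 * (pos[:, None] == neg[None, :]).mean(axis=1)
    )
    v01 = (
        (pos[None, :] > neg[:, None]).mean(axis=1)
        + 0.5 * (pos[None, :] == neg[:, None]).mean(axis=1)
    )
    var = 0.0
    if pos.size > 1:
        var += v10.var(ddof=1) / pos.size
    if neg.size > 1:
        var += v01.var(ddof=1) / neg.size
    half = _Z975 * np.sqrt(var)
    return (max(0.0, auc - half), min(1.0, auc + half))


def _bootstrap_ci(
    pos: np.ndarray, neg: np.ndarray, n_boot: int, seed: int
) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        p = rng.choice(pos, pos.size, replace=True)
        n = rng.choice(neg, neg.size, replace=True)
        aucs[b] = (
            (p[:, None] > n[None, :]).mean()
            + 0.5 * (p[:, None] == n[None, :]).mean()
        )
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return (float(lo), float(hi))


def roc(
    scores,
    labels,
    positive=True,
    ci: str = "delong",
    n_boot: int = 2000,
    seed: int = 0,
) -> RocCurve:
    """Build the empirical ROC curve with AUC and its 95% CI.

    ``labels`` may be booleans or arbitrary labels with ``positive`` naming
    the positive class. ``ci`` is ``delong`` (default) or ``bootstrap``
    (stratified, seeded).
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    is_pos = np.asarray(labels) == positive
    n1, n0 = int(is_pos.sum()), int((~is_pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to build a ROC curve")

    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    pos_sorted = is_pos[order].astype(float)
    # group tied scores: cumulative counts at each distinct threshold
    distinct = np.flatnonzero(np.diff(s_sorted)) if s_sorted.size > 1 else np.array([], int)
    last = np.concatenate([distinct, [s_sorted.size - 1]])
    tp = np.cumsum(pos_sorted)[last]
    fp = np.cumsum(1.0 - pos_sorted)[last]
    thresholds = np.concatenate([[np.inf], s_sorted[last]])
    tpr = np.concatenate([[0.0], tp / n1])
    fpr = np.concatenate([[0.0], fp / n0])
    auc = float(np.trapezoid(tpr, fpr))

    pos_scores, neg_scores = scores[is_pos], scores[~is_pos]
    if ci == "delong":
        auc_ci = _delong_ci(pos_scores, neg_scores, auc)
    elif ci == "bootstrap":
        auc_ci = _bootstrap_ci(pos_scores, neg_scores, n_boot, seed)
    else:
        raise ValueError(f"unknown CI method {ci!r}")
    return RocCurve(
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        auc=auc,
        auc_ci=auc_ci,
        ci_method=ci,
        scores=scores,
        labels=is_pos,
    )


def youden_threshold(curve: RocCurve) -> tuple[float, float]:
    """Threshold maximizing J = TPR - FPR, and the accuracy (%) at it.

    Ties in J are broken by higher accuracy, then by the smaller threshold,
    so reports are deterministic. The +inf end point competes like any other
    threshold (it classifies everyone negative).
    """
    j = curve.tpr - curve.fpr
    n1 = int(curve.labels.sum())
    n0 = curve.labels.size - n1
    acc = 100.0 * (curve.tpr * n1 + (1.0 - curve.fpr) * n0) / (n1 + n0)
    best = np.flatnonzero(j >= j.max() - 1e-15)
    best = best[acc[best] >= acc[best].max() - 1e-12]
    pick = best[np.argmin(curve.thresholds[best])]
    return float(curve.thresholds[pick]), float(acc[pick])


# ---------------------------------------------------------------------------
# univariate tests


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variances t-test: (t, Satterthwaite df, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    sa, sb = va / a.size, vb / b.size
    diff = a.mean() - b.mean()
    if sa + sb == 0.0:
        # both groups constant: identical means are indistinguishable (p=1),
        # different means are trivially separated
        return (0.0, float(a.size + b.size - 2), 1.0) if diff == 0 else (
            np.inf * np.sign(diff),
            float(a.size + b.size - 2),
            0.0,
        )
    t = diff / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def welch_bonferroni(a, b, m: int = 1) -> dict:
    """Welch test with Bonferroni adjustment over ``m`` planned comparisons."""
    t, df, p = welch_t(a, b)
    return {
        "t": t,
        "df": df,
        "p": p,
        "p_adjusted": min(1.0, m * p),
        "m": m,
    }


def anova_tukey(groups: list[np.ndarray]):
    """One-way fixed-effects ANOVA plus Tukey HSD pairwise comparisons.

    Returns ``(F, p, pairwise)`` where ``pairwise`` maps group-index pairs
    (i, j) to the studentized-range p-value of the contrast.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    for g in groups:
        if g.size < 2:
            raise ValueError("each group needs at least 2 values")
    ns = np.array([g.size for g in groups])
    means = np.array([g.mean() for g in groups])
    n_total = int(ns.sum())
    grand = float(np.concatenate(groups).mean())
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(np.sum((g - g.mean()) ** 2) for g in groups))
    df_b, df_w = k - 1, n_total - k
    if ss_between == 0.0:
        f_stat, p = 0.0, 1.0
    elif ss_within == 0.0:
        f_stat, p = np.inf, 0.0
    else:
        f_stat = (ss_between / df_b) / (ss_within / df_w)
        p = float(stats.f.sf(f_stat, df_b, df_w))
    msw = ss_within / df_w if df_w > 0 else 0.0
    pairwise = {}
    for i in range(k):
        for j in range(i + 1, k):
            if msw == 0.0:
                pairwise[(i, j)] = 1.0 if means[i] == means[j] else 0.0
                continue
            se = np.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            q = abs(means[i] - means[j]) / se
            pairwise[(i, j)] = float(stats.studentized_range.sf(q, k, df_w))
    return float(f_stat), float(p), pairwise


def chi_squared(table) -> tuple[float, int, float]:
    """Pearson's chi-squared test of independence, no continuity correction."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    rows, cols = obs.sum(axis=1), obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("degenerate table: zero row or column margin")
    expected = np.outer(rows, cols) / obs.sum()
    chi2 = float(np.sum((obs - expected) ** 2 / expected))
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return chi2, df, p


# ---------------------------------------------------------------------------
# ROUT outliers


def _robust_location(x: np.ndarray, n_iter: int = 50) -> tuple[float, float]:
    """Location fit minimizing Lorentzian loss, with RSDR scale.

    RSDR is the 68.27th percentile of absolute residuals times N/(N-K)
    (K = 1 parameter), the robust analogue of the residual standard
    deviation. Location and scale are refined alternately.
    """
    m = float(np.median(x))
    n = x.size
    correction = n / (n - 1)
    rsdr = float(np.percentile(np.abs(x - m), 68.27)) * correction
    if rsdr == 0.0:
        return m, 0.0
    lo, hi = float(x.min()), float(x.max())
    for _ in range(n_iter):
        s2 = rsdr**2
        res = optimize.minimize_scalar(
            lambda mu: float(np.sum(np.log1p((x - mu) ** 2 / s2))),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-10},
        )
        m_new = float(res.x)
        rsdr_new = float(np.percentile(np.abs(x - m_new), 68.27)) * correction
        if abs(m_new - m) < 1e-12 and abs(rsdr_new - rsdr) < 1e-12:
            m, rsdr = m_new, rsdr_new
            break
        m, rsdr = m_new, max(rsdr_new, 1e-300)
    return m, rsdr


def rout_outliers(values, q: float = 0.1, ids=None) -> list:
    """ROUT outlier detection specialized to a single variable.

    Fits a robust constant (location) model with Lorentzian loss, then tests
    residuals largest-first with a t-type statistic |r|/RSDR at
    FDR-controlled (Benjamini-Hochberg step-down) levels: the i-th largest
    residual (i = 1, 2, ...) is tested at alpha_i = (Q/100) * i / N and
    testing stops at the first non-significant point. ``q`` is the FDR rate
    in percent (default 0.1%). Returns the ids (or indices) of flagged
    values.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 5:
        raise ValueError(f"ROUT needs at least 5 values, got {x.size}")
    if not 0.0 < q <= 10.0:
        raise ValueError("Q must lie in (0, 10] percent")
    if ids is None:
        ids = list(range(x.size))
    center, rsdr = _robust_location(x)
    if rsdr == 0.0:
        flagged = np.flatnonzero(x != center)
        return [ids[i] for i in flagged]
    resid = np.abs(x - center)
    order = np.argsort(-resid, kind="stable")
    n = x.size
    df = n - 1
    flagged = []
    for rank, idx in enumerate(order, start=1):
        alpha = (q / 100.0) * rank / n
        p = 2.0 * stats.t.sf(resid[idx] / rsdr, df)
        if p < alpha:
            flagged.append(ids[idx])
        else:
            break
    return flagged


# ---------------------------------------------------------------------------
# report builders


def _median_iqr(x: np.ndarray) -> str:
    x = x[np.isfinite(x)]
    if x.size == 0:
        return "-"
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.2f} ({q1:.2f}-{q3:.2f})"


def table_one(
    cohort: pd.DataFrame,
    continuous: list[str],
    categorical: list[str],
    group_col: str = "group",
) -> pd.DataFrame:
    """Three-group clinical summary: median (IQR) + ANOVA/Tukey for
    continuous variables, counts (%) + chi-squared for categorical ones."""
    group_labels = sorted(cohort[group_col].unique().tolist())
    rows = []
    for var in continuous:
        groups = [
            cohort.loc[cohort[group_col] == g, var].dropna().to_numpy()
            for g in group_labels
        ]
        _, p, _ = anova_tukey(groups)
        row = {"variable": var, "test": "anova", "p": p}
        for g, vals in zip(group_labels, groups):
            row[g] = _median_iqr(vals)
        rows.append(row)
    for var in categorical:
        counts = np.array(
            [
                [
                    int((cohort.loc[cohort[group_col] == g, var]).sum()),
                    int((~cohort.loc[cohort[group_col] == g, var].astype(bool)).sum()),
                ]
                for g in group_labels
            ]
        )
        _, _, p = chi_squared(counts)
        row = {"variable": var, "test": "chi_squared", "p": p}
        for g, (yes, no) in zip(group_labels, counts):
            row[g] = f"{yes} ({100.0 * yes / (yes + no):.1f}%)"
        rows.append(row)
    return pd.DataFrame(rows)


def welch_report(
    features: pd.DataFrame,
    labels,
    variables: list[str],
    positive="recent",
    rout_q: float | None = 0.1,
) -> pd.DataFrame:
    """Two-group key-variable comparison: ROUT outlier removal, Welch's t,
    Bonferroni over the tested set (m = number of variables)."""
    is_pos = np.asarray(labels) == positive
    m = len(variables)
    rows = []
    for var in variables:
        x = features[var].to_numpy(dtype=float)
        keep = np.isfinite(x)
        if rout_q is not None:
            flagged = set(rout_outliers(x[keep], q=rout_q, ids=np.flatnonzero(keep).tolist()))
            keep &= ~np.isin(np.arange(x.size), list(flagged))
        res = welch_bonferroni(x[keep & is_pos], x[keep & ~is_pos], m=m)
        rows.append(
            {
                "variable": var,
                "median_iqr_positive": _median_iqr(x[keep & is_pos]),
                "median_iqr_rest": _median_iqr(x[keep & ~is_pos]),
                "t": res["t"],
                "df": res["df"],
                "p": res["p"],
                "p_adjusted": res["p_adjusted"],
                "n_outliers_removed": int(np.isfinite(x).sum() - keep.sum()),
            }
        )
    return pd.DataFrame(rows)
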