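"""ROC/Youden, univariate tests and ROUT against independent references."""

import numpy as np
import pytest
from scipy import stats

from _oracles import auc_mann_whitney, youden_brute_force
from seropls import (
    anova_tukey,
    chi_squared,
    roc,
    rout_outliers,
    welch_bonferroni,
    welch_t,
    youden_threshold,
)


def random_scores(seed, n_max=40):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(8, n_max))
    scores = np.round(rng.standard_normal(n), 1)  # rounding forces ties
    labels = rng.random(n) < 0.5
    if labels.all() or not labels.any():
        labels[:2] = [True, False]
    return scores, labels


# --- ROC -------------------------------------------------------------------


def test_perfect_separation():
    scores = np.array([1.0, 2.0, 3.0, 11.0, 12.0, 13.0])
    labels = np.array([False] * 3 + [True] * 3)
    curve = roc(scores, labels)
    assert curve.auc == 1.0
    thr, acc = youden_threshold(curve)
    assert 3.0 < thr <= 11.0
    assert acc == 100.0


def test_uninformative_scores():
    curve = roc(np.ones(10), np.array([True, False] * 5))
    assert curve.auc == 0.5


def test_curve_endpoints_and_monotonicity():
    scores, labels = random_scores(0)
    curve = roc(scores, labels)
    assert curve.tpr[0] == curve.fpr[0] == 0.0
    assert curve.tpr[-1] == curve.fpr[-1] == 1.0
    assert np.all(np.diff(curve.tpr) >= 0)
    assert np.all(np.diff(curve.fpr) >= 0)


def test_auc_equals_mann_whitney_statistic():
    for seed in range(50):
        scores, labels = random_scores(seed)
        curve = roc(scores, labels)
        assert abs(curve.auc - auc_mann_whitney(scores, labels)) < 1e-12


def test_auc_antisymmetry_and_monotone_invariance():
    for seed in range(10):
        scores, labels = random_scores(seed)
        auc = roc(scores, labels).auc
        assert roc(-scores, labels).auc + auc == pytest.approx(1.0, abs=1e-12)
        transformed = np.exp(3.0 * scores)  # strictly monotone
        curve_t = roc(transformed, labels)
        assert curve_t.auc == pytest.approx(auc, abs=1e-12)
        np.testing.assert_allclose(curve_t.tpr, roc(scores, labels).tpr)


def test_single_class_rejected():
    with pytest.raises(ValueError, match="both classes"):
        roc(np.arange(4.0), np.array([True] * 4))


def test_delong_ci_brackets_auc_and_tightens():
    rng = np.random.default_rng(3)
    small = roc(rng.standard_normal(30) + np.repeat([0, 1.0], 15), np.repeat([False, True], 15))
    big = roc(rng.standard_normal(600) + np.repeat([0, 1.0], 300), np.repeat([False, True], 300))
    for c in (small, big):
        assert c.auc_ci[0] <= c.auc <= c.auc_ci[1]
    assert (big.auc_ci[1] - big.auc_ci[0]) < (small.auc_ci[1] - small.auc_ci[0])


def test_bootstrap_ci_is_seeded():
    scores, labels = random_scores(5)
    c1 = roc(scores, labels, ci="bootstrap", n_boot=200, seed=1)
    c2 = roc(scores, labels, ci="bootstrap", n_boot=200, seed=1)
    assert c1.auc_ci == c2.auc_ci


def test_youden_matches_exhaustive_search():
    for seed in range(100):
        scores, labels = random_scores(seed)
        thr, acc = youden_threshold(roc(scores, labels))
        thr_ref, _, acc_ref = youden_brute_force(scores, labels)
        assert thr == thr_ref
        assert acc == pytest.approx(acc_ref, abs=1e-9)


def test_youden_symmetric_gaussians_midpoint():
    rng = np.random.default_rng(11)
    n = 20000
    scores = np.concatenate([rng.normal(-1, 1, n), rng.normal(1, 1, n)])
    labels = np.repeat([False, True], n)
    thr, _ = youden_threshold(roc(scores, labels))
    assert abs(thr) < 0.12


# --- Welch / ANOVA / chi-squared ------------------------------------------


def test_welch_identical_groups():
    x = np.arange(10.0)
    t, _, p = welch_t(x, x)
    assert t == 0.0 and p == 1.0
    res = welch_bonferroni(x, x, m=5)
    assert res["p_adjusted"] == 1.0


def test_welch_matches_closed_form():
    rng = np.random.default_rng(2)
    for _ in range(50):
        a = rng.standard_normal(int(rng.integers(3, 30))) * 2 + 1
        b = rng.standard_normal(int(rng.integers(3, 30)))
        t, df, p = welch_t(a, b)
        sa, sb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        t_ref = (a.mean() - b.mean()) / np.sqrt(sa + sb)
        df_ref = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
        assert abs(t - t_ref) < 1e-10
        assert abs(df - df_ref) < 1e-10
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert abs(t - ref.statistic) < 1e-10
        assert abs(p - ref.pvalue) < 1e-10


def test_welch_degenerate_variance_convention():
    t, _, p = welch_t([2.0, 2.0], [2.0, 2.0])
    assert (t, p) == (0.0, 1.0)
    t, _, p = welch_t([3.0, 3.0], [2.0, 2.0])
    assert np.isinf(t) and p == 0.0


def test_bonferroni_monotone_and_capped():
    rng = np.random.default_rng(0)
    ps = np.sort(rng.random(20))
    adj = [min(1.0, 7 * p) for p in ps]
    for p, a in zip(ps, adj):
        assert a >= p
    assert adj == sorted(adj)
    assert welch_bonferroni(np.arange(5.0), np.arange(5.0) + 0.01, m=1000)["p_adjusted"] == 1.0


def test_anova_identical_groups():
    x = np.arange(6.0)
    f, p, pair = anova_tukey([x, x, x])
    assert f == 0.0 and p == 1.0
    assert all(v == 1.0 for v in pair.values())


def test_anova_matches_reference():
    rng = np.random.default_rng(4)
    for _ in range(50):
        groups = [
            rng.standard_normal(int(rng.integers(3, 25))) + rng.normal()
            for _ in range(int(rng.integers(2, 5)))
        ]
        f, p, _ = anova_tukey(groups)
        ref = stats.f_oneway(*groups)
        assert abs(f - ref.statistic) < 1e-8
        assert abs(p - ref.pvalue) < 1e-8


def test_tukey_matches_reference_and_dominates_t():
    """Tukey p agrees with the reference implementation and is never smaller
    than the unadjusted t-test p for the same contrast computed with the
    same pooled within-group variance (the studentized range with k groups
    stochastically dominates the k=2 case)."""
    rng = np.random.default_rng(5)
    for _ in range(20):
        groups = [rng.standard_normal(int(rng.integers(4, 20))) + rng.normal() for _ in range(3)]
        _, _, pair = anova_tukey(groups)
        ref = stats.tukey_hsd(*groups)
        ns = [len(g) for g in groups]
        df_w = sum(ns) - len(groups)
        msw = sum(((len(g) - 1) * np.var(g, ddof=1) for g in groups)) / df_w
        for (i, j), p in pair.items():
            assert abs(p - ref.pvalue[i, j]) < 1e-8
            se = np.sqrt(msw * (1 / ns[i] + 1 / ns[j]))
            t_stat = abs(np.mean(groups[i]) - np.mean(groups[j])) / se
            t_p = 2 * stats.t.sf(t_stat, df_w)
            assert p >= t_p - 1e-12


def test_chi_squared_independence_and_hand_value():
    outer = np.outer([10, 20], [3, 7]) / 1.0
    chi2, df, p = chi_squared(outer)
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)
    chi2, df, p = chi_squared([[10, 20], [20, 10]])
    assert df == 1
    assert chi2 == pytest.approx(20 / 3, abs=1e-10)  # 4 cells of (5^2)/15
    ref = stats.chi2_contingency([[10, 20], [20, 10]], correction=False)
    assert chi2 == pytest.approx(ref.statistic, abs=1e-10)
    assert p == pytest.approx(ref.pvalue, abs=1e-10)


def test_chi_squared_degenerate_margin_rejected():
    with pytest.raises(ValueError, match="margin"):
        chi_squared([[0, 0], [5, 3]])


# --- ROUT ------------------------------------------------------------------


def test_rout_clean_data_rarely_flags():
    non_empty = 0
    for seed in range(200):
        x = np.random.default_rng(seed).standard_normal(100)
        non_empty += len(rout_outliers(x, q=0.1)) > 0
    assert non_empty <= 4  # ~0.1% expected rate


def test_rout_flags_gross_outlier():
    x = np.random.default_rng(0).standard_normal(50)
    x[7] = 100.0
    assert rout_outliers(x, q=0.1) == [7]
    # custom ids pass through
    ids = [f"s{i}" for i in range(50)]
    assert rout_outliers(x, q=0.1, ids=ids) == ["s7"]


def test_rout_input_validation():
    with pytest.raises(ValueError, match="at least 5"):
        rout_outliers([1.0, 2.0, 3.0])
    with pytest.raises(ValueError, match="Q must"):
        rout_outliers(np.arange(10.0), q=50.0)
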