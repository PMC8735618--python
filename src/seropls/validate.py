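"""Repeated external cross-validation of OPLS-DA against a permutation null.

The evidence for a real class signal is built in four steps:

1. per repetition, subsample the majority class down to the minority size
   (*matched classes*), so a constant classifier scores 50% and accuracy is
   directly interpretable;
2. split the matched set into stratified folds and, for each fold, fit
   OPLS-DA on the remaining folds — column centers and scales are estimated
   on the training folds only and applied to the held-out fold, so no
   information leaks into the test data;
3. repeat the whole procedure with labels permuted uniformly at random to
   build the null accuracy distribution;
4. compare real and null per-repetition mean accuracies with a two-sided
   two-sample Kolmogorov-Smirnov test.

Every subsample, fold assignment and permutation is a deterministic
function of (data, config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .opls import OplsModel, fit_opls, predict_scores, vip
from .preprocess import FeatureMatrix, fit_scaler

__all__ = [
    "ValidationConfig",
    "ValidationResult",
    "NullDistribution",
    "external_cv",
    "permutation_null",
    "compare_to_null",
    "ensemble_vip",
    "stratified_folds",
]

_Z975 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class ValidationConfig:
    """Knobs of the repeated external cross-validation.

    Defaults mirror the standard design: 10 stratified folds, 100
    repetitions, matched class sizes, one orthogonal component, unit-variance
    scaling estimated inside each training split.
    """

    n_folds: int = 10
    n_repetitions: int = 100
    matched_classes: bool = True
    k_ortho: int = 1
    scaling: str = "unit_variance"
    compute_q2: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")


@dataclass
class ValidationResult:
    """Aggregated output of one repeated external cross-validation run."""

    rep_accuracy: np.ndarray        # per-repetition mean held-out accuracy, %
    fold_accuracy: np.ndarray       # repetitions x folds, %
    rep_sensitivity: np.ndarray     # %
    rep_specificity: np.ndarray     # %
    vip_mean: np.ndarray            # ensemble mean VIP per feature
    vip_sd: np.ndarray
    feature_names: list[str]
    model_metrics: dict             # mean/sd of R2X, R2Y, Q2 across models, %
    config: ValidationConfig

    @property
    def accuracy_mean(self) -> float:
        return float(self.rep_accuracy.mean())

    @property
    def accuracy_ci(self) -> tuple[float, float]:
        """Normal-approximation 95% CI of the mean accuracy across repetitions."""
        m = self.accuracy_mean
        if self.rep_accuracy.size < 2:
            return (m, m)
        half = _Z975 * self.rep_accuracy.std(ddof=1) / np.sqrt(self.rep_accuracy.size)
        return (m - half, m + half)

    def vip_table(self) -> list[tuple[str, float, float]]:
        """(feature, mean VIP, sd) sorted by descending mean."""
        order = np.argsort(-self.vip_mean, kind="stable")
        return [
            (self.feature_names[i], float(self.vip_mean[i]), float(self.vip_sd[i]))
            for i in order
        ]

    def to_dict(self) -> dict:
        lo, hi = self.accuracy_ci
        return {
            "mean_accuracy_pct": self.accuracy_mean,
            "accuracy_ci95_pct": [lo, hi],
            "mean_sensitivity_pct": float(self.rep_sensitivity.mean()),
            "mean_specificity_pct": float(self.rep_specificity.mean()),
            "rep_accuracy_pct": self.rep_accuracy.tolist(),
            "model_metrics_pct": self.model_metrics,
            "vip": [
                {"feature": f, "mean_vip": m, "sd_vip": s}
                for f, m, s in self.vip_table()
            ],
            "config": {
                "n_folds": self.config.n_folds,
                "n_repetitions": self.config.n_repetitions,
                "matched_classes": self.config.matched_classes,
                "k_ortho": self.config.k_ortho,
                "scaling": self.config.scaling,
                "seed": self.config.seed,
            },
        }


@dataclass
class NullDistribution:
    """Per-repetition mean accuracies under label permutation."""

    rep_accuracy: np.ndarray        # %
    config: ValidationConfig

    def to_dict(self) -> dict:
        return {
            "mean_accuracy_pct": float(self.rep_accuracy.mean()),
            "rep_accuracy_pct": self.rep_accuracy.tolist(),
        }


def stratified_folds(
    y: np.ndarray, n_folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Fold id per subject: within-class seeded shuffle, then round-robin deal.

    Dealing each class from fold 0 keeps per-fold class counts as equal as
    possible, so under matched classes every fold is class-balanced.
    """
    fold_of = np.empty(y.size, dtype=int)
    for label in np.unique(y):
        idx = np.flatnonzero(y == label)
        if idx.size < n_folds:
            raise ValueError(
                f"class {label!r} has {idx.size} members, fewer than "
                f"{n_folds} folds"
            )
        idx = rng.permutation(idx)
        fold_of[idx] = np.arange(idx.size) % n_folds
    return fold_of


def _matched_subsample(
    y: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Indices keeping all of the minority class and a random equal-size
    draw of the majority class."""
    labels, counts = np.unique(y, return_counts=True)
    n_min = counts.min()
    keep = []
    for label in labels:
        idx = np.flatnonzero(y == label)
        if idx.size > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        keep.append(idx)
    return np.sort(np.concatenate(keep))


def _as_matrix(X) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(X, FeatureMatrix):
        return X.values, list(X.feature_names)
    X = np.asarray(X, dtype=float)
    return X, None


def _run_cv(
    X, y, cfg: ValidationConfig, positive, permute: bool, stream: int
):
    """Shared engine behind external_cv and permutation_null."""
    cfg.validate()
    values, feature_names = _as_matrix(X)
    y = np.asarray(y)
    if np.unique(y).size != 2:
        raise ValueError("external cross-validation needs exactly 2 classes")
    if positive is None:
        labels = sorted(np.unique(y).tolist())
        positive = "recent" if "recent" in labels else labels[1]

    R, F = cfg.n_repetitions, cfg.n_folds
    fold_acc = np.full((R, F), np.nan)
    fold_sens = np.full((R, F), np.nan)
    fold_spec = np.full((R, F), np.nan)
    vips: list[np.ndarray] = []
    r2x, r2y, q2 = [], [], []

    for rep in range(R):
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, rep, stream])
        )
        yy = rng.permutation(y) if permute else y
        idx = (
            _matched_subsample(yy, rng)
            if cfg.matched_classes
            else np.arange(yy.size)
        )
        y_sub = yy[idx]
        fold_of = stratified_folds(y_sub, F, rng)
        for f in range(F):
            train = idx[fold_of != f]
            test = idx[fold_of == f]
            centers, scales = fit_scaler(values[train], cfg.scaling)
            model = fit_opls(
                (values[train] - centers) / scales,
                yy[train],
                cfg.k_ortho,
                positive=positive,
                feature_names=feature_names,
                centers=centers,
                scales=scales,
                compute_q2=cfg.compute_q2,
            )
            _, pred = predict_scores(model, values[test])
            truth = yy[test]
            is_pos = truth == positive
            correct = pred == truth
            fold_acc[rep, f] = 100.0 * correct.mean()
            if is_pos.any():
                fold_sens[rep, f] = 100.0 * correct[is_pos].mean()
            if (~is_pos).any():
                fold_spec[rep, f] = 100.0 * correct[~is_pos].mean()
            vips.append(vip(model))
            r2x.append(model.r2x)
            r2y.append(model.r2y)
            q2.append(model.q2)

    vip_arr = np.array(vips)
    metrics = {
        "R2X": _mean_sd_pct(r2x),
        "R2Y": _mean_sd_pct(r2y),
        "Q2": _mean_sd_pct(q2),
    }
    result = ValidationResult(
        rep_accuracy=fold_acc.mean(axis=1),
        fold_accuracy=fold_acc,
        rep_sensitivity=np.nanmean(fold_sens, axis=1),
        rep_specificity=np.nanmean(fold_spec, axis=1),
        vip_mean=vip_arr.mean(axis=0),
        vip_sd=vip_arr.std(axis=0, ddof=1) if vip_arr.shape[0] > 1 else np.zeros(vip_arr.shape[1]),
        feature_names=(
            feature_names
            if feature_names is not None
            else [f"x{j}" for j in range(values.shape[1])]
        ),
        model_metrics=metrics,
        config=cfg,
    )
    return result


def _mean_sd_pct(values) -> dict:
    arr = 100.0 * np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        return {"mean": float("nan"), "sd": float("nan")}
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return {"mean": float(arr.mean()), "sd": sd}


def external_cv(X, y, cfg: ValidationConfig | None = None, positive=None) -> ValidationResult:
    """Class-matched, stratified, repeated external cross-validation."""
    return _run_cv(X, y, cfg or ValidationConfig(), positive, permute=False, stream=0)


def permutation_null(X, y, cfg: ValidationConfig | None = None, positive=None) -> NullDistribution:
    """The same procedure with labels permuted once per repetition."""
    result = _run_cv(X, y, cfg or ValidationConfig(), positive, permute=True, stream=1)
    return NullDistribution(rep_accuracy=result.rep_accuracy, config=result.config)


def compare_to_null(real, null) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test on per-repetition mean
    accuracies; exact small-sample p when both samples have n <= 25."""
    a = np.asarray(real.rep_accuracy if hasattr(real, "rep_accuracy") else real, dtype=float)
    b = np.asarray(null.rep_accuracy if hasattr(null, "rep_accuracy") else null, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both accuracy distributions must be non-empty")
    method = "exact" if (a.size <= 25 and b.size <= 25) else "asymp"
    res = stats.ks_2samp(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def ensemble_vip(models: list[OplsModel]):
    """Mean and sd of per-feature VIP over fold models, sorted descending.

    Returns a list of ``(feature, mean, sd)`` tuples.
    """
    if not models:
        raise ValueError("need at least one fitted model")
    names = models[0].feature_names
    for m in models[1:]:
        if m.feature_names != names:
            raise ValueError("models were fitted on different feature sets")
    vips = np.array([vip(m) for m in models])
    mean = vips.mean(axis=0)
    sd = vips.std(axis=0, ddof=1) if len(models) > 1 else np.zeros(mean.size)
    if names is None:
        names = [f"x{j}" for j in range(mean.size)]
    order = np.argsort(-mean, kind="stable")
    return [(names[i], float(mean[i]), float(sd[i])) for i in order]
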