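"""Orthogonal projections to latent structures discriminant analysis (OPLS-DA).

A from-scratch NIPALS implementation for binary classification: a single
predictive component plus ``k_ortho`` orthogonal components that capture
X-variation uncorrelated with the class contrast. Removing the orthogonal
variation first concentrates the between-class difference on one score axis,
which is what makes the scores plot and its ROC threshold interpretable.

The predictive weight ``w`` is the (normalized) covariance direction
``X'y``; each orthogonal component is extracted from the current loading
``p`` by removing its projection on ``w``, then deflating X. Predictions of
a (1 predictive + k orthogonal)-component OPLS model are mathematically
identical to those of a plain (k+1)-component PLS model on the same data;
the value of OPLS is the rotated, interpretable score space, not extra
predictive power.

Model metrics follow the usual definitions: R2X (fraction of X
sum-of-squares captured, per component), R2Y (fraction of y sum-of-squares
explained in training) and Q2 (1 - PRESS/TSS under internal venetian-blind
cross-validation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["OplsModel", "fit_opls", "predict_scores", "vip", "select_k_ortho"]

# NIPALS iteration guards; with a single y the weight converges in one pass,
# the loop is kept for a multi-response extension.
NIPALS_TOL = 1e-12
NIPALS_MAX_ITER = 500

# stop extracting orthogonal components once the deflated X carries less
# than this fraction of the original sum of squares
_RESIDUAL_SS_FLOOR = 1e-10

# below this, X'y is treated as numerically zero (no class signal in X)
_DEGENERATE_NORM = 1e-12


@dataclass
class OplsModel:
    """Fitted OPLS-DA model (1 predictive + ``k_ortho`` orthogonal components)."""

    w: np.ndarray                 # predictive weights, unit norm
    p_load: np.ndarray            # predictive loadings
    t: np.ndarray                 # predictive training scores
    c: float                      # y-loading
    W_o: np.ndarray               # orthogonal weights, (n_features, k_ortho)
    P_o: np.ndarray               # orthogonal loadings
    T_o: np.ndarray               # orthogonal training scores
    encoding: dict                # class label -> -1.0 / +1.0
    feature_names: list[str] | None = None
    centers: np.ndarray | None = None   # training scaler, applied in predict
    scales: np.ndarray | None = None
    r2x_pred: float = 0.0
    r2x_ortho: tuple[float, ...] = ()
    r2y: float = 0.0
    q2: float = float("nan")
    degenerate: bool = False      # X carried no covariance with y

    @property
    def k_ortho(self) -> int:
        return self.W_o.shape[1]

    @property
    def r2x(self) -> float:
        """Total fraction of X sum-of-squares captured by all components."""
        return self.r2x_pred + float(sum(self.r2x_ortho))

    @property
    def classes(self) -> tuple:
        neg = next(k for k, v in self.encoding.items() if v < 0)
        pos = next(k for k, v in self.encoding.items() if v > 0)
        return (neg, pos)

    # -- plain-text serialization so validation runs can be resumed --------

    def save(self, path: str | Path) -> None:
        lines = []

        def put(key, arr):
            flat = np.asarray(arr, dtype=float).ravel()
            shape = "x".join(str(s) for s in np.asarray(arr).shape)
            body = " ".join("%.17g" % v for v in flat)
            lines.append(f"{key} [{shape}] {body}")

        neg, pos = self.classes
        lines.append(f"classes {neg} {pos}")
        lines.append(f"degenerate {int(self.degenerate)}")
        if self.feature_names is not None:
            lines.append("features " + " ".join(self.feature_names))
        put("w", self.w)
        put("p_load", self.p_load)
        put("t", self.t)
        put("c", [self.c])
        put("W_o", self.W_o)
        put("P_o", self.P_o)
        put("T_o", self.T_o)
        if self.centers is not None:
            put("centers", self.centers)
            put("scales", self.scales)
        put("r2x_pred", [self.r2x_pred])
        put("r2x_ortho", list(self.r2x_ortho))
        put("r2y", [self.r2y])
        put("q2", [self.q2])
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "OplsModel":
        arrays: dict[str, np.ndarray] = {}
        classes: tuple[str, str] | None = None
        features: list[str] | None = None
        degenerate = False
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            key, rest = line.split(" ", 1)
            if key == "classes":
                neg, pos = rest.split()
                classes = (neg, pos)
            elif key == "features":
                features = rest.split()
            elif key == "degenerate":
                degenerate = bool(int(rest))
            else:
                shape_s, _, body = rest.partition("] ")
                shape = tuple(
                    int(s) for s in shape_s.lstrip("[").split("x") if s
                )
                data = (
                    np.array([float(v) for v in body.split()])
                    if body.strip()
                    else np.empty(0)
                )
                arrays[key] = data.reshape(shape)
        if classes is None:
            raise ValueError(f"{path}: missing class encoding")
        return cls(
            w=arrays["w"],
            p_load=arrays["p_load"],
            t=arrays["t"],
            c=float(arrays["c"][0]),
            W_o=arrays["W_o"],
            P_o=arrays["P_o"],
            T_o=arrays["T_o"],
            encoding={classes[0]: -1.0, classes[1]: 1.0},
            feature_names=features,
            centers=arrays.get("centers"),
            scales=arrays.get("scales"),
            r2x_pred=float(arrays["r2x_pred"][0]),
            r2x_ortho=tuple(arrays["r2x_ortho"].tolist()),
            r2y=float(arrays["r2y"][0]),
            q2=float(arrays["q2"][0]),
            degenerate=degenerate,
        )


def encode_labels(y, positive=None) -> tuple[np.ndarray, dict]:
    """Map two class labels onto -1/+1.

    The positive class defaults to ``'recent'`` when present, otherwise the
    last label in sorted order. Encoded y is used uncentered: with the
    symmetric ±1 codes the class midpoint sits at 0, which keeps the score
    axis threshold of the downstream ROC/Youden step meaningful even for
    unbalanced training sets.
    """
    y = np.asarray(y)
    labels = sorted(np.unique(y).tolist())
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 classes, got {labels}")
    if positive is None:
        positive = "recent" if "recent" in labels else labels[1]
    if positive not in labels:
        raise ValueError(f"positive class {positive!r} not among labels {labels}")
    negative = labels[0] if labels[1] == positive else labels[1]
    encoding = {negative: -1.0, positive: 1.0}
    return np.array([encoding[v] for v in y.tolist()]), encoding


def _pls1_weight(X: np.ndarray, yv: np.ndarray) -> np.ndarray:
    """NIPALS weight vector for the current X block.

    With a single response the score of the y block is y itself, so the
    weight update w ∝ X'u converges on the first pass; the loop with its
    tolerance is the general NIPALS scheme and only matters for a
    multi-response extension.
    """
    u = yv  # y-block score; fixed at y for a single response
    w = np.zeros(X.shape[1])
    for _ in range(NIPALS_MAX_ITER):
        w_new = X.T @ u
        norm = np.linalg.norm(w_new)
        if norm < _DEGENERATE_NORM:
            return np.zeros_like(w_new)
        w_new /= norm
        if np.linalg.norm(w_new - w) < NIPALS_TOL:
            return w_new
        w = w_new
    return w


def fit_opls(
    X: np.ndarray,
    y,
    k_ortho: int = 1,
    *,
    positive=None,
    feature_names: list[str] | None = None,
    centers: np.ndarray | None = None,
    scales: np.ndarray | None = None,
    compute_q2: bool = True,
) -> OplsModel:
    """Fit OPLS-DA on a centered/scaled matrix ``X`` and two-class labels.

    ``centers``/``scales`` are optional bookkeeping: the statistics that were
    used to scale ``X``, stored so :func:`predict_scores` can scale new raw
    data identically. Fitting itself is deterministic and randomness-free.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if k_ortho < 0:
        raise ValueError("k_ortho must be >= 0")
    yv, encoding = encode_labels(y, positive)
    if yv.size != n:
        raise ValueError("X and y lengths differ")

    ssx_total = float(np.sum(X**2))
    w = _pls1_weight(X, yv)
    degenerate = not w.any()
    if not degenerate and k_ortho + 1 > np.linalg.matrix_rank(X):
        raise ValueError(
            f"k_ortho={k_ortho} needs rank >= {k_ortho + 1}, X has rank "
            f"{np.linalg.matrix_rank(X)}"
        )

    Xd = X.copy()
    W_o, P_o, T_o, r2x_o = [], [], [], []
    if not degenerate:
        for _ in range(k_ortho):
            if np.sum(Xd**2) < _RESIDUAL_SS_FLOOR * max(ssx_total, 1.0):
                break
            t = Xd @ w
            p_load = Xd.T @ t / (t @ t)
            w_o = p_load - (w @ p_load) * w
            norm_o = np.linalg.norm(w_o)
            if norm_o < _DEGENERATE_NORM:
                break
            w_o = w_o / norm_o
            t_o = Xd @ w_o
            p_o = Xd.T @ t_o / (t_o @ t_o)
            Xd = Xd - np.outer(t_o, p_o)
            W_o.append(w_o)
            P_o.append(p_o)
            T_o.append(t_o)
            r2x_o.append(float(t_o @ t_o * (p_o @ p_o)) / ssx_total)

    if degenerate:
        t = np.zeros(n)
        p_load = np.zeros(p)
        c = 0.0
        r2x_pred = 0.0
        r2y = 0.0
    else:
        t = Xd @ w
        tt = float(t @ t)
        p_load = Xd.T @ t / tt
        c = float(yv @ t) / tt
        r2x_pred = tt * float(p_load @ p_load) / ssx_total
        r2y = 1.0 - float(np.sum((yv - c * t) ** 2)) / float(np.sum(yv**2))

    model = OplsModel(
        w=w,
        p_load=p_load,
        t=t,
        c=c,
        W_o=np.array(W_o).T if W_o else np.zeros((p, 0)),
        P_o=np.array(P_o).T if P_o else np.zeros((p, 0)),
        T_o=np.array(T_o).T if T_o else np.zeros((n, 0)),
        encoding=encoding,
        feature_names=list(feature_names) if feature_names is not None else None,
        centers=None if centers is None else np.asarray(centers, dtype=float),
        scales=None if scales is None else np.asarray(scales, dtype=float),
        r2x_pred=r2x_pred,
        r2x_ortho=tuple(r2x_o),
        r2y=r2y,
        degenerate=degenerate,
    )
    if compute_q2 and not degenerate:
        model.q2 = _internal_q2(X, yv, k_ortho)
    return model


def _internal_q2(X: np.ndarray, yv: np.ndarray, k_ortho: int, n_folds: int = 7) -> float:
    """Q2 by venetian-blind cross-validation inside the training set."""
    n = X.shape[0]
    n_folds = min(n_folds, n)
    if n_folds < 2:
        return float("nan")
    press = 0.0
    for f in range(n_folds):
        test = np.arange(n) % n_folds == f
        if test.all() or not test.any():
            continue
        yhat = _fit_predict_raw(X[~test], yv[~test], X[test], k_ortho)
        press += float(np.sum((yv[test] - yhat) ** 2))
    tss = float(np.sum(yv**2))
    return 1.0 - press / tss


def _fit_predict_raw(
    Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray, k_ortho: int
) -> np.ndarray:
    """Minimal fit + numeric prediction used by the internal CV loop."""
    w = _pls1_weight(Xtr, ytr)
    if not w.any():
        return np.zeros(Xte.shape[0])
    Xd, Zd = Xtr.copy(), Xte.copy()
    for _ in range(k_ortho):
        t = Xd @ w
        p_load = Xd.T @ t / (t @ t)
        w_o = p_load - (w @ p_load) * w
        norm_o = np.linalg.norm(w_o)
        if norm_o < _DEGENERATE_NORM:
            break
        w_o /= norm_o
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd = Xd - np.outer(t_o, p_o)
        Zd = Zd - np.outer(Zd @ w_o, p_o)
    t = Xd @ w
    tt = float(t @ t)
    if tt < _DEGENERATE_NORM:
        return np.zeros(Xte.shape[0])
    c = float(ytr @ t) / tt
    return c * (Zd @ w)


def predict_scores(model: OplsModel, X_new: np.ndarray):
    """Project new subjects onto the predictive score axis and classify.

    Returns ``(t_new, labels)``. If the model stores training
    centers/scales they are applied first, so ``X_new`` may be raw;
    otherwise it must already be scaled like the training matrix.
    Orthogonal variation is stripped component by component before
    projecting onto the predictive weights; the class is the sign of the
    predicted response mapped through the class encoding (0 maps to the
    positive class).
    """
    Z = np.atleast_2d(np.asarray(X_new, dtype=float))
    if Z.shape[1] != model.w.size:
        raise ValueError(
            f"X_new has {Z.shape[1]} features, model expects {model.w.size}"
        )
    if model.centers is not None:
        Z = (Z - model.centers) / model.scales
    for j in range(model.k_ortho):
        Z = Z - np.outer(Z @ model.W_o[:, j], model.P_o[:, j])
    t_new = Z @ model.w
    yhat = model.c * t_new
    neg, pos = model.classes
    labels = np.where(yhat >= 0, pos, neg)
    return t_new, labels


def vip(model: OplsModel) -> np.ndarray:
    """Variable importance in projection over the predictive component(s).

    VIP_j = sqrt( p * sum_a SSY_a w_aj^2 / sum_a SSY_a ); with one
    predictive component this reduces to sqrt(p) * |w_j|, and the squared
    scores average to exactly 1 across features.
    """
    p = model.w.size
    return np.sqrt(p * model.w**2)


def select_k_ortho(X: np.ndarray, y, cap: int = 5, *, positive=None) -> int:
    """Pick the orthogonal-component count maximizing internal Q2 (first max)."""
    yv, _ = encode_labels(y, positive)
    max_k = min(cap, int(np.linalg.matrix_rank(np.asarray(X, dtype=float))) - 1)
    best_k, best_q2 = 0, -np.inf
    for k in range(max(max_k, 0) + 1):
        q2 = _internal_q2(np.asarray(X, dtype=float), yv, k)
        if np.isfinite(q2) and q2 > best_q2 + 1e-12:
            best_k, best_q2 = k, q2
    return best_k
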