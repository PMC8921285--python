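"""Two-class PLS-DA core: NIPALS fit, prediction, VIP scores.

PLS1 regression of a +/-1-coded class variable on the autoscaled
feature matrix.  The continuous prediction ("canonical score") is the
axis along which samples separate; its sign gives the class call, with
an exact zero resolved to the negative (BPH) class.  Variable
importance is available both as the regression coefficient vector b
and as VIP scores.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .preprocess import ScalingParams, autoscale_apply

__all__ = ["PLSModel", "Prediction", "fit_pls", "predict", "vip_scores"]

#: class coding used throughout: negative class (BPH) -> -1, positive (PCa) -> +1
NEG, POS = -1.0, 1.0


@dataclasses.dataclass
class PLSModel:
    x_weights: np.ndarray  # p x A  (W, unit columns)
    x_loadings: np.ndarray  # p x A  (P)
    y_loadings: np.ndarray  # A      (q)
    coefficients: np.ndarray  # p     (b, on the autoscaled scale)
    n_lv: int
    y_mean: float
    ssy: np.ndarray  # A, y-variance captured per latent variable (q_a^2 t_a't_a)
    scaling: ScalingParams | None = None  # optional raw-scale entry point
    fitted: np.ndarray | None = None  # training continuous predictions


@dataclasses.dataclass
class Prediction:
    score: np.ndarray  # continuous canonical value per sample
    label: np.ndarray  # hard class in {-1, +1}


def fit_pls(X: np.ndarray, y: np.ndarray, n_lv: int, scaling: ScalingParams | None = None) -> PLSModel:
    """Fit PLS1 by sequential NIPALS extraction.

    ``X`` must already be autoscaled; ``y`` is the +/-1 class code.
    Per component: w = X'y normalized, t = Xw, p = X't/t't,
    q = y't/t't, then X is deflated by t p'.  The regression vector is
    b = W (P'W)^{-1} q, so b reproduces the training predictions
    exactly.
    """
    X = np.asarray(X, dtype=float).copy()
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"X has {X.shape[0]} rows but y has {y.shape[0]}")
    if len(np.unique(y)) < 2:
        raise ValueError("y contains a single class; PLS-DA needs both")
    # cheap upper bound first; true rank deficiency surfaces as a
    # degenerate (zero-norm) component during extraction
    if not 1 <= n_lv <= min(X.shape):
        raise ValueError(f"n_lv must lie in [1, {min(X.shape)}], got {n_lv}")
    y_mean = float(y.mean())
    yc = y - y_mean
    n, p = X.shape
    W = np.empty((p, n_lv))
    P = np.empty((p, n_lv))
    q = np.empty(n_lv)
    ssy = np.empty(n_lv)
    Xd = X
    tol = 1e-10 * max(1.0, float(np.linalg.norm(X)) * float(np.linalg.norm(yc)))
    for a in range(n_lv):
        w = Xd.T @ yc
        norm = np.linalg.norm(w)
        if norm <= tol:
            raise ValueError(f"degenerate component {a + 1}: X'y vanished (rank exceeded?)")
        w /= norm
        t = Xd @ w
        tt = float(t @ t)
        if tt <= tol**2:
            raise ValueError(f"degenerate component {a + 1}: zero score vector")
        pa = Xd.T @ t / tt
        qa = float(yc @ t) / tt
        Xd = Xd - np.outer(t, pa)
        W[:, a], P[:, a], q[a] = w, pa, qa
        ssy[a] = qa**2 * tt
    b = W @ np.linalg.solve(P.T @ W, q)
    fitted = X @ b + y_mean
    return PLSModel(
        x_weights=W,
        x_loadings=P,
        y_loadings=q,
        coefficients=b,
        n_lv=n_lv,
        y_mean=y_mean,
        ssy=ssy,
        scaling=scaling,
        fitted=fitted,
    )


def predict(model: PLSModel, X_new: np.ndarray, apply_scaling: bool | None = None) -> Prediction:
    """Continuous canonical score and hard class for new rows.

    If the model carries autoscaling parameters and ``apply_scaling``
    is not explicitly disabled, raw-scale rows are autoscaled first.
    A score of exactly zero is assigned to the negative class.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if apply_scaling is None:
        apply_scaling = model.scaling is not None
    if apply_scaling:
        if model.scaling is None:
            raise ValueError("model carries no scaling parameters")
        X_new = autoscale_apply(X_new, model.scaling)
    if X_new.shape[1] != model.coefficients.shape[0]:
        raise ValueError(
            f"feature count mismatch: model has {model.coefficients.shape[0]}, "
            f"input has {X_new.shape[1]}"
        )
    score = X_new @ model.coefficients + model.y_mean
    label = np.where(score > 0, POS, NEG)
    return Prediction(score=score, label=label)


def vip_scores(model: PLSModel, X: np.ndarray | None = None, y: np.ndarray | None = None) -> np.ndarray:
    """Variable importance in projection.

    VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a )
    with SSY_a the y-variance captured by component a.  The mean
    squared VIP over variables is 1 for any fitted model.  The
    per-component SSY stored at fit time is used; passing the training
    ``X, y`` recomputes it (identical up to round-off).
    """
    W = model.x_weights
    p = W.shape[0]
    ssy = model.ssy
    if X is not None and y is not None:
        X = np.asarray(X, dtype=float).copy()
        yc = np.asarray(y, dtype=float) - model.y_mean
        ssy = np.empty(model.n_lv)
        for a in range(model.n_lv):
            t = X @ W[:, a]
            tt = float(t @ t)
            ssy[a] = (float(yc @ t) / tt) ** 2 * tt
            X -= np.outer(t, model.x_loadings[:, a])
    total = ssy.sum()
    if total <= 0:
        raise ValueError("zero explained y-variance; VIP undefined")
    wnorm2 = (W / np.linalg.norm(W, axis=0)) ** 2
    return np.sqrt(p * (wnorm2 @ ssy) / total)
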