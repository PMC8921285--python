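"""PCA exploration with Hotelling's T2 and Q-residual diagnostics.

Used as an unsupervised quality check on the autoscaled sample matrix:
scores reveal class trends or sequence effects, T2 flags samples with
extreme within-model leverage, Q flags samples poorly described by the
model, and contribution vectors attribute either statistic to
individual features.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["PCAResult", "fit_pca", "contributions", "score_order_correlation"]


@dataclasses.dataclass
class PCAResult:
    scores: np.ndarray  # samples x components
    loadings: np.ndarray  # features x components, orthonormal columns
    explained_variance: np.ndarray  # per component, non-increasing
    t2: np.ndarray  # per-sample Hotelling statistic
    q: np.ndarray  # per-sample squared residual norm

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def fit_pca(X: np.ndarray, n_components: int) -> PCAResult:
    """SVD-based PCA of an autoscaled (already centered) matrix.

    ``explained_variance`` is the squared singular value over (n-1);
    T2_i sums squared scores over their component variances; Q_i is the
    squared norm of the off-model residual.  The sign of each component
    is fixed by forcing its largest-magnitude loading positive.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(
            f"n_components must lie in [1, {min(n - 1, p)}], got {n_components}"
        )
    if n_components > rank:
        raise ValueError(f"n_components ({n_components}) exceeds rank ({rank})")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    U, s, Vt = U[:, :n_components], s[:n_components], Vt[:n_components]
    # deterministic sign: largest |loading| positive per component
    flip = np.sign(Vt[np.arange(n_components), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    scores = U * s
    loadings = Vt.T
    ev = s**2 / (n - 1)
    t2 = np.sum(scores**2 / ev, axis=1)
    resid = X - scores @ loadings.T
    q = np.sum(resid**2, axis=1)
    return PCAResult(scores=scores, loadings=loadings, explained_variance=ev, t2=t2, q=q)


def contributions(result: PCAResult, X: np.ndarray, sample_index: int) -> dict[str, np.ndarray]:
    """Per-feature decomposition of one sample's T2 and Q.

    The T2 contribution of feature j is the part of the score-space
    Mahalanobis distance routed through that feature,
    ``sum_a (t_ia / lambda_a) * x_ij * p_ja``; contributions sum to the
    sample's T2.  Q contributions are the squared residual entries and
    sum to Q.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 0 <= sample_index < n:
        raise IndexError(f"sample_index {sample_index} out of range [0, {n})")
    x = X[sample_index]
    # project rather than reuse stored scores: identical for training
    # rows (scores = X V) and valid for held-out rows as well
    t = x @ result.loadings
    weights = t / result.explained_variance  # per component
    t2_contrib = x * (result.loadings @ weights)
    resid = x - result.loadings @ t
    return {"t2": t2_contrib, "q": resid**2}


def score_order_correlation(result: PCAResult, injection_order: np.ndarray) -> np.ndarray:
    """Pearson correlation of each component's scores with injection order.

    A diagnostic for residual sequence effects after drift correction;
    no acceptance rule is attached, the values are only reported.
    """
    order = np.asarray(injection_order, dtype=float)
    out = np.empty(result.n_components)
    for a in range(result.n_components):
        out[a] = np.corrcoef(result.scores[:, a], order)[0, 1]
    return out
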