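"""Rank-product variable selection with VIP cross-check.

Every sub-model harvested during r-dCV ranks the variables by the
absolute value of its PLS regression coefficient (rank 1 = most
contributing).  A variable's overall contribution is summarized by its
rank product — the geometric mean of its ranks across sub-models — and
variables whose rank product falls strictly below the geometric mean
of all rank products are flagged as putative biomarkers.  The flagged
set is then intersected with the variables whose mean VIP exceeds the
conventional threshold of 1; only the matching ones are retained.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.stats import rankdata

from .rdcv import RDCVResult

__all__ = [
    "SelectionResult",
    "rank_coefficients",
    "rank_product",
    "select_by_rp",
    "vip_crosscheck",
    "select_variables",
]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class SelectionResult:
    rank_matrix: np.ndarray  # sub-models x variables (average ranks on ties)
    rank_products: np.ndarray  # per variable
    rp_threshold: float  # geometric mean of all rank products
    vip_mean: np.ndarray  # per variable
    selected: np.ndarray  # indices surviving both filters
    selected_rp_only: np.ndarray
    selected_vip_only: np.ndarray

    @property
    def n_submodels(self) -> int:
        return self.rank_matrix.shape[0]


def rank_coefficients(coefficient_vectors: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Rank variables by descending |b| within each sub-model.

    Rank 1 goes to the largest absolute coefficient; tied values share
    the average of the tied rank positions.
    """
    B = np.atleast_2d(np.asarray(coefficient_vectors, dtype=float))
    if B.size == 0:
        raise ValueError("no coefficient vectors given")
    return rankdata(-np.abs(B), axis=1, method="average")


def rank_product(rank_matrix: np.ndarray) -> np.ndarray:
    """Geometric mean of each variable's ranks over sub-models.

    Computed as exp(mean(log rank)) so that hundreds of sub-models do
    not overflow the product.
    """
    R = np.atleast_2d(np.asarray(rank_matrix, dtype=float))
    if (R <= 0).any():
        raise ValueError("ranks must be positive")
    return np.exp(np.log(R).mean(axis=0))


def select_by_rp(rp: np.ndarray) -> tuple[np.ndarray, float]:
    """Variables with rank product strictly below the geometric mean
    of all rank products; returns (indices, threshold)."""
    rp = np.asarray(rp, dtype=float)
    if rp.size == 0:
        raise ValueError("empty rank-product vector")
    if (rp <= 0).any():
        raise ValueError("rank products must be positive")
    log_rp = np.log(rp)
    log_thr = log_rp.mean()
    # strict inequality, guarded against round-off so an all-equal
    # vector selects nothing
    eps = 1e-9 * max(1.0, abs(log_thr))
    return np.flatnonzero(log_rp < log_thr - eps), float(np.exp(log_thr))


def vip_crosscheck(
    selected_rp_only: np.ndarray, vip_mean: np.ndarray, vip_threshold: float = 1.0
) -> np.ndarray:
    """Intersect the rank-product selection with the VIP-relevant set."""
    vip_ok = np.flatnonzero(np.asarray(vip_mean, dtype=float) > vip_threshold)
    final = np.intersect1d(np.asarray(selected_rp_only, dtype=int), vip_ok)
    if final.size == 0 and len(selected_rp_only):
        log.warning("rank-product and VIP selections are disjoint; empty final set")
    return final


def select_variables(
    result: RDCVResult | None = None,
    coefficient_vectors: np.ndarray | None = None,
    vip_vectors: np.ndarray | None = None,
    vip_threshold: float = 1.0,
) -> SelectionResult:
    """Full two-stage selection from harvested r-dCV sub-models.

    Either pass an :class:`RDCVResult` (its harvested coefficient and
    VIP vectors are used) or the two matrices directly.
    """
    if result is not None:
        coefficient_vectors = result.harvested_coefficients
        vip_vectors = result.harvested_vips
    if coefficient_vectors is None or vip_vectors is None:
        raise ValueError("need an RDCVResult or explicit coefficient and VIP matrices")
    R = rank_coefficients(coefficient_vectors)
    rp = rank_product(R)
    rp_sel, threshold = select_by_rp(rp)
    vip_mean = np.atleast_2d(np.asarray(vip_vectors, dtype=float)).mean(axis=0)
    final = vip_crosscheck(rp_sel, vip_mean, vip_threshold)
    return SelectionResult(
        rank_matrix=R,
        rank_products=rp,
        rp_threshold=threshold,
        vip_mean=vip_mean,
        selected=final,
        selected_rp_only=rp_sel,
        selected_vip_only=np.flatnonzero(vip_mean > vip_threshold),
    )


def selection_report(
    sel: SelectionResult,
    feature_ids: list[str],
    mean_coefficients: np.ndarray | None = None,
):
    """Tabular selection report: id, RP, mean VIP, expression direction,
    selected flag.  ``mean_coefficients`` (e.g. the mean harvested b)
    supplies the over/under-expression sign for the positive class."""
    import pandas as pd

    direction = None
    if mean_coefficients is not None:
        direction = np.where(np.asarray(mean_coefficients) >= 0, "over_PCa", "under_PCa")
    df = pd.DataFrame(
        {
            "feature_id": feature_ids,
            "rank_product": sel.rank_products,
            "vip_mean": sel.vip_mean,
            "selected": np.isin(np.arange(len(feature_ids)), sel.selected),
        }
    )
    if direction is not None:
        df.insert(3, "direction", direction)
    return df
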