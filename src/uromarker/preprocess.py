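"""Feature filtering, QC-based drift correction, normalization, scaling.

The chain applied to a raw feature table is fixed:

1. drop conditioning QC injections,
2. blank / carry-over filter (features whose mean blank area exceeds
   10 % of the mean QC area are discarded, blank rows removed),
3. QC-anchored drift correction (per feature, the OLS trend of QC area
   on injection order is subtracted from every row),
4. QC presence / stability filter (features absent from any monitoring
   QC or with QC RSD above 25 % are discarded),
5. creatinine normalization of sample rows,
6. autoscaling — performed inside the modelling loops, never here, so
   that validation rows can be scaled with calibration statistics only.

Re-running steps 2-4 on their own output removes nothing further, and
the drift correction is idempotent up to numerical tolerance.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .table import FeatureTable, ROLE_BLANK, ROLE_QC, ROLE_SAMPLE

__all__ = [
    "PreprocessConfig",
    "ScalingParams",
    "filter_blank_and_carryover",
    "qc_drift_correct",
    "filter_qc_presence_rsd",
    "creatinine_normalize",
    "autoscale_fit",
    "autoscale_apply",
    "block_scale_concat",
    "preprocess_chain",
]


class PreprocessError(ValueError):
    pass


@dataclasses.dataclass
class PreprocessConfig:
    carryover_threshold: float = 0.10
    qc_rsd_threshold: float = 0.25
    drift_mode: str = "additive"  # or "multiplicative"

    def validate(self) -> None:
        if not 0 < self.carryover_threshold < 1:
            raise PreprocessError("carryover_threshold must lie in (0, 1)")
        if self.qc_rsd_threshold <= 0:
            raise PreprocessError("qc_rsd_threshold must be positive")
        if self.drift_mode not in ("additive", "multiplicative"):
            raise PreprocessError(f"unknown drift_mode {self.drift_mode!r}")


@dataclasses.dataclass
class ScalingParams:
    """Per-feature centering/scaling statistics learned on training rows."""

    column_means: np.ndarray
    column_sds: np.ndarray


def filter_blank_and_carryover(
    table: FeatureTable, carryover_threshold: float = 0.10
) -> tuple[FeatureTable, list[str]]:
    """Drop features present in blanks above the carry-over threshold.

    A feature is removed when its mean blank area exceeds
    ``carryover_threshold`` times its mean monitoring-QC area; such
    signal is attributed to contamination or carry-over rather than to
    the samples.  Blank rows are removed from the returned table.
    """
    if not 0 < carryover_threshold < 1:
        raise PreprocessError("carryover_threshold must lie in (0, 1)")
    blank_mask = table.role_mask(ROLE_BLANK)
    if not blank_mask.any():
        raise PreprocessError("no blank rows: blank/carry-over filter cannot be applied")
    qc_mask = table.qc_mask()
    if not qc_mask.any():
        raise PreprocessError("no monitoring QC rows: carry-over reference undefined")
    blank_mean = table.areas.loc[blank_mask].mean(axis=0)
    qc_mean = table.areas.loc[qc_mask].mean(axis=0)
    removed = table.feature_ids[
        (blank_mean > carryover_threshold * qc_mean).to_numpy()
    ]
    kept = table.feature_ids.difference(removed, sort=False)
    out = table.subset_features(kept).subset_rows(~blank_mask)
    return out, list(removed)


def qc_drift_correct(table: FeatureTable, mode: str = "additive") -> FeatureTable:
    """Remove the injection-order trend estimated on monitoring QCs.

    Per feature an ordinary least-squares line of QC area on injection
    order is fitted; every row (samples and QCs alike) is corrected so
    that the refitted QC slope is zero.  The additive variant subtracts
    ``slope * (order - mean QC order)``; the multiplicative variant
    divides by the fitted line normalised to its value at the mean QC
    order.  Corrected areas are floored at zero.
    """
    qc_mask = table.qc_mask()
    n_qc = int(qc_mask.sum())
    if n_qc < 3:
        raise PreprocessError(f"need >= 3 monitoring QC rows for drift correction, got {n_qc}")
    orders = table.sample_meta["injection_order"].to_numpy(dtype=float)
    qc_orders = orders[qc_mask]
    if np.ptp(qc_orders) == 0:
        raise PreprocessError("QC injection orders have zero variance")
    Y = table.areas.to_numpy(dtype=float)
    Yqc = Y[qc_mask]
    o_bar = qc_orders.mean()
    d = qc_orders - o_bar
    slope = d @ (Yqc - Yqc.mean(axis=0)) / (d @ d)
    intercept = Yqc.mean(axis=0)  # value of the fit at o_bar
    trend = np.outer(orders - o_bar, slope)
    if mode == "additive":
        corrected = Y - trend
    elif mode == "multiplicative":
        with np.errstate(divide="ignore", invalid="ignore"):
            factor = (intercept + trend) / intercept
        factor = np.where(np.isfinite(factor) & (factor > 0), factor, 1.0)
        corrected = Y / factor
    else:
        raise PreprocessError(f"unknown drift mode {mode!r}")
    corrected = np.clip(corrected, 0.0, None)
    out = table.copy()
    out.areas = pd.DataFrame(corrected, index=table.areas.index, columns=table.areas.columns)
    return out


def filter_qc_presence_rsd(
    table: FeatureTable, rsd_threshold: float = 0.25, ddof: int = 1
) -> tuple[FeatureTable, list[str]]:
    """Drop features missing from any monitoring QC or QC-unstable.

    Presence means area > 0 in every monitoring QC.  Stability means a
    QC relative standard deviation (sd/mean, sample sd with ``ddof``
    degrees-of-freedom correction) at or below ``rsd_threshold``.
    Features with zero QC mean are dropped rather than raising a
    division error.
    """
    if rsd_threshold <= 0:
        raise PreprocessError("rsd_threshold must be positive")
    qc_mask = table.qc_mask()
    if qc_mask.sum() < 2:
        raise PreprocessError("need >= 2 monitoring QC rows for the RSD filter")
    Yqc = table.areas.loc[qc_mask].to_numpy(dtype=float)
    present = (Yqc > 0).all(axis=0)
    mean = Yqc.mean(axis=0)
    sd = Yqc.std(axis=0, ddof=ddof)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = np.where(mean > 0, sd / mean, np.inf)
    keep = present & (rsd <= rsd_threshold)
    removed = list(table.feature_ids[~keep])
    return table.subset_features(table.feature_ids[keep]), removed


def creatinine_normalize(table: FeatureTable) -> FeatureTable:
    """Divide each sample row by its urinary creatinine (mg/dL).

    Corrects for urine dilution.  QC rows are left untouched (the
    pooled QC carries no single-donor creatinine value).
    """
    meta = table.sample_meta
    sample_mask = table.role_mask(ROLE_SAMPLE)
    creat = meta.loc[sample_mask, "creatinine"]
    bad = creat.isna() | (creat <= 0)
    if bad.any():
        raise PreprocessError(
            f"missing or non-positive creatinine for samples: {list(creat.index[bad])}"
        )
    out = table.copy()
    out.areas.loc[sample_mask] = out.areas.loc[sample_mask].div(creat, axis=0)
    return out


def autoscale_fit(X: np.ndarray) -> ScalingParams:
    """Learn per-column mean and sd (ddof=1) from training rows only."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise PreprocessError("autoscale_fit needs a 2-D matrix with >= 2 rows")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sds == 0)
    if zero.size:
        raise PreprocessError(f"zero-variance columns: {zero.tolist()}")
    return ScalingParams(column_means=means, column_sds=sds)


def autoscale_apply(X: np.ndarray, params: ScalingParams) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return (X - params.column_means) / params.column_sds


def block_scale_concat(
    blocks: list[np.ndarray], norms: list[float] | None = None
) -> tuple[np.ndarray, list[float]]:
    """Scale each autoscaled block to unit Frobenius norm and concatenate.

    Equalizes the influence of blocks of different width in a fused
    (multi-block) model.  When ``norms`` is given (the calibration-row
    norms, inside cross-validation) they are reused instead of being
    recomputed, preserving the training/validation separation.
    Returns the concatenated matrix and the norms used.
    """
    if not blocks:
        raise PreprocessError("no blocks given")
    n_rows = {b.shape[0] for b in blocks}
    if len(n_rows) != 1:
        raise PreprocessError(f"blocks disagree on row count: {sorted(n_rows)}")
    if norms is None:
        norms = [float(np.linalg.norm(b)) for b in blocks]
    if any(nu == 0 for nu in norms):
        raise PreprocessError("zero Frobenius norm block")
    scaled = [np.asarray(b, dtype=float) / nu for b, nu in zip(blocks, norms)]
    return np.concatenate(scaled, axis=1), norms


def preprocess_chain(
    table: FeatureTable, config: PreprocessConfig | None = None
) -> tuple[FeatureTable, dict]:
    """Run the full filtering/correction chain; return table + report.

    The report maps each removal reason to the feature ids it removed
    (``blank`` covers both contamination and carry-over; ``qc`` covers
    missing-in-QC and unstable-in-QC features).
    """
    config = config or PreprocessConfig()
    config.validate()
    # conditioning QCs serve column equilibration only
    work = table.subset_rows(~(table.role_mask(ROLE_QC) & table.sample_meta["conditioning"].to_numpy(dtype=bool)))
    work, removed_blank = filter_blank_and_carryover(work, config.carryover_threshold)
    work = qc_drift_correct(work, mode=config.drift_mode)
    work, removed_qc = filter_qc_presence_rsd(work, config.qc_rsd_threshold)
    work = creatinine_normalize(work)
    report = {
        "removed": {"blank": removed_blank, "qc": removed_qc},
        "n_features_in": int(table.n_features),
        "n_features_out": int(work.n_features),
        "carryover_threshold": config.carryover_threshold,
        "qc_rsd_threshold": config.qc_rsd_threshold,
        "drift_mode": config.drift_mode,
    }
    return work, report
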