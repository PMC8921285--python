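"""ROC/AUROC over r-dCV runs, univariate marker performance, t-tests.

One ROC curve is computed per r-dCV run from that run's outer-loop
scores; curves are averaged vertically on a common false-positive-rate
grid, and the AUROC mean and nonparametric confidence interval are
taken across runs.  Single metabolites are benchmarked by running the
same r-dCV engine on one column at a time (one latent variable), so
their figures of merit are directly comparable with the multivariate
model's.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .rdcv import FOM_NAMES, RDCVConfig, RDCVResult, nonparametric_ci, run_rdcv

__all__ = [
    "ROCResult",
    "roc_curve",
    "mean_roc_over_runs",
    "univariate_performance",
    "two_sample_t",
    "boxplot_summary",
]

#: common 1-specificity grid for vertical ROC averaging
FPR_GRID = np.linspace(0.0, 1.0, 101)


@dataclasses.dataclass
class ROCResult:
    fpr_grid: np.ndarray
    mean_tpr: np.ndarray
    per_run_tpr: np.ndarray  # runs x grid
    aurocs: np.ndarray  # per run
    auroc_mean: float
    auroc_ci: tuple[float, float]


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC points and AUROC for continuous scores vs +/-1 labels.

    The threshold sweep runs over the unique scores; the area is the
    trapezoid rule, equal to the Mann-Whitney U statistic normalized
    by n_pos * n_neg.
    """
    labels = np.asarray(labels, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, _ = _sk_roc_curve(labels, np.asarray(scores, dtype=float), pos_label=1.0)
    return fpr, tpr, float(_sk_auc(fpr, tpr))


def mean_roc_over_runs(result: RDCVResult) -> ROCResult:
    """Vertically averaged ROC over the r-dCV runs.

    Each run's outer-loop scores yield one curve; curves are linearly
    interpolated onto a fixed 101-point false-positive grid and
    averaged, and the AUROC mean and nearest-rank CI are computed over
    runs.
    """
    runs = result.scores.shape[0]
    if runs < 2:
        raise ValueError("need >= 2 runs to average ROC curves")
    per_run = np.empty((runs, FPR_GRID.size))
    aurocs = np.empty(runs)
    for r in range(runs):
        fpr, tpr, a = roc_curve(result.scores[r], result.y)
        per_run[r] = np.interp(FPR_GRID, fpr, tpr)
        aurocs[r] = a
    mean_tpr = per_run.mean(axis=0)
    _, lo, hi = nonparametric_ci(aurocs, result.config.ci_level)
    return ROCResult(
        fpr_grid=FPR_GRID.copy(),
        mean_tpr=mean_tpr,
        per_run_tpr=per_run,
        aurocs=aurocs,
        auroc_mean=float(aurocs.mean()),
        auroc_ci=(lo, hi),
    )


def univariate_performance(
    x: np.ndarray, y: np.ndarray, config: RDCVConfig
) -> dict[str, tuple[float, float, float]]:
    """r-dCV figures of merit and AUROC of a single metabolite.

    The single-column model has one latent variable by construction;
    everything else (splits, runs, CI rule) matches the multivariate
    configuration, enabling a like-for-like comparison.
    """
    x = np.asarray(x, dtype=float).reshape(-1, 1)
    if np.ptp(x) == 0:
        raise ValueError("constant column: univariate model undefined")
    cfg = dataclasses.replace(config, max_lv=1)
    res = run_rdcv(x, y, cfg)
    out: dict[str, tuple[float, float, float]] = {}
    for name in FOM_NAMES:
        out[name] = nonparametric_ci(res.fom[name].to_numpy(), cfg.ci_level)
    roc = mean_roc_over_runs(res)
    out["auroc"] = (roc.auroc_mean, *roc.auroc_ci)
    return out


def two_sample_t(
    x1: np.ndarray | None = None,
    x2: np.ndarray | None = None,
    *,
    summary: tuple[float, float, int, float, float, int] | None = None,
    welch: bool = False,
) -> tuple[float, float]:
    """Two-sided Student's t-test between two groups.

    Accepts either raw vectors or a summary
    ``(mean1, sd1, n1, mean2, sd2, n2)``.  The default is the pooled-
    variance Student test (n1 + n2 - 2 degrees of freedom); ``welch``
    switches to the unequal-variance form.
    """
    if summary is not None:
        m1, s1, n1, m2, s2, n2 = summary
        res = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=not welch)
    else:
        if x1 is None or x2 is None:
            raise ValueError("need two vectors or a summary tuple")
        x1 = np.asarray(x1, dtype=float)
        x2 = np.asarray(x2, dtype=float)
        if len(x1) < 2 or len(x2) < 2:
            raise ValueError("need >= 2 observations per class")
        res = stats.ttest_ind(x1, x2, equal_var=not welch)
    t, p = float(res.statistic), float(res.pvalue)
    if not np.isfinite(t):
        raise ValueError("zero pooled variance: t statistic undefined")
    return t, p


def boxplot_summary(x: np.ndarray) -> dict[str, float]:
    """Five-number summary (min, Q1, median, Q3, max) of one group."""
    x = np.asarray(x, dtype=float)
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return {
        "min": float(x.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(x.max()),
    }


def per_metabolite_table(
    X: np.ndarray,
    y: np.ndarray,
    feature_ids: list[str],
    config: RDCVConfig,
) -> pd.DataFrame:
    """Univariate benchmark of every feature: accuracy and AUROC with
    CIs from r-dCV, plus the two-sample t statistic and p-value."""
    rows = []
    for j, fid in enumerate(feature_ids):
        perf = univariate_performance(X[:, j], y, config)
        t, p = two_sample_t(X[y > 0, j], X[y < 0, j])
        acc = perf["accuracy"]
        au = perf["auroc"]
        rows.append(
            {
                "feature_id": fid,
                "accuracy": acc[0],
                "accuracy_low": acc[1],
                "accuracy_high": acc[2],
                "auroc": au[0],
                "auroc_low": au[1],
                "auroc_high": au[2],
                "t": t,
                "p": p,
            }
        )
    return pd.DataFrame(rows)
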