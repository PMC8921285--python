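"""Repeated double cross-validation (r-dCV) for PLS-DA.

Samples are organized in two nested loops: the outer loop holds out
one deletion group at a time to mimic an external test set, while the
inner loop (run on the remaining calibration samples only) selects the
latent-variable count.  The whole procedure is repeated ``runs`` times
with reshuffled splits, yielding distributions — rather than point
estimates — of every figure of merit, sample score and model
coefficient, from which nonparametric (nearest-rank percentile)
confidence intervals are taken.

Autoscaling and block scaling are refitted on calibration rows inside
every loop; held-out rows never influence scaling, latent-variable
selection or the coefficients that predict them.

A permutation test re-estimates the figures of merit under random
label reshuffling.  By default each permutation uses a reduced scheme
— a single dCV pass with the latent-variable count frozen at the modal
value of the unpermuted model — which makes 1000 randomizations cheap;
a full r-dCV per permutation is available behind a flag.
"""

from __future__ import annotations

import dataclasses
from collections import Counter

import numpy as np
import pandas as pd

from .plsda import PLSModel, fit_pls, predict, vip_scores
from .preprocess import ScalingParams, autoscale_apply, autoscale_fit, block_scale_concat

__all__ = [
    "RDCVConfig",
    "RDCVResult",
    "PermutationResult",
    "split_groups",
    "choose_lv",
    "inner_select_lv",
    "run_rdcv",
    "figures_of_merit",
    "nonparametric_ci",
    "permutation_test",
]

FOM_NAMES = ("sensitivity", "specificity", "error_rate", "accuracy")


@dataclasses.dataclass
class RDCVConfig:
    runs: int = 30
    outer_groups: int = 10
    inner_groups: int = 8
    max_lv: int = 5
    stratified: bool = True
    seed: int = 0
    ci_level: float = 0.95
    permutations: int = 1000
    harvest: str = "inner"  # "inner": runs x inner_groups vectors; "nested": x outer too
    block_sizes: tuple[int, ...] | None = None  # column widths for multi-block fusion

    def validate(self, y: np.ndarray | None = None) -> None:
        if self.runs < 1:
            raise ValueError("runs must be >= 1")
        if self.runs < 2 and self.ci_level:
            pass  # CIs simply unavailable with one run
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0, 1)")
        if self.outer_groups < 2 or self.inner_groups < 2:
            raise ValueError("outer_groups and inner_groups must be >= 2")
        if self.max_lv < 1:
            raise ValueError("max_lv must be >= 1")
        if self.harvest not in ("inner", "nested"):
            raise ValueError(f"unknown harvest scheme {self.harvest!r}")
        if y is not None:
            y = np.asarray(y)
            n = len(y)
            if self.outer_groups > n:
                raise ValueError(f"outer_groups ({self.outer_groups}) exceeds n ({n})")
            if self.stratified:
                for cls in np.unique(y):
                    if (y == cls).sum() < 1:
                        raise ValueError("empty class")


@dataclasses.dataclass
class RDCVResult:
    config: RDCVConfig
    scores: np.ndarray  # runs x n, outer-loop continuous scores
    labels: np.ndarray  # runs x n, outer-loop class calls (+/-1)
    fom: pd.DataFrame  # runs x 4, per-run figures of merit (fractions)
    chosen_lv: np.ndarray  # runs x outer_groups
    harvested_coefficients: np.ndarray  # m x p, per the counting scheme
    harvested_vips: np.ndarray  # m x p
    outer_coefficients: np.ndarray  # (runs*outer_groups) x p
    y: np.ndarray  # true +/-1 labels

    @property
    def n_samples(self) -> int:
        return self.scores.shape[1]

    def modal_lv(self) -> int:
        return int(Counter(self.chosen_lv.ravel().tolist()).most_common(1)[0][0])

    def fom_summary(self) -> pd.DataFrame:
        """Mean and nonparametric CI of each figure of merit over runs."""
        rows = {}
        for name in FOM_NAMES:
            rows[name] = nonparametric_ci(self.fom[name].to_numpy(), self.config.ci_level)
        return pd.DataFrame(rows, index=["mean", "low", "high"]).T

    def sample_score_summary(self) -> pd.DataFrame:
        out = np.empty((self.n_samples, 3))
        for i in range(self.n_samples):
            out[i] = nonparametric_ci(self.scores[:, i], self.config.ci_level)
        return pd.DataFrame(out, columns=["mean", "low", "high"])

    def coefficient_summary(self) -> pd.DataFrame:
        B = self.outer_coefficients
        out = np.empty((B.shape[1], 3))
        for j in range(B.shape[1]):
            out[j] = nonparametric_ci(B[:, j], self.config.ci_level)
        return pd.DataFrame(out, columns=["mean", "low", "high"])


def split_groups(
    y: np.ndarray, k: int, stratified: bool = True, rng: np.random.Generator | None = None
) -> list[np.ndarray]:
    """Partition sample indices into k near-equal deletion groups.

    With ``stratified`` the per-group class counts differ by at most
    one from perfect balance (a 20+20 design with k=10 gives exactly
    2+2 per group).
    """
    y = np.asarray(y)
    n = len(y)
    if k > n:
        raise ValueError(f"k ({k}) exceeds sample count ({n})")
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = rng or np.random.default_rng()
    groups: list[list[int]] = [[] for _ in range(k)]
    if stratified:
        start = 0
        for cls in np.unique(y):
            idx = np.flatnonzero(y == cls)
            rng.shuffle(idx)
            # rotate the dealing start so small classes spread across groups
            for pos, i in enumerate(idx):
                groups[(start + pos) % k].append(int(i))
            start += len(idx)
    else:
        idx = rng.permutation(n)
        for pos, i in enumerate(idx):
            groups[pos % k].append(int(i))
    return [np.array(sorted(g), dtype=int) for g in groups]


def choose_lv(errors: np.ndarray) -> int:
    """Latent-variable count minimizing inner-CV error; ties -> smallest."""
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise ValueError("empty error profile")
    return int(np.argmin(errors)) + 1


def _fit_submodel(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    n_lv: int,
    block_sizes: tuple[int, ...] | None,
) -> tuple[ScalingParams, list[float] | None, PLSModel]:
    sp = autoscale_fit(X_cal)
    Z = autoscale_apply(X_cal, sp)
    norms = None
    if block_sizes:
        blocks = _split_blocks(Z, block_sizes)
        Z, norms = block_scale_concat(blocks)
    model = fit_pls(Z, y_cal, n_lv)
    return sp, norms, model


def _predict_submodel(
    bundle: tuple[ScalingParams, list[float] | None, PLSModel],
    X_new: np.ndarray,
    block_sizes: tuple[int, ...] | None,
):
    sp, norms, model = bundle
    Z = autoscale_apply(np.atleast_2d(X_new), sp)
    if block_sizes:
        Z, _ = block_scale_concat(_split_blocks(Z, block_sizes), norms=norms)
    return predict(model, Z, apply_scaling=False)


def _split_blocks(Z: np.ndarray, block_sizes: tuple[int, ...]) -> list[np.ndarray]:
    if sum(block_sizes) != Z.shape[1]:
        raise ValueError(
            f"block sizes {block_sizes} do not sum to column count {Z.shape[1]}"
        )
    cuts = np.cumsum(block_sizes[:-1])
    return np.split(Z, cuts, axis=1)


def _feasible_max_lv(max_lv: int, n_cal_min: int, p: int) -> int:
    return max(1, min(max_lv, n_cal_min - 2, p))


def inner_select_lv(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    inner_groups: int,
    max_lv: int,
    rng: np.random.Generator,
    stratified: bool = True,
    block_sizes: tuple[int, ...] | None = None,
    return_models: bool = False,
):
    """Select the latent-variable count by inner cross-validation.

    For each candidate count 1..max_lv the inner-CV misclassification
    error is computed, with autoscaling (and block scaling) refitted on
    each inner calibration set.  The count minimizing error is
    returned; ties break to the smallest count.  When ``return_models``
    is set, the ``inner_groups`` fold models refitted at the chosen
    count are returned as well (the sub-models harvested for variable
    selection).
    """
    folds = split_groups(y_cal, inner_groups, stratified=stratified, rng=rng)
    n_cal_min = min(len(y_cal) - len(f) for f in folds)
    max_lv_eff = _feasible_max_lv(max_lv, n_cal_min, X_cal.shape[1])
    n = len(y_cal)
    errors = np.empty(max_lv_eff)
    for a in range(1, max_lv_eff + 1):
        wrong = 0
        for fold in folds:
            cal = np.setdiff1d(np.arange(n), fold)
            bundle = _fit_submodel(X_cal[cal], y_cal[cal], a, block_sizes)
            pred = _predict_submodel(bundle, X_cal[fold], block_sizes)
            wrong += int((pred.label != y_cal[fold]).sum())
        errors[a - 1] = wrong / n
    n_lv = choose_lv(errors)
    if not return_models:
        return n_lv, errors
    models = []
    for fold in folds:
        cal = np.setdiff1d(np.arange(n), fold)
        models.append(_fit_submodel(X_cal[cal], y_cal[cal], n_lv, block_sizes))
    return n_lv, errors, models


def figures_of_merit(labels_pred: np.ndarray, labels_true: np.ndarray) -> dict[str, float]:
    """Sensitivity (PCa recall), specificity (BPH recall), error, accuracy."""
    pred = np.asarray(labels_pred, dtype=float)
    true = np.asarray(labels_true, dtype=float)
    pos, neg = true > 0, true < 0
    if not pos.any() or not neg.any():
        raise ValueError("both classes must be present")
    sens = float((pred[pos] > 0).mean())
    spec = float((pred[neg] < 0).mean())
    err = float((pred != true).mean())
    return {
        "sensitivity": sens,
        "specificity": spec,
        "error_rate": err,
        "accuracy": 1.0 - err,
    }


def nonparametric_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    """Mean plus nearest-rank percentile interval.

    The lower/upper bounds are the order statistics at ranks
    ceil(alpha/2 * n) and ceil((1 - alpha/2) * n); no interpolation is
    performed, so the bounds are always observed values.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n < 2:
        raise ValueError("need >= 2 values for a nonparametric CI")
    alpha = 1.0 - level
    lo_rank = max(1, int(np.ceil(alpha / 2 * n)))
    hi_rank = min(n, int(np.ceil((1 - alpha / 2) * n)))
    return float(v.mean()), float(v[lo_rank - 1]), float(v[hi_rank - 1])


def _single_dcv_pass(
    X: np.ndarray,
    y: np.ndarray,
    config: RDCVConfig,
    rng: np.random.Generator,
    fixed_lv: int | None = None,
    harvest: bool = False,
):
    """One double-CV pass: outer split, per-fold LV selection + fit,
    held-out prediction.  Returns scores, labels, chosen LVs, outer
    coefficient vectors and (optionally) the harvested inner models of
    the first outer fold."""
    n, p = X.shape
    outer = split_groups(y, config.outer_groups, stratified=config.stratified, rng=rng)
    scores = np.empty(n)
    labels = np.empty(n)
    chosen = np.empty(len(outer), dtype=int)
    outer_b = np.empty((len(outer), p))
    harvested: list[tuple] = []
    for g, val in enumerate(outer):
        cal = np.setdiff1d(np.arange(n), val)
        if fixed_lv is None:
            want_models = harvest and (config.harvest == "nested" or g == 0)
            sel = inner_select_lv(
                X[cal],
                y[cal],
                config.inner_groups,
                config.max_lv,
                rng,
                stratified=config.stratified,
                block_sizes=config.block_sizes,
                return_models=want_models,
            )
            n_lv = sel[0]
            if want_models:
                harvested.extend(sel[2])
        else:
            n_cal_min = len(cal)
            n_lv = _feasible_max_lv(fixed_lv, n_cal_min, p)
        bundle = _fit_submodel(X[cal], y[cal], n_lv, config.block_sizes)
        pred = _predict_submodel(bundle, X[val], config.block_sizes)
        scores[val] = pred.score
        labels[val] = pred.label
        chosen[g] = n_lv
        outer_b[g] = bundle[2].coefficients
    return scores, labels, chosen, outer_b, harvested


def run_rdcv(X: np.ndarray, y: np.ndarray, config: RDCVConfig) -> RDCVResult:
    """Run the full repeated double cross-validation.

    ``X`` is the preprocessed (filtered, drift-corrected, creatinine-
    normalized) sample matrix on its raw scale; autoscaling happens
    inside the loops on calibration rows only.  Each run produces one
    outer-loop prediction per sample and one value of each figure of
    merit; coefficient vectors of inner-loop sub-models are harvested
    per the configured counting scheme (default: the first outer
    fold's inner models, ``runs x inner_groups`` vectors in total).
    Fixing ``config.seed`` makes the result bit-reproducible.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    config.validate(y)
    n, p = X.shape
    scores = np.empty((config.runs, n))
    labels = np.empty((config.runs, n))
    fom_rows = []
    chosen = np.empty((config.runs, config.outer_groups), dtype=int)
    outer_b_all = np.empty((config.runs * config.outer_groups, p))
    harvested_b: list[np.ndarray] = []
    harvested_v: list[np.ndarray] = []
    seeds = np.random.SeedSequence(config.seed).spawn(config.runs)
    for r in range(config.runs):
        rng = np.random.default_rng(seeds[r])
        s, l, c, ob, models = _single_dcv_pass(X, y, config, rng, harvest=True)
        scores[r], labels[r], chosen[r] = s, l, c
        outer_b_all[r * config.outer_groups : (r + 1) * config.outer_groups] = ob
        fom_rows.append(figures_of_merit(l, y))
        for bundle in models:
            model = bundle[2]
            harvested_b.append(model.coefficients)
            harvested_v.append(vip_scores(model))
    fom = pd.DataFrame(fom_rows, columns=list(FOM_NAMES))
    return RDCVResult(
        config=config,
        scores=scores,
        labels=labels,
        fom=fom,
        chosen_lv=chosen,
        harvested_coefficients=np.vstack(harvested_b),
        harvested_vips=np.vstack(harvested_v),
        outer_coefficients=outer_b_all,
        y=y,
    )


@dataclasses.dataclass
class PermutationResult:
    null_fom: pd.DataFrame  # B x 4, figures of merit under permuted labels
    observed: dict[str, float]  # mean observed figures of merit
    p_values: dict[str, float]
    fixed_lv: int
    n_permutations: int


def permutation_test(
    X: np.ndarray,
    y: np.ndarray,
    config: RDCVConfig,
    B: int | None = None,
    observed: RDCVResult | None = None,
    full_rdcv: bool = False,
) -> PermutationResult:
    """Null distribution of the figures of merit under label permutation.

    The labels are reshuffled B times; each time the classification
    procedure is re-evaluated and its figures of merit recorded.  The
    default reduced scheme evaluates each permutation with a single dCV
    pass at the modal latent-variable count of the unpermuted model;
    ``full_rdcv`` repeats the complete r-dCV per permutation instead.
    p-values use the add-one rule (1 + #{null >= observed}) / (B + 1),
    with the inequality flipped for the error rate.
    """
    B = int(config.permutations if B is None else B)
    if B < 1:
        raise ValueError("need at least one permutation")
    if observed is None:
        observed = run_rdcv(X, y, config)
    fixed_lv = observed.modal_lv()
    obs = {name: float(observed.fom[name].mean()) for name in FOM_NAMES}
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x9E3779B9)))
    rows = []
    for _ in range(B):
        y_perm = rng.permutation(y)
        if full_rdcv:
            perm_cfg = dataclasses.replace(config, seed=int(rng.integers(2**31)))
            res = run_rdcv(X, y_perm, perm_cfg)
            rows.append({name: float(res.fom[name].mean()) for name in FOM_NAMES})
        else:
            _, labels, _, _, _ = _single_dcv_pass(X, y_perm, config, rng, fixed_lv=fixed_lv)
            rows.append(figures_of_merit(labels, y_perm))
    null = pd.DataFrame(rows, columns=list(FOM_NAMES))
    p_values = {}
    for name in FOM_NAMES:
        nv = null[name].to_numpy()
        if name == "error_rate":
            extreme = int((nv <= obs[name]).sum())
        else:
            extreme = int((nv >= obs[name]).sum())
        p_values[name] = (1 + extreme) / (B + 1)
    return PermutationResult(
        null_fom=null, observed=obs, p_values=p_values, fixed_lv=fixed_lv, n_permutations=B
    )
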