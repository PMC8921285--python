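"""End-to-end orchestration: simulate -> preprocess -> explore -> model
-> select -> re-model reduced sets -> fuse blocks -> report.

The pipeline mirrors a two-ionization-mode study: each block (e.g.
ESI+ and ESI-) is preprocessed and modelled independently; variable
selection reduces each block to its putative biomarkers; the reduced
blocks are re-modelled by r-dCV and, when two blocks are present,
additionally fused by unit-Frobenius block scaling into a multi-block
model.  All outputs are delimited text or JSON under a run directory,
and the whole run is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np

from . import __version__
from .evaluate import mean_roc_over_runs
from .io import write_feature_table, write_json
from .pca import fit_pca, score_order_correlation
from .preprocess import PreprocessConfig, autoscale_apply, autoscale_fit, preprocess_chain
from .rdcv import RDCVConfig, permutation_test, run_rdcv
from .simulate import SimulationConfig, generate_feature_table
from .table import FeatureTable, ROLE_SAMPLE
from .varsel import select_variables, selection_report

log = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """Everything one run needs: either input paths per block or
    simulation configs, plus stage parameters and the output directory."""

    blocks: dict[str, SimulationConfig | dict]  # block name -> sim config or file paths
    preprocess: PreprocessConfig = dataclasses.field(default_factory=PreprocessConfig)
    rdcv: RDCVConfig = dataclasses.field(default_factory=RDCVConfig)
    vip_threshold: float = 1.0
    permutations: int = 0  # 0 disables the permutation stage
    out_dir: str | Path = "uromarker_run"
    seed: int = 0
    n_pca_components: int = 2
    stages: tuple[str, ...] = ("simulate", "preprocess", "explore", "model", "select", "evaluate")

    def validate(self) -> None:
        if not self.blocks:
            raise ValueError("at least one block must be configured")
        self.preprocess.validate()


def _load_block(name: str, spec, seed_offset: int):
    """Return (FeatureTable, truth-or-None) for one block."""
    from .io import read_feature_table

    if isinstance(spec, SimulationConfig):
        cfg = dataclasses.replace(spec, seed=spec.seed + seed_offset)
        table, truth = generate_feature_table(cfg)
        return table, truth
    if isinstance(spec, dict):
        table = read_feature_table(
            spec["areas"], spec["samples"], spec.get("features")
        )
        return table, None
    raise TypeError(f"block {name!r}: expected SimulationConfig or path mapping")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages for every block; return the summary.

    The summary JSON lists, per model (one per block plus ``fused``
    when two or more blocks are given), the four figures of merit with
    confidence intervals, the AUROC, the number of selected variables,
    and permutation p-values when that stage is enabled.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}, "outputs": []}
    summary: dict = {"seed": config.seed, "models": {}, "selection": {}}

    def _stage(name):
        t0 = time.perf_counter()

        def done(**info):
            manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3), **info}
            log.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)

        return done

    reduced_blocks: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
    y_ref = None
    try:
        for bi, (bname, bspec) in enumerate(config.blocks.items()):
            done = _stage(f"simulate[{bname}]")
            table, truth = _load_block(bname, bspec, seed_offset=1000 * bi + config.seed)
            paths = write_feature_table(table, out_dir / f"{bname}_raw")
            manifest["outputs"] += [str(p) for p in paths.values()]
            if truth is not None:
                p = out_dir / f"{bname}_truth.json"
                p.write_text(truth.to_json() + "\n")
                manifest["outputs"].append(str(p))
            done(n_injections=table.n_injections, n_features=table.n_features)
            if "preprocess" not in config.stages:
                continue

            done = _stage(f"preprocess[{bname}]")
            clean, report = preprocess_chain(table, config.preprocess)
            write_json(report, out_dir / f"{bname}_filter_report.json")
            manifest["outputs"].append(str(out_dir / f"{bname}_filter_report.json"))
            done(n_features_out=clean.n_features)

            X, y, sample_ids = clean.sample_xy()
            # canonical sample order so blocks can be fused row-aligned
            order = np.argsort(sample_ids)
            X, y, sample_ids = X[order], y[order], sample_ids[order]
            y_ref = y
            feature_ids = list(clean.feature_ids)

            if "explore" in config.stages:
                done = _stage(f"explore[{bname}]")
                Z = autoscale_apply(X, autoscale_fit(X))
                pca = fit_pca(Z, min(config.n_pca_components, X.shape[0] - 1))
                orders = clean.sample_meta.loc[sample_ids, "injection_order"]
                diag = {
                    "t2": pca.t2,
                    "q": pca.q,
                    "explained_variance": pca.explained_variance,
                    "score_order_correlation": score_order_correlation(
                        pca, orders.to_numpy()
                    ),
                    "sample_ids": list(sample_ids),
                }
                write_json(diag, out_dir / f"{bname}_pca_diagnostics.json")
                manifest["outputs"].append(str(out_dir / f"{bname}_pca_diagnostics.json"))
                done()

            if "model" not in config.stages:
                continue
            done = _stage(f"model[{bname}]")
            rd_cfg = dataclasses.replace(config.rdcv, seed=config.rdcv.seed + config.seed + bi)
            full = run_rdcv(X, y, rd_cfg)
            done(modal_lv=full.modal_lv())

            sel = None
            if "select" in config.stages:
                done = _stage(f"select[{bname}]")
                sel = select_variables(full, vip_threshold=config.vip_threshold)
                rep = selection_report(
                    sel, feature_ids, mean_coefficients=full.harvested_coefficients.mean(axis=0)
                )
                rep.to_csv(out_dir / f"{bname}_selection.csv", index=False)
                manifest["outputs"].append(str(out_dir / f"{bname}_selection.csv"))
                summary["selection"][bname] = {
                    "n_selected": int(sel.selected.size),
                    "selected_ids": [feature_ids[j] for j in sel.selected],
                    "rp_threshold": sel.rp_threshold,
                }
                done(n_selected=int(sel.selected.size))

            if "evaluate" in config.stages:
                done = _stage(f"evaluate[{bname}]")
                if sel is not None and sel.selected.size >= 2:
                    X_red = X[:, sel.selected]
                    red_ids = [feature_ids[j] for j in sel.selected]
                else:  # fall back to the full block
                    X_red, red_ids = X, feature_ids
                red = run_rdcv(X_red, y, rd_cfg)
                roc = mean_roc_over_runs(red)
                entry = _model_entry(red, roc)
                if config.permutations > 0:
                    perm = permutation_test(X_red, y, rd_cfg, B=config.permutations)
                    entry["permutation"] = {
                        "null_accuracy_mean": float(perm.null_fom["accuracy"].mean()),
                        "p_values": perm.p_values,
                        "n_permutations": perm.n_permutations,
                    }
                summary["models"][bname] = entry
                reduced_blocks[bname] = (X_red, y, red_ids)
                red.fom.to_csv(out_dir / f"{bname}_fom_runs.csv", index=False)
                red.sample_score_summary().assign(sample_id=list(sample_ids)).to_csv(
                    out_dir / f"{bname}_sample_scores.csv", index=False
                )
                red.coefficient_summary().assign(feature_id=red_ids).to_csv(
                    out_dir / f"{bname}_coefficients.csv", index=False
                )
                manifest["outputs"] += [
                    str(out_dir / f"{bname}_{s}.csv")
                    for s in ("fom_runs", "sample_scores", "coefficients")
                ]
                done()

        # -- fused multi-block model -----------------------------------
        if len(reduced_blocks) >= 2 and "evaluate" in config.stages:
            done = _stage("fuse")
            mats = [v[0] for v in reduced_blocks.values()]
            X_fused = np.concatenate(mats, axis=1)
            block_sizes = tuple(m.shape[1] for m in mats)
            rd_cfg = dataclasses.replace(
                config.rdcv, seed=config.rdcv.seed + config.seed + 99, block_sizes=block_sizes
            )
            fused = run_rdcv(X_fused, y_ref, rd_cfg)
            roc = mean_roc_over_runs(fused)
            entry = _model_entry(fused, roc)
            if config.permutations > 0:
                perm = permutation_test(X_fused, y_ref, rd_cfg, B=config.permutations)
                entry["permutation"] = {
                    "null_accuracy_mean": float(perm.null_fom["accuracy"].mean()),
                    "p_values": perm.p_values,
                    "n_permutations": perm.n_permutations,
                }
            summary["models"]["fused"] = entry
            done()
    finally:
        write_json(manifest, out_dir / "manifest.json")
    write_json(summary, out_dir / "summary.json")
    manifest["outputs"].append(str(out_dir / "summary.json"))
    write_json(manifest, out_dir / "manifest.json")
    return summary


def _model_entry(result, roc) -> dict:
    fs = result.fom_summary()
    entry = {
        name: {
            "mean": float(fs.loc[name, "mean"]),
            "low": float(fs.loc[name, "low"]),
            "high": float(fs.loc[name, "high"]),
        }
        for name in fs.index
    }
    entry["auroc"] = {
        "mean": roc.auroc_mean,
        "low": roc.auroc_ci[0],
        "high": roc.auroc_ci[1],
    }
    entry["modal_lv"] = result.modal_lv()
    entry["n_variables"] = int(result.outer_coefficients.shape[1])
    return entry


def summary_to_json(summary: dict) -> str:
    return json.dumps(summary, indent=2, sort_keys=True)
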