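"""Delimited-text round-trip of feature tables and JSON reports.

A feature table is stored as three CSV files: the area matrix (rows =
injections, columns = features), the per-injection sample metadata and
the per-feature metadata.  Writing then reading reproduces the table
exactly up to floating-point text precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .table import FeatureTable, FeatureTableError, ROLE_SAMPLE

__all__ = ["read_feature_table", "write_feature_table", "write_json"]


def write_feature_table(table: FeatureTable, prefix: str | Path) -> dict[str, Path]:
    """Write ``<prefix>_areas.csv``, ``<prefix>_samples.csv`` and
    ``<prefix>_features.csv``; returns the paths."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "areas": prefix.with_name(prefix.name + "_areas.csv"),
        "samples": prefix.with_name(prefix.name + "_samples.csv"),
        "features": prefix.with_name(prefix.name + "_features.csv"),
    }
    table.areas.to_csv(paths["areas"], index_label="id")
    table.sample_meta.to_csv(paths["samples"], index_label="id")
    table.feature_meta.to_csv(paths["features"], index_label="id")
    return paths


def read_feature_table(
    areas_path: str | Path,
    samples_path: str | Path,
    features_path: str | Path | None = None,
) -> FeatureTable:
    """Parse the CSV triplet back into a validated feature table.

    When no feature-metadata file is given, placeholder metadata
    (NaN molecular weight / retention time) is attached.
    """
    areas = pd.read_csv(areas_path, index_col="id")
    meta = pd.read_csv(samples_path, index_col="id")
    if len(areas) != len(meta):
        raise FeatureTableError(
            f"area file has {len(areas)} rows but sample metadata has {len(meta)}"
        )
    if "conditioning" not in meta.columns:
        meta["conditioning"] = False
    meta["conditioning"] = meta["conditioning"].astype(bool)
    if "class_label" in meta.columns:
        meta["class_label"] = meta["class_label"].fillna("NA")
    sample_rows = meta.get("role") == ROLE_SAMPLE
    if "creatinine" in meta.columns:
        missing = meta.loc[sample_rows, "creatinine"].isna()
        if missing.any():
            raise FeatureTableError(
                f"creatinine missing for sample rows: {list(missing.index[missing])}"
            )
    if features_path is not None:
        fmeta = pd.read_csv(features_path, index_col="id")
    else:
        fmeta = pd.DataFrame(
            {"molecular_weight": np.nan, "retention_time": np.nan}, index=areas.columns
        )
        fmeta.index.name = "id"
    return FeatureTable(areas=areas, sample_meta=meta, feature_meta=fmeta)


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_default) + "\n")
    return path
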