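"""Feature-table container shared by every pipeline stage.

A :class:`FeatureTable` bundles the peak-area matrix (injections x
features) with per-injection metadata (role, class label, injection
order, urinary creatinine) and per-feature metadata (molecular weight,
retention time).  All preprocessing operations consume and return
instances of this class; modelling stages work on the plain sample
matrix extracted with :meth:`FeatureTable.sample_xy`.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

ROLE_SAMPLE = "sample"
ROLE_QC = "QC"
ROLE_BLANK = "blank"
VALID_ROLES = (ROLE_SAMPLE, ROLE_QC, ROLE_BLANK)

CLASS_POS = "PCa"
CLASS_NEG = "BPH"
#: numeric coding of the class variable used by the PLS-DA core
CLASS_CODE = {CLASS_NEG: -1.0, CLASS_POS: 1.0}

SAMPLE_META_COLUMNS = ("role", "class_label", "injection_order", "creatinine", "conditioning")
FEATURE_META_COLUMNS = ("molecular_weight", "retention_time")


class FeatureTableError(ValueError):
    """Raised when a feature table violates its structural invariants."""


@dataclasses.dataclass
class FeatureTable:
    """Peak-area matrix plus sample and feature metadata.

    Parameters
    ----------
    areas
        Non-negative peak areas, one row per injection, one column per
        feature.  The row index must match ``sample_meta``'s index and
        the columns must match ``feature_meta``'s index.
    sample_meta
        Per-injection metadata with columns ``role`` (sample/QC/blank),
        ``class_label`` (PCa/BPH for sample rows, NA otherwise),
        ``injection_order`` (unique positive integers), ``creatinine``
        (mg/dL, positive for sample rows) and ``conditioning`` (bool,
        True for system-conditioning QC injections that are excluded
        from every QC-based statistic).
    feature_meta
        Per-feature metadata with columns ``molecular_weight`` (Da) and
        ``retention_time`` (min).
    """

    areas: pd.DataFrame
    sample_meta: pd.DataFrame
    feature_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        areas, meta, fmeta = self.areas, self.sample_meta, self.feature_meta
        if areas.shape[0] != len(meta):
            raise FeatureTableError(
                f"area rows ({areas.shape[0]}) != sample metadata rows ({len(meta)})"
            )
        if areas.shape[1] != len(fmeta):
            raise FeatureTableError(
                f"area columns ({areas.shape[1]}) != feature metadata rows ({len(fmeta)})"
            )
        if not areas.index.equals(meta.index):
            raise FeatureTableError("area row index does not match sample metadata index")
        if not areas.columns.equals(fmeta.index):
            raise FeatureTableError("area columns do not match feature metadata index")
        for col in SAMPLE_META_COLUMNS:
            if col not in meta.columns:
                raise FeatureTableError(f"sample metadata lacks column {col!r}")
        bad_roles = set(meta["role"]) - set(VALID_ROLES)
        if bad_roles:
            raise FeatureTableError(f"unknown sample roles: {sorted(bad_roles)}")
        orders = meta["injection_order"].to_numpy()
        if len(np.unique(orders)) != len(orders):
            raise FeatureTableError("injection_order values are not unique")
        sample_rows = meta["role"] == ROLE_SAMPLE
        creat = meta.loc[sample_rows, "creatinine"]
        bad = creat.isna() | (creat <= 0)
        if bad.any():
            names = list(creat.index[bad])
            raise FeatureTableError(
                f"missing or non-positive creatinine for sample rows: {names}"
            )
        bad_labels = set(meta.loc[sample_rows, "class_label"]) - set(CLASS_CODE)
        if bad_labels:
            raise FeatureTableError(f"unknown class labels on sample rows: {sorted(bad_labels)}")
        vals = areas.to_numpy()
        if np.isfinite(vals).all() and (vals < 0).any():
            raise FeatureTableError("negative peak areas")

    # -- convenience views ---------------------------------------------
    @property
    def n_injections(self) -> int:
        return self.areas.shape[0]

    @property
    def n_features(self) -> int:
        return self.areas.shape[1]

    @property
    def feature_ids(self) -> pd.Index:
        return self.areas.columns

    def role_mask(self, role: str) -> np.ndarray:
        return (self.sample_meta["role"] == role).to_numpy()

    def qc_mask(self, include_conditioning: bool = False) -> np.ndarray:
        """Boolean mask over rows selecting QC injections.

        Conditioning QCs (the column-equilibration injections at the
        start of the sequence) are excluded unless requested: they
        monitor nothing and would bias drift and RSD estimates.
        """
        m = self.role_mask(ROLE_QC)
        if not include_conditioning:
            m &= ~self.sample_meta["conditioning"].to_numpy(dtype=bool)
        return m

    def sample_xy(self) -> tuple[np.ndarray, np.ndarray, pd.Index]:
        """Return the sample-row area matrix, the coded class vector
        (BPH = -1, PCa = +1) and the sample ids, in injection order."""
        mask = self.role_mask(ROLE_SAMPLE)
        sub = self.sample_meta.loc[mask].sort_values("injection_order")
        X = self.areas.loc[sub.index].to_numpy(dtype=float)
        y = sub["class_label"].map(CLASS_CODE).to_numpy(dtype=float)
        return X, y, sub.index

    def subset_features(self, keep: pd.Index | list) -> "FeatureTable":
        return FeatureTable(
            areas=self.areas.loc[:, keep].copy(),
            sample_meta=self.sample_meta.copy(),
            feature_meta=self.feature_meta.loc[keep].copy(),
        )

    def subset_rows(self, mask: np.ndarray) -> "FeatureTable":
        return FeatureTable(
            areas=self.areas.loc[mask].copy(),
            sample_meta=self.sample_meta.loc[mask].copy(),
            feature_meta=self.feature_meta.copy(),
        )

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            areas=self.areas.copy(),
            sample_meta=self.sample_meta.copy(),
            feature_meta=self.feature_meta.copy(),
        )
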