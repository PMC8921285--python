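"""Synthetic untargeted LC-MS feature tables with known ground truth.

The generator emulates the structure of a 20 + 20 urinary metabolomics
case/control study: log-normal peak areas, a planted subset of
class-discriminant features, pooled-QC injections interleaved every few
samples, injection-order drift, blank-contaminated features, features
with unstable or missing QC signal, and per-sample urinary creatinine
including an optional low-creatinine outlier.  Every planted artefact
is recorded in a :class:`SimTruth` object so that downstream filters
and variable selection can be tested against the truth.
"""

from __future__ import annotations

import dataclasses
import json
import math

import numpy as np
import pandas as pd

from .table import (
    CLASS_NEG,
    CLASS_POS,
    FeatureTable,
    ROLE_BLANK,
    ROLE_QC,
    ROLE_SAMPLE,
)

__all__ = [
    "SimulationConfig",
    "SimTruth",
    "generate_injection_sequence",
    "generate_feature_table",
]

#: relative half-amplitude of the deterministic QC oscillation planted on
#: "unstable" features; yields a QC RSD well above the 25 % stability cut
UNSTABLE_QC_AMPLITUDE = 0.5
#: blank area of contaminated features, as a fraction of the QC mean
#: (safely above the 10 % carry-over rule)
BLANK_CONTAMINATION_LEVEL = 0.2


@dataclasses.dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the emulated design: two classes of 20 urine
    samples, pooled-QC injections after every block of 5 samples, ten
    conditioning QCs up front, and a planted set of 22 discriminant
    features separated by 1.5 pooled standard deviations on the
    autoscaled axis.
    """

    n_per_class: int = 20
    n_features: int = 200
    n_discriminant: int = 22
    effect_size: float = 1.5
    direction_mix: float = 0.5
    base_log_mean: float = 11.5
    base_log_sd: float = 1.0
    bio_log_sd: float = 0.4
    drift_fraction: float = 0.3
    drift_magnitude: float = 0.005
    qc_rsd: float = 0.10
    n_blank_contaminated: int = 8
    n_unstable_qc: int = 6
    n_qc_missing: int = 4
    n_conditioning_qc: int = 10
    group_size: int = 5
    n_blanks: int = 2
    creatinine_log_mean: float = math.log(100.0)
    creatinine_log_sd: float = 0.5
    low_creatinine_outlier: bool = True
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_per_class": self.n_per_class,
            "n_features": self.n_features,
            "n_discriminant": self.n_discriminant,
            "n_blank_contaminated": self.n_blank_contaminated,
            "n_unstable_qc": self.n_unstable_qc,
            "n_qc_missing": self.n_qc_missing,
            "n_conditioning_qc": self.n_conditioning_qc,
            "n_blanks": self.n_blanks,
        }
        for name, value in counts.items():
            if value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")
        planted = (
            self.n_discriminant
            + self.n_blank_contaminated
            + self.n_unstable_qc
            + self.n_qc_missing
        )
        if planted > self.n_features:
            raise ValueError(
                f"planted feature counts ({planted}) exceed n_features ({self.n_features})"
            )
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.qc_rsd < 0:
            raise ValueError("qc_rsd must be >= 0")
        if not 0 <= self.direction_mix <= 1:
            raise ValueError("direction_mix must lie in [0, 1]")
        if self.n_per_class < 1 or self.group_size < 1:
            raise ValueError("n_per_class and group_size must be positive")


@dataclasses.dataclass
class SimTruth:
    """Ground truth of a simulated table.

    ``discriminant_indices`` are the feature ids of the planted
    biomarkers; ``signed_effects`` maps each of them to its class
    separation on the autoscaled axis (positive = overexpressed in
    PCa).  ``filtered_indices`` maps a removal reason (``blank``,
    ``qc-missing``, ``qc-rsd``) to the feature ids the preprocessing
    filters should remove.
    """

    discriminant_indices: list[str]
    signed_effects: dict[str, float]
    filtered_indices: dict[str, list[str]]

    def all_filtered(self) -> set[str]:
        return set().union(*self.filtered_indices.values()) if self.filtered_indices else set()

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        return cls(**json.loads(text))


def generate_injection_sequence(
    n_samples: int,
    n_conditioning_qc: int = 10,
    group_size: int = 5,
) -> list[tuple[int, str]]:
    """Build the within-batch injection order.

    The sequence starts with ``n_conditioning_qc`` conditioning QC
    injections, then blocks of ``group_size`` study samples each
    followed by one monitoring QC (a trailing partial block is still
    closed by a QC).  Returns ``(injection_order, role)`` pairs with
    orders counting from 1; conditioning QCs carry the role
    ``"conditioning_qc"`` so they can be flagged downstream.
    """
    if n_samples < 1:
        raise ValueError(f"n_samples must be >= 1, got {n_samples}")
    if group_size < 1:
        raise ValueError(f"group_size must be >= 1, got {group_size}")
    if n_conditioning_qc < 0:
        raise ValueError(f"n_conditioning_qc must be >= 0, got {n_conditioning_qc}")
    seq: list[tuple[int, str]] = []
    order = 1
    for _ in range(n_conditioning_qc):
        seq.append((order, "conditioning_qc"))
        order += 1
    remaining = n_samples
    while remaining > 0:
        block = min(group_size, remaining)
        for _ in range(block):
            seq.append((order, ROLE_SAMPLE))
            order += 1
        seq.append((order, ROLE_QC))
        order += 1
        remaining -= block
    return seq


def _pick_special_sets(rng: np.random.Generator, cfg: SimulationConfig) -> dict[str, np.ndarray]:
    perm = rng.permutation(cfg.n_features)
    cuts = np.cumsum(
        [cfg.n_discriminant, cfg.n_blank_contaminated, cfg.n_unstable_qc, cfg.n_qc_missing]
    )
    disc, blank, unstable, missing = np.split(perm[: cuts[-1]], cuts[:-1])
    ordinary = perm[cuts[-1]:]
    return {
        "discriminant": np.sort(disc),
        "blank": np.sort(blank),
        "unstable": np.sort(unstable),
        "missing": np.sort(missing),
        "ordinary": np.sort(ordinary),
    }


def generate_feature_table(config: SimulationConfig) -> tuple[FeatureTable, SimTruth]:
    """Simulate one acquisition batch and its ground truth.

    Peak areas are log-normal; planted discriminant features receive a
    symmetric class offset on the log scale sized so that the class
    separation is ``effect_size`` pooled standard deviations.  Every
    sample's areas are additionally scaled by its urinary dilution
    (proportional to the drawn creatinine), the nuisance that
    creatinine normalization removes downstream.  QC rows
    are the per-feature mean of the sample areas (pooled-QC semantics)
    perturbed by log-normal technical noise of relative standard
    deviation ``qc_rsd``.  A subset of features drifts multiplicatively
    and linearly with injection order; drift is planted only on
    features outside the filtered sets so that QC-stability truth stays
    exact after linear detrending.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = 2 * config.n_per_class
    p = config.n_features
    feat_ids = [f"F{j + 1:04d}" for j in range(p)]

    sets = _pick_special_sets(rng, config)
    disc = sets["discriminant"]

    # signed effects: +1 means overexpressed in PCa
    n_pos = int(round(config.direction_mix * len(disc)))
    signs = np.array([1.0] * n_pos + [-1.0] * (len(disc) - n_pos))
    rng.shuffle(signs)
    delta = config.effect_size * config.bio_log_sd  # log-scale shift

    # class assignment and randomized run order
    classes = np.array([CLASS_POS] * config.n_per_class + [CLASS_NEG] * config.n_per_class)
    code = np.where(classes == CLASS_POS, 1.0, -1.0)
    run_order_of_sample = rng.permutation(n)

    # urinary dilution: metabolite areas and creatinine scale together
    # with urine concentration, so creatinine division corrects it
    creat = np.exp(rng.normal(config.creatinine_log_mean, config.creatinine_log_sd, size=n))
    creat = np.clip(creat, 10.0, None)  # keep the planted outlier unique
    if config.low_creatinine_outlier:
        creat[0] = 5.0
    dilution = creat / np.exp(config.creatinine_log_mean)

    mu = rng.normal(config.base_log_mean, config.base_log_sd, size=p)
    offset = np.zeros((n, p))
    offset[:, disc] = 0.5 * delta * np.outer(code, signs)
    log_areas = mu + offset + rng.normal(0.0, config.bio_log_sd, size=(n, p))
    sample_areas = np.exp(log_areas) * dilution[:, None]

    qc_mean = sample_areas.mean(axis=0)

    seq = generate_injection_sequence(
        n_samples=n,
        n_conditioning_qc=config.n_conditioning_qc,
        group_size=config.group_size,
    )
    # blanks precede the analytical sequence; all orders shifted up
    shift = config.n_blanks
    rows: list[dict] = []
    area_rows: list[np.ndarray] = []

    blank_area = np.zeros(p)
    blank_area[sets["blank"]] = BLANK_CONTAMINATION_LEVEL * qc_mean[sets["blank"]]
    for b in range(config.n_blanks):
        rows.append(
            {
                "id": f"BL{b + 1:02d}",
                "role": ROLE_BLANK,
                "class_label": "NA",
                "injection_order": b + 1,
                "creatinine": np.nan,
                "conditioning": False,
            }
        )
        area_rows.append(blank_area.copy())

    if config.qc_rsd > 0:
        qc_log_sd = math.sqrt(math.log1p(config.qc_rsd**2))
    else:
        qc_log_sd = 0.0

    drifting = np.zeros(p, dtype=bool)
    n_drift = int(round(config.drift_fraction * p))
    ordinary = sets["ordinary"]
    drift_pool = np.concatenate([ordinary, disc])
    if n_drift > 0 and len(drift_pool) > 0:
        chosen = rng.choice(drift_pool, size=min(n_drift, len(drift_pool)), replace=False)
        drifting[chosen] = True

    first_order = 1 + shift  # first non-blank injection
    monitoring_qc_seen = 0
    sample_cursor = 0
    sample_slots = np.argsort(run_order_of_sample)  # sample index per slot

    for order, role in seq:
        order += shift
        drift_factor = np.ones(p)
        drift_factor[drifting] = 1.0 + config.drift_magnitude * (order - first_order)
        if role == "conditioning_qc" or role == ROLE_QC:
            noise = np.exp(rng.normal(0.0, qc_log_sd, size=p) - 0.5 * qc_log_sd**2)
            area = qc_mean * noise
            # deterministic oscillation on planted unstable features
            if len(sets["unstable"]):
                k = monitoring_qc_seen if role == ROLE_QC else 0
                swing = 1.0 + UNSTABLE_QC_AMPLITUDE * (1.0 if k % 2 == 0 else -1.0)
                area[sets["unstable"]] = qc_mean[sets["unstable"]] * swing
            if role == ROLE_QC:
                if monitoring_qc_seen == 0 and len(sets["missing"]):
                    area[sets["missing"]] = 0.0
                monitoring_qc_seen += 1
            rows.append(
                {
                    "id": f"QC{order:03d}",
                    "role": ROLE_QC,
                    "class_label": "NA",
                    "injection_order": order,
                    "creatinine": np.nan,
                    "conditioning": role == "conditioning_qc",
                }
            )
            area_rows.append(area * drift_factor)
        else:
            s = sample_slots[sample_cursor]
            sample_cursor += 1
            rows.append(
                {
                    "id": f"S{s + 1:02d}",
                    "role": ROLE_SAMPLE,
                    "class_label": classes[s],
                    "injection_order": order,
                    "creatinine": np.nan,  # filled below
                    "conditioning": False,
                }
            )
            area_rows.append(sample_areas[s] * drift_factor)

    meta = pd.DataFrame(rows).set_index("id")
    areas = pd.DataFrame(np.vstack(area_rows), index=meta.index, columns=feat_ids)

    creat_by_id = {f"S{s + 1:02d}": creat[s] for s in range(n)}
    sample_rows = meta["role"] == ROLE_SAMPLE
    meta.loc[sample_rows, "creatinine"] = meta.index[sample_rows].map(creat_by_id)

    feature_meta = pd.DataFrame(
        {
            "molecular_weight": rng.uniform(100.0, 650.0, size=p).round(4),
            "retention_time": rng.uniform(0.5, 16.0, size=p).round(2),
        },
        index=pd.Index(feat_ids, name="id"),
    )

    table = FeatureTable(areas=areas, sample_meta=meta, feature_meta=feature_meta)
    truth = SimTruth(
        discriminant_indices=[feat_ids[j] for j in disc],
        signed_effects={
            feat_ids[j]: float(s * config.effect_size) for j, s in zip(disc, signs)
        },
        filtered_indices={
            "blank": [feat_ids[j] for j in sets["blank"]],
            "qc-missing": [feat_ids[j] for j in sets["missing"]],
            "qc-rsd": [feat_ids[j] for j in sets["unstable"]],
        },
    )
    return table, truth
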