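"""Filtering chain, drift correction, normalization and scaling."""

import numpy as np
import pandas as pd
import pytest

import uromarker as um
from uromarker.preprocess import PreprocessError
from uromarker.table import FeatureTable, ROLE_QC, ROLE_SAMPLE


def _tiny_table(areas, roles, orders, creatinine=None, classes=None, conditioning=None):
    n, p = np.asarray(areas).shape
    idx = [f"R{i}" for i in range(n)]
    cols = [f"F{j}" for j in range(p)]
    creatinine = creatinine or [100.0 if r == ROLE_SAMPLE else np.nan for r in roles]
    classes = classes or ["PCa" if r == ROLE_SAMPLE else "NA" for r in roles]
    meta = pd.DataFrame(
        {
            "role": roles,
            "class_label": classes,
            "injection_order": orders,
            "creatinine": creatinine,
            "conditioning": conditioning or [False] * n,
        },
        index=idx,
    )
    fmeta = pd.DataFrame(
        {"molecular_weight": 100.0, "retention_time": 1.0}, index=cols
    )
    return FeatureTable(
        areas=pd.DataFrame(np.asarray(areas, dtype=float), index=idx, columns=cols),
        sample_meta=meta,
        feature_meta=fmeta,
    )


class TestBlankFilter:
    def test_threshold_comparison(self):
        # F0: blank mean 0 -> kept.  F1: blank = 0.2 x QC mean -> removed at 0.10
        table = _tiny_table(
            areas=[[0.0, 20.0], [100.0, 100.0], [100.0, 100.0], [110.0, 90.0]],
            roles=["blank", ROLE_QC, ROLE_QC, ROLE_SAMPLE],
            orders=[1, 2, 3, 4],
        )
        out, removed = um.filter_blank_and_carryover(table, 0.10)
        assert removed == ["F1"]
        assert list(out.feature_ids) == ["F0"]
        assert not out.role_mask("blank").any()

    def test_no_blank_rows_is_an_error(self):
        table = _tiny_table(
            areas=[[1.0], [1.0], [1.0]],
            roles=[ROLE_QC, ROLE_QC, ROLE_SAMPLE],
            orders=[1, 2, 3],
        )
        with pytest.raises(PreprocessError, match="blank"):
            um.filter_blank_and_carryover(table)

    def test_matches_planted_truth(self, default_table):
        table, truth = default_table
        _, removed = um.filter_blank_and_carryover(table)
        assert sorted(removed) == sorted(truth.filtered_indices["blank"])


class TestDriftCorrection:
    def _drift_table(self, slope):
        orders = list(range(1, 9))
        qc = [100.0 + slope * o for o in orders]
        areas = [[v] for v in qc]
        roles = [ROLE_QC] * 8
        return _tiny_table(areas, roles, orders)

    def test_zero_slope_leaves_table_unchanged(self):
        table = self._drift_table(0.0)
        out = um.qc_drift_correct(table)
        assert np.allclose(out.areas.to_numpy(), table.areas.to_numpy())

    def test_exact_linear_series_collapses_to_value_at_mean_order(self):
        table = self._drift_table(5.0)
        out = um.qc_drift_correct(table)
        o_bar = np.mean(range(1, 9))
        expected = 100.0 + 5.0 * o_bar
        assert np.allclose(out.areas.to_numpy().ravel(), expected)
        # refit slope is zero to numerical tolerance
        y = out.areas.to_numpy().ravel()
        o = np.arange(1, 9, dtype=float)
        refit = np.polyfit(o, y, 1)[0]
        assert abs(refit) < 1e-10

    def test_idempotent(self, default_table):
        table, _ = default_table
        once = um.qc_drift_correct(table)
        twice = um.qc_drift_correct(once)
        assert np.allclose(once.areas.to_numpy(), twice.areas.to_numpy(), atol=1e-8)

    def test_reduces_qc_rsd_of_drifting_features(self):
        """Monte-Carlo: drift correction lowers QC RSD on drifted data."""
        wins = 0
        n_seeds = 60
        for seed in range(n_seeds):
            cfg = um.SimulationConfig(seed=seed, n_features=40, n_discriminant=0,
                                      n_blank_contaminated=0, n_unstable_qc=0,
                                      n_qc_missing=0, drift_fraction=1.0,
                                      drift_magnitude=0.01)
            table, _ = um.generate_feature_table(cfg)
            qc = table.qc_mask()
            before = table.areas.loc[qc].to_numpy()
            after = um.qc_drift_correct(table).areas.loc[qc].to_numpy()

            def rsd(M):
                return (M.std(axis=0, ddof=1) / M.mean(axis=0)).mean()

            wins += rsd(after) < rsd(before)
        assert wins / n_seeds > 0.9

    def test_too_few_qcs_rejected(self):
        table = _tiny_table(
            areas=[[1.0], [1.0], [2.0]],
            roles=[ROLE_QC, ROLE_QC, ROLE_SAMPLE],
            orders=[1, 2, 3],
        )
        with pytest.raises(PreprocessError, match=">= 3"):
            um.qc_drift_correct(table)


class TestQCPresenceRSD:
    def test_constant_series_retained(self):
        table = _tiny_table([[50.0], [50.0], [50.0]], [ROLE_QC] * 3, [1, 2, 3])
        out, removed = um.filter_qc_presence_rsd(table)
        assert removed == []
        assert out.n_features == 1

    def test_hand_computed_rsd_at_boundary(self):
        # QC areas {80, 100, 120}: sample sd (ddof=1) = 20, mean = 100,
        # RSD = 0.20 <= 0.25 -> retained
        table = _tiny_table([[80.0], [100.0], [120.0]], [ROLE_QC] * 3, [1, 2, 3])
        out, removed = um.filter_qc_presence_rsd(table, rsd_threshold=0.25)
        assert removed == []
        # tighten the threshold just below 0.20 and the feature drops
        _, removed = um.filter_qc_presence_rsd(table, rsd_threshold=0.199)
        assert removed == ["F0"]

    def test_zero_in_any_qc_drops_feature(self):
        table = _tiny_table([[0.0], [100.0], [100.0]], [ROLE_QC] * 3, [1, 2, 3])
        _, removed = um.filter_qc_presence_rsd(table)
        assert removed == ["F0"]

    def test_zero_mean_is_dropped_not_an_error(self):
        table = _tiny_table([[0.0], [0.0], [0.0]], [ROLE_QC] * 3, [1, 2, 3])
        _, removed = um.filter_qc_presence_rsd(table)
        assert removed == ["F0"]

    def test_matches_planted_truth(self, default_table):
        table, truth = default_table
        work, _ = um.filter_blank_and_carryover(table)
        work = um.qc_drift_correct(work)
        _, removed = um.filter_qc_presence_rsd(work)
        expected = truth.filtered_indices["qc-missing"] + truth.filtered_indices["qc-rsd"]
        assert sorted(removed) == sorted(expected)


class TestCreatinineNormalize:
    def test_direct_division(self):
        table = _tiny_table(
            areas=[[10.0], [20.0], [100.0], [100.0], [100.0]],
            roles=[ROLE_SAMPLE, ROLE_SAMPLE, ROLE_QC, ROLE_QC, ROLE_QC],
            orders=[1, 2, 3, 4, 5],
            creatinine=[5.0, 10.0, np.nan, np.nan, np.nan],
        )
        out = um.creatinine_normalize(table)
        assert np.allclose(out.areas.iloc[:2, 0].to_numpy(), [2.0, 2.0])
        # QC rows untouched
        assert np.allclose(out.areas.iloc[2:, 0].to_numpy(), 100.0)

    def test_common_factor_cancels_under_autoscaling(self, clean_table):
        clean, _, _ = clean_table
        X, _, _ = clean.sample_xy()
        # dividing every sample by the same constant leaves autoscaled X unchanged
        Z1 = um.autoscale_apply(X, um.autoscale_fit(X))
        Z2 = um.autoscale_apply(X / 3.7, um.autoscale_fit(X / 3.7))
        assert np.allclose(Z1, Z2)

    def test_low_creatinine_sample_gains_leverage(self):
        table = _tiny_table(
            areas=[[10.0], [10.0], [100.0], [100.0], [100.0]],
            roles=[ROLE_SAMPLE, ROLE_SAMPLE, ROLE_QC, ROLE_QC, ROLE_QC],
            orders=[1, 2, 3, 4, 5],
            creatinine=[5.0, 100.0, np.nan, np.nan, np.nan],
        )
        out = um.creatinine_normalize(table)
        ratio = out.areas.iloc[0, 0] / out.areas.iloc[1, 0]
        assert ratio == pytest.approx(20.0)


class TestAutoscale:
    def test_fit_apply_standardizes(self, null_xy):
        X, _ = null_xy
        Z = um.autoscale_apply(X, um.autoscale_fit(X))
        assert np.allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(Z.std(axis=0, ddof=1), 1.0)

    def test_row_at_training_mean_maps_to_zero(self, null_xy):
        X, _ = null_xy
        params = um.autoscale_fit(X)
        z = um.autoscale_apply(X.mean(axis=0)[None, :], params)
        assert np.allclose(z, 0.0, atol=1e-12)

    def test_constant_column_named_in_error(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        X[:, 1] = 4.0
        with pytest.raises(PreprocessError, match=r"\[1\]"):
            um.autoscale_fit(X)


class TestBlockScaleConcat:
    def test_single_block_unit_norm(self, null_xy):
        X, _ = null_xy
        out, norms = um.block_scale_concat([X])
        assert np.linalg.norm(out) == pytest.approx(1.0)
        assert np.allclose(out * norms[0], X)

    def test_two_identical_blocks(self, null_xy):
        X, _ = null_xy
        out, norms = um.block_scale_concat([X, X.copy()])
        assert norms[0] == pytest.approx(norms[1])
        assert np.linalg.norm(out) == pytest.approx(np.sqrt(2.0))

    def test_reduced_set_widths_concatenate(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(40, 22)), rng.normal(size=(40, 47))
        out, _ = um.block_scale_concat([a, b])
        assert out.shape == (40, 69)

    def test_row_mismatch_rejected(self):
        with pytest.raises(PreprocessError, match="row count"):
            um.block_scale_concat([np.ones((3, 2)), np.ones((4, 2))])


class TestChain:
    def test_survivors_match_truth_exactly(self, clean_table):
        clean, truth, report = clean_table
        removed = set(report["removed"]["blank"]) | set(report["removed"]["qc"])
        assert removed == truth.all_filtered()
        assert clean.n_features == 200 - len(truth.all_filtered())
        assert set(clean.feature_ids) & truth.all_filtered() == set()

    def test_rerunning_filters_is_noop(self, clean_table):
        clean, _, _ = clean_table
        work, removed = um.filter_qc_presence_rsd(clean)
        assert removed == []
        assert work.n_features == clean.n_features
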