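"""Labels, training, calibration, scoring, and the prior-ratio floor."""

import numpy as np
import pandas as pd
import pytest

from emscore import ems
from emscore.annotate import LabelRule
from tests.conftest import make_labeled_catalog


def pip_frame(rows):
    return pd.DataFrame([{"chrom": "chr1", "pip_a": a, "pip_b": b}
                         for a, b in rows])


class TestLabels:
    @pytest.mark.parametrize("pips,expected", [
        ((0.95, 0.92), "positive"),     # above threshold for both methods
        ((0.95, 0.50), "unlabeled"),    # fails the both-methods condition
        ((5e-5, 1e-6), "negative"),     # below the negative cut for both
        ((0.95, 5e-5), "unlabeled"),
    ])
    def test_rule_application(self, pips, expected):
        labels = ems.construct_labels(pip_frame([pips]))
        assert labels.iloc[0] == expected

    def test_out_of_range_pip_rejected(self):
        with pytest.raises(ValueError):
            ems.construct_labels(pip_frame([(1.2, 0.5)]))

    def test_rule_invariant(self):
        with pytest.raises(ValueError):
            LabelRule(pos_threshold=0.1, neg_threshold=0.5)


class TestFeatureSelection:
    def test_k_all_is_identity_ordered_by_importance(self):
        rng = np.random.default_rng(0)
        y = (rng.uniform(size=600) < 0.5).astype(int)
        X = pd.DataFrame({"informative": y + rng.normal(0, 0.3, 600),
                          "noise_a": rng.normal(size=600),
                          "noise_b": rng.normal(size=600)})
        names = ems.select_features(X, y, k=3, seed=1)
        assert sorted(names) == sorted(X.columns)
        assert names[0] == "informative"

    def test_informative_synthetic_score_ranks_high(self):
        cat = make_labeled_catalog(seed=21, n_genes=10, m_variants=100)
        y = cat.truth.astype(int)
        for seed in range(5):
            top = ems.select_features(cat.features, y, k=3, seed=seed,
                                      n_estimators=100)
            assert {"score_0", "score_1", "tss_distance"} & set(top)

    def test_invalid_k_rejected(self):
        X = pd.DataFrame({"a": [0.0, 1.0]})
        with pytest.raises(ValueError):
            ems.select_features(X, np.array([0, 1]), k=0)
        with pytest.raises(ValueError):
            ems.select_features(X, np.array([0, 1]), k=2)


class TestTuneAndTrain:
    def test_budget_one_fits_default_configuration(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"x": rng.normal(size=100)})
        y = (X["x"] > 0).astype(int).to_numpy()
        clf = ems.tune_and_train(X, y, search_budget=1, seed=0)
        assert clf.n_estimators == 100
        assert clf.search_trace_ == []

    def test_identical_seeds_choose_identical_hyperparameters(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(300, 4)), columns=list("abcd"))
        y = (X["a"] + rng.normal(0, 0.5, 300) > 0).astype(int).to_numpy()
        c1 = ems.tune_and_train(X, y, search_budget=6, seed=3)
        c2 = ems.tune_and_train(X, y, search_budget=6, seed=3)
        assert c1.get_params() == c2.get_params()

    def test_single_class_rejected(self):
        X = pd.DataFrame({"x": [0.0, 1.0]})
        with pytest.raises(ValueError):
            ems.tune_and_train(X, np.array([1, 1]))


class TestCalibration:
    def test_bin_without_positives_maps_to_zero(self):
        raw = np.concatenate([np.full(200, 0.1), np.full(200, 0.9)])
        labels = np.concatenate([np.zeros(200), np.ones(200)])
        tab = ems.calibrate_to_ems(raw, labels, n_bins=2)
        assert tab.ems_value[0] == 0.0

    def test_matched_prevalence_reduces_to_raw_fraction(self):
        rng = np.random.default_rng(4)
        raw = rng.uniform(size=2000)
        labels = (rng.uniform(size=2000) < raw).astype(int)
        pi_t = labels.mean()
        tab = ems.calibrate_to_ems(raw, labels, base_rate=pi_t, n_bins=5)
        monotone_f = np.maximum.accumulate(tab.pos_fraction)
        np.testing.assert_allclose(tab.ems_value, monotone_f, atol=1e-12)

    def test_prevalence_rescaling_formula(self):
        # f=0.8 at training prevalence 0.5 rescaled to base rate 0.001
        out = ems._prevalence_rescale(np.array([0.8]), pi=0.001, pi_t=0.5)
        np.testing.assert_allclose(out[0], 0.003988, atol=5e-7)

    def test_ems_monotone_after_pooling(self):
        rng = np.random.default_rng(5)
        raw = rng.uniform(size=3000)
        labels = (rng.uniform(size=3000) < 0.3 + 0.4 * raw).astype(int)
        tab = ems.calibrate_to_ems(raw, labels, n_bins=10)
        assert (np.diff(tab.ems_value) >= -1e-12).all()
        assert ((tab.ems_value >= 0) & (tab.ems_value <= 1)).all()

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            ems.calibrate_to_ems(np.array([]), np.array([]))


@pytest.fixture(scope="module")
def model(labeled_catalog):
    return ems.train_ems_model(labeled_catalog.pairs, labeled_catalog.features,
                               seed=5)


class TestScoring:
    def test_identical_features_identical_ems(self, model, labeled_catalog):
        fm = labeled_catalog.features
        dup = pd.concat([fm.iloc[[0]], fm.iloc[[0]]], ignore_index=True)
        out = ems.score_pairs(model, dup)
        assert out[0] == out[1]

    def test_fixed_tss_mode_ignores_true_distance(self, model, labeled_catalog):
        fm = labeled_catalog.features.iloc[:50].copy()
        out1 = ems.score_pairs(model, fm, fixed_tss_bp=200)
        fm2 = fm.copy()
        fm2["tss_distance"] = -fm2["tss_distance"] * 3 + 17
        out2 = ems.score_pairs(model, fm2, fixed_tss_bp=200)
        np.testing.assert_array_equal(out1, out2)

    def test_missing_feature_column_named_in_error(self, model, labeled_catalog):
        fm = labeled_catalog.features.drop(columns=["tss_distance"])
        with pytest.raises(ValueError, match="tss_distance"):
            ems.score_pairs(model, fm)

    def test_importance_report_shares_sum_to_one(self, model):
        per_feature, per_category = ems.feature_importance_report(model)
        assert per_feature.sum() == pytest.approx(1.0, abs=1e-12)
        assert per_category.sum() == pytest.approx(1.0, abs=1e-12)

    def test_held_out_auroc_with_informative_features(self, fresh_catalog, model):
        from sklearn.metrics import roc_auc_score

        scores = ems.score_pairs(model, fresh_catalog.features)
        labels = ems.construct_labels(fresh_catalog.pairs)
        mask = (labels != "unlabeled").to_numpy()
        au = roc_auc_score((labels[mask] == "positive").astype(int), scores[mask])
        assert au > 0.9

    def test_loco_metadata_recorded(self, labeled_catalog):
        model = ems.train_ems_model(labeled_catalog.pairs, labeled_catalog.features,
                                    holdout_chrom="chr1", seed=6)
        assert model.holdout_chrom == "chr1"

    def test_model_roundtrip(self, model, labeled_catalog, tmp_path):
        model.save(tmp_path / "model")
        loaded = ems.EMSModel.load(tmp_path / "model")
        fm = labeled_catalog.features.iloc[:20]
        np.testing.assert_allclose(ems.score_pairs(model, fm),
                                   ems.score_pairs(loaded, fm))


class TestPriorRatio:
    def test_floor_applied_as_max_over_ratio(self):
        out = ems.adjust_prior_ratio(np.array([1e-6, 5e-4, 2e-2]), max_ratio=100)
        np.testing.assert_allclose(out, [2e-4, 5e-4, 2e-2])
        assert out.max() / out.min() <= 100

    def test_within_ratio_unchanged(self):
        w = np.array([0.5, 1.0, 2.0])
        np.testing.assert_array_equal(ems.adjust_prior_ratio(w), w)

    def test_idempotent(self):
        rng = np.random.default_rng(6)
        w = rng.lognormal(0, 4, size=200)
        once = ems.adjust_prior_ratio(w)
        twice = ems.adjust_prior_ratio(once)
        np.testing.assert_array_equal(once, twice)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            ems.adjust_prior_ratio(np.array([0.0, 1.0]))
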