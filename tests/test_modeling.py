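"""Ensemble fitting, scoring, evaluation oracles, search, and attributions."""

import numpy as np
import pandas as pd
import pytest

from embryoscreen import (CohortConfig, DEFAULT_GB, DEFAULT_RF, auc_score,
                          evaluate, explain, fit_ensemble,
                          generate_feature_table, integrated_score,
                          predict_score, search_hyperparameters,
                          split_balanced_test)
from embryoscreen.modeling import (EnsemblePredictor, _Fold, ashap,
                                   gb_margin_attributions, make_estimator,
                                   rf_path_attributions)


class _StubModel:
    def __init__(self, p):
        self.p = p

    def predict_proba(self, X):
        return np.c_[1 - np.full(len(X), self.p), np.full(len(X), self.p)]


def _stub_ensemble(probs):
    folds = [_Fold(_StubModel(p), medians=np.zeros(1),
                   train_idx=np.array([0]), val_idx=np.array([1]), val_auc=0.5)
             for p in probs]
    return EnsemblePredictor(spec=DEFAULT_RF, subset=("f",), folds=folds, seed=0)


def _planted_table(seed=0, n_mc=60, n_lb=200, d=1.0):
    return generate_feature_table(
        CohortConfig(n_mc=n_mc, n_lb=n_lb, effect_map={"tPNa": d}, seed=seed))


class TestSpecs:
    def test_default_gb_is_six_stumps_at_quarter_rate(self):
        m = make_estimator(DEFAULT_GB)
        assert (m.n_estimators, m.max_depth, m.learning_rate) == (6, 1, 0.25)

    def test_default_rf_is_65_gini_trees_of_depth_3(self):
        m = make_estimator(DEFAULT_RF)
        assert (m.n_estimators, m.max_depth, m.criterion) == (65, 3, "gini")

    def test_invalid_spec_rejected(self):
        from embryoscreen import ModelSpec
        with pytest.raises(ValueError):
            ModelSpec(family="gb", n_trees=0, max_depth=1)
        with pytest.raises(ValueError):
            ModelSpec(family="gb", n_trees=5, max_depth=1, learning_rate=1.5)


class TestEnsemble:
    def test_constant_label_input_rejected(self):
        t = _planted_table()
        t["label"] = "LB"
        with pytest.raises(ValueError, match="both classes"):
            fit_ensemble(t, ["tPNa"], DEFAULT_GB, n_folds=5)

    def test_fold_count_and_validation_coverage(self):
        t = _planted_table(n_mc=40, n_lb=100)
        ens = fit_ensemble(t, ["tPNa", "tPNf"], DEFAULT_GB, n_folds=100, seed=1)
        assert len(ens.folds) == 100
        assert ens.validation_coverage  # every embryo validated at least once

    def test_predict_score_is_fold_mean(self):
        ens = _stub_ensemble([0.2, 0.6])
        X = pd.DataFrame({"f": [1.0, 2.0]})
        assert predict_score(ens, X) == pytest.approx([0.4, 0.4])

    def test_unanimous_folds_give_extreme_score(self):
        ens = _stub_ensemble([1.0, 1.0, 1.0])
        assert predict_score(ens, pd.DataFrame({"f": [0.0]}))[0] == pytest.approx(1.0)

    def test_score_averaging_is_monotone(self):
        lo = predict_score(_stub_ensemble([0.2, 0.6]), pd.DataFrame({"f": [0.0]}))[0]
        hi = predict_score(_stub_ensemble([0.2, 0.8]), pd.DataFrame({"f": [0.0]}))[0]
        assert hi > lo

    def test_integrated_classifier_averages_family_scores(self):
        X = pd.DataFrame({"f": [0.0]})
        s = integrated_score(_stub_ensemble([0.3]), _stub_ensemble([0.5]), X)
        assert s[0] == pytest.approx(0.4)

    def test_bundle_roundtrip_preserves_scores(self, tmp_path):
        t = _planted_table(n_mc=30, n_lb=90)
        ens = fit_ensemble(t, ["tPNa", "tPNf"], DEFAULT_GB, n_folds=5, seed=2)
        path = tmp_path / "bundle.joblib"
        ens.save(path)
        loaded = EnsemblePredictor.load(path)
        np.testing.assert_allclose(predict_score(loaded, t), predict_score(ens, t))
        assert loaded.subset == ens.subset and loaded.seed == ens.seed

    def test_missing_feature_raises_with_name(self):
        ens = _stub_ensemble([0.5])
        with pytest.raises(KeyError, match="f"):
            predict_score(ens, pd.DataFrame({"g": [1.0]}))


class TestBalancedSplit:
    def test_test_partition_balanced_and_disjoint(self):
        t = _planted_table(n_mc=50, n_lb=150)
        trainval, test = split_balanced_test(t["label"], n_per_class=20, seed=3)
        y_test = t["label"].iloc[test]
        assert (y_test == "MC").sum() == (y_test == "LB").sum() == 20
        assert len(np.intersect1d(trainval, test)) == 0
        assert len(trainval) + len(test) == len(t)


class TestEvaluate:
    def test_oracle_scores_give_perfect_auc(self):
        y = np.r_[np.ones(10), np.zeros(20)]
        rep = evaluate(y.astype(float), y)
        assert rep.auc == pytest.approx(1.0)
        cm = rep.confusion["precision_favoring"]
        assert cm["fp"] == 0 and cm["fn"] == 0

    def test_anti_oracle_scores_give_zero_auc(self):
        y = np.r_[np.ones(10), np.zeros(20)]
        assert evaluate(1 - y, y).auc == pytest.approx(0.0)

    def test_auc_equals_brute_force_concordance(self, rng):
        # Mann-Whitney equivalence: ties count one half
        for _ in range(100):
            y = rng.integers(0, 2, size=30)
            if y.min() == y.max():
                continue
            s = np.round(rng.uniform(0, 1, size=30), 1)  # coarse grid -> ties
            pos, neg = s[y == 1], s[y == 0]
            conc = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            brute = conc / (len(pos) * len(neg))
            assert auc_score(y, s) == pytest.approx(brute, abs=1e-12)

    def test_single_class_partition_is_an_error(self):
        with pytest.raises(ValueError, match="single-class"):
            evaluate(np.array([0.2, 0.8]), np.array([1, 1]))

    def test_confusion_counts_sum_to_partition_size(self, rng):
        y = rng.integers(0, 2, size=50)
        y[:5] = 1
        y[5:10] = 0
        rep = evaluate(rng.uniform(size=50), y)
        for cm in rep.confusion.values():
            assert cm["tp"] + cm["fp"] + cm["fn"] + cm["tn"] == 50
        assert (rep.confusion["precision_favoring"]["threshold"]
                >= rep.confusion["sensitivity_favoring"]["threshold"])

    def test_validation_and_test_auc_agree_on_synthetic_cohorts(self):
        # the Monte-Carlo scheme must not overfit: out-of-fold validation AUC
        # tracks the generalization AUC measured on a large fresh cohort
        diffs = []
        feats = ["tPNa", "tPNf", "t2"]
        effect = {f: d for f, d in zip(feats, (0.8, 0.6, 0.5))}
        for seed in range(3):
            t = generate_feature_table(CohortConfig(
                n_mc=96, n_lb=368, effect_map=effect, seed=900 + seed))
            big = generate_feature_table(CohortConfig(
                n_mc=1000, n_lb=1000, effect_map=effect, seed=5000 + seed))
            ens = fit_ensemble(t, feats, DEFAULT_GB, n_folds=30, seed=seed)
            test_auc = evaluate(predict_score(ens, big), big["label"]).auc
            diffs.append(abs(ens.validation_auc(t["label"]) - test_auc))
        assert np.mean(diffs) <= 0.05


class TestSearch:
    def test_zero_budget_returns_defaults(self):
        spec, trace = search_hyperparameters(_planted_table(), ["tPNa"], "rf",
                                             budget=0)
        assert spec == DEFAULT_RF and trace == []

    def test_budget_one_returns_the_single_sampled_spec(self):
        t = _planted_table(n_mc=30, n_lb=90)
        spec, trace = search_hyperparameters(t, ["tPNa"], "gb", budget=1,
                                             seed=2, n_folds=5)
        assert len(trace) == 1 and spec == trace[0][0]

    def test_collapsed_ranges_return_that_point(self):
        t = _planted_table(n_mc=30, n_lb=90)
        point = {"learning_rate": (0.25, 0.25), "min_child_weight": (30, 30),
                 "max_depth": (2, 2), "subsample": (1.0, 1.0),
                 "colsample_bytree": (0.4, 0.4), "n_trees": (6, 6)}
        spec, _ = search_hyperparameters(t, ["tPNa"], "gb", budget=3, seed=3,
                                         n_folds=5, ranges=point)
        assert (spec.n_trees, spec.max_depth, spec.learning_rate) == (6, 2, 0.25)

    def test_search_not_materially_worse_than_defaults_when_separable(self):
        # cohort large enough that the min_child_weight range is satisfiable
        y = np.r_[np.ones(300), np.zeros(700)]
        t = pd.DataFrame({"tPNa": y * 4.0,
                          "label": np.where(y == 1, "MC", "LB")})
        best, trace = search_hyperparameters(t, ["tPNa"], "gb", budget=5,
                                             seed=4, n_folds=6)
        default_auc = fit_ensemble(t, ["tPNa"], DEFAULT_GB, n_folds=6,
                                   seed=4).fold_aucs.mean()
        assert max(s for _, s in trace) >= default_auc - 0.02


class TestExplain:
    def test_additivity_of_both_attribution_routes(self, rng):
        X = rng.normal(size=(40, 3))
        y = (X[:, 0] + rng.normal(0, 0.5, 40) > 0).astype(int)
        rf = make_estimator(DEFAULT_RF, seed=0).fit(X, y)
        contrib, base = rf_path_attributions(rf, X)
        recon = base + contrib.sum(axis=1)
        assert np.abs(recon - rf.predict_proba(X)[:, 1]).max() < 1e-6
        gb = make_estimator(DEFAULT_GB, seed=0).fit(X, y)
        contrib, base = gb_margin_attributions(gb, X)
        import xgboost as xgb
        margin = gb.get_booster().predict(xgb.DMatrix(X), output_margin=True)
        assert np.abs(base + contrib.sum(axis=1) - margin).max() < 1e-5

    def test_constant_model_has_zero_attributions(self, rng):
        X = np.zeros((30, 2))  # nothing to split on
        y = np.r_[np.ones(10), np.zeros(20)].astype(int)
        rf = make_estimator(DEFAULT_RF, seed=0).fit(X, y)
        contrib, _ = rf_path_attributions(rf, X)
        assert np.abs(contrib).max() == 0.0
        gb = make_estimator(DEFAULT_GB, seed=0).fit(X, y)
        contrib, _ = gb_margin_attributions(gb, X)
        assert np.abs(contrib).max() < 1e-12

    def test_all_misclassified_gives_nonpositive_ashap(self, rng):
        attr = rng.normal(size=(25, 4))
        vals = ashap(attr, np.zeros(25, dtype=bool))
        assert (vals <= 0).all()

    def test_explain_end_to_end(self):
        t = _planted_table(seed=10, n_mc=40, n_lb=120)
        feats = ["tPNa", "tPNf"]
        ens = {"gb": fit_ensemble(t, feats, DEFAULT_GB, n_folds=5, seed=1),
               "rf": fit_ensemble(t, feats, DEFAULT_RF, n_folds=5, seed=1)}
        ex = explain(ens, t)
        assert set(ex.attributions) == {"gb", "rf"}
        assert ex.attributions["rf"].shape == (len(t), 2)
        # planted feature separates classes in the KS summary
        assert ex.ks_summary.loc["tPNa", "ks_p"] < 0.01
        # informative feature dominates aSHAP for both families
        for fam in ("rf", "gb"):
            assert ex.ashap[fam]["tPNa"] > ex.ashap[fam]["tPNf"]
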