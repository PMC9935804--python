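"""Screening cascade stages: distances, grid, CV scoring, wrapper selection."""

import numpy as np
import pandas as pd
import pytest

from embryoscreen import (CohortConfig, backward_eliminate,
                          build_threshold_grid, forward_select_two_step,
                          generate_feature_table, mc_cv_auc, qualified_subsets,
                          rank_and_prune, statistical_distances)
from embryoscreen.screening import SubsetScore, ThresholdGrid


def _table(cols: dict, labels: np.ndarray) -> pd.DataFrame:
    df = pd.DataFrame(cols)
    df["label"] = np.where(labels == 1, "MC", "LB")
    return df


class TestDistances:
    def test_identical_samples_have_zero_distance(self, rng):
        x = rng.normal(size=200)
        t = _table({"f": np.r_[x, x]}, np.r_[np.ones(200), np.zeros(200)])
        d = statistical_distances(t)
        assert d.loc["f", "ks_stat"] == pytest.approx(0.0, abs=1e-12)
        assert d.loc["f", "kl"] == pytest.approx(0.0, abs=1e-9)

    def test_kl_matches_gaussian_closed_form(self, rng):
        # KL(N(1,1) || N(0,1)) = 1/2 nat
        n = 100_000
        t = _table({"f": np.r_[rng.normal(1, 1, n), rng.normal(0, 1, n)]},
                   np.r_[np.ones(n), np.zeros(n)])
        d = statistical_distances(t)
        assert d.loc["f", "kl"] == pytest.approx(0.5, abs=0.05)

    def test_disjoint_support_is_maximally_separated(self, rng):
        t = _table({"f": np.r_[rng.uniform(10, 11, 80), rng.uniform(0, 1, 80)]},
                   np.r_[np.ones(80), np.zeros(80)])
        d = statistical_distances(t)
        assert d.loc["f", "ks_stat"] == pytest.approx(1.0)
        assert d.loc["f", "ks_p"] < 1e-6

    def test_constant_feature(self):
        t = _table({"f": np.full(60, 3.14)}, np.r_[np.ones(20), np.zeros(40)])
        d = statistical_distances(t)
        assert d.loc["f", "ks_p"] == pytest.approx(1.0)
        assert d.loc["f", "kl"] == pytest.approx(0.0)

    def test_sparse_feature_skipped(self):
        col = np.full(60, np.nan)
        col[0] = 1.0  # a single MC value
        t = _table({"f": col}, np.r_[np.ones(20), np.zeros(40)])
        d = statistical_distances(t)
        assert bool(d.loc["f", "skipped"]) and np.isnan(d.loc["f", "kl"])


class TestGrid:
    def test_grid_shape_and_spacing(self):
        g = build_threshold_grid(0.05, 0.25)
        assert len(g.ks) == 6 and len(g.kl) == 3
        assert np.allclose(np.diff(g.ks), 0.05)
        assert np.allclose(np.diff(g.kl), -0.1)

    def test_invalid_spacing_rejected(self):
        with pytest.raises(ValueError):
            ThresholdGrid(ks=(0.05,) * 6, kl=(0.25, 0.15, 0.05))

    def test_always_18_subsets_even_when_empty(self):
        d = pd.DataFrame({"ks_p": [0.9, 0.8], "kl": [0.0, 0.01]},
                         index=["a", "b"])
        subs = qualified_subsets(d, build_threshold_grid())
        assert len(subs) == 18
        assert all(len(v) == 0 for v in subs.values())  # flagged empty

    def test_monotone_inclusion(self, rng):
        d = pd.DataFrame({"ks_p": rng.uniform(0, 0.5, 100),
                          "kl": rng.uniform(0, 0.4, 100)},
                         index=[f"f{i}" for i in range(100)])
        subs = qualified_subsets(d, build_threshold_grid())
        for j in (1, 2, 3):
            for i in range(1, 6):
                assert set(subs[(i, j)]) <= set(subs[(i + 1, j)])
        for i in range(1, 7):
            for j in (1, 2):
                assert set(subs[(i, j)]) <= set(subs[(i, j + 1)])


class TestMcCvAuc:
    def test_perfectly_separating_feature(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        t = _table({"f": y * 10.0}, y)
        s = mc_cv_auc(t, ["f"], n_folds=20, seed=1)
        assert s.mean_auc["rf"] >= 0.99 and s.mean_auc["gb"] >= 0.99

    def test_null_feature_scores_at_chance(self, rng):
        # one MCCV mean is itself noisy (folds are correlated), so the null
        # level is estimated across independent cohorts
        y = np.r_[np.ones(80), np.zeros(320)]
        means = {"rf": [], "gb": []}
        for seed in range(5):
            t = _table({"f": rng.normal(size=400)}, y)
            s = mc_cv_auc(t, ["f"], n_folds=20, seed=seed)
            for fam in means:
                means[fam].append(s.mean_auc[fam])
        for fam, vals in means.items():
            assert np.mean(vals) == pytest.approx(0.5, abs=0.05)

    def test_requested_fold_count_is_recorded(self, rng):
        y = np.r_[np.ones(15), np.zeros(35)]
        t = _table({"f": rng.normal(size=50)}, y)
        s = mc_cv_auc(t, ["f"], n_folds=100, seed=3)
        assert all(len(a) == 100 for a in s.fold_aucs.values())

    def test_empty_subset_and_tiny_classes_rejected(self, rng):
        y = np.r_[np.ones(5), np.zeros(45)]
        t = _table({"f": rng.normal(size=50)}, y)
        with pytest.raises(ValueError):
            mc_cv_auc(t, [], n_folds=5)
        with pytest.raises(ValueError):
            mc_cv_auc(t, ["f"], n_folds=5)


class TestRankAndPrune:
    def _scores(self, feats, imps):
        return SubsetScore(features=tuple(feats),
                           mean_auc={"rf": 0.7, "gb": 0.7},
                           fold_aucs={"rf": np.array([0.7]), "gb": np.array([0.7])},
                           importances={"rf": np.asarray(imps),
                                        "gb": np.asarray(imps)})

    def test_duplicate_column_has_unit_correlation(self, rng):
        x = rng.normal(size=80)
        t = _table({"tPNa": x, "tPNf": x.copy(), "t2": rng.normal(size=80)},
                   np.r_[np.ones(30), np.zeros(50)])
        scores = {(1, 1): self._scores(["tPNa", "tPNf", "t2"], [0.5, 0.3, 0.2])}
        res = rank_and_prune(scores, t, top_k=3)
        p = res.pearson
        assert p.loc["tPNa", "tPNf"] == pytest.approx(1.0)
        assert np.allclose(p.to_numpy(), p.to_numpy().T)
        assert np.allclose(np.diag(p.to_numpy()), 1.0)

    def test_planted_feature_ranked_first(self, rng):
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cfg = CohortConfig(n_mc=300, n_lb=300, effect_map={"tPNa": 1.0},
                               seed=500 + seed)
            t = generate_feature_table(cfg)
            feats = ["tPNa"] + [f"t{k}" for k in range(2, 9)] + ["tPNf"]
            s = mc_cv_auc(t, feats, n_folds=8, seed=seed)
            res = rank_and_prune({(1, 1): s}, t, top_k=3)
            hits += res.top_features[0] == "tPNa"
        assert hits >= 0.9 * n_seeds


class TestWrappers:
    def _planted_table(self, seed, extra=None):
        effect = {"tPNa": 1.2}
        if extra:
            effect.update(extra)
        cfg = CohortConfig(n_mc=60, n_lb=140, effect_map=effect, seed=seed)
        return generate_feature_table(cfg)

    def test_backward_series_sizes_strictly_decreasing(self):
        t = self._planted_table(3)
        feats = ["tPNa", "tPNf", "t2", "t3", "t4", "t5", "t6", "t7"]
        series = backward_eliminate(feats, t, n_folds=4, seed=3)
        sizes = [len(s.features) for s in series]
        assert sizes == list(range(8, 0, -1))

    def test_singleton_returned_unchanged(self):
        t = self._planted_table(4)
        series = backward_eliminate(["tPNa"], t, n_folds=4, seed=4)
        assert len(series) == 1 and series[0].features == ("tPNa",)

    def test_duplicate_informative_feature_eliminated_early(self):
        hits = 0
        n_seeds = 5
        for seed in range(n_seeds):
            # all features informative; tPNf is an exact duplicate of tPNa,
            # so one copy is the only removal that costs no signal
            t = self._planted_table(600 + seed, extra={"t2": 0.8, "t3": 0.8})
            t["tPNf"] = t["tPNa"]
            series = backward_eliminate(["tPNa", "tPNf", "t2", "t3"], t,
                                        n_folds=8, seed=seed)
            removed = [set(series[i].features) - set(series[i + 1].features)
                       for i in range(2)]
            gone = set().union(*removed)
            hits += bool(gone & {"tPNa", "tPNf"})
        assert hits >= 0.8 * n_seeds

    def test_forward_empty_pool_unchanged(self):
        t = self._planted_table(5)
        final, log = forward_select_two_step(["tPNa"], [], t, n_folds=4, seed=5)
        assert final == ("tPNa",) and log == []

    def test_forward_recovers_strong_feature_in_first_cycle(self):
        hits = 0
        n_seeds = 5
        for seed in range(n_seeds):
            t = self._planted_table(700 + seed, extra={"t8": 1.5})
            final, log = forward_select_two_step(
                ["tPNa"], ["t2", "t3", "t4", "t8"], t, n_folds=6, seed=seed)
            hits += log[0]["accepted"] and "t8" in log[0]["pair"]
        assert hits >= 0.8 * n_seeds

    def test_forward_tiebreak_deterministic(self):
        t = self._planted_table(6)
        a = forward_select_two_step(["tPNa"], ["t2", "t3", "t4"], t,
                                    n_folds=4, seed=6)
        b = forward_select_two_step(["tPNa"], ["t4", "t3", "t2"], t,
                                    n_folds=4, seed=6)
        assert a == b  # pool order cannot matter: catalog-index ordering rules
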