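"""Random-forest ranking, pooling and incremental OOB selection."""

import numpy as np
import pandas as pd
import pytest

from lateralize import (FeatureTable, RFConfig, incremental_oob_selection,
                        pool_and_rerank, rank_subcategory, rf_gini_importance,
                        select_features)
from lateralize.selection import _shortest_prefix_argmin

from conftest import toy_feature_table


class TestGiniImportance:
    def test_label_feature_ranks_first(self):
        """A feature equal to the class label beats 99 noise features in
        nearly every seed."""
        wins = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = np.array([0] * 10 + [1] * 10)
            X = rng.standard_normal((20, 100))
            X[:, 37] = y
            imp = rf_gini_importance(X, y, n_trees=200, seed=seed)
            wins += np.argmax(imp) == 37
        assert wins >= 95

    def test_no_stable_winner_under_permuted_labels(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((20, 40))
        y = np.array([0] * 10 + [1] * 10)
        mean_imp = np.zeros(40)
        for rep in range(50):
            y_perm = rng.permutation(y)
            mean_imp += rf_gini_importance(X, y_perm, n_trees=50, seed=rep)
        mean_imp /= 50
        assert mean_imp.max() <= 3 * np.median(mean_imp)

    def test_constant_feature_zero_importance(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((20, 10))
        X[:, 4] = 2.5
        y = np.array([0] * 10 + [1] * 10)
        imp = rf_gini_importance(X, y, n_trees=100, seed=0)
        assert imp[4] == 0.0

    def test_single_class_raises(self):
        X = np.random.default_rng(0).standard_normal((10, 5))
        with pytest.raises(ValueError):
            rf_gini_importance(X, np.zeros(10), n_trees=10, seed=0)


class TestRankSubcategory:
    def test_small_subcategory_returned_whole(self, rng):
        table = toy_feature_table(rng, n_per_subcat=30)
        names = rank_subcategory(table, "ALFF", n_reps=2, top_k=50,
                                 n_trees=20, seed=0)
        assert len(names) == 30
        assert set(names) == set(table.features_of("ALFF"))

    def test_planted_feature_ranked_first(self):
        wins = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            table = toy_feature_table(rng, n_subjects=20, n_per_subcat=20,
                                      informative={"reho_f3": 3.0})
            names = rank_subcategory(table, "ReHo", n_reps=3, top_k=5,
                                     n_trees=50, seed=seed)
            wins += names[0] == "reho_f3"
        assert wins >= 38

    def test_deterministic_given_seed(self, rng):
        table = toy_feature_table(rng)
        a = rank_subcategory(table, "FC", n_reps=2, top_k=4, n_trees=20, seed=7)
        b = rank_subcategory(table, "FC", n_reps=2, top_k=4, n_trees=20, seed=7)
        assert a == b

    def test_empty_subcategory_empty_list(self, rng):
        table = toy_feature_table(rng)
        keep = [n for n in table.values.columns if not n.startswith("fc_")]
        sub = table.select_features(keep)
        assert rank_subcategory(sub, "FC", seed=0) == []


class TestPooling:
    def test_full_top50_lists_pool_to_300(self, rng):
        """Six disjoint 50-feature rankings pool to exactly 300."""
        table = toy_feature_table(rng, n_subjects=12, n_per_subcat=60)
        rankings = [rank_subcategory(table, sc, n_reps=1, top_k=50,
                                     n_trees=10, seed=i)
                    for i, sc in enumerate(
                        ["ALFF", "fALFF", "ReHo", "FC", "NMglobal", "NMnodal"])]
        pooled = pool_and_rerank(rankings, table, n_reps=1, n_trees=10, seed=9)
        assert len(pooled) == 300

    def test_short_subcategories_sum(self, rng):
        table = toy_feature_table(rng, n_per_subcat=6)
        rankings = [rank_subcategory(table, sc, n_reps=1, top_k=50,
                                     n_trees=10, seed=i)
                    for i, sc in enumerate(
                        ["ALFF", "fALFF", "ReHo", "FC", "NMglobal", "NMnodal"])]
        pooled = pool_and_rerank(rankings, table, n_reps=1, n_trees=10, seed=9)
        assert len(pooled) == 6 * 6

    def test_duplicate_names_rejected(self, rng):
        table = toy_feature_table(rng)
        with pytest.raises(ValueError, match="duplicate"):
            pool_and_rerank([["alff_f0"], ["alff_f0"]], table, n_reps=1,
                            n_trees=10, seed=0)

    def test_planted_feature_reaches_pooled_top(self):
        hits = 0
        for seed in range(30):
            rng = np.random.default_rng(1000 + seed)
            table = toy_feature_table(rng, n_subjects=20, n_per_subcat=15,
                                      informative={"nmnodal_f2": 3.0})
            rankings = [rank_subcategory(table, sc, n_reps=2, top_k=10,
                                         n_trees=30, seed=seed + 10 * i)
                        for i, sc in enumerate(
                            ["ALFF", "fALFF", "ReHo", "FC", "NMglobal",
                             "NMnodal"])]
            pooled = pool_and_rerank(rankings, table, n_reps=2, n_trees=30,
                                     seed=seed)
            hits += "nmnodal_f2" in pooled[:10]
        assert hits >= 27


class TestIncrementalOob:
    def test_shortest_prefix_tie_break(self):
        assert _shortest_prefix_argmin([0.3, 0.3, 0.3]) == 1
        assert _shortest_prefix_argmin([0.5, 0.2, 0.2, 0.4]) == 2
        assert _shortest_prefix_argmin([0.4, 0.1]) == 2

    def test_perfect_feature_selects_one(self):
        """A perfectly separating first-ranked feature wins alone in almost
        every replicate."""
        wins = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            table = toy_feature_table(rng, n_subjects=20, n_per_subcat=3,
                                      informative={"alff_f0": 6.0})
            pooled = ["alff_f0"] + [n for n in table.values.columns
                                    if n != "alff_f0"][:9]
            res = incremental_oob_selection(pooled, table, n_trees=60,
                                            seed=seed)
            wins += res.n_selected == 1
        assert wins >= 36

    def test_selected_is_prefix_and_minimises_trace(self, rng):
        table = toy_feature_table(rng, n_subjects=12)
        pooled = list(table.values.columns[:8])
        res = incremental_oob_selection(pooled, table, n_trees=30, seed=3)
        assert res.selected == res.pooled_ranking[: res.n_selected]
        assert res.oob_trace[res.n_selected - 1] == res.oob_trace.min()
        first_min = int(np.argmin(res.oob_trace)) + 1
        assert res.n_selected == first_min
        assert 1 <= res.n_selected <= len(pooled)

    def test_empty_ranking_rejected(self, rng):
        with pytest.raises(ValueError):
            incremental_oob_selection([], toy_feature_table(rng), seed=0)


class TestSelectFeatures:
    def test_rerun_equality(self, rng):
        table = toy_feature_table(rng, n_subjects=12, n_per_subcat=8,
                                  informative={"fc_f1": 2.0})
        cfg = RFConfig(n_trees=20, n_reps=2, top_k=4)
        a = select_features(table, rf=cfg, seed=5)
        b = select_features(table, rf=cfg, seed=5)
        assert a.selected == b.selected
        assert np.array_equal(a.oob_trace, b.oob_trace)

    def test_zero_variance_features_dropped(self, rng):
        table = toy_feature_table(rng, n_subjects=12, n_per_subcat=4)
        table.values["alff_f0"] = 1.0  # constant
        cfg = RFConfig(n_trees=20, n_reps=2, top_k=4)
        res = select_features(table, rf=cfg, seed=1)
        assert "alff_f0" in res.dropped
        assert "alff_f0" not in res.pooled_ranking
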