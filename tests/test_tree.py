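"""Correlation filter, stratified split, CART induction, ROC/AUC, recovery."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

import toposcreen as ts
from toposcreen import tree as tr


def make_xy(rng, n=120, k=3, sep=None):
    X = pd.DataFrame(rng.normal(size=(n, k)),
                     columns=[f"f{i}" for i in range(k)])
    if sep is None:
        y = rng.random(n) < 0.4
    else:
        y = X[sep] > 0
    labels = pd.Series(np.where(y, "high", "low"), index=X.index)
    return X, labels


class TestFilterCorrelated:
    def test_identical_column_dropped(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=50)
        X = pd.DataFrame({"a": a, "b": a.copy(), "c": rng.normal(size=50)})
        kept, log = tr.filter_correlated(X)
        assert list(kept.columns) == ["a", "c"]
        assert log[0]["dropped"] == "b" and log[0]["partner"] == "a"

    def test_independent_columns_survive(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(200, 5)),
                         columns=list("abcde"))
        kept, log = tr.filter_correlated(X)
        assert list(kept.columns) == list("abcde") and not log

    def test_zero_variance_dropped_with_log(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"a": np.ones(30), "b": rng.normal(size=30),
                          "c": rng.normal(size=30)})
        kept, log = tr.filter_correlated(X)
        assert "a" not in kept.columns
        assert any(e["dropped"] == "a" and e["reason"] == "zero variance"
                   for e in log)

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=100)
        X = pd.DataFrame({"a": a, "b": a + rng.normal(scale=0.05, size=100),
                          "c": rng.normal(size=100)})
        once, _ = tr.filter_correlated(X)
        twice, log2 = tr.filter_correlated(once)
        assert list(once.columns) == list(twice.columns) and not log2

    def test_fcpn01_dropped_against_fcp(self, small_descriptors):
        """FCPN01 is FCP plus bounded noise, so the correlation filter
        removes it in favour of the canonical-order-earlier FCP."""
        from toposcreen.pipeline import build_feature_table
        feats = build_feature_table(small_descriptors)
        kept, log = tr.filter_correlated(feats)
        assert "fcp" in kept.columns
        assert any(e["dropped"] == "fcpn01" and e["partner"] == "fcp"
                   for e in log)


class TestSplitTrainTest:
    def test_stratified_counts(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(100, 2)), columns=["a", "b"])
        y = pd.Series(["high"] * 40 + ["low"] * 60, index=X.index)
        train, test = tr.split_train_test(X, y, seed=0)
        assert (y.loc[train] == "high").sum() == 30
        assert (y.loc[train] == "low").sum() == 45

    def test_partition_exact_and_deterministic(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(57, 2)), columns=["a", "b"])
        y = pd.Series(np.where(rng.random(57) < 0.4, "high", "low"),
                      index=X.index)
        t1 = tr.split_train_test(X, y, seed=3)
        t2 = tr.split_train_test(X, y, seed=3)
        assert list(t1[0]) == list(t2[0]) and list(t1[1]) == list(t2[1])
        assert set(t1[0]) | set(t1[1]) == set(X.index)
        assert not set(t1[0]) & set(t1[1])
        assert abs(len(t1[0]) - 0.75 * 57) <= 1

    def test_small_class_rejected(self):
        X = pd.DataFrame({"a": range(10)}, dtype=float)
        y = pd.Series(["high"] * 3 + ["low"] * 7, index=X.index)
        with pytest.raises(ValueError):
            tr.split_train_test(X, y)


def oracle_root(X, y, min_leaf):
    """Brute-force exhaustive search over all features and midpoints."""
    n = len(y)
    best = None
    for f in range(X.shape[1]):
        vals = np.unique(X[:, f])
        for a, b in zip(vals[:-1], vals[1:]):
            thr = (a + b) / 2
            left = X[:, f] < thr
            nl, nr = int(left.sum()), int(n - left.sum())
            if nl < min_leaf or nr < min_leaf:
                continue

            def gini(mask):
                p = y[mask].mean()
                return 2 * p * (1 - p)

            w = (nl * gini(left) + nr * gini(~left)) / n
            if best is None or w < best[2] - 1e-12:
                best = (f, thr, w)
    return best


class TestFitTree:
    def test_perfect_feature_gives_depth_one(self):
        rng = np.random.default_rng(7)
        X, y = make_xy(rng, n=100, sep="f1")
        model = tr.fit_tree(X, y, seed=0)
        assert model.depth() == 1
        assert model.root.feature == "f1"
        assert -0.5 < model.root.threshold < 0.5

    def test_root_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(8)
        checked = 0
        while checked < 50:
            n = int(rng.integers(30, 200))
            k = int(rng.integers(1, 5))
            X = rng.normal(size=(n, k)).round(2)
            y = rng.random(n) < rng.uniform(0.2, 0.5)
            if y.all() or not y.any():
                continue
            expected = oracle_root(X, y, 8)
            got = tr.best_split(X, y, 8)
            assert (expected is None) == (got is None)
            if expected is not None:
                assert got[0] == expected[0]
                assert got[1] == pytest.approx(expected[1], abs=1e-12)
            checked += 1

    def test_recovers_planted_two_level_structure(self):
        """Labels built from a coverage-then-circle-diameter rule yield a
        tree splitting on coverage at the root, circle diameter below."""
        rng = np.random.default_rng(9)
        n = 600
        X = pd.DataFrame({
            "fcp": rng.uniform(0, 0.6, size=n),
            "circ_diam": rng.uniform(0, 30, size=n),
        })
        p = np.where((X["fcp"] >= 0.256) & (X["circ_diam"] >= 8.293), 0.9, 0.1)
        y = pd.Series(np.where(rng.random(n) < p, "high", "low"), index=X.index)
        model = tr.fit_tree(X, y, seed=1)
        assert model.root.feature == "fcp"
        assert {model.root.left.feature, model.root.right.feature} & {"circ_diam"}

    def test_noise_prunes_to_single_leaf(self):
        """Null labels at the screen's hit-class imbalance (~30% high):
        cross-validated cost-complexity pruning collapses the tree."""
        single = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for seed in range(10):
                rng = np.random.default_rng(seed)
                X = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
                y = pd.Series(np.where(rng.random(200) < 0.3, "high", "low"),
                              index=X.index)
                model = tr.fit_tree(X, y, seed=seed)
                single += model.n_leaves() == 1
        assert single >= 9

    def test_single_class_single_leaf(self):
        X = pd.DataFrame({"a": np.arange(20, dtype=float)})
        y = pd.Series(["high"] * 20, index=X.index)
        with pytest.warns(UserWarning, match="single-class"):
            model = tr.fit_tree(X, y, seed=0)
        assert model.n_leaves() == 1

    def test_pruning_monotone_in_cp(self):
        rng = np.random.default_rng(10)
        X, y = make_xy(rng, n=200, k=4)
        leaves = []
        for cp in [0.0, 0.005, 0.01, 0.02, 0.05, 0.2]:
            model = tr.fit_tree(X, y, seed=0, cp=cp)
            leaves.append(model.n_leaves())
        assert all(a >= b for a, b in zip(leaves, leaves[1:]))

    def test_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(11)
        X, y = make_xy(rng, n=100, sep="f0")
        model = tr.fit_tree(X, y, seed=0)
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = tr.TreeModel.from_json(path)
        assert loaded.root.to_dict() == model.root.to_dict()


class TestPredict:
    def test_pure_leaf_scores_one(self):
        rng = np.random.default_rng(12)
        X, y = make_xy(rng, n=100, sep="f0")
        model = tr.fit_tree(X, y, seed=0)
        high_row = pd.DataFrame({"f0": [3.0], "f1": [0.0], "f2": [0.0]})
        assert tr.predict(model, high_row).iloc[0] == 1.0

    def test_single_leaf_scores_prevalence(self):
        X = pd.DataFrame({"a": np.arange(20, dtype=float)})
        y = pd.Series(["high"] * 5 + ["low"] * 15, index=X.index)
        model = tr.fit_tree(X, y, cp=1.0, seed=0)
        assert model.n_leaves() == 1
        scores = tr.predict(model, X)
        assert (scores == 0.25).all()

    def test_row_order_invariance(self):
        rng = np.random.default_rng(13)
        X, y = make_xy(rng, n=80, sep="f1")
        model = tr.fit_tree(X, y, seed=0)
        perm = X.sample(frac=1.0, random_state=1)
        assert tr.predict(model, perm).sort_index().equals(
            tr.predict(model, X).sort_index())

    def test_missing_feature_named(self):
        rng = np.random.default_rng(14)
        X, y = make_xy(rng, n=80, sep="f0")
        model = tr.fit_tree(X, y, seed=0)
        with pytest.raises(ValueError, match="f0"):
            tr.predict(model, pd.DataFrame({"f1": [1.0], "f2": [2.0]}))


class TestRocAuc:
    def test_perfect_separation(self):
        r = tr.roc_auc([0.1, 0.2, 0.8, 0.9], ["low", "low", "high", "high"])
        assert r["auc"] == 1.0

    def test_all_tied_scores(self):
        r = tr.roc_auc([0.5] * 10, ["high"] * 4 + ["low"] * 6)
        assert r["auc"] == 0.5

    def test_matches_rank_statistic_oracle(self):
        rng = np.random.default_rng(15)
        for _ in range(20):
            n = int(rng.integers(10, 500))
            scores = rng.integers(0, 6, size=n).astype(float)
            y = rng.random(n) < 0.5
            if y.all() or not y.any():
                continue
            r = tr.roc_auc(scores, np.where(y, "high", "low"))
            assert abs(r["auc"] - roc_auc_score(y, scores)) < 1e-12
            assert abs(np.trapezoid(r["tpr"], r["fpr"]) - r["auc"]) < 1e-12

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(16)
        scores = rng.random(2000)
        y = np.where(rng.random(2000) < 0.5, "high", "low")
        r = tr.roc_auc(scores, y)
        assert 0.47 <= r["auc"] <= 0.53

    def test_one_class_flagged(self):
        with pytest.warns(UserWarning, match="one-class"):
            r = tr.roc_auc([0.1, 0.9], ["high", "high"])
        assert not r["defined"] and math.isnan(r["auc"])


class TestEvaluateRecovery:
    def test_single_leaf_not_recovered(self):
        model = tr.TreeModel(root=tr.TreeNode(counts=(5, 5)),
                             feature_names=["fcp"])
        rep = tr.evaluate_recovery(model, {"fcp"})
        assert not rep["recovered"]

    def test_root_feature_recovered(self):
        root = tr.TreeNode(counts=(10, 10), feature="fcp", threshold=0.25,
                           left=tr.TreeNode(counts=(10, 0)),
                           right=tr.TreeNode(counts=(0, 10)))
        model = tr.TreeModel(root=root, feature_names=["fcp"])
        rep = tr.evaluate_recovery(model, {"fcp", "line_len"}, auc=0.9)
        assert rep["recovered"] and rep["auc"] == 0.9
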