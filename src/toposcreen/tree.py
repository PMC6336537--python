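"""Binary classification trees for descriptor -> hit-class prediction.

The modelling stage follows the screen's protocol: eliminate highly
correlated features (pairwise Pearson r^2 > 0.75), split designs 75/25
stratified by class, induce a CART-style binary tree (Gini impurity,
exhaustive midpoint threshold search), prune it by cost-complexity with the
complexity parameter chosen by 10-fold cross-validated misclassification
under the one-standard-error rule, and evaluate the held-out ranking with an
ROC curve and its AUC (rank statistic with mid-ranks for ties, identical to
the trapezoidal area under the empirical ROC).

Determinism: threshold ties are broken by canonical feature order, then by
the smaller threshold; the correlation filter drops the later column in
canonical order; all random choices (split, folds) are seeded.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

POSITIVE_LABEL = "high"
NEGATIVE_LABEL = "low"

_TOL = 1e-12


# ---------------------------------------------------------------------------
# feature filtering and splitting
# ---------------------------------------------------------------------------

def filter_correlated(
    features: pd.DataFrame,
    r2_max: float = 0.75,
) -> tuple[pd.DataFrame, list[dict]]:
    """Drop features that are highly correlated with an earlier one.

    Zero-variance columns are dropped first (each with its own log entry).
    Then feature pairs are visited in canonical column order and, whenever
    the pairwise Pearson r^2 exceeds ``r2_max``, the later column is dropped.
    Returns the reduced table and the drop log.
    """
    if features.shape[1] < 2 or len(features) < 3:
        raise ValueError("need at least 2 features and 3 rows")
    log: list[dict] = []
    cols = list(features.columns)
    X = features.to_numpy(dtype=float)
    variances = X.var(axis=0)
    alive = []
    for j, col in enumerate(cols):
        if variances[j] == 0.0:
            log.append({"dropped": col, "reason": "zero variance", "partner": None})
        else:
            alive.append(j)
    for a_pos, j in enumerate(alive):
        if j is None:
            continue
        for b_pos in range(a_pos + 1, len(alive)):
            k = alive[b_pos]
            if k is None:
                continue
            r = np.corrcoef(X[:, j], X[:, k])[0, 1]
            if r * r > r2_max:
                log.append({"dropped": cols[k], "reason": f"r2={r * r:.4f}",
                            "partner": cols[j]})
                alive[b_pos] = None
    kept = [cols[j] for j in alive if j is not None]
    return features[kept], log


def split_train_test(
    features: pd.DataFrame,
    labels: pd.Series,
    frac: float = 0.75,
    seed: int = 0,
) -> tuple[pd.Index, pd.Index]:
    """Stratified train/test partition of the row index (exact, disjoint)."""
    labels = labels.loc[features.index]
    classes = labels.unique()
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for cls in sorted(classes):
        idx = features.index[labels == cls]
        if len(idx) < 4:
            raise ValueError(f"class {cls!r} has fewer than 4 rows")
        perm = rng.permutation(len(idx))
        n_train = int(round(frac * len(idx)))
        train_parts.append(idx[perm[:n_train]])
        test_parts.append(idx[perm[n_train:]])
    train = train_parts[0].append(train_parts[1:])
    test = test_parts[0].append(test_parts[1:])
    return train, test


# ---------------------------------------------------------------------------
# CART
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Internal node (feature/threshold/children) or leaf (children None).

    ``counts`` is (n_negative, n_positive) of the training rows reaching the
    node; routing sends ``value < threshold`` left.
    """

    counts: tuple[int, int]
    feature: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    @property
    def n(self) -> int:
        return self.counts[0] + self.counts[1]

    @property
    def prob_high(self) -> float:
        return self.counts[1] / self.n if self.n else 0.0

    @property
    def errors(self) -> int:
        """Misclassification count under majority vote (ties -> negative)."""
        return min(self.counts)

    def to_dict(self) -> dict:
        d: dict = {"n": self.n, "counts": list(self.counts),
                   "prob_high": self.prob_high}
        if not self.is_leaf:
            d.update(feature=self.feature, threshold=self.threshold,
                     left=self.left.to_dict(), right=self.right.to_dict())
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        node = cls(counts=tuple(d["counts"]))
        if "feature" in d:
            node.feature = d["feature"]
            node.threshold = d["threshold"]
            node.left = cls.from_dict(d["left"])
            node.right = cls.from_dict(d["right"])
        return node


@dataclass
class TreeModel:
    """A fitted (and pruned) classification tree."""

    root: TreeNode
    feature_names: list[str]
    cp: float = 0.0

    def n_leaves(self) -> int:
        return _count_leaves(self.root)

    def depth(self) -> int:
        return _depth(self.root)

    def top_level_features(self, levels: int = 2) -> set[str]:
        """Features used by splits in the first ``levels`` levels."""
        out: set[str] = set()

        def visit(node: TreeNode, depth: int) -> None:
            if node.is_leaf or depth >= levels:
                return
            out.add(node.feature)  # type: ignore[arg-type]
            visit(node.left, depth + 1)
            visit(node.right, depth + 1)

        visit(self.root, 0)
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"feature_names": self.feature_names, "cp": self.cp,
             "root": self.root.to_dict()}, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TreeModel":
        obj = json.loads(Path(path).read_text())
        return cls(root=TreeNode.from_dict(obj["root"]),
                   feature_names=list(obj["feature_names"]),
                   cp=float(obj["cp"]))


def _count_leaves(node: TreeNode) -> int:
    if node.is_leaf:
        return 1
    return _count_leaves(node.left) + _count_leaves(node.right)


def _depth(node: TreeNode) -> int:
    if node.is_leaf:
        return 0
    return 1 + max(_depth(node.left), _depth(node.right))


def _gini(n_neg: np.ndarray, n_pos: np.ndarray) -> np.ndarray:
    n = n_neg + n_pos
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, n_pos / n, 0.0)
    return 2.0 * p * (1.0 - p)


def best_split(
    X: np.ndarray,
    y: np.ndarray,
    min_leaf: int,
) -> tuple[int, float, float] | None:
    """Exhaustive search for the Gini-optimal (feature, midpoint threshold).

    Returns (feature index, threshold, weighted child impurity) or None when
    no split leaves both children with at least ``min_leaf`` rows.  Ties are
    broken by the lower feature index, then by the smaller threshold.
    """
    n = len(y)
    best: tuple[int, float, float] | None = None
    for f in range(X.shape[1]):
        order = np.argsort(X[:, f], kind="stable")
        xs = X[order, f]
        ys = y[order]
        cum_pos = np.cumsum(ys)
        total_pos = cum_pos[-1]
        # candidate cut before position i (left = first i rows)
        i = np.arange(1, n)
        valid = (xs[1:] > xs[:-1]) & (i >= min_leaf) & (n - i >= min_leaf)
        if not valid.any():
            continue
        i = i[valid]
        left_pos = cum_pos[i - 1]
        left_neg = i - left_pos
        right_pos = total_pos - left_pos
        right_neg = (n - i) - right_pos
        impurity = (i * _gini(left_neg, left_pos)
                    + (n - i) * _gini(right_neg, right_pos)) / n
        j = int(np.argmin(impurity))  # first minimum => smallest threshold
        if best is None or impurity[j] < best[2] - _TOL:
            thr = (xs[i[j] - 1] + xs[i[j]]) / 2.0
            best = (f, float(thr), float(impurity[j]))
    return best


def _grow(X: np.ndarray, y: np.ndarray, features: list[str],
          min_leaf: int, max_depth: int, depth: int = 0) -> TreeNode:
    counts = (int((~y).sum()), int(y.sum()))
    node = TreeNode(counts=counts)
    if depth >= max_depth or min(counts) == 0 or len(y) < 2 * min_leaf:
        return node
    found = best_split(X, y, min_leaf)
    if found is None:
        return node
    f, thr, impurity = found
    parent_impurity = float(_gini(np.array(counts[0]), np.array(counts[1])))
    if impurity >= parent_impurity - _TOL:
        return node
    mask = X[:, f] < thr
    node.feature = features[f]
    node.threshold = thr
    node.left = _grow(X[mask], y[mask], features, min_leaf, max_depth, depth + 1)
    node.right = _grow(X[~mask], y[~mask], features, min_leaf, max_depth, depth + 1)
    return node


def _copy(node: TreeNode) -> TreeNode:
    if node.is_leaf:
        return TreeNode(counts=node.counts)
    return TreeNode(counts=node.counts, feature=node.feature,
                    threshold=node.threshold,
                    left=_copy(node.left), right=_copy(node.right))


def _subtree_errors_leaves(node: TreeNode) -> tuple[int, int]:
    if node.is_leaf:
        return node.errors, 1
    el, ll = _subtree_errors_leaves(node.left)
    er, lr = _subtree_errors_leaves(node.right)
    return el + er, ll + lr


def prune_at(node: TreeNode, alpha: float, n_total: int) -> TreeNode:
    """Smallest optimally pruned subtree at complexity penalty ``alpha``.

    An internal node collapses when keeping its subtree improves the training
    misclassification rate by no more than ``alpha`` per extra leaf.
    """
    if node.is_leaf:
        return TreeNode(counts=node.counts)
    left = prune_at(node.left, alpha, n_total)
    right = prune_at(node.right, alpha, n_total)
    pruned = TreeNode(counts=node.counts, feature=node.feature,
                      threshold=node.threshold, left=left, right=right)
    errs, leaves = _subtree_errors_leaves(pruned)
    if (node.errors - errs) / n_total <= alpha * (leaves - 1) + _TOL:
        return TreeNode(counts=node.counts)
    return pruned


def _alpha_path(root: TreeNode, n_total: int) -> list[float]:
    """Ascending weakest-link alphas of the cost-complexity pruning path."""
    alphas: list[float] = []
    tree = _copy(root)
    while not tree.is_leaf:
        links: list[tuple[float, TreeNode]] = []

        def visit(node: TreeNode) -> None:
            if node.is_leaf:
                return
            errs, leaves = _subtree_errors_leaves(node)
            g = (node.errors - errs) / n_total / (leaves - 1)
            links.append((g, node))
            visit(node.left)
            visit(node.right)

        visit(tree)
        g_min = min(g for g, _ in links)
        for g, node in links:
            if g <= g_min + _TOL:
                node.feature = node.threshold = None
                node.left = node.right = None
        alphas.append(max(g_min, 0.0))
    out: list[float] = []
    for a in alphas:
        if not out or a > out[-1] + _TOL:
            out.append(a)
    return out


def _cv_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Stratified fold assignment: per class, a seeded permutation dealt
    round-robin across folds."""
    fold_of = np.empty(len(y), dtype=int)
    for cls in (False, True):
        idx = np.flatnonzero(y == cls)
        perm = rng.permutation(idx)
        fold_of[perm] = np.arange(len(perm)) % k
    return [np.flatnonzero(fold_of == f) for f in range(k)]


def _route_predict(node: TreeNode, x: dict[str, float]) -> float:
    while not node.is_leaf:
        node = node.left if x[node.feature] < node.threshold else node.right
    return node.prob_high


def fit_tree(
    features: pd.DataFrame,
    labels: pd.Series,
    min_leaf: int = 8,
    max_depth: int = 5,
    cv_folds: int = 10,
    seed: int = 0,
    cp: float | None = None,
) -> TreeModel:
    """Grow and prune a binary classification tree.

    The tree is grown to ``max_depth`` / ``min_leaf`` by exhaustive Gini
    search, then cost-complexity pruned.  When ``cp`` is None the penalty is
    chosen by ``cv_folds``-fold cross-validated misclassification with the
    one-standard-error rule (the largest penalty whose CV error is within one
    SE of the minimum); pass an explicit ``cp`` to skip cross-validation.
    """
    labels = labels.loc[features.index]
    X = features.to_numpy(dtype=float)
    if np.isnan(X).any():
        bad = features.columns[np.isnan(X).any(axis=0)].tolist()
        raise ValueError(f"features contain missing values: {bad}")
    y = labels.to_numpy() == POSITIVE_LABEL
    names = list(features.columns)
    if len(y) < 2 * min_leaf:
        raise ValueError(f"need at least {2 * min_leaf} rows")
    if y.all() or not y.any():
        warnings.warn("single-class training set: fitting a single leaf",
                      stacklevel=2)
        return TreeModel(root=TreeNode(counts=(int((~y).sum()), int(y.sum()))),
                         feature_names=names, cp=0.0)

    full = _grow(X, y, names, min_leaf, max_depth)
    n = len(y)
    if cp is None:
        alphas = _alpha_path(full, n)
        if not alphas:
            cp = 0.0
        else:
            candidates = [0.0]
            candidates += [float(np.sqrt(alphas[i] * alphas[i + 1]))
                           for i in range(len(alphas) - 1)]
            candidates.append(alphas[-1])
            candidates = sorted(set(candidates))
            rng = np.random.default_rng(seed)
            k = min(cv_folds, int(min(y.sum(), (~y).sum())))
            folds = _cv_folds(y, k, rng)
            errors = np.zeros(len(candidates))
            for fold in folds:
                mask = np.ones(n, dtype=bool)
                mask[fold] = False
                sub = _grow(X[mask], y[mask], names, min_leaf, max_depth)
                for ci, alpha in enumerate(candidates):
                    pruned = prune_at(sub, alpha, int(mask.sum()))
                    preds = np.array([
                        _route_predict(pruned, dict(zip(names, X[i]))) > 0.5
                        for i in fold
                    ])
                    errors[ci] += int((preds != y[fold]).sum())
            rates = errors / n
            i_min = int(np.argmin(rates))
            se = float(np.sqrt(rates[i_min] * (1 - rates[i_min]) / n))
            threshold = rates[i_min] + se
            chosen = max(i for i in range(len(candidates))
                         if rates[i] <= threshold + _TOL)
            cp = candidates[chosen]
    root = prune_at(full, cp, n)
    return TreeModel(root=root, feature_names=names, cp=float(cp))


def predict(model: TreeModel, rows: pd.DataFrame) -> pd.Series:
    """Probability of the ``high`` class per row (leaf class proportion)."""
    used = sorted({n.feature for n in _iter_internal(model.root)})
    for f in used:
        if f not in rows.columns:
            raise ValueError(f"missing feature {f!r}")
        if rows[f].isna().any():
            raise ValueError(f"missing values in feature {f!r}")
    scores = [
        _route_predict(model.root, row)
        for row in rows[list(rows.columns)].to_dict("records")
    ]
    return pd.Series(scores, index=rows.index, name="score")


def _iter_internal(node: TreeNode):
    if node.is_leaf:
        return
    yield node
    yield from _iter_internal(node.left)
    yield from _iter_internal(node.right)


# ---------------------------------------------------------------------------
# ROC / AUC and recovery
# ---------------------------------------------------------------------------

def roc_auc(scores, labels) -> dict:
    """Empirical ROC points and AUC of a binary score ranking.

    AUC is the normalized Mann-Whitney rank statistic with mid-ranks for
    ties, which equals the trapezoidal area under the empirical ROC curve.
    A one-class label set yields ``auc=nan, defined=False``.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([l == POSITIVE_LABEL if isinstance(l, str) else bool(l)
                    for l in labels])
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        warnings.warn("ROC undefined: one-class label set", stacklevel=2)
        return {"auc": float("nan"), "defined": False, "fpr": [], "tpr": []}
    ranks = rankdata(scores)
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    tps = np.cumsum(y[order])
    fps = np.cumsum(~y[order])
    distinct = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    return {"auc": float(auc), "defined": True,
            "fpr": fpr.tolist(), "tpr": tpr.tolist()}


def evaluate_recovery(model: TreeModel, planted_features: set[str],
                      auc: float | None = None, levels: int = 2) -> dict:
    """Report whether the fitted tree's top-level splits recover any planted
    rule feature, alongside the held-out AUC when supplied."""
    top = model.top_level_features(levels=levels)
    return {
        "top_level_features": sorted(top),
        "planted_features": sorted(planted_features),
        "recovered": bool(top & set(planted_features)),
        "auc": auc,
    }
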