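"""Bagged decision-tree ensemble producing the miR-CERVIX score.

The classifier is a random forest over the nine χ predictors: each tree is
grown on a bootstrap resample of the training cohort by greedy recursive
binary partitioning; at every node a random subset of predictors is drawn
without replacement and the (feature, threshold) pair minimising weighted
Gini impurity is chosen.  A sample's score is the mean, over trees, of the
leaf class-1 (HSIL) frequency — a number in [0, 1] by construction, read as
0 = confidently normal epithelium, 1 = high-grade lesion.

Cross-validation follows the published protocol: the cohort is randomly
partitioned into k folds (stratified by class by default), each fold is
scored by the ensemble trained on the other k−1 folds, and every sample
therefore receives exactly one out-of-fold score.  ``score_external``
implements the complementary mode for samples outside the training cohort:
the average of all k fold-models' predictions.

All randomness — bootstrap draws, per-node feature subsets, fold
assignment — derives deterministically from a single integer seed via
``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .config import ForestConfig, PipelineConfig

__all__ = [
    "BaggedTrees",
    "fit_tree",
    "fit_forest",
    "predict_score",
    "crossval_scores",
    "score_external",
    "model_to_json",
    "model_from_json",
]


# ---------------------------------------------------------------------------
# Single tree


def _gini(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - np.sum(p * p))


def _best_split(x: np.ndarray, y: np.ndarray, min_leaf: int):
    """Best threshold on one feature by weighted Gini; None if no valid split.

    Returns (threshold, weighted_child_impurity) with the threshold at the
    midpoint between adjacent distinct values.  Deterministic: first minimum
    in sorted order wins.
    """
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]
    n = len(xs)
    boundaries = np.nonzero(xs[:-1] < xs[1:])[0]  # split after index i
    if boundaries.size == 0:
        return None
    n_left = boundaries + 1
    n_right = n - n_left
    valid = (n_left >= min_leaf) & (n_right >= min_leaf)
    if not valid.any():
        return None
    boundaries, n_left, n_right = boundaries[valid], n_left[valid], n_right[valid]
    cum1 = np.cumsum(ys)
    left1 = cum1[boundaries]
    total1 = cum1[-1]
    right1 = total1 - left1
    p1l = left1 / n_left
    p1r = right1 / n_right
    gini_left = 2.0 * p1l * (1.0 - p1l)  # binary Gini: 1 - p^2 - (1-p)^2
    gini_right = 2.0 * p1r * (1.0 - p1r)
    weighted = (n_left * gini_left + n_right * gini_right) / n
    best = int(np.argmin(weighted))
    i = boundaries[best]
    threshold = 0.5 * (xs[i] + xs[i + 1])
    return threshold, float(weighted[best])


def _grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    features_per_split: int,
    max_depth: int | None,
    min_leaf: int,
    importances: np.ndarray | None = None,
    n_root: int | None = None,
) -> dict:
    """Recursively grow one tree; returns a nested dict of split/leaf nodes.

    Leaves store ``{"leaf": [n_class0, n_class1]}``; internal nodes store
    ``{"feature": j, "threshold": t, "left": ..., "right": ...}``.  When an
    ``importances`` accumulator is given, each split adds its impurity
    decrease weighted by the fraction of root samples reaching the node.
    """
    n = len(y)
    n_root = n_root or n
    n1 = int(y.sum())
    counts = np.array([n - n1, n1], dtype=float)
    depth_left = None if max_depth is None else max_depth
    pure = n1 == 0 or n1 == n
    if pure or n < 2 * min_leaf or (depth_left is not None and depth_left == 0):
        return {"leaf": [int(counts[0]), int(counts[1])]}
    impurity = _gini(counts)
    candidates = rng.choice(X.shape[1], size=features_per_split, replace=False)
    best = None  # (weighted_impurity, feature, threshold)
    for j in candidates:
        split = _best_split(X[:, j], y, min_leaf)
        if split is None:
            continue
        threshold, weighted = split
        if best is None or weighted < best[0] - 1e-15:
            best = (weighted, int(j), threshold)
    if best is None or best[0] >= impurity - 1e-12:  # no impurity decrease
        return {"leaf": [int(counts[0]), int(counts[1])]}
    weighted, feature, threshold = best
    if importances is not None:
        importances[feature] += (n / n_root) * (impurity - weighted)
    mask = X[:, feature] <= threshold
    child_depth = None if max_depth is None else max_depth - 1
    return {
        "feature": feature,
        "threshold": float(threshold),
        "left": _grow_tree(
            X[mask], y[mask], rng, features_per_split, child_depth, min_leaf,
            importances, n_root,
        ),
        "right": _grow_tree(
            X[~mask], y[~mask], rng, features_per_split, child_depth, min_leaf,
            importances, n_root,
        ),
    }


def _tree_proba1(node: dict, row: np.ndarray) -> float:
    """Leaf class-1 frequency for one sample (empirical leaf probability)."""
    while "leaf" not in node:
        node = node["left"] if row[node["feature"]] <= node["threshold"] else node["right"]
    n0, n1 = node["leaf"]
    total = n0 + n1
    return n1 / total if total else 0.5


# ---------------------------------------------------------------------------
# Estimator


class BaggedTrees(ClassifierMixin, BaseEstimator):
    """Bootstrap-aggregated Gini decision trees with random feature subsets.

    Parameters
    ----------
    n_trees:
        Ensemble size (bootstrap resamples).
    features_per_split:
        Number of predictors drawn without replacement at each node.
    max_depth:
        Maximum tree depth, or None for unlimited.
    min_leaf:
        Minimum samples per leaf.
    hard_voting:
        If True, each tree contributes its majority class (0/1) instead of
        its leaf class frequency.
    random_state:
        Integer seed; all bootstrap and feature draws derive from it.

    Attributes
    ----------
    trees_ : list of nested-dict trees.
    classes_ : array of the two class labels, sorted.
    feature_importances_ : normalised mean impurity decrease per predictor,
        nonnegative, summing to 1.
    """

    def __init__(
        self,
        n_trees: int = 100,
        features_per_split: int = 3,
        max_depth: int | None = None,
        min_leaf: int = 1,
        hard_voting: bool = False,
        random_state: int | None = None,
    ):
        self.n_trees = n_trees
        self.features_per_split = features_per_split
        self.max_depth = max_depth
        self.min_leaf = min_leaf
        self.hard_voting = hard_voting
        self.random_state = random_state

    @classmethod
    def from_config(cls, config: ForestConfig, random_state: int | None = None) -> "BaggedTrees":
        return cls(
            n_trees=config.n_trees,
            features_per_split=config.features_per_split,
            max_depth=config.max_depth,
            min_leaf=config.min_leaf,
            hard_voting=config.hard_voting,
            random_state=random_state,
        )

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if len(self.classes_) == 1:
            raise ValueError("BaggedTrees requires both classes in the training data")
        if len(self.classes_) > 2:
            raise ValueError("binary classification only")
        if self.features_per_split > X.shape[1]:
            raise ValueError(
                f"features_per_split={self.features_per_split} exceeds "
                f"n_features={X.shape[1]}"
            )
        n = X.shape[0]
        seed_seq = np.random.SeedSequence(self.random_state)
        importances = np.zeros(X.shape[1])
        self.trees_ = []
        for child in seed_seq.spawn(self.n_trees):
            rng = np.random.default_rng(child)
            boot = rng.integers(0, n, size=n)
            self.trees_.append(
                _grow_tree(
                    X[boot], y_enc[boot], rng,
                    self.features_per_split, self.max_depth, self.min_leaf,
                    importances,
                )
            )
        total = importances.sum()
        # all-pure bootstrap roots leave nothing to attribute; fall back to uniform
        self.feature_importances_ = (
            importances / total if total > 0 else np.full(X.shape[1], 1.0 / X.shape[1])
        )
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "trees_")
        X = check_array(X)
        scores = np.empty(X.shape[0])
        for i, row in enumerate(X):
            per_tree = [_tree_proba1(tree, row) for tree in self.trees_]
            if self.hard_voting:
                per_tree = [1.0 if p > 0.5 else 0.0 if p < 0.5 else 0.5 for p in per_tree]
            scores[i] = np.mean(per_tree)
        return np.column_stack([1.0 - scores, scores])

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[(proba[:, 1] >= 0.5).astype(int)]


# ---------------------------------------------------------------------------
# Functional wrappers and cross-validation


def fit_tree(
    X: np.ndarray,
    y: np.ndarray,
    features_per_split: int = 3,
    rng: np.random.Generator | int | None = None,
    max_depth: int | None = None,
    min_leaf: int = 1,
) -> dict:
    """Grow one decision tree (no bootstrap); y must be 0/1 encoded."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.size == 0:
        raise ValueError("empty predictor matrix")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return _grow_tree(X, y.astype(int), rng, features_per_split, max_depth, min_leaf)


def fit_forest(
    X: np.ndarray,
    y: np.ndarray,
    config: ForestConfig | None = None,
    seed: int | None = None,
) -> BaggedTrees:
    """Fit the bagged ensemble; thin wrapper over :class:`BaggedTrees`."""
    model = BaggedTrees.from_config(config or ForestConfig(), random_state=seed)
    return model.fit(X, y)


def predict_score(model: BaggedTrees, chi) -> np.ndarray:
    """miR-CERVIX scores (probability of the higher class label, HSIL when
    labels are NILM/HSIL strings or 0/1 indicators) for one or more χ rows."""
    chi = np.atleast_2d(np.asarray(chi, dtype=float))
    return model.predict_proba(chi)[:, 1]


@dataclass
class CrossValResult:
    """Out-of-fold scores plus the k fold models (for external scoring)."""

    scores: np.ndarray          # one out-of-fold score per sample, input order
    folds: np.ndarray           # 1-based fold id per sample
    models: list[BaggedTrees]


def crossval_scores(
    X: np.ndarray,
    y: np.ndarray,
    config: PipelineConfig | None = None,
    seed: int | None = None,
) -> CrossValResult:
    """k-fold out-of-fold scoring.

    Folds are a random partition of the samples, stratified by class when
    ``config.cv.stratified`` (sizes differ by at most one).  Each sample is
    scored exactly once, by the ensemble trained without its fold.
    """
    config = config or PipelineConfig()
    if seed is None:
        seed = config.seed
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    k = config.cv.k
    if k > n:
        raise ValueError(f"k={k} exceeds number of samples ({n})")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present for cross-validation")

    seeds = np.random.SeedSequence(seed).generate_state(k + 1) % (2**31)
    splitter_cls = StratifiedKFold if config.cv.stratified else KFold
    try:
        splitter = splitter_cls(n_splits=k, shuffle=True, random_state=int(seeds[0]))
        splits = list(splitter.split(X, y))
    except ValueError as exc:
        raise ValueError(
            f"cannot build {k} folds: {exc}; use stratified folds or a smaller k"
        ) from exc

    scores = np.full(n, np.nan)
    folds = np.zeros(n, dtype=int)
    models = []
    for fold_id, (train_idx, test_idx) in enumerate(splits, start=1):
        if len(np.unique(y[train_idx])) < 2:
            raise ValueError(
                f"training split for fold {fold_id} contains a single class; "
                "enable stratification or reduce k"
            )
        model = BaggedTrees.from_config(config.forest, random_state=int(seeds[fold_id]))
        model.fit(X[train_idx], y[train_idx])
        scores[test_idx] = predict_score(model, X[test_idx])
        folds[test_idx] = fold_id
        models.append(model)
    assert not np.isnan(scores).any()
    return CrossValResult(scores=scores, folds=folds, models=models)


def score_external(models: Sequence[BaggedTrees], X) -> np.ndarray:
    """Score samples outside the training cohort: mean of all fold models."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.mean([predict_score(m, X) for m in models], axis=0)


# ---------------------------------------------------------------------------
# Serialization — trees as nested split/leaf records


def model_to_json(model: BaggedTrees, path: str | Path | None = None) -> str:
    check_is_fitted(model, "trees_")
    payload = {
        "n_trees": model.n_trees,
        "features_per_split": model.features_per_split,
        "max_depth": model.max_depth,
        "min_leaf": model.min_leaf,
        "hard_voting": model.hard_voting,
        "random_state": model.random_state,
        "classes": [c.item() if hasattr(c, "item") else c for c in model.classes_],
        "feature_importances": model.feature_importances_.tolist(),
        "trees": model.trees_,
    }
    text = json.dumps(payload)
    if path is not None:
        Path(path).write_text(text)
    return text


def model_from_json(source: str | Path) -> BaggedTrees:
    if isinstance(source, Path):
        text = source.read_text()
    else:
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(text).read_text()
    payload = json.loads(text)
    model = BaggedTrees(
        n_trees=payload["n_trees"],
        features_per_split=payload["features_per_split"],
        max_depth=payload["max_depth"],
        min_leaf=payload["min_leaf"],
        hard_voting=payload["hard_voting"],
        random_state=payload["random_state"],
    )
    model.trees_ = payload["trees"]
    model.classes_ = np.asarray(payload["classes"])
    model.feature_importances_ = np.asarray(payload["feature_importances"])
    model.n_features_in_ = len(model.feature_importances_)
    return model
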