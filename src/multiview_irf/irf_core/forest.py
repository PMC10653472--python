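"""Feature-weighted random forests with count-weighted Gini importances."""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

from multiview_irf.irf_core._kernels import apply_tree, grow_tree, tree_proba

__all__ = [
    "ForestParams",
    "TreeArrays",
    "WeightedForest",
    "fit_weighted_forest",
    "gini_importance",
    "iterate_reweighted_forest",
]

REWEIGHT_FLOOR = 1e-6  # fraction of the max importance; keeps features alive


@dataclass(frozen=True)
class ForestParams:
    n_trees: int = 500
    mtry: int | None = None  # default ceil(sqrt(p))
    min_node: int = 1
    max_depth: int | None = None
    in_tree_bootstrap: bool = True  # disable only for deterministic fixtures
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")
        if self.min_node < 1:
            raise ValueError("min_node must be >= 1")
        if self.max_depth is not None and self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")

    def resolve_mtry(self, p: int) -> int:
        m = self.mtry if self.mtry is not None else math.ceil(math.sqrt(p))
        return max(1, min(m, p))


class TreeArrays(NamedTuple):
    """Flat node arrays of one tree; ``feature == -1`` marks a leaf."""

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    count0: np.ndarray
    count1: np.ndarray
    decrease: np.ndarray


class WeightedForest:
    """Ensemble of axis-aligned trees grown with weighted candidate sampling."""

    def __init__(
        self,
        trees: list[TreeArrays],
        feature_weights: np.ndarray,
        n_features: int,
        params: ForestParams,
    ) -> None:
        self.trees = trees
        self.feature_weights = feature_weights
        self.n_features = n_features
        self.params = params

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class-1 probability: mean of leaf class-1 fractions over trees."""
        X = np.ascontiguousarray(X, dtype=np.float64)
        acc = np.zeros(X.shape[0])
        for t in self.trees:
            acc += tree_proba(t.feature, t.threshold, t.left, t.right, t.count0, t.count1, X)
        return acc / len(self.trees)

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Leaf index per (tree, sample)."""
        X = np.ascontiguousarray(X, dtype=np.float64)
        return np.stack(
            [apply_tree(t.feature, t.threshold, t.left, t.right, X) for t in self.trees]
        )

    @property
    def importances(self) -> np.ndarray:
        return gini_importance(self)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n_features": self.n_features,
            "feature_weights": self.feature_weights.tolist(),
            "params": {
                "n_trees": self.params.n_trees,
                "mtry": self.params.mtry,
                "min_node": self.params.min_node,
                "max_depth": self.params.max_depth,
                "in_tree_bootstrap": self.params.in_tree_bootstrap,
                "seed": self.params.seed,
            },
            "trees": [
                {
                    "feature": t.feature.tolist(),
                    "threshold": t.threshold.tolist(),
                    "left": t.left.tolist(),
                    "right": t.right.tolist(),
                    "count0": t.count0.tolist(),
                    "count1": t.count1.tolist(),
                    "decrease": t.decrease.tolist(),
                }
                for t in self.trees
            ],
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "WeightedForest":
        text = Path(source).read_text() if isinstance(source, Path) else source
        payload = json.loads(text)
        trees = [
            TreeArrays(
                feature=np.asarray(t["feature"], dtype=np.int64),
                threshold=np.asarray(t["threshold"], dtype=np.float64),
                left=np.asarray(t["left"], dtype=np.int64),
                right=np.asarray(t["right"], dtype=np.int64),
                count0=np.asarray(t["count0"], dtype=np.int64),
                count1=np.asarray(t["count1"], dtype=np.int64),
                decrease=np.asarray(t["decrease"], dtype=np.float64),
            )
            for t in payload["trees"]
        ]
        params = ForestParams(**payload["params"])
        return cls(
            trees,
            np.asarray(payload["feature_weights"], dtype=np.float64),
            int(payload["n_features"]),
            params,
        )


def _validate_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n_samples, n_features) aligned with y")
    classes = np.unique(y)
    if not np.array_equal(classes, np.array([0, 1])):
        raise ValueError("y must be binary with both classes present")
    return X, y


def fit_weighted_forest(
    X: np.ndarray,
    y: np.ndarray,
    feature_weights: np.ndarray | None = None,
    params: ForestParams | None = None,
) -> WeightedForest:
    """Fit a forest whose split candidates are sampled proportional to
    ``feature_weights``; each tree grows on its own in-tree bootstrap."""
    params = params or ForestParams()
    X, y = _validate_xy(X, y)
    p = X.shape[1]
    if feature_weights is None:
        w = np.full(p, 1.0 / p)
    else:
        w = np.asarray(feature_weights, dtype=np.float64).copy()
        if w.shape != (p,):
            raise ValueError("feature_weights must have one entry per feature")
        if (w < 0).any() or not np.isfinite(w).all():
            raise ValueError("feature_weights must be finite and non-negative")
        total = w.sum()
        if total <= 0:
            raise ValueError("feature_weights must not be all zero")
        w = w / total
    mtry = params.resolve_mtry(p)
    max_depth = params.max_depth or 0
    cumw = np.cumsum(w)
    # per-feature sorted row order, shared by all trees of the forest
    sort_idx = np.ascontiguousarray(np.argsort(X, axis=0, kind="stable").T)
    seeds = np.random.SeedSequence(params.seed).generate_state(params.n_trees)
    trees = []
    for t in range(params.n_trees):
        arrays = grow_tree(
            X, y, w, cumw, sort_idx, mtry, params.min_node, max_depth,
            params.in_tree_bootstrap, np.int64(seeds[t] & 0x7FFFFFFF),
        )
        trees.append(TreeArrays(*arrays))
    return WeightedForest(trees, w, p, params)


def gini_importance(forest: WeightedForest) -> np.ndarray:
    """Per-feature mean (over trees) of summed count-weighted Gini decreases."""
    imp = np.zeros(forest.n_features)
    for t in forest.trees:
        used = t.feature >= 0
        np.add.at(imp, t.feature[used], t.decrease[used])
    return imp / len(forest.trees)


def iterate_reweighted_forest(
    X: np.ndarray,
    y: np.ndarray,
    K: int,
    params: ForestParams | None = None,
    initial_weights: np.ndarray | None = None,
) -> tuple[WeightedForest, list[np.ndarray]]:
    """K rounds of importance-reweighted forests.

    Iteration 1 uses uniform weights (so ``K=1`` is an ordinary random
    forest); iteration k > 1 samples candidates proportional to the
    previous iteration's Gini importances, floored at ``1e-6`` of their
    maximum so no feature is permanently excluded.  Returns the final
    forest and the weight history (one vector per iteration, the weights
    *used* by that iteration).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    params = params or ForestParams()
    X, y = _validate_xy(X, y)
    p = X.shape[1]
    w = np.full(p, 1.0 / p) if initial_weights is None else np.asarray(initial_weights, float)
    w = w / w.sum()
    iter_seeds = [params.seed] + [
        int(s) for s in np.random.SeedSequence((params.seed, 0xA5)).generate_state(max(K - 1, 1))
    ]
    history: list[np.ndarray] = []
    forest: WeightedForest | None = None
    for k in range(K):
        history.append(w.copy())
        forest = fit_weighted_forest(X, y, w, replace(params, seed=int(iter_seeds[k])))
        if k == K - 1:
            break
        imps = forest.importances
        top = imps.max()
        if top <= 0.0:
            warnings.warn("all importances zero; falling back to uniform weights", stacklevel=2)
            w = np.full(p, 1.0 / p)
        else:
            w = np.maximum(imps, REWEIGHT_FLOOR * top)
            w = w / w.sum()
    assert forest is not None
    return forest, history
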