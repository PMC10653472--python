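"""Signed decision-path itemsets and generalized Random Intersection Trees.

Items are encoded as signed integers: ``+(f + 1)`` for the "> threshold"
branch of feature ``f`` (activation) and ``-(f + 1)`` for the "<=" branch
(inactivation).  An itemset is the set of signed items on a root-to-leaf
path; intersecting itemsets that co-occur in class-1 leaves recovers
feature combinations that are frequent in the positive class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from multiview_irf.irf_core.forest import WeightedForest

__all__ = [
    "RitParams",
    "SignedItemset",
    "encode_item",
    "decode_item",
    "itemset_features",
    "format_itemset",
    "extract_signed_itemsets",
    "run_rit",
]


def encode_item(feature: int, sign: int) -> int:
    return (feature + 1) if sign > 0 else -(feature + 1)


def decode_item(item: int) -> tuple[int, int]:
    return abs(item) - 1, (1 if item > 0 else -1)


def itemset_features(items: Iterable[int]) -> frozenset[int]:
    """Strip signs, keeping only the feature indices."""
    return frozenset(abs(i) - 1 for i in items)


def format_itemset(items: Iterable[int], names: Sequence[str] | None = None) -> str:
    parts = []
    for item in sorted(items, key=lambda i: (abs(i), -i)):
        f, s = decode_item(item)
        label = names[f] if names is not None else f"f{f}"
        parts.append(f"{label}{'+' if s > 0 else '-'}")
    return "_".join(parts)


@dataclass(frozen=True)
class RitParams:
    n_rit_trees: int = 500
    depth: int = 5
    n_child: int = 2
    min_order: int = 2

    def __post_init__(self) -> None:
        for name in ("n_rit_trees", "depth", "n_child", "min_order"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass(frozen=True)
class SignedItemset:
    """Signed root-to-leaf path set weighted by the leaf's class-1 count."""

    items: frozenset[int]
    weight: int


def extract_signed_itemsets(
    forest: WeightedForest, X: np.ndarray, y: np.ndarray
) -> list[SignedItemset]:
    """One itemset per (tree, leaf) holding >= 1 class-1 sample of (X, y).

    The itemset is the signed root-to-leaf path (sign - for the <= branch,
    + for the > branch; a feature split twice on a path keeps the sign of
    the deepest, binding split), weighted by the leaf's class-1 count.
    Root-only trees contribute nothing (their path set is empty).
    """
    from multiview_irf.irf_core._kernels import class1_leaf_paths

    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64).ravel()
    pos = np.nonzero(y == 1)[0]
    out: list[SignedItemset] = []
    if pos.size == 0:
        return out
    Xpos = np.ascontiguousarray(X[pos])
    for tree in forest.trees:
        items, offsets, weights = class1_leaf_paths(
            tree.feature, tree.threshold, tree.left, tree.right, Xpos
        )
        for i in range(weights.shape[0]):
            path = items[offsets[i] : offsets[i + 1]]
            if path.shape[0]:
                out.append(
                    SignedItemset(items=frozenset(int(v) for v in path), weight=int(weights[i]))
                )
    return out


def run_rit(
    itemsets: Sequence[SignedItemset],
    params: RitParams | None = None,
    seed: int = 0,
) -> list[frozenset[int]]:
    """Recover candidate interactions by randomized itemset intersection.

    Each of ``n_rit_trees`` intersection trees starts from an itemset drawn
    with probability proportional to its weight; every node at depth < D
    has ``n_child`` children, each the intersection of the node's set with
    a freshly drawn itemset.  Sets of size >= ``min_order`` surviving at
    depth D are returned, deduplicated, in a deterministic order.
    """
    params = params or RitParams()
    if len(itemsets) == 0:
        raise ValueError("run_rit requires at least one itemset")
    rng = np.random.default_rng(seed)
    sets = [s.items for s in itemsets]
    weights = np.asarray([s.weight for s in itemsets], dtype=np.float64)
    if (weights <= 0).any():
        raise ValueError("itemset weights must be positive")
    probs = weights / weights.sum()

    nc, D = params.n_child, params.depth
    draws_per_tree = 1 + sum(nc**d for d in range(1, D + 1))
    draw = rng.choice(len(sets), size=(params.n_rit_trees, draws_per_tree), p=probs)

    survivors: set[frozenset[int]] = set()
    for t in range(params.n_rit_trees):
        cursor = 1
        level = [sets[draw[t, 0]]]
        for _ in range(D):
            nxt = []
            for node in level:
                for _c in range(nc):
                    child = node & sets[draw[t, cursor]]
                    cursor += 1
                    if len(child) >= params.min_order:
                        nxt.append(child)
            level = nxt
            if not level:
                cursor = draws_per_tree  # rest of this tree's draws unused
                break
        for s in level:
            survivors.add(s)
    return sorted(survivors, key=lambda s: (len(s), sorted(s)))
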