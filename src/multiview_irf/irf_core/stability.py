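"""Bagged stability scores for recovered interactions (outer-layer bootstrap)."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from multiview_irf.irf_core.forest import ForestParams, fit_weighted_forest
from multiview_irf.irf_core.rit import (
    RitParams,
    extract_signed_itemsets,
    format_itemset,
    run_rit,
)

__all__ = ["SignedInteraction", "bagged_stability"]


@dataclass(frozen=True)
class SignedInteraction:
    """A set of signed items plus the fraction of bootstraps recovering it."""

    items: frozenset[int]
    stability: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.stability <= 1.0:
            raise ValueError("stability must lie in [0, 1]")

    def name(self, feature_names: Sequence[str] | None = None) -> str:
        return format_itemset(self.items, feature_names)


def bagged_stability(
    X: np.ndarray,
    y: np.ndarray,
    feature_weights: np.ndarray,
    B: int,
    forest_params: ForestParams | None = None,
    rit_params: RitParams | None = None,
    seed: int = 0,
) -> list[SignedInteraction]:
    """Stability(I) = fraction of B bootstrap replicates whose refitted
    forest + RIT recover the signed set I.

    Each replicate bootstraps the training samples, refits the forest at
    the supplied (final-iteration) feature weights, extracts class-1
    signed path itemsets and runs RIT on them.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    forest_params = forest_params or ForestParams()
    rit_params = rit_params or RitParams()
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64).ravel()
    n = X.shape[0]
    counts: Counter[frozenset[int]] = Counter()
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = root.spawn(B)
    for b in range(B):
        rng = np.random.default_rng(children[b])
        bidx = rng.integers(0, n, n)
        for _ in range(10):
            if np.unique(y[bidx]).size == 2:
                break
            bidx = rng.integers(0, n, n)
        else:
            continue  # degenerate bootstrap; contributes no recoveries
        sub_seed = int(children[b].generate_state(1)[0])
        forest = fit_weighted_forest(
            X[bidx], y[bidx], feature_weights, replace(forest_params, seed=sub_seed)
        )
        itemsets = extract_signed_itemsets(forest, X[bidx], y[bidx])
        if not itemsets:
            continue
        recovered = run_rit(itemsets, rit_params, seed=sub_seed)
        counts.update(set(recovered))
    return sorted(
        (SignedInteraction(items=s, stability=c / B) for s, c in counts.items()),
        key=lambda it: (-it.stability, len(it.items), sorted(it.items)),
    )
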