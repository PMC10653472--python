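"""Outer bootstrap layer: multiview training, persistence-based feature
selection, interaction aggregation, and AUPR/AUROC evaluation.

For each of R outer replicates the whole dataset is bootstrapped, split
(stratified) into train/test, the reweighted forest is trained with K
iterations on the train part, test AUPR is computed from the forest's
class-1 probabilities, and B bagged-stability bootstraps score the
recovered interactions.  Features are retained when their importance
clears ``gini_min`` in at least ``persistence_min`` of the replicates
(both thresholds inclusive); interactions are retained when their mean
stability strictly exceeds ``stability_min`` and every member feature is
retained.

Note ``gini_min`` is on the count-weighted importance scale (impurity
decrease summed over in-tree bootstrap sample counts, averaged over
trees), so its natural magnitude grows with the training-set size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from multiview_irf import preprocess
from multiview_irf.irf_core import (
    ForestParams,
    RitParams,
    SignedInteraction,
    bagged_stability,
    format_itemset,
    itemset_features,
    iterate_reweighted_forest,
)
from multiview_irf.synthetic_data import MultiviewCohort

__all__ = [
    "MirfConfig",
    "ReplicateResult",
    "DesignResult",
    "MirfResult",
    "MetricSummary",
    "aupr",
    "auroc",
    "replicate_ci",
    "run_replicate",
    "run_design",
    "run_mirf",
    "select_persistent_features",
    "aggregate_interactions",
]

DESIGNS = ("gene", "protein", "integrated")


@dataclass(frozen=True)
class MirfConfig:
    K: int = 5
    B: int = 50
    R: int = 100
    train_fraction: float = 0.8
    gini_min: float = 1.0
    persistence_min: float = 0.5
    stability_min: float = 0.5
    forest: ForestParams = field(default_factory=ForestParams)
    rit: RitParams = field(default_factory=RitParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1 or self.B < 1 or self.R < 1:
            raise ValueError("K, B and R must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if not 0.0 <= self.persistence_min <= 1.0:
            raise ValueError("persistence_min must lie in [0, 1]")
        if not 0.0 <= self.stability_min <= 1.0:
            raise ValueError("stability_min must lie in [0, 1]")


def aupr(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall step curve over all score thresholds.

    Thresholds sweep the distinct score values from high to low; the area
    is sum over threshold steps of (recall increment) * precision, i.e.
    average precision.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).astype(int).ravel()
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == labels.shape[0]:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    l = labels[order]
    tp = np.cumsum(l)
    fp = np.cumsum(1 - l)
    # keep only the last index of each tied block of scores
    last = np.nonzero(np.diff(s, append=-np.inf) != 0)[0]
    tp, fp = tp[last], fp[last]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    return float(np.sum(np.diff(recall, prepend=0.0) * precision))


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUROC with ties counted half."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).astype(int).ravel()
    n_pos = int(labels.sum())
    n_neg = labels.shape[0] - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass(frozen=True)
class MetricSummary:
    mean: float
    ci_low: float
    ci_high: float
    p_value: float  # one-sample t vs baseline; NaN when degenerate
    baseline: float
    n: int


def replicate_ci(values: Sequence[float], baseline: float) -> MetricSummary:
    """Mean, t-based 95% CI, and one-sample t-test p against ``baseline``."""
    vals = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 finite values")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    if sd <= 1e-12 * max(1.0, abs(mean)):  # constant vector: degenerate CI, p undefined
        return MetricSummary(mean, mean, mean, float("nan"), baseline, vals.size)
    half = stats.t.ppf(0.975, vals.size - 1) * sd / np.sqrt(vals.size)
    t_stat = (mean - baseline) / (sd / np.sqrt(vals.size))
    p = float(2.0 * stats.t.sf(abs(t_stat), vals.size - 1))
    return MetricSummary(mean, mean - half, mean + half, p, baseline, vals.size)


@dataclass
class ReplicateResult:
    importances: np.ndarray
    qualifying: np.ndarray  # bool mask, importance >= gini_min
    interactions: dict[frozenset[int], float]  # itemset -> stability
    test_aupr: float
    train_aupr: float
    interaction_auroc: float  # stability vs replicate-qualifying membership
    prevalence: float


def _stratified_split(
    y: np.ndarray, train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train_parts, test_parts = [], []
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        perm = rng.permutation(idx)
        n_train = int(round(train_fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1) if idx.size >= 2 else n_train
        train_parts.append(perm[:n_train])
        test_parts.append(perm[n_train:])
    return np.concatenate(train_parts), np.concatenate(test_parts)


def run_replicate(
    X: np.ndarray,
    y: np.ndarray,
    config: MirfConfig,
    replicate_seed: int | tuple,
) -> ReplicateResult:
    """One outer bootstrap replicate (deterministic in ``replicate_seed``)."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64).ravel()
    if np.unique(y).size != 2:
        raise ValueError("both classes must be present")
    root = np.random.SeedSequence(replicate_seed)
    boot_ss, split_ss, forest_ss, bag_ss = root.spawn(4)

    n = X.shape[0]
    rng = np.random.default_rng(boot_ss)
    bidx = rng.integers(0, n, n)

    # Split by unique sample identity so bootstrap duplicates of the same
    # subject never straddle the train/test boundary (identity leakage
    # would let purity-grown trees memorize the held-out samples).  Train
    # keeps bootstrap multiplicities; test uses each held-out subject once.
    split_rng = np.random.default_rng(split_ss)
    uniq = np.unique(bidx)
    for attempt in range(10):
        tr_u, te_u = _stratified_split(y[uniq], config.train_fraction, split_rng)
        train_orig, test_orig = uniq[tr_u], uniq[te_u]
        ok = (
            np.unique(y[train_orig]).size == 2 and np.unique(y[test_orig]).size == 2
        )
        if ok:
            break
    else:
        raise ValueError("could not obtain a split with both classes on both sides")

    train_draws = bidx[np.isin(bidx, train_orig)]
    Xtr, ytr = X[train_draws], y[train_draws]
    Xte, yte = X[test_orig], y[test_orig]
    fp = replace(config.forest, seed=int(forest_ss.generate_state(1)[0]))
    forest, weight_history = iterate_reweighted_forest(Xtr, ytr, config.K, fp)

    test_aupr = aupr(forest.predict_proba(Xte), yte)
    train_aupr = aupr(forest.predict_proba(Xtr), ytr)
    importances = forest.importances
    qualifying = importances >= config.gini_min

    interactions = {
        it.items: it.stability
        for it in bagged_stability(
            Xtr,
            ytr,
            weight_history[-1],
            config.B,
            config.forest,
            config.rit,
            seed=bag_ss,
        )
    }
    inter_auroc = _interaction_auroc(interactions, np.nonzero(qualifying)[0])
    return ReplicateResult(
        importances=importances,
        qualifying=qualifying,
        interactions=interactions,
        test_aupr=test_aupr,
        train_aupr=train_aupr,
        interaction_auroc=inter_auroc,
        prevalence=float(yte.mean()),
    )


def _interaction_auroc(
    interactions: Mapping[frozenset[int], float], active: Sequence[int]
) -> float:
    """AUROC of stability against "all members active" membership."""
    if not interactions:
        return float("nan")
    active_set = set(int(a) for a in active)
    scores = np.asarray(list(interactions.values()), dtype=float)
    labels = np.asarray(
        [itemset_features(s) <= active_set for s in interactions], dtype=int
    )
    if labels.min() == labels.max():
        return float("nan")
    return auroc(scores, labels)


def select_persistent_features(
    replicates: Sequence[ReplicateResult],
    gini_min: float,
    persistence_min: float,
    feature_names: Sequence[str],
) -> pd.DataFrame:
    """Features qualifying (importance >= gini_min) in >= persistence_min of
    replicates; both boundaries inclusive.  ``mean_gini`` averages over the
    qualifying replicates."""
    if len(replicates) == 0:
        raise ValueError("need at least one replicate")
    imp = np.stack([r.importances for r in replicates])
    qual = imp >= gini_min
    freq = qual.mean(axis=0)
    with np.errstate(invalid="ignore"):
        mean_imp = np.where(
            qual.any(axis=0), (imp * qual).sum(axis=0) / np.maximum(qual.sum(axis=0), 1), 0.0
        )
    retained = freq >= persistence_min
    table = pd.DataFrame(
        {
            "feature": list(feature_names),
            "frequency": freq,
            "mean_gini": mean_imp,
            "retained": retained,
        }
    ).sort_values(["retained", "frequency", "mean_gini"], ascending=False, kind="stable")
    return table.reset_index(drop=True)


def aggregate_interactions(
    replicates: Sequence[ReplicateResult],
    active_features: Sequence[int],
    stability_min: float,
) -> tuple[list[SignedInteraction], pd.DataFrame]:
    """Average stability over replicates (absent replicates count 0); keep
    interactions with mean stability strictly > ``stability_min`` whose
    member features are all active."""
    R = len(replicates)
    if R == 0:
        raise ValueError("need at least one replicate")
    sums: dict[frozenset[int], float] = {}
    for rep in replicates:
        for items, stab in rep.interactions.items():
            sums[items] = sums.get(items, 0.0) + stab
    active_set = set(int(a) for a in active_features)
    rows = []
    selected = []
    for items, total in sums.items():
        mean_stab = total / R
        all_active = itemset_features(items) <= active_set
        rows.append((items, mean_stab, all_active))
        if mean_stab > stability_min and all_active:
            selected.append(SignedInteraction(items=items, stability=mean_stab))
    table = pd.DataFrame(rows, columns=["items", "mean_stability", "all_active"])
    table = table.sort_values("mean_stability", ascending=False, kind="stable").reset_index(
        drop=True
    )
    selected.sort(key=lambda it: (-it.stability, len(it.items), sorted(it.items)))
    return selected, table


@dataclass
class DesignResult:
    design: str
    feature_names: list[str]
    replicates: list[ReplicateResult]
    features: pd.DataFrame  # from select_persistent_features
    interactions: list[SignedInteraction]
    interaction_table: pd.DataFrame
    aupr_summary: MetricSummary | None
    interaction_auroc_summary: MetricSummary | None

    @property
    def persistent_features(self) -> list[str]:
        return list(self.features.loc[self.features["retained"], "feature"])

    def named_interactions(self) -> list[tuple[str, float]]:
        return [(it.name(self.feature_names), it.stability) for it in self.interactions]


def run_design(
    matrix: pd.DataFrame,
    labels: np.ndarray,
    config: MirfConfig,
    design: str = "design",
    design_index: int = 0,
) -> DesignResult:
    """Run R outer replicates on one feature-by-sample matrix."""
    X = np.ascontiguousarray(matrix.to_numpy(dtype=float).T)
    y = np.asarray(labels, dtype=np.int64).ravel()
    feature_names = list(matrix.index)
    replicates = []
    for r in range(config.R):
        try:
            replicates.append(
                run_replicate(X, y, config, (config.seed, design_index, r))
            )
        except ValueError as exc:
            raise ValueError(f"design {design!r}, replicate {r}: {exc}") from exc
    features = select_persistent_features(
        replicates, config.gini_min, config.persistence_min, feature_names
    )
    active_idx = [feature_names.index(f) for f in features.loc[features["retained"], "feature"]]
    interactions, table = aggregate_interactions(replicates, active_idx, config.stability_min)
    table = table.assign(
        name=[format_itemset(items, feature_names) for items in table["items"]]
    )
    prevalence = float(np.mean([r.prevalence for r in replicates]))
    auprs = [r.test_aupr for r in replicates]
    aurocs = [r.interaction_auroc for r in replicates]
    aupr_summary = replicate_ci(auprs, prevalence) if len(auprs) >= 2 else None
    n_finite = np.sum(np.isfinite(aurocs))
    auroc_summary = replicate_ci(aurocs, 0.5) if n_finite >= 2 else None
    return DesignResult(
        design=design,
        feature_names=feature_names,
        replicates=replicates,
        features=features,
        interactions=interactions,
        interaction_table=table,
        aupr_summary=aupr_summary,
        interaction_auroc_summary=auroc_summary,
    )


@dataclass
class MirfResult:
    task: str
    config: MirfConfig
    designs: dict[str, DesignResult]
    consensus_features: list[str]

    @property
    def metadata(self) -> dict:
        return {"K": self.config.K, "B": self.config.B, "R": self.config.R, "task": self.task}


def _consensus(designs: Mapping[str, DesignResult]) -> list[str]:
    """Features persistent both in a single-view design and in the
    integrated design (under the integrated view-prefixed names)."""
    if "integrated" not in designs:
        return []
    integrated = set(designs["integrated"].persistent_features)
    consensus = []
    for view in ("gene", "protein"):
        if view not in designs:
            continue
        for feat in designs[view].persistent_features:
            if f"{view}:{feat}" in integrated:
                consensus.append(f"{view}:{feat}")
    return sorted(consensus)


def run_mirf(
    cohort: MultiviewCohort,
    task: str,
    config: MirfConfig | None = None,
    labels: pd.Series | np.ndarray | None = None,
    designs: Sequence[str] = DESIGNS,
) -> MirfResult:
    """Train the three designs (gene view, protein view, integrated) on a
    preprocessed cohort for the chosen task.

    ``labels`` overrides the clinical binarization: pass a binary vector
    aligned with the cohort samples (e.g. a synthetic cohort's planted
    outcome) to train directly against a known truth.
    """
    config = config or MirfConfig()
    if labels is None:
        lab = preprocess.binarize_outcomes(cohort.clinical).task_labels(task)
    elif isinstance(labels, pd.Series):
        lab = labels.astype(np.int64)
    else:
        lab = pd.Series(np.asarray(labels, dtype=np.int64), index=cohort.sample_ids)
    samples = list(lab.index)
    views = {
        "gene": cohort.gene_matrix.loc[:, samples],
        "protein": cohort.protein_matrix.loc[:, samples],
    }
    matrices: dict[str, pd.DataFrame] = {}
    for d in designs:
        if d == "integrated":
            matrices[d] = preprocess.integrate_views(views)
        elif d in views:
            matrices[d] = views[d]
        else:
            raise ValueError(f"unknown design {d!r}")
    results = {}
    for d, mat in matrices.items():
        results[d] = run_design(mat, lab.to_numpy(), config, design=d, design_index=DESIGNS.index(d))
    return MirfResult(
        task=task,
        config=config,
        designs=results,
        consensus_features=_consensus(results),
    )
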