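"""Signature scores, expression-mean cutoffs, zone assignment, and
PCA / t-SNE embeddings for visual validation.

The zone rule assigns a sample to the "long" or "short" survival zone
when its mean signature score lies beyond the corresponding group mean
(inclusive at the boundary), leaving a middle band unassigned; the
alternative midpoint rule assigns every sample by side of the midpoint
between the two means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StratificationCutoffs",
    "ZoneAssignment",
    "signature_score",
    "derive_cutoffs",
    "assign_zones",
    "pca_embed",
    "tsne_embed",
]


@dataclass(frozen=True)
class StratificationCutoffs:
    signature: str
    long_mean: float  # mean score among long survivors
    short_mean: float
    p_value: float  # Bonferroni-corrected Welch t-test p
    orientation: int  # sign of (short_mean - long_mean)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.long_mean) and np.isfinite(self.short_mean)):
            raise ValueError("cutoffs must be finite")


@dataclass
class ZoneAssignment:
    zones: pd.Series  # per-sample in {"long", "short", "unassigned"}
    assigned_fraction: float

    def __post_init__(self) -> None:
        counts = self.zones.value_counts()
        total = counts.sum()
        frac = (counts.get("long", 0) + counts.get("short", 0)) / total
        if abs(frac - self.assigned_fraction) > 1e-12:
            raise ValueError("assigned_fraction inconsistent with zones")


def signature_score(
    matrix: pd.DataFrame, signature_features: Sequence[str]
) -> pd.Series:
    """Unweighted per-sample mean of the signature features' expression.

    Duplicated signature entries are deduplicated and features absent from
    the matrix are skipped, both with a warning; no overlap is an error.
    """
    seen: dict[str, None] = {}
    for f in signature_features:
        if f in seen:
            warnings.warn(f"duplicated signature feature {f!r} deduplicated", stacklevel=2)
        seen.setdefault(f)
    present = [f for f in seen if f in matrix.index]
    absent = [f for f in seen if f not in matrix.index]
    if absent:
        warnings.warn(f"signature features absent from matrix, skipped: {absent}", stacklevel=2)
    if not present:
        raise ValueError("no overlap between signature and matrix features")
    return matrix.loc[present].mean(axis=0)


def derive_cutoffs(
    scores: pd.Series | np.ndarray,
    os_class: pd.Series | np.ndarray,
    n_tests: int = 1,
    signature: str = "signature",
) -> StratificationCutoffs:
    """Group-mean cutoffs with a Bonferroni-corrected non-paired t-test.

    ``os_class`` must label each sample "long" or "short" (other labels are
    ignored); the p-value is the two-sided Welch t-test p multiplied by
    ``n_tests``, capped at 1.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    cls = np.asarray(os_class).ravel()
    long_scores = scores[cls == "long"]
    short_scores = scores[cls == "short"]
    if long_scores.size < 2 or short_scores.size < 2:
        raise ValueError("each group needs at least 2 samples")
    _, p_raw = stats.ttest_ind(long_scores, short_scores, equal_var=False)
    p = min(float(p_raw) * n_tests, 1.0)
    long_mean = float(long_scores.mean())
    short_mean = float(short_scores.mean())
    return StratificationCutoffs(
        signature=signature,
        long_mean=long_mean,
        short_mean=short_mean,
        p_value=p,
        orientation=int(np.sign(short_mean - long_mean)),
    )


def assign_zones(
    scores: pd.Series,
    cutoffs: StratificationCutoffs,
    rule: str = "beyond-mean",
) -> ZoneAssignment:
    """Assign samples to survival zones by the group-mean cutoffs.

    ``beyond-mean`` (default): with long_mean < short_mean, a sample is
    "long" iff score <= long_mean and "short" iff score >= short_mean
    (boundaries inclusive), else unassigned; orientation mirrors when the
    long mean is the larger one.  ``midpoint``: every sample is assigned by
    its side of the midpoint between the two means.
    """
    if cutoffs.long_mean == cutoffs.short_mean:
        raise ValueError("equal cutoffs give no zone separation")
    if not isinstance(scores, pd.Series):
        scores = pd.Series(np.asarray(scores, dtype=float))
    values = scores.to_numpy(dtype=float)
    zones = np.full(values.shape[0], "unassigned", dtype=object)
    lo_is_long = cutoffs.long_mean < cutoffs.short_mean
    if rule == "beyond-mean":
        if lo_is_long:
            zones[values <= cutoffs.long_mean] = "long"
            zones[values >= cutoffs.short_mean] = "short"
        else:
            zones[values >= cutoffs.long_mean] = "long"
            zones[values <= cutoffs.short_mean] = "short"
    elif rule == "midpoint":
        mid = 0.5 * (cutoffs.long_mean + cutoffs.short_mean)
        if lo_is_long:
            zones[values <= mid] = "long"
            zones[values > mid] = "short"
        else:
            zones[values > mid] = "long"
            zones[values <= mid] = "short"
    else:
        raise ValueError("rule must be 'beyond-mean' or 'midpoint'")
    series = pd.Series(zones, index=scores.index)
    frac = float(np.mean(zones != "unassigned"))
    return ZoneAssignment(zones=series, assigned_fraction=frac)


def pca_embed(
    matrix: pd.DataFrame, n_components: int = 3
) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered-SVD principal components of samples (columns of ``matrix``).

    Returns (samples x components scores, explained variance ratios).
    Requests beyond the matrix rank are truncated with a warning.
    """
    from sklearn.decomposition import PCA

    X = matrix.to_numpy(dtype=float).T  # samples x features
    max_comp = min(X.shape[0] - 1, X.shape[1]) if X.shape[0] > 1 else 1
    if n_components > max_comp:
        warnings.warn(
            f"n_components reduced from {n_components} to {max_comp} (rank limit)",
            stacklevel=2,
        )
        n_components = max_comp
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    # truncate components beyond the numerical rank of the centered data
    sv = pca.singular_values_
    keep = int(np.sum(sv > 1e-10 * max(sv[0], 1e-300)))
    if keep < scores.shape[1]:
        warnings.warn(
            f"data rank {keep} below requested {scores.shape[1]} components; truncating",
            stacklevel=2,
        )
        scores = scores[:, :keep]
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return (
        pd.DataFrame(scores, index=matrix.columns, columns=cols),
        pca.explained_variance_ratio_[: scores.shape[1]],
    )


def tsne_embed(
    matrix: pd.DataFrame,
    perplexity: float | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Seed-stable 2-D t-SNE of the samples (columns of ``matrix``).

    The default perplexity is floor(sqrt(n_samples)); a stated perplexity
    must satisfy perplexity < (n_samples - 1) / 3.
    """
    from sklearn.manifold import TSNE

    X = matrix.to_numpy(dtype=float).T
    n = X.shape[0]
    limit = (n - 1) / 3.0
    if perplexity is None:
        perplexity = float(max(min(np.floor(np.sqrt(n)), np.ceil(limit) - 1), 1.0))
    if not 0 < perplexity < limit:
        raise ValueError(
            f"perplexity must lie in (0, {limit:.2f}) for n={n}; got {perplexity}"
        )
    emb = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
        n_jobs=1,
    ).fit_transform(X)
    return pd.DataFrame(emb, index=matrix.columns, columns=["tsne1", "tsne2"])
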