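"""Cleaning, imputation, standardization, outcome binarization and
differential-expression screening.

Conventions: expression matrices are feature-by-sample DataFrames on a
log/z scale.  "Effect" in the screen is the difference of class means,
which is the fold-change convention for data that are already on a log
scale; the moderated statistic shrinks per-feature variances toward a
common prior fitted by moments on the log sample variances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "ScreenConfig",
    "OutcomeLabels",
    "read_expression_matrix",
    "read_clinical",
    "drop_high_missing",
    "knn_impute",
    "zscore_standardize",
    "binarize_outcomes",
    "deg_screen",
    "integrate_views",
    "split_views",
]

OS_SHORT_MAX = 6.0  # months; short-term survivors
OS_LONG_MIN = 24.0  # months; long-term survivors
KPS_HIGH_MIN = 80
KPS_LOW_MAX = 60


@dataclass
class ScreenConfig:
    fdr_threshold: float = 0.05
    lfc_threshold: float = 0.5
    missing_threshold: float = 0.8
    impute_k: int = 10

    def __post_init__(self) -> None:
        for name in ("fdr_threshold", "missing_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.lfc_threshold < 0:
            raise ValueError("lfc_threshold must be >= 0")
        if self.impute_k < 1:
            raise ValueError("impute_k must be >= 1")


@dataclass
class OutcomeLabels:
    """Per-sample class labels for the survival and performance tasks.

    ``os_class`` is ``short`` (os_months <= 6), ``long`` (os_months >= 24)
    or ``excluded``; ``kps_class`` is ``high`` (kps >= 80), ``low``
    (kps <= 60) or ``excluded``.  Excluded samples are dropped before
    training the respective task.
    """

    os_class: pd.Series
    kps_class: pd.Series

    def task_labels(self, task: str) -> pd.Series:
        """Binary labels (1 = long survival / high KPS) for non-excluded samples."""
        if task == "os":
            cls = self.os_class
            mapping = {"long": 1, "short": 0}
        elif task == "kps":
            cls = self.kps_class
            mapping = {"high": 1, "low": 0}
        else:
            raise ValueError(f"unknown task {task!r}; expected 'os' or 'kps'")
        usable = cls[cls != "excluded"]
        return usable.map(mapping).astype(np.int64)


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a Firehose-style TSV: first column feature symbols, then samples."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df.index.name = "feature"
    return df.astype(float)


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a cBioPortal-style clinical TSV into os_months/os_event/kps columns."""
    raw = pd.read_csv(path, sep="\t")
    required = {"SAMPLE_ID", "OS_MONTHS", "OS_STATUS"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    status = raw["OS_STATUS"].astype(str).str.upper()
    # cBioPortal encodes status either as LIVING/DECEASED or "1:DECEASED".
    event = status.str.contains("DECEASED").astype(np.int64)
    out = pd.DataFrame(
        {
            "os_months": raw["OS_MONTHS"].astype(float).to_numpy(),
            "os_event": event.to_numpy(),
        },
        index=raw["SAMPLE_ID"].astype(str).to_numpy(),
    )
    if "KPS" in raw.columns:
        out["kps"] = raw["KPS"].to_numpy()
    return out


def drop_high_missing(
    matrix: pd.DataFrame, missing_threshold: float = 0.8
) -> tuple[pd.DataFrame, list[str]]:
    """Remove features whose missing fraction is >= threshold (inclusive)."""
    if matrix.shape[0] < 1:
        raise ValueError("matrix must have at least one feature")
    frac = matrix.isna().mean(axis=1)
    removed = list(matrix.index[frac >= missing_threshold])
    kept = matrix.drop(index=removed)
    if kept.shape[0] == 0:
        raise ValueError(
            "all features exceed the missingness threshold; "
            "raise missing_threshold or inspect the input"
        )
    return kept, removed


def _masked_feature_distances(arr: np.ndarray) -> np.ndarray:
    """Pairwise root-mean-square distance between features over mutually
    observed samples; inf where no sample is shared."""
    obs = ~np.isnan(arr)
    filled = np.where(obs, arr, 0.0)
    m = obs.astype(float)
    shared = m @ m.T
    sq = filled**2
    ssd = sq @ m.T + m @ sq.T - 2.0 * (filled @ filled.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.sqrt(np.maximum(ssd, 0.0) / shared)
    d[shared == 0] = np.inf
    return d


def knn_impute(matrix: pd.DataFrame, impute_k: int = 10) -> pd.DataFrame:
    """Replace each missing entry by the mean of the k nearest features.

    Neighbors are *features* (the convention of expression-array imputation):
    distance is root-mean-square difference over mutually observed samples.
    Among the k nearest features, only values observed at the target sample
    contribute; if none are observed the feature's own observed mean is used
    (with a warning).  Observed entries are never altered.
    """
    arr = matrix.to_numpy(dtype=float, copy=True)
    nan_rows = np.isnan(arr).all(axis=1)
    if nan_rows.any():
        bad = list(matrix.index[nan_rows])
        raise ValueError(
            f"features with zero observed values cannot be imputed: {bad}; "
            "drop them with drop_high_missing first"
        )
    if not np.isnan(arr).any():
        return matrix.copy()
    dist = _masked_feature_distances(arr)
    np.fill_diagonal(dist, np.inf)
    p = arr.shape[0]
    k = min(impute_k, p - 1)
    order = np.argsort(dist, axis=1, kind="stable")
    row_means = np.nanmean(arr, axis=1)
    out = arr.copy()
    miss_r, miss_c = np.nonzero(np.isnan(arr))
    for f, s in zip(miss_r, miss_c):
        neighbors = [g for g in order[f] if np.isfinite(dist[f, g])][:k]
        vals = [arr[g, s] for g in neighbors if not np.isnan(arr[g, s])]
        if vals:
            out[f, s] = float(np.mean(vals))
        else:
            warnings.warn(
                f"no observed neighbor value for feature {matrix.index[f]!r} "
                f"at sample {matrix.columns[s]!r}; using the feature mean",
                stacklevel=2,
            )
            out[f, s] = row_means[f]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def zscore_standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Center and scale each feature to mean 0, population sd 1."""
    arr = matrix.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValueError("matrix must be complete; impute missing values first")
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)
    constant = sd[:, 0] == 0.0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature(s) mapped to all-zeros",
            stacklevel=2,
        )
    sd[sd == 0.0] = 1.0
    return pd.DataFrame((arr - mean) / sd, index=matrix.index, columns=matrix.columns)


def binarize_outcomes(clinical: pd.DataFrame) -> OutcomeLabels:
    """Binarize OS months and KPS into the two classification tasks."""
    os_months = clinical["os_months"].astype(float)
    if (os_months < 0).any():
        raise ValueError("os_months must be non-negative")
    os_class = pd.Series("excluded", index=clinical.index, dtype=object)
    os_class[os_months <= OS_SHORT_MAX] = "short"
    os_class[os_months >= OS_LONG_MIN] = "long"
    if (os_class == "excluded").all():
        raise ValueError("OS task is empty: no sample is short- or long-term")
    if "kps" in clinical.columns:
        kps = clinical["kps"].astype(float)
        kps_class = pd.Series("excluded", index=clinical.index, dtype=object)
        kps_class[kps >= KPS_HIGH_MIN] = "high"
        kps_class[kps <= KPS_LOW_MAX] = "low"
    else:
        kps_class = pd.Series("excluded", index=clinical.index, dtype=object)
    return OutcomeLabels(os_class=os_class, kps_class=kps_class)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (moments fit helper)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Fit (d0, s0^2) by moments on log sample variances.

    E[log s^2] = log sigma^2 + psi(d/2) - log(d/2) and Var[log s^2] =
    psi'(d/2); excess spread of the observed log-variances over psi'(d/2)
    determines the prior degrees of freedom d0, the mean determines s0^2.
    """
    s2 = np.maximum(s2, 1e-300)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    excess = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0)) if len(e) > 1 else 0.0
    if excess <= 0.0:
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def deg_screen(
    matrix: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    config: ScreenConfig | None = None,
    method: str = "moderated",
) -> tuple[list[str], pd.DataFrame]:
    """Two-group differential screen with empirical-Bayes variance shrinkage.

    Returns the selected feature names (FDR < ``fdr_threshold`` and
    ``|effect| > lfc_threshold``) and a per-feature table with columns
    ``effect`` (difference of class means, class 1 minus class 0), ``t``,
    ``p`` and ``fdr`` (Benjamini-Hochberg).  ``method="welch"`` gives a
    plain Welch t-test for comparison.
    """
    config = config or ScreenConfig()
    if isinstance(labels, pd.Series):
        matrix = matrix.loc[:, labels.index]
        labels = labels.to_numpy()
    labels = np.asarray(labels).astype(int)
    arr = matrix.to_numpy(dtype=float)
    x1 = arr[:, labels == 1]
    x0 = arr[:, labels == 0]
    n1, n0 = x1.shape[1], x0.shape[1]
    if n1 < 2 or n0 < 2:
        raise ValueError("each class needs at least 2 samples")
    effect = x1.mean(axis=1) - x0.mean(axis=1)
    if method == "welch":
        t, p = stats.ttest_ind(x1, x0, axis=1, equal_var=False)
    elif method == "moderated":
        df = n1 + n0 - 2
        pooled = (x1.var(axis=1, ddof=1) * (n1 - 1) + x0.var(axis=1, ddof=1) * (n0 - 1)) / df
        d0, s0_sq = _fit_variance_prior(pooled, df)
        if np.isinf(d0):
            post = np.full_like(pooled, s0_sq)
            df_total = np.inf
        else:
            post = (d0 * s0_sq + df * pooled) / (d0 + df)
            df_total = df + d0
        se = np.sqrt(post * (1.0 / n1 + 1.0 / n0))
        t = effect / se
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df_total)
    else:
        raise ValueError(f"unknown method {method!r}")
    fdr = _benjamini_hochberg(p)
    table = pd.DataFrame(
        {"effect": effect, "t": t, "p": p, "fdr": fdr}, index=matrix.index
    )
    selected_mask = (table["fdr"] < config.fdr_threshold) & (
        table["effect"].abs() > config.lfc_threshold
    )
    return list(table.index[selected_mask]), table


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    m = p.shape[0]
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def integrate_views(views: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Concatenate views feature-wise with view-prefixed feature names."""
    frames = []
    ref_cols: list[str] | None = None
    for view, mat in views.items():
        if ref_cols is None:
            ref_cols = list(mat.columns)
        elif list(mat.columns) != ref_cols:
            raise ValueError("views must share an identical sample order")
        renamed = mat.copy()
        renamed.index = [f"{view}:{f}" for f in mat.index]
        frames.append(renamed)
    if not frames:
        raise ValueError("no views to integrate")
    return pd.concat(frames, axis=0)


def split_views(integrated: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Invert :func:`integrate_views`, recovering the per-view matrices."""
    out: dict[str, pd.DataFrame] = {}
    for name in integrated.index:
        view, _, feat = name.partition(":")
        out.setdefault(view, []).append((feat, name))
    views = {}
    for view, pairs in out.items():
        feats = [f for f, _ in pairs]
        rows = [orig for _, orig in pairs]
        mat = integrated.loc[rows].copy()
        mat.index = feats
        views[view] = mat
    return views
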