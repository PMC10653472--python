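"""Synthetic two-omics cohort generator with known planted signal.

Every downstream stage of the pipeline is exercised against cohorts whose
ground truth is known exactly: a small set of planted features acts on a
binary outcome through a low-order Boolean rule, survival times follow a
Weibull proportional-hazards model that is linear in the planted features,
and a KPS-like ordinal covariate is positively coupled to the survival
score.

All distributional choices here (independent standard-normal background,
Gaussian cross-view coupling, Weibull baseline) are stand-ins: they are not
estimated from any real cohort and exist only to give the pipeline a
controllable truth.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "ConfigError",
    "BooleanRule",
    "PlantedFeature",
    "SimulationConfig",
    "MultiviewCohort",
    "simulate_multiomics",
    "boolean_outcome",
    "simulate_survival",
    "inject_missing",
    "write_cohort_files",
    "gene_name",
    "protein_name",
]

VIEWS = ("gene", "protein")


class ConfigError(ValueError):
    """Raised when a simulation configuration field is invalid."""


def gene_name(index: int) -> str:
    return f"G{index:04d}"


def protein_name(index: int) -> str:
    return f"P{index:04d}"


_LITERAL_RE = re.compile(r"^(?P<name>[A-Za-z0-9_.:]+)(?P<sign>[+-])$")


@dataclass(frozen=True)
class BooleanRule:
    """OR-of-AND rule over zero-thresholded features.

    A literal ``(name, +1)`` is true when the feature value is > 0 and
    ``(name, -1)`` when it is <= 0.  The rule is true when at least one
    clause has all its literals true.  An empty rule is always false.
    """

    clauses: tuple[tuple[tuple[str, int], ...], ...] = ()

    @classmethod
    def parse(cls, clauses: Sequence[Sequence[str]]) -> "BooleanRule":
        """Build a rule from string literals such as ``[["G0001+", "P0000-"]]``."""
        parsed = []
        for clause in clauses:
            lits = []
            for lit in clause:
                m = _LITERAL_RE.match(lit.strip())
                if m is None:
                    raise ConfigError(f"boolean_rule: cannot parse literal {lit!r}")
                lits.append((m.group("name"), 1 if m.group("sign") == "+" else -1))
            parsed.append(tuple(lits))
        return cls(tuple(parsed))

    @property
    def features(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for clause in self.clauses:
            for name, _ in clause:
                seen.setdefault(name)
        return tuple(seen)

    def evaluate(self, values: Mapping[str, np.ndarray]) -> np.ndarray:
        """Vectorised truth value of the rule for each sample."""
        n = None
        for name in self.features:
            if name not in values:
                raise ConfigError(f"boolean_rule references unknown feature {name!r}")
            n = np.asarray(values[name]).shape[0]
        if n is None:  # empty rule
            lengths = {np.asarray(v).shape[0] for v in values.values()}
            n = lengths.pop() if len(lengths) == 1 else 0
            return np.zeros(n, dtype=bool)
        out = np.zeros(n, dtype=bool)
        for clause in self.clauses:
            truth = np.ones(n, dtype=bool)
            for name, sign in clause:
                v = np.asarray(values[name], dtype=float)
                truth &= (v > 0.0) if sign > 0 else (v <= 0.0)
            out |= truth
        return out


@dataclass(frozen=True)
class PlantedFeature:
    view: str
    index: int
    sign: int = 1

    @property
    def name(self) -> str:
        return gene_name(self.index) if self.view == "gene" else protein_name(self.index)


@dataclass
class SimulationConfig:
    n_samples: int = 200
    p_gene: int = 100
    p_protein: int = 50
    planted_features: tuple[PlantedFeature, ...] = ()
    boolean_rule: BooleanRule = field(default_factory=BooleanRule)
    p_signal: float = 0.9
    p_noise: float = 0.1
    beta: tuple[float, ...] = ()
    weibull_shape: float = 1.5
    weibull_scale: float = 18.0
    censor_rate: float = 0.2
    missing_rate: float = 0.0
    # (gene index, protein index) pairs whose protein feature is a noisy copy
    # of the gene feature at correlation cross_view_rho.
    coupled_pairs: tuple[tuple[int, int], ...] = ()
    cross_view_rho: float = 0.6
    kps_coupling: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ConfigError("n_samples must be >= 1")
        if self.p_gene < 1 or self.p_protein < 1:
            raise ConfigError("p_gene and p_protein must be >= 1")
        if not 0.0 <= self.p_noise <= 1.0 or not 0.0 <= self.p_signal <= 1.0:
            raise ConfigError("p_signal and p_noise must lie in [0, 1]")
        if self.p_signal < self.p_noise:
            raise ConfigError("p_signal must be >= p_noise")
        for frac, fname in ((self.censor_rate, "censor_rate"), (self.missing_rate, "missing_rate")):
            if not 0.0 <= frac < 1.0:
                raise ConfigError(f"{fname} must lie in [0, 1)")
        self.planted_features = tuple(
            pf if isinstance(pf, PlantedFeature) else PlantedFeature(*pf)
            for pf in self.planted_features
        )
        bounds = {"gene": self.p_gene, "protein": self.p_protein}
        for pf in self.planted_features:
            if pf.view not in VIEWS:
                raise ConfigError(f"planted_features: unknown view {pf.view!r}")
            if not 0 <= pf.index < bounds[pf.view]:
                raise ConfigError(
                    f"planted_features: index {pf.index} out of bounds for view {pf.view!r}"
                )
        if self.beta and len(self.beta) != len(self.planted_features):
            raise ConfigError("beta must align with planted_features")
        if self.beta and not np.all(np.isfinite(self.beta)):
            raise ConfigError("beta must be finite")
        planted_names = {pf.name for pf in self.planted_features}
        for name in self.boolean_rule.features:
            if name not in planted_names:
                raise ConfigError(f"boolean_rule references non-planted feature {name!r}")
        for gi, pi in self.coupled_pairs:
            if not (0 <= gi < self.p_gene and 0 <= pi < self.p_protein):
                raise ConfigError("coupled_pairs: index out of bounds")
        if not -1.0 < self.cross_view_rho < 1.0:
            raise ConfigError("cross_view_rho must lie in (-1, 1)")
        if self.weibull_shape <= 0 or self.weibull_scale <= 0:
            raise ConfigError("weibull_shape and weibull_scale must be > 0")


@dataclass
class MultiviewCohort:
    """Aligned sample set: two feature-by-sample views plus clinical outcomes."""

    sample_ids: list[str]
    gene_matrix: pd.DataFrame
    protein_matrix: pd.DataFrame
    clinical: pd.DataFrame
    truth: dict | None = None

    def __post_init__(self) -> None:
        ids = list(self.sample_ids)
        for mat in (self.gene_matrix, self.protein_matrix):
            if list(mat.columns) != ids:
                raise ValueError("all views must share an identical sample order")
            if mat.index.duplicated().any():
                raise ValueError("duplicated feature names within a view")
        if list(self.clinical.index) != ids:
            raise ValueError("clinical table must share the sample order of the views")
        if (self.clinical["os_months"] < 0).any():
            raise ValueError("os_months must be >= 0")

    @property
    def views(self) -> dict[str, pd.DataFrame]:
        return {"gene": self.gene_matrix, "protein": self.protein_matrix}


def boolean_outcome(
    values: Mapping[str, np.ndarray] | pd.DataFrame,
    rule: BooleanRule,
    p_signal: float,
    p_noise: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Binary labels: 1 w.p. ``p_signal`` where the rule is true, else ``p_noise``."""
    if isinstance(values, pd.DataFrame):
        values = {name: values.loc[name].to_numpy() for name in values.index}
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    truth = rule.evaluate(values)
    prob = np.where(truth, p_signal, p_noise)
    return (rng.random(truth.shape[0]) < prob).astype(np.int64)


def simulate_survival(
    values: np.ndarray,
    beta: Sequence[float],
    weibull_shape: float,
    weibull_scale: float,
    censor_rate: float,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Weibull proportional-hazards event times with calibrated random censoring.

    The hazard is ``h0(t) * exp(values @ beta)`` with a Weibull baseline, so
    ``T = scale * (E / exp(lp)) ** (1 / shape)`` for a unit exponential ``E``.
    Censoring times are exponential with a rate chosen (by root finding on
    the realised event times) so that the expected censored fraction equals
    ``censor_rate``.  Returns ``(os_months, os_event)``; ``os_event == 0``
    means censored.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 1 and len(beta) == 1 and values.shape[1] != 1:
        values = values.T
    beta = np.asarray(beta, dtype=float)
    if beta.shape[0] != values.shape[1]:
        raise ValueError("beta must align with the provided features")
    if not np.all(np.isfinite(beta)):
        raise ValueError("beta must be finite")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = values.shape[0]
    lp = values @ beta
    event_t = weibull_scale * (rng.exponential(size=n) / np.exp(lp)) ** (1.0 / weibull_shape)
    if censor_rate <= 0.0:
        return event_t, np.ones(n, dtype=np.int64)

    def expected_censored(rate: float) -> float:
        # P(C < t) = 1 - exp(-rate * t) for exponential censoring.
        return float(np.mean(-np.expm1(-rate * event_t))) - censor_rate

    lo, hi = 1e-12, 1e-6
    while expected_censored(hi) < 0 and hi < 1e12:
        hi *= 10.0
    rate = brentq(expected_censored, lo, hi)
    censor_t = rng.exponential(scale=1.0 / rate, size=n)
    os_months = np.minimum(event_t, censor_t)
    os_event = (event_t <= censor_t).astype(np.int64)
    return os_months, os_event


def inject_missing(
    matrix: pd.DataFrame | np.ndarray,
    missing_rate: float,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame | np.ndarray:
    """Set entries missing completely at random at the stated rate."""
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must lie in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arr = matrix.to_numpy(dtype=float, copy=True) if isinstance(matrix, pd.DataFrame) else np.array(matrix, dtype=float)
    if missing_rate > 0.0:
        mask = rng.random(arr.shape) < missing_rate
        arr[mask] = np.nan
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(arr, index=matrix.index, columns=matrix.columns)
    return arr


def _simulate_kps(lp: np.ndarray, coupling: float, rng: np.random.Generator) -> np.ndarray:
    """Ordinal KPS in {40, 60, 80, 100}, positively coupled to survival.

    The latent score is a convex Gaussian mixture of the negated (higher
    hazard -> worse status) standardized linear predictor and fresh noise,
    thresholded at the standard-normal quartiles.
    """
    n = lp.shape[0]
    sd = lp.std()
    z = (lp - lp.mean()) / sd if sd > 0 else np.zeros(n)
    latent = coupling * (-z) + np.sqrt(max(1.0 - coupling**2, 0.0)) * rng.standard_normal(n)
    from scipy.stats import norm

    cuts = norm.ppf([0.25, 0.5, 0.75])
    return np.asarray([40, 60, 80, 100])[np.searchsorted(cuts, latent)]


def simulate_multiomics(config: SimulationConfig) -> MultiviewCohort:
    """Generate a two-view cohort whose truth block records the planted signal.

    Both views are independent standard normal except for cross-view coupled
    pairs; the Boolean rule over the planted features drives the binary
    outcome, and the survival log-hazard is linear in the planted features.
    Bit-identical output for a fixed seed.
    """
    if not isinstance(config, SimulationConfig):
        raise ConfigError("config must be a SimulationConfig")
    root = np.random.SeedSequence(config.seed)
    views_ss, outcome_ss, surv_ss, kps_ss, miss_ss = root.spawn(5)
    rng = np.random.default_rng(views_ss)

    n = config.n_samples
    sample_ids = [f"S{i:04d}" for i in range(n)]
    gene = rng.standard_normal((config.p_gene, n))
    protein = rng.standard_normal((config.p_protein, n))
    rho = config.cross_view_rho
    for gi, pi in config.coupled_pairs:
        protein[pi] = rho * gene[gi] + np.sqrt(1.0 - rho**2) * protein[pi]

    raw = {"gene": gene, "protein": protein}
    planted_values = {
        pf.name: raw[pf.view][pf.index].copy() for pf in config.planted_features
    }
    outcome = boolean_outcome(
        planted_values,
        config.boolean_rule,
        config.p_signal,
        config.p_noise,
        np.random.default_rng(outcome_ss),
    )

    beta = np.asarray(
        config.beta if config.beta else np.zeros(len(config.planted_features)), dtype=float
    )
    if planted_values:
        design = np.column_stack([planted_values[pf.name] for pf in config.planted_features])
    else:
        design = np.zeros((n, 0))
    os_months, os_event = simulate_survival(
        design,
        beta,
        config.weibull_shape,
        config.weibull_scale,
        config.censor_rate,
        np.random.default_rng(surv_ss),
    )
    lp = design @ beta if design.size else np.zeros(n)
    kps = _simulate_kps(lp, config.kps_coupling, np.random.default_rng(kps_ss))

    gene_df = pd.DataFrame(gene, index=[gene_name(i) for i in range(config.p_gene)], columns=sample_ids)
    protein_df = pd.DataFrame(
        protein, index=[protein_name(i) for i in range(config.p_protein)], columns=sample_ids
    )
    if config.missing_rate > 0.0:
        miss_rng = np.random.default_rng(miss_ss)
        gene_df = inject_missing(gene_df, config.missing_rate, miss_rng)
        protein_df = inject_missing(protein_df, config.missing_rate, miss_rng)

    clinical = pd.DataFrame(
        {"os_months": os_months, "os_event": os_event, "kps": kps}, index=sample_ids
    )
    truth = {
        "planted_features": [(pf.view, pf.index, pf.name, pf.sign) for pf in config.planted_features],
        "planted_names": [pf.name for pf in config.planted_features],
        "rule": config.boolean_rule,
        "beta": beta,
        "outcome": outcome,
        "linear_predictor": lp,
    }
    return MultiviewCohort(
        sample_ids=sample_ids,
        gene_matrix=gene_df,
        protein_matrix=protein_df,
        clinical=clinical,
        truth=truth,
    )


def write_cohort_files(cohort: MultiviewCohort, directory: str | Path) -> dict[str, Path]:
    """Write Firehose-style expression TSVs and a cBioPortal-style clinical TSV.

    Missing entries are serialized as ``NA``.  The files round-trip through
    :func:`multiview_irf.preprocess.read_expression_matrix` and
    :func:`multiview_irf.preprocess.read_clinical`.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - filesystem dependent
        raise OSError(f"cannot create output directory {directory}: {exc}") from exc
    paths = {
        "gene": directory / "gene_expression.tsv",
        "protein": directory / "protein_expression.tsv",
        "clinical": directory / "clinical.tsv",
    }
    for view, mat in cohort.views.items():
        out = mat.copy()
        out.index.name = "feature"
        out.to_csv(paths[view], sep="\t", na_rep="NA", float_format="%.17g")
    clin = pd.DataFrame(
        {
            "SAMPLE_ID": cohort.sample_ids,
            "OS_MONTHS": cohort.clinical["os_months"].to_numpy(),
            "OS_STATUS": np.where(
                cohort.clinical["os_event"].to_numpy() == 1, "DECEASED", "LIVING"
            ),
            "KPS": cohort.clinical["kps"].to_numpy(),
        }
    )
    clin.to_csv(paths["clinical"], sep="\t", index=False, float_format="%.17g")
    return paths
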