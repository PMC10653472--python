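import numpy as np
import pandas as pd
import pytest
from scipy import stats

from multiview_irf import preprocess, survival
from multiview_irf.synthetic_data import (
    BooleanRule,
    ConfigError,
    MultiviewCohort,
    PlantedFeature,
    SimulationConfig,
    boolean_outcome,
    inject_missing,
    simulate_multiomics,
    simulate_survival,
    write_cohort_files,
)
from tests.conftest import make_config


class TestBooleanRule:
    def test_parse_and_features(self):
        rule = BooleanRule.parse([["G0001+", "P0000-"], ["G0002+"]])
        assert rule.features == ("G0001", "P0000", "G0002")

    def test_evaluate_or_of_ands(self):
        rule = BooleanRule.parse([["a+", "b+"], ["c-"]])
        vals = {
            "a": np.array([1.0, 1.0, -1.0]),
            "b": np.array([1.0, -1.0, -1.0]),
            "c": np.array([1.0, 1.0, -1.0]),
        }
        assert rule.evaluate(vals).tolist() == [True, False, True]

    def test_empty_rule_always_false(self):
        rule = BooleanRule()
        assert not rule.evaluate({"x": np.zeros(4)}).any()

    def test_unknown_feature_errors(self):
        rule = BooleanRule.parse([["zz+"]])
        with pytest.raises(ConfigError, match="zz"):
            rule.evaluate({"a": np.zeros(3)})

    def test_bad_literal(self):
        with pytest.raises(ConfigError):
            BooleanRule.parse([["G0001"]])


class TestConfigValidation:
    def test_p_signal_below_p_noise(self):
        with pytest.raises(ConfigError, match="p_signal"):
            make_config(p_signal=0.1, p_noise=0.9)

    def test_planted_index_out_of_bounds(self):
        with pytest.raises(ConfigError, match="index"):
            make_config(planted_features=(PlantedFeature("gene", 999),), beta=(1.0,),
                        boolean_rule=BooleanRule(), coupled_pairs=())

    def test_censor_rate_bounds(self):
        with pytest.raises(ConfigError, match="censor_rate"):
            make_config(censor_rate=1.0)

    def test_rule_must_reference_planted(self):
        with pytest.raises(ConfigError, match="non-planted"):
            make_config(boolean_rule=BooleanRule.parse([["G0039+"]]))


class TestSimulateMultiomics:
    def test_no_signal_association_null(self):
        cfg = make_config(
            n_samples=1000, p_gene=20, p_protein=10, p_signal=0.5, p_noise=0.5, seed=3
        )
        cohort = simulate_multiomics(cfg)
        y = cohort.truth["outcome"]
        for mat in (cohort.gene_matrix, cohort.protein_matrix):
            for _, row in mat.iterrows():
                r = stats.pointbiserialr(y, row.to_numpy()).statistic
                assert abs(r) < 0.1

    def test_outcome_prevalence_matches_rule_probability(self):
        # spec example rule (g1>0 & g2>0) | (p1>0) on independent normals:
        # P(rule) = 1 - (1 - 1/4) * 1/2 = 0.625 -> prevalence 0.9*.625+.1*.375
        cfg = make_config(
            n_samples=500,
            boolean_rule=BooleanRule.parse([["G0000+", "G0001+"], ["P0000+"]]),
            coupled_pairs=(),
            seed=2,
        )
        cohort = simulate_multiomics(cfg)
        expected = 0.9 * 0.625 + 0.1 * 0.375
        assert abs(cohort.truth["outcome"].mean() - expected) < 0.05

    def test_determinism(self):
        a = simulate_multiomics(make_config(seed=5))
        b = simulate_multiomics(make_config(seed=5))
        pd.testing.assert_frame_equal(a.gene_matrix, b.gene_matrix)
        pd.testing.assert_frame_equal(a.protein_matrix, b.protein_matrix)
        pd.testing.assert_frame_equal(a.clinical, b.clinical)
        assert np.array_equal(a.truth["outcome"], b.truth["outcome"])

    def test_cross_view_coupling(self):
        cohort = simulate_multiomics(make_config(n_samples=2000, seed=9))
        g = cohort.gene_matrix.loc["G0000"].to_numpy()
        p = cohort.protein_matrix.loc["P0000"].to_numpy()
        assert abs(np.corrcoef(g, p)[0, 1] - 0.6) < 0.06

    def test_kps_levels_and_coupling(self, small_cohort):
        assert set(small_cohort.clinical["kps"]) <= {40, 60, 80, 100}

    def test_cohort_invariants_enforced(self, small_cohort):
        clin = small_cohort.clinical.copy()
        clin.iloc[0, clin.columns.get_loc("os_months")] = -1.0
        with pytest.raises(ValueError, match="os_months"):
            MultiviewCohort(
                small_cohort.sample_ids,
                small_cohort.gene_matrix,
                small_cohort.protein_matrix,
                clin,
            )


class TestBooleanOutcome:
    def test_deterministic_rule_exact(self):
        rng = np.random.default_rng(0)
        vals = {"g1": rng.standard_normal(500)}
        labels = boolean_outcome(vals, BooleanRule.parse([["g1+"]]), 1.0, 0.0, seed=1)
        assert np.array_equal(labels, (vals["g1"] > 0).astype(int))

    def test_empty_rule_bernoulli_noise(self):
        labels = boolean_outcome(
            {"g1": np.zeros(4000)}, BooleanRule(), 0.9, 0.25, seed=2
        )
        assert abs(labels.mean() - 0.25) < 0.03

    def test_and_rule_closed_form_fraction(self):
        # 0.1 + 0.8 * P(both > 0) = 0.1 + 0.8 * 0.25 = 0.3
        rng = np.random.default_rng(3)
        vals = {"a": rng.standard_normal(2000), "b": rng.standard_normal(2000)}
        labels = boolean_outcome(vals, BooleanRule.parse([["a+", "b+"]]), 0.9, 0.1, seed=4)
        assert abs(labels.mean() - 0.3) < 0.03


class TestSimulateSurvival:
    def test_null_beta_matches_baseline_weibull(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((2000, 1))
        t, e = simulate_survival(x, [0.0], 1.5, 18.0, 0.0, seed=6)
        assert e.all()
        ks = stats.kstest(t, stats.weibull_min(1.5, scale=18.0).cdf)
        assert ks.pvalue > 0.01

    def test_cox_recovers_beta(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(1000)
        t, e = simulate_survival(x[:, None], [1.0], 1.5, 18.0, 0.0, seed=8)
        fit = survival.cox_fit(
            survival.SurvivalData(t, e, pd.DataFrame({"x": x}))
        )
        assert abs(fit.beta["x"] - 1.0) < 0.15

    def test_censor_rate_calibration(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal((2000, 1))
        t, e = simulate_survival(x, [0.5], 1.5, 18.0, 0.3, seed=10)
        censored = 1.0 - e.mean()
        assert 0.25 <= censored <= 0.35

    def test_nonfinite_beta_errors(self):
        with pytest.raises(ValueError, match="finite"):
            simulate_survival(np.zeros((5, 1)), [np.nan], 1.5, 18.0, 0.0, seed=0)

    def test_proportional_hazards_logrank_property(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(600)
        t, e = simulate_survival(x[:, None], [1.0], 1.5, 18.0, 0.1, seed=12)
        group = np.where(x > np.median(x), "high", "low")
        _, p = survival.logrank_test(t, e, group)
        assert p < 0.01


class TestInjectMissing:
    def test_rate_zero_identity(self):
        m = pd.DataFrame(np.arange(12.0).reshape(3, 4))
        pd.testing.assert_frame_equal(inject_missing(m, 0.0, seed=1), m)

    def test_missing_count_binomial_bounds(self):
        m = pd.DataFrame(np.zeros((100, 100)))
        out = inject_missing(m, 0.1, seed=2)
        count = int(out.isna().to_numpy().sum())
        lo, hi = stats.binom(10000, 0.1).ppf([0.005, 0.995])
        assert lo <= count <= hi

    def test_same_seed_identical_mask(self):
        m = pd.DataFrame(np.random.default_rng(0).standard_normal((30, 30)))
        a = inject_missing(m, 0.2, seed=3)
        b = inject_missing(m, 0.2, seed=3)
        assert a.isna().equals(b.isna())

    def test_observed_entries_unchanged(self):
        m = pd.DataFrame(np.random.default_rng(1).standard_normal((20, 20)))
        out = inject_missing(m, 0.3, seed=4)
        obs = ~out.isna()
        assert np.array_equal(out.to_numpy()[obs.to_numpy()], m.to_numpy()[obs.to_numpy()])

    def test_rate_one_rejected(self):
        with pytest.raises(ValueError):
            inject_missing(np.zeros((2, 2)), 1.0, seed=0)


class TestWriteCohortFiles:
    def test_round_trip(self, small_cohort, tmp_path):
        paths = write_cohort_files(small_cohort, tmp_path)
        gene = preprocess.read_expression_matrix(paths["gene"])
        prot = preprocess.read_expression_matrix(paths["protein"])
        assert np.allclose(gene.to_numpy(), small_cohort.gene_matrix.to_numpy(), atol=1e-12)
        assert np.allclose(prot.to_numpy(), small_cohort.protein_matrix.to_numpy(), atol=1e-12)
        clin = preprocess.read_clinical(paths["clinical"])
        assert np.allclose(clin["os_months"], small_cohort.clinical["os_months"])
        assert np.array_equal(clin["os_event"], small_cohort.clinical["os_event"])

    def test_clinical_line_count(self, tmp_path):
        cfg = make_config(n_samples=3, p_gene=2, p_protein=2,
                          planted_features=(), beta=(), coupled_pairs=(),
                          boolean_rule=BooleanRule())
        cohort = simulate_multiomics(cfg)
        paths = write_cohort_files(cohort, tmp_path)
        assert len(paths["clinical"].read_text().strip().splitlines()) == 4

    def test_missing_round_trips_as_na(self, tmp_path):
        cfg = make_config(missing_rate=0.2, seed=13)
        cohort = simulate_multiomics(cfg)
        assert cohort.gene_matrix.isna().any().any()
        paths = write_cohort_files(cohort, tmp_path)
        assert "NA" in paths["gene"].read_text()
        gene = preprocess.read_expression_matrix(paths["gene"])
        assert gene.isna().equals(cohort.gene_matrix.isna())


def test_null_config_chi2_association_controlled():
    # with p_signal == p_noise no feature associates with the label
    cfg = make_config(n_samples=600, p_gene=25, p_protein=10, p_signal=0.4, p_noise=0.4, seed=21)
    cohort = simulate_multiomics(cfg)
    y = cohort.truth["outcome"]
    pvals = []
    for mat in cohort.views.values():
        for _, row in mat.iterrows():
            high = row.to_numpy() > 0
            table = pd.crosstab(high, y)
            if table.shape == (2, 2):
                pvals.append(stats.chi2_contingency(table).pvalue)
    # Bonferroni-controlled: no rejection at alpha=0.01
    assert min(pvals) > 0.01 / len(pvals)
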