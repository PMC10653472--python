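# multiview-irf

Multiview iteratively-reweighted random forests for two-omics cohorts:
feature and signed-interaction discovery under three nested layers of
bootstrap resampling, with survival validation and signature-based patient
stratification. Ships with a synthetic cohort generator that plants known
marginal and interaction signal so every stage can be tested against
ground truth.

## What it does

1. **`synthetic_data`** — generates an aligned two-view cohort
   (gene-expression-like and protein-like z-scored matrices): planted
   features drive a binary outcome through a configurable Boolean rule
   (with `p_signal`/`p_noise` label noise), survival times follow a
   Weibull proportional-hazards model linear in the planted features with
   calibrated random censoring, a KPS-like ordinal covariate is coupled to
   the survival score, and missingness is MCAR. All distributional choices
   are stand-ins with known truth, not estimates of any real cohort.
2. **`preprocess`** — missingness filtering (features with >= 80% missing
   dropped), k-nearest-*feature* mean imputation, per-feature z-scoring,
   outcome binarization (overall survival <= 6 months vs >= 24 months;
   KPS >= 80 vs <= 60), and a moderated-t differential screen
   (empirical-Bayes variance shrinkage, Benjamini-Hochberg FDR, effect =
   difference of class means on the z scale).
3. **`irf_core`** — from-scratch feature-weighted random forests (numba
   kernels; candidate features sampled without replacement proportional to
   weights), iterated reweighting by count-weighted Gini importances,
   signed root-to-leaf itemsets from class-1 leaves, generalized Random
   Intersection Trees, and bagged stability scores.
4. **`pipeline`** — the outer bootstrap layer: R replicates of
   bootstrap -> stratified 80/20 split -> K reweighting iterations ->
   held-out AUPR -> B stability bootstraps; per-view and integrated
   designs; persistence-based feature selection (importance >= `gini_min`
   in >= `persistence_min` of replicates, both inclusive) and interaction
   aggregation (mean stability strictly > `stability_min`, members all
   persistent); replicate confidence intervals.
5. **`survival`** — Kaplan-Meier curves, two-group log-rank test,
   mean-expression dichotomization, unpenalized Cox (Newton, Breslow ties
   by default, Efron optional), elastic-net Cox over a λ path with
   10-fold event-stratified CV maximizing Harrell's C (`rule="1se"`
   optional), backward stepwise by AIC, and Harrell's concordance index.
6. **`stratify`** — signature scores (unweighted mean expression),
   group-mean cutoffs with Bonferroni-corrected Welch t-test, zone
   assignment (`beyond-mean` rule with an unassigned middle band, or
   `midpoint`), PCA with explained variance, and seed-stable t-SNE.

Note on scales: Gini importances are count-weighted (impurity decrease
summed over in-tree bootstrap sample counts, averaged over trees), so the
`gini_min` retention threshold is n-dependent; the default 1.0 matches the
convention of R `randomForest`'s MeanDecreaseGini.

## CLI

A single entry point `multiview-irf` with five subcommands:

```bash
# 1. generate a synthetic cohort (Firehose-style TSVs + clinical table)
multiview-irf simulate --config sim.yaml --out data/ --seed 3

# 2. clean / impute / standardize / binarize / DEG-screen
multiview-irf preprocess --expr data/gene_expression.tsv \
    --prot data/protein_expression.tsv --clin data/clinical.tsv \
    --task os --out prep/

# 3. multiview training (gene, protein, integrated designs)
multiview-irf train --expr data/gene_expression.tsv \
    --prot data/protein_expression.tsv --clin data/clinical.tsv \
    --task os --views gene,protein,integrated --config train.yaml \
    --out run/ --seed 1

# 4. KM / log-rank, elastic-net Cox, uni-/multivariate Cox, stepwise
multiview-irf survival --features signature.txt \
    --expr data/gene_expression.tsv --clin data/clinical.tsv --out surv/

# 5. mean cutoffs on a reference cohort, zones on an external one
multiview-irf stratify --signature signature.txt \
    --train-expr data/gene_expression.tsv --train-clin data/clinical.tsv \
    --apply-expr external_expression.tsv --out strat/
```

`sim.yaml` example:

```yaml
n_samples: 400
p_gene: 150
p_protein: 150
planted_features: [[gene, 0], [gene, 1], [protein, 0]]
boolean_rule: [["G0000+", "P0000+"], ["G0000-", "G0001+"]]
p_signal: 0.9
p_noise: 0.1
beta: [0.5, 0.5, 0.5]
coupled_pairs: [[0, 0]]     # protein 0 is a rho=0.6 noisy copy of gene 0
censor_rate: 0.2
```

`train.yaml` example:

```yaml
K: 3          # reweighting iterations (default 5)
B: 10         # stability bootstraps (default 50)
R: 20         # outer replicates (default 100)
gini_min: 8.0
forest: {n_trees: 100}
```

## Layout

```
src/multiview_irf/
  synthetic_data.py   cohort generator (planted truth)
  preprocess.py       cleaning, imputation, screening, binarization
  irf_core/           weighted forests, RIT, stability (numba kernels)
  pipeline.py         outer bootstrap, persistence selection, metrics
  survival.py         KM, log-rank, Cox, coxnet, stepwise, concordance
  stratify.py         signature scores, cutoffs, zones, PCA/t-SNE
  benchmarks.py       planted-signal benchmark harness
  cli.py              click entry points
tests/                unit, property and acceptance suites
scripts/acceptance.py acceptance report generator
```
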