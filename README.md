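# riskpath

Recurrence-risk analysis of paired tumor/normal expression cohorts via
reference-interval outlier statistics, pathway deviation scores, and a
two-circle geometric classifier — with downstream survival stratification.

## The method

Recurrent ("poor prognosis") tumors often dysregulate genes in *subgroups*
of patients rather than shifting the group mean: a gene may be wildly
over-expressed in 40% of recurrent patients and normal in the rest.
Mean-difference tests (t-test, limma-style moderated tests) dilute such
signals across the whole case group; this package instead measures how far
each case sample falls **outside the normal interval** fitted on
good-prognosis samples.

The pipeline, per tissue (tumor and adjacent normal):

1. **Reference intervals & DEGs** (`deg_exceedance`). Each gene's normal
   interval is `mean ± 1.96·SD` over good-prognosis samples. The gene's
   score is the summed exceedance of poor-prognosis samples beyond that
   interval; significance comes from a label-permutation test (intervals
   refitted per shuffle, add-one p-value estimator) with
   Benjamini–Hochberg control at q < 0.05. A signed variant assigns each
   DEG an up/down direction.
2. **Clustering & at-risk subgroup** (`clustering`). Samples are clustered
   on DEG profiles (centered-Pearson distance, average linkage). Good
   samples whose subgroup sits nearest the poor centroid are flagged
   *at-risk*.
3. **Pathway deviation scores** (`pathway_deviation`). For every pathway
   and sample, `U` (`D`) is the mean **cubed** deviation from the
   good-group gene means over the pathway's up- (down-) regulated DEGs —
   cubing preserves sign and amplifies outlying deviations.
4. **Two-circle classifier** (`center_classifier`). In the (U, D) plane
   each group gets a circle at its geometric center with the minimal
   radius covering 80% of its own samples. Samples inside exactly one
   circle are called for that group; samples in both ("intersection") or
   neither ("isolation") are *fuzzy* and excluded. Pathways whose calls
   achieve mean precision > 0.65 are risk-associated; the top 4 are kept.
5. **Models** (`models`). The risk pathways' (U, D) columns feed a
   random-forest (or RBF-SVM) classifier of prognosis group under
   stratified 5-fold cross-validation with mean ROC/AUC. Risk genes can be
   tested for hallmark enrichment (hypergeometric).
6. **Survival** (`survival`). A patient is *altered* when at least one
   risk gene (risk-pathway member ∩ DEG, screened by single-gene log-rank)
   lies outside its reference interval. Altered vs unaltered patients are
   compared by Kaplan–Meier curves and the log-rank test; finally the two
   tissues' screened gene sets are integrated by union — the tissues carry
   complementary risk information, so the union stratifies better than
   either alone.

`synthetic_data` generates seeded paired cohorts with all of this
structure planted (subgroup outlier genes in risk pathways, within-interval
decoy mean shifts, module-coherent diffuse dysregulation, at-risk good
samples, and exponential survival with elevated hazard for carriers), plus
truth tables for verification. `pipeline` runs the whole workflow from a
config and emits a deterministic, content-hashed run manifest.

## Worked example

Generate the default cohort (38 good / 15 poor patients, 2000 genes, 50
pathways of 38 genes; 4 planted risk pathways per tissue) and run the
analysis scripts:

```bash
python analysis/01_simulate_cohort.py --seed 0
python analysis/02_differential_expression.py
python analysis/03_clustering.py
python analysis/04_pathway_classifier.py
python analysis/05_models.py
python analysis/06_survival.py
```

Actual output of the above (seed 0; warning lines about score-free null
pathways omitted):

```
tumor: 188 DEGs at q<0.05 (88 up, 100 down) -> results/tumor_degs.tsv
normal: 192 DEGs at q<0.05 (97 up, 95 down) -> results/normal_degs.tsv
tumor: poor recall 0.867, 7 at-risk good samples ['S002', 'S005', 'S008', 'S013', 'S015', 'S019', 'S023'] -> results/tumor_clusters.tsv
normal: poor recall 0.867, 5 at-risk good samples ['S002', 'S004', 'S012', 'S026', 'S030'] -> results/normal_clusters.tsv
tumor: risk pathways P002 (0.970), P003 (0.970), P001 (0.859), P004 (0.823) -> results/tumor_pathway_eval.tsv
normal: risk pathways P007 (0.984), P008 (0.984), P006 (0.970), P005 (0.813) -> results/normal_pathway_eval.tsv
tumor random_forest: mean AUC 0.892, mean accuracy 0.964
tumor svm: mean AUC 0.892, mean accuracy 0.964
normal random_forest: mean AUC 0.933, mean accuracy 0.962
normal svm: mean AUC 0.942, mean accuracy 0.962
tumor: 31/116 genes kept, log-rank p = 2.18e-05
normal: 16/116 genes kept, log-rank p = 1.18e-06
integrated: 47 genes, log-rank p = 2.46e-07
```

The planted truth for this seed is risk pathways P001–P004 (tumor) and
P005–P008 (normal): all eight are recovered at mean precision > 0.65, and
the integrated tumor+normal gene set stratifies survival more sharply than
either tissue alone (2.5e-07 vs 2.2e-05 / 1.2e-06).

The same workflow is available as one command with a YAML config:

```bash
riskpath run --config run.yaml        # writes outputs + manifest.json
```

or stage by stage via `riskpath simulate / normalize / degs / cluster /
pathways / classify / model / survival` (see `riskpath --help`).

### Library use

```python
from riskpath import (SimulationConfig, generate, zscore_normalize,
                      call_degs, score_matrix)
cohort = generate(SimulationConfig(seed=0))
z = zscore_normalize(cohort.tumor)
degs = call_degs(z, alpha=0.05, n_perm=10000, seed=0)
scores = score_matrix(z, cohort.pathways, degs)   # per-sample (U, D)
```

## Layout

```
src/riskpath/       library (io_preprocess, deg_exceedance,
                    pathway_deviation, center_classifier, clustering,
                    models, survival, synthetic_data, pipeline, cli)
analysis/           numbered drivers writing tables to results/
tests/              pytest suite incl. end-to-end acceptance checks
scripts/            acceptance.py
docs/methods.md     modeling notes, parameter choices, limitations
```
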