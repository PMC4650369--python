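# plasmaselect

Supervised analysis toolkit for plasma miRNA hybridization-array data.
It implements an end-to-end strategy for building a cross-validated
classifier from a small case–control cohort:

1. **Labeling** — samples are called case / control / excluded from a
   hemolysis score (control: HS ≤ 0.057, case: HS > 0.14).
2. **Cohort construction** — 1:2 propensity-score caliper matching
   (logistic model on disease status, age at drawing, drawing year;
   caliper = 0.2 × SD of the propensity logit; greedy nearest-neighbor
   without replacement), then a randomized half split of whole matched
   triplets into training and validation sets, preserving the 1:2 ratio.
3. **Preprocessing** — features kept when detected in ≥ 90 % of the
   reference samples; ratio normalization forms one log2 ratio per
   unordered feature pair (88 features → 3828 ratios).
4. **Class comparison** — two-sample t-test (location) and the
   asymptotic ties-corrected two-sample Anderson–Darling test (omnibus)
   per feature; the two p-value families are BH-adjusted separately and
   a feature is significant when either adjusted p < α (union rule),
   with a concordance-quadrant classification (both / t_only / ad_only /
   neither).
5. **Bootstrap ranking** — three conceptually different selectors
   (nearest shrunken centroids, Boruta random forest, elastic-SCAD
   linear SVM) run on stratified bootstrap replicates; features are
   ranked by how often all three select them simultaneously, and the
   pairwise co-occurrence network is exported as GraphML (edge filter:
   co-occurrence ≥ 300 at B = 1000).
6. **Classifier selection** — forward inclusion of ranked features into
   linear SVMs over a (k, cost, class-weight) grid, scored by
   leave-one-out cross-validated sensitivity / specificity / Youden
   index, grouped by exact ROC position, with the parsimonious model of
   each group evaluated on the validation set with stratified percentile
   bootstrap 95 % CIs.

A synthetic-data module generates cohorts with the structure the method
assumes (mean-shifted markers, equal-mean shape-only signals, correlated
blocks, intensity-dependent detection dropout, covariate imbalance for
matching), so the whole pipeline is testable without external data.

## Tests

```sh
python -m pytest tests/
```

The suite includes `tests/test_acceptance.py`, which checks the
pipeline's fixed arithmetic (ratio counts, cohort sizes, Youden values)
plus property-based criteria: oracle agreement for BH and the AD
statistic (including a 10⁴-permutation p-value check), FDR calibration
under a global null, AD-vs-t power ordering on variance-only
alternatives, planted-feature recovery through the full bootstrap
ranking (20 meta-replicates at B = 200; the long-running test), and
LOOCV behaviour on hand-enumerable and permuted data. The full run
takes roughly 15–20 minutes on one CPU.

## CLI

Every stage is a subcommand of `plasmaselect`:

```sh
plasmaselect simulate --seed 1 --out sim/
plasmaselect label --meta sim/matching_pool.tsv --out labeled.tsv
plasmaselect match --meta labeled.tsv --seed 1 --out matched.tsv
plasmaselect preprocess --expr sim/expression.tsv --meta matched.tsv --out-dir pre/
plasmaselect compare --expr pre/filtered.tsv --meta matched.tsv --out-dir cmp/
plasmaselect rank --expr pre/filtered.tsv --meta matched.tsv --b 1000 --seed 1 --out-dir rank/
plasmaselect train --expr pre/filtered.tsv --meta matched.tsv \
    --rank-order rank/rank_order.tsv --out models.tsv
```

File formats are plain TSV throughout (expression: features × samples
with a parallel 0/1 detection TSV; metadata: `sample_id, hs,
disease_status, age_at_drawing, drawing_year` plus derived `label` and
`split` columns); the co-occurrence network is written as GraphML.

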