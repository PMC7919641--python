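# pgxpipe

A pharmacogenomic (PGx) variant prediction pipeline built around a
"common treatment, common variant" premise: functional pharmacogene variants
tend to be common rather than rare, so their prediction leans on global
allele frequency, candidate adaptive polymorphisms, evolutionary statistics,
and protein feature annotations rather than on deleteriousness scores.

The package provides:

- **`pgxpipe.simulate`** — synthetic gene universes, labeled variant feature
  tables (14 predictors), per-population non-reference allele frequencies for
  the 26 global population samples (Balding–Nichols divergence with one FST
  parameter), and adaptive-signature gene sets, so every downstream stage is
  testable with no downloads.
- **`pgxpipe.enrichment`** — permutation test of pharmacogene
  over-representation in selection-scan gene sets (uniform draws without
  replacement; inclusive upper-tail p) plus a normal-approximation empirical
  p-value.
- **`pgxpipe.features`** — assembly of the 14-variable model matrix from BED
  feature tracks (0-based half-open), per-position evolutionary statistics,
  CAP membership, and global minor allele frequency, with an explicit
  retention rule and drop log.
- **`pgxpipe.balance`** — SMOTE re-implemented from scratch with exact count
  semantics and full synthesis provenance (parent/neighbour of every
  synthetic point), so resampling harnesses can prove no leakage.
- **`pgxpipe.model`** — stratified 70/30 partition, repeated stratified CV
  (5 folds × 10 repeats) with SMOTE applied inside each analysis fold only,
  sensitivity-weighted hyperparameter selection over three tree-ensemble
  learners (random forest, boosted stumps, gradient-boosted trees), held-out
  confusion matrices, rank-based AUC, gain-based variable importance scaled
  to a top score of 100, comparator-method metrics, and prediction of new
  (not-yet-annotated) PGx variants.
- **`pgxpipe.reporting`** — Europe/non-Europe presence partition of
  segregating variants, newly-predicted counts by CPIC drug-count category,
  per-population allele-frequency summaries by variant class, and a
  single-config end-to-end runner with a deterministic manifest.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (enrichment oracle
and calibration, SMOTE count/geometry/kNN oracles, metric oracles, leakage
safety, signal recovery on the default 20,000-variant synthetic dataset,
pipeline determinism, degenerate-generator checks). The full suite takes
roughly 7 minutes on one CPU.

## CLI

```sh
pgxpipe simulate --seed 1 --config sim.yaml --out-dir data/
pgxpipe enrich --universe-size 29521 --pharmacogenes pgx.txt \
    --signatures ihs.txt --signatures xpclr.txt --n-perm 1000 --seed 1 --out enrich.tsv
pgxpipe train --input data/variants.tsv --learner xgb --folds 5 --repeats 10 \
    --metric sens --seed 1 --out-dir runs/
pgxpipe predict --model runs/gradient_boosted_trees_model.pkl \
    --input data/variants.tsv --annotated annotated.txt --out scores.tsv
pgxpipe evaluate --scores comparators.tsv --method sift:0.05:lower \
    --method cadd:20:higher --out metrics.tsv
pgxpipe report --variants data/variants.tsv --genes data/genes.tsv --out-dir report/
pgxpipe run --config pipeline.yaml --out-dir run1/
```

A pipeline config is a single YAML file, e.g.

```yaml
seed: 1
simulate:
  n_genes: 2000
  n_variants: 20000
  pgx_fraction: 0.10
signatures:
  sizes: {iHS: 600, XP-CLR: 500, D: 900}
enrich:
  n_permutations: 1000
train:
  learner: gradient_boosted_trees
  folds: 5
  repeats: 10
```

`pgxpipe run` writes `genes.tsv`, `variants.tsv`, `enrichment.tsv`,
`resamples.tsv`, `cv_summary.tsv`, `confusion.tsv`, `importance.tsv`,
`predictions.tsv`, `venn.tsv`, `category_counts.tsv`, `af_by_class.tsv`, and
a `manifest.json` with seeds, version, and output hashes; the run is
byte-identical for a fixed config.

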