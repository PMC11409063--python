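# lncbench

Leakage-aware evaluation of lncRNA subcellular-localization classifiers.

## The problem

Databases of quantitative subcellular localization report, per gene and per
human cell line, a **CNRCI** — the base-2 log of the cytoplasmic-to-nuclear
normalized abundance ratio (positive ⇒ cytoplasmic preference, negative ⇒
nuclear). Sequence-based classifiers for this task are routinely trained and
tested after **middle exclusion**: genes with CNRCI in a central interval such
as [-1, 1] are removed *before* the train/test split. Since those are exactly
the hard, weakly-localized genes, filtering the *test* data by the response
variable inflates every reported metric without improving the model on
uncharacterized genes.

This package is for people who build or review such classifiers. It provides:

* **`synthetic_data`** — a cohort generator (gene × cell-line CNRCI matrix
  with missing entries and one decorrelated outlier line; per-gene sequences
  whose k-mer signal is monotone in the latent localization `z`, vanishing at
  `z = 0`), so everything below is demonstrable with no downloads;
* **`data_io`** — readers for the real formats: long-format CNRCI CSV,
  FASTA, and GFF3 with `Ensembl_canonical` transcript tags, plus the id
  normalization needed to join them;
* **`localization_prep`** — labeling protocols (log-of-mean-of-ratios or
  mean-CNRCI aggregation, configurable thresholds), a training-only cell-line
  screen, the middle-exclusion filter as an explicit, pure operation with an
  application mode, and exact majority down-sampling;
* **`kmer_features`** — k ∈ {3, 4, 5} frequency profiles (1344 dimensions);
* **`cv_engine`** — gene-grouped, stratified, repeated CV with an enforced
  access audit (fitting code that touches an evaluation fold raises), metric
  computation (accuracy, F1, MCC, AUPRC, AUROC), and the **four-condition
  factorial**: the filter applied to `all` / `none` / `train_only` /
  `eval_only` on identical folds and seeds, plus an interval-width sweep;
* **`experiments` / `lncbench` CLI** — the canned demonstration and the
  benchmark protocol (threshold 0, no middle exclusion, balanced classes,
  2 × 5-fold CV, default-hyperparameter LightGBM).

The statistic at the core is the boost
`Δ = mean AUROC(eval_only) − mean AUROC(none)`, judged against the pooled fold
standard deviation. On data with weak middles, Δ is large and positive while
`AUROC(train_only) ≈ AUROC(none)`: the filter boosts metrics, not models.

## Worked example

```
$ cat demo_cfg.yaml
synthetic:
  n_genes: 800
  seq_len_mean: 600.0
  seq_len_sd: 100.0
  alpha: 1.0
  seed: 13
folds:
  n_folds: 5
  n_repeats: 1
seed: 13

$ lncbench demo --config demo_cfg.yaml --out demo/ --no-sweep
Middle-exclusion factorial, mean AUROC (%) by filter application:
  all          89.48 +/- 2.40
  none         76.21 +/- 2.31
  train_only   76.16 +/- 3.45
  eval_only    89.12 +/- 1.48
Verdict: filtering the evaluation folds inflated AUROC by 12.9 points (pooled fold sd 1.9) with the very same trained models — metrics boosted, performance not.
Training-side filtering moved AUROC by -0.0 points relative to no filtering.
```

Reading the output: the same fold plan and model seeds were evaluated under
all four filter applications. The two conditions that filter the evaluation
folds (`all`, `eval_only`) report ≈ 89% AUROC; the two that do not (`none`,
`train_only`) report ≈ 76%. The 13-point gap is produced entirely by deleting
hard genes from the test side — `eval_only` scores literally the same trained
models as `none`. Filtering the training side moves nothing. A classifier
deployed on uncharacterized genes, where CNRCI cannot be used to pre-filter,
would perform at the `none` level.

The library surface mirrors the CLI:

```python
import lncbench as lb

cohort = lb.generate_cohort(lb.SyntheticConfig(seed=1))
screen = lb.screen_cell_lines(cohort.cnrci, 0.5, cohort.genes)
spec = lb.LabelSpec(excluded_cell_lines=screen.excluded)
values = lb.aggregate_cnrci(cohort.cnrci, spec)
dataset = lb.binarize(values, spec, sequences=cohort.sequences)
dataset = lb.downsample_majority(dataset, seed=42)
dataset = lb.featurize_dataset(dataset)
plan = lb.make_fold_plan(dataset, n_folds=5, n_repeats=2, seed=7)
reports = lb.run_factorial(dataset, lb.ModelSpec("gbdt_default"), plan, (-1.0, 1.0))
print(reports["eval_only"].mean("auroc") - reports["none"].mean("auroc"))
```

Other subcommands: `simulate` (write a cohort as CSV/FASTA/TSV), `prepare`
(join real or simulated files into a labeled dataset), `featurize`,
`evaluate` (one condition), `factorial` (all four, optional `--sweep`), and
`benchmark` (the full protocol on supplied files — this tool never downloads
data). Every run writes a manifest with the config echo, resolved seeds and
stage-level record counts.

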