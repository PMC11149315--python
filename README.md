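# tabready

Quantify how ready a labeled tabular dataset is for machine learning, and
search for its best "cleansed" sub-table.

Given a master CSV with numeric feature columns and one categorical label
column, `tabready`:

1. scores any (sub-)table with **five quality metrics**, each in [0, 1]
   with higher = better:
   - `pc_q` — 1 − mean absolute pairwise Pearson correlation,
   - `spearman_q` — 1 − mean absolute pairwise Spearman correlation,
   - `missing_q` — 1 − fraction of missing cells,
   - `outlier_q` — 1 − fraction of rows with a 3-MAD outlier cell,
   - `overlap_q` — 1 − class-overlap R value (fraction of samples with
     more than θ of their k nearest neighbors in a foreign class;
     defaults k=7, θ=3);
2. scores the table's **ML usefulness**: the equal-weight mean of
   stratified-CV classification accuracy (random forest + SGD) and the
   clamped mean silhouette of k-means and Ward clusterings;
3. samples random sub-tables (dropping at most `RER` of rows and `CER` of
   columns; defaults 0.2 / 0.5), builds the *readiness space* of their
   quality/accuracy scores, and **learns dataset-specific metric weights**
   by forest regression of accuracy on the metrics;
4. runs a **random-restart search** (`R` runs × `d` sub-tables) and reports
   the sub-table with the highest weighted total quality
   `f̃ = Σ wᵢ·fᵢ` as the cleansed dataset.

A synthetic-data module plants controlled defects (duplicate features,
noise columns, MCAR missingness, MAD-calibrated outliers, label flips) so
the whole pipeline is testable without any external data.

## CLI

```bash
tabready --input data.csv --label diagnosis \
         --runs 4 --subtables 200 --seed 7 --outdir out/
```

Useful flags: `--rer/--cer` (exclusion ratios), `--knn-k/--knn-theta`
(class overlap), `--folds`, `--jobs` (parallel runs), `--standardize`,
`--exclude COL,...` (drop named columns on load), `--config params.json`
(JSON file with `SearchConfig` field names; flags override it).
Exit status is 0 on success and 2 on validation errors.

Outputs in `--outdir` (all plain text, reproducible under a fixed seed):

- `run_XXX.csv` — one row per sampled sub-table: the five quality scores,
  the three accuracies, `f_tilde`, and the kept row/column indices as
  compact 0-based range strings (`"0-4,7,9"`);
- `best_per_run.csv` — the best record of each run;
- `cleansed.csv` — the global-best sub-table, materialized with header and
  label column;
- `summary.txt` — global best run, `f̃`, learned mean weights, selected
  indices/names, and the master-table baseline scores.

## Library

```python
from tabready import (load_master, SearchConfig, run_search, write_reports)

master = load_master("data.csv", label_name="diagnosis")
config = SearchConfig(d=200, R=4, seed=7)
result = run_search(master, config)
write_reports(result, master, "out/")
```

`SyntheticSpec` / `generate_dataset` build defect-planted fixtures with a
ground-truth annotation of every planted defect.

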