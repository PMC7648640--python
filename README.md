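# deconvbench

A benchmarking framework for reference-based cell-type deconvolution of
transcriptomes. It generates pseudo-bulk mixtures with known composition
from (real or synthetic) scRNA-seq count data, runs a grid of data
transformations × normalizations × marker-selection strategies ×
deconvolution solvers, and scores every combination by RMSE and Pearson
correlation — including missing-cell-type experiments.

## What's inside

| Module | Role |
| --- | --- |
| `deconvbench.io_qc` | MTX/delimited count-matrix I/O, MAD-based QC, 50:50 train/test splitting (by cell or by donor) |
| `deconvbench.synthetic` | Negative-binomial scRNA-seq generator with planted markers, donor effects, tunable between-type correlation; `pancreas_like` / `pbmc_like` / `kidney_like` presets |
| `deconvbench.transforms` | linear, log, sqrt, and an NB variance-stabilizing transform |
| `deconvbench.normalize` | column/row scaling, min-max, z-scores, quantile, upper quartile, TPM, TMM+CPM, LogNormalize-in-linear-scale, median of ratios; compatibility checking; plugin hook for external normalizers |
| `deconvbench.markers` | per-type gene ranking (fold change vs. second-highest-expressing type, BH-adjusted Welch tests), eight marker strategies, marker non-specificity statistic |
| `deconvbench.reference` | signature-matrix construction, marker subsetting, cell-type removal, cell-type profile correlations |
| `deconvbench.pseudobulk` | uniform grid-composition sampling, pseudo-bulk summation with per-mixture cell provenance |
| `deconvbench.solvers` | OLS, NNLS, robust (Huber IRLS), simplex-constrained QP, ridge/lasso/elastic-net, ν-SVR (CIBERSORT-style), dampened weighted least squares; solver registry for external methods |
| `deconvbench.evaluate` | RMSE/Pearson at several granularities, relative error by proportion magnitude, removal experiment, full benchmark driver |
| `deconvbench.cli` | `deconvbench` command-line interface |

## Command-line usage

```sh
# synthesize a benchmark dataset (MTX + genes.tsv + cells.tsv)
deconvbench simulate-data --preset pancreas_like --seed 7 --out data/sim

# quality control
deconvbench qc --input data/sim --out data/qc

# marker selection
deconvbench markers --preset pancreas_like --seed 7 --strategy all --out markers.tsv

# 1000 pseudo-bulk mixtures at pool size 100
deconvbench mixtures --preset pancreas_like --seed 7 --n 1000 --pool-size 100 --out data/mix

# the full grid benchmark
deconvbench run-benchmark --preset pancreas_like --seed 7 --out bench_out
deconvbench report bench_out

# missing-cell-type experiment
deconvbench remove-celltype --preset pbmc_like --seed 7 --out removal_out
```

`run-benchmark` accepts a YAML config (`--config`) mirroring
`deconvbench.PipelineConfig`; flags override the file, the file overrides
the defaults, and the effective config is written into the output
directory. One master seed deterministically derives per-stage seeds, so
stages can be rerun independently yet reproducibly.

Input layouts: a directory with `matrix.mtx`, `genes.tsv` (`gene_id`,
`symbol`) and `cells.tsv` (`cell_id`, `cell_type`, `donor`), or a
delimited matrix (header row = cell ids, first column = gene ids) with a
sibling `cells.tsv`.

## Python API sketch

```python
import deconvbench as db

X = db.make_benchmark_fixture("pancreas_like", seed=7)
Xqc, report = db.qc_filter(X)
train, test = db.split_train_test(Xqc, seed=1)

C = db.build_reference(train)
stats = db.rank_genes(train, fc_threshold=2.0)
markers = db.select_markers(stats, "all")

mix = db.generate_mixtures(test, db.CompositionRules(n_mixtures=1000, pool_size=100, seed=3))
res = db.deconvolve(mix, C, markers=markers, method="nnls",
                    transform_kind="linear", scaling_t="column", scaling_c="column")
print(db.rmse(mix.P_E, res.P_C, "per_mixture_median"))
```
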