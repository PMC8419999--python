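# umires

Normalization and highly-variable-gene (HVG) selection for single-cell UMI
count data using **analytic Pearson residuals**, together with the diagnostic
simulations and the cell-type-separation benchmark that motivate the method.

The core model treats every gene as occupying a fixed fraction `p_g` of each
cell's sequencing depth `n_c`, so the expected count is `mu_cg = n_c * p_g`.
Under Poisson noise the maximum-likelihood fit is just the matrix margins
(`mu = row_sum * col_sum / total`), which makes normalization closed-form:

```
Z_cg = (X_cg - mu_cg) / sqrt(mu_cg + mu_cg^2 / theta)        (theta = 100)
```

Residuals are clipped to `±sqrt(n_cells)` by default. Genes whose residual
variance exceeds 1 carry more variance than technical noise explains and are
good HVG candidates; rare-population markers in particular score highly here
while square-root/log criteria miss them.

## Package layout

| module | contents |
| --- | --- |
| `umires.count_model` | `CountMatrix`, closed-form null fit, Pearson/deviance residuals, rank-one Poisson/NB log-likelihoods, streaming per-gene residual variance |
| `umires.regression_diagnostics` | per-gene Poisson IRLS on log-depth (overspecification diagnostic), per-gene overdispersion MLE and its bias experiment |
| `umires.transforms` | depth normalization (median/CPM), sqrt/Anscombe/Freeman-Tukey, log1p, standardization, Fano factor |
| `umires.hvg` | min-cells gene filter, gene scoring (`pearson_var`, `deviance_var`, `sqrt_var`, `log_var`, `fano`), deterministic top-k selection |
| `umires.synthetic_data` | null/negative-control simulators and the labeled 8-type benchmark with an injected rare population |
| `umires.benchmark` | pipeline grid: HVG x transform -> 50-dim PCA -> leave-one-out kNN -> macro F1 |
| `umires.io`, `umires.cli` | Matrix Market / TSV / CSV readers and writers, provenance records, `umires` command |

## CLI

```bash
# simulate a null dataset (Matrix Market + TSVs + provenance.json)
umires simulate --cells 2000 --genes 1000 --seed 1 --out out/null

# analytic Pearson residuals and per-gene variance table
umires residuals out/null --theta 100 --clip sqrt_n --out out/residuals

# score genes and select the 100 most variable
umires hvg out/null --method pearson_var --n-top 100 --out out/hvg

# overdispersion estimation bias experiment
umires theta-bias --cells 2000 --genes 200 --theta 10 --out out/bias

# pipeline benchmark on a simulated labeled dataset
umires benchmark --genes 2000 --out out/benchmark
```

Every command writes a `provenance.json` (parameters, seed, version) next to
its outputs.

## Conventions

- Cells are rows, genes are columns; `read_counts(..., orientation="genes_rows")`
  transposes the 10x Matrix-Market dialect on load.
- `theta = umires.POISSON` (infinity) selects the Poisson model everywhere a
  `theta` is accepted; code branches on the sentinel explicitly.
- Zero-count genes get residual 0 and are flagged, not dropped.
- Variances are population variances (divide by n); the median depth uses the
  lower median; top-k ties break by ascending gene index.
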