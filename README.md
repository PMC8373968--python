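# lncland

Cross-dataset analysis of the long-noncoding-RNA (lncRNA) expression
landscape of thyroid neoplasms — and, more generally, of any study design
in which several expression datasets with overlapping but non-identical
group coverage must be combined into consensus differential-expression
calls, subtype-specificity categories, and guilt-by-association functional
annotations.

## Who this is for

Bioinformaticians combining bulk RNA-seq count datasets and microarray
log-intensity datasets over the same disease subtypes. The package
implements the whole chain as a tested, deterministic pipeline and ships a
synthetic-data generator that emulates the three-dataset structure (two
RNA-seq cohorts, one microarray cohort with probe-level values and
incomplete probe coverage) with planted ground truth, so every stage can be
scored against known answers.

## The model

Differential expression uses the gene-wise group-means linear model with
empirical-Bayes variance moderation. For gene *g* with (optionally
precision-weighted) residual variance *s²_g* on *d_g* degrees of freedom,
an inverse-chi-square prior with parameters (*d₀*, *s₀²*) is fitted by
moments on log *s²*, giving the posterior variance

    s̃²_g = (d₀ s₀² + d_g s²_g) / (d₀ + d_g)

and the moderated statistic *t_g* = β̂_g / (s̃_g · u_g) on *d₀ + d_g*
degrees of freedom, where β̂_g is the contrast of group means and *u_g*
its unscaled standard error. RNA-seq counts enter the model as log₂-CPM on
TMM-scaled (trimmed mean of M-values) library sizes with precision weights
from a lowess-smoothed mean-variance trend; microarray intensities are
quantile-normalised and probe-collapsed (per-sample median). A gene is
differentially expressed when BH-adjusted p ≤ 0.01 and |log₂FC| ≥ 1.

On top of the DE calls:

* **Validation** — a clPTC or fvPTC call is *validated* when the gene is DE
  versus normal tissue in all three datasets, or in both RNA-seq datasets
  while absent from the microarray probe coverage.
* **Categories** — each lncRNA is assigned one of seven labels (common to
  FA+WDTC, common to WDTC, common to papillary carcinomas, specific to
  FTC/fvPTC/clPTC/ATC) by a strict decision cascade over its DE-versus-NT
  pattern, validation status and between-subtype contrasts; ATC-specific
  genes come from a subtraction funnel on the microarray, the only platform
  carrying ATC.
* **Function inference** — for the strongest DE lncRNAs of each category,
  coding genes with |Pearson r| ≥ 0.7 and p < 0.05 are collected as
  coexpression partners and tested for gene-set over-representation with
  the one-sided Fisher exact test (BH-adjusted per collection).

## Worked example

```python
from lncland.pipeline import run_pipeline

result = run_pipeline({"seed": 1}, out_dir="results")
print(result.lnc_results["rnaseqA"].summary())
print(result.recovery.to_string(index=False))
```

prints the fitted model summary for the primary RNA-seq dataset

```
Gene-wise linear model (empirical-Bayes moderated)
==================================================
genes:              800
samples:            67
groups:             FA, FTC, NT, clPTC, fvPTC
residual df:        62
prior df (d0):      74.81
prior var (s0^2):   0.9994
total df:           136.8
weighted:           True
```

(800 lncRNAs; the empirical-Bayes prior contributes d₀ ≈ 75 pseudo-degrees
of freedom, so each gene's variance is strongly shrunk toward the common
prior s₀² ≈ 1.0) and the recovery of the planted truth:

```
        category  n_true  n_called  true_positives  sensitivity  precision
  common_FA_WDTC      20        20              20         1.00        1.0
     common_WDTC      20        20              20         1.00        1.0
common_papillary      20        20              20         1.00        1.0
    specific_FTC      20        20              20         1.00        1.0
  specific_fvPTC      20        20              20         1.00        1.0
  specific_clPTC      20        20              20         1.00        1.0
    specific_ATC      20        19              19         0.95        1.0
```

All 140 planted lncRNAs carry a known category; at the default conditions
139 are recovered with no false assignments (one ATC gene narrowly misses
the fold-change gate). `results/` additionally contains the per-dataset DE
tables, `categories.tsv`, the ATC selection funnel, coexpression and
enrichment tables, and a `manifest.json` with per-stage digests and wall
times.

The same run from a shell:

```sh
lncland run --config run.yaml --out results   # run.yaml may be just "seed: 1"
lncland simulate --seed 1 --out simdata       # write the fixtures as TSV/GMT
```

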