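# Methods

## Study structure

The pipeline targets a multi-dataset design: several expression datasets
over the same histological subtypes, with overlapping but non-identical
group coverage. The default (and the synthetic generator's default)
mirrors a three-dataset thyroid study:

| dataset  | platform   | groups (n)                                         |
|----------|------------|----------------------------------------------------|
| rnaseqA  | RNA-seq    | NT 20, FA 10, FTC 10, fvPTC 12, clPTC 15           |
| rnaseqB  | RNA-seq    | NT 15, fvPTC 12, clPTC 15                          |
| array    | microarray | NT 15, fvPTC 10, clPTC 10, ATC 10                  |

NT (normal thyroid) is the reference in every contrast. rnaseqA is the
*primary* dataset — the only one covering all four differentiated
subtypes — and supplies the DE-versus-NT pattern and all between-subtype
contrasts for the category cascade. ATC exists only on the microarray, so
the ATC rule and the ATC coexpression analysis run there.

## Normalisation

**RNA-seq.** Genes are kept when at least *smallest-group-size* samples
have count ≥ `min_count` (2 for the deeper cohort, 1 for the shallower
one; both configurable). TMM scaling factors follow the published
trimmed-mean-of-M-values recipe: reference sample by 75th-percentile count
fraction, genes zero in either sample dropped, 30% two-sided trim on M and
5% on A, inverse-(asymptotic-binomial)-variance weighting of the remaining
M-values, factors rescaled to geometric mean 1. Log-CPM uses a prior count
of 0.5 on TMM-effective library sizes. Precision weights come from the
mean-variance trend: per-gene group-means fit, lowess (span 0.5, 3
robustness iterations) of the quarter-root residual variance against mean
log-count, weights = predicted⁻⁴ with predictions clamped to the curve's
endpoints and floored at 1e-4 (a flat-zero trend would otherwise explode
the weights). The whole stack reproduces the reference R implementations
(edgeR `calcNormFactors`, limma `voom`) to ~1e-6 relative on factors and
~1e-3 on weights; the residual weight difference is the two lowess
implementations' treatment of edge points.

**Microarray.** Input is probe-level log₂ intensities. Columns are
quantile-normalised (ties receive the mean of the reference values at
their tied ranks), then probes are collapsed to genes by the per-sample
median over each gene's uniquely mapped probes. The collapse rule is a
package choice: median is deterministic and robust to a single aberrant
probe. Background correction of raw array images is out of scope; the
contract starts at log-intensities.

## Differential expression

Gene-wise group-means linear model, weighted least squares when voom
weights are present. The empirical-Bayes step estimates the prior
(d₀, s₀²) by moments on log s² with digamma/trigamma corrections; when the
spread of log s² does not exceed its pure-sampling expectation, d₀ = ∞ and
every gene shares s₀². The moderated t uses the posterior variance and
d₀ + d degrees of freedom. Identities covered by tests: d₀ = 0 recovers
the classical (weighted) t exactly; d₀ = ∞ recovers the pooled-prior t.

FDR is Benjamini–Hochberg, applied per contrast over the post-filter
lncRNA universe of the dataset in hand — adjusting within each dataset and
contrast is an assumption, recorded here because the choice changes the
effective threshold. A DE call requires FDR ≤ 0.01 *and* |log₂FC| ≥ 1,
two-sided: down-regulated genes qualify through the absolute value. The
fold-change threshold is interpreted on the log₂ scale throughout.
Between-subtype contrasts reuse the same thresholds (the defining
publication-style criteria name no separate between-subtype threshold) and
come from the single per-dataset fit, not pairwise refits.

## Validation and categories

A clPTC/fvPTC call is validated if DE versus NT in all three datasets, or
DE in both RNA-seq datasets while absent from the microarray probe map.
Direction consistency across datasets is *not* required (the rule is
presence-based). With only RNA-seq datasets configured, the pipeline
refuses to run unless `validation.mode: two_dataset` is set, in which case
the microarray clause is dropped.

Categories form a strict cascade on the vs-NT DE pattern
P ⊆ {FA, FTC, fvPTC, clPTC} in the primary dataset:

1. P = all four, validated in both PTC variants → **common to FA+WDTC**
2. P = {FTC, fvPTC, clPTC}, validated, both PTC variants DE vs FA →
   **common to WDTC** (the vs-FA requirement applies to both PTC variants
   but not to FTC)
3. P = {fvPTC, clPTC}, validated, each PTC variant DE vs FA and vs FTC →
   **common to papillary**
4. P = {clPTC} (resp. {fvPTC}), validated for that variant, DE versus the
   other three differentiated subtypes → **specific to clPTC/fvPTC**
5. P = {FTC}, DE vs clPTC and vs fvPTC → **specific to FTC** (no
   validation — no second dataset carries FTC — and no vs-FA requirement)
6. otherwise → none.

Patterns are matched exactly, so the rules are mutually exclusive and each
gene gets one label; the evaluated criteria are kept as a per-gene trace.
**ATC-specific** genes start from DE(ATC vs NT) on the array, subtract
every gene DE in any differentiated subtype in any dataset, then require
DE versus both PTC variants on the array — a monotone three-step funnel,
disjoint from the differentiated categories by construction.

Category reports order genes by |log₂FC| in the category's shared subtype
(clPTC for the common categories, the defining subtype otherwise).

## Function inference

The 5 largest-|log₂FC| lncRNAs per category (FDR, then gene id, break
ties) are correlated against all coding genes across *all* samples of the
designated dataset (primary RNA-seq; microarray for ATC). Partners need
|r| ≥ 0.7 and raw two-sided p < 0.05 — both gates, both signs. The p-gate
is deliberately unadjusted, mirroring the common guilt-by-association
practice; this is anticonservative and is documented as such.
Over-representation uses the one-sided hypergeometric tail with BH
adjustment within each gene-set collection and a 0.05 significance
threshold; the universe is the post-filter coding gene set of the
designated dataset.

## Synthetic data

The generator plants, per category, 20 lncRNAs with |log₂FC| ~
Uniform(1.5, 3) (random sign, consistent across the category's subtypes)
on a baseline of log₂ mean expression ~ Normal(6, 1.5) clipped to [3, 12].
RNA-seq counts are negative binomial (dispersion 0.1, Poisson–gamma
mixture) with log-normal library factors (σ = 0.15); microarray values are
Gaussian (σ = 0.4) at probe level with 1–3 probes per gene, per-probe
affinity offsets (σ = 0.3), per-cell jitter (σ = 0.15), and 15% of genes
without probes. Planted genes have baselines ≥ 2⁵ so the planted truth
stays well defined after the low-count filter.

One coexpression module per category ties the category's strongest lncRNA
(the *hub*, planted at the top of the effect range so the top-5 selection
interrogates it) to 20 coding genes through a shared latent factor; the
loading is a² = v·r/(1−r) against each gene's log₂-scale noise variance v
(delta-method count noise for RNA-seq, σ² for the array), targeting
pairwise correlation r = 0.8. Module coding partners are co-regulated with
their hub (same group effects), which is both the biological premise of
guilt-by-association and what pushes realised correlations slightly above
the target. Module genes use baselines ≥ 2^6.5 — coexpression modules are
planted on well-expressed genes. Each module has one planted gene set
containing 60% of its coding partners plus random filler; 50 background
terms are uniform draws (term sizes 20–50 over the 1200-gene coding
universe). One planted gene per validation-dependent category is
deliberately left unprobed on the array, so the missing-probe validation
branch is always exercised.

Randomness is organised as named substreams of a single seed
(`default_rng([seed, crc32(name)])`), so adding a stage or gene never
shifts another stage's draws; identical configuration and seed give
byte-identical outputs.

What the generator does **not** emulate: probe GC/affinity bias beyond a
random offset, batch effects between cohorts, gene length effects,
alignment/counting artefacts, outlier samples, or correlated background
gene-gene structure. Passing the recovery checks therefore shows the
pipeline's selection logic and statistics behave as designed under the
stated noise model — not that real cross-platform cohorts would reach the
same operating characteristics.

## Numerical choices and degenerate inputs

- Trigamma inversion by Newton iteration (75 iterations max, relative
  tolerance 1e-10); d₀ set to ∞ on non-positive excess variance.
- Genes with zero residual variance are excluded from prior moment
  estimation; an all-zero-variance fit is a hard error.
- TMM: a sample identical to the reference (or with |M| < 1e-6 throughout)
  gets factor 1; all-zero samples are hard errors.
- Quantile-normalisation tie rule: mean of reference values over the tied
  positions (exact, not interpolated).
- Pearson p-values use the t transform on n−2 df; |r| within 1e-14 of 1 is
  treated as collinear (p = 0). Zero-variance partners are skipped with a
  logged reason; a zero-variance query gene is a hard error.
- Classification with a required between-subtype contrast missing from the
  configured datasets fails hard, naming the contrast.

## Scale of the shipped checks

The default study (2000 genes, three datasets, 154 samples total) runs in
a couple of seconds; the acceptance script repeats it over ten seeds and
adds the oracle checks, a few tens of seconds in total. These sizes were
chosen so the whole evidence chain reruns casually on a laptop; the
implementation is vectorised over genes and scales linearly in genes and
samples.
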