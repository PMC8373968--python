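"""Platform-specific preprocessing.

RNA-seq counts: low-count filtering, TMM scaling factors (trimmed mean of
M-values, Robinson & Oshlack 2010), log-CPM, and voom-style precision
weights from a lowess-smoothed mean-variance trend. Microarray
log-intensities: quantile normalisation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess as _lowess

from lncland.datasets import DataContractError, ExpressionDataset, NormalizedDataset

__all__ = [
    "filter_low_counts",
    "tmm_factors",
    "log_cpm",
    "voom_weights",
    "quantile_normalize",
]


def filter_low_counts(ds: ExpressionDataset, min_count: int = 2) -> ExpressionDataset:
    """Remove genes expressed in too few samples.

    A gene is kept iff the number of samples with count >= ``min_count`` is
    at least the size of the smallest sample group. ``min_count`` is 2 for
    deeply sequenced cohorts and 1 for shallower ones.
    """
    if ds.platform != "rnaseq":
        raise DataContractError("low-count filtering applies to RNA-seq counts only")
    sizes = ds.group_sizes()
    if len(sizes) < 2:
        raise DataContractError("low-count filtering needs at least two sample groups")
    smallest = int(sizes.min())
    n_ok = (ds.values.to_numpy() >= min_count).sum(axis=1)
    keep = ds.gene_ids[n_ok >= smallest]
    if len(keep) == 0:
        raise DataContractError("all genes filtered out by the low-count rule")
    return ds.subset_genes(keep)


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              trim_m: float, trim_a: float) -> float:
    """Log2 TMM factor of one sample against the reference sample."""
    pos = (obs > 0) & (ref > 0)
    o, r = obs[pos].astype(float), ref[pos].astype(float)
    if o.size == 0:
        return 0.0
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    if np.max(np.abs(m)) < 1e-6:
        return 0.0
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm, ra = rankdata(m), rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 0.0
    # inverse-variance weighting: w is the asymptotic variance of M
    return float(np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))


def tmm_factors(counts: pd.DataFrame, trim_m: float = 0.3, trim_a: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, one per sample.

    The reference sample is the one whose 75th-percentile count fraction is
    closest to the mean of those fractions. For each sample, genes with a
    zero in either the sample or the reference are dropped, the most extreme
    ``trim_m`` of M-values and ``trim_a`` of A-values are trimmed from each
    tail, and the factor is 2 to the inverse-variance-weighted mean of the
    remaining M-values. Factors are rescaled to geometric mean 1.
    """
    if counts.shape[1] < 2:
        raise DataContractError("TMM needs at least two samples")
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    if np.any(lib <= 0):
        bad = counts.columns[lib <= 0].tolist()
        raise DataContractError(f"sample(s) with all-zero counts: {bad}")
    f75 = np.quantile(x / lib, 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    logf = np.zeros(x.shape[1])
    for j in range(x.shape[1]):
        if j == ref_idx:
            continue
        logf[j] = _tmm_pair(x[:, j], x[:, ref_idx], lib[j], lib[ref_idx], trim_m, trim_a)
    factors = 2.0 ** logf
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def log_cpm(counts: pd.DataFrame, tmm_factor: pd.Series, prior: float = 0.5) -> pd.DataFrame:
    """Log2 counts-per-million on TMM-effective library sizes.

    value = log2((count + prior) / (lib_size * tmm_factor + 2 * prior) * 1e6).
    """
    if np.any(tmm_factor.to_numpy() <= 0):
        raise DataContractError("TMM factors must be positive")
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    eff = lib * tmm_factor.loc[counts.columns].to_numpy()
    vals = np.log2((counts.to_numpy(dtype=float) + prior) / (eff + 2.0 * prior) * 1e6)
    return pd.DataFrame(vals, index=counts.index, columns=counts.columns)


def _group_mean_fit(y: np.ndarray, groups: np.ndarray):
    """Per-row group means, fitted values and residual sd for equal weights."""
    levels, inv = np.unique(groups, return_inverse=True)
    n, k = y.shape[1], len(levels)
    means = np.empty((y.shape[0], k))
    for gi in range(k):
        means[:, gi] = y[:, inv == gi].mean(axis=1)
    fitted = means[:, inv]
    df = n - k
    if df < 1:
        raise DataContractError("no residual degrees of freedom for the group-means fit")
    s2 = ((y - fitted) ** 2).sum(axis=1) / df
    return fitted, np.sqrt(s2), df


def voom_weights(
    counts: pd.DataFrame,
    tmm_factor: pd.Series,
    groups: pd.Series,
    span: float = 0.5,
    prior: float = 0.5,
) -> NormalizedDataset:
    """Precision weights from the empirical mean-variance trend of log-CPM.

    Fits per-gene group means on log-CPM, lowess-smooths the quarter-root
    residual variance against mean log-count (span 0.5), predicts each
    observation's square-root standard deviation from its fitted log-count
    on the smoothed curve, and returns weights = predicted**-4. Predictions
    are clamped to the curve's endpoints (no extrapolation).
    """
    y = log_cpm(counts, tmm_factor, prior=prior)
    g = groups.loc[y.columns].to_numpy()
    if len(np.unique(g)) < 1 or counts.shape[1] - len(np.unique(g)) < 2:
        raise DataContractError("voom needs at least 2 residual degrees of freedom")
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    eff = lib * tmm_factor.loc[y.columns].to_numpy()

    fitted_logcpm, sigma, _ = _group_mean_fit(y.to_numpy(), g)
    # mean log2 count per gene and the observation-level fitted log2 count
    sx = y.to_numpy().mean(axis=1) + np.mean(np.log2(eff + 1.0)) - np.log2(1e6)
    sy = np.sqrt(sigma)
    smooth = _lowess(sy, sx, frac=span, return_sorted=True)
    xs, ys = smooth[:, 0], smooth[:, 1]
    xs, uniq = np.unique(xs, return_index=True)
    ys = ys[uniq]
    fitted_logcount = fitted_logcpm + (np.log2(eff + 1.0) - np.log2(1e6))[None, :]
    pred = np.interp(fitted_logcount, xs, ys)
    pred = np.maximum(pred, 1e-4)  # a flat-zero trend would blow up pred**-4
    w = pred ** -4.0
    samples = pd.DataFrame({"group": groups.loc[y.columns]})
    return NormalizedDataset(
        log2_expr=y,
        samples=samples,
        weights=pd.DataFrame(w, index=y.index, columns=y.columns),
        lib_size=pd.Series(lib, index=y.columns, name="lib_size"),
        tmm_factor=tmm_factor.loc[y.columns],
        provenance={"method": "voom", "span": span, "prior": prior},
    )


def quantile_normalize(log_matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common distribution of sorted-row means.

    Each column's sorted values are replaced by the across-column mean of
    sorted values; ties within a column receive the mean of the reference
    values at their tied ranks, so column value multisets become identical
    (up to tie averaging).
    """
    if log_matrix.shape[1] < 2:
        raise DataContractError("quantile normalisation needs at least two samples")
    x = log_matrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise DataContractError("quantile normalisation requires complete, finite values")
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(ref)
        assigned[order] = ref
        # average the reference values over tied positions
        s = pd.Series(assigned).groupby(col, sort=False).transform("mean")
        out[:, j] = s.to_numpy()
    return pd.DataFrame(out, index=log_matrix.index, columns=log_matrix.columns)
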