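"""Gene-wise linear modelling with empirical-Bayes variance moderation.

The model is the group-means parameterisation fitted independently per gene
by (optionally weighted) least squares on log2 expression. The
empirical-Bayes step shrinks per-gene residual variances toward a common
prior estimated by the method of moments on log variances (Smyth 2004):
the moderated t divides the contrast estimate by the posterior standard
deviation, and p-values use the augmented degrees of freedom d0 + df.

A differential-expression call requires BH-adjusted p <= ``fdr_max`` and
|log2 fold change| >= log2(``min_fc``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from lncland.datasets import DataContractError, NormalizedDataset

__all__ = [
    "GeneWiseLinearModel",
    "LinearFitResults",
    "EBayesResults",
    "fit_group_means",
    "ebayes_moderate",
    "bh_adjust",
    "call_de",
    "contrast_table",
    "contrast_name",
]


def contrast_name(numerator: str, denominator: str) -> str:
    return f"{numerator}_vs_{denominator}"


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise DataContractError("p-values must be finite and within [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(table: pd.DataFrame, fdr_max: float = 0.01, min_fc: float = 2.0) -> pd.DataFrame:
    """Set the ``is_de`` flag: fdr <= fdr_max and |log2fc| >= log2(min_fc)."""
    out = table.copy()
    out["is_de"] = (out["fdr"] <= fdr_max) & (out["log2fc"].abs() >= np.log2(min_fc))
    return out


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone, convex)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(75):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


class GeneWiseLinearModel:
    """Group-means linear model for a gene-by-sample log2 expression matrix.

    Parameters
    ----------
    log2_expr : DataFrame
        Genes x samples, log2 scale.
    groups : Series
        Group label per sample (indexed by sample id).
    weights : DataFrame, optional
        Strictly positive precision weights with the same shape as
        ``log2_expr`` (e.g. voom weights); omitted means ordinary least
        squares.
    """

    def __init__(self, log2_expr: pd.DataFrame, groups: pd.Series, weights: pd.DataFrame | None = None):
        groups = groups.loc[log2_expr.columns]
        sizes = groups.value_counts()
        small = sizes[sizes < 2]
        if len(small):
            raise DataContractError(
                f"group(s) with fewer than 2 samples: {small.index.tolist()}"
            )
        if weights is not None:
            weights = weights.loc[log2_expr.index, log2_expr.columns]
            w = weights.to_numpy()
            if np.any(w <= 0) or not np.all(np.isfinite(w)):
                raise DataContractError("weights must be strictly positive and finite")
        self.log2_expr = log2_expr
        self.groups = groups
        self.weights = weights

    @classmethod
    def from_normalized(cls, nd: NormalizedDataset) -> "GeneWiseLinearModel":
        return cls(nd.log2_expr, nd.groups, nd.weights)

    def fit(self) -> "LinearFitResults":
        y = self.log2_expr.to_numpy(dtype=float)
        w = np.ones_like(y) if self.weights is None else self.weights.to_numpy(dtype=float)
        levels, inv = np.unique(self.groups.to_numpy(), return_inverse=True)
        n_genes, n_samples = y.shape
        k = len(levels)
        coef = np.empty((n_genes, k))
        wsum = np.empty((n_genes, k))
        for gi in range(k):
            cols = inv == gi
            wg = w[:, cols]
            wsum[:, gi] = wg.sum(axis=1)
            coef[:, gi] = (wg * y[:, cols]).sum(axis=1) / wsum[:, gi]
        fitted = coef[:, inv]
        df_resid = n_samples - k
        if df_resid < 1:
            raise DataContractError("model is saturated: no residual degrees of freedom")
        rss = (w * (y - fitted) ** 2).sum(axis=1)
        s2 = rss / df_resid
        return LinearFitResults(
            model=self,
            coef=pd.DataFrame(coef, index=self.log2_expr.index, columns=levels),
            group_wsum=pd.DataFrame(wsum, index=self.log2_expr.index, columns=levels),
            s2=pd.Series(s2, index=self.log2_expr.index, name="s2"),
            df_resid=df_resid,
        )


@dataclass
class LinearFitResults:
    """Group means, residual variances and degrees of freedom per gene."""

    model: GeneWiseLinearModel
    coef: pd.DataFrame
    group_wsum: pd.DataFrame
    s2: pd.Series
    df_resid: int

    def stdunscaled(self, group_a: str, group_b: str) -> np.ndarray:
        """Unscaled standard error multiplier of the A-minus-B contrast."""
        return np.sqrt(
            1.0 / self.group_wsum[group_a].to_numpy()
            + 1.0 / self.group_wsum[group_b].to_numpy()
        )

    def ebayes(self, d0: float | None = None, s0_2: float | None = None) -> "EBayesResults":
        """Moderate variances with an empirical-Bayes inverse-chi-square prior.

        ``d0`` (prior degrees of freedom) and ``s0_2`` (prior variance) are
        estimated by moments on log s2 with digamma/trigamma corrections
        unless supplied explicitly. If the spread of log s2 does not exceed
        its pure-sampling expectation, d0 is infinite and every gene shares
        the prior variance.
        """
        s2 = self.s2.to_numpy()
        df = float(self.df_resid)
        if d0 is None or s0_2 is None:
            pos = s2 > 0
            if not pos.any():
                raise DataContractError("all residual variances are zero")
            if pos.sum() < 10:
                raise DataContractError(
                    "empirical-Bayes moment estimation needs >= 10 genes with positive variance"
                )
            z = np.log(s2[pos])
            e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
            emean = e.mean()
            evar = e.var(ddof=1)
            excess = evar - special.polygamma(1, df / 2.0)
            if d0 is None:
                d0 = 2.0 * _trigamma_inverse(excess) if excess > 0 else np.inf
            if s0_2 is None:
                if np.isinf(d0) or d0 == 0:
                    s0_2 = float(np.exp(emean))
                else:
                    s0_2 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_2)
        elif d0 == 0:
            s2_post = s2.copy()
        else:
            s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
        return EBayesResults(
            model=self.model,
            coef=self.coef,
            group_wsum=self.group_wsum,
            s2=self.s2,
            df_resid=self.df_resid,
            d0=float(d0),
            s0_2=float(s0_2),
            s2_post=pd.Series(s2_post, index=self.s2.index, name="s2_post"),
        )


@dataclass
class EBayesResults(LinearFitResults):
    """Linear fit with moderated variances; provides contrast tables."""

    d0: float = np.inf
    s0_2: float = 1.0
    s2_post: pd.Series | None = None

    @property
    def df_total(self) -> float:
        return self.d0 + self.df_resid

    def contrast(
        self,
        group_a: str,
        group_b: str,
        fdr_max: float = 0.01,
        min_fc: float = 2.0,
    ) -> pd.DataFrame:
        """Moderated-t table for the ``group_a`` minus ``group_b`` contrast.

        Columns: gene_id, contrast, log2fc, t, p, fdr, is_de. The BH
        adjustment runs over the genes of this fit (the post-filter gene
        universe of the dataset).
        """
        if group_a == group_b:
            raise DataContractError(f"degenerate contrast {group_a} vs {group_b}")
        for g in (group_a, group_b):
            if g not in self.coef.columns:
                raise DataContractError(f"group {g!r} not present in the fit")
        lfc = self.coef[group_a].to_numpy() - self.coef[group_b].to_numpy()
        se = np.sqrt(self.s2_post.to_numpy()) * self.stdunscaled(group_a, group_b)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, lfc / se, 0.0)
        df_tot = self.df_total
        if np.isinf(df_tot):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df_tot)
        table = pd.DataFrame(
            {
                "gene_id": self.coef.index,
                "contrast": contrast_name(group_a, group_b),
                "log2fc": lfc,
                "t": t,
                "p": p,
                "fdr": bh_adjust(p),
            }
        )
        return call_de(table, fdr_max=fdr_max, min_fc=min_fc)

    def summary(self) -> str:
        lines = [
            "Gene-wise linear model (empirical-Bayes moderated)",
            "=" * 50,
            f"genes:              {len(self.s2)}",
            f"samples:            {len(self.model.groups)}",
            f"groups:             {', '.join(map(str, self.coef.columns))}",
            f"residual df:        {self.df_resid}",
            f"prior df (d0):      {self.d0:.4g}",
            f"prior var (s0^2):   {self.s0_2:.4g}",
            f"total df:           {self.df_total:.4g}",
            f"weighted:           {self.model.weights is not None}",
        ]
        return "\n".join(lines)


def fit_group_means(nd: NormalizedDataset, groups: pd.Series | None = None) -> LinearFitResults:
    """Fit per-gene group means (weighted if voom weights are present)."""
    g = nd.groups if groups is None else groups
    return GeneWiseLinearModel(nd.log2_expr, g, nd.weights).fit()


def ebayes_moderate(fit: LinearFitResults, d0: float | None = None, s0_2: float | None = None) -> EBayesResults:
    return fit.ebayes(d0=d0, s0_2=s0_2)


def contrast_table(
    fit: LinearFitResults | EBayesResults,
    group_a: str,
    group_b: str,
    fdr_max: float = 0.01,
    min_fc: float = 2.0,
) -> pd.DataFrame:
    """DE table for one contrast, moderating variances first if needed."""
    if not isinstance(fit, EBayesResults):
        fit = fit.ebayes()
    return fit.contrast(group_a, group_b, fdr_max=fdr_max, min_fc=min_fc)
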