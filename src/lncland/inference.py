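"""Guilt-by-association functional inference for lncRNAs.

For the most strongly differentially expressed lncRNAs of each category,
coding genes correlated with them (|Pearson r| >= 0.7 and raw p < 0.05
across the samples of the designated dataset) are collected, and gene-set
over-representation among those partners is tested by the one-sided
Fisher exact (hypergeometric tail) test with BH adjustment per collection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from lncland.datasets import DataContractError, GeneSetCollection, NormalizedDataset
from lncland.de import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "top_de",
    "pearson_with_p",
    "coexpressed_genes",
    "fisher_enrichment",
    "CoexpressionResult",
]


def top_de(category_genes, de_table: pd.DataFrame, k: int = 5) -> list[str]:
    """The k most differentially expressed genes of a category.

    Ranked by |log2fc| (descending) with ties broken by smaller FDR and then
    gene id; genes must appear in ``de_table`` (indexed or keyed by
    gene_id). An empty category yields an empty list with a warning.
    """
    genes = list(category_genes)
    if not genes:
        warnings.warn("top_de called on an empty category", stacklevel=2)
        return []
    tab = de_table if de_table.index.name == "gene_id" else de_table.set_index("gene_id")
    missing = [g for g in genes if g not in tab.index]
    if missing:
        raise DataContractError(f"gene(s) without DE statistics: {missing[:5]}")
    sub = tab.loc[genes]
    order = sorted(
        genes,
        key=lambda g: (-abs(float(sub.loc[g, "log2fc"])), float(sub.loc[g, "fdr"]), g),
    )
    return order[:k]


def pearson_with_p(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with its two-sided p-value.

    The p-value is the classical t-transform p (t = r sqrt((n-2)/(1-r^2))
    on n-2 degrees of freedom); perfectly collinear input gives p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise DataContractError("pearson_with_p needs two equal-length vectors, n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DataContractError("zero-variance input to pearson_with_p")
    r, p = stats.pearsonr(x, y)
    if 1.0 - abs(r) < 1e-14:  # collinear input: the t transform diverges
        return float(np.sign(r)), 0.0
    return float(r), float(p)


@dataclass
class CoexpressionResult:
    """Coding genes coexpressed with one lncRNA in one dataset."""

    lncrna_id: str
    dataset_id: str
    partners: pd.DataFrame  # columns gene_id, r, p

    def partner_ids(self) -> list[str]:
        return self.partners["gene_id"].tolist()


def coexpressed_genes(
    lncrna: str,
    expr: NormalizedDataset,
    coding_ids,
    r_min: float = 0.7,
    p_max: float = 0.05,
    dataset_id: str = "",
) -> CoexpressionResult:
    """Coding genes passing both coexpression gates against one lncRNA.

    Correlations are computed across all samples of the dataset; both
    positive and negative correlations are retained (the gate is on |r|).
    Raw p-values are used (no multiplicity adjustment), matching the
    guilt-by-association convention; this is anticonservative.
    """
    if lncrna not in expr.gene_ids:
        raise DataContractError(f"lncRNA {lncrna!r} not present in the expression matrix")
    coding = [g for g in coding_ids if g != lncrna]
    if not coding:
        raise DataContractError("no coding genes supplied")
    x = expr.log2_expr.loc[lncrna].to_numpy(dtype=float)
    n = x.size
    if np.std(x) == 0:
        raise DataContractError(f"lncRNA {lncrna!r} has zero variance")
    ymat = expr.log2_expr.loc[coding].to_numpy(dtype=float)
    ysd = ymat.std(axis=1)
    degenerate = ysd == 0
    if degenerate.any():
        skipped = [g for g, bad in zip(coding, degenerate) if bad]
        logger.info(
            "skipping %d zero-variance coding gene(s) for %s: %s",
            len(skipped), lncrna, skipped[:5],
        )
    xc = x - x.mean()
    yc = ymat - ymat.mean(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (yc @ xc) / (np.sqrt((yc**2).sum(axis=1)) * np.sqrt((xc**2).sum()))
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = np.where(np.abs(r) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), n - 2))
    ok = ~degenerate & (np.abs(r) >= r_min) & (p < p_max)
    partners = pd.DataFrame(
        {
            "gene_id": np.asarray(coding, dtype=object)[ok],
            "r": r[ok],
            "p": p[ok],
        }
    ).sort_values(["p", "gene_id"], kind="mergesort", ignore_index=True)
    return CoexpressionResult(lncrna_id=lncrna, dataset_id=dataset_id, partners=partners)


def fisher_enrichment(
    gene_list,
    collection: GeneSetCollection,
    universe,
    alpha: float = 0.05,
    two_sided: bool = False,
) -> pd.DataFrame:
    """Over-representation of each gene set in ``gene_list``.

    One term per row with the hypergeometric-tail Fisher p-value
    P(X >= overlap), BH-adjusted across all terms of the collection.
    Term members are intersected with the universe before testing.
    """
    universe = set(universe)
    gene_list = set(gene_list)
    if not universe:
        raise DataContractError("empty universe")
    if not gene_list:
        raise DataContractError("empty gene list")
    if not gene_list <= universe:
        raise DataContractError(
            f"gene list is not a subset of the universe "
            f"({len(gene_list - universe)} genes outside)"
        )
    big_n, n = len(universe), len(gene_list)
    rows = []
    for tid, name, members in collection.items():
        term = members & universe
        k = len(term & gene_list)
        big_k = len(term)
        if big_k == 0:
            continue
        if two_sided:
            table = [[k, big_k - k], [n - k, big_n - big_k - (n - k)]]
            p = stats.fisher_exact(table, alternative="two-sided")[1]
        else:
            p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append(
            {
                "term_id": tid,
                "term_name": name,
                "overlap_count": k,
                "list_size": n,
                "term_size": big_k,
                "universe_size": big_n,
                "p": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["p_adj"] <= alpha
        out = out.sort_values(["p", "term_id"], kind="mergesort", ignore_index=True)
    return out
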