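"""Cross-dataset validation and subtype-category assignment of lncRNAs.

A differential-expression call for clPTC or fvPTC is *validated* when the
gene is DE versus normal tissue in all three datasets, or in both RNA-seq
datasets while absent from the microarray's probe coverage.

Every lncRNA is then assigned at most one of seven categories by a strict
decision cascade over its DE-versus-NT pattern in the primary RNA-seq
dataset (the only one covering FA, FTC, fvPTC and clPTC), refined by
validation and by between-subtype contrasts; ATC-specific genes are picked
on the microarray (the only platform with ATC) by subtracting everything DE
in a differentiated subtype and requiring DE against both PTC variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from lncland.datasets import DataContractError
from lncland.de import contrast_name

CATEGORIES = (
    "common_FA_WDTC",
    "common_WDTC",
    "common_papillary",
    "specific_FTC",
    "specific_fvPTC",
    "specific_clPTC",
    "specific_ATC",
)

DIFFERENTIATED = ("FA", "FTC", "fvPTC", "clPTC")

#: Subtype whose vs-NT log2FC orders each category's report (the subtype
#: shared by every member of the category).
REPORT_SUBTYPE = {
    "common_FA_WDTC": "clPTC",
    "common_WDTC": "clPTC",
    "common_papillary": "clPTC",
    "specific_FTC": "FTC",
    "specific_fvPTC": "fvPTC",
    "specific_clPTC": "clPTC",
    "specific_ATC": "ATC",
}


@dataclass
class DECallMatrix:
    """DE flags per (gene, dataset, contrast) plus per-dataset coverage.

    ``tables`` maps (dataset_id, contrast) to a gene-indexed frame with at
    least ``is_de`` and ``log2fc``; ``measured`` maps dataset_id to the set
    of genes covered by that platform. A gene absent from a table is simply
    not DE there; a gene can only be DE where it is measured.
    """

    tables: dict = field(default_factory=dict)
    measured: dict = field(default_factory=dict)

    def add_table(self, dataset_id: str, table: pd.DataFrame) -> None:
        for contrast, sub in table.groupby("contrast"):
            self.tables[(dataset_id, contrast)] = sub.set_index("gene_id")
        if dataset_id not in self.measured:
            self.measured[dataset_id] = set(table["gene_id"])

    def set_measured(self, dataset_id: str, gene_ids) -> None:
        self.measured[dataset_id] = set(gene_ids)

    def has_contrast(self, dataset_id: str, contrast: str) -> bool:
        return (dataset_id, contrast) in self.tables

    def is_de(self, gene: str, dataset_id: str, contrast: str) -> bool:
        tab = self.tables.get((dataset_id, contrast))
        if tab is None or gene not in tab.index:
            return False
        return bool(tab.loc[gene, "is_de"])

    def log2fc(self, gene: str, dataset_id: str, contrast: str) -> float:
        tab = self.tables.get((dataset_id, contrast))
        if tab is None or gene not in tab.index:
            return np.nan
        return float(tab.loc[gene, "log2fc"])

    def is_measured(self, gene: str, dataset_id: str) -> bool:
        return gene in self.measured.get(dataset_id, set())


def validate_gene(
    gene: str,
    subtype: str,
    calls: DECallMatrix,
    rnaseq_ids: tuple[str, str] = ("rnaseqA", "rnaseqB"),
    array_id: str = "array",
) -> bool:
    """Cross-dataset validation of a vs-NT DE call for clPTC or fvPTC.

    True iff the gene is DE in all three datasets, or DE in both RNA-seq
    datasets while not measured on the microarray platform.
    """
    if subtype not in ("clPTC", "fvPTC"):
        raise DataContractError(f"validation is defined for clPTC/fvPTC, not {subtype!r}")
    c = contrast_name(subtype, "NT")
    de_rna = all(calls.is_de(gene, ds, c) for ds in rnaseq_ids)
    if not de_rna:
        return False
    if calls.is_de(gene, array_id, c):
        return True
    return not calls.is_measured(gene, array_id)


def validation_table(
    genes,
    calls: DECallMatrix,
    rnaseq_ids: tuple[str, str] = ("rnaseqA", "rnaseqB"),
    array_id: str = "array",
) -> pd.DataFrame:
    """Per-gene validation flags for the two PTC variants."""
    return pd.DataFrame(
        {
            st: [validate_gene(g, st, calls, rnaseq_ids, array_id) for g in genes]
            for st in ("clPTC", "fvPTC")
        },
        index=pd.Index(genes, name="gene_id"),
    )


def _between_de(calls: DECallMatrix, gene: str, dataset: str, a: str, b: str) -> bool:
    c = contrast_name(a, b)
    if not calls.has_contrast(dataset, c):
        raise DataContractError(
            f"between-subtype contrast {c!r} missing from dataset {dataset!r}"
        )
    return calls.is_de(gene, dataset, c)


def classify_differentiated(
    genes,
    calls: DECallMatrix,
    validated: pd.DataFrame,
    primary: str = "rnaseqA",
) -> pd.DataFrame:
    """Assign differentiated-subtype categories by the decision cascade.

    ``validated`` is a gene-indexed frame with boolean columns ``clPTC``
    and ``fvPTC``. The vs-NT DE pattern P over {FA, FTC, fvPTC, clPTC} and
    all between-subtype contrasts are read from the ``primary`` RNA-seq
    dataset. Each gene receives exactly one label (possibly "none"); the
    criteria evaluated for it are recorded in ``criteria_trace``.
    """
    rows = []
    for gene in genes:
        pattern = frozenset(
            st for st in DIFFERENTIATED if calls.is_de(gene, primary, contrast_name(st, "NT"))
        )
        trace: list[tuple[str, bool]] = [
            (f"de_vs_nt:{st}", st in pattern) for st in DIFFERENTIATED
        ]
        v_cl = bool(validated.loc[gene, "clPTC"]) if gene in validated.index else False
        v_fv = bool(validated.loc[gene, "fvPTC"]) if gene in validated.index else False
        category = "none"

        def between(a: str, b: str) -> bool:
            ok = _between_de(calls, gene, primary, a, b)
            trace.append((f"between:{a}_vs_{b}", ok))
            return ok

        if pattern == frozenset(DIFFERENTIATED):
            trace += [("validated:clPTC", v_cl), ("validated:fvPTC", v_fv)]
            if v_cl and v_fv:
                category = "common_FA_WDTC"
        elif pattern == frozenset({"FTC", "fvPTC", "clPTC"}):
            trace += [("validated:clPTC", v_cl), ("validated:fvPTC", v_fv)]
            if v_cl and v_fv and between("fvPTC", "FA") and between("clPTC", "FA"):
                category = "common_WDTC"
        elif pattern == frozenset({"fvPTC", "clPTC"}):
            trace += [("validated:clPTC", v_cl), ("validated:fvPTC", v_fv)]
            if (
                v_cl
                and v_fv
                and between("fvPTC", "FA")
                and between("fvPTC", "FTC")
                and between("clPTC", "FA")
                and between("clPTC", "FTC")
            ):
                category = "common_papillary"
        elif pattern == frozenset({"clPTC"}):
            trace.append(("validated:clPTC", v_cl))
            if (
                v_cl
                and between("clPTC", "fvPTC")
                and between("clPTC", "FTC")
                and between("clPTC", "FA")
            ):
                category = "specific_clPTC"
        elif pattern == frozenset({"fvPTC"}):
            trace.append(("validated:fvPTC", v_fv))
            if (
                v_fv
                and between("fvPTC", "clPTC")
                and between("fvPTC", "FTC")
                and between("fvPTC", "FA")
            ):
                category = "specific_fvPTC"
        elif pattern == frozenset({"FTC"}):
            if between("FTC", "clPTC") and between("FTC", "fvPTC"):
                category = "specific_FTC"
        rows.append(
            {
                "gene_id": gene,
                "category": category,
                "criteria_trace": ";".join(f"{k}={'T' if ok else 'F'}" for k, ok in trace),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def classify_atc(
    calls: DECallMatrix,
    differentiated_union: set,
    array_id: str = "array",
) -> tuple[set, dict]:
    """ATC-specific genes and the three-step selection funnel.

    Start from genes DE in ATC vs NT on the microarray, remove everything DE
    in any differentiated subtype in any dataset, then keep genes DE against
    both PTC variants on the microarray. Returns the final set and the funnel
    counts {de_vs_nt, after_subtraction, after_ptc_filter}.
    """
    c_nt = contrast_name("ATC", "NT")
    tab = calls.tables.get((array_id, c_nt))
    if tab is None:
        raise DataContractError(f"no ATC vs NT table for dataset {array_id!r}")
    de_atc = set(tab.index[tab["is_de"].astype(bool)])
    not_in_diff = de_atc - set(differentiated_union)
    final = {
        g
        for g in not_in_diff
        if _between_de(calls, g, array_id, "ATC", "clPTC")
        and _between_de(calls, g, array_id, "ATC", "fvPTC")
    }
    funnel = {
        "de_vs_nt": len(de_atc),
        "after_subtraction": len(not_in_diff),
        "after_ptc_filter": len(final),
    }
    return final, funnel


def differentiated_union(calls: DECallMatrix, dataset_ids) -> set:
    """Genes DE vs NT in any differentiated subtype in any listed dataset."""
    union: set = set()
    for ds in dataset_ids:
        for st in DIFFERENTIATED:
            tab = calls.tables.get((ds, contrast_name(st, "NT")))
            if tab is not None:
                union |= set(tab.index[tab["is_de"].astype(bool)])
    return union


def assemble_assignments(
    diff_assign: pd.DataFrame,
    atc_genes: set,
    all_lncrna,
) -> pd.DataFrame:
    """Merge the differentiated cascade and the ATC rule into one table.

    ATC-specific genes are disjoint from every differentiated category by
    construction (the ATC rule subtracts the differentiated union), so each
    gene ends with exactly one label.
    """
    out = pd.DataFrame(index=pd.Index(all_lncrna, name="gene_id"))
    out["category"] = "none"
    out["criteria_trace"] = ""
    common = diff_assign.index.intersection(out.index)
    out.loc[common, ["category", "criteria_trace"]] = diff_assign.loc[
        common, ["category", "criteria_trace"]
    ]
    overlap = atc_genes & set(out.index[out["category"] != "none"])
    if overlap:
        raise DataContractError(
            f"ATC-specific genes overlap differentiated categories: {sorted(overlap)[:5]}"
        )
    atc_in = [g for g in out.index if g in atc_genes]
    out.loc[atc_in, "category"] = "specific_ATC"
    out.loc[atc_in, "criteria_trace"] = "atc_rule=T"
    return out


def intersection_report(
    assignments: pd.DataFrame,
    calls: DECallMatrix,
    primary: str = "rnaseqA",
    array_id: str = "array",
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Category counts plus per-category gene lists.

    Lists are ordered by |log2FC| in the category's defining vs-NT contrast
    (descending; ties broken by gene id), read from the primary RNA-seq
    dataset for differentiated categories and from the microarray for ATC.
    """
    counts = {cat: int((assignments["category"] == cat).sum()) for cat in CATEGORIES}
    lists: dict[str, list[str]] = {}
    for cat in CATEGORIES:
        genes = assignments.index[assignments["category"] == cat].tolist()
        ds = array_id if cat == "specific_ATC" else primary
        c = contrast_name(REPORT_SUBTYPE[cat], "NT")
        keyed = sorted(
            genes,
            key=lambda g: (-abs(calls.log2fc(g, ds, c)) if np.isfinite(calls.log2fc(g, ds, c)) else 0.0, g),
        )
        lists[cat] = keyed
    table = pd.DataFrame(
        {"category": list(counts), "n_genes": [counts[c] for c in counts]}
    )
    return table, lists
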