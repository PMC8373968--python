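"""Reading/writing expression matrices, metadata, annotation, probe maps
and GMT gene-set collections; biotype-based lncRNA selection; probe collapse.

All tabular interchange is tab-separated text: expression matrices are
genes x samples with a header row of sample ids and gene ids in the first
column; metadata has columns ``sample_id``, ``dataset_id``, ``group``;
annotation has ``gene_id``, ``symbol``, ``biotype``; probe maps have
``probe_id``, ``gene_id``.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from lncland.datasets import DataContractError, ExpressionDataset, GeneSetCollection, GROUPS

#: Biotypes retained as lncRNA (canonical, normalised spelling). The
#: annotation-dialect normaliser below maps e.g. "Sense_intronic" or
#: "misc-RNA" onto these labels before matching.
LNCRNA_BIOTYPES = frozenset(
    {
        "lincrna",
        "antisense",
        "3 prime overlapping ncrna",
        "bidirectional promoter lncrna",
        "misc rna",
        "processed transcript",
        "sense intronic",
        "sense overlapping",
    }
)

#: Labels we recognise without flagging; anything else is preserved but
#: reported by :func:`unknown_biotypes`.
KNOWN_BIOTYPES = LNCRNA_BIOTYPES | {
    "protein coding",
    "pseudogene",
    "processed pseudogene",
    "unprocessed pseudogene",
    "retained intron",
    "snorna",
    "snrna",
    "mirna",
    "rrna",
    "tec",
}


def normalize_biotype(label: str) -> str:
    """Map biotype spelling dialects onto a canonical form.

    Lower-cases and collapses underscore/hyphen/whitespace separators, so
    "Sense_intronic", "sense-intronic" and "sense intronic" all compare equal.
    """
    return re.sub(r"[\s_\-]+", " ", str(label).strip()).lower()


def read_annotation(path) -> pd.DataFrame:
    """Read a gene annotation table (gene_id, symbol, biotype), indexed by gene_id."""
    ann = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "symbol", "biotype"}
    if not required.issubset(ann.columns):
        raise DataContractError(
            f"annotation table must have columns {sorted(required)}, got {list(ann.columns)}"
        )
    if ann["gene_id"].duplicated().any():
        dups = ann.loc[ann["gene_id"].duplicated(), "gene_id"].unique().tolist()
        raise DataContractError(f"duplicate gene ids in annotation: {dups[:5]}")
    return ann.set_index("gene_id")


def unknown_biotypes(ann: pd.DataFrame) -> list[str]:
    """Biotype labels outside the declared vocabulary (preserved, but flagged)."""
    labels = {normalize_biotype(b) for b in ann["biotype"].unique()}
    return sorted(labels - KNOWN_BIOTYPES)


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group"}
    if not required.issubset(meta.columns):
        raise DataContractError(
            f"metadata must have columns {sorted(required)}, got {list(meta.columns)}"
        )
    bad = sorted(set(meta["group"]) - set(GROUPS))
    if bad:
        raise DataContractError(f"unknown group labels in metadata: {bad}")
    if meta["sample_id"].duplicated().any():
        raise DataContractError("duplicate sample ids in metadata")
    return meta.set_index("sample_id")


def read_expression(path, platform: str, metadata_path, dataset_id: str | None = None) -> ExpressionDataset:
    """Read a delimited gene-by-sample table plus sample metadata.

    RNA-seq tables must contain non-negative integer counts; a fractional or
    negative cell is a hard error naming its gene and sample. Every sample
    column must be present in the metadata.
    """
    mat = pd.read_csv(path, sep="\t", index_col=0)
    mat.index = mat.index.astype(str)
    if mat.index.has_duplicates:
        dups = mat.index[mat.index.duplicated()].unique().tolist()
        raise DataContractError(f"{path}: duplicate gene id(s) {dups[:5]}")
    meta = read_metadata(metadata_path)
    missing = [s for s in mat.columns if s not in meta.index]
    if missing:
        raise DataContractError(
            f"{path}: sample(s) {missing} missing from metadata {metadata_path}"
        )
    samples = meta.loc[list(mat.columns)]
    if dataset_id is None:
        if "dataset_id" in samples.columns and samples["dataset_id"].nunique() == 1:
            dataset_id = samples["dataset_id"].iloc[0]
        else:
            dataset_id = Path(str(path)).stem
    if platform == "rnaseq":
        arr = mat.to_numpy()
        bad = ~np.isfinite(arr) | (arr < 0) | (np.mod(arr, 1) != 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DataContractError(
                f"{path}: non-integer or negative count {arr[i, j]!r} at "
                f"gene {mat.index[i]!r}, sample {mat.columns[j]!r}"
            )
        mat = mat.astype(np.int64)
    return ExpressionDataset(dataset_id, platform, mat, samples)


def write_expression(ds: ExpressionDataset, path) -> None:
    ds.values.to_csv(path, sep="\t", index_label="gene_id")


def filter_lncrna(ds: ExpressionDataset, ann: pd.DataFrame) -> ExpressionDataset:
    """Restrict a dataset to genes with lncRNA biotypes.

    The whitelist covers lincRNA, antisense, 3-prime overlapping ncRNA,
    bidirectional promoter lncRNA, misc RNA, processed transcript, sense
    intronic and sense overlapping; protein-coding and other biotypes are
    removed. Spelling dialects are normalised before matching. The result
    may be empty (downstream stages reject empty inputs).
    """
    absent = [g for g in ds.gene_ids if g not in ann.index]
    if absent:
        raise DataContractError(
            f"dataset {ds.dataset_id}: gene(s) absent from annotation: {absent[:10]}"
        )
    biotypes = ann.loc[ds.gene_ids, "biotype"].map(normalize_biotype)
    keep = ds.gene_ids[biotypes.isin(LNCRNA_BIOTYPES).to_numpy()]
    return ds.subset_genes(keep)


def filter_lncrna_ids(ann: pd.DataFrame) -> list[str]:
    """Gene ids in an annotation table whose biotype is on the lncRNA whitelist."""
    norm = ann["biotype"].map(normalize_biotype)
    return ann.index[norm.isin(LNCRNA_BIOTYPES)].tolist()


def read_probe_map(path) -> pd.Series:
    """Read a probe-to-gene map (uniquely mapped probes only) as probe_id -> gene_id."""
    pm = pd.read_csv(path, sep="\t", dtype=str)
    required = {"probe_id", "gene_id"}
    if not required.issubset(pm.columns):
        raise DataContractError(
            f"probe map must have columns {sorted(required)}, got {list(pm.columns)}"
        )
    if pm["probe_id"].duplicated().any():
        dups = pm.loc[pm["probe_id"].duplicated(), "probe_id"].unique().tolist()
        raise DataContractError(
            f"probe map is not uniquely mapped: probe(s) {dups[:5]} occur more than once"
        )
    return pm.set_index("probe_id")["gene_id"]


def collapse_probes(probe_matrix: pd.DataFrame, probe_map: pd.Series) -> pd.DataFrame:
    """Summarise a probe-by-sample matrix to one row per gene.

    Probes absent from the map (non-uniquely mapped) are dropped; a gene
    measured by several probes is summarised by the per-sample median of its
    probes' values. Gene rows come out in sorted order.
    """
    present = probe_matrix.index.intersection(probe_map.index)
    if len(present) == 0:
        raise DataContractError("no probe in the matrix is present in the probe map")
    sub = probe_matrix.loc[present]
    genes = probe_map.loc[present]
    out = sub.groupby(genes.to_numpy()).median()
    out.index.name = "gene_id"
    return out.sort_index()


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file: tab-separated term_id, description, members..."""
    terms: dict[str, tuple[str, frozenset]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataContractError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3"
                )
            tid, name, *members = fields
            if tid in terms:
                raise DataContractError(f"{path}:{lineno}: duplicate term id {tid!r}")
            terms[tid] = (name, frozenset(m for m in members if m))
    if not terms:
        raise DataContractError(f"{path}: no gene sets")
    return GeneSetCollection(terms)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for tid, name, members in collection.items():
            fh.write("\t".join([tid, name, *sorted(members)]) + "\n")


def write_table(table: pd.DataFrame, path, index: bool = False) -> None:
    """Write a result table as tab-separated text with a header row."""
    table.to_csv(path, sep="\t", index=index)
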