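"""Core containers shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Histological group labels. NT (normal thyroid) is the reference group in
#: every contrast; WDTC = {FTC, fvPTC, clPTC}.
GROUPS = ("NT", "FA", "FTC", "fvPTC", "clPTC", "ATC")

PLATFORMS = ("rnaseq", "microarray")


class DataContractError(ValueError):
    """An input violates a documented data contract (exit code 3 in the CLI)."""


class ConfigError(ValueError):
    """A run configuration is invalid (exit code 2 in the CLI)."""


@dataclass
class ExpressionDataset:
    """One platform's gene-by-sample expression matrix with sample groups.

    ``values`` holds non-negative integer counts for the ``rnaseq`` platform
    and log2-scale intensities for ``microarray``. ``samples`` is indexed by
    sample id and carries a ``group`` column with labels from :data:`GROUPS`.
    """

    dataset_id: str
    platform: str
    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise DataContractError(
                f"unknown platform {self.platform!r}; expected one of {PLATFORMS}"
            )
        if list(self.values.columns) != list(self.samples.index):
            raise DataContractError(
                f"dataset {self.dataset_id}: matrix columns and sample metadata disagree"
            )
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise DataContractError(
                f"dataset {self.dataset_id}: duplicate gene ids {dups[:5]}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def groups(self) -> pd.Series:
        return self.samples["group"]

    def group_sizes(self) -> pd.Series:
        return self.groups.value_counts()

    def subset_genes(self, gene_ids) -> "ExpressionDataset":
        return ExpressionDataset(
            self.dataset_id,
            self.platform,
            self.values.loc[list(gene_ids)],
            self.samples,
        )


@dataclass
class NormalizedDataset:
    """Normalised log2 expression, optionally with voom precision weights.

    ``weights``, ``lib_size`` and ``tmm_factor`` are present only for the
    RNA-seq platform. ``provenance`` records the parameters that produced
    the normalisation (filter threshold, trims, lowess span ...).
    """

    log2_expr: pd.DataFrame
    samples: pd.DataFrame
    weights: pd.DataFrame | None = None
    lib_size: pd.Series | None = None
    tmm_factor: pd.Series | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.weights is not None:
            w = self.weights.to_numpy()
            if not np.all(np.isfinite(w)) or np.any(w <= 0):
                raise DataContractError("voom weights must be strictly positive and finite")

    @property
    def gene_ids(self) -> pd.Index:
        return self.log2_expr.index

    @property
    def groups(self) -> pd.Series:
        return self.samples["group"]

    def subset_genes(self, gene_ids) -> "NormalizedDataset":
        ids = list(gene_ids)
        return NormalizedDataset(
            self.log2_expr.loc[ids],
            self.samples,
            None if self.weights is None else self.weights.loc[ids],
            self.lib_size,
            self.tmm_factor,
            self.provenance,
        )


class GeneSetCollection:
    """Named gene sets (GMT semantics): term id -> (name, member set)."""

    def __init__(self, terms: dict[str, tuple[str, frozenset]]):
        for tid, (_, members) in terms.items():
            if not members:
                raise DataContractError(f"gene set {tid!r} is empty")
        self._terms = dict(terms)

    def __len__(self) -> int:
        return len(self._terms)

    def __iter__(self):
        return iter(self._terms)

    def __contains__(self, term_id) -> bool:
        return term_id in self._terms

    def name(self, term_id: str) -> str:
        return self._terms[term_id][0]

    def members(self, term_id: str) -> frozenset:
        return self._terms[term_id][1]

    def items(self):
        for tid, (name, members) in self._terms.items():
            yield tid, name, members
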