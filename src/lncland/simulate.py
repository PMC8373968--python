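"""Synthetic multi-dataset expression studies with planted ground truth.

The generator emulates the structure of a three-dataset thyroid-tumour
study: two RNA-seq count datasets with overlapping but non-identical
subtype coverage (A: NT/FA/FTC/fvPTC/clPTC; B: NT/fvPTC/clPTC) and one
microarray log-intensity dataset (NT/fvPTC/clPTC/ATC) with probe-level
values, incomplete probe coverage, and ATC present on no other platform.

Ground truth plants, for each of the seven subtype categories, lncRNAs
whose effect patterns make the category recoverable in the infinite-sample
limit, one coexpression module per category (a shared latent factor tying
the category's strongest lncRNA to a block of coding genes), and gene-set
terms enriched in each module's coding partners.

Randomness is organised as named substreams of a single seed, so adding a
stage never shifts the sampling of another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from lncland.datasets import (
    ConfigError,
    DataContractError,
    ExpressionDataset,
    GeneSetCollection,
)
from lncland.classify import CATEGORIES, REPORT_SUBTYPE

SUBTYPES = ("FA", "FTC", "fvPTC", "clPTC", "ATC")

#: Which vs-NT subtypes carry a planted effect in each category.
CATEGORY_PATTERNS = {
    "common_FA_WDTC": ("FA", "FTC", "fvPTC", "clPTC"),
    "common_WDTC": ("FTC", "fvPTC", "clPTC"),
    "common_papillary": ("fvPTC", "clPTC"),
    "specific_FTC": ("FTC",),
    "specific_fvPTC": ("fvPTC",),
    "specific_clPTC": ("clPTC",),
    "specific_ATC": ("ATC",),
}

#: Biotype spellings deliberately mixed across dialects to exercise the
#: annotation normaliser.
LNC_BIOTYPE_SPELLINGS = (
    "lincRNA",
    "Antisense",
    "Sense_intronic",
    "sense overlapping",
    "Processed_transcript",
    "misc_RNA",
    "Bidirectional_promoter_lncRNA",
    "3-prime overlapping ncRNA",
)

LN2_SQ = np.log(2.0) ** 2


@dataclass(frozen=True)
class DatasetSpec:
    dataset_id: str
    platform: str
    groups: tuple[tuple[str, int], ...]  # (group label, n samples)
    min_count: int = 2  # low-count filter threshold for rnaseq

    def group_dict(self) -> dict[str, int]:
        return dict(self.groups)


DEFAULT_DATASETS = (
    DatasetSpec(
        "rnaseqA", "rnaseq",
        (("NT", 20), ("FA", 10), ("FTC", 10), ("fvPTC", 12), ("clPTC", 15)),
        min_count=2,
    ),
    DatasetSpec(
        "rnaseqB", "rnaseq",
        (("NT", 15), ("fvPTC", 12), ("clPTC", 15)),
        min_count=1,
    ),
    DatasetSpec(
        "array", "microarray",
        (("NT", 15), ("fvPTC", 10), ("clPTC", 10), ("ATC", 10)),
    ),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic generator.

    Defaults are the desk-scale study conditions: 2000 genes (1200 coding /
    800 lncRNA) over three datasets, 20 planted lncRNAs per category with
    |log2FC| ~ Uniform(1.5, 3), negative-binomial counts (dispersion 0.1)
    for RNA-seq and Gaussian log2 intensities (sd 0.4) for the microarray,
    15% of genes without microarray probes, and one 20-gene coexpression
    module per category at target pairwise correlation 0.8.
    """

    seed: int = 0
    n_coding: int = 1200
    n_lncrna: int = 800
    datasets: tuple[DatasetSpec, ...] = DEFAULT_DATASETS
    #: genes planted per category: an int for all categories, or a mapping
    #: category -> count (absent categories default to 0)
    planted_per_category: int | dict = 20
    effect_low: float = 1.5
    effect_high: float = 3.0
    nb_dispersion: float = 0.1
    lib_sigma: float = 0.15
    baseline_log2_loc: float = 6.0
    baseline_log2_scale: float = 1.5
    baseline_log2_min: float = 3.0
    baseline_log2_max: float = 12.0
    planted_baseline_min: float = 5.0
    module_baseline_min: float = 6.5
    array_sigma: float = 0.4
    probe_missing_frac: float = 0.15
    max_probes_per_gene: int = 3
    probe_affinity_sd: float = 0.3
    probe_jitter_sd: float = 0.15
    module_size: int = 20
    module_r: float = 0.8
    n_background_terms: int = 50
    term_size_min: int = 20
    term_size_max: int = 50
    planted_overlap_frac: float = 0.6

    def validate(self) -> None:
        if not 0 <= self.probe_missing_frac < 1:
            raise ConfigError("probe_missing_frac must lie in [0, 1)")
        counts = [self.category_count(c) for c in CATEGORIES]
        if any(c < 0 for c in counts):
            raise ConfigError("planted_per_category must be >= 0")
        n_planted = sum(counts)
        if n_planted > self.n_lncrna:
            raise ConfigError(
                f"{n_planted} planted lncRNAs exceed n_lncrna={self.n_lncrna}"
            )
        if len(CATEGORIES) * self.module_size > self.n_coding:
            raise ConfigError("coexpression modules exceed the coding gene pool")
        if not 0 < self.module_r < 1:
            raise ConfigError("module_r must lie in (0, 1)")
        ids = [d.dataset_id for d in self.datasets]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate dataset ids")
        groups_by_ds = {d.dataset_id: set(d.group_dict()) for d in self.datasets}
        for d in self.datasets:
            if "NT" not in groups_by_ds[d.dataset_id]:
                raise ConfigError(f"dataset {d.dataset_id} lacks the NT reference group")
        if any(self.category_count(c) for c in CATEGORIES if c != "specific_ATC"):
            primary = self.primary_rnaseq()
            need = {"FA", "FTC", "fvPTC", "clPTC"}
            if not need <= set(primary.group_dict()):
                raise ConfigError(
                    "the primary RNA-seq dataset must cover FA, FTC, fvPTC and clPTC"
                )
        if self.category_count("specific_ATC"):
            arrays = [d for d in self.datasets if d.platform == "microarray"]
            if not any({"ATC", "fvPTC", "clPTC"} <= set(a.group_dict()) for a in arrays):
                raise ConfigError(
                    "planting specific_ATC needs a microarray dataset with ATC, fvPTC and clPTC"
                )

    def category_count(self, category: str) -> int:
        if isinstance(self.planted_per_category, dict):
            return int(self.planted_per_category.get(category, 0))
        return int(self.planted_per_category)

    def primary_rnaseq(self) -> DatasetSpec:
        for d in self.datasets:
            if d.platform == "rnaseq":
                return d
        raise ConfigError("no RNA-seq dataset configured")

    def rnaseq_ids(self) -> tuple[str, ...]:
        return tuple(d.dataset_id for d in self.datasets if d.platform == "rnaseq")

    def array_id(self) -> str:
        for d in self.datasets:
            if d.platform == "microarray":
                return d.dataset_id
        raise ConfigError("no microarray dataset configured")


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible generator for a named simulation stage."""
    return np.random.default_rng([int(seed) % (2**31), zlib.crc32(name.encode())])


def _count_noise_var_log2(mu: np.ndarray, dispersion: float) -> np.ndarray:
    # delta-method variance of log2(count) under NB(mu, dispersion)
    return (1.0 / mu + dispersion) / LN2_SQ


def generate_truth(cfg: SimulationConfig) -> pd.DataFrame:
    """Ground-truth table: one row per gene.

    Columns: role, symbol, biotype, baseline_log2, true_category,
    lfc_<subtype> for each subtype, module_id, planted_term and the
    module-loading column used by :func:`plant_coexpression`.
    """
    cfg.validate()
    coding_ids = [f"GC{i:05d}" for i in range(cfg.n_coding)]
    lnc_ids = [f"GL{i:05d}" for i in range(cfg.n_lncrna)]
    genes = coding_ids + lnc_ids
    truth = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    truth["role"] = ["coding"] * cfg.n_coding + ["lncrna"] * cfg.n_lncrna
    truth["symbol"] = [f"SYM{i:05d}" for i in range(len(genes))]
    truth["biotype"] = ["protein_coding"] * cfg.n_coding + [
        LNC_BIOTYPE_SPELLINGS[i % len(LNC_BIOTYPE_SPELLINGS)] for i in range(cfg.n_lncrna)
    ]

    rng = substream(cfg.seed, "truth")
    base = rng.normal(cfg.baseline_log2_loc, cfg.baseline_log2_scale, len(genes))
    truth["baseline_log2"] = np.clip(base, cfg.baseline_log2_min, cfg.baseline_log2_max)

    for st in SUBTYPES:
        truth[f"lfc_{st}"] = 0.0
    truth["true_category"] = "none"
    truth["module_id"] = ""
    truth["planted_term"] = ""
    truth["module_loading_var"] = 0.0

    n_planted = sum(cfg.category_count(c) for c in CATEGORIES)
    planted = rng.permutation(lnc_ids)[:n_planted]
    pos = 0
    for cat in CATEGORIES:
        members = planted[pos : pos + cfg.category_count(cat)]
        pos += cfg.category_count(cat)
        for g in members:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            for st in CATEGORY_PATTERNS[cat]:
                truth.loc[g, f"lfc_{st}"] = sign * rng.uniform(cfg.effect_low, cfg.effect_high)
            truth.loc[g, "true_category"] = cat
        # planted genes stay in the expressed range so that the planted truth
        # is well defined after the low-count filter
        idx = truth.index.isin(members)
        truth.loc[idx, "baseline_log2"] = np.maximum(
            truth.loc[idx, "baseline_log2"], cfg.planted_baseline_min
        )

    # one coexpression module per category: its lncRNA is the category member
    # with the strongest effect in the category's reporting subtype
    rng_mod = substream(cfg.seed, "modules")
    free_coding = list(coding_ids)
    for cat in CATEGORIES:
        members = truth.index[truth["true_category"] == cat]
        if len(members) == 0 or cfg.module_size == 0:
            continue
        report_lfc = truth.loc[members, f"lfc_{REPORT_SUBTYPE[cat]}"].abs()
        hub = report_lfc.idxmax()
        # the hub sits at the top of the category's effect range so the
        # guilt-by-association stage (which interrogates the strongest
        # category members) interrogates the module's lncRNA
        col = f"lfc_{REPORT_SUBTYPE[cat]}"
        truth.loc[hub, col] = np.sign(truth.loc[hub, col]) * cfg.effect_high
        partners = rng_mod.choice(free_coding, size=cfg.module_size, replace=False)
        free_coding = [g for g in free_coding if g not in set(partners)]
        module_id = f"M_{cat}"
        module_genes = [hub, *partners]
        truth.loc[module_genes, "module_id"] = module_id
        truth.loc[module_genes, "planted_term"] = f"T_{cat}"
        # coding partners are co-regulated with the hub lncRNA
        for st in SUBTYPES:
            truth.loc[list(partners), f"lfc_{st}"] = truth.loc[hub, f"lfc_{st}"]
        truth.loc[module_genes, "baseline_log2"] = np.maximum(
            truth.loc[module_genes, "baseline_log2"], cfg.module_baseline_min
        )
    return truth


def _sample_frame(spec: DatasetSpec) -> pd.DataFrame:
    sample_ids, groups = [], []
    i = 0
    for grp, n in spec.groups:
        for _ in range(n):
            sample_ids.append(f"{spec.dataset_id}_s{i:03d}")
            groups.append(grp)
            i += 1
    return pd.DataFrame(
        {"dataset_id": spec.dataset_id, "group": groups},
        index=pd.Index(sample_ids, name="sample_id"),
    )


def _spec_for(cfg: SimulationConfig, dataset_id: str) -> DatasetSpec:
    for d in cfg.datasets:
        if d.dataset_id == dataset_id:
            return d
    raise ConfigError(f"dataset {dataset_id!r} not in the configuration")


def _group_lfc_matrix(truth: pd.DataFrame, samples: pd.DataFrame) -> np.ndarray:
    lfc = np.zeros((len(truth), len(samples)))
    for j, grp in enumerate(samples["group"]):
        if grp != "NT":
            lfc[:, j] = truth[f"lfc_{grp}"].to_numpy()
    return lfc


def simulate_rnaseq(truth: pd.DataFrame, cfg: SimulationConfig, dataset_id: str) -> ExpressionDataset:
    """Negative-binomial counts for one RNA-seq dataset.

    Per-cell mean = 2**(baseline + group log2FC) x a log-normal per-sample
    library factor; the NB dispersion is ``cfg.nb_dispersion`` (0 gives
    Poisson counts).
    """
    spec = _spec_for(cfg, dataset_id)
    if spec.platform != "rnaseq":
        raise ConfigError(f"dataset {dataset_id!r} is not an RNA-seq dataset")
    samples = _sample_frame(spec)
    rng = substream(cfg.seed, f"counts:{dataset_id}")
    libfac = np.exp(rng.normal(0.0, cfg.lib_sigma, len(samples)))
    mu = 2.0 ** (truth["baseline_log2"].to_numpy()[:, None] + _group_lfc_matrix(truth, samples))
    mu = mu * libfac[None, :]
    if cfg.nb_dispersion <= 0:
        counts = rng.poisson(mu)
    else:
        shape = 1.0 / cfg.nb_dispersion
        lam = rng.gamma(shape, mu / shape)
        counts = rng.poisson(lam)
    values = pd.DataFrame(counts.astype(np.int64), index=truth.index, columns=samples.index)
    return ExpressionDataset(dataset_id, "rnaseq", values, samples)


def plant_coexpression(truth: pd.DataFrame, cfg: SimulationConfig, ds: ExpressionDataset) -> ExpressionDataset:
    """Overlay the shared latent factor of each coexpression module.

    For a target pairwise correlation r, each module gene receives a loading
    a with a^2 = v * r / (1 - r), where v is the gene's log2-scale noise
    variance (count noise for RNA-seq, ``array_sigma``^2 for microarray), so
    the factor's variance share yields population correlation ~ r; the
    shared group effects of co-regulated members only push pairs above it.
    RNA-seq counts are scaled by 2**(a z_s) and re-rounded; microarray
    intensities receive a z_s additively.
    """
    module_ids = sorted(m for m in truth["module_id"].unique() if m)
    values = ds.values.copy()
    for module_id in module_ids:
        members = truth.index[truth["module_id"] == module_id]
        missing = [g for g in members if g not in values.index]
        if missing:
            raise DataContractError(
                f"module {module_id} member(s) absent from dataset {ds.dataset_id}: {missing[:5]}"
            )
        rng = substream(cfg.seed, f"module:{ds.dataset_id}:{module_id}")
        z = rng.normal(0.0, 1.0, values.shape[1])
        if ds.platform == "rnaseq":
            mu = 2.0 ** truth.loc[members, "baseline_log2"].to_numpy()
            v = _count_noise_var_log2(mu, cfg.nb_dispersion)
        else:
            v = np.full(len(members), cfg.array_sigma**2)
        a = np.sqrt(v * cfg.module_r / (1.0 - cfg.module_r))
        bump = a[:, None] * z[None, :]
        if ds.platform == "rnaseq":
            values.loc[members] = np.rint(
                values.loc[members].to_numpy() * 2.0**bump
            ).astype(np.int64)
        else:
            values.loc[members] = values.loc[members].to_numpy() + bump
    return ExpressionDataset(ds.dataset_id, ds.platform, values, ds.samples)


@dataclass
class ArrayData:
    """Probe-level microarray data: probe matrix, probe map, sample sheet."""

    dataset_id: str
    probe_matrix: pd.DataFrame
    probe_map: pd.Series
    samples: pd.DataFrame
    measured_genes: pd.Index


def simulate_microarray(
    truth: pd.DataFrame,
    cfg: SimulationConfig,
    dataset_id: str,
    plant: bool = True,
) -> ArrayData:
    """Gaussian log2 intensities with probe-level structure.

    A ``probe_missing_frac`` fraction of genes receives no probes at all
    (exercising the missing-probe branch of cross-dataset validation);
    measured genes get 1-3 probes with a per-probe affinity offset and
    per-cell jitter. ATC-specific module genes are always probed: a gene
    unmeasured on the only ATC platform could not be ATC-specific.
    """
    spec = _spec_for(cfg, dataset_id)
    if spec.platform != "microarray":
        raise ConfigError(f"dataset {dataset_id!r} is not a microarray dataset")
    samples = _sample_frame(spec)
    rng = substream(cfg.seed, f"array:{dataset_id}")
    gene_vals = (
        truth["baseline_log2"].to_numpy()[:, None]
        + _group_lfc_matrix(truth, samples)
        + rng.normal(0.0, cfg.array_sigma, (len(truth), len(samples)))
    )
    gene_ds = ExpressionDataset(
        dataset_id, "microarray",
        pd.DataFrame(gene_vals, index=truth.index, columns=samples.index),
        samples,
    )
    if plant:
        gene_ds = plant_coexpression(truth, cfg, gene_ds)

    rng_p = substream(cfg.seed, f"probes:{dataset_id}")
    always_probed = set(truth.index[truth["module_id"] == "M_specific_ATC"]) | set(
        truth.index[truth["true_category"] == "specific_ATC"]
    )
    # one planted gene per validation-dependent category is deliberately left
    # unprobed, so the missing-probe branch of cross-dataset validation is
    # always exercised
    forced_missing: set = set()
    if cfg.probe_missing_frac > 0:
        for cat in (
            "common_FA_WDTC", "common_WDTC", "common_papillary",
            "specific_fvPTC", "specific_clPTC",
        ):
            members = sorted(truth.index[truth["true_category"] == cat])
            non_hub = [g for g in members if truth.loc[g, "module_id"] == ""]
            if non_hub:
                forced_missing.add(non_hub[-1])
    eligible = [g for g in truth.index if g not in always_probed | forced_missing]
    n_missing = int(round(cfg.probe_missing_frac * len(truth)))
    n_extra = max(0, min(n_missing - len(forced_missing), len(eligible)))
    missing = forced_missing | set(rng_p.choice(eligible, size=n_extra, replace=False))
    measured = pd.Index([g for g in truth.index if g not in missing], name="gene_id")

    probe_rows, probe_ids, gene_of_probe = [], [], []
    vals = gene_ds.values
    for g in measured:
        n_probes = int(rng_p.integers(1, cfg.max_probes_per_gene + 1))
        base_row = vals.loc[g].to_numpy()
        for j in range(n_probes):
            offset = rng_p.normal(0.0, cfg.probe_affinity_sd)
            jitter = rng_p.normal(0.0, cfg.probe_jitter_sd, len(base_row))
            probe_rows.append(base_row + offset + jitter)
            probe_ids.append(f"{g}_p{j}")
            gene_of_probe.append(g)
    probe_matrix = pd.DataFrame(
        np.asarray(probe_rows), index=pd.Index(probe_ids, name="probe_id"),
        columns=samples.index,
    )
    probe_map = pd.Series(gene_of_probe, index=probe_matrix.index, name="gene_id")
    return ArrayData(dataset_id, probe_matrix, probe_map, samples, measured)


def simulate_gmt(truth: pd.DataFrame, cfg: SimulationConfig) -> tuple[GeneSetCollection, pd.DataFrame]:
    """Planted-enriched and background gene sets over the coding universe.

    Each module's planted term contains ``planted_overlap_frac`` of the
    module's coding partners plus random background coding genes; background
    terms are uniform random draws. Returns the collection and a term truth
    table (term_id, planted flag, module_id).
    """
    rng = substream(cfg.seed, "gmt")
    coding = truth.index[truth["role"] == "coding"].tolist()
    terms: dict[str, tuple[str, frozenset]] = {}
    rows = []
    for module_id in sorted(m for m in truth["module_id"].unique() if m):
        members = truth.index[(truth["module_id"] == module_id) & (truth["role"] == "coding")]
        tid = f"T_{module_id[2:]}"
        k = max(1, int(round(cfg.planted_overlap_frac * len(members))))
        core = list(rng.choice(list(members), size=k, replace=False))
        size = int(rng.integers(cfg.term_size_min, cfg.term_size_max + 1))
        background_pool = [g for g in coding if g not in set(core)]
        extra = list(rng.choice(background_pool, size=max(0, size - k), replace=False))
        terms[tid] = (f"planted term for {module_id}", frozenset(core + extra))
        rows.append({"term_id": tid, "planted": True, "module_id": module_id})
    for i in range(cfg.n_background_terms):
        tid = f"BG{i:04d}"
        size = int(rng.integers(cfg.term_size_min, cfg.term_size_max + 1))
        members = frozenset(rng.choice(coding, size=size, replace=False))
        terms[tid] = (f"background term {i}", members)
        rows.append({"term_id": tid, "planted": False, "module_id": ""})
    return GeneSetCollection(terms), pd.DataFrame(rows)


@dataclass
class SimulatedStudy:
    """Everything one simulated study comprises."""

    cfg: SimulationConfig
    truth: pd.DataFrame
    annotation: pd.DataFrame
    rnaseq: dict  # dataset_id -> ExpressionDataset (counts)
    arrays: dict  # dataset_id -> ArrayData
    gmt: GeneSetCollection
    gmt_truth: pd.DataFrame


def simulate_study(cfg: SimulationConfig) -> SimulatedStudy:
    """Generate the full multi-dataset study for one configuration."""
    cfg.validate()
    truth = generate_truth(cfg)
    annotation = truth[["symbol", "biotype"]].copy()
    rnaseq, arrays = {}, {}
    for spec in cfg.datasets:
        if spec.platform == "rnaseq":
            ds = simulate_rnaseq(truth, cfg, spec.dataset_id)
            rnaseq[spec.dataset_id] = plant_coexpression(truth, cfg, ds)
        else:
            arrays[spec.dataset_id] = simulate_microarray(truth, cfg, spec.dataset_id)
    gmt, gmt_truth = simulate_gmt(truth, cfg)
    return SimulatedStudy(cfg, truth, annotation, rnaseq, arrays, gmt, gmt_truth)


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a configuration from a plain mapping (YAML-friendly)."""
    d = dict(d)
    if "datasets" in d:
        specs = []
        for item in d["datasets"]:
            specs.append(
                DatasetSpec(
                    item["dataset_id"],
                    item["platform"],
                    tuple((g, int(n)) for g, n in item["groups"].items()),
                    int(item.get("min_count", 2)),
                )
            )
        d["datasets"] = tuple(specs)
    known = set(SimulationConfig.__dataclass_fields__)
    bad = set(d) - known
    if bad:
        raise ConfigError(f"unknown simulation config key(s): {sorted(bad)}")
    return replace(SimulationConfig(), **d)
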