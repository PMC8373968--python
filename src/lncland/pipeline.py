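"""End-to-end orchestration: simulate/ingest -> normalise -> DE -> classify
-> coexpress -> enrich -> report, with a machine-readable run manifest.

The run configuration is a plain mapping (usually loaded from YAML):

.. code-block:: yaml

    seed: 1
    simulate: {n_coding: 1200, n_lncrna: 800}   # SimulationConfig overrides
    de: {fdr_max: 0.01, min_fc: 2.0}
    validation: {mode: three_dataset}           # or two_dataset
    coexpression: {r_min: 0.7, p_max: 0.05, top_k: 5}
    enrichment: {alpha: 0.05}

Stage outputs are pure functions of the configuration and seed; rerunning
with the same config reproduces identical output digests.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from lncland import classify as cls
from lncland import io as lio
from lncland.datasets import ConfigError, DataContractError, ExpressionDataset, NormalizedDataset
from lncland.de import GeneWiseLinearModel, contrast_name
from lncland.inference import coexpressed_genes, fisher_enrichment, top_de
from lncland.normalize import filter_low_counts, quantile_normalize, tmm_factors, voom_weights
from lncland.simulate import SimulatedStudy, config_from_dict, simulate_study

STAGES = ("simulate", "normalize", "de", "classify", "coexpress", "report")


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: list = field(default_factory=list)

    def add_stage(self, name: str, seconds: float, outputs: dict) -> None:
        self.stages.append({"name": name, "seconds": round(seconds, 3), "outputs": outputs})

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "seed": self.seed,
                "version": self.version,
                "stages": self.stages,
            },
            indent=2,
        )


@dataclass
class PipelineResult:
    """In-memory results of one pipeline run."""

    config: dict
    study: SimulatedStudy
    normalized: dict  # dataset_id -> NormalizedDataset (all genes)
    lnc_results: dict  # dataset_id -> EBayesResults on the lncRNA subset
    de_tables: dict  # dataset_id -> DETable (all contrasts concatenated)
    calls: cls.DECallMatrix | None = None
    validated: pd.DataFrame | None = None
    assignments: pd.DataFrame | None = None
    category_counts: pd.DataFrame | None = None
    category_lists: dict | None = None
    atc_funnel: dict | None = None
    coexpression: pd.DataFrame | None = None
    enrichment: pd.DataFrame | None = None
    recovery: pd.DataFrame | None = None
    manifest: RunManifest | None = None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: run configuration must be a mapping")
    return cfg


def _check_config(config: dict) -> dict:
    known = {"seed", "simulate", "de", "validation", "coexpression", "enrichment"}
    bad = set(config) - known
    if bad:
        raise ConfigError(f"unknown config section(s): {sorted(bad)}")
    mode = config.get("validation", {}).get("mode", "three_dataset")
    if mode not in ("three_dataset", "two_dataset"):
        raise ConfigError(f"validation.mode must be three_dataset or two_dataset, got {mode!r}")
    return config


def _normalize_rnaseq(ds: ExpressionDataset, min_count: int) -> NormalizedDataset:
    filtered = filter_low_counts(ds, min_count=min_count)
    factors = tmm_factors(filtered.values)
    nd = voom_weights(filtered.values, factors, filtered.groups)
    nd.provenance.update({"min_count": min_count, "dataset_id": ds.dataset_id})
    return nd


def _normalize_array(array) -> NormalizedDataset:
    qn = quantile_normalize(array.probe_matrix)
    gene_level = lio.collapse_probes(qn, array.probe_map)
    return NormalizedDataset(
        log2_expr=gene_level,
        samples=array.samples,
        provenance={"method": "quantile+median-collapse", "dataset_id": array.dataset_id},
    )


def _vs_nt_contrasts(groups) -> list[tuple[str, str]]:
    return [(g, "NT") for g in sorted(set(groups)) if g != "NT"]


def _between_contrasts(groups, platform: str) -> list[tuple[str, str]]:
    present = set(groups)
    if platform == "microarray":
        return [("ATC", g) for g in ("clPTC", "fvPTC") if g in present and "ATC" in present]
    diff = [g for g in cls.DIFFERENTIATED if g in present]
    return [(a, b) for a in diff for b in diff if a != b]


def run_pipeline(config: dict | str | Path, out_dir=None, stop_after: str | None = None) -> PipelineResult:
    """Execute the full analysis and optionally write its result tables.

    ``config`` is a mapping or a path to a YAML file. Raises
    :class:`ConfigError` before any computation for schema problems and
    :class:`DataContractError` when a stage's inputs violate its contract.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    config = _check_config(config)
    if stop_after is not None and stop_after not in STAGES:
        raise ConfigError(f"unknown stage {stop_after!r}; stages are {STAGES}")
    seed = int(config.get("seed", 0))
    sim_over = dict(config.get("simulate", {}))
    sim_over["seed"] = seed
    sim_cfg = config_from_dict(sim_over)
    mode = config.get("validation", {}).get("mode", "three_dataset")
    if mode == "three_dataset":
        n_rna = len(sim_cfg.rnaseq_ids())
        n_arr = len(sim_cfg.datasets) - n_rna
        if n_rna < 2 or n_arr < 1:
            raise ConfigError(
                "three-dataset validation needs two RNA-seq datasets and a microarray "
                "dataset; set validation.mode=two_dataset to drop the microarray clause"
            )
    de_cfg = {"fdr_max": 0.01, "min_fc": 2.0, **config.get("de", {})}
    co_cfg = {"r_min": 0.7, "p_max": 0.05, "top_k": 5, **config.get("coexpression", {})}
    en_cfg = {"alpha": 0.05, **config.get("enrichment", {})}

    manifest = RunManifest(
        config_hash=hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        seed=seed,
        version=_version(),
    )
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    study = simulate_study(sim_cfg)
    result = PipelineResult(config=config, study=study, normalized={}, lnc_results={}, de_tables={})
    manifest.add_stage("simulate", time.perf_counter() - t0, {})
    result.manifest = manifest
    if stop_after == "simulate":
        return result

    # --- normalise -------------------------------------------------------
    t0 = time.perf_counter()
    ann = study.annotation
    lnc_ids_all = set(lio.filter_lncrna_ids(ann))
    for ds_id, ds in study.rnaseq.items():
        spec = next(d for d in sim_cfg.datasets if d.dataset_id == ds_id)
        result.normalized[ds_id] = _normalize_rnaseq(ds, spec.min_count)
    for ds_id, arr in study.arrays.items():
        result.normalized[ds_id] = _normalize_array(arr)
    manifest.add_stage("normalize", time.perf_counter() - t0, {})
    if stop_after == "normalize":
        return result

    # --- differential expression on the lncRNA universe ------------------
    t0 = time.perf_counter()
    calls = cls.DECallMatrix()
    for ds_id, nd in result.normalized.items():
        platform = "rnaseq" if ds_id in study.rnaseq else "microarray"
        lnc_here = [g for g in nd.gene_ids if g in lnc_ids_all]
        if not lnc_here:
            raise DataContractError(f"dataset {ds_id}: no lncRNA genes after filtering")
        lnc_nd = nd.subset_genes(lnc_here)
        ebayes = GeneWiseLinearModel.from_normalized(lnc_nd).fit().ebayes()
        result.lnc_results[ds_id] = ebayes
        tables = []
        pairs = _vs_nt_contrasts(nd.groups) + _between_contrasts(nd.groups, platform)
        for a, b in pairs:
            tables.append(ebayes.contrast(a, b, fdr_max=de_cfg["fdr_max"], min_fc=de_cfg["min_fc"]))
        det = pd.concat(tables, ignore_index=True)
        result.de_tables[ds_id] = det
        calls.add_table(ds_id, det)
        if platform == "microarray":
            arr_measured = [g for g in study.arrays[ds_id].measured_genes if g in lnc_ids_all]
            calls.set_measured(ds_id, arr_measured)
        else:
            calls.set_measured(ds_id, lnc_here)
    result.calls = calls
    manifest.add_stage("de", time.perf_counter() - t0, _write_de(out, result))
    if stop_after == "de":
        return result

    # --- validation + category assignment --------------------------------
    t0 = time.perf_counter()
    primary = sim_cfg.primary_rnaseq().dataset_id
    rnaseq_ids = sim_cfg.rnaseq_ids()[:2]
    array_id = sim_cfg.array_id() if mode == "three_dataset" else None
    genes_primary = [g for g in result.lnc_results[primary].coef.index]
    if mode == "three_dataset":
        validated = cls.validation_table(genes_primary, calls, rnaseq_ids, array_id)
    else:
        validated = pd.DataFrame(
            {
                st: [
                    all(calls.is_de(g, ds, contrast_name(st, "NT")) for ds in rnaseq_ids)
                    for g in genes_primary
                ]
                for st in ("clPTC", "fvPTC")
            },
            index=pd.Index(genes_primary, name="gene_id"),
        )
    result.validated = validated
    diff_assign = cls.classify_differentiated(genes_primary, calls, validated, primary)
    union = cls.differentiated_union(calls, list(result.normalized))
    if array_id is not None:
        atc_genes, funnel = cls.classify_atc(calls, union, array_id)
    else:
        atc_genes, funnel = set(), {}
    result.atc_funnel = funnel
    all_lnc = sorted(lnc_ids_all)
    assignments = cls.assemble_assignments(diff_assign, atc_genes, all_lnc)
    result.assignments = assignments
    counts, lists = cls.intersection_report(assignments, calls, primary, array_id or "array")
    result.category_counts, result.category_lists = counts, lists
    manifest.add_stage("classify", time.perf_counter() - t0, _write_classify(out, result))
    if stop_after == "classify":
        return result

    # --- coexpression + enrichment ---------------------------------------
    t0 = time.perf_counter()
    co_rows, en_rows = [], []
    for cat in cls.CATEGORIES:
        genes = lists[cat]
        if not genes:
            continue
        ds_id = (sim_cfg.array_id() if cat == "specific_ATC" else primary)
        if cat == "specific_ATC" and not study.arrays:
            continue
        nd = result.normalized[ds_id]
        det = result.de_tables[ds_id]
        sub = det[det["contrast"] == contrast_name(cls.REPORT_SUBTYPE[cat], "NT")]
        in_ds = [g for g in genes if g in set(sub["gene_id"])]
        top = top_de(in_ds, sub, k=co_cfg["top_k"]) if in_ds else []
        coding_here = [g for g in nd.gene_ids if g not in lnc_ids_all]
        for lnc in top:
            co = coexpressed_genes(
                lnc, nd, coding_here, r_min=co_cfg["r_min"], p_max=co_cfg["p_max"],
                dataset_id=ds_id,
            )
            for _, row in co.partners.iterrows():
                co_rows.append(
                    {"category": cat, "lncrna_id": lnc, "dataset_id": ds_id,
                     "gene_id": row["gene_id"], "r": row["r"], "p": row["p"]}
                )
            if len(co.partners):
                enr = fisher_enrichment(
                    co.partner_ids(), study.gmt, coding_here, alpha=en_cfg["alpha"]
                )
                enr.insert(0, "lncrna_id", lnc)
                enr.insert(0, "category", cat)
                en_rows.append(enr)
    result.coexpression = pd.DataFrame(
        co_rows, columns=["category", "lncrna_id", "dataset_id", "gene_id", "r", "p"]
    )
    result.enrichment = (
        pd.concat(en_rows, ignore_index=True) if en_rows else pd.DataFrame(
            columns=["category", "lncrna_id", "term_id", "term_name", "overlap_count",
                     "list_size", "term_size", "universe_size", "p", "p_adj", "significant"]
        )
    )
    manifest.add_stage("coexpress", time.perf_counter() - t0, _write_coexpress(out, result))
    if stop_after == "coexpress":
        return result

    # --- truth recovery ---------------------------------------------------
    t0 = time.perf_counter()
    result.recovery = recovery_report(study.truth, assignments)
    outputs = {}
    if out is not None:
        lio.write_table(result.recovery, out / "recovery.tsv")
        (out / "manifest.json").write_text(manifest.to_json())
        outputs["recovery.tsv"] = _sha256(out / "recovery.tsv")
    manifest.add_stage("report", time.perf_counter() - t0, outputs)
    if out is not None:
        (out / "manifest.json").write_text(manifest.to_json())
    return result


def recovery_report(truth: pd.DataFrame, assignments: pd.DataFrame) -> pd.DataFrame:
    """Per-category sensitivity and precision against the planted truth."""
    lnc = truth[truth["role"] == "lncrna"]
    merged = lnc[["true_category"]].join(assignments[["category"]], how="left")
    merged["category"] = merged["category"].fillna("none")
    rows = []
    for cat in cls.CATEGORIES:
        n_true = int((merged["true_category"] == cat).sum())
        n_called = int((merged["category"] == cat).sum())
        tp = int(((merged["true_category"] == cat) & (merged["category"] == cat)).sum())
        rows.append(
            {
                "category": cat,
                "n_true": n_true,
                "n_called": n_called,
                "true_positives": tp,
                "sensitivity": tp / n_true if n_true else float("nan"),
                "precision": tp / n_called if n_called else 1.0,
            }
        )
    return pd.DataFrame(rows)


def _write_de(out, result: PipelineResult) -> dict:
    if out is None:
        return {}
    digests = {}
    for ds_id, det in result.de_tables.items():
        p = out / f"de_{ds_id}.tsv"
        lio.write_table(det, p)
        digests[p.name] = _sha256(p)
    return digests


def _write_classify(out, result: PipelineResult) -> dict:
    if out is None:
        return {}
    digests = {}
    lio.write_table(result.assignments.reset_index(), out / "categories.tsv")
    lio.write_table(result.category_counts, out / "category_counts.tsv")
    if result.atc_funnel:
        pd.DataFrame([result.atc_funnel]).to_csv(out / "atc_funnel.tsv", sep="\t", index=False)
        digests["atc_funnel.tsv"] = _sha256(out / "atc_funnel.tsv")
    for name in ("categories.tsv", "category_counts.tsv"):
        digests[name] = _sha256(out / name)
    return digests


def _write_coexpress(out, result: PipelineResult) -> dict:
    if out is None:
        return {}
    lio.write_table(result.coexpression, out / "coexpression.tsv")
    lio.write_table(result.enrichment, out / "enrichment.tsv")
    return {
        "coexpression.tsv": _sha256(out / "coexpression.tsv"),
        "enrichment.tsv": _sha256(out / "enrichment.tsv"),
    }


def _version() -> str:
    from lncland import __version__

    return __version__
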