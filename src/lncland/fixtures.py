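"""Write a simulated study as the package's text-fixture formats."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from lncland import io as lio
from lncland.simulate import SimulatedStudy


def write_study(study: SimulatedStudy, out_dir) -> None:
    """Write TSV expression matrices, metadata, annotation, probe map,
    GMT gene sets and the ground-truth table for one simulated study."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta_frames = []
    for ds_id, ds in study.rnaseq.items():
        ds.values.to_csv(out / f"{ds_id}_counts.tsv", sep="\t", index_label="gene_id")
        meta_frames.append(ds.samples.reset_index())
    for ds_id, arr in study.arrays.items():
        arr.probe_matrix.to_csv(out / f"{ds_id}_probes.tsv", sep="\t", index_label="probe_id")
        arr.probe_map.reset_index().to_csv(out / f"{ds_id}_probe_map.tsv", sep="\t", index=False)
        meta_frames.append(arr.samples.reset_index())
    pd.concat(meta_frames, ignore_index=True).to_csv(out / "metadata.tsv", sep="\t", index=False)
    study.annotation.reset_index().to_csv(out / "annotation.tsv", sep="\t", index=False)
    study.truth.reset_index().to_csv(out / "truth.tsv", sep="\t", index=False)
    study.gmt_truth.to_csv(out / "gmt_truth.tsv", sep="\t", index=False)
    lio.write_gmt(study.gmt, out / "genesets.gmt")
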