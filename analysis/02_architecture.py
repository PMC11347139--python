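#!/usr/bin/env python
"""Reconstruct transcript architecture from the synthetic long reads.

Runs read-to-gene assignment (overlap > 100 nt or > 50% of gene length,
antisense reads discarded), builds transcript types (> 10 reads),
transcriptional contexts, operon-boundary extensions, and 10-nt boundary
histograms; writes results/run/ and prints what was found against the
planted truth.
"""

import json

from common import RUN_DIR, STUDY_CFG, ensure_dataset

from btarch.annotation import read_operon_table, read_annotation
from btarch.pipeline import RunConfig, context_bin_table, run_all
from btarch.simulate import GroundTruth

import pandas as pd


def main() -> None:
    paths = ensure_dataset()
    cfg = RunConfig(
        reads=str(paths["reads"]),
        gff=str(paths["gff"]),
        operons=str(paths["operons"]),
        outdir=str(RUN_DIR),
    )
    out = run_all(cfg)
    m = json.loads((out / "manifest.json").read_text())["stages"]
    a = m["architecture"]
    print(f"reads: {a['reads_primary']} primary; "
          f"{a['assigned']} assigned, {a['antisense_discarded']} antisense-discarded, "
          f"{a['no_overlap']} intergenic, {a['all_filtered']} filtered out")
    print(f"transcript types (>10 reads): {a['n_transcript_types']}")

    truth = GroundTruth.from_json(paths["truth"])
    ann = read_annotation(paths["gff"])
    operons = read_operon_table(paths["operons"], ann=ann)
    want_ext = truth.expected_extensions(operons, min_reads=10)
    ext = pd.read_csv(out / "operon_extensions.tsv", sep="\t")
    print(f"extended operons: {len(ext)} detected / {len(want_ext)} planted")

    ctx = pd.read_csv(out / "contexts.tsv", sep="\t")
    bins = context_bin_table(ctx["n_contexts"].tolist())
    print("transcriptional contexts (% of genes): "
          + ", ".join(f"{k}: {v:.1f}%" for k, v in bins.items()))


if __name__ == "__main__":
    main()
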