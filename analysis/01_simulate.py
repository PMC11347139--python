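#!/usr/bin/env python
"""Generate the synthetic study dataset (seed 1) with its ground truth.

Writes results/synthetic/: genome FASTA, GFF3 annotation, operon table,
BED6 long-read alignments with step-wise 3' truncation / 5' processing /
read-through / antisense phenomena, per-tool modification-site tables,
coverage bedGraphs, and native/IVT MeRIP peak pairs.
"""

from common import DATASET_DIR, STUDY_CFG, ensure_dataset

from btarch.simulate import GroundTruth


def main() -> None:
    paths = ensure_dataset()
    truth = GroundTruth.from_json(paths["truth"])
    kinds = {}
    for t in truth.types:
        kinds[t.kind] = kinds.get(t.kind, 0) + 1
    print(f"dataset: {DATASET_DIR}")
    print(f"operons: {STUDY_CFG.n_operons}; planted transcript types: {len(truth.types)}")
    print(f"  by kind: {kinds}")
    print(f"planted m6A sites: {len(truth.modified_positions)}")
    print(f"MeRIP peaks: {len(truth.signal_peaks)} signal + {len(truth.fp_peaks)} false-positive")


if __name__ == "__main__":
    main()
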