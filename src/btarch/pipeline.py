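"""Stage orchestration: one config, full run, manifest, report.

``run_all`` executes the architecture, quantification and epitranscriptome
stages in dependency order, skipping stages whose inputs are absent, and
writes deterministic TSV/BED outputs plus a run manifest whose per-stage
counters satisfy exact conservation identities (every input read/site/peak
lands in exactly one outcome category).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

import btarch
from btarch import annotation as ann_mod
from btarch import architecture as arch
from btarch import epitranscriptome as epi
from btarch import quantify

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All inputs and thresholds for a pipeline run.

    Threshold defaults are the values the analysis is designed around:
    overlap > 100 nt or > 50% of gene length, transcript types supported by
    > 10 reads, 10-nt boundary bins, >= 4 tools for consensus, +-2 nt m6A
    adjacency, coverage depth > 10, and 1 nt minimum peak overlap for IVT
    calibration.
    """

    # inputs (None = stage skipped)
    reads: str | None = None
    gff: str | None = None
    operons: str | None = None
    genome: str | None = None
    tool_sites: dict[str, str] = field(default_factory=dict)
    native_peaks: str | None = None
    ivt_peaks: str | None = None
    cov_native: str | None = None
    cov_control: str | None = None
    # thresholds
    min_overlap_len: int = 100
    min_overlap_frac: float = 0.5
    frac_denominator: str = "gene"
    min_reads: int = 10
    bin_size: int = 10
    count_mode: str = "all"
    biotype_filter: str = "mRNA"
    min_tools: int = 4
    window: int = 2
    min_depth: int = 10
    min_peak_overlap: int = 1
    motif_flank: int = 5
    # run
    seed: int = 0
    outdir: str = "btarch_out"

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def config_hash(self) -> str:
        """Fingerprint of the scientific configuration (output dir excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("outdir")
        return hashlib.sha256(
            yaml.safe_dump(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _require(config: RunConfig, stage: str, **inputs) -> None:
    for name, value in inputs.items():
        if value is None:
            raise FileNotFoundError(f"stage {stage!r} requires input {name!r}")
        if not Path(value).exists():
            raise FileNotFoundError(f"stage {stage!r}: input file not found: {value}")


def run_all(config: RunConfig) -> Path:
    """Run every stage whose inputs are present; returns the output dir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    manifest: dict = {
        "version": btarch.__version__,
        "config_hash": config.config_hash(),
        "inputs": {},
        "stages": {},
    }
    for name in ("reads", "gff", "operons", "genome", "native_peaks", "ivt_peaks",
                 "cov_native", "cov_control"):
        p = getattr(config, name)
        if p is not None and Path(p).exists():
            manifest["inputs"][name] = _sha256(p)
    for tool, p in config.tool_sites.items():
        if Path(p).exists():
            manifest["inputs"][f"sites:{tool}"] = _sha256(p)

    annotation = None
    if config.gff is not None:
        _require(config, "annotation", gff=config.gff)
        annotation = ann_mod.read_annotation(config.gff)

    assignments = None
    if config.reads is not None:
        _require(config, "architecture", reads=config.reads, gff=config.gff)
        assignments = _run_architecture(config, annotation, outdir, manifest)
        _run_quantification(config, assignments, outdir, manifest)

    if config.tool_sites:
        _require(
            config,
            "epitranscriptome",
            gff=config.gff,
            genome=config.genome,
            native_peaks=config.native_peaks,
            ivt_peaks=config.ivt_peaks,
            cov_native=config.cov_native,
            cov_control=config.cov_control,
        )
        _run_epitranscriptome(config, annotation, outdir, manifest)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return outdir


def _run_architecture(config, annotation, outdir, manifest):
    ingest_stats = arch.IngestStats()
    assign_stats = arch.AssignmentStats()
    reads = list(arch.ingest_alignments(config.reads, stats=ingest_stats))
    assignments = [
        arch.assign_read(
            r,
            annotation,
            min_len=config.min_overlap_len,
            min_frac=config.min_overlap_frac,
            frac_denominator=config.frac_denominator,
            stats=assign_stats,
        )
        for r in reads
    ]
    types = arch.build_transcript_types(assignments, min_reads=config.min_reads)
    contexts = arch.count_contexts(types)

    pd.DataFrame(
        [(",".join(t.gene_ids), len(t.gene_ids), t.read_count) for t in types],
        columns=["gene_ids", "n_genes", "read_count"],
    ).to_csv(outdir / "transcript_types.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(c.gene_id, c.n_contexts) for c in contexts],
        columns=["gene_id", "n_contexts"],
    ).to_csv(outdir / "contexts.tsv", sep="\t", index=False)

    n_extensions = 0
    if config.operons is not None:
        operons = ann_mod.read_operon_table(config.operons, ann=annotation)
        extensions = arch.detect_operon_extensions(types, operons)
        n_extensions = len(extensions)
        pd.DataFrame(
            [
                (
                    e.operon_id,
                    ",".join(e.known_gene_ids),
                    ",".join(e.added_gene_ids),
                    sum(e.supporting_types.values()),
                )
                for e in extensions
            ],
            columns=["operon_id", "known_genes", "added_genes", "supporting_reads"],
        ).to_csv(outdir / "operon_extensions.tsv", sep="\t", index=False)
        manifest["stages"]["operons"] = {
            "n_operons": len(operons),
            "n_extended": n_extensions,
        }

    hist = arch.boundary_histogram(reads, bin_size=config.bin_size)
    hist.to_bedgraph(outdir)

    manifest["stages"]["architecture"] = {
        "reads_primary": ingest_stats.primary,
        "reads_secondary": ingest_stats.secondary,
        "reads_supplementary": ingest_stats.supplementary,
        "reads_unmapped": ingest_stats.unmapped,
        "assigned": assign_stats.assigned,
        "antisense_discarded": assign_stats.antisense_discarded,
        "no_overlap": assign_stats.no_overlap,
        "all_filtered": assign_stats.all_filtered,
        "n_transcript_types": len(types),
    }
    if assign_stats.total != ingest_stats.primary:
        raise AssertionError("read conservation identity violated")
    return assignments


def _run_quantification(config, assignments, outdir, manifest):
    table = quantify.count_reads(
        assignments,
        biotype_filter=frozenset({config.biotype_filter}),
        mode=config.count_mode,
    )
    if len(table) and (table["q"] > 0).any():
        table = quantify.compute_tpm(table)
    else:
        logger.warning("no counted genes; expression table empty")
        table = table.assign(tpm=pd.Series(dtype=float))
    table.to_csv(outdir / "expression.tsv", sep="\t", index=False)
    manifest["stages"]["quantification"] = {
        "n_genes": int(len(table)),
        "total_counts": float(table["q"].sum()) if len(table) else 0.0,
    }


def _run_epitranscriptome(config, annotation, outdir, manifest):
    import pyfaidx

    genome = pyfaidx.Fasta(config.genome)
    cov_native = epi.CoverageTrack.from_bedgraph(config.cov_native)
    cov_control = epi.CoverageTrack.from_bedgraph(config.cov_control)

    filtered: dict[str, list] = {}
    site_counts = {}
    for tool, path in sorted(config.tool_sites.items()):
        sites = epi.parse_caller_output(tool, path)
        kept = epi.filter_sites(
            sites, annotation, cov_native, cov_control, min_depth=config.min_depth
        )
        filtered[tool] = kept
        site_counts[tool] = {"parsed": len(sites), "kept": len(kept)}

    cons = epi.consensus(filtered, min_tools=config.min_tools)
    native = epi.read_peaks_bed(config.native_peaks, source="native")
    ivt = epi.read_peaks_bed(config.ivt_peaks, source="ivt")
    calibrated = epi.calibrate_peaks(native, ivt, min_overlap=config.min_peak_overlap)
    if calibrated.n_input != len(native):
        raise AssertionError("peak calibration partition identity violated")

    cands = epi.assign_m6a(
        cons, calibrated, annotation, genome, window=config.window
    )
    counts, per_gene = epi.summarize_by_biotype(cands)

    with open(outdir / "consensus_sites.bed", "w") as fh:
        for s in cons:
            fh.write(
                f"{s.contig}\t{s.position - 1}\t{s.position}\t"
                f"{'|'.join(sorted(s.supporting_tools))}\t{s.n_tools}\t{s.strand}\n"
            )
    for name, peaks in (
        ("peaks_retained.bed", calibrated.retained),
        ("peaks_removed.bed", [p for p, _ in calibrated.removed]),
    ):
        with open(outdir / name, "w") as fh:
            for p in peaks:
                fh.write(f"{p.contig}\t{p.start - 1}\t{p.end}\tpeak\t0\t{p.strand}\n")
    pd.DataFrame(
        [
            (c.contig, c.position, c.strand, c.gene_id, c.gene_relative_position,
             c.biotype, c.evidence)
            for c in cands
        ],
        columns=["contig", "position", "strand", "gene_id", "gene_relative_position",
                 "biotype", "evidence"],
    ).to_csv(outdir / "m6a_candidates.tsv", sep="\t", index=False)
    per_gene.to_csv(outdir / "biotype_summary.tsv", sep="\t", index=False)
    epi.export_motif_windows(
        cands,
        genome,
        flank=config.motif_flank,
        fasta_path=outdir / "motif_windows.fasta",
        bed_path=outdir / "m6a_candidates.bed",
    )

    manifest["stages"]["epitranscriptome"] = {
        "per_tool": site_counts,
        "n_consensus": len(cons),
        "peaks_native": len(native),
        "peaks_retained": len(calibrated.retained),
        "peaks_removed": len(calibrated.removed),
        "n_m6a_candidates": len(cands),
        "m6a_by_biotype": counts,
    }


CONTEXT_BINS = ("1", "2", "3", ">=4")


def context_bin_table(n_contexts: list[int]) -> dict[str, float]:
    """Percentage of genes in {1, 2, 3, >=4} transcriptional contexts."""
    if not n_contexts:
        return {b: 0.0 for b in CONTEXT_BINS}
    counts = {b: 0 for b in CONTEXT_BINS}
    for n in n_contexts:
        counts["1" if n == 1 else "2" if n == 2 else "3" if n == 3 else ">=4"] += 1
    total = len(n_contexts)
    return {b: 100.0 * c / total for b, c in counts.items()}


def report(outdir: str | Path) -> dict:
    """Summarize a completed run: per-stage counts, the transcriptional
    context distribution binned as {1, 2, 3, >=4}, and the per-gene m6A
    table.  Writes ``report.txt`` and returns the summary dict."""
    outdir = Path(outdir)
    manifest_path = outdir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"{outdir} has no manifest.json; run the pipeline first")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    summary: dict = {"stages": manifest["stages"]}

    ctx_path = outdir / "contexts.tsv"
    if ctx_path.exists():
        ctx = pd.read_csv(ctx_path, sep="\t")
        if len(ctx) == 0:
            logger.warning("empty context table")
        summary["context_distribution_pct"] = context_bin_table(
            ctx["n_contexts"].tolist()
        )

    bio_path = outdir / "biotype_summary.tsv"
    if bio_path.exists():
        summary["m6a_per_gene"] = pd.read_csv(bio_path, sep="\t").to_dict("records")

    lines = ["btarch run report", "=================", ""]
    for stage, counts in summary["stages"].items():
        lines.append(f"[{stage}] {json.dumps(counts, sort_keys=True)}")
    if "context_distribution_pct" in summary:
        lines.append("")
        lines.append("transcriptional contexts (% of genes):")
        for b, pct in summary["context_distribution_pct"].items():
            lines.append(f"  {b}: {pct:.1f}%")
    if "m6a_per_gene" in summary:
        lines.append("")
        lines.append(f"m6A-modified genes: {len(summary['m6a_per_gene'])}")
    with open(outdir / "report.txt", "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return summary
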