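"""Seeded synthetic data with a ground-truth manifest.

The generator emulates the phenomena the pipeline is built to detect on a
toy bacterial chromosome: operon-structured gene layouts on both strands,
long reads that start at the operon's primary 5' end and terminate
step-wise at downstream gene boundaries, 5'-processed reads lacking the
first gene, read-through reads extending into the next same-strand operon,
antisense noise reads, per-tool modification calls with configurable
sensitivity / false-positive rate / positional jitter, coverage tracks, and
native/IVT MeRIP peak pairs sharing planted false-positive peaks.

Everything derives from a single integer seed; the same configuration
produces byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from btarch.annotation import AnnotationSet, GeneModel, OperonRecord, write_operon_table
from btarch.architecture import ReadAlignment

_TOOLS = ("differr", "drummer", "eligos2", "nanocompore", "tombo_com")


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic genome, reads and modification data.

    Ranges are inclusive (lo, hi) tuples sampled uniformly.  Probabilities
    must lie in [0, 1].
    """

    seed: int = 0
    # genome layout
    n_operons: int = 20
    genes_per_operon: tuple[int, int] = (1, 4)
    gene_length: tuple[int, int] = (200, 1500)
    intergenic_gap: tuple[int, int] = (40, 150)
    operon_gap: tuple[int, int] = (250, 600)
    frac_minus_strand: float = 0.5
    n_rrna_operons: int = 1
    n_ncrna_genes: int = 2
    contig_name: str = "chrSyn"
    # read simulation
    reads_per_type: tuple[int, int] = (15, 60)
    p_readthrough: float = 0.1
    p_processed: float = 0.15
    antisense_rate: float = 0.02
    # modification calls
    tools: tuple[str, ...] = _TOOLS
    tool_sensitivity: float = 0.9
    tool_fp_rate: float = 5e-5  # false calls per covered base per tool
    jitter: int = 2  # max |positional jitter| in nt; 0 disables
    n_planted_m6a: int = 30
    rrna_m6a_bias: float = 0.5  # fraction of planted sites placed on rRNA genes
    coverage_depth: int = 30
    # MeRIP peaks
    peak_halfwidth: int = 75
    peak_fp_fraction: float = 0.2  # false peaks as a fraction of signal peaks

    def validate(self) -> None:
        for name in ("frac_minus_strand", "p_readthrough", "p_processed",
                     "antisense_rate", "tool_sensitivity", "rrna_m6a_bias",
                     "peak_fp_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.gene_length[0] < 1 or self.intergenic_gap[0] < 1 or self.operon_gap[0] < 1:
            raise ValueError("infeasible layout: gene lengths and gaps must be >= 1 nt")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")


@dataclass
class PlantedType:
    """One planted transcript type with its realized sense read count."""

    gene_ids: tuple[str, ...]
    count: int
    kind: str  # full | truncated | processed | readthrough
    operon_id: str


@dataclass
class GroundTruth:
    """Manifest of everything planted; the oracle for end-to-end recovery."""

    types: list[PlantedType] = field(default_factory=list)
    modified_positions: list[tuple[str, int, str]] = field(default_factory=list)
    signal_peaks: list[tuple[str, int, int, str]] = field(default_factory=list)
    fp_peaks: list[tuple[str, int, int, str]] = field(default_factory=list)

    def type_counts(self, min_reads: int = 0) -> dict[tuple[str, ...], int]:
        out: dict[tuple[str, ...], int] = {}
        for t in self.types:
            out[t.gene_ids] = out.get(t.gene_ids, 0) + t.count
        return {k: v for k, v in out.items() if v > min_reads}

    def expected_extensions(
        self, operons: Sequence[OperonRecord], min_reads: int = 10
    ) -> dict[str, set[str]]:
        """Operon id -> added genes, recomputed from the planted types with
        the same superset criterion the detector applies."""
        counts = self.type_counts(min_reads)
        out: dict[str, set[str]] = {}
        for op in operons:
            known = set(op.gene_ids)
            added: set[str] = set()
            for gids in counts:
                if known < set(gids):
                    added |= set(gids) - known
            if added:
                out[op.operon_id] = added
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "types": [dataclasses.asdict(t) for t in self.types],
            "modified_positions": self.modified_positions,
            "signal_peaks": self.signal_peaks,
            "fp_peaks": self.fp_peaks,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=list)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        truth = cls()
        truth.types = [
            PlantedType(tuple(t["gene_ids"]), t["count"], t["kind"], t["operon_id"])
            for t in payload["types"]
        ]
        truth.modified_positions = [tuple(x) for x in payload["modified_positions"]]
        truth.signal_peaks = [tuple(x) for x in payload["signal_peaks"]]
        truth.fp_peaks = [tuple(x) for x in payload["fp_peaks"]]
        return truth


@dataclass
class SyntheticDataset:
    """In-memory synthetic dataset plus its ground truth."""

    cfg: SyntheticConfig
    sequence: str
    annotation: AnnotationSet
    operons: list[OperonRecord]
    truth: GroundTruth
    reads: list[ReadAlignment] = field(default_factory=list)

    @property
    def genome(self) -> dict[str, str]:
        return {self.cfg.contig_name: self.sequence}


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


def make_genome(cfg: SyntheticConfig) -> SyntheticDataset:
    """Lay out non-overlapping operons (plus standalone ncRNA genes) on a
    random chromosome and return the dataset skeleton with ground truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes: list[GeneModel] = []
    operons: list[OperonRecord] = []
    cursor = 1 + int(rng.integers(cfg.operon_gap[0], cfg.operon_gap[1] + 1))
    gid = 0

    def next_int(lo_hi: tuple[int, int]) -> int:
        return int(rng.integers(lo_hi[0], lo_hi[1] + 1))

    for i in range(cfg.n_operons):
        strand = "-" if rng.random() < cfg.frac_minus_strand else "+"
        biotype = "rRNA" if i < cfg.n_rrna_operons else "mRNA"
        n_genes = next_int(cfg.genes_per_operon)
        member_ids = []
        for _ in range(n_genes):
            length = next_int(cfg.gene_length)
            g = GeneModel(
                gene_id=f"g{gid:04d}",
                contig=cfg.contig_name,
                start=cursor,
                end=cursor + length - 1,
                strand=strand,
                biotype=biotype,
            )
            genes.append(g)
            member_ids.append(g.gene_id)
            gid += 1
            cursor = g.end + 1 + next_int(cfg.intergenic_gap)
        # operon gene order follows transcription: genomic for '+', reversed for '-'
        ordered = member_ids if strand == "+" else list(reversed(member_ids))
        operons.append(
            OperonRecord(
                operon_id=f"op{i:03d}",
                gene_ids=tuple(ordered),
                contig=cfg.contig_name,
                strand=strand,
            )
        )
        cursor += next_int(cfg.operon_gap)

    for _ in range(cfg.n_ncrna_genes):
        strand = "-" if rng.random() < cfg.frac_minus_strand else "+"
        length = max(80, cfg.gene_length[0] // 2)
        g = GeneModel(
            gene_id=f"g{gid:04d}",
            contig=cfg.contig_name,
            start=cursor,
            end=cursor + length - 1,
            strand=strand,
            biotype="ncRNA",
        )
        genes.append(g)
        gid += 1
        cursor = g.end + 1 + next_int(cfg.operon_gap)

    genome_len = max(cursor + 200, 1000)
    sequence = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=genome_len)])
    ann = AnnotationSet(genes)
    operons = [op.resolve(ann) for op in operons]
    return SyntheticDataset(
        cfg=cfg,
        sequence=sequence,
        annotation=ann,
        operons=[op for op in operons if op is not None],
        truth=GroundTruth(),
    )


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------


def _type_span(ann: AnnotationSet, gene_ids: Sequence[str]) -> tuple[int, int]:
    genes = [ann[g] for g in gene_ids]
    return min(g.start for g in genes), max(g.end for g in genes)


def simulate_reads(cfg: SyntheticConfig, dataset: SyntheticDataset) -> list[ReadAlignment]:
    """Draw reads from planted transcript types and record realized counts.

    Planted types per operon: every transcription-order prefix of the gene
    list (full-length plus step-wise 3'-truncated forms), a 5'-processed
    variant lacking the first gene (probability ``p_processed``), and a
    read-through variant extending into the next same-strand operon's first
    gene (probability ``p_readthrough``).  Each planned sense read flips to
    an antisense noise read with probability ``antisense_rate``; realized
    sense counts land in the ground truth.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    ann = dataset.annotation
    planted: list[tuple[tuple[str, ...], str, str]] = []  # (genes, kind, operon)

    ops = dataset.operons
    for idx, op in enumerate(ops):
        k = len(op.gene_ids)
        for j in range(1, k + 1):
            kind = "full" if j == k else "truncated"
            planted.append((tuple(op.gene_ids[:j]), kind, op.operon_id))
        if k > 1 and rng.random() < cfg.p_processed:
            planted.append((tuple(op.gene_ids[1:]), "processed", op.operon_id))
        if rng.random() < cfg.p_readthrough:
            # transcription continues past the 3' boundary into the adjacent
            # operon in the direction of transcription: genomically right for
            # '+', left for '-'
            j = idx + 1 if op.strand == "+" else idx - 1
            nxt = ops[j] if 0 <= j < len(ops) else None
            if nxt is not None and nxt.strand == op.strand and nxt.contig == op.contig:
                planted.append(
                    (tuple(op.gene_ids) + (nxt.gene_ids[0],), "readthrough", op.operon_id)
                )

    reads: list[ReadAlignment] = []
    rid = 0
    for tx_order_ids, kind, operon_id in planted:
        # the pipeline reports gene tuples in genomic order; record truth the
        # same way (prefixes were taken in transcription order above)
        gene_ids = tuple(sorted(tx_order_ids, key=lambda g: ann[g].start))
        n = int(rng.integers(cfg.reads_per_type[0], cfg.reads_per_type[1] + 1))
        start, end = _type_span(ann, gene_ids)
        strand = ann[gene_ids[0]].strand
        n_sense = 0
        for _ in range(n):
            antisense = rng.random() < cfg.antisense_rate
            reads.append(
                ReadAlignment(
                    read_id=f"r{rid:06d}",
                    contig=cfg.contig_name,
                    start=start,
                    end=end,
                    strand=("-" if strand == "+" else "+") if antisense else strand,
                )
            )
            rid += 1
            if not antisense:
                n_sense += 1
        dataset.truth.types.append(
            PlantedType(gene_ids=gene_ids, count=n_sense, kind=kind, operon_id=operon_id)
        )
    dataset.reads = reads
    return reads


def write_reads_bed(reads: Sequence[ReadAlignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"{r.contig}\t{r.start - 1}\t{r.end}\t{r.read_id}\t60\t{r.strand}\n")


def write_reads_sam(
    reads: Sequence[ReadAlignment], path: str | Path, genome_len: int, contig: str
) -> None:
    """Minimal SAM writer (unsorted header, full-span matches) for testing
    the alignment ingest path without binary files."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:{contig}\tLN:{genome_len}\n")
        for r in sorted(reads, key=lambda r: r.start):
            flag = 16 if r.strand == "-" else 0
            span = r.end - r.start + 1
            fh.write(
                f"{r.read_id}\t{flag}\t{contig}\t{r.start}\t60\t{span}M\t*\t0\t0\t*\t*\n"
            )


# ---------------------------------------------------------------------------
# modification calls, coverage, peaks
# ---------------------------------------------------------------------------


def _adenosine_positions(dataset: SyntheticDataset, gene: GeneModel) -> np.ndarray:
    """Strand-aware adenosine positions (1-based) within a gene body."""
    seq = dataset.sequence[gene.start - 1 : gene.end]
    want = "A" if gene.strand == "+" else "T"
    return np.array([gene.start + i for i, b in enumerate(seq) if b == want], dtype=int)


def simulate_mod_calls(
    cfg: SyntheticConfig, dataset: SyntheticDataset, outdir: str | Path
) -> dict[str, Path]:
    """Plant m6A sites and write per-tool site tables, coverage bedGraphs and
    native/IVT peak BEDs; returns a name -> path map.

    Each tool reports each planted site with probability
    ``tool_sensitivity`` at the true position shifted by uniform jitter in
    {-jitter..jitter}; per-tool false positives are scattered over gene
    bodies at ``tool_fp_rate`` per covered base.  Native peaks of
    ``peak_halfwidth`` nt half-width cover every planted site; false-positive
    peaks (a ``peak_fp_fraction`` of the signal peaks, placed clear of any
    planted site) are duplicated into the IVT set.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ann = dataset.annotation
    contig = cfg.contig_name

    rrna_genes = [g for g in ann if g.biotype == "rRNA"]
    other_genes = [g for g in ann if g.biotype != "rRNA"]

    def sample_sites(genes: list[GeneModel], n: int) -> list[tuple[int, str]]:
        pool = []
        for g in genes:
            for p in _adenosine_positions(dataset, g):
                pool.append((int(p), g.strand))
        pool.sort()
        if n >= len(pool):
            return pool
        idx = rng.choice(len(pool), size=n, replace=False)
        return [pool[i] for i in sorted(idx)]

    n_rrna = int(round(cfg.n_planted_m6a * cfg.rrna_m6a_bias)) if rrna_genes else 0
    sites = sample_sites(rrna_genes, n_rrna) + sample_sites(
        other_genes, cfg.n_planted_m6a - n_rrna
    )
    sites = sorted(set(sites))
    dataset.truth.modified_positions = [(contig, p, s) for p, s in sites]

    gene_spans = sorted((g.start, g.end, g.strand) for g in ann)
    total_gene_len = sum(e - s + 1 for s, e, _ in gene_spans)

    # per-tool calls
    paths: dict[str, Path] = {}
    for tool in cfg.tools:
        calls: dict[tuple[int, str], float] = {}
        for pos, strand in sites:
            if rng.random() >= cfg.tool_sensitivity:
                continue
            shift = int(rng.integers(-cfg.jitter, cfg.jitter + 1)) if cfg.jitter else 0
            calls.setdefault((pos + shift, strand), 1e-6)
        n_fp = rng.poisson(cfg.tool_fp_rate * total_gene_len)
        for _ in range(n_fp):
            s, e, strand = gene_spans[int(rng.integers(0, len(gene_spans)))]
            calls.setdefault((int(rng.integers(s, e + 1)), strand), 1e-4)
        p = outdir / f"{tool}_sites.tsv"
        _write_tool_file(tool, contig, sorted(calls.items()), dataset, p)
        paths[tool] = p

    # coverage: constant depth over gene bodies in both samples
    for name in ("coverage_native", "coverage_control"):
        p = outdir / f"{name}.bedgraph"
        with open(p, "w") as fh:
            for s, e, _ in gene_spans:
                fh.write(f"{contig}\t{s - 1}\t{e}\t{cfg.coverage_depth}\n")
        paths[name] = p

    # peaks
    genome_len = len(dataset.sequence)
    signal_peaks = []
    for pos, strand in sites:
        lo = max(1, pos - cfg.peak_halfwidth)
        hi = min(genome_len, pos + cfg.peak_halfwidth)
        signal_peaks.append((contig, lo, hi, strand))
    n_fp_peaks = int(round(cfg.peak_fp_fraction * len(signal_peaks)))
    fp_peaks = []
    attempts = 0
    while len(fp_peaks) < n_fp_peaks and attempts < 1000 * max(1, n_fp_peaks):
        attempts += 1
        s, e, strand = gene_spans[int(rng.integers(0, len(gene_spans)))]
        center = int(rng.integers(s, e + 1))
        lo = max(1, center - cfg.peak_halfwidth)
        hi = min(genome_len, center + cfg.peak_halfwidth)
        if any(lo <= p <= hi for p, _ in sites):
            continue
        if any(not (hi < plo or lo > phi) for _, plo, phi, _ in signal_peaks):
            continue
        fp_peaks.append((contig, lo, hi, strand))
    dataset.truth.signal_peaks = signal_peaks
    dataset.truth.fp_peaks = fp_peaks

    native = sorted(signal_peaks + fp_peaks, key=lambda p: p[1])
    ivt = sorted(fp_peaks, key=lambda p: p[1])
    for name, peaks in (("native_peaks", native), ("ivt_peaks", ivt)):
        p = outdir / f"{name}.bed"
        with open(p, "w") as fh:
            for c, lo, hi, strand in peaks:
                fh.write(f"{c}\t{lo - 1}\t{hi}\tpeak\t0\t{strand}\n")
        paths[name] = p
    return paths


def _write_tool_file(
    tool: str,
    contig: str,
    calls: list[tuple[tuple[int, str], float]],
    dataset: SyntheticDataset,
    path: Path,
) -> None:
    """Emit calls in each tool's documented dialect (all significant)."""

    def base(pos: int, strand: str) -> str:
        b = dataset.sequence[pos - 1].upper() if 1 <= pos <= len(dataset.sequence) else "N"
        if strand == "-":
            b = b.translate(_DNA_COMP)
        return b.replace("T", "U")

    with open(path, "w") as fh:
        if tool == "differr":
            for (pos, strand), p in calls:
                fh.write(
                    f"{contig}\t{pos - 1}\t{pos}\tsite\t100\t{strand}\t5.0\t30.0\t{p}\n"
                )
        elif tool == "drummer":
            fh.write("chromosome\tpos\tref_base\tstrand\todds_ratio\tpadj\n")
            for (pos, strand), p in calls:
                fh.write(f"{contig}\t{pos}\t{base(pos, strand)}\t{strand}\t4.0\t{p}\n")
        elif tool == "eligos2":
            fh.write("chrom\tstart_loc\tend_loc\tref\tstrand\toddR\tadjPval\n")
            for (pos, strand), p in calls:
                fh.write(
                    f"{contig}\t{pos - 1}\t{pos}\t{base(pos, strand)}\t{strand}\t5.0\t{p}\n"
                )
        elif tool == "nanocompore":
            fh.write("pos\tchr\tstrand\tref_kmer\tGMM_logit_pvalue\n")
            for (pos, strand), p in calls:
                kmer = "".join(
                    base(q, strand) for q in (range(pos - 2, pos + 3) if strand == "+"
                                              else range(pos + 2, pos - 3, -1))
                )
                fh.write(f"{pos - 1}\t{contig}\t{strand}\t{kmer}\t{p}\n")
        elif tool == "tombo_com":
            fh.write("chrom\tpos\tstrand\tfrac_modified\n")
            for (pos, strand), _ in calls:
                fh.write(f"{contig}\t{pos - 1}\t{strand}\t0.9\n")
        else:
            raise ValueError(f"no dialect writer for tool {tool!r}")


_DNA_COMP = str.maketrans("ACGTN", "TGCAN")


# ---------------------------------------------------------------------------
# whole-dataset driver
# ---------------------------------------------------------------------------


def write_gff3(dataset: SyntheticDataset, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {dataset.cfg.contig_name} 1 {len(dataset.sequence)}\n")
        for g in sorted(dataset.annotation, key=lambda g: g.start):
            biotype_attr = {
                "mRNA": "protein_coding",
                "rRNA": "rRNA",
                "tRNA": "tRNA",
                "ncRNA": "ncRNA",
            }.get(g.biotype, "ncRNA")
            fh.write(
                f"{g.contig}\tbtarch_sim\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};gene_biotype={biotype_attr}\n"
            )


def write_fasta(dataset: SyntheticDataset, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{dataset.cfg.contig_name}\n")
        seq = dataset.sequence
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


def simulate_all(cfg: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate the complete synthetic dataset on disk.

    Writes genome FASTA, GFF3, operon TSV, BED6 read alignments, per-tool
    site tables, coverage bedGraphs, native/IVT peak BEDs and the
    ground-truth manifest JSON; returns a name -> path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset = make_genome(cfg)
    simulate_reads(cfg, dataset)
    paths = simulate_mod_calls(cfg, dataset, outdir)

    paths["genome"] = outdir / "genome.fasta"
    write_fasta(dataset, paths["genome"])
    paths["gff"] = outdir / "annotation.gff3"
    write_gff3(dataset, paths["gff"])
    paths["operons"] = outdir / "operons.tsv"
    write_operon_table(dataset.operons, paths["operons"])
    paths["reads"] = outdir / "reads.bed"
    write_reads_bed(dataset.reads, paths["reads"])
    paths["truth"] = outdir / "truth.json"
    dataset.truth.to_json(paths["truth"])
    return paths
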