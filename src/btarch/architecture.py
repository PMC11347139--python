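"""Read-to-gene assignment and transcript architecture.

Long DRS reads covering several adjacent genes are the raw material for
operon-level architecture: each primary alignment is overlap-filtered against
same-strand genes, the ordered combination of kept genes defines a transcript
type, and transcript types in turn define per-gene transcriptional contexts
and operon-boundary extensions.

Filtering rules (defaults):

* reads mapped antisense to every gene they touch are discarded;
* a same-strand gene is kept for a read iff the overlap is > 100 nt OR
  exceeds 50% of the gene length (denominator switchable to read length);
* transcript types are retained when supported by strictly more than
  ``min_reads`` reads (default 10).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from btarch.annotation import AnnotationSet, GeneModel, OperonRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReadAlignment:
    """A primary read alignment as a stranded genomic span (1-based incl.)."""

    read_id: str
    contig: str
    start: int
    end: int
    strand: str
    is_secondary: bool = False
    is_supplementary: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"read {self.read_id}: start > end")

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end

    def three_prime(self) -> int:
        return self.end if self.strand == "+" else self.start


@dataclass
class IngestStats:
    primary: int = 0
    secondary: int = 0
    supplementary: int = 0
    unmapped: int = 0


def ingest_alignments(
    path: str | Path, stats: IngestStats | None = None
) -> Iterator[ReadAlignment]:
    """Yield primary alignments from a BED6 file or a coordinate-sorted
    BAM/SAM.

    Secondary, supplementary and unmapped records are skipped and counted in
    *stats*.  BED rows must carry a strand; a BAM that is not
    coordinate-sorted raises with an instruction to sort it first.
    """
    path = Path(path)
    if path.suffix.lower() in (".bam", ".sam"):
        yield from _ingest_bam(path, stats)
    else:
        yield from _ingest_bed(path, stats)


def _ingest_bed(path: Path, stats: IngestStats | None) -> Iterator[ReadAlignment]:
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6 or fields[5] not in ("+", "-"):
                raise ValueError(
                    f"{path}: line {line_no}: BED6 row lacks a +/- strand column"
                )
            if stats is not None:
                stats.primary += 1
            yield ReadAlignment(
                read_id=fields[3],
                contig=fields[0],
                start=int(fields[1]) + 1,
                end=int(fields[2]),
                strand=fields[5],
            )


def _ingest_bam(path: Path, stats: IngestStats | None) -> Iterator[ReadAlignment]:
    import pysam

    mode = "rb" if path.suffix.lower() == ".bam" else "r"
    with pysam.AlignmentFile(str(path), mode) as bam:
        header = bam.header.to_dict()
        so = header.get("HD", {}).get("SO", "unknown")
        if path.suffix.lower() == ".bam" and so != "coordinate":
            raise ValueError(
                f"{path} is not coordinate-sorted (SO={so}); run `samtools sort` first"
            )
        for rec in bam:
            if rec.is_unmapped:
                if stats is not None:
                    stats.unmapped += 1
                continue
            if rec.is_secondary:
                if stats is not None:
                    stats.secondary += 1
                continue
            if rec.is_supplementary:
                if stats is not None:
                    stats.supplementary += 1
                continue
            if stats is not None:
                stats.primary += 1
            yield ReadAlignment(
                read_id=rec.query_name,
                contig=rec.reference_name,
                start=rec.reference_start + 1,
                end=rec.reference_end,
                strand="-" if rec.is_reverse else "+",
            )


@dataclass(frozen=True)
class GeneOverlap:
    """Overlap of a read with one same-strand gene that passed the filter."""

    read_id: str
    gene: GeneModel
    overlap_len: int
    overlap_frac_gene: float
    strand_concordant: bool = True

    @property
    def gene_id(self) -> str:
        return self.gene.gene_id


@dataclass
class AssignmentStats:
    """Per-read outcome counters; categories partition the input exactly."""

    assigned: int = 0
    antisense_discarded: int = 0
    no_overlap: int = 0
    all_filtered: int = 0

    @property
    def total(self) -> int:
        return self.assigned + self.antisense_discarded + self.no_overlap + self.all_filtered


def assign_read(
    read: ReadAlignment,
    ann: AnnotationSet,
    min_len: int = 100,
    min_frac: float = 0.5,
    frac_denominator: str = "gene",
    stats: AssignmentStats | None = None,
) -> list[GeneOverlap]:
    """Overlap-filter one read against the annotation.

    Candidate genes are the same-strand genes intersecting the read span.  A
    read whose overlaps are all antisense is discarded entirely; a read with
    mixed-sense overlaps keeps only the same-strand candidates.  A candidate
    is kept iff overlap length > ``min_len`` OR the overlap fraction (of the
    gene length by default, of the read span with
    ``frac_denominator='read'``) > ``min_frac``.  Kept genes are returned in
    genomic order.
    """
    if read.is_secondary or read.is_supplementary:
        raise ValueError(f"read {read.read_id}: not a primary alignment")
    if frac_denominator not in ("gene", "read"):
        raise ValueError("frac_denominator must be 'gene' or 'read'")

    all_hits = ann.query(read.contig, read.start, read.end, strand=None)
    if not all_hits:
        if stats is not None:
            stats.no_overlap += 1
        return []
    same = [g for g in all_hits if g.strand == read.strand]
    if not same:
        if stats is not None:
            stats.antisense_discarded += 1
        return []

    kept: list[GeneOverlap] = []
    for g in same:
        olen = min(read.end, g.end) - max(read.start, g.start) + 1
        denom = g.length if frac_denominator == "gene" else read.span
        frac = olen / denom
        if olen > min_len or frac > min_frac:
            kept.append(
                GeneOverlap(
                    read_id=read.read_id,
                    gene=g,
                    overlap_len=olen,
                    overlap_frac_gene=olen / g.length,
                )
            )
    kept.sort(key=lambda ov: (ov.gene.start, ov.gene.end, ov.gene_id))
    if stats is not None:
        if kept:
            stats.assigned += 1
        else:
            stats.all_filtered += 1
    return kept


@dataclass(frozen=True)
class TranscriptType:
    """A unique ordered combination of genes covered by reads; the gene
    tuple is the identity key."""

    gene_ids: tuple[str, ...]
    read_count: int

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError("transcript type must contain at least one gene")


def build_transcript_types(
    assignments: Iterable[Sequence[GeneOverlap]],
    min_reads: int = 10,
    diagnostics: dict | None = None,
) -> list[TranscriptType]:
    """Aggregate per-read kept-gene lists into transcript types.

    Types supported by strictly more than ``min_reads`` reads are retained
    (``min_reads=0`` keeps everything).  Reads with an empty kept list are
    ignored.  When *diagnostics* is provided, the number of reads whose kept
    genes are non-contiguous in the candidate list (an interior gene failed
    the overlap filter) is recorded under ``"gapped_tuples"``.
    """
    counts: Counter[tuple[str, ...]] = Counter()
    for kept in assignments:
        if not kept:
            continue
        counts[tuple(ov.gene_id for ov in kept)] += 1
    types = [
        TranscriptType(gene_ids=gids, read_count=n)
        for gids, n in counts.items()
        if n > min_reads
    ]
    types.sort(key=lambda t: (-t.read_count, t.gene_ids))
    if diagnostics is not None:
        diagnostics.setdefault("n_types_unfiltered", len(counts))
    return types


@dataclass
class ContextProfile:
    """Transcriptional context of one gene: the distinct transcript types it
    appears in and the fraction of its reads carried by each."""

    gene_id: str
    n_contexts: int
    context_fractions: dict[tuple[str, ...], float]


def count_contexts(types: Sequence[TranscriptType]) -> list[ContextProfile]:
    """Per-gene context counts and read-fraction profiles over *types*."""
    by_gene: dict[str, dict[tuple[str, ...], int]] = {}
    for t in types:
        for gid in t.gene_ids:
            by_gene.setdefault(gid, {})[t.gene_ids] = t.read_count
    profiles = []
    for gid in sorted(by_gene):
        counts = by_gene[gid]
        total = sum(counts.values())
        profiles.append(
            ContextProfile(
                gene_id=gid,
                n_contexts=len(counts),
                context_fractions={k: v / total for k, v in counts.items()},
            )
        )
    return profiles


@dataclass
class OperonExtension:
    """An operon whose gene content is extended by read-through transcript
    types covering all known member genes plus at least one extra gene."""

    operon_id: str
    known_gene_ids: tuple[str, ...]
    added_gene_ids: tuple[str, ...]
    supporting_types: dict[tuple[str, ...], int]


def detect_operon_extensions(
    types: Sequence[TranscriptType], operons: Sequence[OperonRecord]
) -> list[OperonExtension]:
    """Operons extended by at least one retained transcript type.

    A type supports an extension iff its gene set is a proper superset of
    the operon's complete known gene list.  Each operon is reported at most
    once, with the union of added genes across supporting types.
    """
    out: list[OperonExtension] = []
    for op in operons:
        known = set(op.gene_ids)
        supporting = {
            t.gene_ids: t.read_count
            for t in types
            if known < set(t.gene_ids)
        }
        if not supporting:
            continue
        added = sorted(set().union(*[set(k) for k in supporting]) - known)
        out.append(
            OperonExtension(
                operon_id=op.operon_id,
                known_gene_ids=op.gene_ids,
                added_gene_ids=tuple(added),
                supporting_types=supporting,
            )
        )
    return out


@dataclass
class BoundaryHistogram:
    """Binned counts of read 5' starts and 3' ends per contig and strand.

    Bin ``i`` covers genomic positions ``[i*bin_size + 1, (i+1)*bin_size]``.
    """

    bin_size: int = 10
    starts: dict[tuple[str, str], Counter] = field(default_factory=dict)
    ends: dict[tuple[str, str], Counter] = field(default_factory=dict)
    n_reads: int = 0

    def _bin(self, coord: int) -> int:
        return (coord - 1) // self.bin_size

    def add(self, read: ReadAlignment) -> None:
        key = (read.contig, read.strand)
        self.starts.setdefault(key, Counter())[self._bin(read.five_prime())] += 1
        self.ends.setdefault(key, Counter())[self._bin(read.three_prime())] += 1
        self.n_reads += 1

    def total_counts(self) -> tuple[int, int]:
        s = sum(sum(c.values()) for c in self.starts.values())
        e = sum(sum(c.values()) for c in self.ends.values())
        return s, e

    def to_bedgraph(self, outdir: str | Path) -> list[Path]:
        """Write one bedGraph per (boundary end, strand): four files."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
        for name, table in (("start5", self.starts), ("end3", self.ends)):
            for strand, tag in (("+", "plus"), ("-", "minus")):
                p = outdir / f"boundaries_{name}_{tag}.bedgraph"
                with open(p, "w") as fh:
                    for (contig, s), counter in sorted(table.items()):
                        if s != strand:
                            continue
                        for b in sorted(counter):
                            fh.write(
                                f"{contig}\t{b * self.bin_size}\t"
                                f"{(b + 1) * self.bin_size}\t{counter[b]}\n"
                            )
                paths.append(p)
        return paths


def boundary_histogram(
    reads: Iterable[ReadAlignment], bin_size: int = 10
) -> BoundaryHistogram:
    """Histogram read boundaries (5' starts and 3' ends) at ``bin_size`` nt."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    hist = BoundaryHistogram(bin_size=bin_size)
    for r in reads:
        hist.add(r)
    return hist
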