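"""Multi-tool modification-site consensus, IVT-calibrated MeRIP peaks, and
single-nucleotide m6A assignment.

The workflow: per-tool site tables are harmonized to 1-based genomic
coordinates; significant sites inside same-strand gene bodies with coverage
depth > 10 in both the native and control samples are kept; positions called
by at least four tools form high-confidence consensus sites; MeRIP peaks
called in a modification-free IVT library are treated as antibody/procedure
false positives and subtracted from the native peak set; consensus sites
inside the calibrated peaks yield m6A candidates — directly when the
reference base is an adenosine, or at adenosines within two bases of a
called U/C/G (modification-induced current changes spread to neighbouring
nucleotides, so non-A calls near an A are redeemed as m6A evidence).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from btarch.annotation import AnnotationSet

logger = logging.getLogger(__name__)

SUPPORTED_TOOLS = ("differr", "drummer", "eligos2", "nanocompore", "tombo_com")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ModSite:
    """One per-tool modification call at a single genomic nucleotide."""

    contig: str
    position: int  # 1-based genomic
    strand: str
    tool: str
    significant: bool
    score: float = float("nan")
    ref_base: str | None = None  # RNA-space base on the annotated strand


@dataclass(frozen=True)
class ConsensusSite:
    """A position called by one or more tools; high confidence when
    ``n_tools`` reaches the consensus threshold."""

    contig: str
    position: int
    strand: str
    supporting_tools: frozenset[str]
    ref_base: str | None = None

    @property
    def n_tools(self) -> int:
        return len(self.supporting_tools)


@dataclass(frozen=True)
class PeakInterval:
    """A MeRIP peak (1-based inclusive); ``strand='.'`` matches both."""

    contig: str
    start: int
    end: int
    strand: str = "."
    source: str = "native"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"peak {self.contig}:{self.start}-{self.end}: start > end")


@dataclass
class CalibratedPeakSet:
    """Partition of the native peak set after IVT calibration."""

    retained: list[PeakInterval]
    removed: list[tuple[PeakInterval, PeakInterval]]  # (native, matching IVT)

    @property
    def n_input(self) -> int:
        return len(self.retained) + len(self.removed)


@dataclass(frozen=True)
class M6ACandidate:
    """A single-nucleotide m6A call on an adenosine.

    ``evidence='direct'`` when the consensus site itself sits on an A;
    ``'adjacent'`` when the A lies within the adjacency window of a called
    U/C/G site.
    """

    contig: str
    position: int
    strand: str
    gene_id: str
    gene_length: int
    gene_relative_position: int
    biotype: str
    evidence: str
    source_sites: tuple[ConsensusSite, ...] = ()


# ---------------------------------------------------------------------------
# per-tool parsers
# ---------------------------------------------------------------------------
#
# Each parser documents its column contract.  Coordinates are normalized to
# 1-based genomic positions; the significance flag reproduces the cutoff the
# tool ships in its output columns; rows below the cutoff are retained with
# significant=False.  Duplicate (contig, position, strand) rows within one
# file are malformed input and raise.


def _check_duplicates(sites: list[ModSite], path) -> list[ModSite]:
    seen = set()
    for s in sites:
        key = (s.contig, s.position, s.strand)
        if key in seen:
            raise ValueError(f"{path}: duplicate site {key} for tool {s.tool}")
        seen.add(key)
    return sites


def _parse_differr(path) -> list[ModSite]:
    """differr BED dialect: chrom, start (0-based), end, name, score, strand,
    odds_ratio, g_stat, fdr.  Significant: fdr < 0.05."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand", "odds_ratio", "g_stat", "fdr"],
    )
    return [
        ModSite(
            contig=r.chrom,
            position=int(r.start) + 1,
            strand=r.strand,
            tool="differr",
            significant=bool(r.fdr < 0.05),
            score=float(r.fdr),
        )
        for r in df.itertuples()
    ]


def _parse_drummer(path) -> list[ModSite]:
    """DRUMMER TSV dialect (header): chromosome, pos (1-based), ref_base,
    strand, odds_ratio, padj.  Significant: padj < 0.05."""
    df = pd.read_csv(path, sep="\t")
    _require(df, ["chromosome", "pos", "ref_base", "strand", "padj"], path)
    return [
        ModSite(
            contig=r.chromosome,
            position=int(r.pos),
            strand=r.strand,
            tool="drummer",
            significant=bool(r.padj < 0.05),
            score=float(r.padj),
            ref_base=str(r.ref_base).upper().replace("T", "U"),
        )
        for r in df.itertuples()
    ]


def _parse_eligos2(path) -> list[ModSite]:
    """ELIGOS2 TSV dialect (header): chrom, start_loc (0-based), end_loc,
    ref, strand, oddR, adjPval.  Significant: oddR >= 2.5 and adjPval < 0.05."""
    df = pd.read_csv(path, sep="\t")
    _require(df, ["chrom", "start_loc", "end_loc", "ref", "strand", "oddR", "adjPval"], path)
    return [
        ModSite(
            contig=r.chrom,
            position=int(r.start_loc) + 1,
            strand=r.strand,
            tool="eligos2",
            significant=bool(r.oddR >= 2.5 and r.adjPval < 0.05),
            score=float(r.adjPval),
            ref_base=str(r.ref).upper().replace("T", "U"),
        )
        for r in df.itertuples()
    ]


def _parse_nanocompore(path) -> list[ModSite]:
    """Nanocompore TSV dialect (header): pos (0-based), chr, strand,
    ref_kmer (5-mer centred on the site), GMM_logit_pvalue.
    Significant: GMM_logit_pvalue < 0.01."""
    df = pd.read_csv(path, sep="\t")
    _require(df, ["pos", "chr", "strand", "ref_kmer", "GMM_logit_pvalue"], path)
    out = []
    for r in df.itertuples():
        kmer = str(r.ref_kmer).upper().replace("T", "U")
        out.append(
            ModSite(
                contig=r.chr,
                position=int(r.pos) + 1,
                strand=r.strand,
                tool="nanocompore",
                significant=bool(r.GMM_logit_pvalue < 0.01),
                score=float(r.GMM_logit_pvalue),
                ref_base=kmer[2] if len(kmer) == 5 else None,
            )
        )
    return out


def _parse_tombo_com(path) -> list[ModSite]:
    """Tombo compare TSV dialect (header): chrom, pos (0-based), strand,
    frac_modified.  Significant: frac_modified > 0.5."""
    df = pd.read_csv(path, sep="\t")
    _require(df, ["chrom", "pos", "strand", "frac_modified"], path)
    return [
        ModSite(
            contig=r.chrom,
            position=int(r.pos) + 1,
            strand=r.strand,
            tool="tombo_com",
            significant=bool(r.frac_modified > 0.5),
            score=float(r.frac_modified),
        )
        for r in df.itertuples()
    ]


def _require(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")


_PARSERS = {
    "differr": _parse_differr,
    "drummer": _parse_drummer,
    "eligos2": _parse_eligos2,
    "nanocompore": _parse_nanocompore,
    "tombo_com": _parse_tombo_com,
}


def parse_caller_output(tool: str, path: str | Path) -> list[ModSite]:
    """Parse one modification caller's per-site output into ModSites.

    Supported tools: differr, drummer, eligos2, nanocompore, tombo_com.
    """
    if tool not in _PARSERS:
        raise ValueError(
            f"unknown tool {tool!r}; supported parsers: {', '.join(sorted(_PARSERS))}"
        )
    return _check_duplicates(_PARSERS[tool](path), path)


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------


class CoverageTrack:
    """Per-contig (optionally per-strand) depth from bedGraph intervals.

    bedGraph rows are 0-based half-open; positions not covered by any row
    have depth 0.  bedGraph itself is unstranded; a strand given at load
    time scopes the track to that strand, otherwise it answers for both.
    """

    def __init__(self) -> None:
        self._data: dict[tuple[str, str | None], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    @classmethod
    def from_bedgraph(cls, path: str | Path, strand: str | None = None) -> "CoverageTrack":
        rows: dict[str, list[tuple[int, int, float]]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                c, s, e, v = line.split("\t")[:4]
                rows.setdefault(c, []).append((int(s), int(e), float(v)))
        track = cls()
        for contig, ivs in rows.items():
            ivs.sort()
            starts = np.array([s for s, _, _ in ivs])
            ends = np.array([e for _, e, _ in ivs])
            depths = np.array([v for _, _, v in ivs])
            track._data[(contig, strand)] = (starts, ends, depths)
        return track

    def depth(self, contig: str, position: int, strand: str | None = None) -> float:
        """Depth at a 1-based position (0 when uncovered)."""
        for key in ((contig, strand), (contig, None)):
            if key in self._data:
                starts, ends, depths = self._data[key]
                i = int(np.searchsorted(starts, position - 1, side="right")) - 1
                if i >= 0 and position - 1 < ends[i]:
                    return float(depths[i])
                return 0.0
        return 0.0


# ---------------------------------------------------------------------------
# filtering, consensus, calibration
# ---------------------------------------------------------------------------


def filter_sites(
    sites: Iterable[ModSite],
    ann: AnnotationSet,
    cov_native: CoverageTrack,
    cov_control: CoverageTrack,
    min_depth: int = 10,
) -> list[ModSite]:
    """Keep sites that are significant, inside a same-strand gene body, and
    covered at depth strictly greater than ``min_depth`` in BOTH samples."""
    kept = []
    for s in sites:
        if not s.significant:
            continue
        if not ann.query(s.contig, s.position, s.position, strand=s.strand):
            continue
        if cov_native.depth(s.contig, s.position, s.strand) <= min_depth:
            continue
        if cov_control.depth(s.contig, s.position, s.strand) <= min_depth:
            continue
        kept.append(s)
    return kept


def consensus(
    sites_by_tool: Mapping[str, Sequence[ModSite]], min_tools: int = 4
) -> list[ConsensusSite]:
    """Group sites by (contig, position, strand) across tools and keep
    positions supported by at least ``min_tools`` tools."""
    if len(sites_by_tool) < min_tools:
        raise ValueError(
            f"only {len(sites_by_tool)} tools supplied but min_tools={min_tools}"
        )
    grouped: dict[tuple[str, int, str], dict[str, ModSite]] = {}
    for tool, sites in sites_by_tool.items():
        for s in sites:
            grouped.setdefault((s.contig, s.position, s.strand), {})[tool] = s
    out = []
    for (contig, pos, strand), by_tool in sorted(grouped.items()):
        if len(by_tool) < min_tools:
            continue
        ref = next((s.ref_base for s in by_tool.values() if s.ref_base), None)
        out.append(
            ConsensusSite(
                contig=contig,
                position=pos,
                strand=strand,
                supporting_tools=frozenset(by_tool),
                ref_base=ref,
            )
        )
    return out


def _strands_match(a: str, b: str) -> bool:
    return a == "." or b == "." or a == b


def calibrate_peaks(
    native: Sequence[PeakInterval],
    ivt: Sequence[PeakInterval],
    min_overlap: int = 1,
) -> CalibratedPeakSet:
    """Remove native peaks that overlap any IVT (modification-free control)
    peak by at least ``min_overlap`` nt on the same strand; IVT peaks are
    procedure false positives.  The retained/removed partition is exact."""
    retained, removed = [], []
    for p in native:
        hit = None
        for q in ivt:
            if p.contig != q.contig or not _strands_match(p.strand, q.strand):
                continue
            if min(p.end, q.end) - max(p.start, q.start) + 1 >= min_overlap:
                hit = q
                break
        if hit is None:
            retained.append(p)
        else:
            removed.append((p, hit))
    return CalibratedPeakSet(retained=retained, removed=removed)


def read_peaks_bed(path: str | Path, source: str = "native") -> list[PeakInterval]:
    """Read peaks from BED3/BED6 (missing or '.' strand means both)."""
    peaks = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            strand = fields[5] if len(fields) >= 6 else "."
            peaks.append(
                PeakInterval(
                    contig=fields[0],
                    start=int(fields[1]) + 1,
                    end=int(fields[2]),
                    strand=strand if strand in ("+", "-") else ".",
                    source=source,
                )
            )
    return peaks


# ---------------------------------------------------------------------------
# m6A assignment
# ---------------------------------------------------------------------------


def _genome_base(genome, contig: str, position: int) -> str:
    """Upper-case DNA base at a 1-based position from a pyfaidx Fasta or a
    plain dict of sequences; raises when the position is absent."""
    try:
        if isinstance(genome, Mapping):
            seq = genome[contig]
            base = seq[position - 1]
        else:  # pyfaidx.Fasta-like
            base = str(genome[contig][position - 1 : position])
    except (KeyError, IndexError) as exc:
        raise ValueError(f"no reference base at {contig}:{position}") from exc
    if not base:
        raise ValueError(f"no reference base at {contig}:{position}")
    return base.upper()


def _is_adenosine(genome, contig: str, position: int, strand: str) -> bool:
    base = _genome_base(genome, contig, position)
    return base == "A" if strand == "+" else base == "T"


def assign_m6a(
    cons: Sequence[ConsensusSite],
    peaks: CalibratedPeakSet | Sequence[PeakInterval],
    ann: AnnotationSet,
    genome,
    window: int = 2,
) -> list[M6ACandidate]:
    """Single-nucleotide m6A candidates from consensus sites within
    calibrated MeRIP peaks.

    A consensus site on an adenosine yields a direct candidate at its own
    position; a site on U/C/G yields adjacent candidates at every adenosine
    within ``window`` nt on the same strand.  Adenosines reachable from
    several sites are emitted once (direct evidence preferred) with all
    source sites kept.  Candidates outside annotated same-strand gene bodies
    are dropped; each candidate is annotated with the containing gene,
    biotype and 1-based gene-relative position.
    """
    retained = peaks.retained if isinstance(peaks, CalibratedPeakSet) else list(peaks)
    trees: dict[str, IntervalTree] = {}
    for p in retained:
        trees.setdefault(p.contig, IntervalTree()).addi(p.start, p.end + 1, p)

    def in_peak(site: ConsensusSite) -> bool:
        tree = trees.get(site.contig)
        if tree is None:
            return False
        return any(_strands_match(iv.data.strand, site.strand) for iv in tree.at(site.position))

    found: dict[tuple[str, int, str], tuple[str, list[ConsensusSite]]] = {}
    for site in cons:
        if not in_peak(site):
            continue
        if _is_adenosine(genome, site.contig, site.position, site.strand):
            positions = [(site.position, "direct")]
        else:
            positions = [
                (p, "adjacent")
                for p in range(site.position - window, site.position + window + 1)
                if p != site.position
                and p >= 1
                and _is_adenosine(genome, site.contig, p, site.strand)
            ]
        for pos, evidence in positions:
            key = (site.contig, pos, site.strand)
            if key in found:
                prev_evidence, sources = found[key]
                found[key] = ("direct" if "direct" in (prev_evidence, evidence) else "adjacent",
                              sources + [site])
            else:
                found[key] = (evidence, [site])

    candidates = []
    for (contig, pos, strand), (evidence, sources) in sorted(found.items()):
        genes = ann.query(contig, pos, pos, strand=strand)
        if not genes:
            continue
        gene = genes[0]  # leftmost containing gene on ties
        candidates.append(
            M6ACandidate(
                contig=contig,
                position=pos,
                strand=strand,
                gene_id=gene.gene_id,
                gene_length=gene.length,
                gene_relative_position=gene.relative_position(pos),
                biotype=gene.biotype,
                evidence=evidence,
                source_sites=tuple(sources),
            )
        )
    return candidates


def summarize_by_biotype(
    cands: Sequence[M6ACandidate],
) -> tuple[dict[str, int], pd.DataFrame]:
    """Candidate counts per biotype plus a per-gene table (gene name, gene
    length, comma-separated sorted gene-relative positions)."""
    counts = {bt: 0 for bt in ("rRNA", "mRNA", "ncRNA")}
    per_gene: dict[str, tuple[int, str, list[int]]] = {}
    for c in cands:
        counts[c.biotype] = counts.get(c.biotype, 0) + 1
        length, biotype, positions = per_gene.setdefault(
            c.gene_id, (c.gene_length, c.biotype, [])
        )
        positions.append(c.gene_relative_position)
    rows = [
        (gid, length, biotype, ", ".join(str(p) for p in sorted(set(pos))), len(pos))
        for gid, (length, biotype, pos) in sorted(per_gene.items())
    ]
    table = pd.DataFrame(
        rows, columns=["gene_name", "gene_length", "biotype", "m6a_positions", "n_sites"]
    )
    return counts, table


def export_motif_windows(
    cands: Sequence[M6ACandidate],
    genome,
    flank: int = 5,
    fasta_path: str | Path | None = None,
    bed_path: str | Path | None = None,
) -> list[tuple[str, str]]:
    """Sequence windows of +-``flank`` nt around each candidate for motif
    discovery (Homer-style '-size -5,5' input).

    Windows are clipped at contig ends; minus-strand windows are
    reverse-complemented; sequences are written in DNA alphabet (U as T).
    Returns (name, sequence) pairs and optionally writes FASTA/BED files.
    """
    records = []
    for c in cands:
        if isinstance(genome, Mapping):
            contig_len = len(genome[c.contig])
        else:
            contig_len = len(genome[c.contig])
        lo = max(1, c.position - flank)
        hi = min(contig_len, c.position + flank)
        seq = "".join(_genome_base(genome, c.contig, p) for p in range(lo, hi + 1))
        if c.strand == "-":
            seq = _revcomp(seq)
        records.append((f"{c.contig}:{c.position}:{c.strand}", seq))
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for name, seq in records:
                fh.write(f">{name}\n{seq}\n")
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for c in cands:
                fh.write(
                    f"{c.contig}\t{c.position - 1}\t{c.position}\t"
                    f"{c.gene_id}\t0\t{c.strand}\n"
                )
    return records


# ---------------------------------------------------------------------------
# reference worked example
# ---------------------------------------------------------------------------


def load_reference_mrna_m6a() -> pd.DataFrame:
    """Published high-confidence m6A site list for E. coli K-12 mRNAs
    (21 genes; columns gene_name, gene_length, m6a_positions)."""
    with resources.files("btarch.data").joinpath("ecoli_mrna_m6a_sites.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return df


def candidates_from_gene_table(df: pd.DataFrame, biotype: str = "mRNA") -> list[M6ACandidate]:
    """Rehydrate M6ACandidates from a per-gene position table (the layout
    written by :func:`summarize_by_biotype`), using the gene name as a
    surrogate contig and the gene-relative position as the coordinate."""
    cands = []
    for r in df.itertuples():
        positions = [int(p) for p in str(r.m6a_positions).split(",") if str(p).strip()]
        for pos in positions:
            cands.append(
                M6ACandidate(
                    contig=r.gene_name,
                    position=pos,
                    strand="+",
                    gene_id=r.gene_name,
                    gene_length=int(r.gene_length),
                    gene_relative_position=pos,
                    biotype=biotype,
                    evidence="direct",
                )
            )
    return cands
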