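"""Genome annotation and operon tables with strand-aware interval queries.

Coordinates are 1-based inclusive throughout the library (the GFF convention,
and the convention in which gene-relative modification positions are reported
downstream).  BED input/output is converted at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from gffutils.feature import feature_from_line
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

BIOTYPES = ("mRNA", "rRNA", "ncRNA", "tRNA", "other")

#: Default mapping from GFF/GTF feature type (or *_biotype attribute value)
#: to the biotype vocabulary used here.  Feature types absent from the map
#: are not treated as gene records at all.
DEFAULT_BIOTYPE_MAP: dict[str, str] = {
    "gene": "mRNA",
    "CDS": "mRNA",
    "mRNA": "mRNA",
    "protein_coding": "mRNA",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "ncRNA": "ncRNA",
    "sRNA": "ncRNA",
    "tmRNA": "ncRNA",
    "antisense_RNA": "ncRNA",
    "RNase_P_RNA": "ncRNA",
    "SRP_RNA": "ncRNA",
}

#: BED12 itemRgb colour code per biotype (browser-style colouring); used so
#: that a BED12 round trip preserves biotype.
_BIOTYPE_RGB = {
    "mRNA": "0,0,178",
    "rRNA": "178,0,0",
    "tRNA": "0,128,0",
    "ncRNA": "128,0,128",
    "other": "0,0,0",
}
_RGB_BIOTYPE = {v: k for k, v in _BIOTYPE_RGB.items()}


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class GeneModel:
    """A gene as a stranded genomic interval (1-based inclusive)."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    biotype: str = "mRNA"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise AnnotationError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def relative_position(self, genomic_pos: int) -> int:
        """1-based position within the gene, counted from the gene's 5' end."""
        if self.strand == "+":
            return genomic_pos - self.start + 1
        return self.end - genomic_pos + 1


class AnnotationSet:
    """A collection of :class:`GeneModel` with a per-contig, per-strand
    interval index for overlap queries."""

    def __init__(self, genes: Iterable[GeneModel] = ()) -> None:
        self._genes: dict[str, GeneModel] = {}
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for g in genes:
            self.add(g)

    def add(self, gene: GeneModel) -> None:
        if gene.gene_id in self._genes:
            raise AnnotationError(f"duplicate gene_id {gene.gene_id!r}")
        self._genes[gene.gene_id] = gene
        tree = self._trees.setdefault((gene.contig, gene.strand), IntervalTree())
        # interval tree uses half-open coordinates
        tree.addi(gene.start, gene.end + 1, gene)

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self):
        return iter(self._genes.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def get(self, gene_id: str) -> GeneModel | None:
        return self._genes.get(gene_id)

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._genes[gene_id]

    @property
    def contigs(self) -> list[str]:
        return sorted({g.contig for g in self._genes.values()})

    def query(
        self, contig: str, start: int, end: int, strand: str | None = None
    ) -> list[GeneModel]:
        """Genes whose [start, end] intersects the query interval.

        With ``strand`` given, only same-strand genes are returned; with
        ``strand=None`` both strands are searched.  Unknown contigs yield an
        empty list.  Results are sorted by (start, end, gene_id).
        """
        if start > end:
            raise ValueError(f"query start {start} > end {end}")
        strands = ("+", "-") if strand is None else (strand,)
        hits: list[GeneModel] = []
        for s in strands:
            tree = self._trees.get((contig, s))
            if tree is not None:
                hits.extend(iv.data for iv in tree.overlap(start, end + 1))
        hits.sort(key=lambda g: (g.start, g.end, g.gene_id))
        return hits


def query_overlapping_genes(
    ann: AnnotationSet, contig: str, start: int, end: int, strand: str | None = None
) -> list[GeneModel]:
    """Functional wrapper around :meth:`AnnotationSet.query`."""
    return ann.query(contig, start, end, strand)


@dataclass
class OperonRecord:
    """An operon: an ordered run of co-transcribed genes on one strand."""

    operon_id: str
    gene_ids: tuple[str, ...]
    contig: str
    strand: str
    span: tuple[int, int] | None = None

    def resolve(self, ann: AnnotationSet) -> "OperonRecord | None":
        """Resolve member genes against *ann*.

        Unresolvable gene_ids are dropped with a warning; the operon itself is
        dropped (returns None) when no member resolves.  Resolved genes are
        checked to share contig and strand, the span is set to the coordinate
        envelope, and plus-strand gene lists are sorted by ascending start
        (minus-strand order is kept as stored).
        """
        genes = []
        for gid in self.gene_ids:
            g = ann.get(gid)
            if g is None:
                logger.warning(
                    "operon %s: gene %s not in annotation; dropped from operon",
                    self.operon_id,
                    gid,
                )
            else:
                genes.append(g)
        if not genes:
            logger.warning("operon %s: no resolvable genes; operon dropped", self.operon_id)
            return None
        contigs = {g.contig for g in genes}
        strands = {g.strand for g in genes}
        if len(contigs) > 1 or len(strands) > 1:
            raise AnnotationError(
                f"operon {self.operon_id}: member genes span multiple contigs/strands"
            )
        strand = strands.pop()
        if strand == "+":
            genes.sort(key=lambda g: g.start)
        return OperonRecord(
            operon_id=self.operon_id,
            gene_ids=tuple(g.gene_id for g in genes),
            contig=contigs.pop(),
            strand=strand,
            span=(min(g.start for g in genes), max(g.end for g in genes)),
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _biotype_for(featuretype: str, attrs, biotype_map: Mapping[str, str]) -> str:
    for key in ("gene_biotype", "biotype", "gene_type"):
        if key in attrs:
            val = attrs[key][0]
            return biotype_map.get(val, "ncRNA")
    return biotype_map.get(featuretype, "ncRNA")


def _gene_id_for(attrs, line_no: int) -> str:
    for key in ("ID", "gene_id", "locus_tag", "Name"):
        if key in attrs:
            return attrs[key][0]
    raise AnnotationError(f"line {line_no}: feature has no ID/gene_id/locus_tag attribute")


def read_annotation(
    path: str | Path,
    biotype_map: Mapping[str, str] | None = None,
    fmt: str | None = None,
) -> AnnotationSet:
    """Read a GFF3/GTF or BED6/BED12 file into an :class:`AnnotationSet`.

    GFF coordinates (1-based inclusive) are preserved; BED (0-based
    half-open) is converted.  ``biotype_map`` maps feature types (and
    ``*_biotype`` attribute values) to biotypes and simultaneously selects
    which feature types count as gene records; when the file contains
    ``gene``-type features only those are used, so CDS children of annotated
    genes are not double counted.

    Raises :class:`AnnotationError` naming the offending line for malformed
    rows and for duplicate gene_ids.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = "bed" if suffix == ".bed" else "gff"
    if biotype_map is None:
        biotype_map = DEFAULT_BIOTYPE_MAP

    if fmt == "bed":
        genes = _read_bed_genes(path, biotype_map)
    else:
        genes = _read_gff_genes(path, biotype_map)

    ann = AnnotationSet()
    for g in genes:
        ann.add(g)
    if len(ann) == 0:
        logger.warning("annotation %s contains no gene features", path)
    return ann


def _read_gff_genes(path: Path, biotype_map: Mapping[str, str]) -> list[GeneModel]:
    records: list[tuple[str, GeneModel]] = []  # (featuretype, gene)
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) < 8:
                raise AnnotationError(
                    f"{path}: malformed line {line_no}: expected >=8 tab-separated fields"
                )
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises assorted types
                raise AnnotationError(f"{path}: malformed line {line_no}: {exc}") from exc
            if feat.featuretype not in biotype_map:
                continue
            if feat.start is None or feat.end is None or feat.start < 1:
                raise AnnotationError(f"{path}: line {line_no}: non-positive coordinates")
            gene = GeneModel(
                gene_id=_gene_id_for(feat.attributes, line_no),
                contig=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in ("+", "-") else "+",
                biotype=_biotype_for(feat.featuretype, feat.attributes, biotype_map),
            )
            records.append((feat.featuretype, gene))
    if any(ft == "gene" for ft, _ in records):
        records = [(ft, g) for ft, g in records if ft == "gene"]
    return [g for _, g in records]


def _read_bed_genes(path: Path, biotype_map: Mapping[str, str]) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise AnnotationError(
                    f"{path}: malformed line {line_no}: expected >=6 BED columns"
                )
            try:
                start0, end0 = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}: malformed line {line_no}: non-integer coordinates"
                ) from exc
            biotype = biotype_map.get("gene", "mRNA")
            if len(fields) >= 9 and fields[8] in _RGB_BIOTYPE:
                biotype = _RGB_BIOTYPE[fields[8]]
            genes.append(
                GeneModel(
                    gene_id=fields[3],
                    contig=fields[0],
                    start=start0 + 1,
                    end=end0,
                    strand=fields[5],
                    biotype=biotype,
                )
            )
    return genes


def write_bed12(ann: AnnotationSet, path: str | Path) -> None:
    """Write genes as single-block BED12, encoding biotype in the itemRgb
    column so a round trip through :func:`read_annotation` is lossless."""
    with open(path, "w") as fh:
        for g in sorted(ann, key=lambda g: (g.contig, g.start, g.gene_id)):
            start0 = g.start - 1
            fh.write(
                "\t".join(
                    [
                        g.contig,
                        str(start0),
                        str(g.end),
                        g.gene_id,
                        "0",
                        g.strand,
                        str(start0),
                        str(g.end),
                        _BIOTYPE_RGB.get(g.biotype, "0,0,0"),
                        "1",
                        str(g.length),
                        "0",
                    ]
                )
                + "\n"
            )


def read_operon_table(
    path: str | Path, ann: AnnotationSet | None = None
) -> list[OperonRecord]:
    """Read a TSV operon table (columns: operon_id, gene_ids comma-separated,
    contig, strand; header optional).

    With *ann* given, member genes are resolved immediately: unresolvable
    gene_ids are dropped with a warning and operons with zero resolvable
    genes are dropped entirely.
    """
    operons: list[OperonRecord] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "operon_id":  # header
                continue
            if len(fields) < 4:
                raise AnnotationError(
                    f"{path}: malformed line {line_no}: expected 4 columns "
                    "(operon_id, gene_ids, contig, strand)"
                )
            rec = OperonRecord(
                operon_id=fields[0],
                gene_ids=tuple(g for g in fields[1].split(",") if g),
                contig=fields[2],
                strand=fields[3],
            )
            operons.append(rec)
    if ann is not None:
        resolved = [rec.resolve(ann) for rec in operons]
        operons = [r for r in resolved if r is not None]
    return operons


def write_operon_table(operons: Sequence[OperonRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("operon_id\tgene_ids\tcontig\tstrand\n")
        for op in operons:
            fh.write(f"{op.operon_id}\t{','.join(op.gene_ids)}\t{op.contig}\t{op.strand}\n")
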