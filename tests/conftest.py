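"""Shared fixtures and brute-force oracles.

The oracles deliberately avoid the library's interval index and filtering
code paths: they scan every gene linearly and apply the filtering rules
literally, so that index- and stream-based implementations can be checked
against them.
"""

from __future__ import annotations

import numpy as np
import pytest

from btarch.annotation import AnnotationSet, GeneModel
from btarch.architecture import ReadAlignment


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------


def brute_force_query(genes, contig, start, end, strand=None):
    """Linear-scan overlap query (the oracle for the interval index)."""
    hits = [
        g
        for g in genes
        if g.contig == contig
        and g.start <= end
        and g.end >= start
        and (strand is None or g.strand == strand)
    ]
    return sorted(hits, key=lambda g: (g.start, g.end, g.gene_id))


def brute_force_assign(read, genes, min_len=100, min_frac=0.5):
    """Literal application of the read-to-gene rules: discard the read when
    every overlapped gene is antisense; keep same-strand genes whose overlap
    is > min_len nt or > min_frac of the gene length."""
    overlapped = [
        g
        for g in genes
        if g.contig == read.contig and g.start <= read.end and g.end >= read.start
    ]
    if not overlapped:
        return []
    same = [g for g in overlapped if g.strand == read.strand]
    if not same:
        return []  # antisense-only: read discarded
    kept = []
    for g in same:
        olen = min(read.end, g.end) - max(read.start, g.start) + 1
        if olen > min_len or olen / g.length > min_frac:
            kept.append(g)
    return sorted(kept, key=lambda g: (g.start, g.end, g.gene_id))


def random_annotation(rng, n_genes=30, contig="c", span=10_000):
    """Random, possibly overlapping genes on both strands."""
    genes = []
    for i in range(n_genes):
        start = int(rng.integers(1, span))
        length = int(rng.integers(30, 800))
        genes.append(
            GeneModel(
                gene_id=f"g{i}",
                contig=contig,
                start=start,
                end=start + length - 1,
                strand="+" if rng.random() < 0.5 else "-",
            )
        )
    return genes


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture
def simple_ann():
    """Three genes used across the unit tests:

    A [1000, 2000] +   (1001 nt)
    B [2100, 3000] +   (901 nt)
    C [1400, 1900] -   (501 nt)
    """
    return AnnotationSet(
        [
            GeneModel("geneA", "chr1", 1000, 2000, "+"),
            GeneModel("geneB", "chr1", 2100, 3000, "+"),
            GeneModel("geneC", "chr1", 1400, 1900, "-"),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


def make_read(start, end, strand="+", contig="chr1", read_id="r"):
    return ReadAlignment(read_id=read_id, contig=contig, start=start, end=end, strand=strand)
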