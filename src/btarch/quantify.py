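"""Per-gene read counting, TPM, and cross-sample rank correlation.

TPM for gene *i* with mapped-read count q_i and gene length l_i:

    TPM_i = (q_i / l_i) / sum_j (q_j / l_j) * 1e6

so that TPM sums to one million over the included genes.  Counting is
restricted to protein-coding genes by default (rRNA reads dominate bacterial
libraries and are excluded before TPM), and undetected genes (q = 0) are
dropped from the table.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from btarch.architecture import GeneOverlap

COUNT_MODES = ("all", "primary-gene", "fractional")


def count_reads(
    assignments: Iterable[Sequence[GeneOverlap]],
    biotype_filter: set[str] | frozenset[str] | None = frozenset({"mRNA"}),
    mode: str = "all",
) -> pd.DataFrame:
    """Build an expression table (columns gene_id, q, l, biotype) from
    per-read kept-gene lists.

    Counting modes: ``all`` increments every kept gene of a read by 1 (a read
    spanning k genes contributes k counts); ``primary-gene`` increments only
    the gene with the largest overlap; ``fractional`` splits the read 1/k
    per gene.  Genes outside ``biotype_filter`` (None disables the filter)
    and genes with zero counts are absent from the result.
    """
    if mode not in COUNT_MODES:
        raise ValueError(f"unknown count mode {mode!r}; choose from {COUNT_MODES}")
    q: dict[str, float] = {}
    meta: dict[str, tuple[int, str]] = {}
    for kept in assignments:
        if not kept:
            continue
        if mode == "primary-gene":
            best = max(kept, key=lambda ov: (ov.overlap_len, -ov.gene.start))
            targets = [(best, 1.0)]
        elif mode == "fractional":
            targets = [(ov, 1.0 / len(kept)) for ov in kept]
        else:
            targets = [(ov, 1.0) for ov in kept]
        for ov, w in targets:
            q[ov.gene_id] = q.get(ov.gene_id, 0.0) + w
            meta[ov.gene_id] = (ov.gene.length, ov.gene.biotype)
    rows = []
    for gid in sorted(q):
        length, biotype = meta[gid]
        if biotype_filter is not None and biotype not in biotype_filter:
            continue
        if q[gid] <= 0:
            continue
        rows.append((gid, q[gid], length, biotype))
    df = pd.DataFrame(rows, columns=["gene_id", "q", "l", "biotype"])
    if mode != "fractional":
        df["q"] = df["q"].astype(int)
    return df


def compute_tpm(table: pd.DataFrame) -> pd.DataFrame:
    """Fill the ``tpm`` column of an expression table in place of a copy.

    Requires all gene lengths positive and at least one positive count;
    the returned TPM values sum to 1e6.
    """
    if len(table) == 0 or not (table["q"] > 0).any():
        raise ValueError("cannot compute TPM: no gene has a positive count")
    if not (table["l"] > 0).all():
        raise ValueError("cannot compute TPM: non-positive gene length present")
    out = table.copy()
    rate = out["q"].to_numpy(dtype=float) / out["l"].to_numpy(dtype=float)
    out["tpm"] = rate / rate.sum() * 1e6
    return out


def rank_correlation(a: pd.DataFrame, b: pd.DataFrame, column: str = "tpm") -> float:
    """Spearman's rank correlation of *column* over the gene_id intersection
    of two expression tables (ties get average ranks; genes absent from
    either table are excluded).  Requires an intersection of >= 3 genes."""
    merged = a[["gene_id", column]].merge(
        b[["gene_id", column]], on="gene_id", suffixes=("_a", "_b")
    )
    if len(merged) < 3:
        raise ValueError(
            f"gene intersection too small for rank correlation (n={len(merged)} < 3)"
        )
    rho, _ = sps.spearmanr(merged[f"{column}_a"], merged[f"{column}_b"])
    return float(rho)


def correlation_matrix(
    tables: dict[str, pd.DataFrame], column: str = "tpm"
) -> pd.DataFrame:
    """Pairwise Spearman correlation matrix over named expression tables."""
    names = list(tables)
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, na in enumerate(names):
        for nb in names[i + 1 :]:
            rho = rank_correlation(tables[na], tables[nb], column=column)
            mat.loc[na, nb] = mat.loc[nb, na] = rho
    return mat
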