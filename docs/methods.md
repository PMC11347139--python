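# Methods

## Scope and data model

`btarch` operates on coordinate-level inputs: a gene annotation (GFF3/GTF or
BED), an operon table, long-read alignments (BED6 or coordinate-sorted
BAM/SAM), per-tool modification-site tables, MeRIP peak BEDs, per-base
coverage bedGraphs, and a genome FASTA. Basecalling, alignment, the
modification callers themselves, and peak calling are upstream of the
package and out of scope.

Internal coordinates are 1-based inclusive everywhere (the GFF convention,
and the convention in which gene-relative m6A positions are reported); BED
and bedGraph inputs (0-based half-open) are converted at the boundary.
Gene-relative positions count from the gene's 5′ end on its own strand.

## Read-to-gene assignment

Candidate genes for a read are the same-strand genes intersecting its
aligned span. A read whose overlapped genes are all antisense is discarded
outright; a read with mixed-sense overlaps keeps only same-strand
candidates. This treats antisense transcription as a separate signal rather
than silently assigning it, and the per-category counters (assigned /
antisense-discarded / no-overlap / all-filtered) partition the input reads
exactly — an identity asserted on every run.

A candidate is kept iff overlap length > 100 nt **or** overlap fraction
> 0.5. The fraction's denominator is the **gene length** by default: this is
the reading under which a long read can capture a short gene (e.g. a ~150-nt
sRNA leader) via the fraction criterion even when the 100-nt length
criterion just fails, and conversely lets the length criterion rescue
partial overlaps of long genes. A read-span denominator is available as
`frac_denominator="read"` for sensitivity analysis; it is strictly more
conservative for reads longer than their genes.

Both thresholds are strict inequalities, as is the > 10-read transcript-type
threshold and the > 10 coverage-depth filter below; the tie behaviour is
pinned by unit tests (a depth of exactly 10 fails, a count of exactly 10
reads fails).

## Transcript types, contexts, extensions

The ordered tuple of kept genes (genomic order; reads are single-strand by
construction) is the transcript-type key. If an interior gene fails the
overlap filter while its flanks pass — rare, and impossible in the synthetic
data — the tuple records only kept genes; the unfiltered type count is kept
in a diagnostics channel so such events are visible.

A gene's transcriptional context is the number of retained types containing
it; per-type fractions divide the type's read count by the gene's total
reads over retained types and therefore sum to 1 per gene. Context counting
uses the **thresholded** type set (the same set reported elsewhere), so the
context table is consistent with the reported type counts; counting over
unthresholded types is available by passing `min_reads=0`.

An operon is *extended* when some retained type's gene set is a **proper
superset of the operon's complete known gene list**. This is the strictest
reading of "redefining the gene contents": types covering only part of the
operon plus a neighbour (e.g. (B, C, D) against operon (A, B, C)) do not
qualify, because they are equally consistent with an internal promoter.
Each operon is reported once with the union of added genes and all
supporting types. Read support inherits the type threshold.

Reads spanning the origin of a circular chromosome are not split; alignments
are taken as reported. This is a documented limitation — origin-spanning
operons would need pre-split alignments.

## Quantification

A read kept on k genes increments each of the k genes by 1 (`count-mode
all`, the default): a full-length operon read is evidence for every gene it
covers. `primary-gene` (largest overlap only) and `fractional` (1/k) modes
are provided for sensitivity analysis. Counting is restricted to
protein-coding genes by default — rRNA dominates bacterial libraries and is
excluded before TPM — and genes with zero counts are absent from the table.
TPM follows the rate-normalized form (q_i/l_i rescaled to sum to 10⁶), so it
is invariant to uniform scaling of counts; Spearman correlation is computed
on the gene-id intersection with average ranks for ties (p-values are not
reported). The TPM implementation is the package's own two-line closed form;
Spearman comes from `scipy.stats.spearmanr`, with a hand-computed oracle in
the tests.

## Modification-site integration

Each caller's per-site output is parsed by a tool-specific reader that
documents its column contract (coordinate basis and the significance column
with the tool's shipped cutoff); rows below the cutoff are retained with
`significant=False` so filtering decisions stay visible. Duplicate
(contig, position, strand) rows within one file are treated as malformed
input — replicate comparisons are assumed merged upstream.

Filtering keeps sites that are significant, inside a same-strand annotated
gene body, and covered at depth strictly greater than 10 in **both** the
native and control samples — the depth rule is applied per sample, not to
the pair's minimum by accident of input order. Consensus groups surviving
sites by exact (contig, position, strand); positions supported by ≥ 4 of the
supplied tools are high-confidence. With five tools of independent per-site
sensitivity p, the expected recovery at ≥ 4 tools is
C(5,4)·p⁴(1−p) + p⁵ = 0.91854 at p = 0.9 — the law the acceptance suite
checks by Monte Carlo.

Peak calibration removes a native MeRIP peak when it overlaps any IVT peak
by ≥ 1 nt on the same strand (a "." strand matches both, since peak callers
on unstranded short-read data often emit no strand). A single nucleotide of
overlap suffices by default because shared peaks indicate a shared
antibody/procedure artifact regardless of extent; the threshold is exposed
as `min_peak_overlap`. The retained/removed partition is exact and asserted.

m6A assignment intersects consensus sites with retained peaks, then: a site
on an adenosine (strand-aware: genomic A on +, genomic T on −) yields a
`direct` candidate; a site on U/C/G yields `adjacent` candidates at every
adenosine within ±2 nt on the same strand, reflecting the local spread of
modification-induced current changes. The filter-then-intersect order is
used; with exact-position grouping the two orders commute. An adenosine
reachable from several sites is emitted once, `direct` evidence preferred,
with all source sites retained. Candidates falling outside gene bodies
(possible for adjacent calls near gene edges) are dropped; ties between
overlapping same-strand genes resolve to the leftmost gene. Motif windows of
±5 nt (clipped at contig ends, minus-strand windows reverse-complemented,
DNA alphabet) are exported for external motif discovery.

The package ships a reference table of published high-confidence m6A sites
on *E. coli* K-12 mRNAs (21 genes, 75 gene-relative positions) as the worked
example for the per-gene summary layout; the tests and the acceptance script
roll it up through `summarize_by_biotype` and require exactly 75 sites on 21
genes.

## Synthetic data: what it emulates, and what it does not

The generator lays out non-overlapping operons on both strands (defaults:
20 operons of 1–4 genes, 200–1500 nt genes, 40–150 nt intra-operon gaps,
250–600 nt between operons, one rRNA operon and two standalone ncRNA genes —
sizes chosen so a desk-scale run exercises every code path with realistic
bacterial gene dimensions). Planted transcript types per operon are every
transcription-order prefix (full-length plus step-wise 3′-truncated forms,
the dominant pattern in bacterial DRS), a 5′-processed variant lacking the
first gene (p = 0.15), and a read-through variant extending into the
adjacent same-strand operon's first gene (p = 0.1); each type receives
15–60 reads, and each planned read flips to an antisense noise read with
p = 0.02. Modification calls are drawn per tool at sensitivity 0.9 with
uniform jitter on {−2..2} (the bound the adjacency rule is built for);
false positives are scattered over gene bodies at 5×10⁻⁵ per base per tool.
Coverage is constant (depth 30) over gene bodies. Native peaks of ±75 nt
cover every planted site; false-positive peaks (20% of signal peaks, placed
clear of planted sites) are duplicated into the IVT set.

Deliberately **not** emulated: basecalling errors and quality scores,
sub-gene-boundary end noise (read ends fall exactly on gene boundaries, so
noise-free recovery is exact by construction), coverage heterogeneity,
overlapping genes, origin-spanning reads, and tool-specific score
distributions (synthetic calls are all emitted as significant). Passing the
noise-free recovery tests therefore demonstrates the correctness of the
bookkeeping — filters, grouping, calibration, assignment — not robustness to
alignment artifacts in real libraries; the jitter, false-positive and
antisense knobs probe degradation but are not calibrated to any instrument.

## Numerical and design choices

- Same seed ⇒ byte-identical generator outputs and pipeline re-runs
  (asserted); all randomness flows through `numpy.random.default_rng`.
- Context histogram bins are {1, 2, 3, ≥4}, configurable; percentages sum
  to 100 by construction.
- The interval index (per-contig, per-strand `intervaltree`) is verified
  against a brute-force linear scan on 1,000 randomized instances, as is the
  full assignment filter.
- Degenerate inputs: empty annotation → warning, empty set; operon with no
  resolvable genes → dropped with warning; all-zero count table and
  < 3-gene correlation intersections → errors; unknown contig queries →
  empty results.
- BED12 output encodes biotype in the itemRgb column (browser-style
  colouring) so annotation round trips are lossless.
- Consensus `ref_base` is taken from the first tool that reports one; the
  genome FASTA is the authority at assignment time.

## Known limitations

Exact-position consensus means positional jitter between tools (which the
generator can produce and real tools exhibit) dissolves consensus; a
window-based grouping would trade precision for recall and is not
implemented. Peak calibration is binary per peak; partial-overlap trimming
is not attempted. The operon-extension criterion cannot see extensions
supported only by types that skip an interior operon gene.
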