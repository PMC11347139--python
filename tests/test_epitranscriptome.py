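"""Tool-output parsing, filtering, consensus, peak calibration, m6A calls."""

from pathlib import Path

import pytest

from btarch.annotation import AnnotationSet, GeneModel
from btarch.epitranscriptome import (
    CalibratedPeakSet,
    ConsensusSite,
    CoverageTrack,
    ModSite,
    PeakInterval,
    assign_m6a,
    calibrate_peaks,
    candidates_from_gene_table,
    consensus,
    export_motif_windows,
    filter_sites,
    load_reference_mrna_m6a,
    parse_caller_output,
    summarize_by_biotype,
)

DATA = Path(__file__).parent / "data" / "tool_examples"


class TestParsers:
    @pytest.mark.parametrize(
        "tool", ["differr", "drummer", "eligos2", "nanocompore", "tombo_com"]
    )
    def test_dialect_example_normalizes_to_genomic_coordinates(self, tool):
        sites = parse_caller_output(tool, DATA / f"{tool}_example.tsv")
        assert [s.position for s in sites] == [1000, 2000]
        assert [s.strand for s in sites] == ["+", "-"]
        assert [s.significant for s in sites] == [True, False]
        assert all(s.tool == tool for s in sites)

    def test_ref_base_carried_in_rna_space(self):
        sites = parse_caller_output("drummer", DATA / "drummer_example.tsv")
        assert sites[0].ref_base == "A"
        assert sites[1].ref_base == "U"  # T reported in DNA space

    def test_unknown_tool_lists_supported_parsers(self, tmp_path):
        with pytest.raises(ValueError, match="differr"):
            parse_caller_output("mystery", tmp_path / "x.tsv")

    def test_missing_column_is_parse_error(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("chromosome\tpos\tstrand\nchrSyn\t10\t+\n")
        with pytest.raises(ValueError, match="padj"):
            parse_caller_output("drummer", p)

    def test_duplicate_position_rejected(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text(
            "chromosome\tpos\tref_base\tstrand\todds_ratio\tpadj\n"
            "c\t10\tA\t+\t2.0\t0.01\nc\t10\tA\t+\t3.0\t0.02\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            parse_caller_output("drummer", p)


class TestCoverageAndFilter:
    def _cov(self, tmp_path, depth, name="cov.bedgraph"):
        p = tmp_path / name
        p.write_text(f"chr1\t0\t5000\t{depth}\n")
        return CoverageTrack.from_bedgraph(p)

    def _site(self, pos=1500, strand="+", significant=True):
        return ModSite(
            contig="chr1", position=pos, strand=strand, tool="drummer",
            significant=significant,
        )

    def test_kept_when_significant_genic_and_covered(self, tmp_path, simple_ann):
        kept = filter_sites(
            [self._site()], simple_ann, self._cov(tmp_path, 12), self._cov(tmp_path, 15, "c2.bedgraph")
        )
        assert len(kept) == 1

    def test_dropped_when_either_track_at_or_below_threshold(self, tmp_path, simple_ann):
        kept = filter_sites(
            [self._site()], simple_ann, self._cov(tmp_path, 12), self._cov(tmp_path, 8, "c2.bedgraph")
        )
        assert kept == []
        # depth exactly 10 fails the strictly-greater rule
        kept = filter_sites(
            [self._site()], simple_ann, self._cov(tmp_path, 10), self._cov(tmp_path, 12, "c2.bedgraph")
        )
        assert kept == []

    def test_intergenic_and_antisense_and_nonsignificant_dropped(self, tmp_path, simple_ann):
        cov = self._cov(tmp_path, 50)
        sites = [
            self._site(pos=4500),                      # intergenic
            self._site(pos=2500, strand="-"),          # antisense to geneB
            self._site(significant=False),             # below tool cutoff
        ]
        assert filter_sites(sites, simple_ann, cov, cov) == []

    def test_uncovered_position_has_depth_zero(self, tmp_path):
        cov = self._cov(tmp_path, 30)
        assert cov.depth("chr1", 6000) == 0.0
        assert cov.depth("chrX", 100) == 0.0


class TestConsensus:
    def _by_tool(self, spec):
        """spec: {tool: [positions]}"""
        return {
            tool: [
                ModSite(contig="c", position=p, strand="+", tool=tool, significant=True)
                for p in positions
            ]
            for tool, positions in spec.items()
        }

    def test_four_tool_site_retained_three_tool_dropped(self):
        by_tool = self._by_tool(
            {
                "differr": [100, 200],
                "drummer": [100, 200],
                "eligos2": [100, 200],
                "nanocompore": [100],
                "tombo_com": [300],
            }
        )
        cons = consensus(by_tool, min_tools=4)
        assert [(s.position, s.n_tools) for s in cons] == [(100, 4)]

    def test_min_tools_one_is_the_union(self):
        by_tool = self._by_tool({"differr": [1, 2], "drummer": [2, 3]})
        cons = consensus(by_tool, min_tools=1)
        assert [s.position for s in cons] == [1, 2, 3]

    def test_monotone_in_min_tools(self):
        by_tool = self._by_tool(
            {
                "differr": [1, 2, 3, 4],
                "drummer": [2, 3, 4],
                "eligos2": [3, 4],
                "nanocompore": [4],
            }
        )
        prev = None
        for k in (1, 2, 3, 4):
            cur = {s.position for s in consensus(by_tool, min_tools=k)}
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_too_few_tools_supplied_raises(self):
        with pytest.raises(ValueError, match="min_tools"):
            consensus(self._by_tool({"differr": [1]}), min_tools=4)


class TestCalibratePeaks:
    def _p(self, start, end, strand="+", source="native"):
        return PeakInterval("c", start, end, strand, source)

    def test_overlapping_ivt_peak_removes_native(self):
        cal = calibrate_peaks([self._p(100, 250)], [self._p(240, 300, source="ivt")])
        assert cal.retained == [] and len(cal.removed) == 1

    def test_adjacent_but_disjoint_peak_retained(self):
        cal = calibrate_peaks([self._p(100, 250)], [self._p(251, 300, source="ivt")])
        assert len(cal.retained) == 1 and cal.removed == []

    def test_empty_ivt_set_retains_everything(self):
        natives = [self._p(1, 50), self._p(100, 150)]
        cal = calibrate_peaks(natives, [])
        assert cal.retained == natives

    def test_strand_aware_with_dot_matching_both(self):
        native = [self._p(100, 250, "+"), self._p(100, 250, "-")]
        cal = calibrate_peaks(native, [self._p(200, 220, "-", "ivt")])
        assert [p.strand for p in cal.retained] == ["+"]
        cal2 = calibrate_peaks(native, [self._p(200, 220, ".", "ivt")])
        assert cal2.retained == []

    def test_partition_is_exact(self):
        natives = [self._p(i * 100, i * 100 + 50) for i in range(1, 20)]
        ivt = [self._p(350, 420, source="ivt"), self._p(1500, 1520, source="ivt")]
        cal = calibrate_peaks(natives, ivt)
        assert len(cal.retained) + len(cal.removed) == len(natives)
        removed_natives = {id(p) for p, _ in cal.removed}
        assert all(id(p) not in removed_natives for p in cal.retained)


class TestAssignM6A:
    # gene spans 901..1100 on +, 1201..1400 on -
    def _ann(self):
        return AnnotationSet(
            [
                GeneModel("gPlus", "c", 901, 1100, "+", biotype="mRNA"),
                GeneModel("gMinus", "c", 1201, 1400, "-", biotype="rRNA"),
            ]
        )

    def _genome(self):
        seq = ["C"] * 2000
        for pos in (998, 1000, 1002, 1250):
            seq[pos - 1] = "A"
        seq[1300 - 1] = "T"  # minus-strand adenosine
        return {"c": "".join(seq)}

    def _peaks(self):
        return CalibratedPeakSet(
            retained=[PeakInterval("c", 901, 1500, ".")], removed=[]
        )

    def _cons(self, pos, strand="+", tools=4):
        return ConsensusSite(
            contig="c", position=pos, strand=strand,
            supporting_tools=frozenset(f"t{i}" for i in range(tools)),
        )

    def test_direct_candidate_on_adenosine(self):
        cands = assign_m6a([self._cons(1000)], self._peaks(), self._ann(), self._genome())
        (c,) = cands
        assert (c.position, c.evidence, c.gene_id) == (1000, "direct", "gPlus")
        assert c.gene_relative_position == 100

    def test_adjacent_candidates_around_non_adenosine(self):
        # C at 1000 is not called A: the As at 998 and 1002 are redeemed
        genome = self._genome()
        genome["c"] = genome["c"][:999] + "G" + genome["c"][1000:]
        cands = assign_m6a([self._cons(1000)], self._peaks(), self._ann(), genome)
        assert [(c.position, c.evidence) for c in cands] == [
            (998, "adjacent"),
            (1002, "adjacent"),
        ]

    def test_no_adenosine_in_window_yields_nothing(self):
        genome = {"c": "C" * 2000}
        assert assign_m6a([self._cons(1000)], self._peaks(), self._ann(), genome) == []

    def test_window_zero_emits_direct_only(self):
        genome = self._genome()
        genome["c"] = genome["c"][:999] + "G" + genome["c"][1000:]
        sites = [self._cons(1000), self._cons(998)]
        cands = assign_m6a(sites, self._peaks(), self._ann(), genome, window=0)
        assert [(c.position, c.evidence) for c in cands] == [(998, "direct")]

    def test_adjacent_candidates_stay_within_two_nt(self):
        cands = assign_m6a(
            [self._cons(p) for p in range(990, 1010)],
            self._peaks(), self._ann(), self._genome(),
        )
        for c in cands:
            for s in c.source_sites:
                assert abs(c.position - s.position) <= 2

    def test_direct_preferred_when_reachable_both_ways(self):
        # site on the A itself plus a neighbouring C site both hit pos 1000
        cands = assign_m6a(
            [self._cons(1000), self._cons(1001)],
            self._peaks(), self._ann(), self._genome(),
        )
        at_1000 = [c for c in cands if c.position == 1000]
        assert at_1000[0].evidence == "direct"
        assert len(at_1000[0].source_sites) == 2

    def test_minus_strand_adenosine_is_genomic_t(self):
        cands = assign_m6a(
            [self._cons(1300, strand="-")], self._peaks(), self._ann(), self._genome()
        )
        (c,) = cands
        assert (c.evidence, c.gene_id, c.biotype) == ("direct", "gMinus", "rRNA")
        assert c.gene_relative_position == 1400 - 1300 + 1

    def test_sites_outside_retained_peaks_ignored(self):
        peaks = CalibratedPeakSet(retained=[PeakInterval("c", 1, 500, ".")], removed=[])
        assert assign_m6a([self._cons(1000)], peaks, self._ann(), self._genome()) == []


class TestSummaries:
    def test_reference_table_round_trips_through_summary(self):
        ref = load_reference_mrna_m6a()
        cands = candidates_from_gene_table(ref)
        counts, table = summarize_by_biotype(cands)
        assert counts["mRNA"] == 75
        assert counts["rRNA"] == 0 and counts["ncRNA"] == 0
        assert len(table) == 21
        # per-gene position lists reproduce the input exactly
        merged = table.merge(ref, on="gene_name")
        for r in merged.itertuples():
            got = [int(x) for x in r.m6a_positions_x.split(",")]
            want = [int(x) for x in str(r.m6a_positions_y).split(",")]
            assert got == sorted(want)

    def test_empty_candidate_list(self):
        counts, table = summarize_by_biotype([])
        assert counts == {"rRNA": 0, "mRNA": 0, "ncRNA": 0}
        assert len(table) == 0

    def test_single_biotype_leaves_others_zero(self):
        ref = load_reference_mrna_m6a().head(1)
        cands = candidates_from_gene_table(ref, biotype="rRNA")
        counts, _ = summarize_by_biotype(cands)
        assert counts["rRNA"] == 1 and counts["mRNA"] == 0 and counts["ncRNA"] == 0


class TestMotifWindows:
    def _cand(self, pos, strand="+", contig="c"):
        from btarch.epitranscriptome import M6ACandidate

        return M6ACandidate(
            contig=contig, position=pos, strand=strand, gene_id="g",
            gene_length=100, gene_relative_position=pos, biotype="mRNA",
            evidence="direct",
        )

    def test_full_window_length(self):
        genome = {"c": "ACGT" * 250}
        (rec,) = export_motif_windows([self._cand(100)], genome, flank=5)
        assert len(rec[1]) == 11
        assert rec[1] == genome["c"][94:105]

    def test_clipped_at_contig_start(self):
        genome = {"c": "ACGTACGTACGT"}
        (rec,) = export_motif_windows([self._cand(3)], genome, flank=5)
        assert rec[1] == genome["c"][0:8]

    def test_minus_strand_reverse_complemented(self):
        genome = {"c": "AAAAATTTTTGGGGG"}
        (rec,) = export_motif_windows([self._cand(8, strand="-")], genome, flank=2)
        # window [6,10] = TTTTT -> revcomp AAAAA
        assert rec[1] == "AAAAA"

    def test_fasta_written_in_dna_alphabet(self, tmp_path):
        genome = {"c": "ACGT" * 10}
        fasta = tmp_path / "w.fasta"
        export_motif_windows([self._cand(20)], genome, flank=3, fasta_path=fasta)
        text = fasta.read_text()
        assert text.startswith(">c:20:+")
        assert "U" not in text
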