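"""Small-RNA library filters and NAT-siRNA calling rules, including the
hand-derived toy truth for the residency/reproducibility rules."""

import pytest

from natscape.genome_io import GenomicInterval, SmallRnaRead
from natscape.sirna import (build_library, call_nat_sirnas, pair_regions,
                            summarize)
from natscape.cis_nat import find_cis_pairs

from conftest import make_tx


def read(rid, seq_len, start, dataset, strand="+", n_hits=1, chrom="c",
         tissue="seedling", base="A"):
    hits = [GenomicInterval(chrom, start + i * 3000, start + i * 3000
                            + seq_len, strand) for i in range(n_hits)]
    return SmallRnaRead(rid, base * seq_len, hits, dataset, tissue, 1)


class TestBuildLibrary:
    def test_clean_unique_read_retained(self):
        lib, rejects = build_library([read("r1", 21, 100, "d1")], [])
        assert len(lib) == 1 and rejects == {}

    def test_multi_mapper_removed(self):
        lib, rejects = build_library([read("r1", 21, 100, "d1", n_hits=2)], [])
        assert lib == [] and rejects == {"multi_mapper": 1}

    @pytest.mark.parametrize("length,kept", [(17, False), (18, True),
                                             (28, True), (29, False)])
    def test_length_window_boundaries(self, length, kept):
        lib, _ = build_library([read("r1", length, 100, "d1")], [])
        assert bool(lib) is kept

    def test_excluded_ncrna_overlap_removed_trna_kept(self):
        rrna_locus = [GenomicInterval("c", 90, 190, "+")]
        overlapping = read("r1", 21, 100, "d1")
        elsewhere = read("r2", 21, 5000, "d1")  # e.g. over a tRNA gene
        lib, rejects = build_library([overlapping, elsewhere], rrna_locus)
        assert [r.read_id for r in lib] == ["r2"]
        assert rejects == {"excluded_ncRNA": 1}


def toy_regions():
    """One convergent cis pair with overlap [400, 500) on chromosome c."""
    catalog = [make_tx("a.1", "c", 100, 500, "+"),
               make_tx("b.1", "c", 400, 800, "-", biotype="lncRNA")]
    tx_by_id = {t.transcript_id: t for t in catalog}
    cis = find_cis_pairs(catalog)
    return pair_regions(cis, [], tx_by_id), tx_by_id


class TestCallNatSirnas:
    def test_hand_derived_toy_truth(self):
        """Reads at 17/18/21/24/28/29 nt, present in 1-4 data sets, in and
        out of the overlap region: the surviving set is derived by hand
        from the length window (18-28), unique mapping, overlap residency
        and the >= 3-data-set rule."""
        regions, _ = toy_regions()
        reads = []
        # in-overlap, 3 data sets, 21 nt -> CALLED
        for ds in ("d1", "d2", "d3"):
            reads.append(read(f"in21_{ds}", 21, 410, ds, base="C"))
        # in-overlap, 2 data sets only -> not called
        for ds in ("d1", "d2"):
            reads.append(read(f"in24_{ds}", 24, 440, ds, base="G"))
        # in-overlap but 17 nt (too short) and 29 nt (too long), 4 data sets
        for ds in ("d1", "d2", "d3", "d4"):
            reads.append(read(f"in17_{ds}", 17, 420, ds, base="T"))
            reads.append(read(f"in29_{ds}", 29, 430, ds))
        # outside the overlap, 4 data sets, 28 nt -> library but not called
        for ds in ("d1", "d2", "d3", "d4"):
            reads.append(read(f"out28_{ds}", 28, 150, ds, base="C"))
        # in-overlap, 3 data sets, but multi-mapper -> removed upstream
        for ds in ("d1", "d2", "d3"):
            reads.append(read(f"mm_{ds}", 18, 450, ds, n_hits=2, base="G"))

        lib, _ = build_library(reads, [])
        called = call_nat_sirnas(lib, regions)
        assert len(called) == 1
        (s,) = called
        assert s.length == 21 and s.locus.start == 410
        assert s.source_pairs == ["a.1|b.1"]
        assert s.datasets_present == {"d1", "d2", "d3"}

    def test_threshold_boundary_exactly_three(self):
        regions, _ = toy_regions()
        reads = [read(f"r_{ds}", 21, 410, ds) for ds in ("d1", "d2")]
        lib, _ = build_library(reads, [])
        assert call_nat_sirnas(lib, regions) == []
        reads.append(read("r_d3", 21, 410, "d3"))
        lib, _ = build_library(reads, [])
        assert len(call_nat_sirnas(lib, regions)) == 1

    def test_locus_must_be_fully_inside_overlap(self):
        regions, _ = toy_regions()
        # starts inside the overlap but runs past its end at 500
        reads = [read(f"r_{ds}", 21, 490, ds) for ds in ("d1", "d2", "d3")]
        lib, _ = build_library(reads, [])
        assert call_nat_sirnas(lib, regions) == []

    def test_producing_transcript_by_strand_and_subtype_direction(self):
        regions, _ = toy_regions()  # a.1 is PC on '+', b.1 is NPC on '-'
        plus = [read(f"p_{ds}", 21, 410, ds, strand="+")
                for ds in ("d1", "d2", "d3")]
        minus = [read(f"m_{ds}", 21, 440, ds, strand="-", base="G")
                 for ds in ("d1", "d2", "d3")]
        called = call_nat_sirnas(plus + minus, regions)
        by_strand = {s.locus.strand: s for s in called}
        assert by_strand["+"].directional_subtype == "PC-NPC"
        assert by_strand["-"].directional_subtype == "NPC-PC"

    def test_hub_shared_locus_is_nonunique_and_lists_both_pairs(self):
        # two pairs sharing hub transcript h.1; both overlaps contain the locus
        catalog = [make_tx("h.1", "c", 0, 1000, "+"),
                   make_tx("p.1", "c", 400, 1400, "-"),
                   make_tx("q.1", "c", 450, 520, "-", biotype="lncRNA")]
        tx_by_id = {t.transcript_id: t for t in catalog}
        regions = pair_regions(find_cis_pairs(catalog), [], tx_by_id)
        # p|q share a strand, so only h|p and h|q are NAT pairs
        assert {pr.pair_id for pr in regions} == {"h.1|p.1", "h.1|q.1"}
        reads = [read(f"r_{ds}", 21, 460, ds) for ds in ("d1", "d2", "d3")]
        (s,) = call_nat_sirnas(reads, regions)
        assert s.uniqueness == "nonunique"
        assert sorted(s.source_pairs) == ["h.1|p.1", "h.1|q.1"]

    def test_every_called_locus_inside_a_source_region(self, bundle_analysis):
        regions = bundle_analysis["regions"]
        by_id = {pr.pair_id: pr for pr in regions}
        called = bundle_analysis["called"]
        assert called, "bundle should yield NAT-siRNAs"
        for s in called:
            assert any(
                iv.contains(s.locus)
                for pid in s.source_pairs
                for iv in by_id[pid].regions
            )


class TestSummarize:
    def test_length_histogram(self):
        regions, _ = toy_regions()
        reads = []
        for i, ln in enumerate([21, 21, 24, 21, 18]):
            for ds in ("d1", "d2", "d3"):
                reads.append(read(f"r{i}_{ds}", ln, 405 + 3 * i, ds,
                                  base="ACGT"[i % 4]))
        called = call_nat_sirnas(reads, regions)
        hist = summarize(called, regions)["length_hist"]
        assert dict(zip(hist["length"], hist["count"])) == {18: 1, 21: 3, 24: 1}

    def test_tissue_sharing(self):
        regions, _ = toy_regions()
        reads = [
            read("r_d1", 21, 410, "d1", tissue="seedling"),
            read("r_d2", 21, 410, "d2", tissue="leaf"),
            read("r_d3", 21, 410, "d3", tissue="flower"),
            read("q_d1", 24, 440, "d1", tissue="seedling", base="G"),
            read("q_d2", 24, 440, "d2", tissue="seedling", base="G"),
            read("q_d3", 24, 440, "d3", tissue="seedling", base="G"),
        ]
        called = call_nat_sirnas(reads, regions)
        table = summarize(called, regions)["tissue_table"]
        counts = dict(zip(table["category"], table["count"]))
        assert counts["shared_across_tissues"] == 1
        assert counts["seedling_specific"] == 1

    def test_planted_length_modes_recovered(self, bundle_analysis):
        from collections import Counter
        counts = Counter(s.length for s in bundle_analysis["called"])
        top_two = {ln for ln, _ in counts.most_common(2)}
        assert top_two == {21, 24}
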