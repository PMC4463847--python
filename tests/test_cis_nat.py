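"""cis-NAT orientation classification, checked against an independent
predicate-based classifier on random span pairs, plus pair discovery and
overlap-position labels."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from natscape.genome_io import GenomicInterval
from natscape.cis_nat import (classify_orientation, classify_overlap_position,
                              find_cis_pairs)

from conftest import make_tx


def oracle_classify(a: GenomicInterval, b: GenomicInterval,
                    max_gap: int = 100):
    """Literal predicate classifier: tests containment, then whether both
    3'-terminal (or both 5'-terminal) bases lie inside the partner span."""
    def last_base(iv):
        return iv.end - 1 if iv.strand == "+" else iv.start

    def first_base(iv):
        return iv.start if iv.strand == "+" else iv.end - 1

    if a.contains(b) or b.contains(a):
        return "containing"
    if a.overlaps(b):
        if b.contains_pos(last_base(a)) and a.contains_pos(last_base(b)):
            return "convergent"
        if b.contains_pos(first_base(a)) and a.contains_pos(first_base(b)):
            return "divergent"
        raise AssertionError("unclassifiable overlap")
    left, right = (a, b) if a.start <= b.start else (b, a)
    gap = right.start - left.end
    if not 1 <= gap <= max_gap:
        return None
    # facing ends: a '+' gene on the left presents its 3' end to the gap
    if left.strand == "+" and right.strand == "-":
        return "nearby_tail_to_tail"
    return "nearby_head_to_head"


class TestClassifyOrientation:
    def test_convergent_geometry(self):
        a = GenomicInterval("c", 100, 500, "+")
        b = GenomicInterval("c", 400, 800, "-")
        assert classify_orientation(a, b) == "convergent"

    def test_divergent_geometry(self):
        a = GenomicInterval("c", 400, 800, "+")
        b = GenomicInterval("c", 100, 500, "-")
        assert classify_orientation(a, b) == "divergent"

    def test_containing_geometry(self):
        a = GenomicInterval("c", 100, 1000, "+")
        b = GenomicInterval("c", 300, 600, "-")
        assert classify_orientation(a, b) == "containing"

    def test_equal_spans_tie_break_to_containing(self):
        a = GenomicInterval("c", 100, 500, "+")
        b = GenomicInterval("c", 100, 500, "-")
        assert classify_orientation(a, b) == "containing"

    def test_single_base_overlap_is_convergent(self):
        a = GenomicInterval("c", 100, 200, "+")
        b = GenomicInterval("c", 199, 300, "-")
        assert classify_orientation(a, b) == "convergent"

    def test_nearby_tail_to_tail(self):
        a = GenomicInterval("c", 100, 500, "+")
        b = GenomicInterval("c", 550, 900, "-")
        assert classify_orientation(a, b) == "nearby_tail_to_tail"

    def test_nearby_head_to_head(self):
        a = GenomicInterval("c", 550, 900, "+")
        b = GenomicInterval("c", 100, 500, "-")
        assert classify_orientation(a, b) == "nearby_head_to_head"

    def test_same_strand_rejected(self):
        a = GenomicInterval("c", 100, 500, "+")
        b = GenomicInterval("c", 400, 800, "+")
        with pytest.raises(ValueError, match="strand"):
            classify_orientation(a, b)

    def test_agrees_with_predicate_oracle_on_random_pairs(self):
        rng = np.random.default_rng(2024)
        n_checked = 0
        while n_checked < 10_000:
            s1 = int(rng.integers(0, 5000))
            e1 = s1 + int(rng.integers(1, 1500))
            s2 = int(rng.integers(0, 5000))
            e2 = s2 + int(rng.integers(1, 1500))
            a = GenomicInterval("c", s1, e1, "+")
            b = GenomicInterval("c", s2, e2, "-")
            expected = oracle_classify(a, b)
            if expected is None:
                continue
            assert classify_orientation(a, b, 100) == expected, (a, b)
            n_checked += 1


@settings(max_examples=300, derandomize=True, deadline=None)
@given(
    s1=st.integers(0, 3000), l1=st.integers(1, 1200),
    s2=st.integers(0, 3000), l2=st.integers(1, 1200),
    flip=st.booleans(),
)
def test_classification_symmetric_and_oracle_consistent(s1, l1, s2, l2, flip):
    """classify(a, b) == classify(b, a), and both match the predicate
    oracle whenever the pair is classifiable."""
    a = GenomicInterval("c", s1, s1 + l1, "+" if not flip else "-")
    b = GenomicInterval("c", s2, s2 + l2, "-" if not flip else "+")
    expected = oracle_classify(a, b)
    if expected is None:
        with pytest.raises(ValueError):
            classify_orientation(a, b, 100)
        return
    assert classify_orientation(a, b, 100) == expected
    assert classify_orientation(b, a, 100) == expected


class TestFindCisPairs:
    def make_catalog(self):
        return [
            make_tx("a.1", "c", 100, 500, "+"),
            make_tx("b.1", "c", 400, 800, "-", biotype="lncRNA"),
            make_tx("c.1", "c", 2000, 2500, "+"),
            make_tx("d.1", "c", 2550, 2900, "-"),        # gap 50: nearby
            make_tx("e.1", "c", 5000, 5400, "+"),
            make_tx("f.1", "c", 5200, 5600, "+"),        # same strand
        ]

    def test_pairs_found_and_same_strand_never_emitted(self):
        pairs = find_cis_pairs(self.make_catalog())
        assert {(p.transcript_a, p.transcript_b) for p in pairs} == \
               {("a.1", "b.1"), ("c.1", "d.1")}
        sub = {p.pair_id: p.subtype for p in pairs}
        assert sub["a.1|b.1"] == "convergent"
        assert sub["c.1|d.1"] == "nearby_tail_to_tail"

    def test_overlap_contained_in_both_spans(self):
        pairs = find_cis_pairs(self.make_catalog())
        p = next(p for p in pairs if p.subtype == "convergent")
        assert p.overlap == GenomicInterval("c", 400, 500, ".")
        assert p.interval_a.contains(p.overlap)
        assert p.interval_b.contains(p.overlap)

    def test_canonical_order_input_invariant(self):
        catalog = self.make_catalog()
        fwd = find_cis_pairs(catalog)
        rev = find_cis_pairs(catalog[::-1])
        assert [(p.pair_id, p.subtype) for p in fwd] == \
               [(p.pair_id, p.subtype) for p in rev]
        assert all(p.transcript_a < p.transcript_b for p in fwd)

    def test_empty_catalog(self):
        assert find_cis_pairs([]) == []

    def test_gap_beyond_cutoff_not_emitted(self):
        catalog = [make_tx("a.1", "c", 0, 100, "+"),
                   make_tx("b.1", "c", 250, 400, "-")]
        assert find_cis_pairs(catalog, nearby_max_gap=100) == []
        assert len(find_cis_pairs(catalog, nearby_max_gap=200)) == 1

    def test_coding_class_label(self):
        pairs = find_cis_pairs(self.make_catalog())
        labels = {p.pair_id: p.coding_class for p in pairs}
        assert labels["a.1|b.1"] == "PC/NPC"
        assert labels["c.1|d.1"] == "PC/PC"


class TestOverlapPosition:
    def make_pair(self, cds_start, cds_end):
        cds = GenomicInterval("c", cds_start, cds_end, "+")
        a = make_tx("a.1", "c", 100, 1000, "+", cds=cds)
        b = make_tx("b.1", "c", 850, 1300, "-", biotype="lncRNA")
        (pair,) = find_cis_pairs([a, b])
        return pair, {"a.1": a, "b.1": b}

    def test_three_prime_utr(self):
        pair, txs = self.make_pair(200, 800)   # overlap [850,1000) after CDS
        assert classify_overlap_position(pair, txs)["a.1"] == "3'-UTR"

    def test_across_cds(self):
        pair, txs = self.make_pair(300, 900)   # overlap crosses CDS end
        assert classify_overlap_position(pair, txs)["a.1"] == "across-CDS"

    def test_five_prime_utr_on_minus_gene(self):
        cds = GenomicInterval("c", 950, 1250, "-")
        a = make_tx("a.1", "c", 100, 1000, "+", biotype="lncRNA")
        b = make_tx("b.1", "c", 850, 1300, "-", cds=cds)
        (pair,) = find_cis_pairs([a, b])
        # overlap [850,1000) sits left of the minus gene's CDS = its 3' side
        # .. but crosses cds.start=950, hence across-CDS
        assert classify_overlap_position(pair, {"a.1": a, "b.1": b})["b.1"] \
            == "across-CDS"

    def test_pc_without_cds_labeled_unknown(self):
        a = make_tx("a.1", "c", 100, 1000, "+")
        b = make_tx("b.1", "c", 850, 1300, "-", biotype="lncRNA")
        (pair,) = find_cis_pairs([a, b])
        assert classify_overlap_position(pair, {"a.1": a, "b.1": b})["a.1"] \
            == "unknown"


def test_planted_subtype_counts_recovered_exactly(default_bundle,
                                                  bundle_analysis):
    from collections import Counter
    bundle, _ = default_bundle
    pairs = bundle_analysis["cis"]
    got = Counter(p.subtype for p in pairs)
    want = Counter(p.kind for p in bundle.pairs if p.kind != "trans")
    assert got == want
    planted_ids = {p.pair_id for p in bundle.pairs if p.kind != "trans"}
    assert {p.pair_id for p in pairs} == planted_ids
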