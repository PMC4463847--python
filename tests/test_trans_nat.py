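"""Reverse-complement complementarity search and duplex bubble rule,
cross-checked against Biopython's local aligner as an independent oracle."""

import numpy as np
import pytest
from Bio import Align

from natscape.trans_nat import (TransCandidate, align_revcomp,
                                complementarity_search, revcomp,
                                transcript_to_genomic, verify_duplex,
                                find_trans_pairs)

from conftest import make_tx


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def sw_gapless_score(seq_a, seq_b_rc):
    """Independent gapless local-alignment score: Biopython local aligner
    with gaps priced out."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -10_000
    aligner.extend_gap_score = -10_000
    return aligner.score(seq_a, seq_b_rc)


class TestAlignRevcomp:
    def test_exact_planted_complement(self):
        rng = np.random.default_rng(1)
        a = random_seq(rng, 1000)
        segment = a[300:500]
        b = random_seq(rng, 400) + revcomp(segment) + random_seq(rng, 400)
        cand = align_revcomp(a, b)
        # the maximal-scoring segment covers the planted region (it may
        # extend a few bases into the flanks through chance matches)
        assert cand.region_a[0] <= 300 and cand.region_a[1] >= 500
        assert cand.score >= 200
        assert cand.identity >= 0.95
        # region_b covers the planted insert at b[400:600)
        lo, hi = cand.region_b
        assert lo <= 400 and hi >= 600

    def test_random_sequences_no_long_candidate(self):
        rng = np.random.default_rng(7)
        a, b = random_seq(rng, 1000), random_seq(rng, 1000)
        cand = align_revcomp(a, b)
        if cand is not None:
            assert cand.region_length < 100
        assert sw_gapless_score(a, revcomp(b)) < 100

    def test_score_matches_gapless_smith_waterman(self):
        rng = np.random.default_rng(11)
        n_compared = 0
        for _ in range(50):
            a = random_seq(rng, 300)
            segment = a[50:200]
            # degrade the planted complement so scores are non-trivial
            noisy = list(segment)
            for i in rng.integers(0, len(noisy), size=10):
                noisy[i] = "ACGT"[(("ACGT".index(noisy[i])) + 1) % 4]
            b = (random_seq(rng, 60) + revcomp("".join(noisy))
                 + random_seq(rng, 60))
            cand = align_revcomp(a, b, k=8)
            oracle = sw_gapless_score(a, revcomp(b))
            assert cand is not None
            assert cand.score == oracle
            n_compared += 1
        assert n_compared == 50


class TestVerifyDuplex:
    def make_candidate(self, seq_a, seq_b, n):
        return TransCandidate("A", "B", (0, n), (len(seq_b) - n, len(seq_b)),
                              score=n, identity=1.0)

    def test_perfect_complement_accepted(self):
        rng = np.random.default_rng(3)
        a = random_seq(rng, 200)
        b = revcomp(a)
        duplex, ok = verify_duplex(self.make_candidate(a, b, 200),
                                   {"A": a, "B": b})
        assert ok and duplex.bubbles == [] and duplex.paired_fraction == 1.0

    @pytest.mark.parametrize("run,accepted", [(10, True), (11, False),
                                              (15, False)])
    def test_bubble_boundary_inclusive_at_ten_percent(self, run, accepted):
        rng = np.random.default_rng(4)
        a = random_seq(rng, 100)
        mismatched = list(a)
        for i in range(40, 40 + run):
            mismatched[i] = "ACGT"[("ACGT".index(a[i]) + 1) % 4]
        b = revcomp("".join(mismatched))
        duplex, ok = verify_duplex(self.make_candidate(a, b, 100),
                                   {"A": a, "B": b})
        assert duplex.max_bubble == run
        assert ok is accepted

    def test_symmetry_of_accept_decision(self):
        rng = np.random.default_rng(5)
        a = random_seq(rng, 120)
        noisy = list(a)
        for i in range(50, 62):
            noisy[i] = "ACGT"[("ACGT".index(a[i]) + 1) % 4]
        b = revcomp("".join(noisy))
        seqs = {"A": a, "B": b}
        cand_ab = self.make_candidate(a, b, 120)
        cand_ba = TransCandidate("B", "A", (0, 120), (0, 120),
                                 score=120, identity=1.0)
        _, ok_ab = verify_duplex(cand_ab, seqs)
        _, ok_ba = verify_duplex(cand_ba, seqs)
        assert ok_ab == ok_ba

    def test_wobble_pairs_accepted_when_enabled(self):
        # A=G pairs B=U(T): in the A-vs-revcomp(B) frame that is (G, A)
        a = "G" * 30
        b = "T" * 30  # revcomp(b) = 'A'*30
        cand = self.make_candidate(a, b, 30)
        duplex, ok = verify_duplex(cand, {"A": a, "B": b}, wobble=True)
        assert ok and duplex.paired_fraction == 1.0
        duplex, ok = verify_duplex(cand, {"A": a, "B": b}, wobble=False)
        assert not ok

    def test_zero_length_region_rejected(self):
        with pytest.raises(ValueError):
            verify_duplex(TransCandidate("A", "B", (5, 5), (0, 5), 0, 1.0),
                          {"A": "ACGTAC", "B": "ACGTAC"})


class TestSearch:
    def test_missing_sequence_named(self):
        with pytest.raises(ValueError, match="tX"):
            complementarity_search({"tX": ""})

    def test_cis_overlapping_loci_excluded(self):
        rng = np.random.default_rng(6)
        seq = random_seq(rng, 500)
        catalog = [make_tx("a.1", "c", 100, 600, "+"),
                   make_tx("b.1", "c", 300, 800, "-")]
        seqs = {"a.1": seq, "b.1": revcomp(seq)}
        assert complementarity_search(seqs, catalog) == []
        # same sequences on separate loci are reported
        catalog2 = [make_tx("a.1", "c", 100, 600, "+"),
                    make_tx("b.1", "c2", 300, 800, "-")]
        assert len(complementarity_search(seqs, catalog2)) == 1

    def test_tightening_identity_never_grows_accepted_set(self):
        rng = np.random.default_rng(9)
        catalog, seqs = [], {}
        for i in range(6):
            tid = f"t{i}.1"
            catalog.append(make_tx(tid, f"c{i}", 0, 700, "+"))
            seqs[tid] = random_seq(rng, 700)
        # plant two duplexes with different identities
        seg = seqs["t0.1"][100:300]
        seqs["t1.1"] = seqs["t1.1"][:100] + revcomp(seg) + seqs["t1.1"][300:]
        noisy = list(seqs["t2.1"][100:300])
        for i in rng.integers(0, 200, size=30):
            noisy[i] = "ACGT"[("ACGT".index(noisy[i]) + 1) % 4]
        seqs["t3.1"] = (seqs["t3.1"][:100] + revcomp("".join(noisy))
                        + seqs["t3.1"][300:])
        seqs["t3.1"] = seqs["t3.1"][:700]
        prev = None
        for ident in (0.7, 0.85, 0.99):
            found = {(c.transcript_a, c.transcript_b)
                     for c in complementarity_search(
                         seqs, catalog, min_identity=ident)}
            if prev is not None:
                assert found <= prev
            prev = found


class TestGenomicProjection:
    def test_plus_strand_single_exon(self):
        tx = make_tx("t.1", "c", 1000, 2000, "+")
        iv = transcript_to_genomic(tx, 100, 300)
        assert (iv.start, iv.end) == (1100, 1300)

    def test_minus_strand_single_exon(self):
        tx = make_tx("t.1", "c", 1000, 2000, "-")
        iv = transcript_to_genomic(tx, 0, 100)   # transcript 5' end
        assert (iv.start, iv.end) == (1900, 2000)

    def test_region_outside_transcript_rejected(self):
        tx = make_tx("t.1", "c", 1000, 2000, "+")
        with pytest.raises(ValueError):
            transcript_to_genomic(tx, 900, 1100)


def test_planted_trans_pairs_recovered(default_bundle, bundle_analysis):
    bundle, bundle_dir = default_bundle
    accepted = bundle_analysis["trans"]
    rejected = bundle_analysis["trans_rejected"]
    planted = {p.pair_id for p in bundle.pairs if p.kind == "trans"}
    assert {p.pair_id for p in accepted} == planted
    assert rejected == []
    for p in accepted:
        assert p.duplex.max_bubble <= 0.10 * p.duplex.region_length
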