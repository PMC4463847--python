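"""Domain joining boundaries, gene mark states, metagene profiles against
a per-position oracle, pair-pattern classes and the randomized null."""

from collections import Counter

import numpy as np
import pytest

from natscape.genome_io import ChromatinDomain, ChromatinTile, GenomicInterval
from natscape.chromatin import (GROUP_STATES, PATTERN_CLASSES,
                                classify_pair_patterns, gene_mark_state,
                                gene_states, metagene_profile, pattern_class,
                                pattern_percentages, randomized_null,
                                tiles_to_domains)

from conftest import make_tx


def tile(start, end, mark="H3K4me3", chrom="c"):
    return ChromatinTile(mark, GenomicInterval(chrom, start, end, "."))


def domain(start, end, mark="H3K4me3", chrom="c"):
    return ChromatinDomain(mark, GenomicInterval(chrom, start, end, "."))


class TestTilesToDomains:
    def test_gap_of_200_merges_and_survives(self):
        (d,) = tiles_to_domains([tile(0, 200), tile(400, 600)])
        assert (d.interval.start, d.interval.end) == (0, 600)

    def test_short_lone_tile_dropped(self):
        assert tiles_to_domains([tile(0, 300)]) == []

    def test_gap_201_leaves_two_short_fragments_dropped(self):
        assert tiles_to_domains([tile(0, 200), tile(401, 601)]) == []

    def test_minimum_length_inclusive(self):
        (d,) = tiles_to_domains([tile(0, 400)])
        assert d.interval.length() == 400

    def test_order_invariant_and_idempotent(self):
        tiles = [tile(800, 1000), tile(0, 200), tile(400, 600),
                 tile(2000, 2500, mark="H3K27me3")]
        fwd = tiles_to_domains(tiles)
        rev = tiles_to_domains(tiles[::-1])
        assert fwd == rev
        again = tiles_to_domains(
            [ChromatinTile(d.mark, d.interval) for d in fwd])
        assert again == fwd

    def test_marks_do_not_merge_across_each_other(self):
        domains = tiles_to_domains(
            [tile(0, 400), tile(450, 850, mark="H3K27me3")])
        assert {d.mark for d in domains} == {"H3K4me3", "H3K27me3"}


class TestGeneMarkState:
    def test_single_g1_mark(self):
        gene = make_tx("g.1", "c", 100, 1000, "+")
        state = gene_mark_state(gene, [domain(0, 500)])
        assert state.group_state == "G1"

    def test_g1_plus_g2(self):
        gene = make_tx("g.1", "c", 100, 1000, "+")
        state = gene_mark_state(
            gene, [domain(0, 500), domain(600, 1200, "H3K27me3")])
        assert state.group_state == "G1+G2"

    def test_no_overlap_is_non(self):
        gene = make_tx("g.1", "c", 100, 1000, "+")
        assert gene_mark_state(gene, [domain(2000, 3000)]).group_state == "NON"

    def test_one_base_overlap_counts(self):
        gene = make_tx("g.1", "c", 100, 1000, "+")
        assert gene_mark_state(gene, [domain(999, 1400)]).group_state == "G1"
        assert gene_mark_state(gene, [domain(1000, 1400)]).group_state == "NON"

    def test_unknown_mark_rejected(self):
        gene = make_tx("g.1", "c", 100, 1000, "+")
        with pytest.raises(ValueError, match="mark"):
            gene_mark_state(gene, [domain(0, 500, mark="H3K9ac")])


class TestMetageneProfile:
    def test_gene_exactly_covered_by_domain(self):
        gene = make_tx("g.1", "c", 2000, 3000, "+")
        prof = metagene_profile([gene], [domain(2000, 3000)])
        assert prof.shape == (300,)
        assert np.all(prof[100:200] == 1.0)   # body bins
        assert np.all(prof[:100] == 0.0) and np.all(prof[200:] == 0.0)

    def test_minus_strand_profile_mirrors_plus(self):
        dom = [domain(2000, 2400)]  # covers the left 40% of the span
        plus = metagene_profile([make_tx("g.1", "c", 2000, 3000, "+")], dom)
        minus = metagene_profile([make_tx("g.1", "c", 2000, 3000, "-")], dom)
        assert np.allclose(minus, plus[::-1])

    def test_short_gene_skipped(self):
        with pytest.raises(ValueError):
            metagene_profile([make_tx("g.1", "c", 2000, 2050, "+")], [])

    def test_matches_per_position_oracle(self):
        rng = np.random.default_rng(23)
        genes, domains = [], []
        for i in range(100):
            start = int(rng.integers(2000, 50_000))
            length = int(rng.integers(150, 2500))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(make_tx(f"g{i}.1", "c", start, start + length,
                                 strand))
        for _ in range(60):
            start = int(rng.integers(0, 52_000))
            domains.append(domain(start, start + int(rng.integers(200, 1500))))
        prof = metagene_profile(genes, domains)

        covered = np.zeros(60_000)
        for d in domains:
            covered[d.interval.start:d.interval.end] = 1.0
        per_gene = []
        for g in genes:
            s, e = g.interval.start, g.interval.end
            window = covered[s - 1000:e + 1000]
            up = window[:1000].reshape(100, 10).mean(axis=1)
            down = window[-1000:].reshape(100, 10).mean(axis=1)
            body = window[1000:1000 + (e - s)]
            edges = np.linspace(0, e - s, 101).astype(int)
            bm = np.array([body[edges[i]:edges[i + 1]].mean()
                           for i in range(100)])
            p = np.concatenate([up, bm, down])
            per_gene.append(p[::-1] if g.strand == "-" else p)
        assert np.allclose(prof, np.mean(per_gene, axis=0))


class TestPairPatterns:
    def test_unordered_symmetry(self):
        assert pattern_class("G1", "G2") == pattern_class("G2", "G1") == "G1_G2"
        assert pattern_class("G1+G2", "NON") == "G1+G2_NON"

    def test_sixteen_ordered_combinations_give_ten_classes(self):
        labels = {pattern_class(a, b)
                  for a in GROUP_STATES for b in GROUP_STATES}
        assert labels == set(PATTERN_CLASSES)
        assert len(labels) == 10

    def test_missing_state_dropped_and_counted(self):
        from natscape.chromatin import GeneMarkState
        states = {"a": GeneMarkState("a", frozenset({"H3K4me3"})),
                  "b": GeneMarkState("b", frozenset())}
        counts, dropped = classify_pair_patterns(
            [("a", "b"), ("a", "ghost")], states)
        assert counts == Counter({"G1_NON": 1})
        assert dropped == 1

    def test_percentages_sum_to_100(self):
        counts = Counter({"G1_G1": 3, "G2_G2": 2, "G1_G2": 5})
        assert sum(pattern_percentages(counts).values()) == pytest.approx(100)


class TestRandomizedNull:
    def test_degenerate_pool_all_g1(self):
        null = randomized_null(["G1"] * 40, n_pairs=10, repeats=50, seed=0)
        assert null.loc["G1_G1", "mean_pct"] == pytest.approx(100.0)
        assert null.loc["G1_G1", "pct_2.5"] == pytest.approx(100.0)
        assert null.drop(index="G1_G1")["mean_pct"].sum() == 0.0

    def test_half_half_pool_matches_independence_expectation(self):
        pool = ["G1"] * 500 + ["G2"] * 500
        null = randomized_null(pool, n_pairs=50, repeats=2000, seed=1)
        assert null.loc["G1_G1", "mean_pct"] == pytest.approx(25.0, abs=1.0)
        assert null.loc["G2_G2", "mean_pct"] == pytest.approx(25.0, abs=1.0)
        assert null.loc["G1_G2", "mean_pct"] == pytest.approx(50.0, abs=1.5)

    def test_deterministic_given_seed(self):
        pool = ["G1", "G2", "G1+G2", "NON"] * 20
        a = randomized_null(pool, 10, repeats=200, seed=42)
        b = randomized_null(pool, 10, repeats=200, seed=42)
        assert a.equals(b)

    def test_pool_too_small_rejected(self):
        with pytest.raises(ValueError, match="pool"):
            randomized_null(["G1"] * 10, n_pairs=6, repeats=10, seed=0)


def test_group_state_percentages_sum_and_count():
    from natscape.chromatin import GeneMarkState, group_state_percentages
    states = {
        "a": GeneMarkState("a", frozenset({"H3K4me3"})),
        "b": GeneMarkState("b", frozenset({"H3K27me3"})),
        "c": GeneMarkState("c", frozenset()),
    }
    df = group_state_percentages(states, {"all": ["a", "b", "c"],
                                          "empty": []})
    row = df[df["group"] == "all"].iloc[0]
    assert row["n_genes"] == 3
    assert row["G1"] + row["G2"] + row["G1+G2"] + row["NON"] == \
        pytest.approx(100.0, abs=0.05)  # rounded to 2 decimals per cell
    assert np.isnan(df[df["group"] == "empty"].iloc[0]["G1"])


def test_planted_pair_states_recovered(default_bundle, bundle_analysis):
    """Tile -> domain -> state recovery reproduces every planted pair
    state, and concordant classes exceed the randomized null."""
    from natscape.genome_io import read_tiles
    bundle, bundle_dir = default_bundle
    tiles = read_tiles(bundle_dir / "tiles.bed")
    domains = tiles_to_domains(tiles)
    states = gene_states(bundle.transcripts, domains)
    truth_states = {}
    for p in bundle.pairs:
        truth_states[p.tx_a.split(".")[0]] = p.state_a
        truth_states[p.tx_b.split(".")[0]] = p.state_b
    for gene_id, want in truth_states.items():
        assert states[gene_id].group_state == want, gene_id

    cis_pairs = [(p.tx_a.split(".")[0], p.tx_b.split(".")[0])
                 for p in bundle.pairs
                 if p.kind not in ("trans",)]
    counts, dropped = classify_pair_patterns(cis_pairs, states)
    assert dropped == 0
    obs = pattern_percentages(counts)
    nat_genes = set(truth_states)
    pool = [states[t.gene_id].group_state for t in bundle.transcripts
            if t.gene_id not in nat_genes]
    null = randomized_null(pool, len(cis_pairs), repeats=1000, seed=3)
    concord = obs["G1_G1"] + obs["G2_G2"]
    null_concord = (null.loc["G1_G1", "mean_pct"]
                    + null.loc["G2_G2", "mean_pct"])
    assert concord > null_concord
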