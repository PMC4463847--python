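"""Synthetic input bundles with planted, parameterized structure.

The generator lays out gene units (cis-NAT pairs of each orientation
subtype, trans-NAT partner genes on different chromosomes, and plain
non-NAT genes) on random-sequence chromosomes, then emits every file
format the pipeline reads: GFF3 annotation, genome and transcript FASTA,
small-RNA hit tables, chromatin tile BED, per-cytosine methylation calls,
an expression matrix, a dsRNA read track, an ncRNA exclusion BED and a
lncRNA-candidate table.  A truth table records every planted pair with
its subtype, duplex coordinates, realized siRNA status and epigenetic
pattern class, so recovery tests are exact.

Planted structure:

* cis geometry is constructed literally per the orientation definitions;
  intergenic gaps always exceed the nearby-gap cutoff so no unintended
  pair can arise;
* trans pairs are built by copying the reverse complement of a segment of
  one transcript into its partner's locus on another chromosome; an
  optional "bubble" mutates a centered run of the copy to a configurable
  fraction of the region;
* small-RNA loci are drawn at Poisson rate ``sirna_overlap_rate`` per nt
  inside duplex regions and ``sirna_background_rate`` elsewhere in gene
  spans, each locus observed per data set with probability
  ``dataset_presence`` (so duplex loci recur across data sets);
* histone-mark states are drawn per gene, with NAT pair members sharing
  their G1/G2 state with probability ``epigenetic_concordance``; tiles
  for overlapping cis pairs are laid on each member's exclusive span so
  the planted state is exactly recoverable (containing pairs, whose inner
  gene has no exclusive span, are forced concordant);
* methylation bin levels follow a per-region latent profile drawn from a
  Beta distribution per context, shared (plus noise) between pair genes;
* expression is bivariate log-normal with correlation ``expression_rho``
  for pair genes.

Everything is deterministic given the seed: per-layer RNG streams are
spawned from one root ``SeedSequence`` so regenerating one layer never
perturbs another.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_io import (ChromatinTile, GenomicInterval, MethylationSite,
                        SmallRnaRead, TranscriptRecord, write_coding_table,
                        write_expression_matrix, write_bed_intervals,
                        write_fasta, write_gff3, write_methylation_table,
                        write_smrna_table, write_tiles, write_tsv,
                        extract_transcript_sequence)

ALL_LAYERS = frozenset(
    {"annotation", "smrna", "tiles", "methylation", "expression", "dsrna",
     "candidates"}
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_ROTATE = {"A": "C", "C": "G", "G": "T", "T": "A"}  # guaranteed non-identical

TISSUE_CYCLE = ("seedling", "leaf", "flower", "root")
NPC_BIOTYPES = ("lncRNA", "TE", "other_NPC", "pseudogene")


def _revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


@dataclass
class SynthConfig:
    """Study conditions for one synthetic bundle."""

    seed: int = 0
    n_chromosomes: int = 4
    chrom_length: int = 750_000

    # planted pair counts
    n_convergent: int = 12
    n_divergent: int = 12
    n_containing: int = 12
    n_nearby_head: int = 6
    n_nearby_tail: int = 6
    n_trans_pairs: int = 15
    n_non_nat_genes: int = 400

    # geometry (nt)
    gene_length_range: tuple[int, int] = (800, 2000)
    overlap_length_range: tuple[int, int] = (150, 400)
    nearby_gap_range: tuple[int, int] = (20, 80)
    intergenic_gap_range: tuple[int, int] = (250, 600)
    trans_region_length: int = 300
    trans_bubble_frac: float = 0.0

    # biotypes
    pc_prob_pair_member: float = 0.6
    biotype_mix: dict = field(default_factory=lambda: {
        "PC": 0.70, "TE": 0.10, "lncRNA": 0.06, "other_NPC": 0.08,
        "pseudogene": 0.04, "tRNA": 0.02,
    })

    # small RNA
    sirna_overlap_rate: float = 0.10      # loci per nt in duplex regions
    sirna_background_rate: float = 0.02   # loci per nt elsewhere in genes
    n_smrna_datasets: int = 6
    dataset_presence: float = 0.8
    sirna_length_mass_21: float = 0.40
    sirna_length_mass_24: float = 0.30

    # chromatin
    epigenetic_concordance: float = 0.9
    state_baseline: dict = field(default_factory=lambda: {
        "G1": 0.50, "G2": 0.30, "G1+G2": 0.10, "NON": 0.10,
    })
    tile_length: int = 200

    # methylation
    meth_beta_params: dict = field(default_factory=lambda: {
        "CG": (3.0, 2.0), "CHG": (2.0, 3.0), "CHH": (1.2, 6.0),
    })
    meth_noise_sd: float = 0.05
    meth_profile_sd: float = 0.10
    meth_site_spacing: int = 30
    meth_coverage: int = 20
    meth_n_bins: int = 20

    # expression
    n_expression_samples: int = 15
    expression_rho: float = 0.9
    expression_log_sigma: float = 0.8
    expression_missing_rate: float = 0.05

    # dsRNA track
    dsrna_background_rate: float = 0.01
    dsrna_fold: float = 3.0
    dsrna_read_length: int = 80

    def __post_init__(self):
        counts = [self.n_convergent, self.n_divergent, self.n_containing,
                  self.n_nearby_head, self.n_nearby_tail, self.n_trans_pairs,
                  self.n_non_nat_genes]
        if any(c < 0 for c in counts):
            raise ValueError("planted counts must be >= 0")
        rates = [self.sirna_overlap_rate, self.sirna_background_rate,
                 self.dsrna_background_rate]
        if any(r < 0 for r in rates):
            raise ValueError("rates must be >= 0")
        probs = [self.dataset_presence, self.epigenetic_concordance,
                 self.expression_missing_rate, self.pc_prob_pair_member]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if not 0 <= self.trans_bubble_frac < 1:
            raise ValueError("trans_bubble_frac must lie in [0, 1)")

    @classmethod
    def small(cls, seed: int = 0, **overrides) -> "SynthConfig":
        """A light preset for Monte-Carlo tests over many seeds."""
        base = dict(
            seed=seed, n_chromosomes=2, chrom_length=120_000,
            n_convergent=5, n_divergent=5, n_containing=5,
            n_nearby_head=2, n_nearby_tail=2, n_trans_pairs=3,
            n_non_nat_genes=60,
        )
        base.update(overrides)
        return cls(**base)


# ---------------------------------------------------------------------------
# Internal layout records
# ---------------------------------------------------------------------------

@dataclass
class _Unit:
    kind: str            # cis subtype | "single"
    transcripts: list    # (gene_id, rel_start, rel_end, strand, biotype)
    width: int
    pair_meta: dict = field(default_factory=dict)
    chrom: str = ""
    offset: int = 0


@dataclass
class PlantedPair:
    pair_id: str
    kind: str            # cis subtype or "trans"
    tx_a: str
    tx_b: str
    coding_class: str
    chrom_a: str = ""
    chrom_b: str = ""
    overlap: tuple[int, int] | None = None
    gap: int | None = None
    trans_region_a: tuple[int, int] | None = None  # transcript coords on A
    trans_region_b: tuple[int, int] | None = None
    n_planted_sirna: int = 0
    state_a: str = ""
    state_b: str = ""
    pattern_class: str = ""


class _Streams:
    """Named child RNG streams derived from one root seed."""

    _ORDER = ("layout", "biotype", "sequence", "trans", "smrna", "tiles",
              "methylation", "expression", "dsrna", "candidates")

    def __init__(self, seed: int):
        root = np.random.SeedSequence(seed)
        children = root.spawn(len(self._ORDER))
        for name, child in zip(self._ORDER, children):
            setattr(self, name, np.random.default_rng(child))


# ---------------------------------------------------------------------------
# Gene layout
# ---------------------------------------------------------------------------

def _sample_biotype(rng, config: SynthConfig, pair_member: bool) -> str:
    if pair_member:
        if rng.random() < config.pc_prob_pair_member:
            return "PC"
        return NPC_BIOTYPES[rng.integers(len(NPC_BIOTYPES))]
    names = sorted(config.biotype_mix)
    probs = np.array([config.biotype_mix[n] for n in names], float)
    return names[rng.choice(len(names), p=probs / probs.sum())]


def _coding_class(bio_a: str, bio_b: str) -> str:
    ca = "PC" if bio_a == "PC" else "NPC"
    cb = "PC" if bio_b == "PC" else "NPC"
    first, second = sorted([ca, cb], reverse=True)
    return f"{first}/{second}"


def _build_units(config: SynthConfig, rng, rng_bio
                 ) -> tuple[list[_Unit], list[PlantedPair]]:
    units: list[_Unit] = []
    pairs: list[PlantedPair] = []
    gene_counter = 0

    def next_gene() -> str:
        nonlocal gene_counter
        gene_counter += 1
        return f"g{gene_counter:04d}"

    def lengths() -> tuple[int, int]:
        lo, hi = config.gene_length_range
        return int(rng.integers(lo, hi + 1)), int(rng.integers(lo, hi + 1))

    def overlap_len(la: int, lb: int) -> int:
        lo, hi = config.overlap_length_range
        # Keep each member's exclusive span >= 400 nt so chromatin domains
        # on exclusive spans survive the minimum-domain filter.
        hi = min(hi, la - 400, lb - 400)
        if hi < lo:
            raise ValueError(
                "gene_length_range too small for overlap_length_range"
            )
        return int(rng.integers(lo, hi + 1))

    def make_pair(subtype: str) -> None:
        ga, gb = next_gene(), next_gene()
        bio_a = _sample_biotype(rng_bio, config, True)
        bio_b = _sample_biotype(rng_bio, config, True)
        la, lb = lengths()
        if subtype == "convergent":
            ov = overlap_len(la, lb)
            txs = [(ga, 0, la, "+", bio_a), (gb, la - ov, la - ov + lb, "-", bio_b)]
            overlap = (la - ov, la)
            gap = None
        elif subtype == "divergent":
            ov = overlap_len(la, lb)
            txs = [(gb, 0, lb, "-", bio_b), (ga, lb - ov, lb - ov + la, "+", bio_a)]
            overlap = (lb - ov, lb)
            gap = None
        elif subtype == "containing":
            lb = int(rng.integers(300, 501))
            la = max(la, lb + 300)
            off = int(rng.integers(100, la - lb - 100 + 1))
            txs = [(ga, 0, la, "+", bio_a), (gb, off, off + lb, "-", bio_b)]
            overlap = (off, off + lb)
            gap = None
        elif subtype == "nearby_tail_to_tail":
            gap = int(rng.integers(*config.nearby_gap_range))
            txs = [(ga, 0, la, "+", bio_a), (gb, la + gap, la + gap + lb, "-", bio_b)]
            overlap = None
        elif subtype == "nearby_head_to_head":
            gap = int(rng.integers(*config.nearby_gap_range))
            txs = [(gb, 0, lb, "-", bio_b), (ga, lb + gap, lb + gap + la, "+", bio_a)]
            overlap = None
        else:
            raise AssertionError(subtype)
        width = max(t[2] for t in txs)
        ta, tb = f"{ga}.1", f"{gb}.1"
        units.append(_Unit(kind=subtype, transcripts=txs, width=width,
                           pair_meta={"pair_index": len(pairs)}))
        pairs.append(PlantedPair(
            pair_id="|".join(sorted([ta, tb])), kind=subtype,
            tx_a=ta, tx_b=tb, coding_class=_coding_class(bio_a, bio_b),
            overlap=overlap, gap=gap,
        ))

    for _ in range(config.n_convergent):
        make_pair("convergent")
    for _ in range(config.n_divergent):
        make_pair("divergent")
    for _ in range(config.n_containing):
        make_pair("containing")
    for _ in range(config.n_nearby_head):
        make_pair("nearby_head_to_head")
    for _ in range(config.n_nearby_tail):
        make_pair("nearby_tail_to_tail")

    for _ in range(config.n_trans_pairs):
        ga, gb = next_gene(), next_gene()
        bio_a = _sample_biotype(rng_bio, config, True)
        bio_b = _sample_biotype(rng_bio, config, True)
        la, lb = lengths()
        la = max(la, config.trans_region_length + 200)
        lb = max(lb, config.trans_region_length + 200)
        strand_b = "+" if rng.random() < 0.5 else "-"
        pair_index = len(pairs)
        units.append(_Unit(kind="single", width=la,
                           transcripts=[(ga, 0, la, "+", bio_a)],
                           pair_meta={"trans_role": "a",
                                      "pair_index": pair_index}))
        units.append(_Unit(kind="single", width=lb,
                           transcripts=[(gb, 0, lb, strand_b, bio_b)],
                           pair_meta={"trans_role": "b",
                                      "pair_index": pair_index}))
        ta, tb = f"{ga}.1", f"{gb}.1"
        pairs.append(PlantedPair(
            pair_id="|".join(sorted([ta, tb])), kind="trans",
            tx_a=ta, tx_b=tb, coding_class=_coding_class(bio_a, bio_b),
        ))

    for _ in range(config.n_non_nat_genes):
        g = next_gene()
        bio = _sample_biotype(rng_bio, config, False)
        length = int(rng.integers(*config.gene_length_range))
        strand = "+" if rng.random() < 0.5 else "-"
        units.append(_Unit(kind="single", width=length,
                           transcripts=[(g, 0, length, strand, bio)]))
    return units, pairs


def _place_units(units: list[_Unit], config: SynthConfig, rng) -> None:
    """Greedy balanced placement; trans partners land on distinct
    chromosomes.  Raises before any file is written when a chromosome
    would overflow."""
    margin = 1200
    cursors = {f"chr{i + 1}": margin for i in range(config.n_chromosomes)}
    order = np.arange(len(units))
    rng.shuffle(order)
    trans_a_chrom: dict[int, str] = {}
    for idx in order:
        unit = units[idx]
        forbidden = None
        role = unit.pair_meta.get("trans_role")
        if role == "b":
            forbidden = trans_a_chrom.get(unit.pair_meta["pair_index"])
        candidates = sorted(
            (c for c in cursors if c != forbidden),
            key=lambda c: (cursors[c], c),
        )
        if not candidates:
            raise ValueError("need at least 2 chromosomes for trans pairs")
        chrom = candidates[0]
        gap = int(rng.integers(*config.intergenic_gap_range))
        start = cursors[chrom] + gap
        end = start + unit.width
        if end + margin > config.chrom_length:
            raise ValueError(
                f"planted geometry does not fit on {chrom} "
                f"(need > {end + margin} nt, have {config.chrom_length})"
            )
        unit.chrom, unit.offset = chrom, start
        cursors[chrom] = end
        if role == "a":
            trans_a_chrom[unit.pair_meta["pair_index"]] = chrom


def _units_to_transcripts(units: list[_Unit]) -> list[TranscriptRecord]:
    out = []
    for unit in units:
        for gene_id, rel_start, rel_end, strand, biotype in unit.transcripts:
            iv = GenomicInterval(unit.chrom, unit.offset + rel_start,
                                 unit.offset + rel_end, strand)
            cds = None
            if biotype == "PC":
                pad = max(100, iv.length() // 5)
                if iv.length() >= 2 * pad + 60:
                    cds = GenomicInterval(iv.chrom, iv.start + pad,
                                          iv.end - pad, strand)
            out.append(TranscriptRecord(
                transcript_id=f"{gene_id}.1", gene_id=gene_id,
                interval=iv, biotype=biotype, exons=[iv], cds=cds,
            ))
    out.sort(key=lambda t: (t.chrom, t.interval.start, t.transcript_id))
    return out


# ---------------------------------------------------------------------------
# Bundle generation
# ---------------------------------------------------------------------------

class SynthBundle:
    """In-memory result of one generation run (files optional)."""

    def __init__(self):
        self.transcripts: list[TranscriptRecord] = []
        self.genome: dict[str, str] = {}
        self.pairs: list[PlantedPair] = []
        self.reads: list[SmallRnaRead] = []
        self.exclusion: list[GenomicInterval] = []
        self.tiles: list[ChromatinTile] = []
        self.meth_sites: list[MethylationSite] = []
        self.expression: pd.DataFrame | None = None
        self.dsrna: list[GenomicInterval] = []
        self.candidates: pd.DataFrame | None = None
        self.candidate_seqs: dict[str, str] = {}
        self.truth: pd.DataFrame | None = None
        self.paths: dict[str, Path] = {}


def _duplex_regions(pair: PlantedPair,
                    tx_by_id: dict[str, TranscriptRecord]
                    ) -> list[GenomicInterval]:
    """Genomic duplex regions of a planted pair (empty for nearby)."""
    if pair.kind == "trans":
        out = []
        for tid, region in ((pair.tx_a, pair.trans_region_a),
                            (pair.tx_b, pair.trans_region_b)):
            tx = tx_by_id[tid]
            t_lo, t_hi = region
            if tx.strand == "-":
                g_lo = tx.interval.end - t_hi
                g_hi = tx.interval.end - t_lo
            else:
                g_lo = tx.interval.start + t_lo
                g_hi = tx.interval.start + t_hi
            out.append(GenomicInterval(tx.chrom, g_lo, g_hi, tx.strand))
        return out
    if pair.overlap is None:
        return []
    chrom = tx_by_id[pair.tx_a].chrom
    return [GenomicInterval(chrom, pair.overlap[0], pair.overlap[1], ".")]


def generate_bundle(
    config: SynthConfig,
    out_dir: str | Path | None = None,
    layers: frozenset[str] | set[str] = ALL_LAYERS,
) -> SynthBundle:
    """Generate a complete synthetic bundle.

    ``layers`` restricts which data layers are generated (the annotation
    and genome are always produced).  With ``out_dir`` set, every layer is
    also written in the formats the pipeline readers expect, plus
    ``truth.tsv``; generation is byte-deterministic given the seed.
    """
    streams = _Streams(config.seed)
    bundle = SynthBundle()

    units, pairs = _build_units(config, streams.layout, streams.biotype)
    _place_units(units, config, streams.layout)
    transcripts = _units_to_transcripts(units)
    tx_by_id = {t.transcript_id: t for t in transcripts}

    # absolute coordinates for planted cis pairs
    unit_of_gene = {}
    for unit in units:
        for gene_id, *_ in unit.transcripts:
            unit_of_gene[gene_id] = unit
    for pair in pairs:
        a, b = tx_by_id[pair.tx_a], tx_by_id[pair.tx_b]
        pair.chrom_a, pair.chrom_b = a.chrom, b.chrom
        if pair.overlap is not None:
            off = unit_of_gene[a.gene_id].offset
            pair.overlap = (pair.overlap[0] + off, pair.overlap[1] + off)

    # genome sequence
    for i in range(config.n_chromosomes):
        chrom = f"chr{i + 1}"
        idx = streams.sequence.integers(0, 4, size=config.chrom_length)
        bundle.genome[chrom] = _BASES[idx].tobytes().decode()

    _plant_trans_complementarity(config, streams.trans, pairs, tx_by_id,
                                 bundle.genome)

    bundle.transcripts = transcripts
    bundle.pairs = pairs

    if "smrna" in layers:
        _generate_smrna(config, streams.smrna, bundle, tx_by_id)
    if "tiles" in layers:
        _generate_tiles(config, streams.tiles, bundle, tx_by_id)
    if "methylation" in layers:
        _generate_methylation(config, streams.methylation, bundle, tx_by_id)
    if "candidates" in layers:
        _generate_candidates(config, streams.candidates, bundle)
    if "expression" in layers:
        _generate_expression(config, streams.expression, bundle, tx_by_id)
    if "dsrna" in layers:
        _generate_dsrna(config, streams.dsrna, bundle, tx_by_id)

    bundle.truth = _truth_frame(bundle)
    if out_dir is not None:
        _write_bundle(config, bundle, Path(out_dir), layers)
    return bundle


def _plant_trans_complementarity(config, rng, pairs, tx_by_id, genome):
    L = config.trans_region_length
    for pair in pairs:
        if pair.kind != "trans":
            continue
        a, b = tx_by_id[pair.tx_a], tx_by_id[pair.tx_b]
        la, lb = a.span_length(), b.span_length()
        off_a = int(rng.integers(100, la - L - 100 + 1))
        off_b = int(rng.integers(100, lb - L - 100 + 1))
        # a is always on '+': its transcript equals the genome slice
        segment = genome[a.chrom][a.interval.start + off_a:
                                  a.interval.start + off_a + L]
        paired = segment
        if config.trans_bubble_frac > 0:
            run = int(round(config.trans_bubble_frac * L))
            lo = (L - run) // 2
            paired = (segment[:lo]
                      + "".join(_ROTATE[c] for c in segment[lo:lo + run])
                      + segment[lo + run:])
        # B's transcript must contain revcomp(segment) (with the bubble
        # run left unpaired) at transcript offset off_b.
        if b.strand == "-":
            g_lo = b.interval.end - off_b - L
            content = paired
        else:
            g_lo = b.interval.start + off_b
            content = _revcomp(paired)
        chrom_seq = genome[b.chrom]
        genome[b.chrom] = (chrom_seq[:g_lo] + content
                           + chrom_seq[g_lo + L:])
        pair.trans_region_a = (off_a, off_a + L)
        pair.trans_region_b = (off_b, off_b + L)


def _length_weights(config) -> tuple[np.ndarray, np.ndarray]:
    lengths = np.arange(18, 29)
    rest = 1.0 - config.sirna_length_mass_21 - config.sirna_length_mass_24
    weights = np.full(len(lengths), rest / (len(lengths) - 2))
    weights[lengths == 21] = config.sirna_length_mass_21
    weights[lengths == 24] = config.sirna_length_mass_24
    return lengths, weights / weights.sum()


def _generate_smrna(config, rng, bundle: SynthBundle, tx_by_id):
    lengths, weights = _length_weights(config)
    n_ds = config.n_smrna_datasets
    datasets = [f"d{i + 1:02d}" for i in range(n_ds)]
    tissues = {ds: TISSUE_CYCLE[i % len(TISSUE_CYCLE)]
               for i, ds in enumerate(datasets)}

    loci: list[tuple[GenomicInterval, np.ndarray, int | None]] = []
    seen_loci: set[tuple[str, int, int, str]] = set()

    def draw_loci(region: GenomicInterval, rate: float,
                  strands: list[str], pair_idx: int | None):
        n = rng.poisson(rate * region.length())
        for _ in range(n):
            ln = int(rng.choice(lengths, p=weights))
            if region.length() <= ln:
                continue
            start = int(rng.integers(region.start, region.end - ln + 1))
            strand = strands[rng.integers(len(strands))]
            key = (region.chrom, start, ln, strand)
            if key in seen_loci:   # keep loci distinct (Poisson thinning)
                continue
            seen_loci.add(key)
            presence = rng.random(n_ds) < config.dataset_presence
            if not presence.any():
                presence[rng.integers(n_ds)] = True
            loci.append((GenomicInterval(region.chrom, start, start + ln,
                                         strand), presence, pair_idx))

    # duplex-region loci (shared across data sets -> recur in >= 3 of them)
    for i, pair in enumerate(bundle.pairs):
        strands = [tx_by_id[pair.tx_a].strand, tx_by_id[pair.tx_b].strand]
        for region in _duplex_regions(pair, tx_by_id):
            draw_loci(region, config.sirna_overlap_rate, strands, i)

    # background loci over the non-duplex parts of every gene span
    duplex_by_chrom: dict[str, list[GenomicInterval]] = {}
    for pair in bundle.pairs:
        for region in _duplex_regions(pair, tx_by_id):
            duplex_by_chrom.setdefault(region.chrom, []).append(region)
    for tx in bundle.transcripts:
        span = tx.interval
        segments, cursor = [], span.start
        holes = sorted(
            (h for h in duplex_by_chrom.get(span.chrom, ())
             if h.start < span.end and span.start < h.end),
            key=lambda h: h.start,
        )
        for h in holes:
            if h.start > cursor:
                segments.append((cursor, h.start))
            cursor = max(cursor, h.end)
        if cursor < span.end:
            segments.append((cursor, span.end))
        for lo, hi in segments:
            if hi - lo > 40:
                draw_loci(GenomicInterval(span.chrom, lo, hi, span.strand),
                          config.sirna_background_rate, [span.strand], None)

    # realized planted-siRNA truth: locus in a duplex region observed in
    # >= 3 data sets
    for iv, presence, pair_idx in loci:
        if pair_idx is not None and presence.sum() >= 3:
            bundle.pairs[pair_idx].n_planted_sirna += 1

    reads: list[SmallRnaRead] = []
    counter = 0
    for iv, presence, _ in loci:
        seq = bundle.genome[iv.chrom][iv.start:iv.end]
        if iv.strand == "-":
            seq = _revcomp(seq)
        counter += 1
        for ds_i, present in enumerate(presence):
            if not present:
                continue
            ds = datasets[ds_i]
            reads.append(SmallRnaRead(
                read_id=f"L{counter:06d}", sequence=seq, hits=[iv],
                dataset_id=ds, tissue=tissues[ds], count=1,
            ))

    # excluded structural ncRNA loci (rRNA-like) in intergenic space, and
    # a few multi-mappers, to exercise the library filters
    # the trailing 1200 nt of each chromosome are guaranteed gene-free
    chrom1 = "chr1"
    for j in range(5):
        lo = config.chrom_length - 1100 + 200 * j
        self_iv = GenomicInterval(chrom1, lo, lo + 100, "+")
        bundle.exclusion.append(self_iv)
        read_iv = GenomicInterval(chrom1, lo + 10, lo + 31, "+")
        seq = bundle.genome[chrom1][read_iv.start:read_iv.end]
        for ds in datasets[:4]:
            reads.append(SmallRnaRead(
                read_id=f"X{j:03d}", sequence=seq, hits=[read_iv],
                dataset_id=ds, tissue=tissues[ds], count=1,
            ))
    for j in range(3):
        lo = 100 + 50 * j
        hits = [GenomicInterval(chrom1, lo, lo + 21, "+"),
                GenomicInterval(chrom1, lo + 5000, lo + 5021, "+")]
        seq = bundle.genome[chrom1][lo:lo + 21]
        reads.append(SmallRnaRead(
            read_id=f"M{j:03d}", sequence=seq, hits=hits,
            dataset_id=datasets[0], tissue=tissues[datasets[0]], count=1,
        ))
    bundle.reads = reads


def _draw_state(rng, baseline: dict) -> str:
    names = sorted(baseline)
    probs = np.array([baseline[n] for n in names], float)
    return names[rng.choice(len(names), p=probs / probs.sum())]


_STATE_MARKS = {
    "G1": ("H3K4me3", "H3K36me3"),
    "G2": ("H3K27me3",),
    "G1+G2": ("H3K4me3", "H3K27me3"),
    "NON": (),
}


def _generate_tiles(config, rng, bundle: SynthBundle, tx_by_id):
    states: dict[str, str] = {}
    for pair in bundle.pairs:
        state_a = _draw_state(rng, config.state_baseline)
        if pair.kind == "containing":
            # the inner gene has no exclusive span, so its chromatin is
            # inseparable from the host's: forced concordant
            state_b = state_a
        elif rng.random() < config.epigenetic_concordance:
            state_b = state_a
        else:
            state_b = _draw_state(rng, config.state_baseline)
        states[pair.tx_a], states[pair.tx_b] = state_a, state_b
        pair.state_a, pair.state_b = state_a, state_b
        pair.pattern_class = _pattern_label(state_a, state_b)
    for tx in bundle.transcripts:
        if tx.transcript_id not in states:
            states[tx.transcript_id] = _draw_state(rng, config.state_baseline)

    # tile target span: exclusive span for overlapping cis members
    overlap_of: dict[str, tuple[int, int]] = {}
    for pair in bundle.pairs:
        if pair.overlap is not None and pair.kind != "containing":
            overlap_of[pair.tx_a] = pair.overlap
            overlap_of[pair.tx_b] = pair.overlap

    tiles: list[ChromatinTile] = []
    for tx in bundle.transcripts:
        span = tx.interval
        lo, hi = span.start, span.end
        if tx.transcript_id in overlap_of:
            o_lo, o_hi = overlap_of[tx.transcript_id]
            if lo < o_lo:          # exclusive part is on the left
                hi = min(hi, o_lo)
            else:                  # exclusive part is on the right
                lo = max(lo, o_hi)
        for mark in _STATE_MARKS[states[tx.transcript_id]]:
            pos = lo
            while pos < hi:
                end = min(pos + config.tile_length, hi)
                tiles.append(ChromatinTile(
                    mark, GenomicInterval(span.chrom, pos, end, ".")))
                pos = end
    bundle.tiles = tiles


def _pattern_label(state_a: str, state_b: str) -> str:
    order = ("G1+G2", "G1", "G2", "NON")
    rank = {s: i for i, s in enumerate(order)}
    first, second = sorted((state_a, state_b), key=rank.__getitem__)
    return f"{first}_{second}"


def _generate_methylation(config, rng, bundle: SynthBundle, tx_by_id):
    n_bins = config.meth_n_bins
    contexts = sorted(config.meth_beta_params)

    # latent per-(gene, region, context) bin profiles; pair members share
    # the partner's profile plus noise
    latent: dict[tuple[str, str, str], np.ndarray] = {}

    def base_profile(context: str) -> np.ndarray:
        a, b = config.meth_beta_params[context]
        mean = rng.beta(a, b)
        prof = mean + rng.normal(0.0, config.meth_profile_sd, n_bins)
        return np.clip(prof, 0.01, 0.99)

    def partner_profile(prof: np.ndarray) -> np.ndarray:
        noisy = prof + rng.normal(0.0, config.meth_noise_sd, n_bins)
        return np.clip(noisy, 0.01, 0.99)

    paired_ids = set()
    for pair in bundle.pairs:
        for region in ("body", "promoter"):
            for context in contexts:
                prof = base_profile(context)
                latent[(pair.tx_a, region, context)] = prof
                latent[(pair.tx_b, region, context)] = partner_profile(prof)
        paired_ids.update((pair.tx_a, pair.tx_b))
    for tx in bundle.transcripts:
        if tx.transcript_id in paired_ids:
            continue
        for region in ("body", "promoter"):
            for context in contexts:
                latent[(tx.transcript_id, region, context)] = \
                    base_profile(context)

    emitted: set[tuple[str, int, str]] = set()
    sites: list[MethylationSite] = []
    for tx in bundle.transcripts:
        span = tx.interval
        regions = {"body": (span.start, span.end)}
        if span.strand == "-":
            regions["promoter"] = (span.end, span.end + 1000)
        else:
            regions["promoter"] = (max(0, span.start - 1000), span.start)
        for region, (lo, hi) in regions.items():
            if hi <= lo:
                continue
            edges = np.linspace(lo, hi, n_bins + 1)
            for ci, context in enumerate(contexts):
                prof = latent[(tx.transcript_id, region, context)]
                if span.strand == "-":
                    prof = prof[::-1]  # stored 5'->3'; emit genomically
                start = lo + 7 * ci + 1
                for pos in range(start, hi, config.meth_site_spacing):
                    key = (span.chrom, pos, context)
                    if key in emitted:
                        continue
                    emitted.add(key)
                    b = min(int(np.searchsorted(edges, pos, "right")) - 1,
                            n_bins - 1)
                    level = prof[b]
                    meth = int(rng.binomial(config.meth_coverage, level))
                    sites.append(MethylationSite(
                        chrom=span.chrom, pos=pos,
                        strand="+" if pos % 2 == 0 else "-",
                        context=context, methylated=meth,
                        total=config.meth_coverage,
                    ))
    bundle.meth_sites = sites


def _generate_expression(config, rng, bundle: SynthBundle, tx_by_id):
    samples = [f"s{i + 1:02d}" for i in range(config.n_expression_samples)]
    mu, sigma = np.log(10.0), config.expression_log_sigma
    rho = config.expression_rho
    rows: dict[str, np.ndarray] = {}
    paired_genes = set()
    for pair in bundle.pairs:
        z = rng.normal(size=config.n_expression_samples)
        e = rng.normal(size=config.n_expression_samples)
        ga = tx_by_id[pair.tx_a].gene_id
        gb = tx_by_id[pair.tx_b].gene_id
        rows[ga] = np.exp(mu + sigma * z)
        rows[gb] = np.exp(mu + sigma * (rho * z + np.sqrt(1 - rho ** 2) * e))
        paired_genes.update((ga, gb))
    for tx in bundle.transcripts:
        if tx.gene_id not in rows:
            rows[tx.gene_id] = np.exp(
                mu + sigma * rng.normal(size=config.n_expression_samples))
    df = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    df.index.name = "transcript_id"
    if config.expression_missing_rate > 0:
        mask = rng.random(df.shape) < config.expression_missing_rate
        # keep >= 3 observed samples per gene so planted pairs stay usable
        for i in range(mask.shape[0]):
            if mask[i].sum() > df.shape[1] - 3:
                mask[i, :] = False
        df = df.mask(mask)
    if bundle.candidates is not None:
        # lncRNA candidates get flat expression (never masked); the
        # designed FPKM value lands in the first sample so the FPKM
        # filter rule is exercised
        cand = {}
        for cid, row in bundle.candidates.iterrows():
            vals = np.full(config.n_expression_samples, 5.0)
            vals[0] = float(row["fpkm"])
            cand[cid] = vals
        cand_df = pd.DataFrame.from_dict(cand, orient="index",
                                         columns=samples)
        cand_df.index.name = "transcript_id"
        df = pd.concat([df, cand_df])
    bundle.expression = df.round(3).sort_index()


def _generate_dsrna(config, rng, bundle: SynthBundle, tx_by_id):
    reads: list[GenomicInterval] = []
    rl = config.dsrna_read_length

    def draw(region: GenomicInterval, rate: float):
        n = rng.poisson(rate * region.length())
        for _ in range(n):
            if region.length() <= rl:
                continue
            start = int(rng.integers(region.start, region.end - rl))
            reads.append(GenomicInterval(region.chrom, start, start + rl, "."))

    duplex = []
    for pair in bundle.pairs:
        duplex.extend(_duplex_regions(pair, tx_by_id))
    for region in duplex:
        draw(region, config.dsrna_fold * config.dsrna_background_rate)
    for tx in bundle.transcripts:
        draw(tx.interval, config.dsrna_background_rate)
    reads.sort(key=lambda r: (r.chrom, r.start))
    bundle.dsrna = reads


def _random_seq(rng, length: int, alphabet: str = "ACGT") -> str:
    letters = np.frombuffer(alphabet.encode(), dtype="S1")
    return letters[rng.integers(0, len(letters), size=length)].tobytes().decode()


def _generate_candidates(config, rng, bundle: SynthBundle):
    """A small designed lncRNA-candidate set: several retained candidates
    plus one failure per filter rule.  ORF-free sequences are built over
    {A,C,T} so no ATG can occur."""
    rows = []
    seqs = {}

    def add(cid, seq, class_code, prob, homolog, fpkm, expect, reason):
        seqs[cid] = seq
        rows.append({
            "transcript_id": cid, "class_code": class_code,
            "coding_prob": prob, "homologous": int(homolog),
            "expected_retained": expect, "design_reason": reason,
            "fpkm": fpkm,
        })

    for i in range(5):
        add(f"c{i + 1:02d}", _random_seq(rng, 400, "ACT"), "u", 0.10, False,
            5.0, True, "passes all filters")
    add("c06", _random_seq(rng, 200, "ACT"), "u", 0.10, False, 5.0,
        False, "length not > 200")
    orf_seq = (_random_seq(rng, 30, "ACT") + "ATG" + "AAA" * 150 + "TAA"
               + _random_seq(rng, 30, "ACT"))
    add("c07", orf_seq, "u", 0.10, False, 5.0, False, "ORF 150 aa > 120")
    add("c08", _random_seq(rng, 400, "ACT"), "u", 0.50, False, 5.0,
        False, "coding_prob >= 0.365")
    add("c09", _random_seq(rng, 400, "ACT"), "u", 0.10, True, 5.0,
        False, "homologous to annotation")
    add("c10", _random_seq(rng, 400, "ACT"), "u", 0.10, False, 1.5,
        False, "FPKM < 2 in a sample")
    add("c11", _random_seq(rng, 400, "ACT"), "=", 0.10, False, 5.0,
        False, "class code not u/x/i")

    bundle.candidates = pd.DataFrame(rows).set_index("transcript_id")
    bundle.candidate_seqs = seqs


def _truth_frame(bundle: SynthBundle) -> pd.DataFrame:
    rows = []
    for p in bundle.pairs:
        rows.append({
            "pair_id": p.pair_id, "kind": p.kind,
            "tx_a": p.tx_a, "tx_b": p.tx_b,
            "coding_class": p.coding_class,
            "chrom_a": p.chrom_a, "chrom_b": p.chrom_b,
            "overlap_start": p.overlap[0] if p.overlap else "",
            "overlap_end": p.overlap[1] if p.overlap else "",
            "gap": p.gap if p.gap is not None else "",
            "trans_region_a": (f"{p.trans_region_a[0]}-{p.trans_region_a[1]}"
                               if p.trans_region_a else ""),
            "trans_region_b": (f"{p.trans_region_b[0]}-{p.trans_region_b[1]}"
                               if p.trans_region_b else ""),
            "n_planted_sirna": p.n_planted_sirna,
            "state_a": p.state_a, "state_b": p.state_b,
            "pattern_class": p.pattern_class,
        })
    return pd.DataFrame(rows)


def truth_table(config: SynthConfig,
                layers: frozenset[str] | set[str] = ALL_LAYERS) -> pd.DataFrame:
    """Regenerate (in memory) and return the planted-truth table for a
    config; identical to the ``truth.tsv`` a bundle write produces."""
    return generate_bundle(config, out_dir=None, layers=layers).truth


def _write_bundle(config: SynthConfig, bundle: SynthBundle, out: Path,
                  layers) -> None:
    out.mkdir(parents=True, exist_ok=True)
    params = {f"config.{k}": v for k, v in sorted(
        dataclasses.asdict(config).items()) if not isinstance(v, dict)}

    write_gff3(bundle.transcripts, out / "annotation.gff3")
    write_fasta(bundle.genome, out / "genome.fa")
    tx_seqs = {
        t.transcript_id: extract_transcript_sequence(bundle.genome, t)
        for t in bundle.transcripts
    }
    write_fasta(tx_seqs, out / "transcripts.fa")
    bundle.paths.update({
        "annotation": out / "annotation.gff3",
        "genome": out / "genome.fa",
        "transcripts": out / "transcripts.fa",
    })

    if "smrna" in layers:
        write_smrna_table(bundle.reads, out / "smrna.tsv", params)
        write_bed_intervals(bundle.exclusion, out / "exclusion.bed")
        bundle.paths["smrna"] = out / "smrna.tsv"
        bundle.paths["exclusion"] = out / "exclusion.bed"
    if "tiles" in layers:
        write_tiles(bundle.tiles, out / "tiles.bed")
        bundle.paths["tiles"] = out / "tiles.bed"
    if "methylation" in layers:
        write_methylation_table(bundle.meth_sites, out / "methylation.tsv",
                                params)
        bundle.paths["methylation"] = out / "methylation.tsv"
    if "expression" in layers:
        write_expression_matrix(bundle.expression, out / "expression.tsv",
                                params)
        bundle.paths["expression"] = out / "expression.tsv"
    if "dsrna" in layers:
        write_bed_intervals(bundle.dsrna, out / "dsrna.bed")
        bundle.paths["dsrna"] = out / "dsrna.bed"
    if "candidates" in layers:
        write_coding_table(bundle.candidates, out / "candidates.tsv", params)
        write_fasta(bundle.candidate_seqs, out / "candidates.fa")
        bundle.paths["candidates"] = out / "candidates.tsv"
        bundle.paths["candidate_seqs"] = out / "candidates.fa"

    write_tsv(bundle.truth, out / "truth.tsv", params)
    bundle.paths["truth"] = out / "truth.tsv"
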