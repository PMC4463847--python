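"""Identification of trans-NAT pairs by reverse-complement alignment.

Trans-NATs are transcribed from separate genomic loci and pair through
partial sequence complementarity.  The search aligns each transcript
against the reverse complement of every other using exact k-mer seeding
followed by gapless maximal-segment extension along each seeded diagonal
(Kadane's maximum-sum segment with match +1 / mismatch -1, which bridges
interior mismatch runs whenever the flanking matches outweigh them).
Candidates need an aligned region of at least ``min_region`` nt at
``min_identity`` identity.

Each candidate duplex is then verified positionally: the two regions are
base-paired position by position (Watson-Crick; optional G:U wobble) and
the maximal unpaired runs ("bubbles") are measured.  A pair is accepted
when no bubble exceeds 10% of the pairing-region length (inclusive
boundary).  No free-energy computation is performed: the acceptance
criterion is purely geometric.

The search/verification thresholds (seed k=13, min_region=100,
min_identity=0.8) have no canonical values and are recorded in outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

from .genome_io import GenomicInterval, TranscriptRecord, write_tsv
from .cis_nat import coding_class_label

DEFAULT_MIN_REGION = 100
DEFAULT_MIN_IDENTITY = 0.8
DEFAULT_SEED_K = 13
DEFAULT_BUBBLE_FRACTION = 0.10

#: (base in A, base in revcomp(B)) combinations counting as paired beyond
#: Watson-Crick equality: G:U wobble pairs in RNA space.
WOBBLE_EQUIV = {("G", "A"), ("T", "C")}


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass
class DuplexAlignment:
    """A positional pairing between a region of A and a region of B.

    Regions are half-open transcript coordinates (5'->3' on each
    transcript).  ``bubbles`` lists the maximal unpaired run lengths
    inside the pairing region.
    """

    transcript_a: str
    transcript_b: str
    region_a: tuple[int, int]
    region_b: tuple[int, int]
    paired_fraction: float
    bubbles: list[int]
    region_length: int

    def __post_init__(self):
        if self.region_length <= 0:
            raise ValueError("zero-length pairing region")
        if not 0.0 <= self.paired_fraction <= 1.0:
            raise ValueError("paired_fraction outside [0, 1]")
        if any(b < 1 for b in self.bubbles):
            raise ValueError("bubble lengths must be >= 1")
        if sum(self.bubbles) > self.region_length:
            raise ValueError("bubbles exceed region length")

    @property
    def max_bubble(self) -> int:
        return max(self.bubbles) if self.bubbles else 0


@dataclass
class TransCandidate:
    """A seed-extend hit between transcript A and revcomp(transcript B)."""

    transcript_a: str
    transcript_b: str
    region_a: tuple[int, int]
    region_b: tuple[int, int]
    score: int
    identity: float

    @property
    def region_length(self) -> int:
        return self.region_a[1] - self.region_a[0]


@dataclass
class TransNatPair:
    transcript_a: str
    transcript_b: str
    duplex: DuplexAlignment
    coding_class: str

    @property
    def pair_id(self) -> str:
        return f"{self.transcript_a}|{self.transcript_b}"


# ---------------------------------------------------------------------------
# Seed-and-extend search
# ---------------------------------------------------------------------------

def _kmer_positions(seq: str, k: int) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        out.setdefault(seq[i:i + k], []).append(i)
    return out


def align_revcomp(seq_a: str, seq_b: str, k: int = DEFAULT_SEED_K
                  ) -> TransCandidate | None:
    """Best gapless local alignment between ``seq_a`` and revcomp(``seq_b``).

    Returns None when the two sequences share no exact k-mer.  Regions are
    reported in the native coordinates of each transcript.
    """
    brc = revcomp(seq_b)
    index = _kmer_positions(seq_a, k)
    diagonals: set[int] = set()
    for j in range(len(brc) - k + 1):
        for i in index.get(brc[j:j + k], ()):
            diagonals.add(i - j)
    if not diagonals:
        return None

    best = None  # (score, -length, lo, hi, diag)
    for d in diagonals:
        lo_i = max(0, d)
        hi_i = min(len(seq_a), len(brc) + d)
        # Kadane's maximum-sum segment along the diagonal.
        run_score, run_start = 0, lo_i
        for i in range(lo_i, hi_i):
            step = 1 if seq_a[i] == brc[i - d] else -1
            if run_score <= 0:
                run_score, run_start = step, i
            else:
                run_score += step
            if best is None or (run_score, -(i + 1 - run_start)) > best[:2]:
                best = (run_score, -(i + 1 - run_start), run_start, i + 1, d)
    if best is None:
        return None
    score, neg_len, lo, hi, d = best
    length = -neg_len
    matches = (length + score) // 2
    region_b = (len(seq_b) - (hi - d), len(seq_b) - (lo - d))
    return TransCandidate(
        transcript_a="", transcript_b="",
        region_a=(lo, hi), region_b=region_b,
        score=score, identity=matches / length,
    )


def complementarity_search(
    sequences: dict[str, str],
    catalog: list[TranscriptRecord] | None = None,
    min_region: int = DEFAULT_MIN_REGION,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    k: int = DEFAULT_SEED_K,
) -> list[TransCandidate]:
    """All-vs-all reverse-complement search over the catalog sequences.

    A shared-k-mer prefilter (global k-mer index over all forward
    sequences, probed with each transcript's reverse complement) keeps the
    search linear in practice.  Self pairs and pairs whose genomic loci
    overlap (cis geometry) are excluded; each unordered pair is reported
    at most once, smaller transcript id first.
    """
    ids = sorted(sequences)
    for tid in ids:
        if sequences[tid] is None or sequences[tid] == "":
            raise ValueError(f"no sequence for transcript {tid}")
    loci = {t.transcript_id: t.interval for t in catalog or []}

    index: dict[str, set[str]] = {}
    for tid in ids:
        seq = sequences[tid]
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i:i + k], set()).add(tid)

    candidate_partners: dict[str, set[str]] = {tid: set() for tid in ids}
    for tid in ids:
        rc = revcomp(sequences[tid])
        partners: set[str] = set()
        for i in range(len(rc) - k + 1):
            partners |= index.get(rc[i:i + k], set())
        partners.discard(tid)
        candidate_partners[tid] = partners

    out: list[TransCandidate] = []
    for a in ids:
        for b in sorted(candidate_partners[a]):
            if b <= a:
                continue
            iv_a, iv_b = loci.get(a), loci.get(b)
            if iv_a is not None and iv_b is not None and iv_a.overlaps(iv_b):
                continue  # cis geometry, handled by the cis stage
            cand = align_revcomp(sequences[a], sequences[b], k=k)
            if cand is None:
                continue
            if cand.region_length >= min_region and cand.identity >= min_identity:
                cand.transcript_a, cand.transcript_b = a, b
                out.append(cand)
    return out


# ---------------------------------------------------------------------------
# Duplex verification
# ---------------------------------------------------------------------------

def verify_duplex(
    candidate: TransCandidate,
    sequences: dict[str, str],
    bubble_fraction: float = DEFAULT_BUBBLE_FRACTION,
    wobble: bool = False,
) -> tuple[DuplexAlignment, bool]:
    """Position-wise pairing of the candidate regions and the bubble rule.

    The region of A is laid against the reverse complement of the region
    of B; a position is paired when the bases are Watson-Crick
    complementary (equality in this frame), optionally also under G:U
    wobble.  Accept iff the longest unpaired run is no longer than
    ``bubble_fraction`` of the region (inclusive boundary).
    """
    a_lo, a_hi = candidate.region_a
    b_lo, b_hi = candidate.region_b
    if a_hi <= a_lo or b_hi <= b_lo:
        raise ValueError("zero-length pairing region")
    sub_a = sequences[candidate.transcript_a][a_lo:a_hi]
    sub_b_rc = revcomp(sequences[candidate.transcript_b][b_lo:b_hi])
    n = min(len(sub_a), len(sub_b_rc))

    bubbles: list[int] = []
    paired = 0
    run = 0
    for i in range(n):
        x, y = sub_a[i], sub_b_rc[i]
        ok = x == y or (wobble and (x, y) in WOBBLE_EQUIV)
        if ok:
            paired += 1
            if run:
                bubbles.append(run)
                run = 0
        else:
            run += 1
    if run:
        bubbles.append(run)

    duplex = DuplexAlignment(
        transcript_a=candidate.transcript_a,
        transcript_b=candidate.transcript_b,
        region_a=(a_lo, a_lo + n),
        region_b=(b_hi - n, b_hi),
        paired_fraction=paired / n,
        bubbles=bubbles,
        region_length=n,
    )
    accepted = duplex.max_bubble <= bubble_fraction * duplex.region_length
    return duplex, accepted


def find_trans_pairs(
    catalog: list[TranscriptRecord],
    sequences: dict[str, str],
    min_region: int = DEFAULT_MIN_REGION,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    bubble_fraction: float = DEFAULT_BUBBLE_FRACTION,
    wobble: bool = False,
    k: int = DEFAULT_SEED_K,
) -> tuple[list[TransNatPair], list[TransCandidate]]:
    """Full trans-NAT stage: search, verify, assemble accepted pairs.

    Returns (accepted pairs, rejected candidates).
    """
    tx_by_id = {t.transcript_id: t for t in catalog}
    candidates = complementarity_search(
        sequences, catalog, min_region=min_region,
        min_identity=min_identity, k=k,
    )
    accepted: list[TransNatPair] = []
    rejected: list[TransCandidate] = []
    for cand in candidates:
        duplex, ok = verify_duplex(cand, sequences,
                                   bubble_fraction=bubble_fraction,
                                   wobble=wobble)
        if ok:
            accepted.append(
                TransNatPair(
                    transcript_a=cand.transcript_a,
                    transcript_b=cand.transcript_b,
                    duplex=duplex,
                    coding_class=coding_class_label(
                        tx_by_id[cand.transcript_a], tx_by_id[cand.transcript_b]
                    ),
                )
            )
        else:
            rejected.append(cand)
    return accepted, rejected


# ---------------------------------------------------------------------------
# Coordinate projection and output
# ---------------------------------------------------------------------------

def transcript_to_genomic(tx: TranscriptRecord, t_start: int,
                          t_end: int) -> GenomicInterval:
    """Project a transcript-coordinate region onto the genome.

    The region must lie within the spliced transcript; for multi-exon
    transcripts the projection spans from the genomic position of the
    first base to that of the last (introns included in the span).
    """
    length = tx.exonic_length()
    if not (0 <= t_start < t_end <= length):
        raise ValueError(
            f"region [{t_start},{t_end}) outside transcript "
            f"{tx.transcript_id} of length {length}"
        )
    positions = []
    for t_pos in (t_start, t_end - 1):
        p = t_pos if tx.strand != "-" else length - 1 - t_pos
        offset = 0
        for e in tx.exons:
            if p < offset + e.length():
                positions.append(e.start + (p - offset))
                break
            offset += e.length()
    g_lo, g_hi = min(positions), max(positions)
    return GenomicInterval(tx.chrom, g_lo, g_hi + 1, tx.strand)


def trans_pairs_to_frame(pairs: list[TransNatPair],
                         tx_by_id: dict[str, TranscriptRecord]) -> pd.DataFrame:
    rows = []
    for p in pairs:
        d = p.duplex
        ga = transcript_to_genomic(tx_by_id[p.transcript_a], *d.region_a)
        gb = transcript_to_genomic(tx_by_id[p.transcript_b], *d.region_b)
        rows.append(
            {
                "pair_id": p.pair_id,
                "transcript_a": p.transcript_a,
                "transcript_b": p.transcript_b,
                "coding_class": p.coding_class,
                "region_a": f"{d.region_a[0]}-{d.region_a[1]}",
                "region_b": f"{d.region_b[0]}-{d.region_b[1]}",
                "genomic_a": f"{ga.chrom}:{ga.start}-{ga.end}",
                "genomic_b": f"{gb.chrom}:{gb.start}-{gb.end}",
                "region_length": d.region_length,
                "paired_fraction": round(d.paired_fraction, 4),
                "max_bubble": d.max_bubble,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "pair_id", "transcript_a", "transcript_b", "coding_class",
            "region_a", "region_b", "genomic_a", "genomic_b",
            "region_length", "paired_fraction", "max_bubble",
        ],
    )


def write_trans_pairs(pairs: list[TransNatPair],
                      tx_by_id: dict[str, TranscriptRecord], path,
                      **params) -> None:
    write_tsv(trans_pairs_to_frame(pairs, tx_by_id), path,
              params={"stage": "trans_nat", **params})
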