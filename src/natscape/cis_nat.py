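"""Identification and orientation classification of cis-NAT pairs.

Two transcripts on opposite strands of the same chromosome form a putative
cis-NAT pair when their genomic spans overlap by at least one base (or,
for the "nearby" subtypes, lie within a small gap of each other).  The
overlap subtypes follow the standard orientation vocabulary:

* convergent  — tail-to-tail: the 3' ends of both transcripts lie inside
  the partner's span, so the overlap joins the two 3' ends;
* divergent   — head-to-head: the 5' ends overlap;
* containing  — one span is fully nested in the other (equal spans are
  classified containing as the tie-break);
* nearby_head_to_head / nearby_tail_to_tail — no overlap, but the facing
  ends across a gap of at most ``nearby_max_gap`` are 5' or 3' ends.

Overlap is computed on full transcript spans by default (an exonic mode is
available), and pairs are deduplicated to gene level keeping the longest
overlap.  The gap cutoff for nearby pairs is a free parameter with no
canonical value; the default of 100 nt is recorded in output headers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .genome_io import GenomicInterval, TranscriptRecord, write_tsv

logger = logging.getLogger("natscape")

OVERLAP_SUBTYPES = ("convergent", "divergent", "containing")
NEARBY_SUBTYPES = ("nearby_head_to_head", "nearby_tail_to_tail")
CIS_SUBTYPES = OVERLAP_SUBTYPES + NEARBY_SUBTYPES

DEFAULT_NEARBY_MAX_GAP = 100  # nt; not a canonical value, logged in outputs
DEFAULT_MIN_OVERLAP = 1


def coding_class_label(a: TranscriptRecord, b: TranscriptRecord) -> str:
    """Unordered PC/NPC pair label."""
    classes = sorted([a.coding_class, b.coding_class], reverse=True)  # PC first
    return f"{classes[0]}/{classes[1]}"


@dataclass
class CisNatPair:
    """A classified cis-NAT pair (transcript ids in lexicographic order)."""

    transcript_a: str
    transcript_b: str
    subtype: str
    interval_a: GenomicInterval
    interval_b: GenomicInterval
    coding_class: str
    overlap: GenomicInterval | None = None
    gap: int | None = None

    def __post_init__(self):
        if self.subtype not in CIS_SUBTYPES:
            raise ValueError(f"unknown cis subtype {self.subtype!r}")
        has_overlap = self.overlap is not None
        if has_overlap != (self.subtype in OVERLAP_SUBTYPES):
            raise ValueError("overlap present iff overlap subtype")
        if (self.gap is not None) != (self.subtype in NEARBY_SUBTYPES):
            raise ValueError("gap present iff nearby subtype")

    @property
    def pair_id(self) -> str:
        return f"{self.transcript_a}|{self.transcript_b}"


def classify_orientation(a: GenomicInterval, b: GenomicInterval,
                         nearby_max_gap: int = DEFAULT_NEARBY_MAX_GAP) -> str:
    """Classify an opposite-strand same-chromosome span pair.

    Raises on same-strand input; raises if the spans neither overlap nor
    lie within ``nearby_max_gap`` of each other.
    """
    if a.strand == b.strand:
        raise ValueError("classify_orientation requires opposite strands")
    if a.chrom != b.chrom:
        raise ValueError("classify_orientation requires one chromosome")
    plus, minus = (a, b) if a.strand == "+" else (b, a)

    if a.contains(b) or b.contains(a):
        return "containing"
    if a.overlaps(b):
        # Not nested: the leftmost span runs into the other.  If the plus
        # transcript is the left one, its 3' end (right edge) and the minus
        # transcript's 3' end (left edge) meet in the overlap: convergent.
        return "convergent" if plus.start < minus.start else "divergent"

    left, right = (a, b) if a.start <= b.start else (b, a)
    gap = right.start - left.end
    if 1 <= gap <= nearby_max_gap:
        # Facing ends across the gap: if plus is on the left its 3' end
        # faces the minus transcript's 3' end (tail-to-tail); otherwise
        # the two 5' ends face each other.
        return ("nearby_tail_to_tail" if plus.start < minus.start
                else "nearby_head_to_head")
    raise ValueError(
        f"spans neither overlap nor lie within {nearby_max_gap} nt"
    )


def _pair_geometry(a: TranscriptRecord, b: TranscriptRecord,
                   nearby_max_gap: int, min_overlap: int):
    """Return (subtype, overlap, gap) or None if not a cis pair."""
    ia, ib = a.interval, b.interval
    if ia.overlaps(ib):
        ov = ia.intersection(ib)
        if ov.length() < min_overlap:
            return None
        return classify_orientation(ia, ib, nearby_max_gap), ov, None
    left, right = (ia, ib) if ia.start <= ib.start else (ib, ia)
    gap = right.start - left.end
    if 1 <= gap <= nearby_max_gap:
        return classify_orientation(ia, ib, nearby_max_gap), None, gap
    return None


def find_cis_pairs(
    catalog: list[TranscriptRecord],
    nearby_max_gap: int = DEFAULT_NEARBY_MAX_GAP,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    exonic: bool = False,
) -> list[CisNatPair]:
    """Emit every opposite-strand transcript pair that overlaps (or lies
    within ``nearby_max_gap``), classified by orientation, deduplicated to
    gene level keeping the pair with the longest overlap.

    ``exonic=True`` additionally requires at least one exon-exon overlap
    for the overlap subtypes (span geometry still sets the subtype).
    """
    by_chrom: dict[str, list[TranscriptRecord]] = {}
    for tx in catalog:
        by_chrom.setdefault(tx.chrom, []).append(tx)

    pairs: list[CisNatPair] = []
    for chrom_txs in by_chrom.values():
        chrom_txs = sorted(chrom_txs, key=lambda t: (t.interval.start,
                                                     t.transcript_id))
        for i, a in enumerate(chrom_txs):
            reach = a.interval.end + nearby_max_gap
            for b in chrom_txs[i + 1:]:
                if b.interval.start > reach:
                    break
                if a.strand == b.strand or a.strand == "." or b.strand == ".":
                    continue
                geom = _pair_geometry(a, b, nearby_max_gap, min_overlap)
                if geom is None:
                    continue
                subtype, overlap, gap = geom
                if exonic and overlap is not None and not _exonic_overlap(a, b):
                    continue
                first, second = sorted([a, b], key=lambda t: t.transcript_id)
                pairs.append(
                    CisNatPair(
                        transcript_a=first.transcript_id,
                        transcript_b=second.transcript_id,
                        subtype=subtype,
                        interval_a=first.interval,
                        interval_b=second.interval,
                        coding_class=coding_class_label(a, b),
                        overlap=overlap,
                        gap=gap,
                    )
                )
    return _dedupe_gene_level(pairs, catalog)


def _exonic_overlap(a: TranscriptRecord, b: TranscriptRecord) -> bool:
    return any(ea.overlaps(eb) for ea in a.exons for eb in b.exons)


def _dedupe_gene_level(pairs: list[CisNatPair],
                       catalog: list[TranscriptRecord]) -> list[CisNatPair]:
    gene_of = {t.transcript_id: t.gene_id for t in catalog}
    best: dict[tuple[str, str], CisNatPair] = {}
    for p in pairs:
        key = tuple(sorted((gene_of[p.transcript_a], gene_of[p.transcript_b])))
        cur = best.get(key)
        if cur is None:
            best[key] = p
            continue
        p_len = p.overlap.length() if p.overlap else 0
        c_len = cur.overlap.length() if cur.overlap else 0
        if (p_len, p.pair_id) > (c_len, cur.pair_id):
            best[key] = p
    out = list(best.values())
    out.sort(key=lambda p: (p.interval_a.chrom, p.interval_a.start, p.pair_id))
    return out


def classify_overlap_position(
    pair: CisNatPair, tx_by_id: dict[str, TranscriptRecord]
) -> dict[str, str]:
    """For each protein-coding member of an overlapping pair, label where
    the overlap sits relative to its CDS: 3'-UTR, 5'-UTR, across-CDS, or
    CDS-internal.  A PC member without CDS annotation is labeled unknown.
    """
    if pair.overlap is None:
        raise ValueError("overlap-position labels require an overlap subtype")
    labels: dict[str, str] = {}
    for tid in (pair.transcript_a, pair.transcript_b):
        tx = tx_by_id[tid]
        if tx.coding_class != "PC":
            continue
        if tx.cds is None:
            logger.warning("PC transcript %s has no CDS annotation", tid)
            labels[tid] = "unknown"
            continue
        labels[tid] = _position_label(pair.overlap, tx.cds, tx.strand)
    return labels


def _position_label(ov: GenomicInterval, cds: GenomicInterval,
                    strand: str) -> str:
    if ov.end <= cds.start:      # overlap entirely left of the CDS
        return "5'-UTR" if strand == "+" else "3'-UTR"
    if ov.start >= cds.end:      # entirely right of the CDS
        return "3'-UTR" if strand == "+" else "5'-UTR"
    if cds.start <= ov.start and ov.end <= cds.end:
        return "CDS-internal"
    # Crosses at least one CDS boundary (spans coding and non-coding).
    return "across-CDS"


def pairs_to_frame(pairs: list[CisNatPair]) -> pd.DataFrame:
    """Tabular view of cis pairs; overlap/gap coordinates are kept 0-based
    half-open internally and written 1-based inclusive for human reading."""
    rows = []
    for p in pairs:
        rows.append(
            {
                "pair_id": p.pair_id,
                "transcript_a": p.transcript_a,
                "transcript_b": p.transcript_b,
                "subtype": p.subtype,
                "coding_class": p.coding_class,
                "chrom": p.interval_a.chrom,
                "overlap_start_1based": p.overlap.start + 1 if p.overlap else "",
                "overlap_end_1based": p.overlap.end if p.overlap else "",
                "overlap_length": p.overlap.length() if p.overlap else 0,
                "gap": p.gap if p.gap is not None else "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "pair_id", "transcript_a", "transcript_b", "subtype",
            "coding_class", "chrom", "overlap_start_1based",
            "overlap_end_1based", "overlap_length", "gap",
        ],
    )


def write_cis_pairs(pairs: list[CisNatPair], path,
                    nearby_max_gap: int = DEFAULT_NEARBY_MAX_GAP,
                    min_overlap: int = DEFAULT_MIN_OVERLAP) -> None:
    write_tsv(
        pairs_to_frame(pairs), path,
        params={
            "stage": "cis_nat",
            "coords": "1-based inclusive",
            "nearby_max_gap": nearby_max_gap,
            "min_overlap": min_overlap,
        },
    )
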