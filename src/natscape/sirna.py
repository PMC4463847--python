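"""Small-RNA library construction and NAT-siRNA calling.

The library keeps reads that (i) do not overlap any excluded structural
ncRNA locus (rRNA, snRNA, snoRNA, miRNA — tRNA loci are deliberately kept),
(ii) map to exactly one genomic locus, and (iii) are 18-28 nt long.

A distinct small-RNA sequence is called a NAT-siRNA when its unique locus
lies fully inside the duplex-forming region of at least one NAT pair (the
genomic overlap for cis pairs; either projected pairing region for trans
pairs) and the same sequence is observed in at least three data sets.
"Unique" NAT-siRNAs come from a producing gene with exactly one NAT
partner; the producing gene of a read is the pair member transcribed on
the read's strand.  Directional subtypes are written producing-first
(e.g. NPC-PC: an NPC gene producing the siRNA against a PC partner).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .genome_io import GenomicInterval, SmallRnaRead, TranscriptRecord, write_tsv
from .cis_nat import CisNatPair
from .trans_nat import TransNatPair, transcript_to_genomic

logger = logging.getLogger("natscape")

DEFAULT_MIN_LEN = 18
DEFAULT_MAX_LEN = 28
DEFAULT_MIN_DATASETS = 3

DIRECTIONAL_SUBTYPES = ("PC-PC", "PC-NPC", "NPC-PC", "NPC-NPC")


@dataclass
class PairRegion:
    """The duplex-forming genomic region(s) of one NAT pair, with the
    member metadata needed to orient called siRNAs."""

    pair_id: str
    nat_type: str                      # "cis" | "trans"
    subtype: str                       # cis orientation subtype or "trans"
    regions: list[GenomicInterval]
    tx_a: str
    tx_b: str
    strand_a: str
    strand_b: str
    class_a: str                       # PC | NPC
    class_b: str


def pair_regions(
    cis_pairs: list[CisNatPair],
    trans_pairs: list[TransNatPair],
    tx_by_id: dict[str, TranscriptRecord],
) -> list[PairRegion]:
    """Duplex regions for downstream siRNA work.  Nearby cis pairs have no
    overlap and are excluded."""
    out = []
    for p in cis_pairs:
        if p.overlap is None:
            continue
        a, b = tx_by_id[p.transcript_a], tx_by_id[p.transcript_b]
        out.append(
            PairRegion(
                pair_id=p.pair_id, nat_type="cis", subtype=p.subtype,
                regions=[p.overlap],
                tx_a=a.transcript_id, tx_b=b.transcript_id,
                strand_a=a.strand, strand_b=b.strand,
                class_a=a.coding_class, class_b=b.coding_class,
            )
        )
    for p in trans_pairs:
        a, b = tx_by_id[p.transcript_a], tx_by_id[p.transcript_b]
        ga = transcript_to_genomic(a, *p.duplex.region_a)
        gb = transcript_to_genomic(b, *p.duplex.region_b)
        out.append(
            PairRegion(
                pair_id=p.pair_id, nat_type="trans", subtype="trans",
                regions=[ga, gb],
                tx_a=a.transcript_id, tx_b=b.transcript_id,
                strand_a=a.strand, strand_b=b.strand,
                class_a=a.coding_class, class_b=b.coding_class,
            )
        )
    return out


@dataclass
class NatSiRna:
    """A called NAT-siRNA: one distinct sequence at one unique locus."""

    sequence: str
    locus: GenomicInterval
    source_pairs: list[str]
    subtypes: list[str]                # producing-first label per source pair
    uniqueness: str                    # "unique" | "nonunique"
    datasets_present: set[str] = field(default_factory=set)
    tissues_present: set[str] = field(default_factory=set)
    ambiguous_producer: bool = False

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def directional_subtype(self) -> str:
        return self.subtypes[0]


# ---------------------------------------------------------------------------
# Library construction
# ---------------------------------------------------------------------------

def build_library(
    reads: list[SmallRnaRead],
    exclusion_loci: list[GenomicInterval] | None = None,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> tuple[list[SmallRnaRead], dict[str, int]]:
    """Filter raw alignments into the working small-RNA library.

    Returns the retained reads and per-filter rejection counts.
    ``exclusion_loci`` is the BED-derived union of rRNA/snRNA/snoRNA/miRNA
    loci; tRNA loci must not be included in it.
    """
    exclusion_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in exclusion_loci or []:
        exclusion_by_chrom.setdefault(iv.chrom, []).append(iv)

    retained = []
    rejected = Counter()
    for read in reads:
        if any(
            hit.start < ex.end and ex.start < hit.end
            for hit in read.hits
            for ex in exclusion_by_chrom.get(hit.chrom, ())
        ):
            rejected["excluded_ncRNA"] += 1
            continue
        if len(read.hits) != 1:
            rejected["multi_mapper"] += 1
            continue
        if not (min_len <= read.length <= max_len):
            rejected["length"] += 1
            continue
        retained.append(read)
    logger.info("smRNA library: kept %d reads, rejected %s",
                len(retained), dict(rejected))
    return retained, dict(rejected)


# ---------------------------------------------------------------------------
# NAT-siRNA calling
# ---------------------------------------------------------------------------

def _partner_counts(regions: list[PairRegion]) -> Counter:
    counts: Counter = Counter()
    for pr in regions:
        counts[pr.tx_a] += 1
        counts[pr.tx_b] += 1
    return counts


def _producing_subtype(pr: PairRegion, read_strand: str) -> tuple[str, str, bool]:
    """(producing transcript, producing-first subtype label, ambiguous).

    The producing transcript is the member transcribed on the read's
    strand.  When both members share the read's strand (possible for
    trans pairs) the assignment is ambiguous and defaults to member A.
    """
    match_a = pr.strand_a == read_strand
    match_b = pr.strand_b == read_strand
    if match_a and match_b:
        return pr.tx_a, f"{pr.class_a}-{pr.class_b}", True
    if match_b:
        return pr.tx_b, f"{pr.class_b}-{pr.class_a}", False
    # Read on A's strand, or (degenerate) matching neither: default to A.
    return pr.tx_a, f"{pr.class_a}-{pr.class_b}", not match_a


def call_nat_sirnas(
    library: list[SmallRnaRead],
    regions: list[PairRegion],
    min_datasets: int = DEFAULT_MIN_DATASETS,
    locus_mode: bool = False,
) -> list[NatSiRna]:
    """Call NAT-siRNAs from the filtered library.

    Reads are grouped by exact sequence across data sets (``locus_mode``
    groups by genomic locus instead); a group is called when its unique
    locus is fully contained in at least one pair region and it appears in
    at least ``min_datasets`` data sets.
    """
    region_by_chrom: dict[str, list[tuple[GenomicInterval, PairRegion]]] = {}
    for pr in regions:
        for iv in pr.regions:
            region_by_chrom.setdefault(iv.chrom, []).append((iv, pr))
    partner_counts = _partner_counts(regions)

    # With unique mapping, a sequence determines its locus, so grouping by
    # (sequence, locus) equals exact-sequence grouping on real data while
    # staying well defined if two loci ever share a sequence.
    groups: dict[tuple, list[SmallRnaRead]] = {}
    for read in library:
        if len(read.hits) != 1:
            continue  # library should be unique-mapping already
        hit = read.hits[0]
        locus_key = (hit.chrom, hit.start, hit.end, hit.strand)
        key = locus_key if locus_mode else (read.sequence, *locus_key)
        groups.setdefault(key, []).append(read)

    called: list[NatSiRna] = []
    for key in sorted(groups):
        reads = groups[key]
        locus = reads[0].hits[0]
        datasets = {r.dataset_id for r in reads}
        if len(datasets) < min_datasets:
            continue
        hosts = [
            pr for iv, pr in region_by_chrom.get(locus.chrom, ())
            if iv.contains(locus)
        ]
        if not hosts:
            continue
        hosts.sort(key=lambda pr: pr.pair_id)
        subtypes, ambiguous = [], False
        producers: set[str] = set()
        for pr in hosts:
            producer, subtype, amb = _producing_subtype(pr, locus.strand)
            producers.add(producer)
            subtypes.append(subtype)
            ambiguous = ambiguous or amb
        if ambiguous:
            logger.info("ambiguous producing transcript for siRNA at %s",
                        locus)
        unique = all(partner_counts[p] == 1 for p in producers)
        called.append(
            NatSiRna(
                sequence=reads[0].sequence,
                locus=locus,
                source_pairs=[pr.pair_id for pr in hosts],
                subtypes=subtypes,
                uniqueness="unique" if unique else "nonunique",
                datasets_present=datasets,
                tissues_present={r.tissue for r in reads},
                ambiguous_producer=ambiguous,
            )
        )
    return called


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def summarize(called: list[NatSiRna],
              regions: list[PairRegion] | None = None) -> dict[str, pd.DataFrame]:
    """Length histogram, unique-siRNA subtype x NAT-type matrix, and
    tissue sharing table."""
    lengths = Counter(s.length for s in called)
    length_hist = pd.DataFrame(
        {"length": sorted(lengths), "count": [lengths[k] for k in sorted(lengths)]}
    )

    nat_type_of = {pr.pair_id: pr.nat_type for pr in regions or []}
    matrix = pd.DataFrame(
        0, index=["cis", "trans"], columns=list(DIRECTIONAL_SUBTYPES)
    )
    for s in called:
        if s.uniqueness != "unique":
            continue
        nat_type = nat_type_of.get(s.source_pairs[0], "cis")
        matrix.loc[nat_type, s.directional_subtype] += 1

    tissue_rows = []
    specific = Counter()
    shared = 0
    for s in called:
        if len(s.tissues_present) == 1:
            specific[next(iter(s.tissues_present))] += 1
        else:
            shared += 1
    for tissue in sorted(specific):
        tissue_rows.append({"category": f"{tissue}_specific",
                            "count": specific[tissue]})
    tissue_rows.append({"category": "shared_across_tissues", "count": shared})
    tissue_table = pd.DataFrame(tissue_rows, columns=["category", "count"])

    return {"length_hist": length_hist, "subtype_matrix": matrix,
            "tissue_table": tissue_table}


def sirnas_to_frame(called: list[NatSiRna]) -> pd.DataFrame:
    rows = [
        {
            "sequence": s.sequence,
            "length": s.length,
            "chrom": s.locus.chrom,
            "start": s.locus.start,
            "end": s.locus.end,
            "strand": s.locus.strand,
            "source_pairs": ",".join(s.source_pairs),
            "directional_subtype": s.directional_subtype,
            "uniqueness": s.uniqueness,
            "n_datasets": len(s.datasets_present),
            "tissues": ",".join(sorted(s.tissues_present)),
        }
        for s in called
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "sequence", "length", "chrom", "start", "end", "strand",
            "source_pairs", "directional_subtype", "uniqueness",
            "n_datasets", "tissues",
        ],
    )


def write_sirnas(called: list[NatSiRna], path, **params) -> None:
    write_tsv(sirnas_to_frame(called), path, params={"stage": "sirna", **params})
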