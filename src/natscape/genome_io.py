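"""Domain types and file I/O for the NAT analysis pipeline.

All internal coordinates are 0-based half-open; the GFF3 1-based inclusive
convention is converted at the I/O boundary and nowhere else.  Minus-strand
transcripts have their 5' end on the ``end`` side of the interval and their
3' end on the ``start`` side; orientation-sensitive code should go through
:meth:`GenomicInterval.five_prime` / :meth:`GenomicInterval.three_prime`
instead of touching raw coordinates.

Formats handled here: GFF3 (annotation), FASTA (genome / transcript
sequences, via Bio.SeqIO), BED4 (chromatin tiles and generic interval
tracks), and headered TSV for small-RNA hits, per-cytosine methylation,
expression matrices and coding-potential scores.  Output TSVs carry a ``#``
comment block recording the parameters they were produced with; readers
skip ``#`` lines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("natscape")

VALID_STRANDS = {"+", "-", "."}
BIOTYPES = {"PC", "lncRNA", "TE", "pseudogene", "tRNA", "other_NPC"}
METH_CONTEXTS = ("CG", "CHG", "CHH")
TISSUES = {"seedling", "leaf", "flower", "root", "other"}

#: GFF3 feature types treated as transcripts, with the biotype each implies
#: when no explicit biotype attribute is present (documented fallback map).
FEATURE_BIOTYPE_FALLBACK = {
    "mRNA": "PC",
    "transcript": "other_NPC",
    "lnc_RNA": "lncRNA",
    "lncRNA": "lncRNA",
    "ncRNA": "other_NPC",
    "tRNA": "tRNA",
    "pseudogenic_transcript": "pseudogene",
    "transposable_element": "TE",
}


class GenomeIOError(ValueError):
    """Raised on malformed input files; message names the offending line."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersection(self, other: "GenomicInterval") -> "GenomicInterval | None":
        if not self.overlaps(other):
            return None
        return GenomicInterval(
            self.chrom, max(self.start, other.start), min(self.end, other.end), "."
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def contains_pos(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def five_prime(self) -> int:
        """Coordinate of the 5' extremity (TSS side for a transcript)."""
        return self.start if self.strand != "-" else self.end

    def three_prime(self) -> int:
        """Coordinate of the 3' extremity."""
        return self.end if self.strand != "-" else self.start


@dataclass
class TranscriptRecord:
    """A stranded transcript with biotype, exon structure and expression.

    ``coding_class`` is PC iff biotype is PC; every other biotype (lncRNA,
    TE, pseudogene, tRNA, other_NPC) is NPC.  Expression is a sparse map
    sample -> FPKM; a sample missing from the map means the transcript was
    not observed there (absent, not zero).
    """

    transcript_id: str
    gene_id: str
    interval: GenomicInterval
    biotype: str = "PC"
    exons: list[GenomicInterval] = field(default_factory=list)
    expression: dict[str, float] = field(default_factory=dict)
    cds: GenomicInterval | None = None

    def __post_init__(self):
        if self.biotype not in BIOTYPES:
            logger.warning(
                "unknown biotype %r for %s mapped to other_NPC",
                self.biotype, self.transcript_id,
            )
            self.biotype = "other_NPC"
        if not self.exons:
            self.exons = [self.interval]
        self.exons.sort(key=lambda e: e.start)
        prev_end = None
        for e in self.exons:
            if not self.interval.contains(e) or e.strand != self.interval.strand:
                raise ValueError(
                    f"exon {e} outside transcript {self.transcript_id}"
                )
            if prev_end is not None and e.start < prev_end:
                raise ValueError(
                    f"overlapping exons in transcript {self.transcript_id}"
                )
            prev_end = e.end

    @property
    def coding_class(self) -> str:
        return "PC" if self.biotype == "PC" else "NPC"

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    def exonic_length(self) -> int:
        return sum(e.length() for e in self.exons)

    def span_length(self) -> int:
        return self.interval.length()


@dataclass
class SmallRnaRead:
    """One small-RNA sequence observed in one data set, with genomic hits."""

    read_id: str
    sequence: str
    hits: list[GenomicInterval]
    dataset_id: str
    tissue: str = "other"
    count: int = 1

    def __post_init__(self):
        for h in self.hits:
            if h.length() != len(self.sequence):
                raise ValueError(
                    f"read {self.read_id}: hit span {h.length()} nt does not "
                    f"match sequence length {len(self.sequence)} nt"
                )
        if self.tissue not in TISSUES:
            self.tissue = "other"

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MethylationSite:
    """A per-cytosine methylation observation."""

    chrom: str
    pos: int
    strand: str
    context: str
    methylated: int
    total: int

    def __post_init__(self):
        if self.context not in METH_CONTEXTS:
            raise ValueError(f"invalid methylation context {self.context!r}")
        if not (0 <= self.methylated <= self.total):
            raise ValueError(
                f"invalid counts methylated={self.methylated} total={self.total} "
                f"at {self.chrom}:{self.pos}"
            )

    @property
    def level(self) -> float:
        return self.methylated / self.total if self.total else float("nan")


@dataclass(frozen=True)
class ChromatinTile:
    """An enriched probe tile for one histone mark (unstranded)."""

    mark: str
    interval: GenomicInterval
    enriched: bool = True


@dataclass(frozen=True)
class ChromatinDomain:
    """A merged run of enriched tiles for one mark."""

    mark: str
    interval: GenomicInterval


# ---------------------------------------------------------------------------
# TSV plumbing
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path, params: dict | None = None,
              index: bool = False) -> None:
    """Write a TSV with a '#' comment block recording run parameters."""
    with open(path, "w") as fh:
        if params:
            for k, v in params.items():
                fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", **kwargs)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _parse_attributes(attr_field: str) -> dict[str, str]:
    out = {}
    for item in attr_field.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key] = value
    return out


def read_gff3(path, biotype_attr: str = "biotype") -> list[TranscriptRecord]:
    """Read transcripts from a GFF3 file.

    Coordinates are converted from GFF3 1-based inclusive to internal
    0-based half-open.  The biotype is taken from ``biotype_attr`` on the
    transcript feature; if absent, it falls back to the feature-type map
    :data:`FEATURE_BIOTYPE_FALLBACK`.  A transcript with no exon features
    gets a single exon synthesized from its span.  CDS features, when
    present, are merged into a single genomic CDS span.
    """
    transcripts: dict[str, TranscriptRecord] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    cds_spans: dict[str, list[int]] = {}
    tx_lines: dict[str, int] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GenomeIOError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise GenomeIOError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if strand not in VALID_STRANDS:
                raise GenomeIOError(
                    f"{path}:{lineno}: unknown strand {strand!r}"
                )
            if start1 < 1 or end1 < start1:
                raise GenomeIOError(
                    f"{path}:{lineno}: invalid span {start1}-{end1}"
                )
            iv = GenomicInterval(chrom, start1 - 1, end1, strand)
            attr = _parse_attributes(attrs)

            if ftype == "gene":
                continue
            if ftype in FEATURE_BIOTYPE_FALLBACK:
                tid = attr.get("ID")
                if tid is None:
                    raise GenomeIOError(
                        f"{path}:{lineno}: transcript feature without ID"
                    )
                biotype = attr.get(biotype_attr, FEATURE_BIOTYPE_FALLBACK[ftype])
                transcripts[tid] = TranscriptRecord(
                    transcript_id=tid,
                    gene_id=attr.get("Parent", tid),
                    interval=iv,
                    biotype=biotype,
                    exons=[iv],  # placeholder, replaced after exon collection
                )
                tx_lines[tid] = lineno
            elif ftype == "exon":
                parent = attr.get("Parent")
                if parent is None:
                    raise GenomeIOError(f"{path}:{lineno}: exon without Parent")
                exons.setdefault(parent, []).append(iv)
            elif ftype == "CDS":
                parent = attr.get("Parent")
                if parent is None:
                    raise GenomeIOError(f"{path}:{lineno}: CDS without Parent")
                cds_spans.setdefault(parent, []).extend((iv.start, iv.end))

    for parent in list(exons) + list(cds_spans):
        if parent not in transcripts:
            raise GenomeIOError(
                f"{path}: orphan exon/CDS feature with Parent={parent!r}"
            )

    out = []
    for tid, tx in transcripts.items():
        ex = sorted(exons.get(tid, []), key=lambda e: e.start)
        cds = None
        if tid in cds_spans:
            pos = cds_spans[tid]
            cds = GenomicInterval(tx.chrom, min(pos), max(pos), tx.strand)
        out.append(replace(tx, exons=ex or [tx.interval], cds=cds))
    out.sort(key=lambda t: (t.chrom, t.interval.start, t.transcript_id))
    return out


def write_gff3(transcripts: list[TranscriptRecord], path) -> None:
    """Write transcripts (with exons, optional CDS) as GFF3."""
    type_by_biotype = {
        "PC": "mRNA", "lncRNA": "lnc_RNA", "TE": "transposable_element",
        "pseudogene": "pseudogenic_transcript", "tRNA": "tRNA",
        "other_NPC": "ncRNA",
    }
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for tx in sorted(
            transcripts, key=lambda t: (t.chrom, t.interval.start, t.transcript_id)
        ):
            iv = tx.interval
            fh.write(
                f"{iv.chrom}\tnatscape\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={tx.gene_id}\n"
            )
            ftype = type_by_biotype[tx.biotype]
            fh.write(
                f"{iv.chrom}\tnatscape\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={tx.transcript_id};Parent={tx.gene_id};"
                f"biotype={tx.biotype}\n"
            )
            for i, e in enumerate(tx.exons, start=1):
                fh.write(
                    f"{e.chrom}\tnatscape\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{e.strand}\t.\tID={tx.transcript_id}.exon{i};"
                    f"Parent={tx.transcript_id}\n"
                )
            if tx.cds is not None:
                c = tx.cds
                fh.write(
                    f"{c.chrom}\tnatscape\tCDS\t{c.start + 1}\t{c.end}\t.\t"
                    f"{c.strand}\t0\tID={tx.transcript_id}.cds;"
                    f"Parent={tx.transcript_id}\n"
                )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def extract_transcript_sequence(genome: dict[str, str], tx: TranscriptRecord) -> str:
    """Spliced transcript sequence, reverse-complemented for '-' strand."""
    chunks = [genome[tx.chrom][e.start:e.end] for e in tx.exons]
    seq = "".join(chunks)
    if tx.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


# ---------------------------------------------------------------------------
# Small-RNA hit table
# ---------------------------------------------------------------------------

SMRNA_COLUMNS = [
    "read_id", "sequence", "dataset_id", "tissue", "count",
    "chrom", "start", "end", "strand",
]


def read_smrna_table(path) -> list[SmallRnaRead]:
    """Read small-RNA alignments; one row per genomic hit, grouped by
    (dataset_id, read_id).  Raises if a hit span disagrees with the
    sequence length."""
    df = read_tsv(path, dtype={"chrom": str})
    if df.empty:
        return []
    missing = set(SMRNA_COLUMNS) - set(df.columns)
    if missing:
        raise GenomeIOError(f"{path}: missing columns {sorted(missing)}")
    reads = []
    for (dataset, rid), grp in df.groupby(["dataset_id", "read_id"], sort=True):
        seq = grp["sequence"].iloc[0]
        hits = [
            GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand)
            for r in grp.itertuples()
        ]
        reads.append(
            SmallRnaRead(
                read_id=str(rid), sequence=seq, hits=hits,
                dataset_id=str(dataset), tissue=str(grp["tissue"].iloc[0]),
                count=int(grp["count"].iloc[0]),
            )
        )
    return reads


def write_smrna_table(reads: list[SmallRnaRead], path,
                      params: dict | None = None) -> None:
    rows = [
        {
            "read_id": r.read_id, "sequence": r.sequence,
            "dataset_id": r.dataset_id, "tissue": r.tissue, "count": r.count,
            "chrom": h.chrom, "start": h.start, "end": h.end, "strand": h.strand,
        }
        for r in reads for h in r.hits
    ]
    df = pd.DataFrame(rows, columns=SMRNA_COLUMNS)
    df = df.sort_values(["dataset_id", "read_id", "chrom", "start"],
                        kind="mergesort").reset_index(drop=True)
    write_tsv(df, path, params)


# ---------------------------------------------------------------------------
# Methylation table
# ---------------------------------------------------------------------------

METH_COLUMNS = ["chrom", "pos", "strand", "context", "methylated", "total"]


def read_methylation_table(path) -> list[MethylationSite]:
    df = read_tsv(path, dtype={"chrom": str})
    if df.empty:
        return []
    sites = []
    for r in df.itertuples():
        if int(r.methylated) < 0 or int(r.total) < 0:
            raise GenomeIOError(
                f"{path}: negative count at {r.chrom}:{r.pos}"
            )
        sites.append(
            MethylationSite(
                chrom=str(r.chrom), pos=int(r.pos), strand=str(r.strand),
                context=str(r.context), methylated=int(r.methylated),
                total=int(r.total),
            )
        )
    return sites


def write_methylation_table(sites: list[MethylationSite], path,
                            params: dict | None = None) -> None:
    df = pd.DataFrame(
        [
            {
                "chrom": s.chrom, "pos": s.pos, "strand": s.strand,
                "context": s.context, "methylated": s.methylated,
                "total": s.total,
            }
            for s in sites
        ],
        columns=METH_COLUMNS,
    )
    df = df.sort_values(["chrom", "pos", "context"],
                        kind="mergesort").reset_index(drop=True)
    write_tsv(df, path, params)


# ---------------------------------------------------------------------------
# BED (chromatin tiles, generic interval tracks)
# ---------------------------------------------------------------------------

def read_tiles(path) -> list[ChromatinTile]:
    """Read a BED4 tile track; column 4 is the histone mark name."""
    tiles = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise GenomeIOError(
                    f"{path}:{lineno}: BED4 requires 4 columns"
                )
            chrom, start, end, mark = fields[:4]
            tiles.append(
                ChromatinTile(
                    mark=mark,
                    interval=GenomicInterval(chrom, int(start), int(end), "."),
                )
            )
    return tiles


def write_tiles(tiles: list[ChromatinTile], path) -> None:
    with open(path, "w") as fh:
        for t in sorted(tiles, key=lambda t: (t.mark, t.interval.chrom,
                                              t.interval.start)):
            iv = t.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{t.mark}\n")


def read_bed_intervals(path) -> list[GenomicInterval]:
    """Read a BED3/BED6 file as plain intervals (strand from column 6)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GenomeIOError(f"{path}:{lineno}: BED requires 3 columns")
            strand = fields[5] if len(fields) >= 6 else "."
            out.append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
            )
    return out


def write_bed_intervals(intervals: list[GenomicInterval], path,
                        names: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names else "."
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# Expression matrix and coding-potential table
# ---------------------------------------------------------------------------

def read_expression_matrix(path) -> pd.DataFrame:
    """Transcript x sample FPKM matrix.  Blank cells stay NaN: a missing
    value means the transcript was not assembled in that sample and must
    not be treated as zero expression."""
    df = read_tsv(path, index_col=0)
    return df.astype(float)


def write_expression_matrix(df: pd.DataFrame, path,
                            params: dict | None = None) -> None:
    write_tsv(df, path, params, index=True)


def read_coding_table(path) -> pd.DataFrame:
    """Per-transcript coding-potential scores: columns transcript_id,
    class_code, coding_prob, homologous (0/1)."""
    df = read_tsv(path, index_col="transcript_id")
    df["homologous"] = df["homologous"].astype(bool)
    return df


def write_coding_table(df: pd.DataFrame, path,
                       params: dict | None = None) -> None:
    write_tsv(df, path, params, index=True)
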