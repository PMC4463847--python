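"""lncRNA candidate filtering and assembly of the unified transcript catalog.

Candidate long non-coding RNAs come from a transcript assembly upstream of
this package; each carries a Cuffmerge-style class code ('u' intergenic,
'x' antisense, 'i' intronic), a coding probability from an external
coding-potential model, and per-sample FPKM.  A candidate is retained as a
lncRNA when it is over 200 nt long, its longest ORF is at most 120 amino
acids, its coding probability is below 0.365, it is not homologous to any
annotated transcript, and no sample where it was assembled has FPKM < 2.

The retained lncRNAs are merged with the annotated genes into one catalog,
which is what the cis-/trans-NAT stages pair against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genome_io import TranscriptRecord

STOP_CODONS = {"TAA", "TAG", "TGA"}
LNCRNA_CLASS_CODES = {"u", "x", "i"}

DEFAULT_MIN_LEN = 200        # strict: length must exceed this
DEFAULT_MAX_ORF_AA = 120     # inclusive upper bound
DEFAULT_MAX_CODING_PROB = 0.365  # strict upper bound
DEFAULT_MIN_FPKM = 2.0       # any assembled sample below this rejects


@dataclass
class LncRnaCandidate:
    """A candidate lncRNA with the attributes the retention filter inspects."""

    transcript_id: str
    class_code: str
    length: int
    max_orf_aa: int
    coding_prob: float
    fpkm: dict[str, float] = field(default_factory=dict)
    homologous_to_annotation: bool = False


def longest_orf_aa(sequence: str, both_strands: bool = False) -> int:
    """Length in amino acids (stop excluded) of the longest ATG-initiated,
    stop-terminated ORF over the three forward reading frames.

    Candidates are stranded transcripts, so only forward frames are scanned
    by default; ``both_strands=True`` additionally scans the reverse
    complement.  Returns 0 when no complete ORF exists.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    best = _longest_orf_forward(seq)
    if both_strands:
        comp = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}
        rc = "".join(comp.get(b, "N") for b in reversed(seq))
        best = max(best, _longest_orf_forward(rc))
    return best


def _longest_orf_forward(seq: str) -> int:
    best = 0
    n = len(seq)
    for frame in range(3):
        start = None
        for i in range(frame, n - 2, 3):
            codon = seq[i:i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in STOP_CODONS:
                best = max(best, (i - start) // 3)
                start = None
    return best


def filter_lncrna(
    candidates: list[LncRnaCandidate],
    min_len: int = DEFAULT_MIN_LEN,
    max_orf: int = DEFAULT_MAX_ORF_AA,
    max_coding_prob: float = DEFAULT_MAX_CODING_PROB,
    min_fpkm: float = DEFAULT_MIN_FPKM,
) -> tuple[list[LncRnaCandidate], pd.DataFrame]:
    """Apply the lncRNA retention filters.

    Returns the retained candidates and a per-candidate report with the
    first reject reason ('' for retained ones).  The FPKM rule is applied
    over the samples where the transcript has a value: a transcript absent
    from a sample is not penalized for it.
    """
    retained = []
    report_rows = []
    for c in candidates:
        if c.fpkm is None:
            raise ValueError(f"candidate {c.transcript_id} has no FPKM map")
        reason = ""
        if c.class_code not in LNCRNA_CLASS_CODES:
            reason = f"class_code {c.class_code!r} not in u/x/i"
        elif c.length <= min_len:
            reason = f"length {c.length} <= {min_len}"
        elif c.max_orf_aa > max_orf:
            reason = f"ORF {c.max_orf_aa} aa > {max_orf}"
        elif c.coding_prob >= max_coding_prob:
            reason = f"coding_prob {c.coding_prob} >= {max_coding_prob}"
        elif c.homologous_to_annotation:
            reason = "homologous to annotation"
        elif c.fpkm and min(c.fpkm.values()) < min_fpkm:
            reason = f"FPKM < {min_fpkm} in some sample"
        if reason:
            report_rows.append(
                {"transcript_id": c.transcript_id, "retained": False,
                 "reject_reason": reason}
            )
        else:
            retained.append(c)
            report_rows.append(
                {"transcript_id": c.transcript_id, "retained": True,
                 "reject_reason": ""}
            )
    report = pd.DataFrame(
        report_rows, columns=["transcript_id", "retained", "reject_reason"]
    )
    return retained, report


def candidates_from_tables(
    sequences: dict[str, str],
    coding_table: pd.DataFrame,
    expression: pd.DataFrame,
) -> list[LncRnaCandidate]:
    """Assemble LncRnaCandidate objects from the three input tables
    (FASTA sequences, coding-potential TSV, expression matrix)."""
    out = []
    for tid, row in coding_table.iterrows():
        if tid not in sequences:
            raise ValueError(f"no sequence for candidate {tid}")
        seq = sequences[tid]
        fpkm = {}
        if tid in expression.index:
            vals = expression.loc[tid].dropna()
            fpkm = {str(s): float(v) for s, v in vals.items()}
        out.append(
            LncRnaCandidate(
                transcript_id=str(tid),
                class_code=str(row["class_code"]),
                length=len(seq),
                max_orf_aa=longest_orf_aa(seq),
                coding_prob=float(row["coding_prob"]),
                fpkm=fpkm,
                homologous_to_annotation=bool(row["homologous"]),
            )
        )
    return out


def build_catalog(
    annotated: list[TranscriptRecord],
    lncrna_records: list[TranscriptRecord],
    retained_ids: set[str],
) -> list[TranscriptRecord]:
    """Merge annotated genes with retained lncRNAs into the NAT catalog."""
    keep = [t for t in lncrna_records if t.transcript_id in retained_ids]
    catalog = list(annotated) + keep
    catalog.sort(key=lambda t: (t.chrom, t.interval.start, t.transcript_id))
    return catalog
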