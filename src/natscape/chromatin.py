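"""Histone-modification analysis of NAT genes.

Enriched probe tiles per mark are joined into domains (gaps up to 200 nt
merge, inclusive; only domains of at least 400 nt are kept).  Six marks
are grouped by their chromatin association: the euchromatic group G1
(H3K4me2, H3K4me3, H3K36me3, H2Bub) and the heterochromatic group G2
(H3K27me1, H3K27me3).  A gene is "targeted" by a mark when one of its
domains overlaps the gene span by at least one base; its group state is
G1, G2, G1+G2 or NON accordingly.

NAT pairs are then classified into the ten unordered pair-pattern classes
(G1_G1 ... NON_NON) and compared against a randomized null: repeated
random pairings of non-NAT genes, matched in number to the observed set,
yielding per-class mean percentages and a percentile envelope.

Metagene profiles average domain membership over 100 gene-body bins (1%
of the gene each) plus 1 kb flanks in 10-bp bins, strand-oriented so bin
0 is always the 5' side.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import (ChromatinDomain, ChromatinTile, GenomicInterval,
                        TranscriptRecord, write_tsv)

logger = logging.getLogger("natscape")

G1_MARKS = frozenset({"H3K4me2", "H3K4me3", "H3K36me3", "H2Bub"})
G2_MARKS = frozenset({"H3K27me1", "H3K27me3"})
ALL_MARKS = G1_MARKS | G2_MARKS

GROUP_STATES = ("G1+G2", "G1", "G2", "NON")  # canonical pattern-label order

PATTERN_CLASSES = (
    "G1_G1", "G2_G2", "G1_G2", "G1+G2_G1", "G1+G2_G2", "G1+G2_G1+G2",
    "G1+G2_NON", "G1_NON", "G2_NON", "NON_NON",
)

DEFAULT_MAX_GAP = 200
DEFAULT_MIN_DOMAIN = 400
DEFAULT_REPEATS = 10_000


@dataclass(frozen=True)
class GeneMarkState:
    gene_id: str
    marks_present: frozenset[str]

    @property
    def group_state(self) -> str:
        has_g1 = bool(self.marks_present & G1_MARKS)
        has_g2 = bool(self.marks_present & G2_MARKS)
        if has_g1 and has_g2:
            return "G1+G2"
        if has_g1:
            return "G1"
        if has_g2:
            return "G2"
        return "NON"


# ---------------------------------------------------------------------------
# Domains
# ---------------------------------------------------------------------------

def tiles_to_domains(
    tiles: list[ChromatinTile],
    max_gap: int = DEFAULT_MAX_GAP,
    min_domain: int = DEFAULT_MIN_DOMAIN,
) -> list[ChromatinDomain]:
    """Join neighbouring enriched tiles into domains.

    Tiles of the same mark on the same chromosome merge when the
    edge-to-edge gap is at most ``max_gap`` (inclusive); merged runs
    shorter than ``min_domain`` are discarded.  Output is independent of
    input tile order.
    """
    by_key: dict[tuple[str, str], list[GenomicInterval]] = {}
    for t in tiles:
        if not t.enriched:
            continue
        by_key.setdefault((t.mark, t.interval.chrom), []).append(t.interval)

    domains = []
    for (mark, chrom), ivs in sorted(by_key.items()):
        ivs.sort(key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start - cur_end <= max_gap:
                cur_end = max(cur_end, iv.end)
            else:
                if cur_end - cur_start >= min_domain:
                    domains.append(ChromatinDomain(
                        mark, GenomicInterval(chrom, cur_start, cur_end, ".")))
                cur_start, cur_end = iv.start, iv.end
        if cur_end - cur_start >= min_domain:
            domains.append(ChromatinDomain(
                mark, GenomicInterval(chrom, cur_start, cur_end, ".")))
    domains.sort(key=lambda d: (d.mark, d.interval.chrom, d.interval.start))
    return domains


# ---------------------------------------------------------------------------
# Gene states
# ---------------------------------------------------------------------------

def gene_mark_state(
    gene: TranscriptRecord,
    domains: list[ChromatinDomain],
    promoter_flank: int = 0,
) -> GeneMarkState:
    """Group state of one gene: a mark is present when any of its domains
    overlaps the gene span (optionally extended ``promoter_flank`` nt
    upstream of the TSS) by at least one base."""
    span = gene.interval
    if promoter_flank:
        if span.strand == "-":
            span = GenomicInterval(span.chrom, span.start,
                                   span.end + promoter_flank, span.strand)
        else:
            span = GenomicInterval(span.chrom,
                                   max(0, span.start - promoter_flank),
                                   span.end, span.strand)
    present = set()
    for d in domains:
        if d.mark not in ALL_MARKS:
            raise ValueError(f"unknown histone mark {d.mark!r}")
        if d.interval.chrom == span.chrom and \
                d.interval.start < span.end and span.start < d.interval.end:
            present.add(d.mark)
    return GeneMarkState(gene.gene_id, frozenset(present))


def gene_states(
    genes: list[TranscriptRecord],
    domains: list[ChromatinDomain],
    promoter_flank: int = 0,
) -> dict[str, GeneMarkState]:
    by_chrom: dict[str, list[ChromatinDomain]] = {}
    for d in domains:
        if d.mark not in ALL_MARKS:
            raise ValueError(f"unknown histone mark {d.mark!r}")
        by_chrom.setdefault(d.interval.chrom, []).append(d)
    out = {}
    for g in genes:
        out[g.gene_id] = gene_mark_state(
            g, by_chrom.get(g.chrom, []), promoter_flank
        )
    return out


# ---------------------------------------------------------------------------
# Metagene profiles
# ---------------------------------------------------------------------------

def metagene_profile(
    genes: list[TranscriptRecord],
    domains: list[ChromatinDomain],
    body_bins: int = 100,
    flank: int = 1000,
    flank_bin: int = 10,
) -> np.ndarray:
    """Mean domain-membership profile over upstream flank, scaled gene
    body and downstream flank.

    Returns a vector of ``flank // flank_bin`` upstream bins, ``body_bins``
    body bins (each 1/body_bins of the gene) and ``flank // flank_bin``
    downstream bins, strand-flipped so index 0 is always the 5' side.
    Genes shorter than ``body_bins`` nt are skipped with a warning.
    """
    n_flank = flank // flank_bin
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for d in domains:
        by_chrom.setdefault(d.interval.chrom, []).append(d.interval)

    profiles = []
    for gene in genes:
        span = gene.interval
        if span.length() < body_bins:
            logger.warning("gene %s shorter than %d nt skipped from profile",
                           gene.gene_id, body_bins)
            continue
        win_lo = span.start - flank
        win_hi = span.end + flank
        track = np.zeros(win_hi - win_lo, dtype=float)
        for iv in by_chrom.get(span.chrom, ()):
            lo, hi = max(iv.start, win_lo), min(iv.end, win_hi)
            if lo < hi:
                track[lo - win_lo:hi - win_lo] = 1.0

        up = track[:flank].reshape(n_flank, flank_bin).mean(axis=1)
        down = track[-flank:].reshape(n_flank, flank_bin).mean(axis=1)
        body = track[flank:flank + span.length()]
        edges = np.linspace(0, span.length(), body_bins + 1).astype(int)
        body_means = np.array([
            body[edges[i]:edges[i + 1]].mean() for i in range(body_bins)
        ])
        prof = np.concatenate([up, body_means, down])
        if span.strand == "-":
            prof = prof[::-1]
        profiles.append(prof)
    if not profiles:
        raise ValueError("no gene long enough for a metagene profile")
    return np.mean(profiles, axis=0)


def mark_profiles(
    genes: list[TranscriptRecord],
    domains: list[ChromatinDomain],
    **kwargs,
) -> dict[str, np.ndarray]:
    """One metagene profile per histone mark."""
    out = {}
    for mark in sorted(ALL_MARKS):
        sub = [d for d in domains if d.mark == mark]
        out[mark] = metagene_profile(genes, sub, **kwargs)
    return out


def gene_modification_profile(
    gene: TranscriptRecord,
    domains: list[ChromatinDomain],
    body_bins: int = 20,
) -> np.ndarray:
    """Concatenated per-mark binary domain-overlap profile over gene-body
    bins: the per-gene vector used for modification-pattern similarity."""
    span = gene.interval
    edges = np.linspace(span.start, span.end, body_bins + 1).astype(int)
    chunks = []
    for mark in sorted(ALL_MARKS):
        vec = np.zeros(body_bins)
        for d in domains:
            if d.mark != mark or d.interval.chrom != span.chrom:
                continue
            for i in range(body_bins):
                if d.interval.start < edges[i + 1] and \
                        edges[i] < d.interval.end:
                    vec[i] = 1.0
        if span.strand == "-":
            vec = vec[::-1]
        chunks.append(vec)
    return np.concatenate(chunks)


# ---------------------------------------------------------------------------
# Pair-pattern classes
# ---------------------------------------------------------------------------

def pattern_class(state_a: str, state_b: str) -> str:
    """Unordered pair-pattern label in canonical order
    (G1+G2 before G1 before G2 before NON)."""
    rank = {s: i for i, s in enumerate(GROUP_STATES)}
    first, second = sorted((state_a, state_b), key=rank.__getitem__)
    return f"{first}_{second}"


def classify_pair_patterns(
    pairs: list[tuple[str, str]],
    states: dict[str, GeneMarkState],
) -> tuple[Counter, int]:
    """Counts per pattern class over (gene_a, gene_b) pairs; pairs with a
    member lacking a state are dropped and counted separately."""
    counts: Counter = Counter()
    dropped = 0
    for a, b in pairs:
        if a not in states or b not in states:
            dropped += 1
            continue
        counts[pattern_class(states[a].group_state,
                             states[b].group_state)] += 1
    return counts, dropped


def pattern_percentages(counts: Counter) -> dict[str, float]:
    total = sum(counts.values())
    if total == 0:
        return {c: 0.0 for c in PATTERN_CLASSES}
    return {c: 100.0 * counts.get(c, 0) / total for c in PATTERN_CLASSES}


def randomized_null(
    pool_states: list[str],
    n_pairs: int,
    repeats: int = DEFAULT_REPEATS,
    seed: int = 0,
) -> pd.DataFrame:
    """Null pair-pattern distribution from random non-NAT gene pairings.

    Each repeat draws ``2 * n_pairs`` distinct genes from the pool (without
    replacement within the repeat) and pairs them at random; per-class
    percentages are summarized over repeats (mean, 2.5 and 97.5
    percentiles).  Deterministic given ``seed``.
    """
    m = len(pool_states)
    if m < 2 * n_pairs:
        raise ValueError(
            f"pool of {m} genes too small for {n_pairs} random pairs"
        )
    rank = {s: i for i, s in enumerate(GROUP_STATES)}
    codes = np.array([rank[s] for s in pool_states], dtype=np.int64)
    class_of = np.empty((4, 4), dtype=np.int64)
    class_index = {c: i for i, c in enumerate(PATTERN_CLASSES)}
    for i, si in enumerate(GROUP_STATES):
        for j, sj in enumerate(GROUP_STATES):
            class_of[i, j] = class_index[pattern_class(si, sj)]

    rng = np.random.default_rng(seed)
    pct = np.empty((repeats, len(PATTERN_CLASSES)))
    for r in range(repeats):
        idx = rng.choice(m, size=2 * n_pairs, replace=False)
        ca = codes[idx[:n_pairs]]
        cb = codes[idx[n_pairs:]]
        counts = np.bincount(class_of[ca, cb],
                             minlength=len(PATTERN_CLASSES))
        pct[r] = 100.0 * counts / n_pairs
    return pd.DataFrame(
        {
            "mean_pct": pct.mean(axis=0),
            "pct_2.5": np.percentile(pct, 2.5, axis=0),
            "pct_97.5": np.percentile(pct, 97.5, axis=0),
        },
        index=list(PATTERN_CLASSES),
    )


def group_state_percentages(
    states: dict[str, GeneMarkState],
    groups: dict[str, list[str]],
) -> pd.DataFrame:
    """Percentage of genes in each group state (G1/G2/G1+G2/NON) per gene
    group (e.g. cis-NAT, trans-NAT, non-NAT; optionally TE-only subsets)."""
    rows = []
    for name, gene_ids in groups.items():
        counts = Counter(states[g].group_state for g in gene_ids
                         if g in states)
        total = sum(counts.values())
        row = {"group": name, "n_genes": total}
        for state in GROUP_STATES:
            row[state] = (round(100.0 * counts.get(state, 0) / total, 2)
                          if total else float("nan"))
        rows.append(row)
    return pd.DataFrame(rows, columns=["group", "n_genes", *GROUP_STATES])


def pattern_table(
    observed: Counter,
    null: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Observed-vs-null class percentage table."""
    pcts = pattern_percentages(observed)
    df = pd.DataFrame(
        {
            "count": [observed.get(c, 0) for c in PATTERN_CLASSES],
            "observed_pct": [round(pcts[c], 2) for c in PATTERN_CLASSES],
        },
        index=list(PATTERN_CLASSES),
    )
    if null is not None:
        df["null_mean_pct"] = null["mean_pct"].round(2)
        df["null_pct_2.5"] = null["pct_2.5"].round(2)
        df["null_pct_97.5"] = null["pct_97.5"].round(2)
    return df


def write_pattern_table(df: pd.DataFrame, path, **params) -> None:
    write_tsv(df.rename_axis("pattern_class"), path,
              params={"stage": "chromatin", **params}, index=True)


def write_domains(domains: list[ChromatinDomain], path) -> None:
    with open(path, "w") as fh:
        for d in domains:
            iv = d.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{d.mark}\n")
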