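"""DNA-methylation levels and the pairwise methylation distance D_mC.

Per-cytosine calls (methylated / total read counts, with CG / CHG / CHH
context) are pooled into positional bins over a gene region — the gene
body (transcript span) or the promoter (1 kb upstream of the TSS) — as
absolute levels sum(methylated) / sum(total), strand-combined, oriented
5'->3'.  Bins with no covered cytosine are missing, not zero.

For a NAT pair the methylation distance is D_mC = 1 - r, with r the
Pearson correlation of the two genes' bin-level vectors over mutually
covered bins (at least three required; zero-variance vectors make the
distance undefined).  A smaller D_mC means a more similar methylation
pattern.  Observed pair distances are compared against distances of
randomized non-NAT gene pairs with a one-tailed Wilcoxon rank-sum test
(H1: observed distances smaller).

The correlation support is positional bins by default; correlating
per-sample mean levels across data sets instead is available where
multiple methylation data sets are supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import (GenomicInterval, MethylationSite, TranscriptRecord,
                        write_tsv)

REGIONS = ("promoter", "body")
DEFAULT_N_BINS = 20
DEFAULT_PROMOTER_LEN = 1000
DEFAULT_REPEATS = 10_000
MIN_COVERED_BINS = 3


@dataclass
class RegionMethylation:
    gene_id: str
    region: str
    context: str
    levels: np.ndarray  # per-bin absolute level, NaN = no covered cytosine

    @property
    def n_bins(self) -> int:
        return len(self.levels)


@dataclass
class DmcResult:
    pair_id: str
    region: str
    context: str
    r: float
    dmc: float


def region_interval(gene: TranscriptRecord, region: str,
                    promoter_len: int = DEFAULT_PROMOTER_LEN,
                    ) -> GenomicInterval:
    """Genomic interval of the requested region, strand-aware."""
    span = gene.interval
    if region == "body":
        return span
    if region == "promoter":
        if span.strand == "-":
            return GenomicInterval(span.chrom, span.end,
                                   span.end + promoter_len, span.strand)
        return GenomicInterval(span.chrom, max(0, span.start - promoter_len),
                               span.start, span.strand)
    if region == "5utr":
        if gene.cds is None:
            raise ValueError(f"gene {gene.gene_id} has no CDS for 5'-UTR")
        if span.strand == "-":
            return GenomicInterval(span.chrom, gene.cds.end, span.end,
                                   span.strand)
        return GenomicInterval(span.chrom, span.start, gene.cds.start,
                               span.strand)
    raise ValueError(f"unknown region {region!r}")


class _SiteIndex:
    """Per (chrom, context) sorted position arrays for fast bin pooling."""

    def __init__(self, sites: list[MethylationSite]):
        buckets: dict[tuple[str, str], list[MethylationSite]] = {}
        for s in sites:
            buckets.setdefault((s.chrom, s.context), []).append(s)
        self.arrays = {}
        for key, lst in buckets.items():
            lst.sort(key=lambda s: s.pos)
            self.arrays[key] = (
                np.array([s.pos for s in lst]),
                np.array([s.methylated for s in lst], dtype=float),
                np.array([s.total for s in lst], dtype=float),
            )

    def pooled_bins(self, chrom: str, context: str,
                    edges: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(sum methylated, sum total) per bin defined by ``edges``."""
        n_bins = len(edges) - 1
        if (chrom, context) not in self.arrays:
            return np.zeros(n_bins), np.zeros(n_bins)
        pos, meth, total = self.arrays[(chrom, context)]
        cm = np.concatenate([[0.0], np.cumsum(meth)])
        ct = np.concatenate([[0.0], np.cumsum(total)])
        idx = np.searchsorted(pos, edges)
        return cm[idx[1:]] - cm[idx[:-1]], ct[idx[1:]] - ct[idx[:-1]]


def region_methylation(
    gene: TranscriptRecord,
    sites: list[MethylationSite] | _SiteIndex,
    region: str = "body",
    context: str = "CG",
    n_bins: int = DEFAULT_N_BINS,
    min_coverage: int = 1,
    promoter_len: int = DEFAULT_PROMOTER_LEN,
) -> RegionMethylation:
    """Pooled per-bin absolute methylation levels for one gene region.

    Level per bin = sum(methylated) / sum(total) over the covered
    cytosines of the given context in the bin (pooled, not averaged);
    bins whose total coverage is below ``min_coverage`` are NaN.  The bin
    vector runs 5'->3'.
    """
    index = sites if isinstance(sites, _SiteIndex) else _SiteIndex(sites)
    iv = region_interval(gene, region, promoter_len)
    edges = np.linspace(iv.start, iv.end, n_bins + 1)
    meth, total = index.pooled_bins(iv.chrom, context, edges)
    with np.errstate(invalid="ignore", divide="ignore"):
        levels = np.where(total >= max(min_coverage, 1), meth / total, np.nan)
    if gene.strand == "-":
        levels = levels[::-1]
    return RegionMethylation(gene.gene_id, region, context, levels)


def gene_region_levels(
    genes: list[TranscriptRecord],
    sites: list[MethylationSite],
    region: str = "body",
    context: str = "CG",
    n_bins: int = DEFAULT_N_BINS,
    **kwargs,
) -> dict[str, np.ndarray]:
    index = _SiteIndex(sites)
    return {
        g.gene_id: region_methylation(g, index, region, context, n_bins,
                                      **kwargs).levels
        for g in genes
    }


# ---------------------------------------------------------------------------
# D_mC
# ---------------------------------------------------------------------------

def dmc_value(levels_a: np.ndarray, levels_b: np.ndarray) -> float | None:
    """D_mC = 1 - Pearson r over mutually covered bins; None when fewer
    than three co-covered bins or either vector is constant."""
    a = np.asarray(levels_a, float)
    b = np.asarray(levels_b, float)
    mask = ~(np.isnan(a) | np.isnan(b))
    if mask.sum() < MIN_COVERED_BINS:
        return None
    a, b = a[mask], b[mask]
    if np.std(a) == 0 or np.std(b) == 0:
        return None
    r = float(np.corrcoef(a, b)[0, 1])
    return 1.0 - r


def pair_dmc(
    pair_id: str,
    gene_a: str,
    gene_b: str,
    levels: dict[str, np.ndarray],
    region: str,
    context: str,
) -> DmcResult | None:
    if gene_a not in levels or gene_b not in levels:
        return None
    d = dmc_value(levels[gene_a], levels[gene_b])
    if d is None:
        return None
    return DmcResult(pair_id, region, context, r=1.0 - d, dmc=d)


def pair_dmc_values(
    pairs: list[tuple[str, str]],
    levels: dict[str, np.ndarray],
) -> list[float]:
    out = []
    for a, b in pairs:
        if a in levels and b in levels:
            d = dmc_value(levels[a], levels[b])
            if d is not None:
                out.append(d)
    return out


def random_pair_dmc(
    pool_ids: list[str],
    levels: dict[str, np.ndarray],
    repeats: int = DEFAULT_REPEATS,
    seed: int = 0,
) -> list[float]:
    """D_mC values of ``repeats`` random pairings drawn from the non-NAT
    pool (two distinct genes per draw)."""
    rng = np.random.default_rng(seed)
    ids = sorted(pool_ids)
    if len(ids) < 2:
        raise ValueError("non-NAT pool too small for randomized pairs")
    out = []
    for _ in range(repeats):
        i, j = rng.choice(len(ids), size=2, replace=False)
        d = dmc_value(levels[ids[i]], levels[ids[j]])
        if d is not None:
            out.append(d)
    return out


def dmc_null_comparison(
    pairs: list[tuple[str, str]],
    pool_ids: list[str],
    levels: dict[str, np.ndarray],
    repeats: int = DEFAULT_REPEATS,
    seed: int = 0,
) -> tuple[float, list[float], list[float]]:
    """One-tailed Wilcoxon rank-sum of observed pair D_mC against
    randomized-pair D_mC (H1: observed smaller).

    Returns (p_value, observed D_mC values, null D_mC values).
    """
    observed = pair_dmc_values(pairs, levels)
    null = random_pair_dmc(pool_ids, levels, repeats, seed)
    if len(observed) < 2 or len(null) < 2:
        raise ValueError("too few defined D_mC values for the comparison")
    res = stats.mannwhitneyu(observed, null, alternative="less")
    return float(res.pvalue), observed, null


def dmc_comparison_table(
    pairs: list[tuple[str, str]],
    pool_ids: list[str],
    genes: list[TranscriptRecord],
    sites: list[MethylationSite],
    repeats: int = DEFAULT_REPEATS,
    seed: int = 0,
    n_bins: int = DEFAULT_N_BINS,
) -> pd.DataFrame:
    """All six region x context comparisons for one pair set."""
    rows = []
    for ri, region in enumerate(REGIONS):
        for ci, context in enumerate(("CG", "CHG", "CHH")):
            levels = gene_region_levels(genes, sites, region, context, n_bins)
            sub_seed = seed + 13 * ri + 101 * ci
            try:
                p, obs, null = dmc_null_comparison(
                    pairs, pool_ids, levels, repeats, sub_seed)
                rows.append({
                    "region": region, "context": context,
                    "n_pairs": len(obs),
                    "mean_observed_dmc": round(float(np.mean(obs)), 4),
                    "mean_null_dmc": round(float(np.mean(null)), 4),
                    "wilcoxon_p": p,
                })
            except ValueError:
                rows.append({
                    "region": region, "context": context, "n_pairs": 0,
                    "mean_observed_dmc": np.nan, "mean_null_dmc": np.nan,
                    "wilcoxon_p": np.nan,
                })
    return pd.DataFrame(rows)


def compare_cis_trans_distance(
    cis_dmc: dict[tuple[str, str], list[float]],
    trans_dmc: dict[tuple[str, str], list[float]],
) -> pd.DataFrame:
    """Mean D_mC of cis vs trans pairs per region x context, with the
    difference and a two-sided rank-sum p.  Region suffixes follow the
    -P (promoter) / -B (body) convention."""
    suffix = {"promoter": "P", "body": "B"}
    rows = []
    for region in REGIONS:
        for context in ("CG", "CHG", "CHH"):
            key = (region, context)
            cis_vals = cis_dmc.get(key, [])
            trans_vals = trans_dmc.get(key, [])
            if not cis_vals or not trans_vals:
                rows.append({
                    "measure": f"{context}-{suffix[region]}",
                    "mean_cis_dmc": np.nan, "mean_trans_dmc": np.nan,
                    "difference": np.nan, "ranksum_p": np.nan,
                    "status": "missing",
                })
                continue
            mc, mt = float(np.mean(cis_vals)), float(np.mean(trans_vals))
            if (len(cis_vals) == len(trans_vals)
                    and np.allclose(sorted(cis_vals), sorted(trans_vals))):
                p = 1.0
            else:
                p = float(stats.mannwhitneyu(
                    cis_vals, trans_vals, alternative="two-sided").pvalue)
            rows.append({
                "measure": f"{context}-{suffix[region]}",
                "mean_cis_dmc": round(mc, 4),
                "mean_trans_dmc": round(mt, 4),
                "difference": round(mt - mc, 4),
                "ranksum_p": p,
                "status": "ok",
            })
    return pd.DataFrame(rows)


def write_dmc_table(df: pd.DataFrame, path, **params) -> None:
    write_tsv(df, path, params={"stage": "methylation", **params})
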