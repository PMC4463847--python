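"""NAT coexpression network.

Expression (FPKM/RPKM) across samples gives each NAT pair a Pearson
correlation; genes observed in fewer than three data sets are removed,
and pairs with |PCC| >= 0.8 over at least three shared samples become
network edges (cis vs trans is an edge attribute).  Each edge is then
annotated with two regulatory features: whether the pair produces a
called NAT-siRNA, and whether the two genes' histone-modification
profiles are strongly similar or strongly opposed (|PCC| of the
concatenated per-mark domain-overlap profiles >= 0.8).  Edges with both
features are labeled "both".
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .genome_io import TranscriptRecord, write_tsv
from .cis_nat import CisNatPair
from .trans_nat import TransNatPair
from .sirna import NatSiRna

DEFAULT_PCC_THRESHOLD = 0.8
DEFAULT_MIN_DATASETS = 3
DEFAULT_SIM_THRESHOLD = 0.8


@dataclass
class ExpressionEdge:
    pair_id: str
    gene_a: str
    gene_b: str
    nat_type: str                     # cis | trans
    pcc: float
    n_shared_samples: int
    produces_nat_sirna: bool = False
    modification_similarity: float | None = None
    feature_label: str = "none"       # siRNA | epigenetic | both | none


def network_pairs(
    cis_pairs: list[CisNatPair],
    trans_pairs: list[TransNatPair],
    tx_by_id: dict[str, TranscriptRecord],
) -> list[tuple[str, str, str, str]]:
    """(pair_id, gene_a, gene_b, nat_type) tuples at gene level."""
    out = []
    for p in cis_pairs:
        out.append((p.pair_id, tx_by_id[p.transcript_a].gene_id,
                    tx_by_id[p.transcript_b].gene_id, "cis"))
    for p in trans_pairs:
        out.append((p.pair_id, tx_by_id[p.transcript_a].gene_id,
                    tx_by_id[p.transcript_b].gene_id, "trans"))
    return out


def expression_pcc(
    gene_a: str,
    gene_b: str,
    matrix: pd.DataFrame,
    min_datasets: int = DEFAULT_MIN_DATASETS,
) -> tuple[float | None, int]:
    """(PCC, n shared samples); PCC is None when either gene occurs in
    fewer than ``min_datasets`` samples, when fewer than ``min_datasets``
    samples cover both, or when either vector is constant."""
    if gene_a not in matrix.index or gene_b not in matrix.index:
        return None, 0
    va = matrix.loc[gene_a]
    vb = matrix.loc[gene_b]
    if va.notna().sum() < min_datasets or vb.notna().sum() < min_datasets:
        return None, 0
    mask = va.notna() & vb.notna()
    n_shared = int(mask.sum())
    if n_shared < min_datasets:
        return None, n_shared
    a = va[mask].to_numpy(float)
    b = vb[mask].to_numpy(float)
    if np.std(a) == 0 or np.std(b) == 0:
        return None, n_shared
    return float(np.corrcoef(a, b)[0, 1]), n_shared


def build_network(
    pairs: list[tuple[str, str, str, str]],
    matrix: pd.DataFrame,
    threshold: float = DEFAULT_PCC_THRESHOLD,
    min_datasets: int = DEFAULT_MIN_DATASETS,
    strict_gt: bool = False,
) -> tuple[list[ExpressionEdge], list[str]]:
    """Edges for pairs with |PCC| >= threshold (``strict_gt`` switches to
    a strict inequality).  Returns (edges, pair ids with undefined PCC).
    """
    edges: list[ExpressionEdge] = []
    undefined: list[str] = []
    for pair_id, gene_a, gene_b, nat_type in pairs:
        pcc, n_shared = expression_pcc(gene_a, gene_b, matrix, min_datasets)
        if pcc is None:
            undefined.append(pair_id)
            continue
        passed = abs(pcc) > threshold if strict_gt else abs(pcc) >= threshold
        if passed:
            edges.append(ExpressionEdge(
                pair_id=pair_id, gene_a=gene_a, gene_b=gene_b,
                nat_type=nat_type, pcc=pcc, n_shared_samples=n_shared,
            ))
    return edges, undefined


def modification_similarity(
    gene_a: str,
    gene_b: str,
    profiles: dict[str, np.ndarray],
) -> float | None:
    if gene_a not in profiles or gene_b not in profiles:
        return None
    a, b = np.asarray(profiles[gene_a], float), np.asarray(profiles[gene_b], float)
    if np.std(a) == 0 or np.std(b) == 0:
        return None
    return float(np.corrcoef(a, b)[0, 1])


def annotate_features(
    edges: list[ExpressionEdge],
    called_sirnas: list[NatSiRna],
    profiles: dict[str, np.ndarray] | None = None,
    sim_threshold: float = DEFAULT_SIM_THRESHOLD,
) -> list[ExpressionEdge]:
    """Attach siRNA-production and modification-similarity features.

    An edge produces a NAT-siRNA when any called siRNA lists its pair id
    among source pairs.  The epigenetic feature holds when the absolute
    modification-profile PCC reaches ``sim_threshold``; a missing profile
    leaves the similarity undefined and the label falls back to the
    siRNA-only assessment.
    """
    sirna_pairs = {pid for s in called_sirnas for pid in s.source_pairs}
    for e in edges:
        e.produces_nat_sirna = e.pair_id in sirna_pairs
        sim = (modification_similarity(e.gene_a, e.gene_b, profiles)
               if profiles is not None else None)
        e.modification_similarity = sim
        epigenetic = sim is not None and abs(sim) >= sim_threshold
        if e.produces_nat_sirna and epigenetic:
            e.feature_label = "both"
        elif e.produces_nat_sirna:
            e.feature_label = "siRNA"
        elif epigenetic:
            e.feature_label = "epigenetic"
        else:
            e.feature_label = "none"
    return edges


def to_graph(
    edges: list[ExpressionEdge],
    biotypes: dict[str, str] | None = None,
) -> nx.Graph:
    g = nx.Graph()
    for e in edges:
        g.add_edge(
            e.gene_a, e.gene_b,
            pair_id=e.pair_id, nat_type=e.nat_type, pcc=round(e.pcc, 4),
            produces_nat_sirna=e.produces_nat_sirna,
            feature_label=e.feature_label,
            modification_similarity=(
                round(e.modification_similarity, 4)
                if e.modification_similarity is not None else "NA"
            ),
        )
    for node in g.nodes:
        g.nodes[node]["biotype"] = (biotypes or {}).get(node, "unknown")
        g.nodes[node]["degree"] = g.degree[node]
    return g


def edges_to_frame(edges: list[ExpressionEdge]) -> pd.DataFrame:
    rows = [
        {
            "pair_id": e.pair_id, "gene_a": e.gene_a, "gene_b": e.gene_b,
            "nat_type": e.nat_type, "pcc": round(e.pcc, 4),
            "n_shared_samples": e.n_shared_samples,
            "produces_nat_sirna": e.produces_nat_sirna,
            "modification_similarity": (
                round(e.modification_similarity, 4)
                if e.modification_similarity is not None else ""
            ),
            "feature_label": e.feature_label,
        }
        for e in edges
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "pair_id", "gene_a", "gene_b", "nat_type", "pcc",
            "n_shared_samples", "produces_nat_sirna",
            "modification_similarity", "feature_label",
        ],
    )


def write_network(edges: list[ExpressionEdge], tsv_path,
                  graphml_path=None, biotypes=None, **params) -> None:
    write_tsv(edges_to_frame(edges), tsv_path,
              params={"stage": "network", **params})
    if graphml_path is not None:
        nx.write_graphml(to_graph(edges, biotypes), str(graphml_path))
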