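"""End-to-end orchestration of the NAT analysis stages.

``run_pipeline`` drives the stages in dependency order — lncRNA filter,
cis-NAT identification, trans-NAT search, small-RNA library and NAT-siRNA
calling, overlap enrichment, chromatin pattern classification, DNA
methylation distance, and the coexpression network — reading the input
files named in a :class:`PipelineConfig` and writing one TSV per stage
(each with a ``#`` header recording the parameters used).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import (catalog, chromatin, cis_nat, enrichment, genome_io,
               methylation, network, sirna, trans_nat)

logger = logging.getLogger("natscape")


@dataclass
class PipelineConfig:
    """Every input path and numeric threshold of the pipeline, in one
    auditable place."""

    # inputs (set to None to skip the stage that needs them)
    annotation: str | None = None
    transcripts_fasta: str | None = None
    smrna: str | None = None
    exclusion: str | None = None
    tiles: str | None = None
    methylation_table: str | None = None
    expression: str | None = None
    dsrna: str | None = None
    candidates: str | None = None
    candidates_fasta: str | None = None

    # thresholds
    nearby_max_gap: int = 100
    min_overlap: int = 1
    min_region: int = 100
    min_identity: float = 0.8
    bubble_fraction: float = 0.10
    sirna_min_len: int = 18
    sirna_max_len: int = 28
    min_datasets: int = 3
    max_gap: int = 200
    min_domain: int = 400
    repeats: int = 10_000
    pcc_threshold: float = 0.8
    sim_threshold: float = 0.8
    lncrna_min_len: int = 200
    lncrna_max_orf: int = 120
    lncrna_max_coding_prob: float = 0.365
    lncrna_min_fpkm: float = 2.0
    meth_n_bins: int = 20
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.bubble_fraction < 1:
            raise ValueError("bubble_fraction must lie in (0, 1)")
        positive = {
            "nearby_max_gap": self.nearby_max_gap,
            "min_overlap": self.min_overlap,
            "min_region": self.min_region,
            "min_datasets": self.min_datasets,
            "max_gap": self.max_gap,
            "min_domain": self.min_domain,
            "repeats": self.repeats,
            "lncrna_min_len": self.lncrna_min_len,
            "lncrna_max_orf": self.lncrna_max_orf,
            "meth_n_bins": self.meth_n_bins,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def for_bundle(cls, bundle_dir: str | Path, **overrides) -> "PipelineConfig":
        """Point every input at the files of a synthetic bundle."""
        d = Path(bundle_dir)

        def maybe(name):
            p = d / name
            return str(p) if p.exists() else None

        return cls(
            annotation=maybe("annotation.gff3"),
            transcripts_fasta=maybe("transcripts.fa"),
            smrna=maybe("smrna.tsv"),
            exclusion=maybe("exclusion.bed"),
            tiles=maybe("tiles.bed"),
            methylation_table=maybe("methylation.tsv"),
            expression=maybe("expression.tsv"),
            dsrna=maybe("dsrna.bed"),
            candidates=maybe("candidates.tsv"),
            candidates_fasta=maybe("candidates.fa"),
            **overrides,
        )


@dataclass
class PipelineResult:
    catalog: list = field(default_factory=list)
    cis_pairs: list = field(default_factory=list)
    trans_pairs: list = field(default_factory=list)
    regions: list = field(default_factory=list)
    library: list = field(default_factory=list)
    called_sirnas: list = field(default_factory=list)
    domains: list = field(default_factory=list)
    states: dict = field(default_factory=dict)
    edges: list = field(default_factory=list)
    tables: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)


def _params(config: PipelineConfig) -> dict:
    return {k: v for k, v in dataclasses.asdict(config).items()
            if not isinstance(v, (str, type(None)))}


def run_pipeline(config: PipelineConfig, out_dir: str | Path
                 ) -> PipelineResult:
    """Run every stage the config provides inputs for; write one output
    table per stage under ``out_dir`` and return the in-memory results."""
    if config.annotation is None:
        raise ValueError("pipeline requires an annotation (GFF3)")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    res = PipelineResult()
    params = _params(config)

    transcripts = genome_io.read_gff3(config.annotation)
    tx_by_id = {t.transcript_id: t for t in transcripts}
    res.catalog = transcripts
    expression = (genome_io.read_expression_matrix(config.expression)
                  if config.expression else None)

    # --- lncRNA candidate filter -----------------------------------------
    if config.candidates and config.candidates_fasta:
        coding = genome_io.read_coding_table(config.candidates)
        seqs = genome_io.read_fasta(config.candidates_fasta)
        cands = catalog.candidates_from_tables(
            seqs, coding, expression if expression is not None
            else pd.DataFrame())
        _, report = catalog.filter_lncrna(
            cands, config.lncrna_min_len, config.lncrna_max_orf,
            config.lncrna_max_coding_prob, config.lncrna_min_fpkm)
        genome_io.write_tsv(report, out / "lncrna_filter.tsv", params)
        res.tables["lncrna_filter"] = report
        res.outputs["lncrna_filter"] = out / "lncrna_filter.tsv"

    # --- cis-NAT ----------------------------------------------------------
    res.cis_pairs = cis_nat.find_cis_pairs(
        transcripts, config.nearby_max_gap, config.min_overlap)
    cis_nat.write_cis_pairs(res.cis_pairs, out / "cis_pairs.tsv",
                            config.nearby_max_gap, config.min_overlap)
    res.outputs["cis_pairs"] = out / "cis_pairs.tsv"

    # --- trans-NAT --------------------------------------------------------
    if config.transcripts_fasta:
        seqs = genome_io.read_fasta(config.transcripts_fasta)
        res.trans_pairs, _rejected = trans_nat.find_trans_pairs(
            transcripts, seqs, config.min_region, config.min_identity,
            config.bubble_fraction)
        trans_nat.write_trans_pairs(
            res.trans_pairs, tx_by_id, out / "trans_pairs.tsv",
            min_region=config.min_region, min_identity=config.min_identity,
            bubble_fraction=config.bubble_fraction)
        res.outputs["trans_pairs"] = out / "trans_pairs.tsv"

    res.regions = sirna.pair_regions(res.cis_pairs, res.trans_pairs, tx_by_id)

    # --- small RNA --------------------------------------------------------
    if config.smrna:
        reads = genome_io.read_smrna_table(config.smrna)
        exclusion = (genome_io.read_bed_intervals(config.exclusion)
                     if config.exclusion else [])
        res.library, rejects = sirna.build_library(
            reads, exclusion, config.sirna_min_len, config.sirna_max_len)
        res.called_sirnas = sirna.call_nat_sirnas(
            res.library, res.regions, config.min_datasets)
        sirna.write_sirnas(res.called_sirnas, out / "nat_sirnas.tsv",
                           min_datasets=config.min_datasets, **rejects)
        summaries = sirna.summarize(res.called_sirnas, res.regions)
        genome_io.write_tsv(summaries["length_hist"],
                            out / "sirna_length_hist.tsv", params)
        genome_io.write_tsv(
            summaries["subtype_matrix"].rename_axis("nat_type"),
            out / "sirna_subtype_matrix.tsv", params, index=True)
        res.tables.update(summaries)
        res.outputs["nat_sirnas"] = out / "nat_sirnas.tsv"

        enr = enrichment.enrichment_table(res.regions, res.library, tx_by_id)
        enrichment.write_enrichment_table(enr, out / "enrichment.tsv")
        res.tables["enrichment"] = enr
        res.outputs["enrichment"] = out / "enrichment.tsv"

    if config.dsrna:
        dsrna_reads = genome_io.read_bed_intervals(config.dsrna)
        ds_table, ds_p = enrichment.dsrna_overlap_check(
            res.regions, dsrna_reads, tx_by_id)
        genome_io.write_tsv(ds_table, out / "dsrna_check.tsv",
                            {**params, "aggregate_p": ds_p})
        res.tables["dsrna_check"] = ds_table
        res.tables["dsrna_p"] = ds_p
        res.outputs["dsrna_check"] = out / "dsrna_check.tsv"

    # --- pair sets at gene level -------------------------------------------
    cis_overlap = [p for p in res.cis_pairs if p.overlap is not None]
    cis_gene_pairs = [
        (tx_by_id[p.transcript_a].gene_id, tx_by_id[p.transcript_b].gene_id)
        for p in cis_overlap
    ]
    trans_gene_pairs = [
        (tx_by_id[p.transcript_a].gene_id, tx_by_id[p.transcript_b].gene_id)
        for p in res.trans_pairs
    ]
    nat_gene_ids = {g for pair in cis_gene_pairs + trans_gene_pairs
                    for g in pair}
    nat_gene_ids |= {
        tx_by_id[t].gene_id
        for p in res.cis_pairs if p.overlap is None
        for t in (p.transcript_a, p.transcript_b)
    }
    non_nat_genes = [t for t in transcripts if t.gene_id not in nat_gene_ids]

    # --- chromatin ----------------------------------------------------------
    if config.tiles:
        tiles = genome_io.read_tiles(config.tiles)
        res.domains = chromatin.tiles_to_domains(
            tiles, config.max_gap, config.min_domain)
        chromatin.write_domains(res.domains, out / "domains.bed")
        res.states = chromatin.gene_states(transcripts, res.domains)
        state_rows = pd.DataFrame(
            [{"gene_id": g, "marks": ",".join(sorted(s.marks_present)),
              "group_state": s.group_state}
             for g, s in sorted(res.states.items())]
        )
        genome_io.write_tsv(state_rows, out / "gene_states.tsv", params)
        res.outputs["gene_states"] = out / "gene_states.tsv"

        # per-group state percentages, all genes and TE-only subsets
        cis_genes = sorted({g for ab in cis_gene_pairs for g in ab})
        trans_genes = sorted({g for ab in trans_gene_pairs for g in ab})
        non_nat_ids = [t.gene_id for t in non_nat_genes]
        te_ids = {t.gene_id for t in transcripts if t.biotype == "TE"}
        groups = {
            "cis_NAT": cis_genes, "trans_NAT": trans_genes,
            "non_NAT": non_nat_ids,
            "cis_NAT_TE": [g for g in cis_genes if g in te_ids],
            "trans_NAT_TE": [g for g in trans_genes if g in te_ids],
            "non_NAT_TE": [g for g in non_nat_ids if g in te_ids],
        }
        group_table = chromatin.group_state_percentages(res.states, groups)
        genome_io.write_tsv(group_table, out / "group_states.tsv", params)
        res.tables["group_states"] = group_table
        res.outputs["group_states"] = out / "group_states.tsv"

        profiles_table = pd.DataFrame(
            {mark: prof for mark, prof in chromatin.mark_profiles(
                transcripts, res.domains).items()}
        )
        profiles_table.insert(0, "bin", range(len(profiles_table)))
        genome_io.write_tsv(profiles_table, out / "metagene_profiles.tsv",
                            params)
        res.outputs["metagene_profiles"] = out / "metagene_profiles.tsv"

        pool = [res.states[t.gene_id].group_state for t in non_nat_genes]
        for name, gene_pairs in (("cis", cis_gene_pairs),
                                 ("trans", trans_gene_pairs)):
            if not gene_pairs:
                continue
            counts, dropped = chromatin.classify_pair_patterns(
                gene_pairs, res.states)
            null = None
            if len(pool) >= 2 * len(gene_pairs):
                null = chromatin.randomized_null(
                    pool, len(gene_pairs), config.repeats, config.seed)
            table = chromatin.pattern_table(counts, null)
            chromatin.write_pattern_table(
                table, out / f"pattern_{name}.tsv",
                dropped=dropped, repeats=config.repeats)
            res.tables[f"pattern_{name}"] = table
            res.outputs[f"pattern_{name}"] = out / f"pattern_{name}.tsv"

    # --- methylation ---------------------------------------------------------
    if config.methylation_table:
        sites = genome_io.read_methylation_table(config.methylation_table)
        pool_ids = [t.gene_id for t in non_nat_genes]
        gene_recs = {t.gene_id: t for t in transcripts}
        genes = list(gene_recs.values())
        dmc_tables = {}
        per_set_dmc = {}
        for name, gene_pairs in (("cis", cis_gene_pairs),
                                 ("trans", trans_gene_pairs)):
            if not gene_pairs:
                continue
            table = methylation.dmc_comparison_table(
                gene_pairs, pool_ids, genes, sites,
                repeats=config.repeats, seed=config.seed,
                n_bins=config.meth_n_bins)
            genome_io.write_tsv(table, out / f"dmc_{name}.tsv", params)
            dmc_tables[name] = table
            res.outputs[f"dmc_{name}"] = out / f"dmc_{name}.tsv"
            values = {}
            for region in methylation.REGIONS:
                for context in ("CG", "CHG", "CHH"):
                    levels = methylation.gene_region_levels(
                        genes, sites, region, context, config.meth_n_bins)
                    values[(region, context)] = methylation.pair_dmc_values(
                        gene_pairs, levels)
            per_set_dmc[name] = values
        if {"cis", "trans"} <= per_set_dmc.keys():
            comp = methylation.compare_cis_trans_distance(
                per_set_dmc["cis"], per_set_dmc["trans"])
            genome_io.write_tsv(comp, out / "dmc_cis_vs_trans.tsv", params)
            res.tables["dmc_cis_vs_trans"] = comp
            res.outputs["dmc_cis_vs_trans"] = out / "dmc_cis_vs_trans.tsv"
        res.tables.update({f"dmc_{k}": v for k, v in dmc_tables.items()})

    # --- network --------------------------------------------------------------
    if expression is not None:
        pairs = network.network_pairs(cis_overlap, res.trans_pairs, tx_by_id)
        edges, undefined = network.build_network(
            pairs, expression, config.pcc_threshold, config.min_datasets)
        profiles = None
        if res.domains:
            profiles = {
                t.gene_id: chromatin.gene_modification_profile(t, res.domains)
                for t in transcripts
            }
        network.annotate_features(edges, res.called_sirnas, profiles,
                                  config.sim_threshold)
        biotypes = {t.gene_id: t.biotype for t in transcripts}
        network.write_network(
            edges, out / "network_edges.tsv", out / "network.graphml",
            biotypes, pcc_threshold=config.pcc_threshold,
            n_undefined=len(undefined))
        res.edges = edges
        res.outputs["network_edges"] = out / "network_edges.tsv"

    logger.info("pipeline finished: %d outputs in %s", len(res.outputs), out)
    return res
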