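import logging

import pytest

from natscape.genome_io import GenomicInterval, TranscriptRecord
from natscape.synth import SynthConfig, generate_bundle

logging.getLogger("natscape").setLevel(logging.ERROR)


def make_tx(tid, chrom, start, end, strand, biotype="PC", gene=None, cds=None):
    return TranscriptRecord(
        transcript_id=tid,
        gene_id=gene or tid.split(".")[0],
        interval=GenomicInterval(chrom, start, end, strand),
        biotype=biotype,
        cds=cds,
    )


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """One full-size synthetic bundle shared across the session."""
    out = tmp_path_factory.mktemp("bundle")
    bundle = generate_bundle(SynthConfig(seed=1), out_dir=out)
    return bundle, out


@pytest.fixture(scope="session")
def bundle_analysis(default_bundle):
    """Expensive stage outputs on the session bundle, computed once:
    cis pairs, trans pairs, duplex regions, filtered library, called
    NAT-siRNAs."""
    from natscape import genome_io as gio
    from natscape.cis_nat import find_cis_pairs
    from natscape.trans_nat import find_trans_pairs
    from natscape.sirna import build_library, call_nat_sirnas, pair_regions

    bundle, bundle_dir = default_bundle
    tx_by_id = {t.transcript_id: t for t in bundle.transcripts}
    cis = find_cis_pairs(bundle.transcripts)
    seqs = gio.read_fasta(bundle_dir / "transcripts.fa")
    trans, trans_rejected = find_trans_pairs(bundle.transcripts, seqs)
    regions = pair_regions(cis, trans, tx_by_id)
    reads = gio.read_smrna_table(bundle_dir / "smrna.tsv")
    exclusion = gio.read_bed_intervals(bundle_dir / "exclusion.bed")
    library, _ = build_library(reads, exclusion)
    called = call_nat_sirnas(library, regions)
    return {
        "tx_by_id": tx_by_id, "cis": cis, "trans": trans,
        "trans_rejected": trans_rejected, "regions": regions,
        "library": library, "called": called,
    }


@pytest.fixture(scope="session")
def small_bundle():
    """A light in-memory bundle (annotation + smrna layers only)."""
    return generate_bundle(SynthConfig.small(seed=7),
                           layers={"annotation", "smrna"})
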