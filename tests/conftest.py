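import numpy as np
import pytest

from ripitseq.annotation import GeneModel, TranscriptRecord
from ripitseq.simulate import SimConfig, simulate_dataset


def make_gene(gene_id="g1", chrom="chr1", strand="+", exons=((1000, 1500),), tss=None):
    union = tuple(sorted(exons))
    if tss is None:
        tss = union[0][0] if strand == "+" else union[-1][1]
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        exon_union=union,
        exonic_length=sum(e - s for s, e in union),
        tss=tss,
        member_transcripts=(gene_id + ".1",),
    )


def make_transcript(tx_id, chrom="chr1", strand="+", exons=((0, 100),), symbol="", source="src"):
    exons = tuple(sorted(exons))
    return TranscriptRecord(
        transcript_id=tx_id,
        gene_symbol=symbol,
        chrom=chrom,
        strand=strand,
        tx_start=exons[0][0],
        tx_end=exons[-1][1],
        exons=exons,
        source=source,
    )


@pytest.fixture(scope="session")
def small_sim():
    """One small, fully ground-truthed simulated dataset shared across tests."""
    cfg = SimConfig(
        seed=42,
        n_genes=120,
        n_chroms=2,
        chrom_length=800_000,
        depth=8e4,
        binder_peak_fraction=0.7,
    )
    records, genes, table, truth, peaks, track = simulate_dataset(cfg)
    return {
        "config": cfg,
        "records": records,
        "genes": genes,
        "table": table,
        "truth": truth,
        "peaks": peaks,
        "track": track,
    }
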