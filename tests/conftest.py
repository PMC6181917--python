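import pytest

from splicescape.annotation_model import GeneModel, TranscriptModel
from splicescape.synthetic_data import (
    SimulationConfig,
    simulate_annotation,
    simulate_junction_counts,
)


def make_transcript(
    tid,
    exons,
    strand="+",
    gene_id="g1",
    chrom="chr1",
    cds_span=None,
    novelty="known",
):
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        exons=tuple(exons),
        cds_span=cds_span,
        novelty=novelty,
    )


def make_gene(transcripts, gene_id="g1"):
    t0 = transcripts[0]
    return GeneModel(gene_id, t0.chrom, t0.strand, list(transcripts))


@pytest.fixture(scope="session")
def sim_small():
    """A small simulated dataset shared across integration-style tests."""
    cfg = SimulationConfig(n_genes=40, rng_seed=11, artifact_fraction=0.05)
    ann = simulate_annotation(cfg)
    counts = simulate_junction_counts(ann, cfg)
    return cfg, ann, counts
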