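import numpy as np
import pandas as pd
import pytest

from psiexon.core_io import (
    GenomeSequence,
    JunctionTable,
    JUNCTION_COLUMNS,
    SampleManifest,
    TranscriptModel,
)
from psiexon.synthetic_data import SimConfig, simulate_genome, simulate_junction_counts


def make_junctions(rows):
    """rows: (contig, donor, acceptor, strand, sample, count)."""
    return JunctionTable(pd.DataFrame(rows, columns=JUNCTION_COLUMNS))


def make_manifest(groups: dict[str, list[str]]) -> SampleManifest:
    rows = [
        {"sample_id": s, "group": g, "replicate": i + 1}
        for g, samples in groups.items()
        for i, s in enumerate(samples)
    ]
    return SampleManifest(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def sim_corpus():
    """Small planted corpus shared by read-only tests."""
    config = SimConfig(
        seed=11,
        n_genes=8,
        n_pass=4,
        n_decoy_short=1,
        n_decoy_long=1,
        n_decoy_weak=1,
        n_decoy_annotated=1,
    )
    sim = simulate_genome(config)
    junctions, manifest, event_truth = simulate_junction_counts(sim)
    return sim, junctions, manifest, event_truth


@pytest.fixture()
def three_exon_gene():
    """Plus-strand 3-exon toy gene: exons [0,100), [200,300), [400,500)."""
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGT"), size=600))
    genome = GenomeSequence({"chrT": seq})
    tx = TranscriptModel(
        gene_id="GT1",
        transcript_id="GT1.t1",
        contig="chrT",
        strand="+",
        exons=[(0, 100), (200, 300), (400, 500)],
        cds=(10, 480),
        source="refA",
    )
    return genome, tx
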