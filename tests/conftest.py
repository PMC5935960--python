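import numpy as np
import pytest

from lncflow.genomic_io import GenomicInterval, TranscriptModel
from lncflow.synthetic_data import (
    SimulationConfig,
    simulate_expression,
    simulate_genome,
    simulate_methylation,
)


@pytest.fixture(scope="session")
def noise_free_config():
    return SimulationConfig(seed=11, fpkm_dispersion=0.0, meth_concentration=None)


@pytest.fixture(scope="session")
def sim(noise_free_config):
    """A complete noise-free simulated dataset with planted truth."""
    ds = simulate_genome(noise_free_config)
    simulate_expression(ds)
    return ds


@pytest.fixture(scope="session")
def meth_records(sim):
    return simulate_methylation(sim)


def make_transcript(tid, chrom, exon_coords, strand, biotype="novel"):
    exons = [GenomicInterval(chrom, s, e, strand) for s, e in exon_coords]
    return TranscriptModel.from_exons(tid, f"g_{tid}", exons, biotype)


@pytest.fixture
def two_exon_reference():
    """Reference transcript with exons [1000,1500) and [2000,2500) on +."""
    return make_transcript(
        "ref1", "chr1", [(1000, 1500), (2000, 2500)], "+", biotype="coding"
    )


def random_transcript(rng, tid="t", chrom="chr1", strand=None, max_pos=10_000):
    """Random multi-exon transcript for oracle comparisons."""
    n_exons = int(rng.integers(1, 4))
    pos = int(rng.integers(0, max_pos))
    exons = []
    for _ in range(n_exons):
        length = int(rng.integers(50, 400))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(20, 300))
    strand = strand or ("+" if rng.random() < 0.5 else "-")
    return make_transcript(tid, chrom, exons, strand)
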