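import numpy as np
import pytest

from loophub.core.genes import Gene, GeneModel
from loophub.core.intervals import Genome, GenomicInterval
from loophub.simulate import SimulationConfig, simulate_dataset


def small_sim_config(seed=29, **overrides):
    kwargs = dict(
        seed=seed,
        n_chrom=2,
        chrom_length=4_000_000,
        n_genes=80,
        n_constitutive_peaks=200,
        n_condition_specific_peaks=40,
        n_hubs=12,
        archetype_sizes=(8, 12, 4, 14),
        n_decoy_loops=30,
        specific_loop_fraction=1.0,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def small_config():
    return small_sim_config()


@pytest.fixture(scope="session")
def small_ds(small_config):
    """Small synthetic dataset without contact matrices (shared, read-only)."""
    return simulate_dataset(small_config, with_matrix=False)


@pytest.fixture(scope="session")
def tiny_matrix_ds():
    """Very small dataset including contact matrices."""
    cfg = small_sim_config(
        seed=11,
        chrom_length=2_000_000,
        n_genes=40,
        n_constitutive_peaks=80,
        n_condition_specific_peaks=16,
        n_hubs=8,
        archetype_sizes=(4, 6, 2, 8),
        n_decoy_loops=10,
        loop_distance_range=(50_000, 1_000_000),
    )
    return simulate_dataset(cfg, with_matrix=True)


@pytest.fixture
def toy_genome():
    return Genome({"chr1": 1_000_000, "chr2": 500_000})


@pytest.fixture
def toy_gene_model():
    # + strand gene with two exons, - strand gene with one exon
    g1 = Gene(
        GenomicInterval("chr1", 10_000, 40_000, "+", "gplus"),
        [
            GenomicInterval("chr1", 10_000, 15_000, "+"),
            GenomicInterval("chr1", 30_000, 40_000, "+"),
        ],
    )
    g2 = Gene(
        GenomicInterval("chr1", 100_000, 130_000, "-", "gminus"),
        [GenomicInterval("chr1", 120_000, 130_000, "-")],
    )
    return GeneModel([g1, g2])


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=1_000_000, max_len=5_000):
    out = []
    for i in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, span - max_len))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length, name=f"i{i}"))
    return out
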