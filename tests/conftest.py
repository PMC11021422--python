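import numpy as np
import pandas as pd
import pytest

from finechrom.formats_io import ChromSizes, GeneModel, pairs_frame
from finechrom.synthetic_data import SimulationConfig, generate_genome, plant_loops


@pytest.fixture(scope="session")
def small_config():
    """Compact synthetic study: two 500 kb chromosomes, 200 genes, 40 loops.

    Per-bin-pair contact density matches the full-scale conditions when
    simulated with n_pairs=150_000.
    """
    return SimulationConfig(seed=11, n_chroms=2, chrom_length=500_000,
                            n_genes=200, n_background_pairs=150_000,
                            n_loops=40, n_enhancers=20, hotspot_degree=15)


@pytest.fixture(scope="session")
def small_genome(small_config):
    chromsizes, genes, enhancers = generate_genome(small_config)
    return chromsizes, genes, enhancers


@pytest.fixture(scope="session")
def small_truth(small_config, small_genome):
    chromsizes, genes, _ = small_genome
    return plant_loops(small_config, chromsizes, genes)


@pytest.fixture()
def toy_chromsizes():
    return ChromSizes({"chr1": 10_000, "chr2": 8_000})


@pytest.fixture()
def toy_pairs(toy_chromsizes):
    return pairs_frame([
        ("chr1", 50, "+", "chr1", 100, "+", 30, 30),
        ("chr1", 150, "-", "chr1", 450, "+", 60, 60),
        ("chr1", 200, "+", "chr2", 300, "-", 60, 60),
        ("chr2", 10, "+", "chr2", 5_000, "-", 60, 9),
    ])


def plus_gene(gene_id="gA", chrom="chr1", start=1_000, end=3_000,
              exons=None, strand="+"):
    if exons is None:
        exons = [(start, start + 500), (start + 800, end)]
    return GeneModel(gene_id, chrom, start, end, strand, exons)
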