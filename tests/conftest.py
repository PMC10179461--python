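import numpy as np
import pandas as pd
import pytest

from lncdosage import CountMatrix, GeneRecord, SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A compact simulated experiment shared across tests (seed fixed)."""
    config = SimulationConfig(
        genes_per_chromosome={"2L": 120, "3R": 120, "X": 120, "mito": 20},
        class_mixture={
            "2L": {"inverse": 0.6, "compensated": 0.4},
            "3R": {"inverse": 0.5, "compensated": 0.4, "double_inverse": 0.1},
            "X": {"compensated": 0.8, "dosage_effect": 0.2},
            "mito": {"dosage_effect": 0.7, "double_inverse": 0.3},
        },
        n_cis_planted=8,
        n_trans_planted=8,
        nb_dispersion=0.01,
        seed=7,
    )
    return simulate_dataset(config)


@pytest.fixture
def tiny_counts():
    """Hand-built 4-gene, 2v2 count matrix."""
    counts = pd.DataFrame(
        {
            "c1": [100, 200, 300, 400],
            "c2": [110, 190, 310, 390],
            "t1": [150, 200, 300, 350],
            "t2": [160, 210, 290, 340],
        },
        index=pd.Index(["g1", "g2", "g3", "g4"], name="gene_id"),
    )
    groups = {"c1": "control", "c2": "control", "t1": "case", "t2": "case"}
    return CountMatrix(counts=counts, groups=groups)


def make_gene(gene_id="g", chrom="2L", start=100, end=200, strand="+", biotype="coding"):
    return GeneRecord(gene_id=gene_id, chrom=chrom, start=start, end=end, strand=strand, biotype=biotype)


@pytest.fixture
def gene_factory():
    return make_gene
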