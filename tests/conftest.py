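import numpy as np
import pandas as pd
import pytest

from methylink.io_formats import GeneModel
from methylink.synthetic_data import SimulationConfig, simulate_dataset


def make_calls(rows, sample_id="s1"):
    """Call frame from (chrom, pos0, strand, context, meth, total) tuples."""
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context",
                                     "meth_count", "total_count"])
    df["sample_id"] = sample_id
    return df


@pytest.fixture
def plus_gene():
    return GeneModel("geneA", "chr1", 5000, 8000, "+")


@pytest.fixture
def minus_gene():
    return GeneModel("geneB", "chr1", 5000, 8000, "-")


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete synthetic bundle shared by read-only tests."""
    cfg = SimulationConfig(seed=7, n_genes=60, n_dmrs=8, n_degs=10)
    return simulate_dataset(cfg)
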