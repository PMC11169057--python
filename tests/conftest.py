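import numpy as np
import pandas as pd
import pytest

from modnet import datasets
from modnet.expression import CountMatrix, fpkm


def log_fpkm(ds: datasets.SimulatedDataset) -> pd.DataFrame:
    """log2(FPKM+1) on median-of-ratios-normalized counts."""
    cm = CountMatrix(ds.counts, ds.gene_lengths)
    return np.log2(fpkm(cm).values + 1.0)


@pytest.fixture(scope="session")
def default_ds() -> datasets.SimulatedDataset:
    """Study-scale-down fixture: 40 TFs, 10 modules x 20 genes, 2 x 3 samples."""
    return datasets.default_fixture(seed=3)


@pytest.fixture(scope="session")
def wide_ds() -> datasets.SimulatedDataset:
    """30-condition fixture where network inference is statistically informative."""
    return datasets.wide_fixture(seed=0)


@pytest.fixture(scope="session")
def small_counts() -> CountMatrix:
    """Tiny deterministic count matrix with lengths, for hand-oracle tests."""
    values = pd.DataFrame(
        {
            "s1": [10, 100, 5, 0],
            "s2": [20, 200, 10, 0],
            "s3": [15, 150, 8, 0],
        },
        index=["g1", "g2", "g3", "g0"],
    )
    lengths = pd.Series([1000, 2000, 500, 800], index=["g1", "g2", "g3", "g0"])
    return CountMatrix(values, lengths)
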