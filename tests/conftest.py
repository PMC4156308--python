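import numpy as np
import pandas as pd
import pytest

from ntreprog import synthetic_data as sd
from ntreprog.io_formats import CountMatrix


@pytest.fixture(scope="session")
def toy_genomes():
    """Small divergent host/recipient genome pair shared across tests."""
    return sd.build_toy_genomes(n_chroms=1, chrom_length=200_000, n_genes=20, seed=11)


@pytest.fixture(scope="session")
def b4_reads(toy_genomes):
    host, recip = toy_genomes
    params = sd.ChipSimParams(n_reads=20_000, seed=21)
    return sd.simulate_chip_reads(host, recip, params, "B4")


@pytest.fixture()
def small_counts():
    """2 genes x 3 samples with hand-checkable numbers."""
    df = pd.DataFrame(
        {"s1": [10, 90], "s2": [20, 80], "s3": [30, 70]},
        index=["gA", "gB"],
    )
    cond = {"s1": "donor", "s2": "donor", "s3": "NT"}
    rep = {"s1": 1, "s2": 2, "s3": 1}
    return CountMatrix.from_frame(df, cond, rep)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
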