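import numpy as np
import pandas as pd
import pytest

from karstnet import OtuTable, generate_basis_correlation, generate_design, generate_otu_table


@pytest.fixture(scope="session")
def design40() -> pd.DataFrame:
    """The emulated field design: 8 treatments x 5 blocks."""
    return generate_design(5)


@pytest.fixture(scope="session")
def small_table(design40) -> OtuTable:
    """A 40-sample, 30-taxon synthetic table with one strong planted pair."""
    truth = generate_basis_correlation(30, [(1, 2, 0.8)])
    return generate_otu_table(design40, truth, seed=7)


@pytest.fixture(scope="session")
def null_table(design40) -> OtuTable:
    """Independent-taxa table (identity basis correlation)."""
    truth = generate_basis_correlation(30, [])
    return generate_otu_table(design40, truth, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
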