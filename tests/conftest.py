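import numpy as np
import pytest

from zfcoscan.sequence_scan import BackgroundModel
from zfcoscan.synthetic_data import (SyntheticConfig, generate_dataset,
                                     make_background_model,
                                     make_erm_like_protein_fixture)


@pytest.fixture(scope="session")
def fixture_protein():
    protein, table = make_erm_like_protein_fixture()
    return protein, table


@pytest.fixture(scope="session")
def uniform_bg():
    return BackgroundModel.uniform(order=0)


@pytest.fixture(scope="session")
def small_dataset():
    """Reduced synthetic dataset for fast unit tests (not the study size)."""
    cfg = SyntheticConfig(n_positive_windows=60, n_background_windows=60,
                          flank=100, seed=11)
    return generate_dataset(cfg), make_background_model(cfg)


@pytest.fixture(scope="session")
def default_dataset():
    """The full default-condition dataset (270 + 270 windows of 401 bp)."""
    cfg = SyntheticConfig(seed=1)
    return generate_dataset(cfg), make_background_model(cfg)
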