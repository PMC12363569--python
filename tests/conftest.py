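import numpy as np
import pytest

from locforge.dataset import LabelOntology
from locforge.descriptors import ALPHABET, DescriptorConfig


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_config():
    """Descriptor config with small lags so short test sequences are valid."""
    return DescriptorConfig(autocorr_lag_max=3, qso_lag_max=3, paac_lambda=3)


@pytest.fixture(scope="session")
def tiered_ontology():
    """Three-tier hierarchy: centromere -> chromosome -> nucleus."""
    return LabelOntology(
        {
            "nucleus": None,
            "cytoplasm": None,
            "chromosome": "nucleus",
            "nuclear body": "nucleus",
            "centromere": "chromosome",
        }
    )


def random_sequence(rng, length):
    return "".join(ALPHABET[i] for i in rng.integers(0, 20, size=length))
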