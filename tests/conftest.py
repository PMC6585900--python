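import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from prtup import (
    EncodingConfig,
    PropertyTable,
    SyntheticSpec,
    encode_dataset,
    generate,
)


@pytest.fixture(scope="session")
def table():
    return PropertyTable.default()


@pytest.fixture(scope="session")
def planted_dataset():
    """Strong tripeptide-enrichment signal: motif HAI in every positive."""
    spec = SyntheticSpec(
        n_pos=60, n_neg=60, signal_type="tripeptide-enrichment",
        effect_size=1.0, enriched_motifs=("HAI",), seed=11,
    )
    return generate(spec)


@pytest.fixture(scope="session")
def planted_encoded(planted_dataset, table):
    cfg = EncodingConfig(lam=3, w=0.15)
    X = encode_dataset(planted_dataset.peptides, cfg, table)
    return X, np.asarray(planted_dataset.labels)


@pytest.fixture(scope="session")
def null_dataset():
    spec = SyntheticSpec(n_pos=100, n_neg=100, signal_type="none", seed=7)
    return generate(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
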