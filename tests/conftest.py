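import numpy as np
import pytest

from lglink.io import Config, SupplementConfig
from lglink.synthetic import SyntheticSpec, generate


@pytest.fixture(scope="session")
def tiny_data():
    """Small planted-block dataset for fast model tests."""
    spec = SyntheticSpec(m=30, n=8, k_blocks=2, p_in=0.5, p_out=0.05, seed=7)
    assoc, S_p, S_d, truth = generate(spec)
    return assoc, S_p, S_d, truth


@pytest.fixture(scope="session")
def fast_config():
    """Config scaled down for unit tests (model shape intact, budgets small)."""
    return Config(
        epochs_global=40,
        embed_dim=16,
        dense_dims=(24, 16, 8),
        epochs_local=3,
        local_width=8,
        mlp_hidden=32,
        supplement=SupplementConfig(n_base=3),
    )


def random_similarity(rng: np.random.Generator, k: int) -> np.ndarray:
    """Random valid similarity matrix: symmetric, [0,1], unit diagonal."""
    S = rng.uniform(0.0, 1.0, size=(k, k))
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return S
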