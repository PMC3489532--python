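import numpy as np
import pytest

from psmix.mixture import ComponentDistribution
from psmix.synth import ChargeBlock, SimulationConfig, simulate_psms


NEG_GAMMA = dict(kind="shifted_gamma", alpha=4.0, beta=2.0, shift=-3.0)
POS_NORMAL = dict(kind="normal", mu=3.0, sigma=1.0)


def make_block(**overrides) -> ChargeBlock:
    """A well-separated Normal/shifted-Gamma block; overrides tweak fields."""
    kwargs = dict(
        charge=2,
        pi0=0.7,
        negative=ComponentDistribution(**NEG_GAMMA),
        positive=ComponentDistribution(**POS_NORMAL),
        n_targets=10_000,
        n_decoys=0,
    )
    kwargs.update(overrides)
    return ChargeBlock(**kwargs)


@pytest.fixture(scope="session")
def reference_table():
    """10k-target table from the canonical simulation (pi0=0.7, N(3,1) vs -3+Gamma(4,2))."""
    return simulate_psms(SimulationConfig(blocks=[make_block()], seed=42))


@pytest.fixture(scope="session")
def reference_table_with_decoys():
    """Same mixture plus 7k decoys drawn from the negative component."""
    return simulate_psms(SimulationConfig(blocks=[make_block(n_decoys=7000)], seed=42))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20251001)
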