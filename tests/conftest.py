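import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from racer import SyntheticConfig, generate_bundle


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic cohort shared by read-only tests."""
    config = SyntheticConfig(G=80, M=6, T=4, N=16, edge_density=0.15, seed=7)
    return generate_bundle(config)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Fully specified, noise-free cohort for exact-recovery checks."""
    config = SyntheticConfig(
        G=120, M=5, T=4, N=12, edge_density=0.2, noise_sd=0.0,
        effect_fraction=1.0, seed=11,
    )
    return generate_bundle(config)
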