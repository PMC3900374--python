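"""Shared fixtures: one simulated coupled study reused across the suite.

The reference study mirrors the recorded field design at reduced length:
four dogs, 14 walks of 600 s at 5 Hz, three imposed leader-follower
couplings (D1->D2 at 0.4 s, D1->D3 at 0.8 s, D2->D3 at 0.4 s) and one
uncoupled dog, with default heading/GPS noise.
"""

import numpy as np
import pytest

from walkleader import Coupling, DelayConfig, SimConfig, analyze_study, generate_study

TRUE_DELAYS = {("D1", "D2"): 0.4, ("D1", "D3"): 0.8, ("D2", "D3"): 0.4}


def coupled_config(**overrides) -> SimConfig:
    base = dict(
        n_dogs=4,
        duration=600.0,
        coupling={
            (1, 2): Coupling(0.4),
            (1, 3): Coupling(0.8),
            (2, 3): Coupling(0.4),
        },
        seed=0,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def coupled_study():
    walks, truth = generate_study(coupled_config(), n_walks=14, seed=1)
    return walks, truth


@pytest.fixture(scope="session")
def coupled_result(coupled_study):
    walks, _ = coupled_study
    return analyze_study(walks, DelayConfig(), seed=1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
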