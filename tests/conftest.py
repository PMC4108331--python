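import numpy as np
import pytest

from limits import (
    InteractionMatrix,
    NoiseSpec,
    generate_random_interactions,
    simulate,
)


@pytest.fixture
def single_species():
    """1-D self-limiting community: c = -0.5, xbar = 1 (map Jacobian 0.5)."""
    return InteractionMatrix(coefficients=[[-0.5]], equilibrium=[1.0])


@pytest.fixture
def two_species():
    """Stable 2-species community with one directed interaction (1 -> 0)."""
    return InteractionMatrix(
        coefficients=[[-0.8, 0.3], [0.0, -0.6]], equilibrium=[1.0, 2.0]
    )


@pytest.fixture
def chain_model():
    """3-species chain 0 -> 1 -> 2 with no direct 0 -> 2 coupling."""
    return InteractionMatrix(
        coefficients=[[-0.2, 0.0, 0.0], [0.5, -0.2, 0.0], [0.0, 0.5, -0.2]],
        equilibrium=[1.0, 1.0, 1.0],
    )


@pytest.fixture(scope="session")
def random_model():
    return generate_random_interactions(10, seed=42)


@pytest.fixture(scope="session")
def noisy_series(random_model):
    """Stable 10-species community observed with process noise only."""
    return simulate(
        random_model, T=500, R=10, noise=NoiseSpec(sigma_process=0.05), seed=7
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def recovery_panel():
    """20 random stable 10-species communities with process-noise-only data
    (10 initial conditions x 500 steps) and their LIMITS fits."""
    from limits import LimitsConfig, limits_infer
    from limits.network_eval import recovery_r2

    panel = []
    for k in range(20):
        model = generate_random_interactions(10, seed=500 + k)
        ts = simulate(model, T=500, R=10, noise=NoiseSpec(sigma_process=0.05), seed=600 + k)
        net = limits_infer(ts, LimitsConfig(threshold=0.05, n_bootstrap=25, seed=k))
        panel.append((model, ts, net, recovery_r2(model, net).r_squared))
    return panel
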