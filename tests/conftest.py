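import numpy as np
import pytest

from burstkit.model import ModelSpec, RateParameters


@pytest.fixture(scope="session")
def two_state_spec() -> ModelSpec:
    return ModelSpec(n_states=2, n_alleles=1)


@pytest.fixture(scope="session")
def bursty_rates() -> RateParameters:
    # slow-switching, high-output gene: clearly non-Poisson histogram
    return RateParameters.two_state(k_on=0.01, k_off=0.1, k_eject=0.5, k_decay=0.005)


@pytest.fixture(scope="session")
def rate_grid() -> list[tuple[float, float, float]]:
    """Decay-scaled (alpha, beta, nu) grid spanning the regimes of interest."""
    return [
        (a, b, nu)
        for a in (0.05, 0.3, 2.0, 8.0, 20.0)
        for b in (0.05, 0.5, 3.0, 20.0)
        for nu in (0.5, 8.0, 100.0)
    ][:50]


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240809)
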