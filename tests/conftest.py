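import numpy as np
import pytest

from switchfix import GameSpec, birth_death_model, two_env_chain


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def sweep_spec():
    """Switching-game parameters of the main sweep: N=50, beta=0.5, b=0.5, c=0.9."""
    return GameSpec.switching_game(b=0.5, c=0.9, beta=0.5, N=50)


@pytest.fixture(scope="session")
def sweep_model(sweep_spec):
    return birth_death_model(sweep_spec)


@pytest.fixture(scope="session")
def mutation_spec():
    """Mutation-model parameters of the stationary study: u=0.02 added."""
    return GameSpec.switching_game(b=0.5, c=0.9, beta=0.5, N=50, u=0.02)


@pytest.fixture(scope="session")
def mutation_model(mutation_spec):
    return birth_death_model(mutation_spec)


@pytest.fixture(scope="session")
def warm_engine():
    """Trigger numba compilation once so individual tests time only physics."""
    import switchfix as sf
    spec = GameSpec.switching_game(b=0.5, c=0.9, beta=0.5, N=6)
    model = birth_death_model(spec)
    chain = two_env_chain(0.1, 0.1)
    sf.estimate_fixation(model, chain, i0=1, sigma0=+1, n_runs=2, seed=0)
    spec_u = GameSpec.switching_game(b=0.5, c=0.9, beta=0.5, N=6, u=0.05)
    sf.ensemble_distribution(birth_death_model(spec_u), chain, n_runs=2,
                             T_generations=2, seed=0)
    return True
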