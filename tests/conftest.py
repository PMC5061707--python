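import numpy as np
import pytest

import llsurv as L


@pytest.fixture(scope="session")
def bladder() -> L.SurvivalSample:
    return L.load_bladder_fixture()


@pytest.fixture(scope="session")
def bladder_mle(bladder) -> L.MLEResult:
    return L.fit_mle(bladder)


@pytest.fixture(scope="session")
def bladder_chains(bladder) -> list[L.ChainDraws]:
    """A moderate two-chain run on the fixture, shared across tests."""
    cfg = L.MCMCConfig(n_iter=12_000, burn_in=2_000, thin=5, n_chains=2, seed=7)
    return L.sample_posterior(bladder, config=cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
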