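import numpy as np
import pytest

import sealbycatch as sb


@pytest.fixture(scope="session")
def fixture_dataset() -> sb.StudyDataset:
    return sb.load_table1_fixture()


@pytest.fixture(scope="session")
def default_priors(fixture_dataset) -> sb.PriorSpec:
    return sb.build_default_priors(fixture_dataset)


@pytest.fixture(scope="session")
def fixture_chain(fixture_dataset, default_priors) -> sb.ChainResult:
    """One moderate-length fit of the full survey, shared across tests.

    Two chains of 25k iterations (10k burn-in, thin 5) give ~6000 draws,
    enough for stable medians and the central 90% interval.
    """
    config = sb.RunConfig(
        seed=11, n_chains=2, n_iterations=25_000, n_burnin=10_000, thinning=5
    )
    return sb.run_mcmc(fixture_dataset, default_priors, config)


@pytest.fixture(scope="session")
def fixture_bycatch(fixture_chain, fixture_dataset) -> sb.BycatchDraws:
    return sb.predict_total(fixture_chain, fixture_dataset, seed=101)


@pytest.fixture
def short_config() -> sb.RunConfig:
    return sb.RunConfig(
        seed=5, n_chains=1, n_iterations=4_000, n_burnin=2_000, thinning=2
    )
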