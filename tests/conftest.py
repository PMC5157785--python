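import numpy as np
import pytest

from satox import (
    ModelParams,
    PatientRecord,
    PriorSpec,
    TrialData,
    MCMCConfig,
    REDUCED_MCMC,
    PAPER_GRID,
    load_packaged_scenarios,
)


@pytest.fixture(scope="session")
def grid():
    return PAPER_GRID


@pytest.fixture(scope="session")
def prior():
    return PriorSpec()


@pytest.fixture(scope="session")
def reduced_mcmc():
    return REDUCED_MCMC


@pytest.fixture(scope="session")
def full_mcmc():
    return MCMCConfig()


@pytest.fixture(scope="session")
def scenarios():
    return load_packaged_scenarios()


def draw_prior_params(rng, prior=PriorSpec(), with_lambda=True) -> ModelParams:
    """One draw from the design priors (for property tests)."""
    a_lo, a_hi = prior.alpha_range
    b_lo, b_hi = prior.beta_range
    la, lb = prior.lambda_beta_shapes
    return ModelParams(
        alpha=rng.uniform(a_lo, a_hi),
        beta=rng.uniform(b_lo, b_hi),
        gamma=rng.normal(prior.gamma_mean, np.sqrt(prior.gamma_var)),
        lam=rng.beta(la, lb) if with_lambda else 0.0,
    )


def random_dataset(rng, grid=PAPER_GRID, n=6) -> TrialData:
    """A random but internally consistent trinary-outcome dataset."""
    data = TrialData(grid=grid)
    for _ in range(n):
        y = int(rng.integers(0, 3))
        data.add(
            PatientRecord(
                a_idx=int(rng.integers(1, grid.J + 1)),
                b_idx=int(rng.integers(1, grid.K + 1)),
                b_administered=(y != 1),
                outcome=y,
            )
        )
    return data
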