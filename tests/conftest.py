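import numpy as np
import pytest

from shrinksurv import (
    DynamicSurvivalModel,
    IntervalPartition,
    PosteriorDraws,
    SurvivalDataset,
    build_gumbel_mixture,
)


@pytest.fixture(scope="session")
def gumbel_mixture():
    return build_gumbel_mixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_draws(beta, partition, theta=None, **extra):
    """Assemble a minimal PosteriorDraws object from explicit coefficient paths.

    ``beta`` has shape (D, J+1, m); scalar shrinkage fields are filled with
    placeholder ones so prediction code can run on hand-built posteriors.
    """
    beta = np.asarray(beta, dtype=float)
    D, _, m = beta.shape
    if theta is None:
        theta = np.full((D, m), 1e-12)
    ones_m = np.ones((D, m))
    ones_d = np.ones(D)
    return PosteriorDraws(
        beta=beta,
        beta_mean=beta[:, 0, :],
        theta=np.asarray(theta, dtype=float),
        lam_beta=ones_m,
        tau_beta=ones_d,
        lam_theta=ones_m,
        tau_theta=ones_d,
        a_beta=ones_d * 0.1,
        c_beta=ones_d * 0.1,
        a_theta=ones_d * 0.1,
        c_theta=ones_d * 0.1,
        partition=partition,
        covar_names=[f"z{k + 1}" for k in range(m - 1)],
        seed=0,
        **extra,
    )


@pytest.fixture(scope="session")
def small_exponential_fit():
    """A short fit on clean constant-hazard data, reused by several tests."""
    rng = np.random.default_rng(7)
    N = 300
    Z = rng.standard_normal((N, 2))
    beta_true = np.array([0.3, -1.0, 1.5])
    lam = np.exp(beta_true[0] + Z @ beta_true[1:])
    y = rng.exponential(1.0 / lam)
    d = np.ones(N, dtype=int)
    model = DynamicSurvivalModel(y, d, Z, events_per_interval=10)
    res = model.fit(n_iter=1200, burn_in=400, thin=2, seed=11)
    return model, res, beta_true
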