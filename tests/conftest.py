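import numpy as np
import pytest

from curefrail import MCFMParams, SimulationDesign, SurvivalDataset, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_params():
    """Unit-parameter model: alpha=gamma=theta=1, no covariates."""
    return MCFMParams(alpha=1.0, gamma=1.0, theta=1.0)


@pytest.fixture
def small_lowdim_data():
    """Moderate low-dimensional simulated dataset with latent truth."""
    design = SimulationDesign(
        n=400,
        p_pen=0,
        s=0,
        p2u=2,
        b0_bu=(0.0, -1.0, 1.0),
        beta_u_low=-1.0,
        beta_u_high=1.0,
    )
    data, truth = simulate_dataset(design, seed=11)
    return data, truth


def random_params(rng, p1u=0, p1p=0, p2u=0, p2p=0, frailty=True):
    return MCFMParams(
        alpha=float(rng.uniform(0.3, 3.0)),
        gamma=float(rng.uniform(0.5, 3.0)),
        theta=float(rng.uniform(0.2, 5.0)) if frailty else None,
        b0=float(rng.normal(0, 1)),
        b_u=rng.normal(0, 1, p1u),
        b_p=rng.normal(0, 0.5, p1p),
        beta_u=rng.normal(0, 1, p2u),
        beta_p=rng.normal(0, 0.5, p2p),
    )


def random_survival_data(rng, n=50, p1u=1, p2u=1):
    """Small arbitrary right-censored dataset (not model-generated)."""
    return SurvivalDataset(
        time=rng.uniform(0.05, 3.0, n),
        event=(rng.uniform(size=n) < 0.5).astype(int),
        z_u=rng.normal(size=(n, p1u)),
        x_u=rng.normal(size=(n, p2u)),
    )
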