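"""Synthetic data generation for the Weibull mixture cure frailty model.

Sampling uses the inverse of the (improper) population CDF: a uniform
draw ``u`` falling beyond the uncured probability ``pi(z)`` marks a
cured subject (infinite latent event time); otherwise the event time is
the closed-form quantile of the marginal uncured distribution.  An
independent exponential censoring time is then applied.

The default study design mirrors a high-dimensional omics setting:
n=500 subjects, a shared block of P=1000 block-correlated Gaussian
penalized covariates used by both model parts, a 3-level categorical
unpenalized incidence covariate, 10 standard-normal unpenalized latency
covariates, s=20 equal-magnitude signals (one per correlation block of
50), Weibull baseline (1.25, 2.5), frailty theta=0.5 and exponential
censoring with rate 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import core
from .data import MCFMParams, SurvivalDataset

__all__ = [
    "SimulationDesign",
    "build_design",
    "inverse_population_cdf",
    "simulate_dataset",
    "summarize_rates",
]


@dataclass
class SimulationDesign:
    """Parameters of the simulation study design."""

    n: int = 500
    p_pen: int = 1000  # shared penalized block (z_p = x_p)
    p2u: int = 10  # unpenalized latency covariates, iid N(0,1)
    s: int = 20  # number of nonzero penalized coefficients per block type
    v: float = 0.5  # common magnitude of the nonzero coefficients
    rho: float = 0.0  # within-block correlation base, corr = rho**|i-j|
    block_size: int = 50
    cat_probs: tuple = (0.4, 0.35, 0.25)  # 3-level categorical incidence covariate
    b0_bu: tuple = (-2.0, -1.0, 1.0)  # (b0, b_u for levels 2 and 3)
    beta_u_low: float = -3.0  # beta_u ~ Uniform[low, high], drawn per dataset
    beta_u_high: float = 3.0
    alpha: float = 1.25
    gamma: float = 2.5
    theta: float | None = 0.5
    censor_rate: float = 0.5  # exponential censoring rate lambda_c

    def __post_init__(self) -> None:
        if self.n <= 0 or self.p_pen < 0 or self.s < 0:
            raise ValueError("n, p_pen and s must be nonnegative (n positive)")
        if self.p_pen:
            n_blocks = int(np.ceil(self.p_pen / self.block_size))
            if self.s > n_blocks:
                raise ValueError(
                    "one-signal-per-block placement requires s <= number of blocks"
                )
        if abs(sum(self.cat_probs) - 1.0) > 1e-12:
            raise ValueError("categorical level probabilities must sum to 1")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be nonnegative")


def _block_gaussian(rng, n, p, rho, block_size):
    """MVN(0, Sigma) with block-diagonal AR(1)-within-block Sigma."""
    if p == 0:
        return np.empty((n, 0))
    x = rng.standard_normal((n, p))
    if rho == 0:
        return x
    out = np.empty_like(x)
    for start in range(0, p, block_size):
        stop = min(start + block_size, p)
        m = stop - start
        cov = rho ** np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
        chol = np.linalg.cholesky(cov)
        out[:, start:stop] = x[:, start:stop] @ chol.T
    return out


def signal_indices(design: SimulationDesign) -> np.ndarray:
    """First index of each of the first ``s`` blocks (one signal per block)."""
    return np.arange(design.s) * design.block_size


def build_design(design: SimulationDesign, seed=None, rng=None):
    """Draw covariates and true parameters for one replicate.

    Returns ``(covariates, params)`` where covariates is a dict with
    ``z_u`` (dummy-coded categorical, reference = first level), ``x_u``,
    and the shared penalized matrix under both ``z_p`` and ``x_p``.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    pen = _block_gaussian(rng, design.n, design.p_pen, design.rho, design.block_size)
    levels = rng.choice(3, size=design.n, p=np.asarray(design.cat_probs))
    z_u = np.column_stack([(levels == 1).astype(float), (levels == 2).astype(float)])
    x_u = rng.standard_normal((design.n, design.p2u))
    beta_u = rng.uniform(design.beta_u_low, design.beta_u_high, size=design.p2u)
    coef_p = np.zeros(design.p_pen)
    if design.s:
        coef_p[signal_indices(design)] = design.v
    params = MCFMParams(
        alpha=design.alpha,
        gamma=design.gamma,
        theta=design.theta,
        b0=design.b0_bu[0],
        b_u=np.asarray(design.b0_bu[1:], float),
        b_p=coef_p.copy(),
        beta_u=beta_u,
        beta_p=coef_p.copy(),
    )
    covariates = {"z_u": z_u, "z_p": pen, "x_u": x_u, "x_p": pen}
    return covariates, params


def inverse_population_cdf(u, params: MCFMParams, z_u=None, z_p=None, x_u=None, x_p=None):
    """Quantile of the improper population CDF for ``0 <= u < pi(z)``.

    F^-1(u) = {theta * alpha^-1 * exp(-x'beta) * ([1 - u/pi(z)]^(-1/theta) - 1)}^(1/gamma);
    in the no-frailty limit the inner factor becomes -log(1 - u/pi(z)).
    """
    u = np.asarray(u, dtype=float)
    pi = core.uncured_probability(params, z_u=z_u, z_p=z_p)
    if np.any(u < 0) or np.any(u >= pi):
        raise ValueError("u must satisfy 0 <= u < pi(z) (u >= pi is the cured region)")
    eta_x = core.latency_linpred(params, x_u=x_u, x_p=x_p)
    frac = u / pi
    if params.theta is None:
        inner = -np.log1p(-frac)
    else:
        inner = params.theta * np.expm1(-np.log1p(-frac) / params.theta)
    return (inner * np.exp(-eta_x) / params.alpha) ** (1.0 / params.gamma)


def simulate_dataset(
    design: SimulationDesign | None = None,
    seed=None,
    covariates: dict | None = None,
    params: MCFMParams | None = None,
    rng=None,
):
    """Generate one right-censored dataset with latent truth.

    Either a :class:`SimulationDesign` (covariates and true parameters are
    drawn) or explicit ``(covariates, params)`` can be supplied.  Returns
    ``(dataset, params)``.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    if covariates is None or params is None:
        if design is None:
            raise ValueError("either a design or explicit (covariates, params) needed")
        covariates, params = build_design(design, rng=rng)
    censor_rate = design.censor_rate if design is not None else 0.5
    z_u, z_p = covariates.get("z_u"), covariates.get("z_p")
    x_u, x_p = covariates.get("x_u"), covariates.get("x_p")
    n = None
    for block in (z_u, z_p, x_u, x_p):
        if block is not None and np.size(block):
            n = np.asarray(block).shape[0]
            break
    pi = np.atleast_1d(core.uncured_probability(params, z_u=z_u, z_p=z_p))
    if n is None:
        n = pi.shape[0]
    pi = np.broadcast_to(pi, (n,)) if pi.shape[0] != n else pi
    u = rng.uniform(size=n)
    uncured = u < pi
    event_time = np.full(n, np.inf)
    if uncured.any():
        idx = np.flatnonzero(uncured)
        event_time[idx] = inverse_population_cdf(
            u[idx],
            params,
            z_u=None if z_u is None else z_u[idx],
            z_p=None if z_p is None else z_p[idx],
            x_u=None if x_u is None else x_u[idx],
            x_p=None if x_p is None else x_p[idx],
        )
    if censor_rate > 0:
        censor_time = rng.exponential(scale=1.0 / censor_rate, size=n)
    else:
        censor_time = np.full(n, np.inf)
    time = np.minimum(event_time, censor_time)
    delta = (event_time <= censor_time).astype(int)
    # guard the (measure-zero) case of both times infinite or a zero time
    bad = ~np.isfinite(time)
    if bad.any():
        time[bad] = np.max(time[~bad]) if np.any(~bad) else 1.0
        delta[bad] = 0
    time = np.maximum(time, 1e-12)
    # latent frailty draw, stored for reference (consistent posterior given y)
    if params.theta is not None:
        frailty = rng.gamma(shape=params.theta, scale=1.0 / params.theta, size=n)
    else:
        frailty = np.ones(n)
    dataset = SurvivalDataset(
        time=time,
        event=delta,
        z_u=z_u,
        z_p=z_p,
        x_u=x_u,
        x_p=x_p,
        latent_cure=uncured.astype(int),
        latent_frailty=frailty,
    )
    return dataset, params


def summarize_rates(datasets) -> dict:
    """Mean censoring %% and mean cured %% over datasets with latent truth."""
    cens, cured = [], []
    for ds in datasets:
        cens.append(100.0 * np.mean(ds.event == 0))
        if ds.latent_cure is None:
            raise ValueError("summarize_rates needs latent cure status")
        cured.append(100.0 * np.mean(ds.latent_cure == 0))
    return {
        "mean_censoring_pct": float(np.mean(cens)),
        "mean_cured_pct": float(np.mean(cured)),
    }
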