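"""Parametric building blocks of the Weibull mixture cure frailty model.

The population survival function is the improper mixture

    S_pop(t | x, z) = 1 - pi(z) + pi(z) * S_u(t | x)

with logistic incidence ``pi(z) = expit(z'b)`` and, after marginalizing a
mean-one gamma frailty with variance ``1/theta`` out of the Weibull
proportional-hazards latency,

    S_u(t | x) = (1 + alpha * t**gamma * exp(x'beta) / theta)**(-theta).

With ``theta=None`` (no frailty) the latency reduces to the plain Weibull
mixture cure survival ``exp(-alpha * t**gamma * exp(x'beta))``.

Everything is evaluated on the log scale so that linear predictors of
magnitude far beyond 700 stay finite; probabilities are clipped to
``[1e-15, 1 - 1e-15]`` before logs.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .data import MCFMParams, SurvivalDataset

__all__ = [
    "uncured_probability",
    "gamma_frailty_laplace",
    "latency_survival",
    "population_survival",
    "observed_loglik",
]

_CLIP = 1e-15
_LOG_CLIP = np.log(_CLIP)


def _softplus(u):
    """log(1 + exp(u)), overflow-safe."""
    return np.logaddexp(0.0, u)


def _dot_block(mat: np.ndarray, coef: np.ndarray, name: str):
    if mat.shape[-1] != coef.shape[0]:
        raise ValueError(
            f"{name}: covariate width {mat.shape[-1]} does not match "
            f"coefficient length {coef.shape[0]}"
        )
    return mat @ coef


def incidence_linpred(params: MCFMParams, z_u=None, z_p=None):
    """z'b = b0 + z_u'b_u + z_p'b_p (intercept implicit)."""
    eta = np.asarray(params.b0, dtype=float)
    if z_u is not None and np.size(z_u):
        eta = eta + _dot_block(np.asarray(z_u, float), params.b_u, "z_u")
    elif params.b_u.size:
        raise ValueError("params carry b_u but no z_u covariates were given")
    if z_p is not None and np.size(z_p):
        eta = eta + _dot_block(np.asarray(z_p, float), params.b_p, "z_p")
    elif params.b_p.size:
        raise ValueError("params carry b_p but no z_p covariates were given")
    return eta


def latency_linpred(params: MCFMParams, x_u=None, x_p=None):
    """x'beta = x_u'beta_u + x_p'beta_p (no intercept; absorbed by alpha)."""
    eta = np.asarray(0.0)
    if x_u is not None and np.size(x_u):
        eta = eta + _dot_block(np.asarray(x_u, float), params.beta_u, "x_u")
    elif params.beta_u.size:
        raise ValueError("params carry beta_u but no x_u covariates were given")
    if x_p is not None and np.size(x_p):
        eta = eta + _dot_block(np.asarray(x_p, float), params.beta_p, "x_p")
    elif params.beta_p.size:
        raise ValueError("params carry beta_p but no x_p covariates were given")
    return eta


def uncured_probability(params: MCFMParams, z_u=None, z_p=None):
    """Logistic incidence pi(z) = exp(z'b) / (1 + exp(z'b)) in (0, 1)."""
    return expit(incidence_linpred(params, z_u=z_u, z_p=z_p))


def gamma_frailty_laplace(s, theta):
    """Laplace transform (1 + s/theta)**(-theta) of the mean-one gamma frailty.

    ``theta=None`` is the degenerate (no-frailty) limit exp(-s).
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("s must be nonnegative")
    if theta is None:
        return np.exp(-s)
    if not theta > 0:
        raise ValueError("theta must be strictly positive")
    return np.exp(-theta * np.log1p(s / theta))


def _log_cum_hazard(t, params: MCFMParams, eta_x):
    """log(alpha * t**gamma * exp(x'beta)); -inf at t=0."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    with np.errstate(divide="ignore"):
        log_t = np.log(t)
    return np.log(params.alpha) + params.gamma * log_t + eta_x


def log_latency_survival_from_linpred(t, params: MCFMParams, eta_x):
    """log S_u(t | x) from a precomputed latency linear predictor."""
    log_h = _log_cum_hazard(t, params, eta_x)
    if params.theta is None:
        with np.errstate(over="ignore"):
            return -np.exp(log_h)
    # -theta * log(1 + A/theta), A/theta on log scale to dodge overflow
    return -params.theta * _softplus(log_h - np.log(params.theta))


def latency_survival(t, params: MCFMParams, x_u=None, x_p=None):
    """Marginal survival of the uncured, S_u(t|x); 1 at t=0, nonincreasing."""
    eta = latency_linpred(params, x_u=x_u, x_p=x_p)
    return np.exp(log_latency_survival_from_linpred(t, params, eta))


def log_population_survival_from_linpreds(t, params: MCFMParams, eta_z, eta_x):
    log_su = log_latency_survival_from_linpred(t, params, eta_x)
    # log(1 - pi + pi * S_u) = -softplus(eta_z) + log(1 + exp(eta_z + log S_u))
    return -_softplus(eta_z) + _softplus(eta_z + log_su)


def population_survival(t, params: MCFMParams, z_u=None, z_p=None, x_u=None, x_p=None):
    """Improper population survival S_pop(t|x,z); plateaus at 1 - pi(z)."""
    eta_z = incidence_linpred(params, z_u=z_u, z_p=z_p)
    eta_x = latency_linpred(params, x_u=x_u, x_p=x_p)
    return np.exp(log_population_survival_from_linpreds(t, params, eta_z, eta_x))


def observed_loglik(params: MCFMParams, data: SurvivalDataset) -> float:
    """Observed-data log-likelihood of right-censored survival data.

    Events contribute log f_pop(t) with
    f_pop(t) = pi(z) * alpha*gamma*t**(gamma-1) * exp(x'beta)
               * (1 + alpha*t**gamma*exp(x'beta)/theta)**(-theta-1),
    censored subjects contribute log S_pop(t).
    """
    params.validate_against(data)
    eta_z = incidence_linpred(params, z_u=data.z_u, z_p=data.z_p)
    eta_x = latency_linpred(params, x_u=data.x_u, x_p=data.x_p)
    eta_z = np.broadcast_to(np.asarray(eta_z, float), (data.n,))
    eta_x = np.broadcast_to(np.asarray(eta_x, float), (data.n,))
    return float(np.sum(_per_subject_loglik(params, data, eta_z, eta_x)))


def _per_subject_loglik(params, data, eta_z, eta_x):
    t, delta = data.time, data.event
    log_t = np.log(t)
    log_h = np.log(params.alpha) + params.gamma * log_t + eta_x
    log_pi = eta_z - _softplus(eta_z)  # log pi(z), clipped below
    log_pi = np.maximum(log_pi, _LOG_CLIP)
    if params.theta is None:
        log_tail = -np.exp(log_h)  # exp(-A)
    else:
        log_tail = -(params.theta + 1.0) * _softplus(log_h - np.log(params.theta))
    # log f_pop = log pi + log(alpha*gamma) + (gamma-1) log t + eta_x + log_tail
    log_f = (
        log_pi
        + np.log(params.alpha * params.gamma)
        + (params.gamma - 1.0) * log_t
        + eta_x
        + log_tail
    )
    log_s = log_population_survival_from_linpreds(t, params, eta_z, eta_x)
    log_s = np.maximum(log_s, _LOG_CLIP)
    log_f = np.maximum(log_f, 3 * _LOG_CLIP)  # density floor keeps sums finite
    return np.where(delta == 1, log_f, log_s)
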