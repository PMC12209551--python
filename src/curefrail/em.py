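"""Penalized EM algorithm for the Weibull mixture cure frailty model.

The complete-data log-likelihood over the latent uncured indicators
``y_i`` and frailties ``w_i`` separates into an incidence part (logistic
in ``b``), a latency part (Weibull regression in ``alpha, gamma, beta``
with multiplicative weight ``w_i y_i``) and a frailty part (gamma in
``theta``).  The E-step therefore only needs the posterior expectations

    p_i = E[y_i | .],  a_i = E[w_i | .],  b_i = E[log w_i | .],
    c_i = E[w_i y_i | .],

and the M-step maximizes each part separately, with a (multi-step
adaptive) elastic-net penalty on the high-dimensional coefficient blocks
``b_p`` and ``beta_p``.  The outer loop re-runs the whole EM
``k_adaptive`` times, refreshing the per-coefficient L1 weights with the
reciprocal-magnitude rule in between, which sharpens selection and
suppresses false positives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import digamma, expit, gammaln

from . import core
from .data import MCFMParams, SurvivalDataset
from .solvers import solve_partially_linear, solve_penalized

_WS_MIN_COLS = 100  # use the working-set solver for penalized blocks this wide

__all__ = [
    "PosteriorExpectations",
    "PenaltySpec",
    "EMControl",
    "FitResult",
    "e_step",
    "m_step_incidence",
    "m_step_latency",
    "m_step_frailty",
    "update_adaptive_weights",
    "initialize_params",
    "run_em",
]

THETA_MIN, THETA_MAX = 1e-4, 1e6
_P_CLIP = 1e-12


@dataclass
class PosteriorExpectations:
    """Per-subject E-step quantities given the current parameters."""

    p: np.ndarray  # E[y_i | Lambda, D] in [0, 1]; exactly 1 for events
    a: np.ndarray  # E[w_i | Lambda, D] > 0
    b_dig: np.ndarray  # E[log w_i | Lambda, D]
    c: np.ndarray  # E[w_i y_i | Lambda, D] in [0, a_i]


@dataclass
class PenaltySpec:
    """Adaptive elastic-net penalty configuration.

    ``lambda_enet`` is the shared tuning parameter for both penalized
    blocks (a ``(lambda_incidence, lambda_latency)`` pair may be passed
    to override the shared default).  ``alpha_enet`` mixes L1 and L2.
    The weight vectors carry the adaptive per-coefficient L1 weights
    (``+inf`` = hard exclusion); ``k_adaptive`` counts the re-weighting
    rounds, ``k_adaptive=1`` with unit weights being the plain elastic net.
    """

    lambda_enet: float | tuple[float, float] = 0.0
    alpha_enet: float = 1.0
    weights_incidence: np.ndarray | None = None
    weights_latency: np.ndarray | None = None
    k_adaptive: int = 1
    weight_mode: str = "hard"  # "hard": 1/0 -> +inf; "epsilon": 1/(|b|+1e-6)

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha_enet <= 1.0:
            raise ValueError("alpha_enet must lie in [0, 1]")
        lam = self.lambda_enet
        pair = lam if isinstance(lam, (tuple, list)) else (lam, lam)
        if min(pair) < 0:
            raise ValueError("lambda_enet must be nonnegative")
        if self.k_adaptive < 1:
            raise ValueError("k_adaptive must be >= 1")
        for name in ("weights_incidence", "weights_latency"):
            w = getattr(self, name)
            if w is not None:
                w = np.asarray(w, dtype=float)
                if np.any(w < 0):
                    raise ValueError(f"{name} must be nonnegative")
                setattr(self, name, w)

    @property
    def lambda_incidence(self) -> float:
        lam = self.lambda_enet
        return float(lam[0]) if isinstance(lam, (tuple, list)) else float(lam)

    @property
    def lambda_latency(self) -> float:
        lam = self.lambda_enet
        return float(lam[1]) if isinstance(lam, (tuple, list)) else float(lam)

    def w_incidence(self, p1p: int) -> np.ndarray:
        w = self.weights_incidence
        return np.ones(p1p) if w is None else w

    def w_latency(self, p2p: int) -> np.ndarray:
        w = self.weights_latency
        return np.ones(p2p) if w is None else w


@dataclass
class EMControl:
    """Convergence and solver knobs for :func:`run_em`."""

    tol: float = 1e-6  # relative change of the penalized observed log-lik
    max_iter: int = 500  # EM iterations per adaptive round
    inner_max_iter: int = 1000  # iterations of the penalized M-step solver
    inner_tol: float = 1e-6  # KKT tolerance of the M-step solver
    frailty: bool = True  # False: plain Weibull mixture cure model
    fix_theta: float | None = None  # freeze theta at this value (no update)
    standardize: bool = True  # standardize penalized covariate blocks


@dataclass
class FitResult:
    """Fitted parameters plus selection and convergence bookkeeping."""

    params: MCFMParams
    support_incidence: np.ndarray
    support_latency: np.ndarray
    loglik_trace: list = field(default_factory=list)  # one array per round
    n_iter: int = 0
    converged: bool = False
    penalty: PenaltySpec | None = None
    params_std: MCFMParams | None = None  # standardized-covariate scale
    negligible_frailty: bool = False
    meta: dict = field(default_factory=dict)  # fitter-specific extras

    def coef_table(self):
        """Flat coefficient table (term, block, estimate, penalized flag)."""
        import pandas as pd

        rows = [("b0", "incidence_intercept", self.params.b0, False)]
        rows += [
            (f"b_u{j}", "incidence_unpenalized", v, False)
            for j, v in enumerate(self.params.b_u)
        ]
        rows += [
            (f"b_p{j}", "incidence_penalized", v, True)
            for j, v in enumerate(self.params.b_p)
        ]
        rows += [
            (f"beta_u{j}", "latency_unpenalized", v, False)
            for j, v in enumerate(self.params.beta_u)
        ]
        rows += [
            (f"beta_p{j}", "latency_penalized", v, True)
            for j, v in enumerate(self.params.beta_p)
        ]
        rows += [
            ("alpha", "weibull", self.params.alpha, False),
            ("gamma", "weibull", self.params.gamma, False),
            ("theta", "frailty", self.params.theta, False),
        ]
        return pd.DataFrame(rows, columns=["term", "block", "estimate", "penalized"])

    def to_dict(self) -> dict:
        p = self.params
        return {
            "alpha": p.alpha,
            "gamma": p.gamma,
            "theta": p.theta,
            "b0": p.b0,
            "b_u": p.b_u.tolist(),
            "b_p": p.b_p.tolist(),
            "beta_u": p.beta_u.tolist(),
            "beta_p": p.beta_p.tolist(),
            "support_incidence": np.asarray(self.support_incidence).tolist(),
            "support_latency": np.asarray(self.support_latency).tolist(),
            "loglik_trace": [np.asarray(t).tolist() for t in self.loglik_trace],
            "n_iter": int(self.n_iter),
            "converged": bool(self.converged),
            "negligible_frailty": bool(self.negligible_frailty),
        }


# ---------------------------------------------------------------------------
# E-step


def e_step(params: MCFMParams, data: SurvivalDataset) -> PosteriorExpectations:
    """Posterior expectations of the latent (y_i, w_i) given the data.

    For censored subjects ``p_i = pi * S_u / (1 - pi + pi * S_u)``; events
    have ``p_i = 1``.  The frailty posterior given ``y_i`` is gamma, giving
    closed forms for ``a_i``, ``b_i`` (via the digamma function) and
    ``c_i``.  With no frailty (``theta=None``) the latent reduces to
    ``y_i`` alone and ``c_i = p_i``.
    """
    params.validate_against(data)
    delta = data.event
    eta_z = np.broadcast_to(
        np.asarray(core.incidence_linpred(params, data.z_u, data.z_p), float),
        (data.n,),
    )
    eta_x = np.broadcast_to(
        np.asarray(core.latency_linpred(params, data.x_u, data.x_p), float),
        (data.n,),
    )
    log_su = core.log_latency_survival_from_linpred(data.time, params, eta_x)
    # pi*S_u / (1-pi+pi*S_u) = expit(eta_z + log S_u)
    p = np.where(delta == 1, 1.0, expit(eta_z + log_su))
    if params.theta is None:
        ones = np.ones_like(p)
        return PosteriorExpectations(p=p, a=ones, b_dig=np.zeros_like(p), c=p.copy())
    theta = params.theta
    log_h = np.log(params.alpha) + params.gamma * np.log(data.time) + eta_x
    with np.errstate(over="ignore"):
        denom = theta + np.exp(log_h)  # theta + A, may saturate to inf
    ratio = np.where(np.isinf(denom), 0.0, (delta + theta) / denom)
    a = p * ratio + (1.0 - p) * (delta + theta) / theta
    log_denom = np.log(theta) + core._softplus(log_h - np.log(theta))
    b_dig = digamma(delta + theta) - (1.0 - p) * np.log(theta) - p * log_denom
    c = p * ratio
    return PosteriorExpectations(p=p, a=a, b_dig=b_dig, c=c)


# ---------------------------------------------------------------------------
# M-steps


def _incidence_design(data: SurvivalDataset) -> np.ndarray:
    return np.column_stack([np.ones(data.n), data.z_u, data.z_p])


def m_step_incidence(
    p: np.ndarray,
    data: SurvivalDataset,
    penalty: PenaltySpec,
    start: MCFMParams | None = None,
    control: EMControl | None = None,
):
    """Penalized fractional-response logistic M-step.

    Minimizes ``-(1/n) sum[p_i z_i'b - log(1+exp(z_i'b))]`` plus the
    weighted elastic-net penalty on ``b_p``; the intercept and ``b_u``
    stay unpenalized.  ``p`` may be any vector in [0,1] (the posterior
    uncured probabilities are fractional, which is what rules out
    standard GLM solvers).
    """
    control = control or EMControl()
    p = np.clip(np.asarray(p, float), 0.0, 1.0)
    if p.shape != (data.n,):
        raise ValueError("p must have one entry per subject")
    n = data.n
    lam, ae = penalty.lambda_incidence, penalty.alpha_enet
    l1_pen = lam * ae * penalty.w_incidence(data.p1p)
    l2_pen = lam * (1.0 - ae)
    if start is not None:
        u0 = np.concatenate([[start.b0], start.b_u])
        v0 = start.b_p
    else:
        u0 = np.zeros(1 + data.p1u)
        v0 = np.zeros(data.p1p)

    if data.p1p >= _WS_MIN_COLS and np.any(l1_pen > 0):
        Zu = np.column_stack([np.ones(n), data.z_u])

        def resid(u, eta_pen):
            eta = Zu @ u + eta_pen
            f = float(np.mean(core._softplus(eta) - p * eta))
            r = (expit(eta) - p) / n
            return f, Zu.T @ r, r

        res = solve_partially_linear(
            resid, data.z_p, u0, v0, l1_pen, l2_pen,
            tol=control.inner_tol, max_iter=control.inner_max_iter,
        )
        b = res.x
        return float(b[0]), b[1 : 1 + data.p1u].copy(), b[1 + data.p1u :].copy()

    Z = _incidence_design(data)

    def fg(b):
        eta = Z @ b
        f = float(np.mean(core._softplus(eta) - p * eta))
        g = Z.T @ (expit(eta) - p) / n
        return f, g

    d = Z.shape[1]
    l1 = np.zeros(d)
    l2 = np.zeros(d)
    if data.p1p:
        sl = slice(1 + data.p1u, d)
        l1[sl] = l1_pen
        l2[sl] = l2_pen
    res = solve_penalized(
        fg,
        np.concatenate([u0, v0]),
        l1=l1,
        l2=l2,
        tol=control.inner_tol,
        max_iter=control.inner_max_iter,
    )
    b = res.x
    return float(b[0]), b[1 : 1 + data.p1u].copy(), b[1 + data.p1u :].copy()


def m_step_latency(
    c: np.ndarray,
    data: SurvivalDataset,
    penalty: PenaltySpec,
    start: MCFMParams | None = None,
    control: EMControl | None = None,
):
    """Penalized Weibull-regression M-step with multiplicative weights ``c``.

    Minimizes ``-(1/n) sum[delta_i log(alpha gamma t^(gamma-1) e^(x'beta))
    - c_i alpha t^gamma e^(x'beta)]`` plus the weighted elastic net on
    ``beta_p``; ``alpha`` and ``gamma`` are optimized on the log scale.
    """
    control = control or EMControl()
    c = np.asarray(c, float)
    if c.shape != (data.n,):
        raise ValueError("c must have one entry per subject")
    if np.any(c < 0):
        raise ValueError("c must be nonnegative")
    if not np.any(c > 0):
        raise ValueError("all latency weights are zero (no uncured mass)")
    if not np.any(data.event == 1):
        raise ValueError("latency M-step needs at least one event")
    delta = data.event
    log_t = np.log(data.time)
    n = data.n
    n_events = float(delta.sum())
    lam, ae = penalty.lambda_latency, penalty.alpha_enet
    l1_pen = lam * ae * penalty.w_latency(data.p2p)
    l2_pen = lam * (1.0 - ae)
    if start is not None:
        u0 = np.concatenate([[np.log(start.alpha), np.log(start.gamma)], start.beta_u])
        v0 = start.beta_p
    else:
        u0 = np.zeros(2 + data.p2u)
        v0 = np.zeros(data.p2p)

    if data.p2p >= _WS_MIN_COLS and np.any(l1_pen > 0):

        def resid(u, eta_pen):
            log_a, log_g = u[0], u[1]
            gamma = np.exp(log_g)
            eta = (data.x_u @ u[2:] if data.p2u else 0.0) + eta_pen
            log_A = log_a + gamma * log_t + eta
            with np.errstate(over="ignore"):
                cA = c * np.exp(log_A)
            f = -(
                np.sum(delta * (log_a + log_g + (gamma - 1.0) * log_t + eta)) - cA.sum()
            ) / n
            if not np.isfinite(f):
                return np.inf, np.zeros(2 + data.p2u), np.zeros(n)
            r = (cA - delta) / n
            gu = np.empty(2 + data.p2u)
            gu[0] = -(n_events - cA.sum()) / n
            gu[1] = -(np.sum(delta * (1.0 + gamma * log_t)) - np.sum(cA * gamma * log_t)) / n
            if data.p2u:
                gu[2:] = data.x_u.T @ r
            return float(f), gu, r

        res = solve_partially_linear(
            resid, data.x_p, u0, v0, l1_pen, l2_pen,
            tol=control.inner_tol, max_iter=control.inner_max_iter,
        )
        v = res.x
        return (
            float(np.exp(v[0])),
            float(np.exp(v[1])),
            v[2 : 2 + data.p2u].copy(),
            v[2 + data.p2u :].copy(),
        )

    X = np.column_stack([data.x_u, data.x_p])

    def fg(v):
        log_a, log_g = v[0], v[1]
        beta = v[2:]
        gamma = np.exp(log_g)
        eta = X @ beta if beta.size else np.zeros(n)
        log_A = log_a + gamma * log_t + eta
        with np.errstate(over="ignore"):
            A = np.exp(log_A)
        cA = c * A
        f = -(np.sum(delta * (log_a + log_g + (gamma - 1.0) * log_t + eta)) - cA.sum()) / n
        if not np.isfinite(f):
            return np.inf, np.zeros_like(v)
        g = np.empty_like(v)
        g[0] = -(n_events - cA.sum()) / n
        g[1] = -(np.sum(delta * (1.0 + gamma * log_t)) - np.sum(cA * gamma * log_t)) / n
        if beta.size:
            g[2:] = X.T @ (cA - delta) / n
        return float(f), g

    d = 2 + data.p2u + data.p2p
    l1 = np.zeros(d)
    l2 = np.zeros(d)
    if data.p2p:
        sl = slice(2 + data.p2u, d)
        l1[sl] = l1_pen
        l2[sl] = l2_pen
    res = solve_penalized(
        fg,
        np.concatenate([u0, v0]),
        l1=l1,
        l2=l2,
        tol=control.inner_tol,
        max_iter=control.inner_max_iter,
    )
    v = res.x
    alpha, gamma = float(np.exp(v[0])), float(np.exp(v[1]))
    beta_u = v[2 : 2 + data.p2u].copy()
    beta_p = v[2 + data.p2u :].copy()
    return alpha, gamma, beta_u, beta_p


def frailty_objective(theta, a, b_dig, event):
    """Expected complete-data log-likelihood of the frailty part."""
    theta = np.asarray(theta, float)
    n = len(event)
    s = np.sum(
        (event[:, None] + theta[None, :] - 1.0) * np.asarray(b_dig)[:, None]
        - np.asarray(a)[:, None] * theta[None, :],
        axis=0,
    )
    return s + n * (theta * np.log(theta) - gammaln(theta))


def m_step_frailty(a, b_dig, event, return_flag: bool = False):
    """Update the frailty parameter theta by 1-D root finding.

    The objective ``sum[(delta_i + theta - 1) b_i - a_i theta] +
    n (theta log theta - log Gamma(theta))`` has derivative
    ``n (log theta + 1 - digamma(theta)) + sum(b_i - a_i)``, which is
    strictly decreasing, so the maximizer is the unique root, boxed to
    ``[1e-4, 1e6]``.  Hitting the upper box means the posterior frailty
    variance is negligible (homogeneous population); the flag reports it.
    """
    a = np.asarray(a, float)
    b_dig = np.asarray(b_dig, float)
    event = np.asarray(event)
    n = len(event)
    const = float(np.sum(b_dig - a)) / n

    def deriv(theta):
        return np.log(theta) + 1.0 - digamma(theta) + const

    at_bound = False
    if deriv(THETA_MAX) >= 0:
        theta, at_bound = THETA_MAX, True
    elif deriv(THETA_MIN) <= 0:
        theta = THETA_MIN
    else:
        # root-find on the log scale for conditioning
        theta = float(
            np.exp(brentq(lambda u: deriv(np.exp(u)), np.log(THETA_MIN), np.log(THETA_MAX), xtol=1e-12))
        )
    return (theta, at_bound) if return_flag else theta


def update_adaptive_weights(previous_fit: FitResult, mode: str | None = None) -> PenaltySpec:
    """Reciprocal-magnitude adaptive weights from a previous fit.

    ``w_j = 1 / |b_hat_p,j|``; exact zeros get ``+inf`` (the variable is
    excluded from the next adaptive round) under the default "hard" mode,
    or ``1/(|b|+1e-6)`` under the "epsilon" mode.
    """
    pen = previous_fit.penalty or PenaltySpec()
    mode = mode or pen.weight_mode
    src = previous_fit.params_std or previous_fit.params
    return PenaltySpec(
        lambda_enet=pen.lambda_enet,
        alpha_enet=pen.alpha_enet,
        weights_incidence=_reciprocal_weights(src.b_p, mode),
        weights_latency=_reciprocal_weights(src.beta_p, mode),
        k_adaptive=pen.k_adaptive,
        weight_mode=mode,
    )


def _reciprocal_weights(coef: np.ndarray, mode: str) -> np.ndarray:
    coef = np.abs(np.asarray(coef, float))
    if mode == "epsilon":
        return 1.0 / (coef + 1e-6)
    with np.errstate(divide="ignore"):
        return np.where(coef > 0, 1.0 / np.where(coef > 0, coef, 1.0), np.inf)


# ---------------------------------------------------------------------------
# Initialization


def _weibull_moment_estimates(times: np.ndarray) -> tuple[float, float]:
    """Moment-matching (alpha, gamma) for H0(t) = alpha * t**gamma."""
    from scipy.special import gamma as gamma_fn

    m = float(np.mean(times))
    s = float(np.std(times, ddof=1)) if len(times) > 1 else 0.0
    if not (m > 0) or s <= 0:
        raise ValueError("degenerate event times")
    target = s / m

    def cv(k):
        g1 = gamma_fn(1.0 + 1.0 / k)
        g2 = gamma_fn(1.0 + 2.0 / k)
        return np.sqrt(max(g2 - g1 * g1, 0.0)) / g1 - target

    k = brentq(cv, 0.05, 50.0, xtol=1e-10)
    scale = m / gamma_fn(1.0 + 1.0 / k)
    return float(scale ** (-k)), float(k)


def initialize_params(data: SurvivalDataset, frailty: bool = True) -> MCFMParams:
    """Starting values: Cox estimates for beta_u, Weibull moment estimates
    for (alpha, gamma) from the event times, zeros elsewhere, theta = 1."""
    events = data.time[data.event == 1]
    if events.size == 0:
        raise ValueError("initialization requires at least one event")
    try:
        alpha, gamma = _weibull_moment_estimates(events)
    except (ValueError, RuntimeError):
        warnings.warn(
            "Weibull moment matching failed; falling back to gamma=1",
            RuntimeWarning,
            stacklevel=2,
        )
        alpha, gamma = 1.0 / float(np.mean(events)), 1.0
    beta_u = np.zeros(data.p2u)
    if data.p2u:
        beta_u = _cox_start(data)
    return MCFMParams(
        alpha=alpha,
        gamma=gamma,
        theta=1.0 if frailty else None,
        b0=0.0,
        b_u=np.zeros(data.p1u),
        b_p=np.zeros(data.p1p),
        beta_u=beta_u,
        beta_p=np.zeros(data.p2p),
    )


def _cox_start(data: SurvivalDataset) -> np.ndarray:
    import pandas as pd
    from lifelines import CoxPHFitter

    df = pd.DataFrame(data.x_u, columns=[f"x{j}" for j in range(data.p2u)])
    df["time"] = data.time
    df["event"] = data.event
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph = CoxPHFitter(penalizer=1e-6)
            cph.fit(df, duration_col="time", event_col="event")
        beta = cph.params_.to_numpy()
        if np.all(np.isfinite(beta)):
            return beta
    except Exception:  # lifelines convergence failure on degenerate input
        pass
    warnings.warn(
        "Cox initialization failed; starting beta_u at zero", RuntimeWarning, stacklevel=2
    )
    return np.zeros(data.p2u)


# ---------------------------------------------------------------------------
# Main loop


def _standardize(data: SurvivalDataset):
    """Zero-mean/unit-variance copies of the penalized blocks."""

    def stats(mat):
        mu = mat.mean(axis=0) if mat.size else np.zeros(mat.shape[1])
        sd = mat.std(axis=0) if mat.size else np.ones(mat.shape[1])
        sd = np.where(sd > 0, sd, 1.0)
        return mu, sd

    mu_z, sd_z = stats(data.z_p)
    mu_x, sd_x = stats(data.x_p)
    std = SurvivalDataset(
        time=data.time,
        event=data.event,
        z_u=data.z_u,
        z_p=(data.z_p - mu_z) / sd_z,
        x_u=data.x_u,
        x_p=(data.x_p - mu_x) / sd_x,
        latent_cure=data.latent_cure,
        latent_frailty=data.latent_frailty,
    )
    return std, (mu_z, sd_z), (mu_x, sd_x)


def _destandardize(params: MCFMParams, zstats, xstats) -> MCFMParams:
    """Map standardized-scale coefficients back to the original covariates."""
    mu_z, sd_z = zstats
    mu_x, sd_x = xstats
    out = params.copy()
    if params.b_p.size:
        out.b_p = params.b_p / sd_z
        out.b0 = params.b0 - float(np.dot(params.b_p, mu_z / sd_z))
    if params.beta_p.size:
        out.beta_p = params.beta_p / sd_x
        # the constant shift folds into the Weibull scale alpha
        out.alpha = params.alpha * float(np.exp(-np.dot(params.beta_p, mu_x / sd_x)))
    return out


def penalized_observed_loglik(
    params: MCFMParams, data: SurvivalDataset, penalty: PenaltySpec
) -> float:
    """(1/n) observed log-likelihood minus the active elastic-net penalty."""
    ll = core.observed_loglik(params, data) / data.n
    ae = penalty.alpha_enet
    pen = 0.0
    for lam, coef, w in (
        (penalty.lambda_incidence, params.b_p, penalty.w_incidence(len(params.b_p))),
        (penalty.lambda_latency, params.beta_p, penalty.w_latency(len(params.beta_p))),
    ):
        if lam > 0 and coef.size:
            finite = np.isfinite(w)
            pen += lam * (
                0.5 * (1.0 - ae) * float(np.sum(coef**2))
                + ae * float(np.sum(w[finite] * np.abs(coef[finite])))
            )
    return ll - pen


def run_em(
    data: SurvivalDataset,
    penalty: PenaltySpec | None = None,
    control: EMControl | None = None,
    init: MCFMParams | None = None,
) -> FitResult:
    """Fit the (pen)MCFM by the penalized EM algorithm.

    Iterates E-step -> incidence M-step -> latency M-step -> frailty
    update until the relative change of the penalized observed
    log-likelihood drops below ``control.tol``, and repeats the whole EM
    ``penalty.k_adaptive`` times with adaptive-weight updates in between.
    The trace is nondecreasing within each round (generalized EM with
    warm-started, monotone M-steps).
    """
    penalty = penalty or PenaltySpec()
    control = control or EMControl()
    if control.standardize:
        sdata, zstats, xstats = _standardize(data)
    else:
        sdata, zstats, xstats = data, None, None

    if init is not None:
        params = init.copy()
    else:
        params = initialize_params(sdata, frailty=control.frailty)
    if control.fix_theta is not None:
        params.theta = control.fix_theta
    if not control.frailty:
        params.theta = None

    w_inc = penalty.w_incidence(data.p1p)
    w_lat = penalty.w_latency(data.p2p)
    round_penalty = PenaltySpec(
        lambda_enet=penalty.lambda_enet,
        alpha_enet=penalty.alpha_enet,
        weights_incidence=w_inc,
        weights_latency=w_lat,
        k_adaptive=penalty.k_adaptive,
        weight_mode=penalty.weight_mode,
    )

    traces: list[np.ndarray] = []
    total_iter = 0
    converged = False
    negligible = False
    for _round in range(penalty.k_adaptive):
        trace = []
        ll_prev = -np.inf
        converged = False
        for _it in range(control.max_iter):
            post = e_step(params, sdata)
            p = np.clip(post.p, _P_CLIP, 1.0 - _P_CLIP)
            params.b0, params.b_u, params.b_p = m_step_incidence(
                p, sdata, round_penalty, start=params, control=control
            )
            weight = post.c if params.theta is not None else p
            params.alpha, params.gamma, params.beta_u, params.beta_p = m_step_latency(
                weight, sdata, round_penalty, start=params, control=control
            )
            if (
                control.frailty
                and control.fix_theta is None
                and params.theta is not None
            ):
                post = e_step(params, sdata)
                params.theta, negligible = m_step_frailty(
                    post.a, post.b_dig, sdata.event, return_flag=True
                )
            ll = penalized_observed_loglik(params, sdata, round_penalty)
            if not np.isfinite(ll):
                raise FloatingPointError(
                    f"non-finite penalized log-likelihood at EM iteration "
                    f"{total_iter + len(trace) + 1}"
                )
            trace.append(ll)
            if np.isfinite(ll_prev) and abs(ll - ll_prev) <= control.tol * (
                abs(ll_prev) + 1e-10
            ):
                converged = True
                break
            ll_prev = ll
        traces.append(np.asarray(trace))
        total_iter += len(trace)
        if _round < penalty.k_adaptive - 1:
            round_penalty = PenaltySpec(
                lambda_enet=penalty.lambda_enet,
                alpha_enet=penalty.alpha_enet,
                weights_incidence=_reciprocal_weights(params.b_p, penalty.weight_mode),
                weights_latency=_reciprocal_weights(params.beta_p, penalty.weight_mode),
                k_adaptive=penalty.k_adaptive,
                weight_mode=penalty.weight_mode,
            )

    params_out = (
        _destandardize(params, zstats, xstats) if control.standardize else params.copy()
    )
    return FitResult(
        params=params_out,
        support_incidence=np.flatnonzero(params.b_p),
        support_latency=np.flatnonzero(params.beta_p),
        loglik_trace=traces,
        n_iter=total_iter,
        converged=converged,
        penalty=round_penalty,
        params_std=params if control.standardize else None,
        negligible_frailty=negligible,
    )
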