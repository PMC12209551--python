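"""Containers for right-censored survival data and model parameters.

A mixture cure frailty model (MCFM) splits the population into a cured
fraction (never experiences the event) and an uncured fraction whose
event hazard carries a multiplicative gamma frailty.  Covariates enter
twice: the *incidence* block ``z`` drives the logistic probability of
being uncured, the *latency* block ``x`` drives the conditional survival
of the uncured.  Each block is further split into unpenalized
(low-dimensional, e.g. clinical) and penalized (high-dimensional, e.g.
omics) columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["SurvivalDataset", "MCFMParams"]


def _as_matrix(a, n: int, name: str) -> np.ndarray:
    if a is None:
        return np.empty((n, 0), dtype=float)
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if a.ndim != 2 or a.shape[0] != n:
        raise ValueError(f"{name} must have {n} rows, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")
    return a


def _as_vector(a, name: str) -> np.ndarray:
    a = np.atleast_1d(np.asarray(a, dtype=float))
    if a.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return a


@dataclass
class SurvivalDataset:
    """One row per subject: observed time, event flag and four covariate blocks.

    ``latent_cure`` / ``latent_frailty`` hold the simulated ground truth
    (uncured indicator ``y`` and frailty ``w``) when the data come from the
    simulator; they are ``None`` for real data.
    """

    time: np.ndarray
    event: np.ndarray
    z_u: np.ndarray = None
    z_p: np.ndarray = None
    x_u: np.ndarray = None
    x_p: np.ndarray = None
    latent_cure: np.ndarray | None = None
    latent_frailty: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = _as_vector(self.time, "time")
        n = self.time.shape[0]
        if not np.all(np.isfinite(self.time)) or np.any(self.time <= 0):
            raise ValueError("all observed times must be strictly positive")
        self.event = np.asarray(self.event)
        if self.event.shape != (n,) or not np.isin(self.event, [0, 1]).all():
            raise ValueError("event must be a length-n vector with values in {0,1}")
        self.event = self.event.astype(int)
        self.z_u = _as_matrix(self.z_u, n, "z_u")
        self.z_p = _as_matrix(self.z_p, n, "z_p")
        self.x_u = _as_matrix(self.x_u, n, "x_u")
        self.x_p = _as_matrix(self.x_p, n, "x_p")
        if self.latent_cure is not None:
            self.latent_cure = np.asarray(self.latent_cure).astype(int)
            if self.latent_cure.shape != (n,):
                raise ValueError("latent_cure must be length n")
            if np.any((self.event == 1) & (self.latent_cure == 0)):
                raise ValueError("an event implies uncured status (latent_cure=1)")
        if self.latent_frailty is not None:
            self.latent_frailty = _as_vector(self.latent_frailty, "latent_frailty")
            if np.any(self.latent_frailty <= 0):
                raise ValueError("frailties must be positive")

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def p1u(self) -> int:
        return self.z_u.shape[1]

    @property
    def p1p(self) -> int:
        return self.z_p.shape[1]

    @property
    def p2u(self) -> int:
        return self.x_u.shape[1]

    @property
    def p2p(self) -> int:
        return self.x_p.shape[1]

    def subset(self, idx) -> "SurvivalDataset":
        """Row subset (copy); latent truth is carried along when present."""
        idx = np.asarray(idx)
        return SurvivalDataset(
            time=self.time[idx],
            event=self.event[idx],
            z_u=self.z_u[idx],
            z_p=self.z_p[idx],
            x_u=self.x_u[idx],
            x_p=self.x_p[idx],
            latent_cure=None if self.latent_cure is None else self.latent_cure[idx],
            latent_frailty=(
                None if self.latent_frailty is None else self.latent_frailty[idx]
            ),
        )


@dataclass
class MCFMParams:
    """Full parameter state Lambda = (alpha, gamma, theta, b, beta).

    ``alpha``/``gamma`` are the Weibull baseline scale/shape (cumulative
    hazard ``H0(t) = alpha * t**gamma``), ``theta`` the gamma-frailty
    parameter (frailty has mean 1, variance ``1/theta``; ``theta=None``
    drops the frailty entirely, i.e. the plain mixture cure model).
    ``b = (b0, b_u, b_p)`` are the logistic incidence coefficients and
    ``beta = (beta_u, beta_p)`` the latency coefficients; there is no
    latency intercept (it is absorbed by ``alpha``).
    """

    alpha: float
    gamma: float
    theta: float | None
    b0: float = 0.0
    b_u: np.ndarray = field(default_factory=lambda: np.empty(0))
    b_p: np.ndarray = field(default_factory=lambda: np.empty(0))
    beta_u: np.ndarray = field(default_factory=lambda: np.empty(0))
    beta_p: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.gamma > 0):
            raise ValueError("alpha and gamma must be strictly positive")
        if self.theta is not None:
            if np.isinf(self.theta):
                self.theta = None
            elif not self.theta > 0:
                raise ValueError("theta must be strictly positive (or None)")
        self.b0 = float(self.b0)
        for name in ("b_u", "b_p", "beta_u", "beta_p"):
            setattr(self, name, _as_vector(getattr(self, name), name))

    @property
    def has_frailty(self) -> bool:
        return self.theta is not None

    def copy(self) -> "MCFMParams":
        return replace(
            self,
            b_u=self.b_u.copy(),
            b_p=self.b_p.copy(),
            beta_u=self.beta_u.copy(),
            beta_p=self.beta_p.copy(),
        )

    def validate_against(self, data: SurvivalDataset) -> None:
        for coef, width, name in (
            (self.b_u, data.p1u, "b_u"),
            (self.b_p, data.p1p, "b_p"),
            (self.beta_u, data.p2u, "beta_u"),
            (self.beta_p, data.p2p, "beta_p"),
        ):
            if coef.shape[0] != width:
                raise ValueError(
                    f"{name} has length {coef.shape[0]} but the dataset block "
                    f"has {width} columns"
                )
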