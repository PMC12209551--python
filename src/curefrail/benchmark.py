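"""Replicated simulation benchmark: simulate, tune, fit, evaluate.

Reproduces the simulation-study pipeline at configurable scale: for each
replicate a dataset is simulated, split 80/20 into train/test, the
penalty is tuned by K-fold cross-validation on the training set, each
requested method is fitted, and the full metric panel (concordance,
selection, RME/ERR against the oracle refit, uncured-probability bias)
is emitted as one tidy row per (replicate, method).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import core
from .data import MCFMParams, SurvivalDataset
from .em import EMControl, PenaltySpec, run_em
from .gmifs import GMIFSControl, gmifs_fit
from .metrics import c_index_cure, c_index_harrell, pi_bias_mse, rme_err, selection_metrics
from .simulate import SimulationDesign, simulate_dataset
from .tuning import cross_validate, lambda_path

__all__ = ["BenchmarkConfig", "benchmark"]


@dataclass
class BenchmarkConfig:
    """Scenario configuration; defaults follow the simulation design."""

    design: SimulationDesign = field(default_factory=SimulationDesign)
    n_replicates: int = 1
    methods: tuple = ("penMCFM-EM",)  # also: penMCFM-GMIFS, MCM-GMIFS
    alpha_grid: tuple = (0.5,)
    n_lambda: int = 50
    lambda_min_ratio: float = 0.01
    cv_folds: int = 4
    train_frac: float = 0.8
    k_adaptive: int = 2
    seed: int = 0
    em_control: EMControl = field(default_factory=lambda: EMControl(tol=1e-4, max_iter=40))
    gmifs_control: GMIFSControl = field(default_factory=GMIFSControl)


def _train_test_split(data: SurvivalDataset, frac: float, rng) -> tuple:
    """Event-stratified random split."""
    idx_e = np.flatnonzero(data.event == 1)
    idx_c = np.flatnonzero(data.event == 0)
    rng.shuffle(idx_e)
    rng.shuffle(idx_c)
    ne, nc = int(round(frac * len(idx_e))), int(round(frac * len(idx_c)))
    train = np.sort(np.concatenate([idx_e[:ne], idx_c[:nc]]))
    test = np.sort(np.concatenate([idx_e[ne:], idx_c[nc:]]))
    return data.subset(train), data.subset(test)


def _oracle_refit(data: SurvivalDataset, truth: MCFMParams, control: EMControl):
    """Unpenalized EM restricted to the true-support penalized columns."""
    sup_z = np.flatnonzero(truth.b_p)
    sup_x = np.flatnonzero(truth.beta_p)
    reduced = SurvivalDataset(
        time=data.time,
        event=data.event,
        z_u=data.z_u,
        z_p=data.z_p[:, sup_z],
        x_u=data.x_u,
        x_p=data.x_p[:, sup_x],
    )
    ctl = EMControl(
        tol=control.tol,
        max_iter=control.max_iter,
        frailty=control.frailty,
        standardize=control.standardize,
    )
    fit = run_em(reduced, PenaltySpec(lambda_enet=0.0), control=ctl)
    b_p = np.zeros_like(truth.b_p)
    beta_p = np.zeros_like(truth.beta_p)
    b_p[sup_z] = fit.params.b_p
    beta_p[sup_x] = fit.params.beta_p
    return b_p, beta_p


def _pen_covariance(design: SimulationDesign):
    if design.rho == 0:
        return None  # identity
    p, bs = design.p_pen, design.block_size
    S = np.zeros((p, p))
    for start in range(0, p, bs):
        stop = min(start + bs, p)
        m = stop - start
        S[start:stop, start:stop] = design.rho ** np.abs(
            np.subtract.outer(np.arange(m), np.arange(m))
        )
    return S


def _evaluate(fit, data_train, data_test, truth, oracle, cov) -> dict:
    params = fit.params
    out = {}
    for split, ds in (("train", data_train), ("test", data_test)):
        risk = np.broadcast_to(
            np.asarray(core.latency_linpred(params, ds.x_u, ds.x_p), float), (ds.n,)
        )
        pi_hat = np.broadcast_to(
            np.asarray(core.uncured_probability(params, ds.z_u, ds.z_p), float), (ds.n,)
        )
        out[f"c_cure_{split}"] = c_index_cure(ds.time, ds.event, risk, pi_hat)
        out[f"c_harrell_{split}"] = c_index_harrell(ds.time, ds.event, risk)
    for block, est, true_c, orc in (
        ("beta_p", params.beta_p, truth.beta_p, oracle[1]),
        ("b_p", params.b_p, truth.b_p, oracle[0]),
    ):
        sel = selection_metrics(true_c, est)
        out.update({f"{k}_{block}": v for k, v in sel.items()})
        ratios = rme_err(true_c, est, orc, covariance=cov)
        out[f"rme_{block}"] = ratios["rme"]
        out[f"err_{block}"] = ratios["err"]
    pi_true = np.broadcast_to(
        np.asarray(
            core.uncured_probability(truth, data_train.z_u, data_train.z_p), float
        ),
        (data_train.n,),
    )
    pi_est = np.broadcast_to(
        np.asarray(
            core.uncured_probability(params, data_train.z_u, data_train.z_p), float
        ),
        (data_train.n,),
    )
    pm = pi_bias_mse([pi_true], [pi_est])
    out["pi_bias"] = pm["bias"]
    out["pi_mse"] = pm["mse"]
    return out


def _fit_pencox(train: SurvivalDataset, cfg: BenchmarkConfig, seed: int):
    """Thin adapter around an elastic-net Cox solver (lasso, 1-SE lambda).

    Covers only the latency part of the model on (x_u, x_p); returned as
    a pseudo parameter set with a null incidence model.
    """
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    X = np.column_stack([train.x_u, train.x_p])
    y = Surv.from_arrays(event=train.event.astype(bool), time=train.time)
    pen_factor = np.concatenate([np.zeros(train.p2u), np.ones(train.p2p)])
    base = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, alpha_min_ratio=0.01, n_alphas=cfg.n_lambda,
        penalty_factor=pen_factor,
    )
    base.fit(X, y)
    alphas = base.alphas_
    # K-fold CV of the held-out concordance per alpha, then 1-SE backoff
    from sklearn.model_selection import StratifiedKFold
    from sksurv.metrics import concordance_index_censored

    skf = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=seed)
    fold_scores = []
    for tr, te in skf.split(X, train.event):
        m = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, alphas=alphas, penalty_factor=pen_factor
        ).fit(X[tr], y[tr])
        row = []
        for a in alphas:
            risk = m.predict(X[te], alpha=a)
            if np.ptp(risk) == 0:
                row.append(0.5)
            else:
                row.append(
                    concordance_index_censored(
                        train.event[te].astype(bool), train.time[te], risk
                    )[0]
                )
        fold_scores.append(row)
    fold_scores = np.asarray(fold_scores)
    mean = fold_scores.mean(axis=0)
    se = fold_scores.std(axis=0, ddof=1) / np.sqrt(cfg.cv_folds)
    i_best = int(np.argmax(mean))
    # alphas_ are decreasing: the 1-SE choice is the largest admissible alpha
    ok = np.flatnonzero(mean >= mean[i_best] - se[i_best])
    i_sel = int(ok.min())
    coef = np.asarray(
        CoxnetSurvivalAnalysis(
            l1_ratio=1.0, alphas=[alphas[i_sel]], penalty_factor=pen_factor
        )
        .fit(X, y)
        .coef_
    ).ravel()
    params = MCFMParams(
        alpha=1.0,
        gamma=1.0,
        theta=None,
        b0=0.0,
        b_u=np.zeros(train.p1u),
        b_p=np.zeros(train.p1p),
        beta_u=coef[: train.p2u],
        beta_p=coef[train.p2u :],
    )
    from .em import FitResult

    return FitResult(
        params=params,
        support_incidence=np.empty(0, dtype=int),
        support_latency=np.flatnonzero(params.beta_p),
        meta={"alpha_1se": float(alphas[i_sel])},
    )


def _fit_method(method, train, cfg: BenchmarkConfig, seed: int):
    if method == "penMCFM-EM":
        lams = lambda_path(train, n_lambda=cfg.n_lambda, min_ratio=cfg.lambda_min_ratio)
        cv = cross_validate(
            train,
            lams,
            alpha_grid=cfg.alpha_grid,
            K=cfg.cv_folds,
            seed=seed,
            control=cfg.em_control,
            k_adaptive=1,
        )
        penalty = PenaltySpec(
            lambda_enet=cv.best_lambda,
            alpha_enet=cv.best_alpha,
            k_adaptive=cfg.k_adaptive,
        )
        fit = run_em(train, penalty=penalty, control=cfg.em_control)
        meta = {"lambda": cv.best_lambda, "alpha_enet": cv.best_alpha}
    elif method in ("penMCFM-GMIFS", "MCM-GMIFS"):
        variant = "penMCFM" if method == "penMCFM-GMIFS" else "MCM"
        fit = gmifs_fit(train, variant=variant, control=cfg.gmifs_control)
        meta = {"lambda": np.nan, "alpha_enet": np.nan}
    elif method == "penCox.1se":
        fit = _fit_pencox(train, cfg, seed)
        meta = {"lambda": fit.meta["alpha_1se"], "alpha_enet": np.nan}
    else:
        raise ValueError(f"unknown method {method!r}")
    return fit, meta


def benchmark(cfg: BenchmarkConfig) -> pd.DataFrame:
    """Run the replicated study; returns one row per (replicate, method)."""
    rows = []
    cov = _pen_covariance(cfg.design)
    for rep in range(cfg.n_replicates):
        rep_seed = int(cfg.seed + 1000 * rep)
        rng = np.random.default_rng(rep_seed)
        data, truth = simulate_dataset(cfg.design, rng=rng)
        train, test = _train_test_split(data, cfg.train_frac, rng)
        try:
            oracle = _oracle_refit(train, truth, cfg.em_control)
        except Exception as exc:  # degenerate replicate (e.g. no events in split)
            warnings.warn(f"replicate {rep} skipped: {exc}", RuntimeWarning, stacklevel=2)
            continue
        for method in cfg.methods:
            try:
                fit, meta = _fit_method(method, train, cfg, seed=rep_seed)
            except Exception as exc:
                warnings.warn(
                    f"replicate {rep}, method {method} failed: {exc}",
                    RuntimeWarning,
                    stacklevel=2,
                )
                rows.append({"replicate": rep, "method": method, "failed": True})
                continue
            row = {
                "replicate": rep,
                "method": method,
                "seed": rep_seed,
                "failed": False,
                **meta,
                **_evaluate(fit, train, test, truth, oracle, cov),
            }
            if method == "penCox.1se":
                # latency-only comparator: incidence-based metrics undefined
                for key in list(row):
                    if key.startswith(("pi_", "c_cure")) or key.endswith("_b_p"):
                        row[key] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)
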