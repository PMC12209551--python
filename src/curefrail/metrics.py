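"""Performance metrics: concordance, variable selection, error ratios,
uncured-probability accuracy, and the prognostic risk score.

Undefined metrics (no evaluable pairs, zero denominators) are signalled
by ``numpy.nan`` rather than an exception, so callers can aggregate over
replicates without special-casing degenerate draws.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "c_index_harrell",
    "c_index_cure",
    "selection_metrics",
    "rme_err",
    "pi_bias_mse",
    "prognostic_risk_score",
]


def _evaluable_pairs(times, events):
    """I_ij = I[t_i < t_j, d_i=1] + I[t_i = t_j, d_i=1, d_j=0] (i != j)."""
    t = np.asarray(times, float)
    d = np.asarray(events)
    lt = t[:, None] < t[None, :]
    eq = t[:, None] == t[None, :]
    I = (lt & (d[:, None] == 1)) | (eq & (d[:, None] == 1) & (d[None, :] == 0))
    np.fill_diagonal(I, False)
    return I


def c_index_harrell(times, events, risk_scores) -> float:
    """Harrell's concordance index with strict score inequality.

    A pair (i, j) is evaluable when subject i has the event strictly
    before j's observed time (or at a tie against a censored j);
    concordance requires the earlier subject to carry the strictly
    larger risk score.  Returns NaN if there are no evaluable pairs.
    """
    s = np.asarray(risk_scores, float)
    if len(s) < 2:
        raise ValueError("need at least two subjects")
    I = _evaluable_pairs(times, events)
    den = I.sum()
    if den == 0:
        return float("nan")
    conc = (s[:, None] > s[None, :]) & I
    return float(conc.sum() / den)


def c_index_cure(times, events, risk_scores, uncured_prob_hat, known_cure_status=None) -> float:
    """Cure-adjusted concordance index.

    Every evaluable pair is weighted by the second member's cure-status
    weight: the known uncured indicator ``y_j`` where the status is
    known, otherwise the estimated uncured probability ``pi_hat(z_j)``.
    ``known_cure_status`` holds ``y_j`` (0/1) where known and NaN where
    latent; by default events are known uncured and censored subjects
    are unknown.  Reduces to :func:`c_index_harrell` when every weight
    is 1.
    """
    t = np.asarray(times, float)
    d = np.asarray(events)
    s = np.asarray(risk_scores, float)
    pi_hat = np.asarray(uncured_prob_hat, float)
    if np.any((pi_hat < 0) | (pi_hat > 1)):
        raise ValueError("uncured probabilities must lie in [0, 1]")
    if known_cure_status is None:
        known_cure_status = np.where(d == 1, 1.0, np.nan)
    y = np.asarray(known_cure_status, float)
    w = np.where(np.isnan(y), pi_hat, y)
    I = _evaluable_pairs(t, d)
    den = float((I * w[None, :]).sum())
    if den == 0:
        return float("nan")
    num = float((((s[:, None] > s[None, :]) & I) * w[None, :]).sum())
    return num / den


def selection_metrics(true_coefs, est_coefs) -> dict:
    """Sensitivity / specificity / FPR of support recovery plus model size."""
    truth = np.asarray(true_coefs, float)
    est = np.asarray(est_coefs, float)
    if truth.shape != est.shape:
        raise ValueError("coefficient vectors must have equal length")
    true_nz = truth != 0
    est_nz = est != 0
    n_pos = int(true_nz.sum())
    n_neg = int((~true_nz).sum())
    sens = float((true_nz & est_nz).sum() / n_pos) if n_pos else float("nan")
    spec = float((~true_nz & ~est_nz).sum() / n_neg) if n_neg else float("nan")
    fpr = float((~true_nz & est_nz).sum() / n_neg) if n_neg else float("nan")
    return {
        "sensitivity": sens,
        "specificity": spec,
        "fpr": fpr,
        "n_selected": int(est_nz.sum()),
    }


def rme_err(true_coefs, est_coefs, oracle_coefs, covariance=None) -> dict:
    """Relative model error and estimation error versus the oracle refit.

    RME = (est-true)' Sigma (est-true) / (oracle-true)' Sigma (oracle-true)
    and ERR is the same ratio with the identity in place of Sigma; the
    oracle is the unpenalized fit restricted to the true support.  The
    two coincide whenever Sigma is the identity.
    """
    truth = np.asarray(true_coefs, float)
    est = np.asarray(est_coefs, float)
    oracle = np.asarray(oracle_coefs, float)
    d_est = est - truth
    d_or = oracle - truth
    if covariance is None:
        num_w, den_w = float(d_est @ d_est), float(d_or @ d_or)
    else:
        S = np.asarray(covariance, float)
        num_w, den_w = float(d_est @ S @ d_est), float(d_or @ S @ d_or)
    num_i, den_i = float(d_est @ d_est), float(d_or @ d_or)
    return {
        "rme": num_w / den_w if den_w > 0 else float("nan"),
        "err": num_i / den_i if den_i > 0 else float("nan"),
    }


def pi_bias_mse(true_uncured_probs, est_uncured_probs) -> dict:
    """Bias and MSE of estimated uncured probabilities over replicates.

    Both arguments are sequences of per-subject probability vectors, one
    per Monte Carlo replicate; the inner mean runs over subjects, the
    outer mean over replicates.
    """
    if len(true_uncured_probs) != len(est_uncured_probs):
        raise ValueError("replicate counts differ")
    biases, mses = [], []
    for truth, est in zip(true_uncured_probs, est_uncured_probs):
        truth = np.asarray(truth, float)
        est = np.asarray(est, float)
        if truth.shape != est.shape:
            raise ValueError("per-replicate subject counts differ")
        diff = est - truth
        biases.append(diff.mean())
        mses.append((diff**2).mean())
    return {"bias": float(np.mean(biases)), "mse": float(np.mean(mses))}


def prognostic_risk_score(expression: pd.DataFrame, avg_coefs: pd.Series):
    """Linear risk score over selected features, dichotomized at the median.

    ``expression`` is subjects x features; ``avg_coefs`` is indexed by
    feature name (the averaged estimated coefficients of the selected
    features).  Ties at the median go to the low-risk group.  Returns
    ``(scores, groups)``; ``groups`` is ``None`` (undefined) when all
    scores are identical, e.g. for an empty/all-zero coefficient set.
    """
    missing = [c for c in avg_coefs.index if c not in expression.columns]
    if missing:
        raise ValueError(f"features absent from the expression matrix: {missing}")
    scores = expression[list(avg_coefs.index)].to_numpy() @ avg_coefs.to_numpy()
    scores = pd.Series(scores, index=expression.index, name="prs")
    if np.ptp(scores.to_numpy()) == 0:
        return scores, None
    med = float(scores.median())
    groups = pd.Series(
        np.where(scores.to_numpy() > med, "high", "low"),
        index=expression.index,
        name="risk_group",
    )
    return scores, groups
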