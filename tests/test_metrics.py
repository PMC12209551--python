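"""Evaluation-metric checks against brute-force pair enumeration."""

import numpy as np
import pandas as pd
import pytest

from curefrail import (
    c_index_cure,
    c_index_harrell,
    pi_bias_mse,
    prognostic_risk_score,
    rme_err,
    selection_metrics,
)


def brute_force_cindex(times, events, scores, weights=None):
    """Direct double loop over the printed pair-indicator definition."""
    n = len(times)
    if weights is None:
        weights = np.ones(n)
    num = den = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            I = float(
                (times[i] < times[j] and events[i] == 1)
                or (times[i] == times[j] and events[i] == 1 and events[j] == 0)
            )
            den += weights[j] * I
            num += weights[j] * I * float(scores[i] > scores[j])
    return num / den if den > 0 else np.nan


class TestHarrellC:
    def test_perfect_and_reversed(self):
        t = np.array([1.0, 2.0, 3.0])
        d = np.ones(3, dtype=int)
        assert c_index_harrell(t, d, np.array([3.0, 2.0, 1.0])) == 1.0
        assert c_index_harrell(t, d, np.array([1.0, 2.0, 3.0])) == 0.0

    def test_censored_example_against_enumeration(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        d = np.array([1, 1, 0, 1])
        s = np.array([4.0, 3.0, 2.0, 1.0])
        assert c_index_harrell(t, d, s) == pytest.approx(brute_force_cindex(t, d, s))
        assert c_index_harrell(t, d, s) == 1.0

    def test_random_against_enumeration(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 12))
            t = rng.choice([1.0, 2.0, 3.0, 4.0], size=n)
            d = (rng.uniform(size=n) < 0.6).astype(int)
            s = rng.normal(size=n)
            expected = brute_force_cindex(t, d, s)
            got = c_index_harrell(t, d, s)
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected)

    def test_no_evaluable_pairs_is_undefined(self):
        assert np.isnan(c_index_harrell([1.0, 2.0], [0, 0], [1.0, 2.0]))


class TestCureAdjustedC:
    def test_reduces_to_harrell_with_unit_weights(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 15))
            t = rng.uniform(0.1, 3.0, n)
            d = (rng.uniform(size=n) < 0.5).astype(int)
            s = rng.normal(size=n)
            h = c_index_harrell(t, d, s)
            c = c_index_cure(t, d, s, np.ones(n), known_cure_status=np.ones(n))
            if np.isnan(h):
                assert np.isnan(c)
            else:
                assert c == h

    def test_all_events_equals_harrell(self, rng):
        t = rng.uniform(0.1, 3.0, 10)
        d = np.ones(10, dtype=int)
        s = rng.normal(size=10)
        assert c_index_cure(t, d, s, rng.uniform(size=10)) == c_index_harrell(t, d, s)

    def test_weighted_example_against_enumeration(self):
        t = np.array([1.0, 2.0, 3.0])
        d = np.array([1, 0, 0])
        s = np.array([3.0, 2.0, 1.0])
        pi_hat = np.array([0.9, 0.5, 0.25])
        # subject 0 has an event (weight 1); others weighted by pi_hat
        w = np.array([1.0, 0.5, 0.25])
        expected = brute_force_cindex(t, d, s, weights=w)
        assert c_index_cure(t, d, s, pi_hat) == pytest.approx(expected)

    def test_zero_total_weight_is_undefined(self):
        t = np.array([1.0, 2.0, 3.0])
        d = np.array([1, 0, 0])
        s = np.array([3.0, 2.0, 1.0])
        # only pairs (0, j) with j censored are evaluable; pi_hat = 0 kills them
        assert np.isnan(c_index_cure(t, d, s, np.zeros(3)))

    def test_permutation_invariance(self, rng):
        n = 12
        t = rng.uniform(0.1, 3.0, n)
        d = (rng.uniform(size=n) < 0.5).astype(int)
        s = rng.normal(size=n)
        pi_hat = rng.uniform(size=n)
        base = c_index_cure(t, d, s, pi_hat)
        perm = rng.permutation(n)
        assert c_index_cure(t[perm], d[perm], s[perm], pi_hat[perm]) == pytest.approx(base)


class TestSelectionMetrics:
    @pytest.mark.parametrize(
        "truth,est,expected",
        [
            ([1.0, 0, 2.0, 0], [1.0, 0, 2.0, 0], (1.0, 1.0, 0.0)),
            ([1.0, 0, 2.0, 0], [0, 0, 0, 0], (0.0, 1.0, 0.0)),
            ([1.0, 1.0, 0, 0], [0.5, 0, 0.1, 0], (0.5, 0.5, 0.5)),
        ],
    )
    def test_enumerated_cases(self, truth, est, expected):
        m = selection_metrics(truth, est)
        assert (m["sensitivity"], m["specificity"], m["fpr"]) == expected

    def test_fpr_complements_specificity(self, rng):
        truth = rng.choice([0.0, 1.0], size=30)
        est = rng.choice([0.0, 0.3], size=30)
        m = selection_metrics(truth, est)
        assert m["fpr"] == pytest.approx(1.0 - m["specificity"])


class TestRmeErr:
    def test_oracle_and_truth_anchors(self):
        truth = np.array([1.0, 0.0, -1.0])
        oracle = np.array([1.2, 0.0, -0.9])
        assert rme_err(truth, oracle, oracle) == {"rme": 1.0, "err": 1.0}
        out = rme_err(truth, truth, oracle)
        assert out["rme"] == 0.0 and out["err"] == 0.0

    def test_identity_covariance_makes_them_equal(self, rng):
        for _ in range(10):
            truth = rng.normal(size=6)
            est = rng.normal(size=6)
            oracle = rng.normal(size=6)
            out = rme_err(truth, est, oracle, covariance=np.eye(6))
            assert out["rme"] == pytest.approx(out["err"], rel=1e-12)

    def test_nonidentity_covariance_separates_them(self, rng):
        S = np.diag([1.0, 4.0, 9.0])
        truth = np.zeros(3)
        out = rme_err(truth, [1.0, 1.0, 0.0], [0.0, 0.0, 1.0], covariance=S)
        assert out["rme"] != pytest.approx(out["err"])


class TestPiBiasMse:
    def test_exact_and_shifted(self):
        truth = [np.full(5, 0.4), np.full(5, 0.6)]
        assert pi_bias_mse(truth, truth) == {"bias": 0.0, "mse": 0.0}
        est = [t + 0.1 for t in truth]
        out = pi_bias_mse(truth, est)
        assert out["bias"] == pytest.approx(0.1)
        assert out["mse"] == pytest.approx(0.01)

    def test_matches_flat_double_loop(self, rng):
        truth = [rng.uniform(size=7) for _ in range(4)]
        est = [rng.uniform(size=7) for _ in range(4)]
        out = pi_bias_mse(truth, est)
        b = np.mean([np.mean([e - t for t, e in zip(tr, es)]) for tr, es in zip(truth, est)])
        m = np.mean([np.mean([(e - t) ** 2 for t, e in zip(tr, es)]) for tr, es in zip(truth, est)])
        assert out["bias"] == pytest.approx(b, abs=1e-12)
        assert out["mse"] == pytest.approx(m, abs=1e-12)


class TestPrognosticRiskScore:
    def test_single_feature_identity(self):
        expr = pd.DataFrame({"g1": [0.5, -1.0, 2.0]})
        scores, groups = prognostic_risk_score(expr, pd.Series({"g1": 1.0}))
        np.testing.assert_allclose(scores, expr["g1"])

    def test_hand_example_with_tie_rule(self):
        expr = pd.DataFrame([[2.0, 1.0], [1.0, 1.0], [0.0, 0.0], [-1.0, 0.0]],
                            columns=["g1", "g2"])
        scores, groups = prognostic_risk_score(expr, pd.Series({"g1": 1.0, "g2": -1.0}))
        np.testing.assert_allclose(scores, [1.0, 0.0, 0.0, -1.0])
        # median 0; ties go to the low-risk group
        assert list(groups) == ["high", "low", "low", "low"]

    def test_all_zero_coefficients_undefined_grouping(self):
        expr = pd.DataFrame({"g1": [1.0, 2.0]})
        scores, groups = prognostic_risk_score(expr, pd.Series({"g1": 0.0}))
        assert groups is None
        assert (scores == 0).all()

    def test_name_mismatch_raises(self):
        expr = pd.DataFrame({"g1": [1.0]})
        with pytest.raises(ValueError):
            prognostic_risk_score(expr, pd.Series({"g2": 1.0}))
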