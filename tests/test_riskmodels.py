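"""Probability-of-death model families and cross-validated log loss."""

import itertools
import math

import numpy as np
import pytest

from traumascores import (
    cross_validate,
    fit_logistic,
    fit_monotone,
    fit_spline,
    log_loss,
    pava,
)
from traumascores.riskmodels import rcs_basis


def pava_bruteforce(y, w=None):
    """Exhaustive search over monotone block partitions (n <= 10)."""
    y = np.asarray(y, float)
    w = np.ones_like(y) if w is None else np.asarray(w, float)
    n = len(y)
    best, best_sse = None, np.inf
    # choose block boundaries among the n-1 gaps
    for mask in itertools.product([0, 1], repeat=n - 1):
        bounds = [0] + [i + 1 for i, b in enumerate(mask) if b] + [n]
        means = []
        for a, b in zip(bounds, bounds[1:]):
            means.append(np.average(y[a:b], weights=w[a:b]))
        if any(m2 < m1 for m1, m2 in zip(means, means[1:])):
            continue
        fit = np.concatenate([np.full(b - a, m) for (a, b), m
                              in zip(zip(bounds, bounds[1:]), means)])
        sse = np.sum(w * (y - fit) ** 2)
        if sse < best_sse - 1e-12:
            best, best_sse = fit, sse
    return best


class TestLogLoss:
    def test_half_probability_gives_ln2(self):
        assert log_loss([0.5] * 6, [0, 1, 0, 1, 1, 0]) == pytest.approx(
            math.log(2))

    def test_perfect_predictions_near_zero(self):
        assert log_loss([0, 1, 1, 0], [0, 1, 1, 0]) < 1e-12

    def test_prevalence_entropy_closed_form(self):
        # constant p = prevalence 0.025 -> Bernoulli entropy 0.1175
        n = 1000
        y = np.zeros(n)
        y[:25] = 1
        expected = -(0.025 * math.log(0.025) + 0.975 * math.log(0.975))
        assert log_loss(np.full(n, 0.025), y) == pytest.approx(expected)
        assert round(expected, 4) == 0.1169

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            log_loss([0.5, 0.5], [1])


class TestPAVA:
    def test_classic_hand_example(self):
        assert pava([0, 1, 0, 1]).tolist() == [0, 0.5, 0.5, 1]

    def test_monotone_input_identity(self):
        y = [0.0, 0.1, 0.1, 0.4, 0.9]
        assert pava(y).tolist() == y

    def test_matches_bruteforce(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 11))
            y = rng.random(n).round(2)
            w = rng.integers(1, 4, size=n).astype(float)
            assert pava(y, w) == pytest.approx(pava_bruteforce(y, w), abs=1e-10)

    def test_matches_sklearn(self, rng):
        from sklearn.isotonic import IsotonicRegression
        y = rng.random(200)
        x = np.arange(200, dtype=float)
        ours = pava(y)
        theirs = IsotonicRegression().fit(x, y).predict(x)
        assert ours == pytest.approx(theirs, abs=1e-10)


class TestLogistic:
    def test_fitted_mean_equals_prevalence(self, rng):
        x = rng.normal(size=2000)
        y = (rng.random(2000) < 1 / (1 + np.exp(-(x - 2)))).astype(int)
        model = fit_logistic(x, y)
        assert model.predict(x).mean() == pytest.approx(y.mean(), abs=1e-6)

    def test_parameter_recovery(self, rng):
        a, b, n = -3.66, 0.8, 50_000
        x = rng.normal(size=n) * 2
        y = (rng.random(n) < 1 / (1 + np.exp(-(a + b * x)))).astype(int)
        model = fit_logistic(x, y)
        assert model.params["intercept"] == pytest.approx(a, abs=0.15)
        assert model.params["slope"] == pytest.approx(b, abs=0.08)

    def test_null_slope_recovery(self, rng):
        x = rng.normal(size=10_000)
        y = (rng.random(10_000) < 0.2).astype(int)
        model = fit_logistic(x, y)
        assert abs(model.params["slope"]) < 0.05

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm
        x = rng.normal(size=500)
        y = (rng.random(500) < 1 / (1 + np.exp(-x))).astype(int)
        ours = fit_logistic(x, y)
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert ours.params["intercept"] == pytest.approx(ref.params[0], abs=1e-5)
        assert ours.params["slope"] == pytest.approx(ref.params[1], abs=1e-5)

    def test_separation_handled_with_warning(self):
        x = np.concatenate([np.zeros(20), np.ones(20)])
        y = np.concatenate([np.zeros(20, int), np.ones(20, int)])
        with pytest.warns(UserWarning, match="separation"):
            model = fit_logistic(x, y)
        p = model.predict(x)
        assert np.all((p >= 0) & (p <= 1))


class TestSpline:
    def test_linear_tails_in_logit(self, rng):
        x = rng.normal(size=3000) * 3
        y = (rng.random(3000) < 1 / (1 + np.exp(-x / 2))).astype(int)
        model = fit_spline(x, y)
        hi = x.max()
        s = np.array([hi + 1, hi + 2, hi + 3, hi + 4])
        p = np.clip(model.predict(s), 1e-12, 1 - 1e-12)
        logit = np.log(p / (1 - p))
        second_diff = np.diff(logit, n=2)
        assert np.all(np.abs(second_diff) < 1e-8)

    def test_rcs_basis_shape_and_tail(self):
        knots = np.array([-1.0, 0.0, 1.0])
        B = rcs_basis(np.linspace(-3, 3, 100), knots)
        assert B.shape == (100, 2)
        # nonlinear term linear beyond the last knot
        tail = rcs_basis(np.array([2.0, 3.0, 4.0]), knots)[:, 1]
        assert np.diff(tail, n=2) == pytest.approx(0.0, abs=1e-9)

    def test_nested_recovery_on_linear_truth(self, rng):
        n = 20_000
        x = rng.normal(size=n) * 2
        y = (rng.random(n) < 1 / (1 + np.exp(-(x - 2)))).astype(int)
        l_log = cross_validate("logistic", x, y, seed=0)
        l_spl = cross_validate("spline", x, y, seed=0)
        assert l_spl <= l_log + 0.005

    def test_beats_logistic_on_threshold_truth(self, rng):
        n = 20_000
        x = rng.normal(size=n) * 2
        p = np.where(x > 1.5, 0.6, 0.02)
        y = (rng.random(n) < p).astype(int)
        l_log = cross_validate("logistic", x, y, seed=0)
        l_spl = cross_validate("spline", x, y, seed=0)
        assert l_spl < l_log

    def test_few_distinct_values_fallback(self):
        x = np.array([0.0, 1.0] * 50)
        y = np.array([0, 1] * 50)
        with pytest.warns(UserWarning, match="knot"):
            model = fit_spline(x, y)
        assert model.params.get("fallback") == "logistic"


class TestMonotone:
    def test_predictions_nondecreasing(self, rng):
        x = rng.normal(size=500)
        y = (rng.random(500) < 1 / (1 + np.exp(-x))).astype(int)
        model = fit_monotone(x, y)
        grid = np.linspace(x.min() - 1, x.max() + 1, 200)
        p = model.predict(grid)
        assert np.all(np.diff(p) >= -1e-12)
        assert np.all((p >= 0) & (p <= 1))

    def test_tied_scores_share_prediction(self):
        x = np.array([1, 1, 2, 2, 3, 3], dtype=float)
        y = np.array([0, 1, 0, 0, 1, 1])
        model = fit_monotone(x, y)
        p = model.predict(x)
        assert p[0] == p[1] and p[2] == p[3] and p[4] == p[5]


class TestCV:
    def test_deterministic_given_seed(self, rng):
        x = rng.normal(size=600)
        y = (rng.random(600) < 1 / (1 + np.exp(-x))).astype(int)
        assert cross_validate("monotone", x, y, seed=5) == \
            cross_validate("monotone", x, y, seed=5)

    def test_intercept_only_matches_entropy(self, rng):
        # a constant predictor's CV loss is the Bernoulli entropy of the
        # prevalence; logistic on pure-noise x is nearly constant
        n, prev = 20_000, 0.025
        x = rng.normal(size=n) * 0  # constant score -> intercept-only fit
        x += rng.normal(size=n) * 1e-9
        y = (rng.random(n) < prev).astype(int)
        pi = y.mean()
        entropy = -(pi * math.log(pi) + (1 - pi) * math.log(1 - pi))
        loss = cross_validate("logistic", x, y, seed=1)
        assert loss == pytest.approx(entropy, abs=0.01)
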