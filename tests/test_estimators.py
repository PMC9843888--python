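"""Estimator correctness: closed forms, independent oracles, invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.special import expit, logit

from ecasim import (
    compute_weights,
    draw_samples,
    estimate_gcomputation,
    estimate_raw,
    estimate_weighted,
    fit_propensity,
    generate_population,
)


def _sample(pop, n=200, seed=0):
    (_, s), = draw_samples(pop, 1, n, seed=seed)
    return s


def _toy_binary_sample(n_t, e_t, n_c, e_c):
    """Sample with given event counts per arm for the binary outcome."""
    a = np.repeat([1, 0], [n_t, n_c])
    yb = np.concatenate([
        np.repeat([1, 0], [e_t, n_t - e_t]),
        np.repeat([1, 0], [e_c, n_c - e_c]),
    ])
    n = n_t + n_c
    return pd.DataFrame({
        "C": np.zeros(n), "L": np.zeros(n), "A": a, "Ya": yb.astype(float),
        "Yb": yb, "Yc": np.ones(n), "D": yb,
    })


class TestRaw:
    def test_two_by_two_log_odds_ratio(self):
        s = _toy_binary_sample(100, 30, 100, 10)
        est = estimate_raw(s, "binary")
        assert est.point == pytest.approx(np.log(30 * 90 / (70 * 10)), abs=1e-6)
        assert est.ci_low <= est.point <= est.ci_high

    def test_identical_arms_give_zero_difference(self, rng):
        y = rng.normal(size=100)
        s = pd.DataFrame({
            "C": np.zeros(200), "L": np.zeros(200),
            "A": np.repeat([1, 0], 100), "Ya": np.concatenate([y, y]),
            "Yb": np.zeros(200, dtype=int), "Yc": np.ones(200),
            "D": np.ones(200, dtype=int),
        })
        assert estimate_raw(s, "continuous").point == pytest.approx(0.0, abs=1e-10)

    def test_single_arm_rejected(self):
        s = _toy_binary_sample(100, 30, 100, 10)
        s["A"] = 1
        with pytest.raises(ValueError, match="both arms"):
            estimate_raw(s, "continuous")

    def test_zero_events_in_arm_flags_nonconvergence(self):
        s = _toy_binary_sample(100, 30, 100, 0)
        est = estimate_raw(s, "binary")
        assert not est.converged


class TestPropensity:
    def test_matches_independent_likelihood_oracle(self):
        """Coefficients agree with direct numerical maximization of the
        Bernoulli log-likelihood on a small hand-made dataset."""
        s = pd.DataFrame({
            "C": [1.0, 2.0, 0.5, 3.0, 1.5, 2.5, 0.8, 2.2],
            "L": [0, 1, 0, 1, 1, 0, 0, 1],
            "A": [0, 1, 0, 1, 0, 1, 0, 0],
        })
        X = np.column_stack([np.ones(8), s["C"], s["L"]])
        y = s["A"].to_numpy(float)

        def nll(beta):
            lp = X @ beta
            return float(np.sum(np.log1p(np.exp(lp)) - y * lp))

        oracle = minimize(nll, np.zeros(3), method="BFGS", tol=1e-12).x
        fit = fit_propensity(s.assign(Ya=0.0, Yb=0, Yc=1.0, D=1))
        assert fit.converged
        np.testing.assert_allclose(fit.coefficients, oracle, atol=1e-5)

    def test_null_assignment_gives_flat_scores(self, rng):
        n = 2_000
        s = pd.DataFrame({
            "C": rng.normal(50, 7, n), "L": rng.integers(0, 2, n),
            "A": rng.integers(0, 2, n),
        })
        fit = fit_propensity(s)
        assert np.std(fit.scores) < 0.05
        assert fit.scores.mean() == pytest.approx(s["A"].mean(), abs=0.02)

    def test_scores_track_c_under_confounded_assignment(self, coeffs2):
        pop = generate_population(coeffs2, 20_000, seed=5)
        s = _sample(pop, 500, seed=1)
        fit = fit_propensity(s)
        assert np.corrcoef(fit.scores, s["C"])[0, 1] > 0.3


class TestWeights:
    @pytest.mark.parametrize(
        "p,arm,expected",
        [
            (0.5, 1, {"IPTW": 2.0, "SMR": 1.0, "OW": 0.5}),
            (0.5, 0, {"IPTW": 2.0, "SMR": 1.0, "OW": 0.5}),
            (0.8, 1, {"IPTW": 1.25, "SMR": 1.0, "OW": 0.2}),
            (0.8, 0, {"IPTW": 5.0, "SMR": 4.0, "OW": 0.8}),
        ],
    )
    def test_formula_table(self, p, arm, expected):
        for method, want in expected.items():
            w = compute_weights(np.array([p]), np.array([arm]), method)
            assert w[0] == pytest.approx(want, abs=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(
        p=st.floats(0.001, 0.999),
        arm=st.integers(0, 1),
        method=st.sampled_from(["IPTW", "SMR", "OW"]),
    )
    def test_weights_always_finite_positive(self, p, arm, method):
        w = compute_weights(np.array([p]), np.array([arm]), method)
        assert np.isfinite(w[0]) and w[0] > 0

    def test_degenerate_scores_rejected(self):
        with pytest.raises(ValueError):
            compute_weights(np.array([0.0]), np.array([1]), "IPTW")


class TestWeighted:
    def test_equal_weights_reproduce_raw_point(self, pop1):
        s = _sample(pop1, 300, seed=2)
        w = np.full(len(s), 2.5)
        for outcome in ("continuous", "binary", "survival"):
            raw = estimate_raw(s, outcome)
            weighted = estimate_weighted(s, outcome, w)
            assert weighted.point == pytest.approx(raw.point, abs=1e-6)

    def test_weighted_mean_difference_closed_form(self):
        s = pd.DataFrame({
            "C": np.zeros(4), "L": np.zeros(4), "A": [1, 1, 0, 0],
            "Ya": [3.0, 5.0, 1.0, 2.0], "Yb": [0, 1, 0, 1],
            "Yc": np.ones(4), "D": np.ones(4, dtype=int),
        })
        w = np.array([1.0, 3.0, 2.0, 2.0])
        est = estimate_weighted(s, "continuous", w, min_ess=0.0)
        # weighted arm means: treated (1*3+3*5)/(1+3); control (2*1+2*2)/(2+2)
        hand = (1 * 3 + 3 * 5) / 4 - (2 * 1 + 2 * 2) / 4
        assert est.point == pytest.approx(hand, abs=1e-10)

    def test_overlap_weights_balance_covariates_exactly(self, pop1):
        """Algebraic property of overlap weights with logistic scores:
        weighted covariate means coincide between arms, replicate by
        replicate."""
        for _, s in draw_samples(pop1, 10, 200, seed=77):
            fit = fit_propensity(s)
            if not fit.converged:
                continue
            w = compute_weights(fit.scores, s["A"].to_numpy(), "OW")
            a = s["A"].to_numpy()
            for var in ("C", "L"):
                x = s[var].to_numpy(float)
                mt = np.average(x[a == 1], weights=w[a == 1])
                mc = np.average(x[a == 0], weights=w[a == 0])
                assert mt == pytest.approx(mc, abs=1e-6)

    def test_iptw_weight_mass_rebuilds_full_sample(self, pop1):
        s = _sample(pop1, 200, seed=5)
        fit = fit_propensity(s)
        w = compute_weights(fit.scores, s["A"].to_numpy(), "IPTW")
        a = s["A"].to_numpy()
        assert w[a == 1].sum() == pytest.approx(len(s), rel=0.25)
        assert w[a == 0].sum() == pytest.approx(len(s), rel=0.25)


class TestGComputation:
    def test_linear_case_equals_adjusted_ols_coefficient(self, pop1, rng):
        s = _sample(pop1, 200, seed=3)
        est = estimate_gcomputation(s, "continuous", ci_bootstrap_reps=0, rng=rng)
        X = np.column_stack([np.ones(len(s)), s["A"], s["C"], s["L"]])
        beta, *_ = np.linalg.lstsq(X, s["Ya"].to_numpy(float), rcond=None)
        assert est.point == pytest.approx(beta[1], abs=1e-10)

    def test_binary_standardization_matches_cell_enumeration(self, rng):
        """With binary C, L and a correctly-specified main-effects model,
        the estimated marginal log OR matches brute-force standardization
        over the four covariate cells using the true risks."""
        n = 40_000
        c = rng.integers(0, 2, n).astype(float)
        l = rng.integers(0, 2, n)
        a = rng.integers(0, 2, n)
        true = dict(b0=-1.0, bA=1.2, bC=0.8, bL=-0.6)
        p = expit(true["b0"] + true["bA"] * a + true["bC"] * c + true["bL"] * l)
        s = pd.DataFrame({
            "C": c, "L": l, "A": a,
            "Ya": p, "Yb": (rng.random(n) < p).astype(int),
            "Yc": np.ones(n), "D": np.ones(n, dtype=int),
        })
        est = estimate_gcomputation(s, "binary", ci_bootstrap_reps=0, rng=rng)
        cells = [(ci, li, np.mean((c == ci) & (l == li))) for ci in (0, 1) for li in (0, 1)]
        m1 = sum(wt * expit(true["b0"] + true["bA"] + true["bC"] * ci + true["bL"] * li)
                 for ci, li, wt in cells)
        m0 = sum(wt * expit(true["b0"] + true["bC"] * ci + true["bL"] * li)
                 for ci, li, wt in cells)
        oracle = logit(m1) - logit(m0)
        assert est.point == pytest.approx(oracle, abs=0.05)

    def test_bootstrap_ci_brackets_point(self, pop1, rng):
        s = _sample(pop1, 200, seed=4)
        est = estimate_gcomputation(s, "continuous", ci_bootstrap_reps=100, rng=rng)
        assert est.converged
        assert est.ci_low <= est.point <= est.ci_high
        assert est.ci_method == "bootstrap_normal"

    def test_survival_point_recovers_marginal_loghr(self, coeffs1, rng):
        """On one large sample the survival g-computation estimate lands
        near the population marginal log hazard ratio."""
        from ecasim import true_effects_counterfactual

        pop = generate_population(coeffs1, 20_000, seed=6)
        s = _sample(pop, 4_000, seed=1)
        est = estimate_gcomputation(s, "survival", ci_bootstrap_reps=0, rng=rng)
        truth = true_effects_counterfactual(coeffs1, size=100_000, seed=2).ate_survival
        assert est.point == pytest.approx(truth, abs=0.12)


def test_all_methods_agree_without_confounding(no_confounding_coeffs, rng):
    """When treatment is randomized and covariates touch nothing, all six
    strategies estimate the same quantity within Monte-Carlo error."""
    from ecasim import estimate_tmle

    pop = generate_population(no_confounding_coeffs, 30_000, seed=9)
    s = _sample(pop, 4_000, seed=2)
    points = {"raw": estimate_raw(s, "continuous").point,
              "GC": estimate_gcomputation(s, "continuous", 0, rng=rng).point,
              "TMLE": estimate_tmle(s, "continuous").point}
    fit = fit_propensity(s)
    for m in ("IPTW", "SMR", "OW"):
        w = compute_weights(fit.scores, s["A"].to_numpy(), m)
        points[m] = estimate_weighted(s, "continuous", w, method=m).point
    vals = np.array(list(points.values()))
    assert vals.max() - vals.min() < 0.05
    truth = no_confounding_coeffs.ya_model.gA
    assert np.all(np.abs(vals - truth) < 3 * 2.0 / np.sqrt(1000))
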