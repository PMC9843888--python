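"""TMLE internals: clever covariate, fluctuation, identities, conversion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, logit

from ecasim import (
    clever_covariate,
    draw_samples,
    estimate_gcomputation,
    estimate_tmle,
    fit_propensity,
    generate_population,
    rr_to_hr,
)
from ecasim.tmle import TmleState, fluctuate, tmle_initial_state, tmle_risks


class TestCleverCovariate:
    @pytest.mark.parametrize(
        "p,arm,expected",
        [(0.5, 1, 2.0), (0.5, 0, -2.0), (0.25, 1, 4.0), (0.25, 0, -4.0 / 3.0)],
    )
    def test_substitution_values(self, p, arm, expected):
        h = clever_covariate(np.array([arm]), np.array([p]))
        assert h[0] == pytest.approx(expected, abs=1e-12)

    def test_treated_mean_inverts_prevalence(self):
        """With scores equal to the arm prevalence, the mean of H over the
        treated is 1/prevalence."""
        a = np.repeat([1, 0], [30, 70])
        h = clever_covariate(a, np.full(100, 0.3))
        assert h[a == 1].mean() == pytest.approx(1 / 0.3, abs=1e-12)

    def test_domain_check(self):
        with pytest.raises(ValueError):
            clever_covariate(np.array([1]), np.array([1.0]))


def _hand_state():
    """Four-individual worked example with fixed initial predictions."""
    pred_obs = np.array([0.30, 0.60, 0.40, 0.70])
    p = np.array([0.5, 0.25, 0.8, 0.4])
    a = np.array([1, 1, 0, 0])
    return TmleState(
        pred_obs=pred_obs,
        pred1=pred_obs.copy(),
        pred0=pred_obs.copy(),
        h_obs=clever_covariate(a, p),
        h1=1.0 / p,
        h0=-1.0 / (1.0 - p),
    ), np.array([1.0, 0.0, 1.0, 0.0])


class TestFluctuate:
    def test_epsilon_matches_grid_search_oracle(self):
        """The ML fluctuation parameter agrees with a brute-force 1-D grid
        search over the Bernoulli likelihood."""
        state, y = _hand_state()
        grid = np.arange(-2.0, 2.0, 1e-4)
        off = logit(state.pred_obs)
        ll = [
            np.sum(y * np.log(expit(off + e * state.h_obs)) +
                   (1 - y) * np.log(1 - expit(off + e * state.h_obs)))
            for e in grid
        ]
        oracle = grid[int(np.argmax(ll))]
        out = fluctuate(state, y)
        assert out.epsilon == pytest.approx(oracle, abs=1e-4)

    def test_zero_epsilon_is_identity(self):
        state, y = _hand_state()
        out = fluctuate(state, y, epsilon=0.0)
        np.testing.assert_allclose(out.pred1, state.pred1)
        np.testing.assert_allclose(out.pred0, state.pred0)
        assert out.epsilon == 0.0

    def test_stationary_initial_fit_needs_no_update(self, rng):
        """If the initial predictions already solve the influence-curve
        equation (true model, randomized treatment), epsilon is near 0."""
        n = 20_000
        c = rng.normal(size=n)
        a = rng.integers(0, 2, n).astype(float)
        p_true = expit(0.2 + 0.9 * a + 0.5 * c)
        y = (rng.random(n) < p_true).astype(float)
        s = pd.DataFrame({"C": c, "L": np.zeros(n, dtype=int), "A": a,
                          "Ya": y, "Yb": y.astype(int), "Yc": np.ones(n),
                          "D": np.ones(n, dtype=int)})
        ps = fit_propensity(s)
        state = tmle_initial_state(s, y, ps, continuous=False)
        out = fluctuate(state, y)
        assert abs(out.epsilon) < 0.02


def test_zero_epsilon_equals_plugin_of_initial_model(pop1, rng):
    """Forcing epsilon = 0 reduces TMLE to the g-computation plug-in of its
    own initial outcome model."""
    (_, s), = draw_samples(pop1, 1, 500, seed=11)
    y = s["Yb"].to_numpy(float)
    ps = fit_propensity(s)
    state = tmle_initial_state(s, y, ps, continuous=False)
    frozen = fluctuate(state, y, epsilon=0.0)
    mu1, mu0 = tmle_risks(frozen)
    plugin = logit(mu1) - logit(mu0)
    init_mu1, init_mu0 = tmle_risks(state)
    assert plugin == pytest.approx(logit(init_mu1) - logit(init_mu0), abs=1e-12)


def test_tmle_matches_gcomputation_when_targeting_is_unneeded(
    no_confounding_coeffs, rng
):
    pop = generate_population(no_confounding_coeffs, 30_000, seed=21)
    (_, s), = draw_samples(pop, 1, 3_000, seed=3)
    tm = estimate_tmle(s, "continuous")
    gc = estimate_gcomputation(s, "continuous", ci_bootstrap_reps=0, rng=rng)
    assert tm.converged
    assert tm.point == pytest.approx(gc.point, abs=0.05)


def test_tmle_returns_interval_bracketing_point(pop1):
    (_, s), = draw_samples(pop1, 1, 400, seed=13)
    for outcome in ("continuous", "binary", "survival"):
        est = estimate_tmle(s, outcome)
        assert est.converged
        assert est.ci_low <= est.point <= est.ci_high
        assert est.ci_method == "influence_curve"


class TestRrToHr:
    def test_identity_at_rr_one(self):
        assert rr_to_hr(1.0, 0.4) == pytest.approx(1.0, abs=1e-12)

    def test_printed_formula_value(self):
        assert rr_to_hr(0.5, 0.4) == pytest.approx(np.log(0.8) / np.log(0.6), abs=1e-12)
        assert rr_to_hr(0.5, 0.4) == pytest.approx(0.4368, abs=5e-4)

    def test_small_risk_limit_approaches_rr(self):
        assert rr_to_hr(0.7, 1e-6) == pytest.approx(0.7, abs=1e-4)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            rr_to_hr(2.6, 0.4)  # rr >= 1/d
        with pytest.raises(ValueError):
            rr_to_hr(0.5, 0.0)

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(0.05, 2.3), st.floats(0.05, 2.3))
    def test_strictly_increasing(self, r1, r2):
        lo, hi = sorted([r1, r2])
        if hi - lo < 1e-9:  # below float resolution of the transform
            return
        assert rr_to_hr(lo, 0.4) < rr_to_hr(hi, 0.4)
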