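"""Recover data-generating coefficients from published population summaries.

The generating constants behind the benchmark were never published, but the
population they produced was summarized in detail: arm-wise confounder
means/SDs, correlations of the unmeasured confounder with outcomes and
treatment, a U-on-A odds ratio adjusted for L, true marginal treatment
effects on each outcome scale, and the unadjusted estimator's bias.  Those
summaries over-determine most coefficients, so calibration is a staged
sequence of one-dimensional solves on a single large evaluation population
built from common random numbers (fixed uniform / normal / exponential
draws), which makes every target statistic a deterministic, near-smooth
function of the coefficient being solved for:

1. assignment block — ``a0`` (L prevalence), ``bC`` (between-arm C gap),
   ``bL`` (L gap), ``b0`` (treated share), ``aU`` (U gap); scenario 3 adds
   ``bU`` against the joint (r(U,A), adjusted-OR) targets;
2. continuous outcome — ``gA`` equals the target marginal effect exactly
   (linear model), ``gC``/``gU``/``sigma`` solved against the unadjusted
   bias, the r(Ya,U) correlation, and the stated sampling-SD closure for
   the adjusted estimator at n=200;
3. binary outcome — intercept (control-arm risk), ``hA`` (marginal log OR),
   ``hC`` (unadjusted bias), ``hU`` (r(Yb,U)), all via expectations of the
   logistic risks, no Bernoulli noise;
4. survival outcome — ``tau_cens`` (control-arm event proportion), ``kU``
   (r(Yc,U)), then ``kA``/``kC`` by secant iteration against the marginal
   stacked-counterfactual log hazard ratio and the unadjusted bias, each
   evaluation being a Cox fit on a fixed subsample.

Scenario 3 reuses scenario 2's L and outcome models wholesale (the direct
U -> A arrow is the only structural change).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from scipy.optimize import brentq
from scipy.special import expit, logit

from .coefficients import (
    C_CENTER,
    BinaryModel,
    ContinuousModel,
    LModel,
    ScenarioCoefficients,
    SurvivalModel,
    TreatmentModel,
)

__all__ = ["CALIBRATION_TARGETS", "calibrate_scenario", "calibrate_all"]

# Published population summaries used as calibration targets.  Gaps are
# treated-minus-control differences in the 50/50 population; biases are
# population-level unadjusted estimate minus true marginal effect.
CALIBRATION_TARGETS: dict[int, dict] = {
    1: dict(
        treated_share=0.50,
        l_prevalence=0.2597,   # mean of arm percentages 17.96 / 33.98
        l_gap=0.1602,
        c_gap=7.42,            # 54.39 - 46.97
        u_gap=0.11,            # 0.56 - 0.45
        ate_continuous=3.99,
        raw_bias_continuous=-0.800,
        r_ya_u=-0.15,
        gc_sd_continuous=(0.351, 200),  # sampling-SD closure at n=200
        control_risk_binary=0.30,
        ate_binary=1.21,
        raw_bias_binary=-0.267,
        r_yb_u=-0.12,
        ate_survival=-0.83,
        raw_bias_survival=0.181,
        r_yc_u=-0.07,
        control_event_rate=0.87,
    ),
    2: dict(
        treated_share=0.50,
        l_prevalence=0.30505,  # 20.63 / 40.38
        l_gap=0.1975,
        c_gap=7.50,            # 54.24 - 46.74
        u_gap=0.22,            # 0.62 - 0.40
        ate_continuous=4.04,
        raw_bias_continuous=-1.086,
        r_ya_u=-0.44,
        gc_sd_continuous=(0.408, 200),
        control_risk_binary=0.30,
        ate_binary=1.17,
        raw_bias_binary=-0.326,
        r_yb_u=-0.23,
        ate_survival=-0.83,
        raw_bias_survival=0.201,
        r_yc_u=-0.12,
        control_event_rate=0.87,
    ),
    3: dict(
        treated_share=0.50,
        r_u_a=0.24,
        adjusted_or_u=1.34,
        # Scales used to balance the two (jointly infeasible) targets:
        # absolute tolerance for correlations, relative tolerance for the OR.
        tol_r_u_a=0.03,
        tol_adjusted_or=0.067,
    ),
}

_LAMBDA0 = 0.1  # fixed baseline hazard; the time unit is arbitrary


class _Draws:
    """Common random numbers for one evaluation population."""

    def __init__(self, n: int, seed: int):
        rng = np.random.default_rng(seed)
        self.n = n
        self.u = 0.5 + rng.standard_normal(n)
        self.c = C_CENTER + np.sqrt(50.0) * rng.standard_normal(n)
        self.v_l = rng.random(n)
        self.v_a = rng.random(n)
        self.e_t = rng.exponential(size=n)

    def l_of(self, a0: float, aU: float) -> np.ndarray:
        return (self.v_l < expit(a0 + aU * self.u)).astype(float)

    def a_of(self, l: np.ndarray, b0: float, bL: float, bC: float, bU: float) -> np.ndarray:
        lp = b0 + bL * l + bC * (self.c - C_CENTER) + bU * self.u
        return (self.v_a < expit(lp)).astype(float)


def _gap(x: np.ndarray, a: np.ndarray) -> float:
    return float(x[a == 1].mean() - x[a == 0].mean())


# ---------------------------------------------------------------------------
# assignment block
# ---------------------------------------------------------------------------

def _solve_assignment_block(d: _Draws, t: dict, n_rounds: int = 5):
    a0, aU = -1.2, 0.5
    b0, bL, bC = 0.0, 1.0, 0.15
    for _ in range(n_rounds):
        a0 = brentq(lambda x: d.l_of(x, aU).mean() - t["l_prevalence"], -8.0, 4.0, xtol=1e-8)

        def with_params(b0_=None, bL_=None, bC_=None, aU_=None):
            l = d.l_of(a0, aU if aU_ is None else aU_)
            a = d.a_of(
                l,
                b0 if b0_ is None else b0_,
                bL if bL_ is None else bL_,
                bC if bC_ is None else bC_,
                0.0,
            )
            return l, a

        bC = brentq(lambda x: _gap(d.c, with_params(bC_=x)[1]) - t["c_gap"], 0.01, 1.5, xtol=1e-9)
        bL = brentq(lambda x: _gap(*with_params(bL_=x)) - t["l_gap"], 0.0, 5.0, xtol=1e-9)
        b0 = brentq(lambda x: with_params(b0_=x)[1].mean() - t["treated_share"], -8.0, 8.0, xtol=1e-9)
        aU = brentq(lambda x: _gap(d.u, with_params(aU_=x)[1]) - t["u_gap"], 0.0, 4.0, xtol=1e-9)
    l = d.l_of(a0, aU)
    a = d.a_of(l, b0, bL, bC, 0.0)
    return LModel(a0=a0, aU=aU), TreatmentModel(b0=b0, bL=bL, bC=bC, bU=0.0), l, a


def _adjusted_or(u: np.ndarray, l: np.ndarray, a: np.ndarray) -> float:
    X = sm.add_constant(np.column_stack([u, l]))
    fit = sm.Logit(a, X).fit(disp=0)
    return float(np.exp(fit.params[1]))


def _solve_scenario3_assignment(d: _Draws, lm: LModel, base: TreatmentModel, t: dict,
                                n_rounds: int = 4):
    """Add the direct U -> A arrow, balancing r(U,A) against the adjusted OR.

    The two targets cannot both be met exactly under a logistic assignment
    model; ``bU`` is solved so that their residuals, scaled by the stated
    calibration tolerances, cancel.
    """
    l = d.l_of(lm.a0, lm.aU)
    b0, bU = base.b0, 0.3

    def stats(b0_, bU_):
        a = d.a_of(l, b0_, base.bL, base.bC, bU_)
        r = float(np.corrcoef(d.u, a)[0, 1])
        return a, r

    for _ in range(n_rounds):
        b0 = brentq(lambda x: stats(x, bU)[0].mean() - t["treated_share"], -8.0, 8.0, xtol=1e-9)

        def residual(bU_):
            a, r = stats(b0, bU_)
            orr = _adjusted_or(d.u, l, a)
            return (r - t["r_u_a"]) / t["tol_r_u_a"] + (orr - t["adjusted_or_u"]) / t["tol_adjusted_or"]

        bU = brentq(residual, 0.0, 2.0, xtol=1e-6)
    a = d.a_of(l, b0, base.bL, base.bC, bU)
    return TreatmentModel(b0=b0, bL=base.bL, bC=base.bC, bU=bU), l, a


# ---------------------------------------------------------------------------
# continuous outcome
# ---------------------------------------------------------------------------

def _residual_variance(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r.var())


def _solve_continuous(d: _Draws, l: np.ndarray, a: np.ndarray, t: dict) -> ContinuousModel:
    gA = t["ate_continuous"]
    gc_sd, n_sample = t["gc_sd_continuous"]
    du, dc = _gap(d.u, a), _gap(d.c, a)

    ones = np.ones(d.n)
    var_resid_a = _residual_variance(a, np.column_stack([ones, d.c, l]))
    var_resid_u = _residual_variance(d.u, np.column_stack([ones, a, d.c, l]))
    # sample covariance matrix of (A, C, U) in the evaluation population
    S = np.cov(np.vstack([a, d.c, d.u]))

    gU, gC, sigma = -0.5, -0.1, 2.0
    for _ in range(40):
        gC = (t["raw_bias_continuous"] - gU * du) / dc
        # per-observation residual variance implied by the adjusted
        # estimator's sampling SD at the stated replicate size
        sigma_e2 = gc_sd**2 * n_sample * var_resid_a
        sigma = float(np.sqrt(max(sigma_e2 - gU**2 * var_resid_u, 0.05)))

        def r_of(gU_):
            w = np.array([gA, gC, gU_])
            cov_y_u = w @ S[:, 2]
            var_y = w @ S @ w + sigma**2
            return cov_y_u / np.sqrt(var_y * S[2, 2]) - t["r_ya_u"]

        gU = brentq(r_of, -6.0, 0.0, xtol=1e-10)
    g0 = 20.0 - gC * float(d.c[a == 0].mean()) - gU * float(d.u[a == 0].mean())
    return ContinuousModel(g0=g0, gA=gA, gC=gC, gU=gU, sigma=sigma)


# ---------------------------------------------------------------------------
# binary outcome
# ---------------------------------------------------------------------------

def _solve_binary(d: _Draws, a: np.ndarray, t: dict, n_rounds: int = 10) -> BinaryModel:
    h0, hA, hC, hU = -1.0, 1.3, -0.03, -0.3
    var_u = float(d.u.var())

    def risks(h0_, hA_, hC_, hU_, arm):
        return expit(h0_ + hA_ * arm + hC_ * d.c + hU_ * d.u)

    def marginal(h0_, hA_, hC_, hU_):
        return float(
            logit(risks(h0_, hA_, hC_, hU_, 1.0).mean())
            - logit(risks(h0_, hA_, hC_, hU_, 0.0).mean())
        )

    def raw(h0_, hA_, hC_, hU_):
        p = risks(h0_, hA_, hC_, hU_, a)
        return float(logit(p[a == 1].mean()) - logit(p[a == 0].mean()))

    for _ in range(n_rounds):
        h0 = brentq(
            lambda x: risks(x, hA, hC, hU, a)[a == 0].mean() - t["control_risk_binary"],
            -12.0, 6.0, xtol=1e-10,
        )
        hA = brentq(lambda x: marginal(h0, x, hC, hU) - t["ate_binary"], 0.0, 6.0, xtol=1e-10)
        hC = brentq(
            lambda x: raw(h0, hA, x, hU) - marginal(h0, hA, x, hU) - t["raw_bias_binary"],
            -1.0, 1.0, xtol=1e-12,
        )

        def r_yb_u(hU_):
            p = risks(h0, hA, hC, hU_, a)
            pbar = p.mean()
            cov = float(np.cov(p, d.u)[0, 1])
            return cov / np.sqrt(pbar * (1 - pbar) * var_u) - t["r_yb_u"]

        hU = brentq(r_yb_u, -6.0, 0.0, xtol=1e-10)
    return BinaryModel(h0=h0, hA=hA, hC=hC, hU=hU)


# ---------------------------------------------------------------------------
# survival outcome
# ---------------------------------------------------------------------------

def _cox_loghr(time, event, arm) -> float:
    df = pd.DataFrame({"time": time, "event": event, "arm": arm})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    return float(cph.params_["arm"])


def _secant(f, x0, x1, ftol=2e-3, max_iter=8):
    f0, f1 = f(x0), f(x1)
    for _ in range(max_iter):
        if abs(f1) < ftol or f1 == f0:
            break
        x0, x1, f0 = x1, x1 - f1 * (x1 - x0) / (f1 - f0), f1
        f1 = f(x1)
    return x1


def _solve_survival(d: _Draws, a: np.ndarray, t: dict, n_cox: int = 30_000,
                    n_rounds: int = 3) -> SurvivalModel:
    kA, kC, kU, tau = -0.9, 0.02, 0.05, 15.0
    idx = np.arange(min(n_cox, d.n))
    u_s, c_s, a_s, e_s = d.u[idx], d.c[idx], a[idx], d.e_t[idx]

    def rate(kA_, kC_, kU_, arm, u_, c_):
        return _LAMBDA0 * np.exp(kA_ * arm + kC_ * (c_ - C_CENTER) + kU_ * u_)

    def truth(kA_, kC_, kU_, tau_):
        # marginal log HR from stacked counterfactual event data
        t1 = e_s / rate(kA_, kC_, kU_, 1.0, u_s, c_s)
        t0 = e_s / rate(kA_, kC_, kU_, 0.0, u_s, c_s)
        time = np.concatenate([np.minimum(t1, tau_), np.minimum(t0, tau_)])
        event = np.concatenate([t1 <= tau_, t0 <= tau_]).astype(float)
        arm = np.concatenate([np.ones_like(t1), np.zeros_like(t0)])
        return _cox_loghr(time, event, arm)

    def raw(kA_, kC_, kU_, tau_):
        te = e_s / rate(kA_, kC_, kU_, a_s, u_s, c_s)
        return _cox_loghr(np.minimum(te, tau_), (te <= tau_).astype(float), a_s)

    for _ in range(n_rounds):
        def control_events(tau_):
            lam = rate(kA, kC, kU, 0.0, d.u, d.c)[a == 0]
            return float((1.0 - np.exp(-lam * tau_)).mean()) - t["control_event_rate"]

        tau = brentq(control_events, 0.05, 500.0, xtol=1e-6)

        def r_yc_u(kU_):
            te = d.e_t / rate(kA, kC, kU_, a, d.u, d.c)
            yc = np.minimum(te, tau)
            return float(np.corrcoef(yc, d.u)[0, 1]) - t["r_yc_u"]

        kU = brentq(r_yc_u, 0.0, 2.0, xtol=1e-8)
        kA = _secant(lambda x: truth(x, kC, kU, tau) - t["ate_survival"], kA, kA - 0.08)
        kC = _secant(
            lambda x: raw(kA, x, kU, tau) - truth(kA, x, kU, tau) - t["raw_bias_survival"],
            kC, kC + 0.01,
        )
    return SurvivalModel(lambda0=_LAMBDA0, kA=kA, kC=kC, kU=kU, tau_cens=tau)


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------

def calibrate_scenario(
    scenario_id: int,
    targets: dict | None = None,
    n_eval: int = 200_000,
    seed: int = 20230117,
    base: ScenarioCoefficients | None = None,
    n_cox: int = 30_000,
) -> ScenarioCoefficients:
    """Calibrate one scenario's coefficient set against its targets.

    Deterministic given ``(n_eval, seed)``.  Scenario 3 requires the
    calibrated scenario-2 set via ``base`` (it shares the L and outcome
    models and only re-solves the treatment model); scenarios 1-2 are
    self-contained.
    """
    if targets is None:
        targets = CALIBRATION_TARGETS[scenario_id]
    d = _Draws(n_eval, seed)

    if scenario_id == 3:
        if base is None:
            base = calibrate_scenario(2, n_eval=n_eval, seed=seed, n_cox=n_cox)
        am, l, a = _solve_scenario3_assignment(d, base.l_model, base.a_model, targets)
        return ScenarioCoefficients(
            scenario_id=3,
            l_model=base.l_model,
            a_model=am,
            ya_model=base.ya_model,
            yb_model=base.yb_model,
            yc_model=base.yc_model,
        )

    lm, am, l, a = _solve_assignment_block(d, targets)
    ya = _solve_continuous(d, l, a, targets)
    yb = _solve_binary(d, a, targets)
    yc = _solve_survival(d, a, targets, n_cox=n_cox)
    return ScenarioCoefficients(
        scenario_id=scenario_id, l_model=lm, a_model=am, ya_model=ya, yb_model=yb, yc_model=yc
    )


def calibrate_all(n_eval: int = 200_000, seed: int = 20230117, n_cox: int = 30_000):
    """Calibrate all three scenarios; returns ``{scenario_id: coefficients}``."""
    out = {1: calibrate_scenario(1, n_eval=n_eval, seed=seed, n_cox=n_cox)}
    out[2] = calibrate_scenario(2, n_eval=n_eval, seed=seed, n_cox=n_cox)
    out[3] = calibrate_scenario(3, n_eval=n_eval, seed=seed, base=out[2], n_cox=n_cox)
    return out
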