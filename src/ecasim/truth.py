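"""Population-level true marginal treatment effects.

The gold standard every estimator is scored against.  The canonical truth
is the direct counterfactual computation from the generating models: every
individual's paired potential outcomes are evaluated under A=1 and A=0 with
shared noise draws, and the marginal contrast is taken on each outcome's
scale (mean difference, log odds ratio of averaged risks, and — for the
time-to-event outcome — the log hazard ratio of a univariate
proportional-hazards fit to the stacked counterfactual event data, the same
marginal-HR device the g-computation estimator uses, so truth and estimator
target one estimand).

A second, regression-based route (fit outcome models on the realized
population *including U*, then standardize) serves as an independent
cross-check of the same estimand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from scipy.special import expit, logit

from .coefficients import C_CENTER, ScenarioCoefficients
from .estimators import _gcomp_cox_univariate, simulate_counterfactual_loghr

__all__ = ["TrueEffects", "true_effects_counterfactual", "true_effects_regression"]


@dataclass(frozen=True)
class TrueEffects:
    """Marginal average treatment effects, one per outcome scale."""

    ate_continuous: float  # mean difference
    ate_binary: float      # log odds ratio
    ate_survival: float    # log hazard ratio
    evaluation_size: int
    method_tag: str        # "dgp_counterfactual" or "regression_marginal"

    def as_dict(self) -> dict:
        return {
            "ate_continuous": self.ate_continuous,
            "ate_binary": self.ate_binary,
            "ate_survival": self.ate_survival,
            "evaluation_size": self.evaluation_size,
            "method_tag": self.method_tag,
        }


def true_effects_counterfactual(
    coeffs: ScenarioCoefficients, size: int = 200_000, seed: int | None = 0
) -> TrueEffects:
    """Canonical truth: paired potential outcomes from the generating models."""
    coeffs.validate()
    rng = np.random.default_rng(seed)
    u = 0.5 + rng.standard_normal(size)
    c = C_CENTER + np.sqrt(50.0) * rng.standard_normal(size)

    ym = coeffs.ya_model
    eps = ym.sigma * rng.standard_normal(size)
    ya1 = ym.g0 + ym.gA + ym.gC * c + ym.gU * u + eps
    ya0 = ym.g0 + ym.gC * c + ym.gU * u + eps
    ate_cont = float(np.mean(ya1 - ya0))

    bm = coeffs.yb_model
    v = rng.random(size)
    yb1 = (v < expit(bm.h0 + bm.hA + bm.hC * c + bm.hU * u)).astype(float)
    yb0 = (v < expit(bm.h0 + bm.hC * c + bm.hU * u)).astype(float)
    ate_bin = float(logit(yb1.mean()) - logit(yb0.mean()))

    sv = coeffs.yc_model
    e = rng.exponential(size=size)
    base = sv.kC * (c - C_CENTER) + sv.kU * u
    t1 = e / (sv.lambda0 * np.exp(sv.kA + base))
    t0 = e / (sv.lambda0 * np.exp(base))
    time = np.concatenate([np.minimum(t1, sv.tau_cens), np.minimum(t0, sv.tau_cens)])
    event = np.concatenate([t1 <= sv.tau_cens, t0 <= sv.tau_cens]).astype(float)
    arm = np.concatenate([np.ones(size), np.zeros(size)])
    ate_surv = _gcomp_cox_univariate(time, event, arm)

    return TrueEffects(
        ate_continuous=ate_cont,
        ate_binary=ate_bin,
        ate_survival=ate_surv,
        evaluation_size=size,
        method_tag="dgp_counterfactual",
    )


def true_effects_regression(pop: pd.DataFrame, seed: int | None = 0) -> TrueEffects:
    """Cross-check truth: marginal standardization of fits that include U."""
    if "U" not in pop.columns:
        raise ValueError("regression truth needs the full population including U")
    n = len(pop)
    a = pop["A"].to_numpy(dtype=float)
    ones = np.ones(n)
    covs = pop[["C", "L", "U"]].to_numpy(dtype=float)
    X = np.column_stack([ones, a, covs])
    X1 = np.column_stack([ones, ones, covs])
    X0 = np.column_stack([ones, np.zeros(n), covs])

    beta, *_ = np.linalg.lstsq(X, pop["Ya"].to_numpy(dtype=float), rcond=None)
    ate_cont = float((X1 @ beta).mean() - (X0 @ beta).mean())

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        logit_res = sm.Logit(pop["Yb"].to_numpy(dtype=float), X).fit(disp=0)
    if not np.isfinite(logit_res.params).all():
        raise RuntimeError("binary outcome fit did not converge on the population")
    m1 = expit(X1 @ logit_res.params).mean()
    m0 = expit(X0 @ logit_res.params).mean()
    ate_bin = float(logit(m1) - logit(m0))

    df = pop[["Yc", "D", "A", "C", "L", "U"]].astype(float)
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="Yc", event_col="D")
    Xs1 = df[["A", "C", "L", "U"]].copy()
    Xs1["A"] = 1.0
    Xs0 = df[["A", "C", "L", "U"]].copy()
    Xs0["A"] = 0.0
    e = np.random.default_rng(seed).exponential(size=n)
    ate_surv = simulate_counterfactual_loghr(cph, Xs1, Xs0, e, float(df["Yc"].max()))

    return TrueEffects(
        ate_continuous=ate_cont,
        ate_binary=ate_bin,
        ate_survival=ate_surv,
        evaluation_size=n,
        method_tag="regression_marginal",
    )
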