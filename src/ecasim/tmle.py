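"""Targeted maximum likelihood estimation of the average treatment effect.

TMLE combines an initial outcome regression with a propensity-score-driven
"targeting" update.  The initial fit E(Y | A, C, L) supplies counterfactual
predictions for both arms; the targeting step regresses the observed
outcome on the clever covariate

    H(A, C, L) = 1{A=1} / p(C, L)  -  1{A=0} / (1 - p(C, L)),

with logit of the initial prediction as a fixed offset, estimating the
one-dimensional fluctuation parameter epsilon by maximum likelihood.  The
updated predictions solve the efficient-influence-curve equation, and the
ATE is the mean updated counterfactual contrast.  Confidence intervals come
from the empirical variance of the influence curve, delta-method-propagated
to the reported scale.

Working models are parametric main-effects fits throughout (logistic for
the propensity and — after linear scaling to [0, 1] — for the outcome).

For the time-to-event outcome, the event status is binarized at the median
follow-up of all individuals, a binary TMLE supplies counterfactual risks,
and the resulting relative risk is converted to a hazard ratio via
``HR = log(1 - d*RR) / log(1 - d)`` with reference-group event proportion
``d`` (0.4 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit

from .estimators import (
    SCALES,
    EffectEstimate,
    PropensityFit,
    _check_arms,
    _failed,
    _Z,
    fit_propensity,
)

__all__ = [
    "TmleState",
    "clever_covariate",
    "fluctuate",
    "tmle_initial_state",
    "tmle_risks",
    "estimate_tmle",
    "rr_to_hr",
    "DEFAULT_REFERENCE_EVENT_RATE",
]

#: Reference-group event proportion used in the RR -> HR conversion.
DEFAULT_REFERENCE_EVENT_RATE = 0.4

_PBOUND = 1e-8


@dataclass
class TmleState:
    """State of one TMLE computation on the [0, 1] working scale.

    ``pred_obs``/``pred1``/``pred0`` are the (initial or updated) outcome
    predictions at the observed arm and under each counterfactual arm;
    ``epsilon`` is 0.0 until :func:`fluctuate` runs.  ``lo``/``hi`` record
    the linear scaling bounds used for continuous outcomes (0/1 for binary).
    """

    pred_obs: np.ndarray
    pred1: np.ndarray
    pred0: np.ndarray
    h_obs: np.ndarray
    h1: np.ndarray
    h0: np.ndarray
    epsilon: float = 0.0
    lo: float = 0.0
    hi: float = 1.0
    converged: bool = True


def clever_covariate(arms: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """H_i = 1/p_i for treated individuals, -1/(1-p_i) for controls."""
    a = np.asarray(arms, dtype=float)
    p = np.asarray(scores, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("propensity scores must lie strictly inside (0, 1)")
    return np.where(a == 1, 1.0 / p, -1.0 / (1.0 - p))


def rr_to_hr(rr: float, d: float = DEFAULT_REFERENCE_EVENT_RATE) -> float:
    """Convert a relative risk to a hazard ratio: log(1 - d*rr) / log(1 - d).

    ``d`` is the reference-group event proportion; requires ``rr < 1/d``.
    The transform is strictly increasing in ``rr`` and maps rr=1 to 1.
    """
    if not 0.0 < d < 1.0:
        raise ValueError(f"d must lie in (0, 1), got {d}")
    if rr <= 0.0:
        raise ValueError(f"rr must be positive, got {rr}")
    if rr >= 1.0 / d:
        raise ValueError(f"rr={rr} >= 1/d={1.0 / d}: conversion undefined")
    return float(np.log1p(-d * rr) / np.log1p(-d))


def _scaled_logistic_fit(y01: np.ndarray, X: np.ndarray):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y01, X, family=sm.families.Binomial()).fit()
    return np.asarray(res.params, dtype=float)


def tmle_initial_state(
    sample: pd.DataFrame, outcome_values: np.ndarray, ps: PropensityFit,
    continuous: bool,
) -> TmleState:
    """Initial outcome fit and clever covariates, on the [0, 1] working scale.

    Continuous outcomes are linearly scaled to [0, 1] using the sample
    min/max widened by a 10% range cushion so that logits stay finite.
    """
    a = sample["A"].to_numpy(dtype=float)
    n = len(sample)
    y = np.asarray(outcome_values, dtype=float)
    if continuous:
        span = y.max() - y.min()
        if span == 0:
            span = 1.0
        lo, hi = y.min() - 0.1 * span, y.max() + 0.1 * span
    else:
        lo, hi = 0.0, 1.0
    ys = (y - lo) / (hi - lo)

    ones = np.ones(n)
    X = np.column_stack([ones, a, sample["C"].to_numpy(float), sample["L"].to_numpy(float)])
    X1 = X.copy()
    X1[:, 1] = 1.0
    X0 = X.copy()
    X0[:, 1] = 0.0
    beta = _scaled_logistic_fit(ys, X)
    clip = lambda p: np.clip(p, _PBOUND, 1 - _PBOUND)
    state = TmleState(
        pred_obs=clip(expit(X @ beta)),
        pred1=clip(expit(X1 @ beta)),
        pred0=clip(expit(X0 @ beta)),
        h_obs=clever_covariate(a, ps.scores),
        h1=1.0 / ps.scores,
        h0=-1.0 / (1.0 - ps.scores),
        lo=lo,
        hi=hi,
        converged=bool(np.isfinite(beta).all()),
    )
    return state


def fluctuate(state: TmleState, observed: np.ndarray, epsilon: float | None = None) -> TmleState:
    """Targeting step: update predictions along the clever covariate.

    ``epsilon`` is estimated by maximum likelihood in a one-parameter
    logistic working model with logit of the initial prediction as offset
    and H as sole covariate, unless supplied explicitly (``epsilon=0``
    leaves the predictions unchanged — the g-computation plug-in).
    """
    ys = (np.asarray(observed, dtype=float) - state.lo) / (state.hi - state.lo)
    converged = state.converged
    if epsilon is None:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(
                    ys,
                    state.h_obs[:, None],
                    family=sm.families.Binomial(),
                    offset=logit(state.pred_obs),
                ).fit()
            epsilon = float(res.params[0])
            converged = converged and bool(np.isfinite(epsilon))
        except Exception:
            epsilon, converged = 0.0, False
    clip = lambda p: np.clip(p, _PBOUND, 1 - _PBOUND)
    return TmleState(
        pred_obs=clip(expit(logit(state.pred_obs) + epsilon * state.h_obs)),
        pred1=clip(expit(logit(state.pred1) + epsilon * state.h1)),
        pred0=clip(expit(logit(state.pred0) + epsilon * state.h0)),
        h_obs=state.h_obs,
        h1=state.h1,
        h0=state.h0,
        epsilon=float(epsilon),
        lo=state.lo,
        hi=state.hi,
        converged=converged,
    )


def tmle_risks(state: TmleState) -> tuple[float, float]:
    """Mean updated counterfactual predictions (mu1, mu0) on the working scale."""
    return float(state.pred1.mean()), float(state.pred0.mean())


def _influence_curves(state: TmleState, observed: np.ndarray, a: np.ndarray):
    """Per-individual influence curves for (mu1, mu0) on the working scale."""
    ys = (np.asarray(observed, dtype=float) - state.lo) / (state.hi - state.lo)
    mu1, mu0 = tmle_risks(state)
    ic1 = a * state.h1 * (ys - state.pred1) + state.pred1 - mu1
    ic0 = -(1 - a) * state.h0 * (ys - state.pred0) + state.pred0 - mu0
    # note: h0 is negative, so -(1-a)*h0 = (1-a)/(1-p) >= 0
    return ic1, ic0


def _run_binary_tmle(sample: pd.DataFrame, y: np.ndarray, ps: PropensityFit, continuous: bool):
    state = tmle_initial_state(sample, y, ps, continuous=continuous)
    state = fluctuate(state, y)
    return state


def estimate_tmle(
    sample: pd.DataFrame,
    outcome: str,
    ps: PropensityFit | None = None,
    d: float = DEFAULT_REFERENCE_EVENT_RATE,
) -> EffectEstimate:
    """TMLE effect estimate on the outcome's reporting scale.

    continuous -> mean difference (back-scaled from the [0, 1] working
    scale); binary -> log OR of the averaged counterfactual risks;
    survival -> counterfactual risks of an event by the median follow-up of
    all individuals, converted from RR to a log HR with reference event
    proportion ``d``.  CIs use the influence-curve variance, delta-method
    propagated to the reported scale.
    """
    if outcome not in SCALES:
        raise ValueError(f"unknown outcome {outcome!r}")
    a = sample["A"].to_numpy(dtype=float)
    _check_arms(a)
    if ps is None:
        ps = fit_propensity(sample)
    if not ps.converged:
        return _failed("TMLE", outcome, ci_method="influence_curve")
    n = len(sample)

    try:
        if outcome == "continuous":
            y = sample["Ya"].to_numpy(dtype=float)
            state = _run_binary_tmle(sample, y, ps, continuous=True)
            if not state.converged:
                return _failed("TMLE", outcome, ci_method="influence_curve")
            mu1, mu0 = tmle_risks(state)
            span = state.hi - state.lo
            point = (mu1 - mu0) * span
            ic1, ic0 = _influence_curves(state, y, a)
            se = float(np.std(ic1 - ic0) / np.sqrt(n)) * span
        elif outcome == "binary":
            y = sample["Yb"].to_numpy(dtype=float)
            state = _run_binary_tmle(sample, y, ps, continuous=False)
            if not state.converged:
                return _failed("TMLE", outcome, ci_method="influence_curve")
            mu1, mu0 = tmle_risks(state)
            if min(mu1, mu0) <= 0 or max(mu1, mu0) >= 1:
                return _failed("TMLE", outcome, ci_method="influence_curve")
            point = float(logit(mu1) - logit(mu0))
            ic1, ic0 = _influence_curves(state, y, a)
            g1, g0 = 1.0 / (mu1 * (1 - mu1)), 1.0 / (mu0 * (1 - mu0))
            se = float(np.std(g1 * ic1 - g0 * ic0) / np.sqrt(n))
        else:  # survival: risk at the median follow-up, then RR -> HR
            t_med = float(np.median(sample["Yc"].to_numpy(dtype=float)))
            y = (
                (sample["Yc"].to_numpy(dtype=float) <= t_med)
                & (sample["D"].to_numpy() == 1)
            ).astype(float)
            state = _run_binary_tmle(sample, y, ps, continuous=False)
            if not state.converged:
                return _failed("TMLE", outcome, ci_method="influence_curve")
            mu1, mu0 = tmle_risks(state)
            if mu0 <= 0 or mu1 <= 0:
                return _failed("TMLE", outcome, ci_method="influence_curve")
            rr = mu1 / mu0
            try:
                hr = rr_to_hr(rr, d)
            except ValueError:
                return _failed("TMLE", outcome, ci_method="influence_curve")
            point = float(np.log(hr))
            ic1, ic0 = _influence_curves(state, y, a)
            # delta method: d(log HR)/d(mu) through RR and the conversion
            dlhr_drr = -d / ((1.0 - d * rr) * np.log1p(-d * rr))
            g1 = dlhr_drr * (1.0 / mu0)
            g0 = dlhr_drr * (-rr / mu0)
            se = float(np.std(g1 * ic1 + g0 * ic0) / np.sqrt(n))
    except (np.linalg.LinAlgError, ValueError):
        return _failed("TMLE", outcome, ci_method="influence_curve")

    if not np.isfinite([point, se]).all():
        return _failed("TMLE", outcome, ci_method="influence_curve")
    return EffectEstimate(
        "TMLE", outcome, SCALES[outcome],
        float(point), float(point - _Z * se), float(point + _Z * se),
        ci_method="influence_curve",
    )
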