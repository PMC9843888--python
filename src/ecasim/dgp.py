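"""Population generation, replicate sampling and confounder diagnostics.

The simulated target population mirrors a single-arm trial compared against
an external control arm: a treated arm and a control arm drawn from one
population whose treatment assignment depends on two measured covariates
(continuous C, binary L) and — in scenario 3 — directly on an unmeasured
confounder U.  Outcomes of three types (continuous, binary, time-to-event)
all depend on (A, C, U), so U confounds every comparison unless its path to
treatment is blocked by L.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .coefficients import C_CENTER, ScenarioCoefficients

__all__ = [
    "generate_population",
    "draw_samples",
    "standardized_mean_difference",
    "confounder_summary",
    "ConfounderSummary",
]

#: Columns visible to the estimators (U is unmeasured and therefore hidden).
OBSERVED_COLUMNS = ["C", "L", "A", "Ya", "Yb", "Yc", "D"]


def generate_population(
    coeffs: ScenarioCoefficients, size: int = 20_000, seed: int | None = None
) -> pd.DataFrame:
    """Generate a target population from a scenario's coefficient set.

    Parameters
    ----------
    coeffs
        Generating coefficients for one scenario; validated on construction.
    size
        Number of individuals (>= 2); the study default is 20,000.
    seed
        Seed for the random generator; identical inputs give bit-identical
        populations.

    Returns
    -------
    pandas.DataFrame
        Columns ``U, C, L, A, Ya, Yb, Yc, D``; ``df.attrs`` carries
        ``scenario_id`` and ``seed``.

    Raises
    ------
    ValueError
        If ``size < 2`` or the realized population is degenerate (an empty
        treatment or control arm).
    """
    if size < 2:
        raise ValueError(f"size must be >= 2, got {size}")
    coeffs.validate()
    rng = np.random.default_rng(seed)

    u = 0.5 + rng.standard_normal(size)
    c = C_CENTER + np.sqrt(50.0) * rng.standard_normal(size)

    lm, am = coeffs.l_model, coeffs.a_model
    l = (rng.random(size) < expit(lm.a0 + lm.aU * u)).astype(np.int8)
    p_a = expit(am.b0 + am.bL * l + am.bC * (c - C_CENTER) + am.bU * u)
    a = (rng.random(size) < p_a).astype(np.int8)
    n_treated = int(a.sum())
    if n_treated == 0 or n_treated == size:
        raise ValueError(
            f"degenerate population: all individuals in one arm "
            f"(treated={n_treated}/{size}); check the treatment model"
        )

    ym = coeffs.ya_model
    ya = ym.g0 + ym.gA * a + ym.gC * c + ym.gU * u + ym.sigma * rng.standard_normal(size)

    bm = coeffs.yb_model
    yb = (rng.random(size) < expit(bm.h0 + bm.hA * a + bm.hC * c + bm.hU * u)).astype(np.int8)

    sv = coeffs.yc_model
    rate = sv.lambda0 * np.exp(sv.kA * a + sv.kC * (c - C_CENTER) + sv.kU * u)
    t_event = rng.exponential(size=size) / rate
    d = (t_event <= sv.tau_cens).astype(np.int8)
    yc = np.minimum(t_event, sv.tau_cens)

    pop = pd.DataFrame(
        {"U": u, "C": c, "L": l, "A": a, "Ya": ya, "Yb": yb, "Yc": yc, "D": d}
    )
    pop.attrs["scenario_id"] = coeffs.scenario_id
    pop.attrs["seed"] = seed
    return pop


def draw_samples(
    pop: pd.DataFrame,
    n_reps: int,
    n_per: int,
    seed: int | None = None,
    hide_u: bool = True,
):
    """Draw independent replicate samples from a target population.

    Each replicate is a uniform draw of ``n_per`` rows without replacement
    (replicates are independent of each other).  The unmeasured confounder
    ``U`` is dropped from the returned frames by default, so downstream
    estimators can only see what a real analysis would see.

    Yields ``(replicate_index, sample)`` pairs.  Replicate ``i`` is seeded
    by ``(seed, i)``, so any single replicate can be regenerated without
    drawing its predecessors.
    """
    if n_per > len(pop):
        raise ValueError(f"n_per={n_per} exceeds population size {len(pop)}")
    if n_per < 20:
        warnings.warn(
            f"n_per={n_per} is very small; outcome-model fits may not converge",
            UserWarning,
            stacklevel=2,
        )
    columns = OBSERVED_COLUMNS if hide_u else list(pop.columns)
    for i in range(n_reps):
        rng = np.random.default_rng([0 if seed is None else seed, i])
        idx = rng.choice(len(pop), size=n_per, replace=False)
        sample = pop.iloc[idx][columns].reset_index(drop=True)
        sample.attrs["replicate_index"] = i
        yield i, sample


def standardized_mean_difference(x_treated, x_control, binary: bool | None = None) -> float:
    """Standardized mean difference between two groups.

    Defined here as ``|mean_t - mean_c| / sqrt(var_t + var_c)`` with
    population (ddof=0) variances; for binary 0/1 variables the variance is
    ``p(1-p)``.  This root-sum denominator is the convention of the summary
    table this package is calibrated against (a factor sqrt(2) smaller than
    Cohen's d).

    ``binary`` is auto-detected when ``None`` (all values in {0, 1}).
    """
    xt = np.asarray(x_treated, dtype=float)
    xc = np.asarray(x_control, dtype=float)
    if xt.size == 0 or xc.size == 0:
        raise ValueError("both groups must be non-empty")
    if binary is None:
        binary = bool(np.isin(np.concatenate([xt, xc]), [0.0, 1.0]).all())
    if binary:
        pt, pc = xt.mean(), xc.mean()
        var_t, var_c = pt * (1 - pt), pc * (1 - pc)
    else:
        var_t, var_c = xt.var(), xc.var()
    denom = np.sqrt(var_t + var_c)
    if denom == 0.0:
        raise ValueError("zero pooled SD: SMD undefined")
    return float(abs(xt.mean() - xc.mean()) / denom)


@dataclass
class ConfounderSummary:
    """Arm-wise confounder summaries for one population.

    ``arm_stats`` has one row per variable (U, C, L) with control/treated
    means and SDs (proportions for L) and the standardized mean difference.
    ``correlations`` holds the Pearson correlations of U with each outcome
    and of (U, C, L) with treatment.  ``adjusted_or_u`` is exp(coef of U)
    from a logistic fit of A on (U, L) — the degree to which L fails to
    block the U -> A path; ``None`` if that fit did not converge.
    """

    arm_stats: pd.DataFrame
    correlations: dict = field(default_factory=dict)
    adjusted_or_u: float | None = None

    def to_frame(self) -> pd.DataFrame:
        out = self.arm_stats.copy()
        out.attrs["correlations"] = dict(self.correlations)
        out.attrs["adjusted_or_u"] = self.adjusted_or_u
        return out


def confounder_summary(pop: pd.DataFrame) -> ConfounderSummary:
    """Summarize confounder balance and associations in a population."""
    treated = pop[pop["A"] == 1]
    control = pop[pop["A"] == 0]
    if len(treated) == 0 or len(control) == 0:
        raise ValueError("both arms must be non-empty")

    rows = []
    for var in ("U", "C", "L"):
        binary = var == "L"
        rows.append(
            {
                "variable": var,
                "mean_control": control[var].mean(),
                "sd_control": control[var].values.std(),
                "mean_treated": treated[var].mean(),
                "sd_treated": treated[var].values.std(),
                "smd": standardized_mean_difference(
                    treated[var].values, control[var].values, binary=binary
                ),
            }
        )
    arm_stats = pd.DataFrame(rows).set_index("variable")

    corr = {
        "r_ya_u": float(np.corrcoef(pop["Ya"], pop["U"])[0, 1]),
        "r_yb_u": float(np.corrcoef(pop["Yb"], pop["U"])[0, 1]),
        "r_yc_u": float(np.corrcoef(pop["Yc"], pop["U"])[0, 1]),
        "r_u_a": float(np.corrcoef(pop["U"], pop["A"])[0, 1]),
        "r_c_a": float(np.corrcoef(pop["C"], pop["A"])[0, 1]),
        "r_l_a": float(np.corrcoef(pop["L"], pop["A"])[0, 1]),
    }

    adjusted_or = None
    try:
        X = sm.add_constant(pop[["U", "L"]].astype(float))
        fit = sm.Logit(pop["A"].astype(float), X).fit(disp=0)
        if np.isfinite(fit.params["U"]):
            adjusted_or = float(np.exp(fit.params["U"]))
    except Exception:  # singular/separated fit: value absent, summary still valid
        adjusted_or = None

    return ConfounderSummary(arm_stats=arm_stats, correlations=corr, adjusted_or_u=adjusted_or)
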