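"""Monte-Carlo performance measures for replicate-level effect estimates.

Four measures per (scenario x outcome x method) cell, computed against the
population-level true effect on the analysis scale (raw scale for the
continuous outcome, log scale for odds and hazard ratios):

* bias — mean(estimate - truth),
* RMSE — sqrt(mean((estimate - truth)^2)),
* coverage — fraction of 95% CIs containing the truth (closed interval),
* width — mean CI width.

Only converged replicates enter the aggregates; ``n_used`` reports how many.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["bias", "rmse", "coverage", "mean_width", "summarize"]


def _points(points) -> np.ndarray:
    x = np.asarray(points, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one converged point")
    return x


def bias(points, truth: float) -> float:
    """Mean of (estimate - truth); negative means underestimation."""
    return float(np.mean(_points(points) - truth))


def rmse(points, truth: float) -> float:
    """Root mean squared error around the truth."""
    return float(np.sqrt(np.mean((_points(points) - truth) ** 2)))


def coverage(ci_low, ci_high, truth: float) -> float:
    """Fraction of closed intervals [low, high] containing the truth."""
    lo, hi = _points(ci_low), _points(ci_high)
    if lo.shape != hi.shape:
        raise ValueError("ci_low and ci_high must have equal length")
    return float(np.mean((lo <= truth) & (truth <= hi)))


def mean_width(ci_low, ci_high) -> float:
    """Mean difference between upper and lower CI bounds."""
    return float(np.mean(_points(ci_high) - _points(ci_low)))


def summarize(records: pd.DataFrame, truths: dict) -> pd.DataFrame:
    """Aggregate replicate records into one performance row per cell.

    Parameters
    ----------
    records
        One row per (replicate x method x outcome) with columns
        ``scenario, outcome, method, replicate_index, point, ci_low,
        ci_high, converged``.
    truths
        Mapping ``(scenario, outcome) -> true effect`` on the analysis
        scale.

    Returns
    -------
    pandas.DataFrame
        Columns ``scenario, outcome, method, n_used, bias, rmse, coverage,
        width, mc_se_bias``; empty cells are dropped with a warning.
        Invariant to record ordering.
    """
    rows = []
    for (scenario, outcome, method), grp in records.groupby(
        ["scenario", "outcome", "method"], sort=True
    ):
        ok = grp[grp["converged"].astype(bool) & np.isfinite(grp["point"])]
        if len(ok) == 0:
            warnings.warn(
                f"no converged replicates for {(scenario, outcome, method)}; row omitted",
                UserWarning,
                stacklevel=2,
            )
            continue
        truth = truths[(scenario, outcome)]
        pts = ok["point"].to_numpy(dtype=float)
        has_ci = np.isfinite(ok["ci_low"].to_numpy(float)) & np.isfinite(
            ok["ci_high"].to_numpy(float)
        )
        ci = ok[has_ci]
        rows.append(
            {
                "scenario": scenario,
                "outcome": outcome,
                "method": method,
                "n_used": len(ok),
                "bias": bias(pts, truth),
                "rmse": rmse(pts, truth),
                "coverage": coverage(ci["ci_low"], ci["ci_high"], truth)
                if len(ci)
                else np.nan,
                "width": mean_width(ci["ci_low"], ci["ci_high"]) if len(ci) else np.nan,
                "mc_se_bias": float(pts.std(ddof=1) / np.sqrt(len(pts)))
                if len(pts) > 1
                else np.nan,
            }
        )
    return pd.DataFrame(rows)
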