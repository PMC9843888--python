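"""Coefficient sets for the scenario-specific data-generating processes.

A scenario is fully described by five small parametric models:

* an ``L`` model — a logistic model for the binary measured covariate L
  given the unmeasured confounder U,
* an ``A`` model — a logistic treatment-assignment model in (L, C) for the
  blocked-path scenarios 1-2, plus a direct U term in scenario 3,
* three outcome models (linear, logistic, exponential proportional hazards)
  in (A, C, U).

C enters the treatment and hazard models centered at its marginal mean of 50
so intercepts stay interpretable; the continuous and binary outcome models
use C on its raw scale, with the intercept absorbing the difference.

The package ships one frozen, calibrated coefficient set per scenario
(``ecasim/data/scenario{1,2,3}.yaml``) recovered by :mod:`ecasim.calibrate`
from published population summaries.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from importlib import resources

import yaml

__all__ = [
    "LModel",
    "TreatmentModel",
    "ContinuousModel",
    "BinaryModel",
    "SurvivalModel",
    "ScenarioCoefficients",
    "load_frozen",
]

#: Centering constant for C in the treatment and hazard linear predictors.
C_CENTER = 50.0


@dataclass(frozen=True)
class LModel:
    """Logistic model P(L=1 | U) = expit(a0 + aU * U)."""

    a0: float
    aU: float


@dataclass(frozen=True)
class TreatmentModel:
    """Logistic model P(A=1 | L, C, U) = expit(b0 + bL*L + bC*(C-50) + bU*U).

    ``bU`` is exactly zero in scenarios 1-2 (no direct U -> A arrow) and
    strictly positive in scenario 3.
    """

    b0: float
    bL: float
    bC: float
    bU: float = 0.0


@dataclass(frozen=True)
class ContinuousModel:
    """Linear model Ya = g0 + gA*A + gC*C + gU*U + Normal(0, sigma)."""

    g0: float
    gA: float
    gC: float
    gU: float
    sigma: float


@dataclass(frozen=True)
class BinaryModel:
    """Logistic model P(Yb=1 | A, C, U) = expit(h0 + hA*A + hC*C + hU*U)."""

    h0: float
    hA: float
    hC: float
    hU: float


@dataclass(frozen=True)
class SurvivalModel:
    """Exponential proportional-hazards model with administrative censoring.

    The event time T has hazard ``lambda0 * exp(kA*A + kC*(C-50) + kU*U)``;
    follow-up is Yc = min(T, tau_cens), with event flag D = 1{T <= tau_cens}.
    """

    lambda0: float
    kA: float
    kC: float
    kU: float
    tau_cens: float


@dataclass(frozen=True)
class ScenarioCoefficients:
    """All generating coefficients for one confounding scenario."""

    scenario_id: int
    l_model: LModel
    a_model: TreatmentModel
    ya_model: ContinuousModel
    yb_model: BinaryModel
    yc_model: SurvivalModel
    version: str = "1"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Check structural invariants; raise ``ValueError`` on violation."""
        if self.scenario_id not in (1, 2, 3):
            raise ValueError(f"scenario_id must be 1, 2 or 3, got {self.scenario_id}")
        values = [
            v
            for model in (self.l_model, self.a_model, self.ya_model, self.yb_model, self.yc_model)
            for v in dataclasses.astuple(model)
        ]
        if not all(math.isfinite(v) for v in values):
            raise ValueError("all coefficients must be finite")
        if self.scenario_id in (1, 2) and self.a_model.bU != 0.0:
            raise ValueError("bU must be exactly 0 in scenarios 1 and 2")
        if self.scenario_id == 3 and not self.a_model.bU > 0.0:
            raise ValueError("bU must be positive in scenario 3")
        if not self.ya_model.sigma > 0.0:
            raise ValueError("sigma must be positive")
        if not self.yc_model.lambda0 > 0.0:
            raise ValueError("lambda0 must be positive")
        if not self.yc_model.tau_cens > 0.0:
            raise ValueError("tau_cens must be positive")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "scenario_id": self.scenario_id,
            "version": self.version,
            "l_model": dataclasses.asdict(self.l_model),
            "a_model": dataclasses.asdict(self.a_model),
            "ya_model": dataclasses.asdict(self.ya_model),
            "yb_model": dataclasses.asdict(self.yb_model),
            "yc_model": dataclasses.asdict(self.yc_model),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioCoefficients":
        return cls(
            scenario_id=int(d["scenario_id"]),
            l_model=LModel(**d["l_model"]),
            a_model=TreatmentModel(**d["a_model"]),
            ya_model=ContinuousModel(**d["ya_model"]),
            yb_model=BinaryModel(**d["yb_model"]),
            yc_model=SurvivalModel(**d["yc_model"]),
            version=str(d.get("version", "1")),
        )

    def save_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load_yaml(cls, path) -> "ScenarioCoefficients":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def load_frozen(scenario_id: int) -> ScenarioCoefficients:
    """Load the calibrated coefficient set shipped with the package."""
    if scenario_id not in (1, 2, 3):
        raise ValueError(f"scenario_id must be 1, 2 or 3, got {scenario_id}")
    ref = resources.files("ecasim.data").joinpath(f"scenario{scenario_id}.yaml")
    with ref.open() as fh:
        return ScenarioCoefficients.from_dict(yaml.safe_load(fh))
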