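"""Shared fixtures: frozen coefficient sets and reusable populations."""

import numpy as np
import pytest

from ecasim import generate_population, load_frozen
from ecasim.coefficients import (
    BinaryModel,
    ContinuousModel,
    LModel,
    ScenarioCoefficients,
    SurvivalModel,
    TreatmentModel,
)


@pytest.fixture(scope="session")
def coeffs1():
    return load_frozen(1)


@pytest.fixture(scope="session")
def coeffs2():
    return load_frozen(2)


@pytest.fixture(scope="session")
def coeffs3():
    return load_frozen(3)


@pytest.fixture(scope="session")
def pop1(coeffs1):
    """Scenario-1 study population at the default size."""
    return generate_population(coeffs1, 20_000, seed=42)


@pytest.fixture(scope="session")
def no_confounding_coeffs(coeffs1):
    """Scenario-1 set with every U path and both measured-confounder outcome
    paths severed: treatment is assigned at random and nothing confounds."""
    c = coeffs1
    return ScenarioCoefficients(
        scenario_id=1,
        l_model=LModel(a0=c.l_model.a0, aU=0.0),
        a_model=TreatmentModel(b0=0.0, bL=0.0, bC=0.0, bU=0.0),
        ya_model=ContinuousModel(
            g0=c.ya_model.g0, gA=c.ya_model.gA, gC=0.0, gU=0.0, sigma=c.ya_model.sigma
        ),
        yb_model=BinaryModel(h0=0.0, hA=c.yb_model.hA, hC=0.0, hU=0.0),
        yc_model=SurvivalModel(
            lambda0=c.yc_model.lambda0, kA=c.yc_model.kA, kC=0.0, kU=0.0,
            tau_cens=c.yc_model.tau_cens,
        ),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
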