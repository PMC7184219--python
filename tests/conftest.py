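import numpy as np
import pytest

from cofactorkit import gem, toynet
from cofactorkit.pk import PKParameters


@pytest.fixture
def serine_like_params() -> PKParameters:
    """Fast-elimination compound: absorption-limited plasma curve."""
    return PKParameters(k1=0.60916, k2=18.16688, c0=100.0, scale=1709.8)


@pytest.fixture
def carnitine_like_params() -> PKParameters:
    """Slow-elimination compound: pronounced accumulation under dosing."""
    return PKParameters(k1=0.20350, k2=1.67995, c0=40.0, scale=97.15)


@pytest.fixture(scope="session")
def toy_model_pristine():
    """Session-scoped toy liver model; never mutate, copy instead."""
    return toynet.build_toy_liver_network()


@pytest.fixture
def toy_model(toy_model_pristine):
    return toy_model_pristine.copy()


@pytest.fixture(scope="session")
def toy_reference(toy_model_pristine):
    """Reference flux state of the FAO-objective toy model (1000 samples)."""
    model = toy_model_pristine.copy()
    weights = gem.build_fao_objective(model)
    gem.set_objective(model, weights)
    reference = gem.compute_reference(model, n=1000, seed=11)
    return model, reference


def closed_form_increment(params: PKParameters, dose_g: float, t: np.ndarray):
    """Analytic plasma increment of the k1,k1,k2 cascade (test oracle).

    Solves the convolution integral symbolically: for a != 0 (a = k1-k2)
    dC(t) = s*k1^2*F*exp(-k2 t) * (1 - exp(-a t)(1 + a t)) / a^2, with the
    repeated-eigenvalue limit s*k1^2*F*t^2*exp(-k1 t)/2 as a -> 0.
    """
    F = params.bioavailability * dose_g
    k1, k2, s = params.k1, params.k2, params.scale
    a = k1 - k2
    if abs(a) < 1e-10:
        return s * k1**2 * F * t**2 * np.exp(-k1 * t) / 2.0
    return s * k1**2 * F * np.exp(-k2 * t) * (1 - np.exp(-a * t) * (1 + a * t)) / a**2
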