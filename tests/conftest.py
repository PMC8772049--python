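import numpy as np
import pytest

from edacircuit import (
    InitialConditions,
    MarkLaw,
    NoiseSpec,
    RateConstants,
    derive_coefficients,
)


@pytest.fixture
def toy_rates() -> RateConstants:
    """Well-scaled rates with k1 != k_minus1 and 2*k_minus1 != k2."""
    return RateConstants(k1=1.0, k_minus1=0.8, k2=1.2)


@pytest.fixture
def toy_init() -> InitialConditions:
    """Loadings with x0 > c0 so the published invariant region is non-empty."""
    return InitialConditions(x0=1.0, a0=0.5, c0=0.4)


@pytest.fixture
def toy_coeffs(toy_rates, toy_init):
    return derive_coefficients(toy_rates, toy_init)


@pytest.fixture
def mild_noise() -> NoiseSpec:
    return NoiseSpec(
        sigma=0.2,
        lambda_Y=1.0,
        mark=MarkLaw(type="constant", gamma=0.1),
        delta=0.3,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
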