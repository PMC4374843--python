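import numpy as np
import pytest

from decoyburst import GeneCircuitParams
from decoyburst.stationary_density import q_exponents


@pytest.fixture
def fig1_y100():
    """Worked-example circuit with 100 decoy sites (bimodal regime)."""
    return GeneCircuitParams(a0=0.75, a1=25.0, kp=500.0, b=50.0, y=100.0,
                             kb=1.0, gamma_b=1.0)


@pytest.fixture
def fig1_y0():
    """Same circuit without decoys (unimodal on log scale)."""
    return GeneCircuitParams(a0=0.75, a1=25.0, kp=500.0, b=50.0, y=0.0,
                             kb=1.0, gamma_b=1.0)


@pytest.fixture
def gamma_case():
    """No feedback, no decoys: stationary law is Gamma(shape a0, scale b)."""
    return GeneCircuitParams(a0=2.0, a1=0.0, kp=500.0, b=50.0, y=0.0,
                             kb=1.0, gamma_b=1.0)


def random_params(rng: np.random.Generator, *, gamma_b=None, y=None,
                  require_valid_closed_form=False) -> GeneCircuitParams:
    """Draw a random parameter set from biologically plausible ranges."""
    while True:
        p = GeneCircuitParams(
            a0=rng.uniform(0.05, 4.0),
            a1=rng.uniform(0.0, 50.0),
            kp=rng.uniform(1.0, 1500.0),
            b=rng.uniform(10.0, 100.0),
            y=rng.uniform(1.0, 500.0) if y is None else y,
            kb=rng.uniform(0.1, 10.0),
            gamma_b=rng.uniform(0.2, 2.0) if gamma_b is None else gamma_b,
        )
        if not require_valid_closed_form or q_exponents(p).valid:
            return p
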