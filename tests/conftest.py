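import numpy as np
import pytest

from venafit import FourFiberParams, StripDirection


def neo_hookean(mu: float) -> FourFiberParams:
    """Pure matrix response: all fiber stiffnesses zero."""
    return FourFiberParams(
        mu=mu, k1_circ=0.0, k2_circ=1.0, k1_axial=0.0, k2_axial=1.0,
        k1_diag=0.0, k2_diag=1.0, beta_deg=45.0,
    )


def random_params(
    rng: np.random.Generator,
    *,
    mu_range=(10.0, 1e3),
    k1_range=(1.0, 2e3),
    k2_range=(0.5, 50.0),
    beta_range=(0.0, 90.0),
) -> FourFiberParams:
    """Log-uniform parameter draw spanning venous-tissue magnitudes."""

    def logu(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    return FourFiberParams(
        mu=logu(*mu_range),
        k1_circ=logu(*k1_range),
        k2_circ=logu(*k2_range),
        k1_axial=logu(*k1_range),
        k2_axial=logu(*k2_range),
        k1_diag=logu(*k1_range),
        k2_diag=logu(*k2_range),
        beta_deg=float(rng.uniform(*beta_range)),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230515)


@pytest.fixture
def anisotropic_params():
    return FourFiberParams(
        mu=100.0, k1_circ=10.0, k2_circ=1.0, k1_axial=5.0, k2_axial=2.0,
        k1_diag=20.0, k2_diag=3.0, beta_deg=45.0,
    )


@pytest.fixture(params=list(StripDirection), ids=lambda d: d.short)
def direction(request):
    return request.param
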