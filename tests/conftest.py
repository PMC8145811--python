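import numpy as np
import pytest

from saxsflow.composition import ContrastSet
from saxsflow.curves import ScatteringCurve
from saxsflow.models import DisplacedCoreShellParams


@pytest.fixture(scope="session")
def contrasts() -> ContrastSet:
    return ContrastSet.from_config()


@pytest.fixture(scope="session")
def q_grid() -> np.ndarray:
    return np.geomspace(0.005, 0.4, 200)


@pytest.fixture()
def simple_curve() -> ScatteringCurve:
    q = np.linspace(0.01, 0.5, 100)
    I = np.exp(-(q * 20) ** 2 / 3)
    return ScatteringCurve(q=q, I=I, sigma=0.02 * I, time_s=1.5, label="test")


@pytest.fixture(scope="session")
def complex_params_10p5() -> DisplacedCoreShellParams:
    """Displaced-core geometry of the SDS-saturated end state with
    representative contrast weights."""
    return DisplacedCoreShellParams(
        R2=13.7, eps2=1.8, Dshell=10.1, s=1.9, k1=1.61e-9, k2=-6.9e-10
    )
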