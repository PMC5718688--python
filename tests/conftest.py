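import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mosdose as m

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def pristine() -> m.DepthDoseCurve:
    """Default analytic pristine Bragg curve: peak at 160 mm PE."""
    return m.make_pristine_bragg(160.0)


@pytest.fixture(scope="session")
def sobp_spec(pristine) -> m.SOBPSpec:
    """Fitted 80 mm modulation ridge-filter weights."""
    return m.fit_sobp_weights(pristine, 80.0)


@pytest.fixture(scope="session")
def sobp(pristine, sobp_spec) -> m.DepthDoseCurve:
    return m.synthesize_sobp(pristine, sobp_spec)


@pytest.fixture(scope="session")
def l_bolus() -> m.BolusGeometry:
    return m.BolusGeometry.l_shape()


@pytest.fixture(scope="session")
def sigma_model() -> m.SigmaModel:
    return m.SigmaModel()


@pytest.fixture(scope="session")
def field_pencils(l_bolus) -> m.PencilBeamSet:
    """Full-field decomposition behind the L-bolus (100 mm radius, 1 mm)."""
    return m.decompose_broad_beam(100.0, 1.0, geometry=l_bolus)


@pytest.fixture(scope="session")
def flat_dd() -> m.DepthDoseCurve:
    """Constant unit depth-dose, for isolating the lateral Gaussian term."""
    z = np.arange(0.0, 501.0, 1.0)
    return m.DepthDoseCurve(depths=z, outputs=np.ones_like(z), kind="pristine")


@pytest.fixture(scope="session")
def scan_x() -> np.ndarray:
    """Default lateral scan grid: 5 mm steps over [-60, 60] mm."""
    return np.arange(-60.0, 61.0, 5.0)
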