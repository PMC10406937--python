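import numpy as np
import pytest

from slicemech import GroundTruth, ProbeParameters, TissueMechanics, simulate_force_curve


@pytest.fixture
def probe() -> ProbeParameters:
    """Methods probe: 10 um bead (R = 5 um), 0.01 N/m cantilever."""
    return ProbeParameters()


@pytest.fixture
def soft_tissue() -> TissueMechanics:
    """Incompressible tissue at the 0.5 h / 300 mOsm mean stiffness."""
    return TissueMechanics(youngs_modulus=330.0, poisson=0.5)


@pytest.fixture
def clean_hertz_curve(probe, soft_tissue):
    """Noise-free Hertz approach/retract recording at the 700 pN setpoint."""
    truth = GroundTruth(tissue=soft_tissue, noise_sigma=0.0, seed=0)
    return simulate_force_curve(truth, probe)


@pytest.fixture
def clean_adhesive_curve(probe):
    """Noise-free adhesive recording (E = 246 Pa, w = 5 uJ/m^2)."""
    tissue = TissueMechanics(youngs_modulus=246.0, poisson=0.5, adhesion_energy=5e-6)
    truth = GroundTruth(tissue=tissue, noise_sigma=0.0, seed=0)
    return simulate_force_curve(truth, probe)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
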