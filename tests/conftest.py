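import pytest

from embryodose.kinematics import load_growth_model, load_structure_map
from embryodose.medium import Calibration, MediumProperties, agar_block


@pytest.fixture
def medium():
    """Central isotropic medium: D = 6e-6 cm^2/s, no decay, no sorption."""
    return MediumProperties.isotropic(6e-6)


@pytest.fixture
def medium_band():
    """Medium with the D uncertainty half-width 3e-6 cm^2/s."""
    return MediumProperties.isotropic(6e-6, sigma_D=3e-6)


@pytest.fixture
def at_source():
    """Standard atropine agar block: 2x2x3 mm soaked with 3 uL of 1 mM."""
    return agar_block((2, 2, 3), 3.0, 1e-3, Calibration.VOLUMETRIC)


@pytest.fixture
def at_source_calibrated():
    """Same block under the diluted c0 convention (c0 = 2e-4 M)."""
    return agar_block((2, 2, 3), 3.0, 1e-3, Calibration.DILUTED)


@pytest.fixture
def ea_model():
    return load_growth_model("EA")


@pytest.fixture
def ea_map():
    return load_structure_map("EA")
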