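import pytest

from spindrop import ChannelGeometry, FluidSystem, RotorConfig


@pytest.fixture
def hydrophobic_fluids():
    """Water-like aqueous phase against fluorinated oil, hydrophobic walls."""
    return FluidSystem.from_lab(rho_kg_m3=1000.0, mu_mPa_s=1.0, gamma_mN_m=5.0, theta_deg=120.0)


@pytest.fixture
def square20():
    """20 um square nozzle, 5 mm long channel."""
    return ChannelGeometry.from_lab(20.0, 20.0, 5.0)


@pytest.fixture
def rotor_case():
    """Rotor at 5000 rpm with an 18 mm surface radius and 6 mm liquid column."""
    return RotorConfig(523.599, 0.018, 0.006)
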