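import pytest
from hypothesis import HealthCheck, settings

from dcflow import (
    CellSuspension,
    Chamber,
    DesignConstraints,
    DeviceNetwork,
    RectChannel,
    Reservoir,
    SeedingProtocol,
)

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def reference_chamber() -> Chamber:
    """The reference rectangular deposition chamber: 5000 x 2200 x 550 um."""
    return Chamber(height=5.5e-4, length=5.0e-3, width=2.2e-3)


@pytest.fixture(scope="session")
def reference_network(reference_chamber) -> DeviceNetwork:
    """The reference device: 4 mm reservoirs, 1000x100x1000 um inlet channel,
    1000x50 um outlet channel of the nominal ~9900 um length."""
    return DeviceNetwork(
        inlet_reservoir=Reservoir(4.0e-3),
        inlet_channel=RectChannel(1.0e-3, 1.0e-4, 1.0e-3, role="inlet"),
        chamber=reference_chamber,
        outlet_channel=RectChannel(1.0e-3, 5.0e-5, 9.9e-3, role="outlet"),
        outlet_reservoir=Reservoir(4.0e-3),
    )


@pytest.fixture(scope="session")
def reference_suspension() -> CellSuspension:
    """5e7 cells/mL, 3 um radius, 2 um/s settling velocity."""
    return CellSuspension(number_concentration=5.0e13)


@pytest.fixture(scope="session")
def reference_protocol(reference_suspension) -> SeedingProtocol:
    """20 uL of the reference suspension, open-ended deposition."""
    return SeedingProtocol(reference_suspension, infused_volume=2.0e-8)


@pytest.fixture(scope="session")
def default_constraints() -> DesignConstraints:
    return DesignConstraints()
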