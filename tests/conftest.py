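import numpy as np
import pytest

from stimwell import (
    CPEParams,
    DeviceModel,
    MonitorSpec,
    SourceSpec,
    WaveformSpec,
    WellParams,
)


@pytest.fixture
def ideal_well() -> WellParams:
    """Randles cell with an ideal capacitor: tau = 2.5 ms."""
    return WellParams(r_e=250.0, r_f=1e5, c_dl=1e-5)


@pytest.fixture
def cpe_well() -> WellParams:
    """Randles cell with a dispersive interface (CPE, n = 0.85)."""
    return WellParams(r_e=300.0, r_f=8e4, cpe=CPEParams(q_mag=2e-5, n_exp=0.85))


@pytest.fixture
def parallel_device(ideal_well) -> DeviceModel:
    """8-well micro-dish wired for voltage-controlled stimulation."""
    return DeviceModel(well=ideal_well, n_wells=8, wiring="parallel", spacing_d_mm=10.0)


@pytest.fixture
def series_device(ideal_well) -> DeviceModel:
    """8-well micro-dish wired for current-controlled stimulation."""
    return DeviceModel(well=ideal_well, n_wells=8, wiring="series", spacing_d_mm=10.0)


@pytest.fixture
def vc_source() -> SourceSpec:
    return SourceSpec(mode="voltage_controlled", z_output=50.0)


@pytest.fixture
def cc_source() -> SourceSpec:
    return SourceSpec(mode="current_controlled")


@pytest.fixture
def monitor() -> MonitorSpec:
    return MonitorSpec(r_m=50.0)


@pytest.fixture
def biphasic_1v_100hz() -> WaveformSpec:
    """Charge-balanced symmetric biphasic pulse train, 1 V, 100 Hz, 25%/phase."""
    return WaveformSpec(
        shape="biphasic_symmetric", amplitude=1.0, frequency=100.0, duty_percent=25.0
    )
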