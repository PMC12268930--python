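import numpy as np
import pytest

from ventloop import (
    GasProperties,
    LungParams,
    VenturiGeometry,
    VentSettings,
    apply_calibration,
    default_sensor_bank,
    reconstruct_flow,
    simulate,
)
from ventloop.sensing import mark_zeroed


@pytest.fixture
def geom():
    return VenturiGeometry()


@pytest.fixture
def gas():
    return GasProperties()


@pytest.fixture
def ideal_bank():
    """Noise-free, unquantized sensors, pre-zeroed (simulator oracle runs)."""
    bank = default_sensor_bank(noise_sd=0.0, quantization_bits=None)
    mark_zeroed(bank)
    return bank


@pytest.fixture
def flow_factory():
    return make_flow


def make_flow(lung=None, vent=None, duration_s=60.0, fs=160.0, seed=0,
              noise_sd=0.0, quantization_bits=None):
    """Simulate -> calibrate -> reconstruct, returning (FlowStream, SimTrace)."""
    lung = lung or LungParams(elastance=20.0, resistance=5.0)
    vent = vent or VentSettings(p_set=10.0, peep=5.0, rate=15.0)
    bank = default_sensor_bank(noise_sd, quantization_bits)
    mark_zeroed(bank)
    trace = simulate(lung, vent, duration_s, fs=fs, seed=seed, sensors=bank)
    flow = reconstruct_flow(apply_calibration(trace.frames, bank))
    return flow, trace
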