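"""Shared fixtures: surrogate targets are expensive, build them once."""

import numpy as np
import pytest

from tracefit.simulators import (
    HHStepBackend,
    ProtocolSpec,
    SynapticVCBackend,
    VOLTAGE_CLAMP,
)

UC1_TRUE = np.array([0.12, 0.036, 0.0003])  # S/cm^2
UC2_TRUE = np.array([0.3, 3.0, 0.01, 2.0])  # ms, ms, uS, ms


@pytest.fixture(scope="session")
def uc1_protocol():
    return ProtocolSpec(
        amplitudes=[0.2], delay=200.0, duration=500.0, tstop=1000.0,
        dt=0.025, v_init=-70.0,
    )


@pytest.fixture(scope="session")
def hh_backend():
    return HHStepBackend(diam_um=10.0, length_um=100.0)


@pytest.fixture(scope="session")
def uc1_target(hh_backend, uc1_protocol):
    """The spiking Hodgkin-Huxley surrogate target (28 APs)."""
    return hh_backend.simulate(UC1_TRUE, uc1_protocol)


@pytest.fixture(scope="session")
def uc2_protocol():
    return ProtocolSpec(
        mode=VOLTAGE_CLAMP, amplitudes=[-70.0], delay=0.0, duration=0.0,
        tstop=420.0, dt=0.025, v_init=-70.0, record="i",
    )


@pytest.fixture(scope="session")
def synapse_backend():
    return SynapticVCBackend(spike_times=(10.0, 110.0, 210.0, 310.0))


@pytest.fixture(scope="session")
def uc2_target(synapse_backend, uc2_protocol):
    """The synaptic voltage-clamp surrogate target (4 EPSCs)."""
    return synapse_backend.simulate(UC2_TRUE, uc2_protocol)
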