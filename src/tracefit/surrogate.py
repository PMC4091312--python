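"""Surrogate-data generation: targets with known ground-truth parameters.

A surrogate target is a trace set produced by one of the built-in
backends at known ("true") parameter values, optionally with additive
Gaussian recording noise.  Fitting the same backend to such a target
tests whether the optimization machinery can recover the generating
parameters -- the standard way to validate a model-fitting pipeline
before pointing it at experimental data.

Three cases are provided:

``uc1_hh``
    Single-compartment Hodgkin-Huxley neuron (10 um x 100 um), classic
    squid-axon densities gna 0.12 / gk 0.036 / gl 0.0003 S/cm^2,
    driven by a 200 pA step from 200 ms to 700 ms of a 1000 ms sweep.
    The target trace contains 28 action potentials at a 0 mV detection
    threshold.
``uc2_synapse_vc``
    The same compartment held in ideal voltage clamp at -70 mV while a
    double-exponential synapse (rise 0.3 ms, decay 3 ms, peak 10 nS =
    0.01 uS, delay 2 ms) is driven by 4 input spikes 100 ms apart; the
    target is the clamp current.
``uc5_adexp_like``
    An adaptive exponential integrate-and-fire neuron with a
    CA3-pyramidal-like parameter set (documented below) responding to
    current steps of 0.30/0.35/0.40/0.45 nA, 1100 ms sweeps sampled at
    5 kHz.  This case exercises the multi-trace, multi-amplitude path.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .costs import CostSpec
from .simulators import (
    AdExpBackend,
    HHStepBackend,
    ProtocolSpec,
    ParameterSpec,
    SynapticVCBackend,
    CURRENT_CLAMP,
    VOLTAGE_CLAMP,
)
from .traces import Trace, TraceSet, write_traces

__all__ = ["SurrogateCase", "make_surrogate", "CASES"]

# CA3-pyramidal-like AdExpIF parameters: input resistance 125 MOhm,
# membrane time constant 15 ms, rheobase ~0.17 nA so the 0.30-0.45 nA
# steps are suprathreshold, moderate spike-frequency adaptation.
_ADEXP_TRUE = {
    "C": 0.12,      # nF
    "gL": 0.008,    # uS
    "EL": -70.0,    # mV
    "VT": -50.0,    # mV
    "Vr": -56.0,    # mV
    "tref": 2.0,    # ms
    "deltaT": 2.0,  # mV
    "a": 0.004,     # uS
    "b": 0.03,      # nA
    "tauw": 100.0,  # ms
}


@dataclass
class SurrogateCase:
    """One surrogate-data study condition."""

    case_id: str
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.case_id not in CASES:
            raise ValueError(
                f"unknown surrogate case {self.case_id!r}; valid: {', '.join(CASES)}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def _uc1():
    backend = HHStepBackend(diam_um=10.0, length_um=100.0)
    protocol = ProtocolSpec(
        mode=CURRENT_CLAMP, stim_kind="step", amplitudes=[0.2],
        delay=200.0, duration=500.0, tstop=1000.0, dt=0.025, v_init=-70.0,
        record="v",
    )
    true_params = {"gna": 0.12, "gk": 0.036, "gl": 0.0003}
    parameters = [
        ParameterSpec("gna", 0.0, 1.0),
        ParameterSpec("gk", 0.0, 0.3),
        ParameterSpec("gl", 0.0, 0.003),
    ]
    cost = CostSpec(
        terms=[("mse_excl_spikes", 0.5), ("spike_count", 0.5)],
        spike_threshold=0.0, exclusion_halfwidth=5.0,
        stim_window=(200.0, 700.0), normalize_weights=True,
    )
    return backend, protocol, true_params, parameters, cost


def _uc2():
    backend = SynapticVCBackend(spike_times=(10.0, 110.0, 210.0, 310.0))
    protocol = ProtocolSpec(
        mode=VOLTAGE_CLAMP, stim_kind="step", amplitudes=[-70.0],
        delay=0.0, duration=0.0, tstop=420.0, dt=0.025, v_init=-70.0,
        record="i",
    )
    true_params = {"tau1": 0.3, "tau2": 3.0, "weight": 0.01, "delay": 2.0}
    parameters = [
        ParameterSpec("tau1", 0.1, 5.0),
        ParameterSpec("tau2", 0.5, 10.0),
        ParameterSpec("weight", 0.001, 0.1),
        ParameterSpec("delay", 0.1, 10.0),
    ]
    cost = CostSpec(terms=[("mse", 1.0)], normalize_weights=True)
    return backend, protocol, true_params, parameters, cost


def _uc5():
    backend = AdExpBackend()
    protocol = ProtocolSpec(
        mode=CURRENT_CLAMP, stim_kind="step",
        amplitudes=[0.30, 0.35, 0.40, 0.45],
        delay=100.0, duration=900.0, tstop=1100.0, dt=0.2, v_init=-70.0,
        record="v",
    )
    true_params = dict(_ADEXP_TRUE)
    parameters = [
        ParameterSpec("C", 0.05, 0.5),
        ParameterSpec("gL", 0.002, 0.05),
        ParameterSpec("EL", -90.0, -60.0),
        ParameterSpec("VT", -60.0, -40.0),
        ParameterSpec("Vr", -70.0, -45.0),
        ParameterSpec("tref", 0.5, 10.0),
        ParameterSpec("deltaT", 0.5, 5.0),
        ParameterSpec("a", 0.0, 0.02),
        ParameterSpec("b", 0.0, 0.2),
        ParameterSpec("tauw", 20.0, 300.0),
    ]
    cost = CostSpec(
        terms=[
            ("spike_count", 0.25), ("mse_excl_spikes", 0.25),
            ("latency", 0.25), ("isi_diff", 0.25),
        ],
        spike_threshold=-40.0,  # V_cut of the generating parameters
        exclusion_halfwidth=5.0,
        stim_window=(100.0, 1000.0), normalize_weights=True,
    )
    return backend, protocol, true_params, parameters, cost


CASES = {"uc1_hh": _uc1, "uc2_synapse_vc": _uc2, "uc5_adexp_like": _uc5}


def make_surrogate(case: SurrogateCase, out_dir=None):
    """Generate the target trace set (and config template) for a case.

    Returns ``(traces, config)`` where ``config`` is a ready-to-run
    :class:`tracefit.session.SessionConfig` whose parameter bounds
    bracket the generating values.  With ``out_dir`` set, the trace
    file and the XML configuration are also written there and the
    config's data path points at the written file.
    """
    backend, protocol, true_params, parameters, cost = CASES[case.case_id]()
    params = [true_params[p.name] for p in parameters]
    traces = backend.simulate(params, protocol)
    if case.noise_sd > 0:
        rng = np.random.default_rng(case.seed)
        noisy = [
            Trace(
                values=tr.values + rng.normal(scale=case.noise_sd, size=tr.n),
                kind=tr.kind, dt=tr.dt, t0=tr.t0,
            )
            for tr in traces
        ]
        traces = TraceSet(traces=noisy, amplitudes=traces.amplitudes)

    from .session import BackendConfig, DataConfig, SessionConfig
    from .optimizers import OptimizerSettings

    backend_id = {"uc1_hh": "hh_step", "uc2_synapse_vc": "synaptic_vc",
                  "uc5_adexp_like": "adexp"}[case.case_id]
    backend_settings = {}
    if backend_id == "hh_step":
        backend_settings = {"diam": backend.diam_um, "L": backend.length_um}
    elif backend_id == "synaptic_vc":
        backend_settings = {
            "spike_times": list(backend.spike_times),
            "e_rev": backend.e_rev,
            "diam": backend.diam_um, "L": backend.length_um,
        }
    config = SessionConfig(
        data=DataConfig(
            path="", kind=traces.kind,
            unit={"voltage": "mV", "current": "nA"}[traces.kind],
            dt=traces.dt, n_traces=len(traces),
        ),
        backend=BackendConfig(id=backend_id, settings=backend_settings),
        parameters=parameters,
        protocol=protocol,
        cost=cost,
        optimizer=OptimizerSettings(
            algorithm="EO", bounds=[(p.lower, p.upper) for p in parameters],
            seed=case.seed,
        ),
        output_dir="results",
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        trace_path = out_dir / f"{case.case_id}_target.txt"
        write_traces(traces, trace_path)
        config = replace(
            config, data=replace(config.data, path=str(trace_path)),
            output_dir=str(out_dir / "results"),
        )
        from .session import write_config

        write_config(config, out_dir / f"{case.case_id}_config.xml")
    return traces, config


def true_parameters(case_id: str) -> dict:
    """Ground-truth generating parameters of a surrogate case."""
    _, _, true_params, _, _ = CASES[case_id]()
    return dict(true_params)
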