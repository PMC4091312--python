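"""Model backends that turn parameter vectors into simulated trace sets.

Three desk-scale backends are built in:

* a single-compartment Hodgkin-Huxley membrane under current-clamp
  step stimulation (tunable Na+/K+/leak conductance densities),
* an ideal voltage clamp on the same compartment with a double-
  exponential conductance synapse (tunable rise/decay times, peak
  conductance and axonal delay),
* an adaptive exponential integrate-and-fire neuron (10 tunable
  parameters) under multi-amplitude current steps.

Arbitrary external simulators plug in as black boxes through
:class:`ExternalBackend`: parameters are appended to a command line,
the process writes a trace file in the package dialect, and the file
is read back.  Every backend satisfies the same contract: an ordered
``parameter_names`` attribute and a ``simulate(params, protocol)``
method returning one trace per stimulus amplitude, sampled at the
protocol's dt.  A ``user_mapping`` hook may be attached to translate
abstract optimization parameters into backend parameters first.
"""

from __future__ import annotations

import subprocess
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .traces import CURRENT, VOLTAGE, Trace, TraceSet, read_traces

__all__ = [
    "ProtocolSpec",
    "ParameterSpec",
    "Backend",
    "HHStepBackend",
    "SynapticVCBackend",
    "AdExpBackend",
    "ExternalBackend",
    "simulate_hh_step",
    "simulate_synaptic_vc",
    "simulate_adexp",
    "run_external",
]

CURRENT_CLAMP = "current_clamp"
VOLTAGE_CLAMP = "voltage_clamp"


@dataclass
class ProtocolSpec:
    """Stimulation and recording description.

    Times in ms; step amplitudes in nA (current clamp) or mV (voltage
    clamp).  ``record`` selects the measured variable (``"v"`` or
    ``"i"``); ``waveform`` optionally carries a custom stimulus trace
    used instead of the step.
    """

    mode: str = CURRENT_CLAMP
    stim_kind: str = "step"
    amplitudes: list = field(default_factory=lambda: [0.2])
    delay: float = 200.0
    duration: float = 500.0
    tstop: float = 1000.0
    dt: float = 0.025
    v_init: float = -70.0
    record: str = "v"
    waveform: Trace | None = None

    def __post_init__(self) -> None:
        if self.mode not in (CURRENT_CLAMP, VOLTAGE_CLAMP):
            raise ValueError(f"unknown clamp mode {self.mode!r}")
        if self.stim_kind not in ("step", "custom_waveform"):
            raise ValueError(f"unknown stimulus kind {self.stim_kind!r}")
        if self.stim_kind == "step" and not 1 <= len(self.amplitudes) <= 10:
            raise ValueError("step protocols take 1 to 10 stimulus amplitudes")
        if not self.dt > 0:
            raise ValueError("integration time step must be positive")
        if self.delay + self.duration > self.tstop + 1e-9:
            raise ValueError("stimulus must end before tstop")
        if self.record not in ("v", "i"):
            raise ValueError("record must be 'v' or 'i'")

    @property
    def n_samples(self) -> int:
        return int(np.floor(self.tstop / self.dt)) + 1

    def stim_array(self, amplitude: float) -> np.ndarray:
        """Stimulus waveform sampled on the protocol grid (nA or mV)."""
        t = self.dt * np.arange(self.n_samples)
        if self.stim_kind == "custom_waveform":
            if self.waveform is None:
                raise ValueError("custom_waveform protocol without a waveform")
            from .traces import align_sampling  # local import avoids cycle

            wf, _ = align_sampling(TraceSet(traces=[self.waveform]), self.dt)
            stim = np.zeros(self.n_samples)
            n = min(self.n_samples, wf[0].n)
            stim[:n] = wf[0].values[:n]
            return stim
        stim = np.zeros(self.n_samples)
        on = (t >= self.delay) & (t < self.delay + self.duration)
        stim[on] = amplitude
        return stim


@dataclass
class ParameterSpec:
    """A named tunable parameter with mandatory finite bounds."""

    name: str
    lower: float
    upper: float
    initial: float | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lower) and np.isfinite(self.upper)):
            raise ValueError(f"bounds of {self.name!r} must be finite")
        if not self.lower < self.upper:
            raise ValueError(f"lower bound of {self.name!r} must be below upper")
        if self.initial is not None and not (
            self.lower <= self.initial <= self.upper
        ):
            raise ValueError(f"initial value of {self.name!r} outside bounds")


class Backend:
    """Base class for simulator backends.

    Subclasses set ``parameter_names`` and implement ``_simulate``.
    ``user_mapping``, when set, is a pure function applied to the
    abstract parameter vector before simulation.
    """

    parameter_names: tuple = ()

    def __init__(self) -> None:
        self.user_mapping = None

    def simulate(self, params, protocol: ProtocolSpec) -> TraceSet:
        params = np.asarray(params, dtype=float)
        if self.user_mapping is not None:
            params = np.asarray(self.user_mapping(params), dtype=float)
        if params.size != len(self.parameter_names):
            raise ValueError(
                f"expected {len(self.parameter_names)} parameters "
                f"({', '.join(self.parameter_names)}), got {params.size}"
            )
        return self._simulate(params, protocol)

    def _simulate(self, params, protocol):  # pragma: no cover - abstract
        raise NotImplementedError


def _area_cm2(diam_um: float, length_um: float) -> float:
    # lateral surface of a cylinder, um^2 -> cm^2
    return np.pi * diam_um * length_um * 1e-8


class HHStepBackend(Backend):
    """Single-compartment Hodgkin-Huxley membrane, current clamp.

    Tunable parameters: gna, gk, gl (S/cm^2).  Geometry is fixed at
    construction; classical squid-axon kinetics at 6.3 C with reversal
    potentials 50 / -77 / -54.3 mV and C_m = 1 uF/cm^2.
    """

    parameter_names = ("gna", "gk", "gl")

    def __init__(self, diam_um: float = 10.0, length_um: float = 100.0) -> None:
        super().__init__()
        if diam_um <= 0 or length_um <= 0:
            raise ValueError("geometry must be positive")
        self.diam_um = diam_um
        self.length_um = length_um
        self.area_cm2 = _area_cm2(diam_um, length_um)

    def _simulate(self, params, protocol: ProtocolSpec) -> TraceSet:
        if protocol.mode != CURRENT_CLAMP:
            raise ValueError("the HH step backend runs in current clamp only")
        gna, gk, gl = params
        if gna < 0 or gk < 0 or gl < 0:
            raise ValueError("conductance densities must be nonnegative")
        traces = []
        for amp in protocol.amplitudes:
            stim_na = protocol.stim_array(amp)  # nA
            # nA -> uA/cm^2 : 1e-3 uA per nA over the membrane area
            stim_dens = stim_na * 1e-3 / self.area_cm2
            v = _kernels.hh_step_rk4(
                gna * 1e3, gk * 1e3, gl * 1e3, stim_dens, protocol.dt,
                protocol.v_init,
            )
            traces.append(Trace(values=v, kind=VOLTAGE, dt=protocol.dt))
        return TraceSet(traces=traces, amplitudes=list(protocol.amplitudes))


class SynapticVCBackend(Backend):
    """Double-exponential conductance synapse under ideal voltage clamp.

    Tunable parameters: tau1 (rise, ms), tau2 (decay, ms), weight (peak
    conductance, uS), delay (ms).  The membrane carries the classical
    HH conductances of :class:`HHStepBackend`, held ideally at the
    clamp level, so the holding current is the steady-state ionic
    current and each input spike adds a conductance transient

        g(t) = weight * N * (exp(-t'/tau2) - exp(-t'/tau1)),

    t' measured from spike time + delay, with N normalizing the peak
    to ``weight``.  The recorded clamp current (nA, outward positive)
    is i(t) = I_ion(V_hold) + g(t) * (V_hold - E_rev), E_rev = 0 mV.

    Following the usual two-state kinetic synapse convention, a rise
    time >= the decay time is clamped to 0.999 * tau2.
    """

    parameter_names = ("tau1", "tau2", "weight", "delay")

    def __init__(
        self,
        spike_times=(10.0, 110.0, 210.0, 310.0),
        e_rev: float = 0.0,
        diam_um: float = 10.0,
        length_um: float = 100.0,
        densities=(0.12, 0.036, 0.0003),
    ) -> None:
        super().__init__()
        self.spike_times = tuple(float(t) for t in spike_times)
        self.e_rev = e_rev
        self.area_cm2 = _area_cm2(diam_um, length_um)
        self.diam_um = diam_um
        self.length_um = length_um
        self.densities = tuple(densities)

    def holding_current(self, hold_mv: float) -> float:
        """Steady-state ionic current (nA) at the holding potential."""
        gna, gk, gl = self.densities
        dens = _kernels.hh_membrane_current(hold_mv, gna * 1e3, gk * 1e3, gl * 1e3)
        return dens * self.area_cm2 * 1e3  # uA/cm^2 * cm^2 -> uA -> nA

    def _simulate(self, params, protocol: ProtocolSpec) -> TraceSet:
        if protocol.mode != VOLTAGE_CLAMP:
            raise ValueError("the synaptic backend runs in voltage clamp only")
        tau1, tau2, weight, delay = params
        if tau1 <= 0 or tau2 <= 0:
            raise ValueError("synaptic time constants must be positive")
        tau1 = min(tau1, 0.999 * tau2)
        traces = []
        for hold in protocol.amplitudes:
            t = protocol.dt * np.arange(protocol.n_samples)
            # normalization so that the conductance peak equals `weight`
            t_peak = tau1 * tau2 / (tau2 - tau1) * np.log(tau2 / tau1)
            norm = 1.0 / (np.exp(-t_peak / tau2) - np.exp(-t_peak / tau1))
            g = np.zeros_like(t)
            for t_sp in self.spike_times:
                t_on = t_sp + delay
                rel = t - t_on
                act = rel >= 0
                g[act] += weight * norm * (
                    np.exp(-rel[act] / tau2) - np.exp(-rel[act] / tau1)
                )
            i = self.holding_current(hold) + g * (hold - self.e_rev)
            traces.append(Trace(values=i, kind=CURRENT, dt=protocol.dt))
        return TraceSet(traces=traces, amplitudes=list(protocol.amplitudes))


class AdExpBackend(Backend):
    """Adaptive exponential integrate-and-fire neuron, current clamp.

    Ten tunable parameters: C (nF), gL (uS), EL, VT, Vr (mV), tref
    (ms), deltaT (mV), a (uS), b (nA), tauw (ms).  Spikes are emitted
    when V reaches V_cut = VT + 5 * deltaT (the detection threshold of
    the exponential model); the crossing sample is drawn at V_cut so a
    fixed-threshold detector finds it, then V resets to Vr for tref ms
    and the adaptation current w jumps by b.
    """

    parameter_names = (
        "C", "gL", "EL", "VT", "Vr", "tref", "deltaT", "a", "b", "tauw",
    )

    def _simulate(self, params, protocol: ProtocolSpec) -> TraceSet:
        if protocol.mode != CURRENT_CLAMP:
            raise ValueError("the AdExpIF backend runs in current clamp only")
        C, gL, EL, VT, Vr, tref, deltaT, a, b, tauw = params
        if C <= 0 or gL <= 0 or tauw <= 0 or deltaT <= 0:
            raise ValueError("C, gL, tauw and deltaT must be positive")
        traces = []
        for amp in protocol.amplitudes:
            stim = protocol.stim_array(amp)  # nA
            v, _ = _kernels.adexp_rk4(
                C, gL, EL, VT, Vr, tref, deltaT, a, b, tauw,
                stim, protocol.dt, protocol.v_init, 0.0,
            )
            traces.append(Trace(values=v, kind=VOLTAGE, dt=protocol.dt))
        return TraceSet(traces=traces, amplitudes=list(protocol.amplitudes))

    @staticmethod
    def v_cut(VT: float, deltaT: float) -> float:
        return VT + 5.0 * deltaT


class ExternalBackend(Backend):
    """Black-box simulator driven through the file system.

    The command is a list of argv tokens; the parameter values are
    appended in declared order as full-precision decimals.  The process
    must write ``output_path`` in the package trace dialect (one column
    per stimulus amplitude), which is read back with
    :func:`tracefit.traces.read_traces`.
    """

    def __init__(
        self,
        command,
        output_path,
        parameter_names,
        kind: str = VOLTAGE,
        unit: str | None = None,
        timeout: float = 300.0,
    ) -> None:
        super().__init__()
        self.command = list(command)
        self.output_path = output_path
        self.parameter_names = tuple(parameter_names)
        self.kind = kind
        self.unit = unit or {VOLTAGE: "mV", CURRENT: "nA"}[kind]
        self.timeout = timeout

    def _simulate(self, params, protocol: ProtocolSpec) -> TraceSet:
        argv = self.command + [repr(float(p)) for p in params]
        try:
            proc = subprocess.run(
                argv, capture_output=True, text=True, timeout=self.timeout
            )
        except subprocess.TimeoutExpired as exc:
            raise RuntimeError(
                f"external simulator {self.command[0]!r} timed out after "
                f"{self.timeout} s"
            ) from exc
        if proc.returncode != 0:
            raise RuntimeError(
                f"external simulator {self.command[0]!r} exited with status "
                f"{proc.returncode}: {proc.stderr.strip()}"
            )
        try:
            return read_traces(
                self.output_path, self.kind, self.unit, protocol.dt,
                len(protocol.amplitudes),
            )
        except (OSError, ValueError) as exc:
            raise RuntimeError(
                f"external simulator {self.command[0]!r} produced an unusable "
                f"output file {self.output_path}: {exc}"
            ) from exc


# ------------------------------------------------------------------
# functional entry points

def simulate_hh_step(params: dict, geometry: dict, protocol: ProtocolSpec) -> TraceSet:
    """One-call wrapper around :class:`HHStepBackend`."""
    backend = HHStepBackend(diam_um=geometry["diam"], length_um=geometry["L"])
    return backend.simulate(
        [params["gna"], params["gk"], params["gl"]], protocol
    )


def simulate_synaptic_vc(
    params: dict, spike_times, hold_v: float, protocol: ProtocolSpec, **kwargs
) -> TraceSet:
    """One-call wrapper around :class:`SynapticVCBackend` at one holding level."""
    backend = SynapticVCBackend(spike_times=spike_times, **kwargs)
    proto = ProtocolSpec(
        mode=VOLTAGE_CLAMP, stim_kind=protocol.stim_kind,
        amplitudes=[hold_v], delay=protocol.delay, duration=protocol.duration,
        tstop=protocol.tstop, dt=protocol.dt, v_init=hold_v, record="i",
    )
    return backend.simulate(
        [params["tau1"], params["tau2"], params["weight"], params["delay"]], proto
    )


def simulate_adexp(params: dict, protocol: ProtocolSpec) -> TraceSet:
    """One-call wrapper around :class:`AdExpBackend`."""
    backend = AdExpBackend()
    return backend.simulate(
        [params[k] for k in AdExpBackend.parameter_names], protocol
    )


def run_external(command, params, protocol: ProtocolSpec, output_path, **kwargs) -> TraceSet:
    """One-call wrapper around :class:`ExternalBackend`."""
    backend = ExternalBackend(
        command, output_path,
        parameter_names=[f"p{i}" for i in range(len(params))], **kwargs,
    )
    return backend.simulate(params, protocol)
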