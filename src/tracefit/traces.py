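"""Physical time-series containers and trace-file I/O.

All comparisons in this package operate on uniformly sampled traces in
canonical units: membrane potential in mV, current in nA, time in ms.
A :class:`Trace` is one recorded (or simulated) channel; a
:class:`TraceSet` bundles traces of identical type, sampling interval
and length -- e.g. the voltage responses to a family of current steps.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "Trace",
    "TraceSet",
    "read_traces",
    "write_traces",
    "convert_units",
    "align_sampling",
]

VOLTAGE = "voltage"
CURRENT = "current"

# factor that brings a value in the given unit onto the canonical scale
# (mV for voltage-kind units, nA for current-kind units)
_UNIT_FACTORS = {
    "V": (VOLTAGE, 1e3),
    "mV": (VOLTAGE, 1.0),
    "uV": (VOLTAGE, 1e-3),
    "μV": (VOLTAGE, 1e-3),
    "uA": (CURRENT, 1e3),
    "μA": (CURRENT, 1e3),
    "nA": (CURRENT, 1.0),
    "pA": (CURRENT, 1e-3),
}

CANONICAL_UNIT = {VOLTAGE: "mV", CURRENT: "nA"}


@dataclass
class Trace:
    """A uniformly sampled physical time series.

    Parameters
    ----------
    values
        Sample values in canonical units (mV or nA).
    kind
        ``"voltage"`` or ``"current"``.
    dt
        Sampling interval in ms.
    t0
        Time of the first sample in ms.
    """

    values: np.ndarray
    kind: str
    dt: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in (VOLTAGE, CURRENT):
            raise ValueError(f"unknown trace kind {self.kind!r}")
        if not self.dt > 0:
            raise ValueError(f"sampling interval must be positive, got {self.dt}")
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("a trace needs at least 2 samples in one dimension")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite samples")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Time spanned by the samples, (n-1)*dt, in ms."""
        return (self.n - 1) * self.dt

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n)

    def copy(self) -> "Trace":
        return replace(self, values=self.values.copy())


@dataclass
class TraceSet:
    """An ordered set of traces of identical kind, dt and length."""

    traces: list
    amplitudes: list | None = None

    def __post_init__(self) -> None:
        if not self.traces:
            raise ValueError("TraceSet needs at least one trace")
        first = self.traces[0]
        for tr in self.traces[1:]:
            if tr.kind != first.kind:
                raise ValueError("all traces in a set must share kind")
            if not np.isclose(tr.dt, first.dt, rtol=1e-9, atol=0.0):
                raise ValueError("all traces in a set must share dt")
            if tr.n != first.n:
                raise ValueError("all traces in a set must share length")
        if self.amplitudes is not None and len(self.amplitudes) != len(self.traces):
            raise ValueError("need one stimulus amplitude per trace")

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self):
        return iter(self.traces)

    def __getitem__(self, i):
        return self.traces[i]

    @property
    def kind(self) -> str:
        return self.traces[0].kind

    @property
    def dt(self) -> float:
        return self.traces[0].dt

    @property
    def n(self) -> int:
        return self.traces[0].n


def convert_units(values, from_unit: str, to_unit: str):
    """Rescale *values* between units of the same physical kind.

    Supported units: V, mV, uV (μV) for voltage; uA (μA), nA, pA for
    current.  Raises ``ValueError`` on unknown labels or cross-kind
    conversion (e.g. mV -> nA).
    """
    try:
        kind_from, f_from = _UNIT_FACTORS[from_unit]
    except KeyError:
        raise ValueError(f"unknown unit {from_unit!r}") from None
    try:
        kind_to, f_to = _UNIT_FACTORS[to_unit]
    except KeyError:
        raise ValueError(f"unknown unit {to_unit!r}") from None
    if kind_from != kind_to:
        raise ValueError(
            f"cannot convert {from_unit} ({kind_from}) to {to_unit} ({kind_to})"
        )
    factor = f_from / f_to
    return np.asarray(values, dtype=float) * factor


def read_traces(path, kind: str, unit: str, dt: float, n_traces: int) -> TraceSet:
    """Load a whitespace-separated trace file.

    The file dialect is one column per trace, no header and no time
    column; sample *i* of every trace lies at ``i * dt``.  Values are
    converted from *unit* to the canonical unit for *kind*.
    """
    if kind not in (VOLTAGE, CURRENT):
        raise ValueError(f"unknown trace kind {kind!r}")
    try:
        raw = np.loadtxt(path, dtype=float, ndmin=2)
    except FileNotFoundError:
        raise
    except ValueError as exc:
        raise ValueError(f"malformed trace file {path}: {exc}") from exc
    if raw.shape[1] != n_traces:
        raise ValueError(
            f"trace file {path} has {raw.shape[1]} columns, expected {n_traces}"
        )
    canonical = CANONICAL_UNIT[kind]
    data = convert_units(raw, unit, canonical)
    traces = [Trace(values=data[:, j], kind=kind, dt=dt) for j in range(n_traces)]
    return TraceSet(traces=traces)


def write_traces(traces: TraceSet, path) -> None:
    """Write a TraceSet in the package's text dialect (9 significant digits)."""
    data = np.column_stack([tr.values for tr in traces])
    np.savetxt(path, data, fmt="%.9g")


def _resample(trace: Trace, new_dt: float) -> Trace:
    n_new = int(np.floor(trace.duration / new_dt)) + 1
    t_new = trace.t0 + new_dt * np.arange(n_new)
    v_new = np.interp(t_new, trace.times, trace.values)
    return Trace(values=v_new, kind=trace.kind, dt=new_dt, t0=trace.t0)


def align_sampling(target: TraceSet, model_dt: float):
    """Bring target data and simulation onto one sampling grid.

    If the target is sampled faster than the model step the target is
    kept and the simulation step must follow (``effective_dt`` is the
    target's dt); if the target is sampled slower it is re-sampled onto
    the model grid by linear interpolation, and the re-sampled set
    replaces the original from then on.

    Returns ``(trace_set, effective_dt)``.
    """
    if not model_dt > 0:
        raise ValueError("model_dt must be positive")
    if target.dt <= model_dt * (1 + 1e-12):
        if np.isclose(target.dt, model_dt, rtol=1e-9, atol=0.0):
            return target, model_dt
        return target, target.dt
    resampled = TraceSet(
        traces=[_resample(tr, model_dt) for tr in target],
        amplitudes=target.amplitudes,
    )
    return resampled, model_dt
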