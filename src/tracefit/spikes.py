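"""Action-potential detection and per-spike feature extraction.

A spike is a maximal contiguous excursion of the membrane potential
above a user-set detection threshold (default 0 mV).  Feature
definitions follow the common electrophysiology conventions:

* amplitude -- peak voltage minus threshold voltage,
* width -- time spent above the half-amplitude level, with linear
  interpolation at the two crossings,
* AHP depth -- how far the voltage dips below threshold between one
  spike's offset and the next spike's onset (reported nonnegative).

The threshold voltage attributed to each spike is the detection
threshold itself; no dV/dt criterion is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .traces import Trace, VOLTAGE

__all__ = ["Spike", "detect_spikes", "spike_features"]

DEFAULT_THRESHOLD = 0.0  # mV


@dataclass
class Spike:
    """One detected action potential (times in ms, voltages in mV)."""

    onset_t: float
    peak_t: float
    peak_v: float
    offset_t: float
    threshold_v: float
    width: float = np.nan
    ahp_depth: float = np.nan

    @property
    def amplitude(self) -> float:
        return self.peak_v - self.threshold_v


def detect_spikes(trace: Trace, threshold: float = DEFAULT_THRESHOLD):
    """Find supra-threshold excursions of a voltage trace.

    Returns one :class:`Spike` per maximal run of samples at or above
    *threshold*, ordered by onset time.  Onset and offset times are the
    linearly interpolated threshold crossings; an excursion still open
    at the end of the trace is closed at the last sample.
    """
    if trace.kind != VOLTAGE:
        raise ValueError("spike detection requires a voltage trace")
    v = trace.values
    t = trace.times
    above = v >= threshold
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1  # first index back below
    if above[0]:
        starts = np.concatenate(([0], starts))
    if above[-1]:
        ends = np.concatenate((ends, [v.size]))
    spikes = []
    for s, e in zip(starts, ends):
        seg = v[s:e]
        k = s + int(np.argmax(seg))
        if s > 0:
            # fractional crossing between samples s-1 and s
            frac = (threshold - v[s - 1]) / (v[s] - v[s - 1])
            onset = t[s - 1] + frac * trace.dt
        else:
            onset = t[0]
        if e < v.size:
            frac = (v[e - 1] - threshold) / (v[e - 1] - v[e])
            offset = t[e - 1] + frac * trace.dt
        else:
            offset = t[-1]
        spikes.append(
            Spike(
                onset_t=float(onset),
                peak_t=float(t[k]),
                peak_v=float(v[k]),
                offset_t=float(offset),
                threshold_v=float(threshold),
            )
        )
    return spikes


def _half_width(trace: Trace, spike: Spike) -> float:
    """Time above the half-amplitude level, interpolated at crossings."""
    level = spike.threshold_v + spike.amplitude / 2.0
    v = trace.values
    t = trace.times
    k = int(round((spike.peak_t - trace.t0) / trace.dt))
    # walk left from the peak to the first sample below the level
    i = k
    while i > 0 and v[i - 1] >= level:
        i -= 1
    if i > 0:
        left = t[i - 1] + (level - v[i - 1]) / (v[i] - v[i - 1]) * trace.dt
    else:
        left = t[0]
    j = k
    while j < v.size - 1 and v[j + 1] >= level:
        j += 1
    if j < v.size - 1:
        right = t[j] + (v[j] - level) / (v[j] - v[j + 1]) * trace.dt
    else:
        right = t[-1]
    return float(right - left)


def spike_features(trace: Trace, spikes, stim_window=None):
    """Fill in width and AHP depth for spikes detected on *trace*.

    The AHP search window for spike *k* runs from its offset to the
    onset of spike *k+1*; for the last spike it runs to the stimulus
    end (if *stim_window* is given and ends before the trace does) or
    the end of the trace.  Returns the same list with fields completed.
    """
    if trace.kind != VOLTAGE:
        raise ValueError("spike features require a voltage trace")
    v = trace.values
    t = trace.times
    t_end = t[-1]
    if stim_window is not None:
        t_end = min(t_end, stim_window[1])
    for k, sp in enumerate(spikes):
        if not (trace.t0 <= sp.peak_t <= t[-1]):
            raise ValueError("spike list inconsistent with trace")
        sp.width = _half_width(trace, sp)
        lo = sp.offset_t
        hi = spikes[k + 1].onset_t if k + 1 < len(spikes) else max(t_end, lo)
        mask = (t >= lo) & (t <= hi)
        if mask.any():
            sp.ahp_depth = float(sp.threshold_v - v[mask].min())
        else:
            sp.ahp_depth = 0.0
    return spikes
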