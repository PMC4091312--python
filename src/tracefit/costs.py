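"""Cost (fitness) functions comparing simulated and target trace sets.

Every feature maps a (simulated, target) trace pair to a nonnegative
scalar normalized toward the 0-1 range, so that user-chosen weights
reflect the relative importance of the features in the combined cost.
Trace pairs must already share dt and length; no silent resampling is
performed here (alignment is done once, up front, by
:func:`tracefit.traces.align_sampling`).

Available feature identifiers
-----------------------------
``mse``
    Pointwise mean squared difference, normalized by the squared range
    of the target.
``mse_excl_spikes``
    Same, restricted to samples outside windows around every spike
    detected in either trace (the subthreshold error).
``deriv_diff``
    Mean squared difference of the temporal derivatives, normalized by
    the squared range of the target derivative.
``spike_count`` / ``spike_count_stim``
    |n_sim - n_target| / (n_sim + n_target + 1), over the whole trace
    or restricted to spikes peaking inside the stimulus window.
``isi_diff``
    Sum of absolute differences of corresponding inter-spike intervals,
    normalized by the trace duration.
``latency``
    Squared difference of first-spike times over the squared duration;
    a spikeless trace contributes a latency equal to the duration.
``ap_overshoot`` / ``ap_width`` / ``ahp_depth``
    Squared differences of paired spike amplitudes / widths / AHP
    depths with the normalizations described in each function.
``pptd``
    Phase-plane trajectory density: total-variation distance between
    the normalized 2-D histograms of (V, dV/dt) points of the two
    traces on a shared grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spikes import detect_spikes, spike_features
from .traces import Trace, TraceSet

__all__ = [
    "CostSpec",
    "FEATURE_IDS",
    "pointwise_error",
    "spike_timing_error",
    "spike_shape_error",
    "pptd_error",
    "evaluate_feature",
    "combine_features",
]

FEATURE_IDS = (
    "mse",
    "mse_excl_spikes",
    "deriv_diff",
    "spike_count",
    "spike_count_stim",
    "isi_diff",
    "latency",
    "ap_overshoot",
    "ap_width",
    "ahp_depth",
    "pptd",
)


@dataclass
class CostSpec:
    """Weighted feature combination plus shared feature parameters.

    Parameters
    ----------
    terms
        List of ``(feature_id, weight)`` with nonnegative finite
        weights; at least one term.
    spike_threshold
        AP detection threshold in mV.
    exclusion_halfwidth
        Half-width in ms of the exclusion window centred on each spike
        peak (subthreshold MSE, subthreshold range).
    stim_window
        ``(t_on, t_off)`` in ms; required by ``spike_count_stim``.
    pptd_bins
        Grid resolution per axis for the phase-plane histogram.
    normalize_weights
        If true, weights are rescaled to sum to one before combining.
    ahp_mean_of_squares
        The AHP-depth feature squares the mean of the per-spike depth
        differences by default; set this to average the squared
        differences instead.
    """

    terms: list
    spike_threshold: float = 0.0
    exclusion_halfwidth: float = 5.0
    stim_window: tuple | None = None
    pptd_bins: int = 64
    normalize_weights: bool = False
    ahp_mean_of_squares: bool = False

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("CostSpec needs at least one feature term")
        for fid, w in self.terms:
            if fid not in FEATURE_IDS:
                raise ValueError(
                    f"unknown feature {fid!r}; valid: {', '.join(FEATURE_IDS)}"
                )
            if not (np.isfinite(w) and w >= 0):
                raise ValueError(f"weight for {fid!r} must be finite and nonnegative")
        if self.pptd_bins < 2:
            raise ValueError("pptd_bins must be at least 2")


def _check_aligned(sim: Trace, target: Trace) -> None:
    if sim.n != target.n:
        raise ValueError("sim and target traces differ in length")
    if not np.isclose(sim.dt, target.dt, rtol=1e-9, atol=0.0):
        raise ValueError("sim and target traces differ in dt")


def _exclusion_mask(sim: Trace, target: Trace, spec: CostSpec) -> np.ndarray:
    """True for samples inside a window around any spike of either trace."""
    h = spec.exclusion_halfwidth
    t = target.times
    mask = np.zeros(target.n, dtype=bool)
    for tr in (sim, target):
        for sp in detect_spikes(tr, spec.spike_threshold):
            mask |= np.abs(t - sp.peak_t) <= h
    return mask


def _derivative(trace: Trace) -> np.ndarray:
    # central differences in the interior, one-sided at the ends
    return np.gradient(trace.values, trace.dt)


def pointwise_error(kind: str, sim: Trace, target: Trace, spec: CostSpec) -> float:
    """mse / mse_excl_spikes / deriv_diff for one trace pair."""
    _check_aligned(sim, target)
    s, x = sim.values, target.values
    if kind == "mse":
        rng = x.max() - x.min()
        if rng == 0:
            raise ValueError("target trace has zero range")
        return float(np.mean((s - x) ** 2) / rng**2)
    if kind == "mse_excl_spikes":
        rng = x.max() - x.min()
        if rng == 0:
            raise ValueError("target trace has zero range")
        keep = ~_exclusion_mask(sim, target, spec)
        if not keep.any():
            raise ValueError("all samples fall inside spike exclusion windows")
        return float(np.mean((s[keep] - x[keep]) ** 2) / rng**2)
    if kind == "deriv_diff":
        ds, dx = _derivative(sim), _derivative(target)
        rng = dx.max() - dx.min()
        if rng == 0:
            raise ValueError("target derivative has zero range")
        return float(np.mean((ds - dx) ** 2) / rng**2)
    raise ValueError(f"unknown pointwise error kind {kind!r}")


def spike_timing_error(kind: str, sim: Trace, target: Trace, spec: CostSpec) -> float:
    """spike_count / spike_count_stim / isi_diff / latency for one pair."""
    _check_aligned(sim, target)
    sp_s = detect_spikes(sim, spec.spike_threshold)
    sp_x = detect_spikes(target, spec.spike_threshold)
    T = target.duration
    if kind == "spike_count":
        return abs(len(sp_s) - len(sp_x)) / (len(sp_s) + len(sp_x) + 1)
    if kind == "spike_count_stim":
        if spec.stim_window is None:
            raise ValueError("spike_count_stim requires a stimulus window")
        t_on, t_off = spec.stim_window
        n_s = sum(t_on <= sp.peak_t <= t_off for sp in sp_s)
        n_x = sum(t_on <= sp.peak_t <= t_off for sp in sp_x)
        return abs(n_s - n_x) / (n_s + n_x + 1)
    if kind == "isi_diff":
        k = min(len(sp_s), len(sp_x)) - 1
        if k < 1:
            return 0.0
        isi_s = np.diff([sp.peak_t for sp in sp_s])[:k]
        isi_x = np.diff([sp.peak_t for sp in sp_x])[:k]
        return float(np.sum(np.abs(isi_s - isi_x)) / T)
    if kind == "latency":
        t_s = sp_s[0].peak_t if sp_s else T
        t_x = sp_x[0].peak_t if sp_x else T
        return min(float((t_s - t_x) ** 2 / T**2), 1.0)
    raise ValueError(f"unknown spike timing error kind {kind!r}")


def _paired_features(sim: Trace, target: Trace, spec: CostSpec):
    sp_s = spike_features(sim, detect_spikes(sim, spec.spike_threshold), spec.stim_window)
    sp_x = spike_features(
        target, detect_spikes(target, spec.spike_threshold), spec.stim_window
    )
    return sp_s, sp_x


def spike_shape_error(kind: str, sim: Trace, target: Trace, spec: CostSpec) -> float:
    """ap_overshoot / ap_width / ahp_depth for one trace pair.

    Spikes are paired in order of occurrence and truncated to the
    shorter train.  With no pairs at all the value is 1 when the counts
    differ (worst case) and 0 when both traces are spikeless.
    """
    _check_aligned(sim, target)
    sp_s, sp_x = _paired_features(sim, target, spec)
    K = min(len(sp_s), len(sp_x))
    if K == 0:
        return 1.0 if len(sp_s) != len(sp_x) else 0.0
    if kind == "ap_overshoot":
        a_s = np.array([sp.amplitude for sp in sp_s[:K]])
        a_x = np.array([sp.amplitude for sp in sp_x[:K]])
        denom = np.max([sp.amplitude for sp in sp_x]) ** 2
        return float(np.mean((a_s - a_x) ** 2) / denom)
    if kind == "ap_width":
        w_s = np.array([sp.width for sp in sp_s[:K]])
        w_x = np.array([sp.width for sp in sp_x[:K]])
        denom = np.mean([sp.width for sp in sp_x]) ** 2
        return float(np.mean((w_s - w_x) ** 2) / denom)
    if kind == "ahp_depth":
        d_s = np.array([sp.ahp_depth for sp in sp_s[:K]])
        d_x = np.array([sp.ahp_depth for sp in sp_x[:K]])
        keep = ~_exclusion_mask(sim, target, spec)
        sub = target.values[keep] if keep.any() else target.values
        rng = sub.max() - sub.min()
        if rng == 0:
            raise ValueError("target subthreshold range is zero")
        if spec.ahp_mean_of_squares:
            return float(np.mean((d_s - d_x) ** 2) / rng**2)
        return float(np.mean(d_s - d_x) ** 2 / rng**2)
    raise ValueError(f"unknown spike shape error kind {kind!r}")


def pptd_error(sim: Trace, target: Trace, spec: CostSpec) -> float:
    """Phase-plane trajectory density distance between two traces.

    Both traces are mapped to point clouds (V_i, dV/dt_i), binned on a
    shared ``pptd_bins`` x ``pptd_bins`` grid spanning the joint
    bounding box, and the normalized histograms are compared by
    total-variation distance, which lies in [0, 1].
    """
    _check_aligned(sim, target)
    G = spec.pptd_bins
    clouds = []
    for tr in (sim, target):
        clouds.append((tr.values, _derivative(tr)))
    v_all = np.concatenate([c[0] for c in clouds])
    d_all = np.concatenate([c[1] for c in clouds])
    v_lo, v_hi = v_all.min(), v_all.max()
    d_lo, d_hi = d_all.min(), d_all.max()
    if v_lo == v_hi and d_lo == d_hi:
        return 0.0  # both traces constant: identical phase portraits
    # pad any zero-width axis so histogram2d has a valid box
    if v_lo == v_hi:
        v_lo, v_hi = v_lo - 0.5, v_hi + 0.5
    if d_lo == d_hi:
        d_lo, d_hi = d_lo - 0.5, d_hi + 0.5
    hists = []
    for v, d in clouds:
        h, _, _ = np.histogram2d(v, d, bins=G, range=[[v_lo, v_hi], [d_lo, d_hi]])
        hists.append(h / h.sum())
    return float(0.5 * np.abs(hists[0] - hists[1]).sum())


_POINTWISE = {"mse", "mse_excl_spikes", "deriv_diff"}
_TIMING = {"spike_count", "spike_count_stim", "isi_diff", "latency"}
_SHAPE = {"ap_overshoot", "ap_width", "ahp_depth"}


def evaluate_feature(fid: str, sim: Trace, target: Trace, spec: CostSpec) -> float:
    """Dispatch a single feature on one trace pair."""
    if fid in _POINTWISE:
        return pointwise_error(fid, sim, target, spec)
    if fid in _TIMING:
        return spike_timing_error(fid, sim, target, spec)
    if fid in _SHAPE:
        return spike_shape_error(fid, sim, target, spec)
    if fid == "pptd":
        return pptd_error(sim, target, spec)
    raise ValueError(f"unknown feature {fid!r}")


def combine_features(spec: CostSpec, sim: TraceSet, target: TraceSet):
    """Weighted combination of features accumulated over trace pairs.

    Each feature is summed over corresponding (sim, target) pairs; the
    total is the weight-weighted sum over features, with weights first
    normalized to unit sum when ``spec.normalize_weights`` is set.

    Returns ``(total, per_feature)`` where ``per_feature`` maps feature
    id to its accumulated (unweighted) value.
    """
    if len(sim) != len(target):
        raise ValueError("sim and target trace sets differ in trace count")
    weights = np.array([w for _, w in spec.terms], dtype=float)
    if spec.normalize_weights:
        s = weights.sum()
        if s == 0:
            raise ValueError("cannot normalize an all-zero weight vector")
        weights = weights / s
    per_feature = {}
    for fid, _ in spec.terms:
        per_feature[fid] = sum(
            evaluate_feature(fid, s_tr, x_tr, spec) for s_tr, x_tr in zip(sim, target)
        )
    total = float(
        sum(w * per_feature[fid] for (fid, _), w in zip(spec.terms, weights))
    )
    return total, per_feature
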