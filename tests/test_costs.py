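"""Cost functions: oracle equivalence, normalization bounds, combination.

The oracle below is a deliberately naive, loop-based transcription of
each cost definition, written independently of the implementation in
``tracefit.costs``; the main test checks exact agreement on a bank of
randomized trace pairs.
"""

import numpy as np
import pytest

from tracefit.costs import (
    CostSpec,
    FEATURE_IDS,
    combine_features,
    evaluate_feature,
    pointwise_error,
)
from tracefit.traces import Trace, TraceSet


# ------------------------------------------------------------------
# naive oracle

def _oracle_spikes(v, t, dt, thr):
    """Threshold-crossing spike detection, transcribed sample by sample."""
    spikes = []
    i = 0
    n = len(v)
    while i < n:
        if v[i] >= thr:
            j = i
            while j < n and v[j] >= thr:
                j += 1
            k = i + max(range(j - i), key=lambda q: v[i + q])
            if i > 0:
                onset = t[i - 1] + (thr - v[i - 1]) / (v[i] - v[i - 1]) * dt
            else:
                onset = t[0]
            if j < n:
                offset = t[j - 1] + (v[j - 1] - thr) / (v[j - 1] - v[j]) * dt
            else:
                offset = t[-1]
            spikes.append(dict(onset=onset, peak_t=t[k], peak_v=v[k], offset=offset))
            i = j
        else:
            i += 1
    return spikes


def _oracle_width(v, t, dt, peak_t, level):
    k = int(round((peak_t - t[0]) / dt))
    i = k
    while i > 0 and v[i - 1] >= level:
        i -= 1
    left = t[0] if i == 0 else t[i - 1] + (level - v[i - 1]) / (v[i] - v[i - 1]) * dt
    j = k
    while j < len(v) - 1 and v[j + 1] >= level:
        j += 1
    right = (
        t[-1] if j == len(v) - 1
        else t[j] + (v[j] - level) / (v[j] - v[j + 1]) * dt
    )
    return right - left


def _oracle_derivative(v, dt):
    d = np.empty_like(v)
    d[0] = (v[1] - v[0]) / dt
    d[-1] = (v[-1] - v[-2]) / dt
    for i in range(1, len(v) - 1):
        d[i] = (v[i + 1] - v[i - 1]) / (2 * dt)
    return d


def _oracle_excl_mask(t, peaks, h):
    keep = np.ones(len(t), dtype=bool)
    for i, ti in enumerate(t):
        for pk in peaks:
            if abs(ti - pk) <= h:
                keep[i] = False
                break
    return keep


def oracle_feature(fid, sim, target, spec):
    s, x = sim.values, target.values
    t = target.times
    dt = target.dt
    T = (len(x) - 1) * dt
    thr = spec.spike_threshold
    sp_s = _oracle_spikes(s, t, dt, thr)
    sp_x = _oracle_spikes(x, t, dt, thr)

    if fid == "mse":
        return np.mean((s - x) ** 2) / (x.max() - x.min()) ** 2
    if fid == "mse_excl_spikes":
        peaks = [sp["peak_t"] for sp in sp_s + sp_x]
        keep = _oracle_excl_mask(t, peaks, spec.exclusion_halfwidth)
        return np.mean((s[keep] - x[keep]) ** 2) / (x.max() - x.min()) ** 2
    if fid == "deriv_diff":
        ds, dx = _oracle_derivative(s, dt), _oracle_derivative(x, dt)
        return np.mean((ds - dx) ** 2) / (dx.max() - dx.min()) ** 2
    if fid == "spike_count":
        return abs(len(sp_s) - len(sp_x)) / (len(sp_s) + len(sp_x) + 1)
    if fid == "spike_count_stim":
        t_on, t_off = spec.stim_window
        ns = sum(t_on <= sp["peak_t"] <= t_off for sp in sp_s)
        nx = sum(t_on <= sp["peak_t"] <= t_off for sp in sp_x)
        return abs(ns - nx) / (ns + nx + 1)
    if fid == "isi_diff":
        K = min(len(sp_s), len(sp_x)) - 1
        if K < 1:
            return 0.0
        total = 0.0
        for k in range(K):
            isi_s = sp_s[k + 1]["peak_t"] - sp_s[k]["peak_t"]
            isi_x = sp_x[k + 1]["peak_t"] - sp_x[k]["peak_t"]
            total += abs(isi_s - isi_x)
        return total / T
    if fid == "latency":
        ts_ = sp_s[0]["peak_t"] if sp_s else T
        tx_ = sp_x[0]["peak_t"] if sp_x else T
        return min((ts_ - tx_) ** 2 / T**2, 1.0)

    if fid == "pptd":
        ds, dx = _oracle_derivative(s, dt), _oracle_derivative(x, dt)
        v_lo = min(s.min(), x.min())
        v_hi = max(s.max(), x.max())
        d_lo = min(ds.min(), dx.min())
        d_hi = max(ds.max(), dx.max())
        if v_lo == v_hi and d_lo == d_hi:
            return 0.0
        if v_lo == v_hi:
            v_lo, v_hi = v_lo - 0.5, v_hi + 0.5
        if d_lo == d_hi:
            d_lo, d_hi = d_lo - 0.5, d_hi + 0.5
        G = spec.pptd_bins
        h1, _, _ = np.histogram2d(s, ds, bins=G, range=[[v_lo, v_hi], [d_lo, d_hi]])
        h2, _, _ = np.histogram2d(x, dx, bins=G, range=[[v_lo, v_hi], [d_lo, d_hi]])
        return 0.5 * np.abs(h1 / h1.sum() - h2 / h2.sum()).sum()

    # paired spike-shape features
    K = min(len(sp_s), len(sp_x))
    if K == 0:
        return 1.0 if len(sp_s) != len(sp_x) else 0.0
    if fid == "ap_overshoot":
        amp_s = [sp["peak_v"] - thr for sp in sp_s]
        amp_x = [sp["peak_v"] - thr for sp in sp_x]
        num = sum((amp_s[k] - amp_x[k]) ** 2 for k in range(K)) / K
        return num / max(amp_x) ** 2
    if fid == "ap_width":
        w_s = [
            _oracle_width(s, t, dt, sp["peak_t"], thr + (sp["peak_v"] - thr) / 2)
            for sp in sp_s
        ]
        w_x = [
            _oracle_width(x, t, dt, sp["peak_t"], thr + (sp["peak_v"] - thr) / 2)
            for sp in sp_x
        ]
        num = sum((w_s[k] - w_x[k]) ** 2 for k in range(K)) / K
        return num / (sum(w_x) / len(w_x)) ** 2
    if fid == "ahp_depth":
        def depths(v, sp_list, t_end):
            out = []
            for k, sp in enumerate(sp_list):
                lo = sp["offset"]
                hi = sp_list[k + 1]["onset"] if k + 1 < len(sp_list) else max(t_end, lo)
                window = [v[i] for i in range(len(t)) if lo <= t[i] <= hi]
                out.append(thr - min(window) if window else 0.0)
            return out
        t_end = min(t[-1], spec.stim_window[1]) if spec.stim_window else t[-1]
        d_s = depths(s, sp_s, t_end)
        d_x = depths(x, sp_x, t_end)
        peaks = [sp["peak_t"] for sp in sp_s + sp_x]
        keep = _oracle_excl_mask(t, peaks, spec.exclusion_halfwidth)
        sub = x[keep] if keep.any() else x
        rng = sub.max() - sub.min()
        mean_diff = sum(d_s[k] - d_x[k] for k in range(K)) / K
        return mean_diff**2 / rng**2
    raise AssertionError(fid)


# ------------------------------------------------------------------
# randomized trace bank

def random_pair(rng, spiky=True):
    """A (sim, target) pair: smooth subthreshold wander, optional spikes."""
    n = 240
    dt = 0.5
    t = np.arange(n) * dt

    def one(n_spikes):
        base = -65 + np.cumsum(rng.normal(0, 0.6, n))
        base -= (base.mean() + 65)
        v = base.copy()
        peaks = rng.choice(np.arange(20, n - 20, 10), size=n_spikes, replace=False)
        for pk in peaks:
            width = rng.integers(2, 5)
            height = rng.uniform(20, 45)
            for q in range(-width, width + 1):
                tri = height * (1 - abs(q) / width)
                v[pk + q] = max(v[pk + q], tri)
        return v

    k1 = rng.integers(0, 5) if spiky else 0
    k2 = rng.integers(0, 5) if spiky else 0
    sim = Trace(values=one(k1), kind="voltage", dt=dt)
    target = Trace(values=one(k2), kind="voltage", dt=dt)
    return sim, target


SPEC = CostSpec(
    terms=[(fid, 1.0) for fid in FEATURE_IDS],
    spike_threshold=0.0,
    exclusion_halfwidth=4.0,
    stim_window=(10.0, 100.0),
    pptd_bins=16,
)


class TestOracleEquivalence:
    @pytest.mark.parametrize("fid", FEATURE_IDS)
    def test_feature_matches_naive_recomputation(self, fid):
        rng = np.random.default_rng(42)
        checked = 0
        for i in range(100):
            sim, target = random_pair(rng, spiky=(i % 4 != 3))
            got = evaluate_feature(fid, sim, target, SPEC)
            want = oracle_feature(fid, sim, target, SPEC)
            assert got == pytest.approx(want, rel=1e-12, abs=1e-15), f"pair {i}"
            checked += 1
        assert checked == 100

    @pytest.mark.parametrize("fid", FEATURE_IDS)
    def test_identity_gives_zero_and_values_nonnegative(self, fid):
        rng = np.random.default_rng(11)
        sim, target = random_pair(rng)
        assert evaluate_feature(fid, sim.copy(), sim, SPEC) == pytest.approx(0.0, abs=1e-14)
        assert evaluate_feature(fid, sim, target, SPEC) >= 0.0

    @pytest.mark.parametrize("fid", ["spike_count", "spike_count_stim", "pptd"])
    def test_bounded_features_never_exceed_one(self, fid):
        rng = np.random.default_rng(5)
        for _ in range(50):
            sim, target = random_pair(rng)
            assert evaluate_feature(fid, sim, target, SPEC) <= 1.0 + 1e-12


class TestPointwise:
    def test_uniform_offset_mse_forced_by_formula(self):
        x = np.linspace(-70, -60, 100)  # range 10 mV
        target = Trace(values=x, kind="voltage", dt=0.1)
        sim = Trace(values=x + 1.0, kind="voltage", dt=0.1)
        spec = CostSpec(terms=[("mse", 1.0)])
        assert pointwise_error("mse", sim, target, spec) == pytest.approx(0.01)

    def test_differences_inside_exclusion_windows_are_invisible(self):
        t = np.arange(400) * 0.1
        x = np.full(400, -65.0)
        x[200:205] = np.array([10, 35, 30, 20, -10.0])  # one spike at ~20 ms
        s = x.copy()
        s[201] = 45.0  # differ only at the spike peak
        spec = CostSpec(terms=[("mse", 1.0)], exclusion_halfwidth=3.0)
        target = Trace(values=x, kind="voltage", dt=0.1)
        sim = Trace(values=s, kind="voltage", dt=0.1)
        assert pointwise_error("mse_excl_spikes", sim, target, spec) == 0.0
        assert pointwise_error("mse", sim, target, spec) > 0.0

    def test_mse_excl_equals_mse_without_spikes(self):
        rng = np.random.default_rng(0)
        x = -65 + rng.normal(0, 1, 300)
        s = -65 + rng.normal(0, 1, 300)
        spec = CostSpec(terms=[("mse", 1.0)])
        target = Trace(values=x, kind="voltage", dt=0.1)
        sim = Trace(values=s, kind="voltage", dt=0.1)
        assert pointwise_error("mse_excl_spikes", sim, target, spec) == pytest.approx(
            pointwise_error("mse", sim, target, spec), rel=1e-12
        )

    def test_misaligned_traces_rejected(self):
        a = Trace(values=np.zeros(100) - 65, kind="voltage", dt=0.1)
        b = Trace(values=np.zeros(101) - 60, kind="voltage", dt=0.1)
        c = Trace(values=np.arange(100.0), kind="voltage", dt=0.2)
        spec = CostSpec(terms=[("mse", 1.0)])
        with pytest.raises(ValueError):
            pointwise_error("mse", a, b, spec)
        with pytest.raises(ValueError):
            pointwise_error("mse", a, c, spec)

    def test_zero_target_range_rejected(self):
        flat = Trace(values=np.full(50, -65.0), kind="voltage", dt=0.1)
        spec = CostSpec(terms=[("mse", 1.0)])
        with pytest.raises(ValueError, match="range"):
            pointwise_error("mse", flat, flat, spec)


class TestCombination:
    def _pair_sets(self):
        rng = np.random.default_rng(19)
        sims, targets = [], []
        for _ in range(2):
            sim, target = random_pair(rng)
            sims.append(sim)
            targets.append(target)
        return TraceSet(traces=sims), TraceSet(traces=targets)

    def test_weight_normalization_is_convex_combination(self):
        sim, target = self._pair_sets()
        spec = CostSpec(
            terms=[("mse", 2.0), ("spike_count", 2.0)],
            normalize_weights=True,
        )
        total, per = combine_features(spec, sim, target)
        assert total == pytest.approx(0.5 * per["mse"] + 0.5 * per["spike_count"])
        assert min(per.values()) - 1e-12 <= total <= max(per.values()) + 1e-12

    def test_accumulation_over_trace_pairs(self):
        sim, target = self._pair_sets()
        spec = CostSpec(terms=[("mse", 1.0)])
        total, per = combine_features(spec, sim, target)
        parts = [
            pointwise_error("mse", s, x, spec) for s, x in zip(sim, target)
        ]
        assert total == pytest.approx(sum(parts), rel=1e-12)

    def test_unpaired_trace_counts_rejected(self):
        sim, target = self._pair_sets()
        solo = TraceSet(traces=[sim[0]])
        spec = CostSpec(terms=[("mse", 1.0)])
        with pytest.raises(ValueError):
            combine_features(spec, solo, target)

    def test_all_zero_weights_under_normalization_rejected(self):
        sim, target = self._pair_sets()
        spec = CostSpec(terms=[("mse", 0.0)], normalize_weights=True)
        with pytest.raises(ValueError):
            combine_features(spec, sim, target)

    def test_zero_costs_combine_to_zero(self):
        sim, _ = self._pair_sets()
        spec = CostSpec(terms=[("mse", 1.0), ("spike_count", 1.0)])
        total, _ = combine_features(spec, sim, sim)
        assert total == pytest.approx(0.0, abs=1e-14)
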