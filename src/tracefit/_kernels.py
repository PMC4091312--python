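"""Compiled fixed-step integrators for the built-in model backends.

Both kernels use classical 4th-order Runge-Kutta.  Units follow the
usual conventions of each model family:

* Hodgkin-Huxley: V in mV, t in ms, conductance densities in mS/cm^2,
  current densities in uA/cm^2, C_m = 1 uF/cm^2.
* Adaptive exponential integrate-and-fire: V in mV, t in ms, C in nF,
  conductances in uS, currents in nA.
"""

import numpy as np
from numba import njit

# canonical squid-axon reversal potentials (mV) and capacitance (uF/cm^2)
E_NA = 50.0
E_K = -77.0
E_L = -54.3
C_M = 1.0

# rate table resolution (NEURON-style tabulated rate functions)
V_LO = -200.0
V_HI = 200.0
V_STEP = 0.05


@njit(cache=True)
def _hh_rates(v):
    # rate constants (1/ms) of the classical squid-axon model at 6.3 C
    dm = v + 40.0
    if abs(dm) < 1e-7:
        am = 1.0
    else:
        am = 0.1 * dm / (1.0 - np.exp(-dm / 10.0))
    bm = 4.0 * np.exp(-(v + 65.0) / 18.0)
    ah = 0.07 * np.exp(-(v + 65.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    dn = v + 55.0
    if abs(dn) < 1e-7:
        an = 0.1
    else:
        an = 0.01 * dn / (1.0 - np.exp(-dn / 10.0))
    bn = 0.125 * np.exp(-(v + 65.0) / 80.0)
    return am, bm, ah, bh, an, bn


@njit(cache=True)
def hh_steady_state(v):
    am, bm, ah, bh, an, bn = _hh_rates(v)
    return am / (am + bm), ah / (ah + bh), an / (an + bn)


@njit(cache=True)
def _build_rate_table():
    n = int((V_HI - V_LO) / V_STEP) + 1
    tab = np.empty((n, 6))
    for i in range(n):
        am, bm, ah, bh, an, bn = _hh_rates(V_LO + i * V_STEP)
        tab[i, 0] = am
        tab[i, 1] = bm
        tab[i, 2] = ah
        tab[i, 3] = bh
        tab[i, 4] = an
        tab[i, 5] = bn
    return tab


_RATE_TABLE = _build_rate_table()


@njit(cache=True, fastmath=True)
def _hh_deriv(v, m, h, n, gna, gk, gl, i_dens, tab):
    # linearly interpolated rate table inside its range, exact outside
    if V_LO <= v < V_HI:
        x = (v - V_LO) / V_STEP
        i = int(x)
        f = x - i
        am = tab[i, 0] + (tab[i + 1, 0] - tab[i, 0]) * f
        bm = tab[i, 1] + (tab[i + 1, 1] - tab[i, 1]) * f
        ah = tab[i, 2] + (tab[i + 1, 2] - tab[i, 2]) * f
        bh = tab[i, 3] + (tab[i + 1, 3] - tab[i, 3]) * f
        an = tab[i, 4] + (tab[i + 1, 4] - tab[i, 4]) * f
        bn = tab[i, 5] + (tab[i + 1, 5] - tab[i, 5]) * f
    else:
        am, bm, ah, bh, an, bn = _hh_rates(v)
    ina = gna * m * m * m * h * (v - E_NA)
    ik = gk * n * n * n * n * (v - E_K)
    il = gl * (v - E_L)
    dv = (-ina - ik - il + i_dens) / C_M
    dm = am * (1.0 - m) - bm * m
    dh = ah * (1.0 - h) - bh * h
    dn_ = an * (1.0 - n) - bn * n
    return dv, dm, dh, dn_


@njit(cache=True)
def _hh_try(gna, gk, gl, stim, dt, v0, n_sub, v_out, tab):
    """One integration pass with `n_sub` RK4 sub-steps per output step.

    Returns False if the voltage diverges (explicit-scheme instability
    at very large conductance densities), True on success.
    """
    n_pts = stim.size
    v = v0
    m, h, n = hh_steady_state(v0)
    v_out[0] = v
    dts = dt / n_sub
    for i in range(n_pts - 1):
        s = stim[i]
        for _ in range(n_sub):
            k1 = _hh_deriv(v, m, h, n, gna, gk, gl, s, tab)
            k2 = _hh_deriv(
                v + 0.5 * dts * k1[0], m + 0.5 * dts * k1[1],
                h + 0.5 * dts * k1[2], n + 0.5 * dts * k1[3], gna, gk, gl, s, tab,
            )
            k3 = _hh_deriv(
                v + 0.5 * dts * k2[0], m + 0.5 * dts * k2[1],
                h + 0.5 * dts * k2[2], n + 0.5 * dts * k2[3], gna, gk, gl, s, tab,
            )
            k4 = _hh_deriv(
                v + dts * k3[0], m + dts * k3[1],
                h + dts * k3[2], n + dts * k3[3], gna, gk, gl, s, tab,
            )
            v += dts / 6.0 * (k1[0] + 2.0 * k2[0] + 2.0 * k3[0] + k4[0])
            m += dts / 6.0 * (k1[1] + 2.0 * k2[1] + 2.0 * k3[1] + k4[1])
            h += dts / 6.0 * (k1[2] + 2.0 * k2[2] + 2.0 * k3[2] + k4[2])
            n += dts / 6.0 * (k1[3] + 2.0 * k2[3] + 2.0 * k3[3] + k4[3])
            # a near-passive membrane may legitimately ramp to volts;
            # only genuine blow-up triggers sub-stepped retries
            if not np.isfinite(v) or v < -1e6 or v > 1e6:
                return False
        v_out[i + 1] = v
    return True


@njit(cache=True)
def hh_step_rk4(gna, gk, gl, stim, dt, v0):
    """Integrate the single-compartment HH membrane.

    `stim` is the injected current density (uA/cm^2) sampled at every
    output point; `stim[i]` is taken to hold on [t_i, t_{i+1}).  The
    gating variables start at their steady state for `v0`.  If the
    explicit scheme diverges (membrane time constant below the step at
    extreme conductance densities) the pass is retried with doubled
    sub-stepping.  Returns the voltage at the `len(stim)` sample
    points.
    """
    v_out = np.empty(stim.size)
    n_sub = 1
    for _ in range(9):
        if _hh_try(gna, gk, gl, stim, dt, v0, n_sub, v_out, _RATE_TABLE):
            return v_out
        n_sub *= 2
    raise ValueError("HH integration diverged even at 256-fold sub-stepping")


@njit(cache=True)
def hh_membrane_current(v, gna, gk, gl):
    """Instantaneous ionic current density (uA/cm^2) at steady-state gating."""
    m, h, n = hh_steady_state(v)
    return (
        gna * m * m * m * h * (v - E_NA)
        + gk * n * n * n * n * (v - E_K)
        + gl * (v - E_L)
    )


@njit(cache=True)
def _adexp_dv(v, w, gl_, el, vt, dT, i_now, c, exp_cap):
    arg = (v - vt) / dT
    if arg > exp_cap:
        arg = exp_cap
    return (-gl_ * (v - el) + gl_ * dT * np.exp(arg) - w + i_now) / c


@njit(cache=True)
def adexp_rk4(c, gl_, el, vt, vr, tref, dT, a, b, tauw, stim, dt, v0, w0):
    """Adaptive exponential integrate-and-fire with reset and refractoriness.

    When V reaches V_cut = VT + 5*dT the crossing sample is drawn at
    V_cut (so threshold-based detection sees one spike), V is reset to
    Vr and clamped there for `tref` ms while the adaptation current w
    (incremented by b at the spike) keeps evolving.  The exponential
    argument is capped at (V_cut - VT)/dT.  Returns (voltage trace,
    spike times).
    """
    v_cut = vt + 5.0 * dT
    exp_cap = (v_cut - vt) / dT
    n_pts = stim.size
    v_out = np.empty(n_pts)
    spike_times = []
    v = v0
    w = w0
    v_out[0] = v
    refrac_until = -1.0
    t = 0.0
    for i in range(n_pts - 1):
        s = stim[i]
        t = i * dt
        if t < refrac_until:
            # clamped at reset; adaptation still relaxes
            kw1 = (a * (vr - el) - w) / tauw
            w_mid = w + 0.5 * dt * kw1
            kw2 = (a * (vr - el) - w_mid) / tauw
            w += dt * kw2
            v = vr
            v_out[i + 1] = v
            continue
        # RK4 on (V, w)
        k1v = _adexp_dv(v, w, gl_, el, vt, dT, s, c, exp_cap)
        k1w = (a * (v - el) - w) / tauw
        k2v = _adexp_dv(v + 0.5 * dt * k1v, w + 0.5 * dt * k1w, gl_, el, vt, dT, s, c, exp_cap)
        k2w = (a * (v + 0.5 * dt * k1v - el) - (w + 0.5 * dt * k1w)) / tauw
        k3v = _adexp_dv(v + 0.5 * dt * k2v, w + 0.5 * dt * k2w, gl_, el, vt, dT, s, c, exp_cap)
        k3w = (a * (v + 0.5 * dt * k2v - el) - (w + 0.5 * dt * k2w)) / tauw
        k4v = _adexp_dv(v + dt * k3v, w + dt * k3w, gl_, el, vt, dT, s, c, exp_cap)
        k4w = (a * (v + dt * k3v - el) - (w + dt * k3w)) / tauw
        v_new = v + dt / 6.0 * (k1v + 2.0 * k2v + 2.0 * k3v + k4v)
        w_new = w + dt / 6.0 * (k1w + 2.0 * k2w + 2.0 * k3w + k4w)
        if v_new >= v_cut:
            # locate the crossing within the step by linear interpolation
            frac = (v_cut - v) / (v_new - v) if v_new > v else 1.0
            t_spike = t + frac * dt
            spike_times.append(t_spike)
            v_out[i + 1] = v_cut
            v = vr
            w = w_new + b
            refrac_until = t_spike + tref
        else:
            v = v_new
            w = w_new
            v_out[i + 1] = v
    return v_out, np.array(spike_times)
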