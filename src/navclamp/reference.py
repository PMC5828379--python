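"""Fixed-step reference integrator for validating the analytic simulator.

Integrates the three-gate relaxation ODEs with classical 4th-order
Runge-Kutta at a fine fixed step (1 microsecond by default) and records the
current at the acquisition sample times.  The piecewise-analytic stepper in
:mod:`navclamp.protocols` must agree with this integrator to within a small
fraction of the peak current on every protocol; the two paths share no
integration code.

Compiled with numba; the first call pays a JIT cost of a few seconds.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .gating import (
    TAU_H_ANCHOR_DEPOL_MV,
    TAU_H_ANCHOR_HYPER_MV,
    GatingParameterSet,
    equilibrium_state,
)
from .protocols import Sweep, SweepSet, VoltageProtocol

__all__ = ["reference_simulate"]


@njit(cache=False)
def _derivs(v, m, h, s, p):
    act_vh, act_k, fast_vh, fast_k = p[0], p[1], p[2], p[3]
    slow_vh, slow_k, r_in = p[4], p[5], p[6]
    tau_m, tau_hd, tau_hh, tau_floor, tau_s = p[7], p[8], p[9], p[10], p[11]
    m_t = 1.0 / (1.0 + np.exp((act_vh - v) / act_k))
    h_t = 1.0 / (1.0 + np.exp((v - fast_vh) / fast_k))
    s_t = r_in + (1.0 - r_in) / (1.0 + np.exp((v - slow_vh) / slow_k))
    frac = (v - TAU_H_ANCHOR_HYPER_MV) / (TAU_H_ANCHOR_DEPOL_MV - TAU_H_ANCHOR_HYPER_MV)
    if frac < 0.0:
        frac = 0.0
    elif frac > 1.0:
        frac = 1.0
    th = np.exp(np.log(tau_hh) + frac * (np.log(tau_hd) - np.log(tau_hh)))
    if th < tau_floor:
        th = tau_floor
    return (m_t - m) / tau_m, (h_t - h) / th, (s_t - s) / tau_s


@njit(cache=False)
def _integrate_sweep(
    seg_dur, seg_is_ramp, seg_v0, seg_v1, p, g_max, e_rev,
    m0, h0, s0, dt_ms, steps_per_sample, n_samples,
):
    out = np.empty(n_samples)
    m, h, s = m0, h0, s0
    sample_idx = 0
    step_idx = 0
    for j in range(seg_dur.shape[0]):
        n_steps = int(round(seg_dur[j] / dt_ms))
        slope = (seg_v1[j] - seg_v0[j]) / seg_dur[j] if seg_is_ramp[j] else 0.0
        for k in range(n_steps):
            t_loc = k * dt_ms
            v = seg_v0[j] + slope * t_loc
            if step_idx % steps_per_sample == 0 and sample_idx < n_samples:
                out[sample_idx] = g_max * m * h * s * (v - e_rev)
                sample_idx += 1
            v_half = seg_v0[j] + slope * (t_loc + 0.5 * dt_ms)
            v_full = seg_v0[j] + slope * (t_loc + dt_ms)
            k1m, k1h, k1s = _derivs(v, m, h, s, p)
            k2m, k2h, k2s = _derivs(
                v_half, m + 0.5 * dt_ms * k1m, h + 0.5 * dt_ms * k1h, s + 0.5 * dt_ms * k1s, p
            )
            k3m, k3h, k3s = _derivs(
                v_half, m + 0.5 * dt_ms * k2m, h + 0.5 * dt_ms * k2h, s + 0.5 * dt_ms * k2s, p
            )
            k4m, k4h, k4s = _derivs(
                v_full, m + dt_ms * k3m, h + dt_ms * k3h, s + dt_ms * k3s, p
            )
            m += dt_ms / 6.0 * (k1m + 2.0 * k2m + 2.0 * k3m + k4m)
            h += dt_ms / 6.0 * (k1h + 2.0 * k2h + 2.0 * k3h + k4h)
            s += dt_ms / 6.0 * (k1s + 2.0 * k2s + 2.0 * k3s + k4s)
            step_idx += 1
    return out


def reference_simulate(
    protocol: VoltageProtocol,
    p: GatingParameterSet,
    dt_us: float = 1.0,
    sweep_indices=None,
) -> SweepSet:
    """Brute-force RK4 simulation of a protocol at a fine fixed step.

    ``sweep_indices`` restricts the computation to a subset of sweeps
    (all by default).  Output matches the schema of
    :func:`navclamp.protocols.simulate`.
    """
    dt_ms = dt_us * 1e-3
    steps_per_sample = int(round(protocol.dt_ms / dt_ms))
    if abs(steps_per_sample * dt_ms - protocol.dt_ms) > 1e-12:
        raise ValueError("integrator step must divide the sample interval")
    params = np.array(
        [
            p.act_v_half, p.act_k, p.fast_v_half, p.fast_k,
            p.slow_v_half, p.slow_k, p.slow_r_in,
            p.tau_m, p.tau_h_depol, p.tau_h_hyper, p.tau_h_floor, p.tau_s,
        ]
    )
    eq = equilibrium_state(protocol.holding_mv, p)
    indices = list(range(protocol.n_sweeps)) if sweep_indices is None else list(sweep_indices)
    sweeps = []
    for idx in indices:
        segs = protocol.realize(idx)
        seg_dur = np.array([s.duration_ms for s in segs])
        seg_is_ramp = np.array([s.mode == "ramp" for s in segs])
        seg_v0 = np.array([s.v_start for s in segs])
        seg_v1 = np.array([s.v_end for s in segs])
        n_samples = sum(protocol.segment_samples(idx))
        cur = _integrate_sweep(
            seg_dur, seg_is_ramp, seg_v0, seg_v1, params, p.g_max, p.e_rev,
            eq.m, eq.h, eq.s, dt_ms, steps_per_sample, n_samples,
        )
        t, v = protocol.command(idx)
        sweeps.append(
            Sweep(
                index=idx,
                value=float(protocol.sweep_values[idx]),
                time_ms=t,
                command_mv=v,
                current_pa=cur,
            )
        )
    return SweepSet(
        protocol=protocol,
        sweeps=sweeps,
        meta={"group": p.label, "noiseless": True, "cell_id": p.label, "integrator": "rk4"},
    )
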