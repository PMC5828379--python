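"""Declarative voltage-clamp protocols and their noiseless simulation.

A :class:`VoltageProtocol` is a per-sweep sequence of command-voltage
segments (constant steps or linear ramps) with one segment field optionally
varied across sweeps (the step level for conditioning-prepulse protocols,
the segment duration for the two-pulse recovery protocol).  The five
standard characterization protocols — step I-V, steady-state fast
inactivation, steady-state slow inactivation, recovery from inactivation,
and a slow depolarizing ramp — are built by the ``make_*`` factories with
the acquisition conventions used throughout: holding -100 mV, 10-s
intersweep interval, 20 kHz sampling, 5 kHz filtering, P/5 leak
subtraction after the test pulse.

:func:`simulate` produces noiseless sweeps.  Because every gate relaxes as
a first-order process, constant-voltage segments are integrated exactly:
x(t) = x_inf + (x0 - x_inf) * exp(-t / tau).  Ramp segments use
exponential-Euler substeps at the sample interval with the command voltage
evaluated at the substep midpoint.  The 10-s intersweep interval at holding
far exceeds every time constant except tau_s (for which conditioning
effects are the point of the slow protocol), so each sweep starts from
equilibrium at the holding potential.

Segment boundaries are half-open [t_start, t_end): the sample on a
boundary belongs to the later segment.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .gating import GatingParameterSet, equilibrium_state, h_inf, m_inf, s_inf, tau_h

__all__ = [
    "Segment",
    "VoltageProtocol",
    "Sweep",
    "SweepSet",
    "make_step_iv",
    "make_fast_inactivation",
    "make_slow_inactivation",
    "make_recovery",
    "make_ramp",
    "simulate",
    "PROTOCOL_FACTORIES",
]

_MODES = ("step", "ramp")


@dataclass(frozen=True)
class Segment:
    """One command-voltage segment: a constant step or a linear ramp."""

    duration_ms: float
    mode: str
    v_start: float
    v_end: float

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"unknown segment mode {self.mode!r}")
        if self.duration_ms <= 0:
            raise ValueError("segment duration must be positive")
        if self.mode == "step" and self.v_start != self.v_end:
            raise ValueError("step segments need v_start == v_end")

    def voltage_at(self, t_ms):
        """Command voltage at local time(s) ``t_ms`` within the segment."""
        if self.mode == "step":
            return np.full_like(np.asarray(t_ms, dtype=float), self.v_start)
        frac = np.asarray(t_ms, dtype=float) / self.duration_ms
        return self.v_start + (self.v_end - self.v_start) * frac


def step(duration_ms: float, v: float) -> Segment:
    return Segment(duration_ms, "step", v, v)


def ramp(duration_ms: float, v_start: float, v_end: float) -> Segment:
    return Segment(duration_ms, "ramp", v_start, v_end)


@dataclass(frozen=True)
class VoltageProtocol:
    """A declarative multi-sweep command-voltage program.

    ``sweep_segment``/``sweep_field`` name the segment and field that vary
    across sweeps; ``sweep_values`` holds one value per sweep.  A protocol
    with ``sweep_segment=None`` has a single sweep (``sweep_values`` then
    carries one placeholder value).
    """

    name: str
    segments: tuple[Segment, ...]
    sweep_values: tuple[float, ...]
    sweep_segment: int | None = None
    sweep_field: str = "voltage"  # "voltage" | "duration"
    holding_mv: float = -100.0
    intersweep_s: float = 10.0
    leak_sub: str = "p_over_n"
    leak_n: int = 5
    sample_rate_khz: float = 20.0
    filter_cutoff_khz: float = 5.0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        if not self.sweep_values:
            raise ValueError("protocol needs at least one sweep")
        if self.sweep_segment is not None:
            if not 0 <= self.sweep_segment < len(self.segments):
                raise ValueError("sweep_segment out of range")
            if self.sweep_field not in ("voltage", "duration"):
                raise ValueError(f"unknown sweep_field {self.sweep_field!r}")
        vals = np.asarray(self.sweep_values, dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("sweep values must be finite")
        if len(vals) > 1 and not (np.all(np.diff(vals) > 0) or np.all(np.diff(vals) < 0)):
            raise ValueError("sweep values must be strictly ordered")
        if self.leak_sub not in ("none", "p_over_n"):
            raise ValueError(f"unknown leak_sub {self.leak_sub!r}")
        if not self.sample_rate_khz > 2.0 * self.filter_cutoff_khz:
            raise ValueError("sample rate must exceed twice the filter cutoff")

    @property
    def n_sweeps(self) -> int:
        return len(self.sweep_values)

    @property
    def dt_ms(self) -> float:
        return 1.0 / self.sample_rate_khz

    def realize(self, sweep_index: int) -> tuple[Segment, ...]:
        """Concrete segment list for one sweep."""
        value = self.sweep_values[sweep_index]
        if self.sweep_segment is None:
            return self.segments
        segs = list(self.segments)
        target = segs[self.sweep_segment]
        if self.sweep_field == "voltage":
            segs[self.sweep_segment] = dataclasses.replace(
                target, v_start=value, v_end=value
            )
        else:
            segs[self.sweep_segment] = dataclasses.replace(target, duration_ms=value)
        return tuple(segs)

    def segment_samples(self, sweep_index: int) -> list[int]:
        """Number of samples per segment for one sweep."""
        return [
            int(round(seg.duration_ms * self.sample_rate_khz))
            for seg in self.realize(sweep_index)
        ]

    def command(self, sweep_index: int) -> tuple[np.ndarray, np.ndarray]:
        """(time_ms, command_mv) arrays for one sweep (exactly reproducible)."""
        dt = self.dt_ms
        t_parts, v_parts = [], []
        t0 = 0.0
        for seg, n in zip(self.realize(sweep_index), self.segment_samples(sweep_index)):
            t_local = np.arange(n) * dt
            t_parts.append(t0 + t_local)
            v_parts.append(seg.voltage_at(t_local))
            t0 += seg.duration_ms
        return np.concatenate(t_parts), np.concatenate(v_parts)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["segments"] = [dataclasses.asdict(s) for s in self.segments]
        d["sweep_values"] = list(self.sweep_values)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "VoltageProtocol":
        d = dict(d)
        d["segments"] = tuple(Segment(**s) for s in d["segments"])
        d["sweep_values"] = tuple(float(v) for v in d["sweep_values"])
        return cls(**d)


@dataclass
class Sweep:
    """One acquired (or simulated) sweep."""

    index: int
    value: float
    time_ms: np.ndarray
    command_mv: np.ndarray
    current_pa: np.ndarray


@dataclass
class SweepSet:
    """All sweeps of one protocol for one cell, plus acquisition metadata."""

    protocol: VoltageProtocol
    sweeps: list[Sweep]
    meta: dict = field(default_factory=dict)

    def segment_bounds(self, sweep_index: int) -> list[tuple[int, int]]:
        """Half-open sample-index ranges of each segment of one sweep."""
        bounds, i0 = [], 0
        for n in self.protocol.segment_samples(sweep_index):
            bounds.append((i0, i0 + n))
            i0 += n
        return bounds

    def segment_slice(self, sweep_index: int, segment: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(time, command, current) arrays restricted to one segment."""
        i0, i1 = self.segment_bounds(sweep_index)[segment]
        sw = self.sweeps[sweep_index]
        return sw.time_ms[i0:i1], sw.command_mv[i0:i1], sw.current_pa[i0:i1]


def _snap(values: Iterable[float], dt_ms: float) -> tuple[float, ...]:
    """Round durations onto the sampling grid."""
    return tuple(float(np.round(v / dt_ms) * dt_ms) for v in values)


def make_step_iv(
    v_min: float = -80.0,
    v_max: float = 40.0,
    dv: float = 5.0,
    step_ms: float = 50.0,
) -> VoltageProtocol:
    """Step I-V protocol: 50-ms test pulses from -80 to +40 mV in 5-mV steps."""
    values = tuple(np.arange(v_min, v_max + dv / 2, dv))
    return VoltageProtocol(
        name="step_iv",
        segments=(step(step_ms, 0.0),),
        sweep_values=values,
        sweep_segment=0,
        sweep_field="voltage",
    )


def make_fast_inactivation(
    prepulse_ms: float = 500.0,
    pre_min: float = -130.0,
    pre_max: float = -10.0,
    dpre: float = 10.0,
    test_mv: float = -10.0,
    test_ms: float = 20.0,
) -> VoltageProtocol:
    """Steady-state fast inactivation: 500-ms prepulses, then a -10 mV test."""
    values = tuple(np.arange(pre_min, pre_max + dpre / 2, dpre))
    return VoltageProtocol(
        name="fast_inactivation",
        segments=(step(prepulse_ms, 0.0), step(test_ms, test_mv)),
        sweep_values=values,
        sweep_segment=0,
        sweep_field="voltage",
    )


def make_slow_inactivation(
    prepulse_ms: float = 30_000.0,
    pre_min: float = -110.0,
    pre_max: float = 10.0,
    dpre: float = 10.0,
    removal_mv: float = -120.0,
    removal_ms: float = 500.0,
    test_mv: float = -10.0,
    test_ms: float = 20.0,
) -> VoltageProtocol:
    """Steady-state slow inactivation: 30-s prepulses, a -120 mV pulse to
    remove fast inactivation, then a -10 mV test pulse."""
    values = tuple(np.arange(pre_min, pre_max + dpre / 2, dpre))
    return VoltageProtocol(
        name="slow_inactivation",
        segments=(
            step(prepulse_ms, 0.0),
            step(removal_ms, removal_mv),
            step(test_ms, test_mv),
        ),
        sweep_values=values,
        sweep_segment=0,
        sweep_field="voltage",
    )


def make_recovery(
    min_interpulse_ms: float = 1.0,
    max_interpulse_ms: float = 3000.0,
    n_durations: int = 12,
    pulse_ms: float = 20.0,
    pulse_mv: float = -10.0,
    interpulse_mv: float = -100.0,
) -> VoltageProtocol:
    """Recovery from inactivation: two 20-ms -10 mV pulses separated by a
    logarithmic ladder of interpulse durations at the holding potential."""
    proto_dt = 1.0 / 20.0
    values = _snap(
        np.geomspace(min_interpulse_ms, max_interpulse_ms, n_durations), proto_dt
    )
    return VoltageProtocol(
        name="recovery",
        segments=(
            step(pulse_ms, pulse_mv),
            step(1.0, interpulse_mv),
            step(pulse_ms, pulse_mv),
        ),
        sweep_values=values,
        sweep_segment=1,
        sweep_field="duration",
    )


def make_ramp(
    rate_mv_per_ms: float = 0.2,
    v_start: float = -100.0,
    v_end: float = 0.0,
) -> VoltageProtocol:
    """Slow depolarizing ramp (0.2 mV/ms from -100 to 0 mV: 500 ms)."""
    duration = (v_end - v_start) / rate_mv_per_ms
    return VoltageProtocol(
        name="ramp",
        segments=(ramp(duration, v_start, v_end),),
        sweep_values=(0.0,),
        sweep_segment=None,
    )


PROTOCOL_FACTORIES = {
    "step_iv": make_step_iv,
    "fast_inactivation": make_fast_inactivation,
    "slow_inactivation": make_slow_inactivation,
    "recovery": make_recovery,
    "ramp": make_ramp,
}


def _relax_step(seg: Segment, state, n: int, dt: float, p: GatingParameterSet):
    """Exact relaxation over a constant-voltage segment.

    Returns per-sample gate arrays and the end-of-segment state."""
    v = seg.v_start
    targets = (m_inf(v, p), h_inf(v, p), s_inf(v, p))
    taus = (p.tau_m, tau_h(v, p), p.tau_s)
    t_local = np.arange(n) * dt
    gates = []
    end_state = []
    for x0, x_inf_v, tau in zip(state, targets, taus):
        gates.append(x_inf_v + (x0 - x_inf_v) * np.exp(-t_local / tau))
        end_state.append(x_inf_v + (x0 - x_inf_v) * np.exp(-seg.duration_ms / tau))
    v_arr = np.full(n, float(v))
    return v_arr, gates, tuple(end_state)


def _relax_ramp(seg: Segment, state, n: int, dt: float, p: GatingParameterSet):
    """Exponential-Euler substeps over a ramp, midpoint command voltage."""
    t_local = np.arange(n) * dt
    v_arr = np.asarray(seg.voltage_at(t_local), dtype=float)
    v_mid = np.asarray(
        seg.voltage_at(np.minimum(t_local + dt / 2.0, seg.duration_ms)), dtype=float
    )
    m_t = m_inf(v_mid, p)
    h_t = h_inf(v_mid, p)
    s_t = s_inf(v_mid, p)
    a_m = np.exp(-dt / p.tau_m)
    a_h = np.exp(-dt / tau_h(v_mid, p))
    a_s = np.exp(-dt / p.tau_s)
    m = np.empty(n)
    h = np.empty(n)
    s = np.empty(n)
    xm, xh, xs = state
    for i in range(n):
        m[i], h[i], s[i] = xm, xh, xs
        xm = m_t[i] + (xm - m_t[i]) * a_m
        xh = h_t[i] + (xh - h_t[i]) * a_h[i]
        xs = s_t[i] + (xs - s_t[i]) * a_s
    return v_arr, [m, h, s], (xm, xh, xs)


def simulate(protocol: VoltageProtocol, p: GatingParameterSet, meta: dict | None = None) -> SweepSet:
    """Noiseless forward simulation of every sweep of a protocol.

    Each sweep starts from gate equilibrium at the holding potential.
    Constant-voltage segments are solved exactly; ramps use
    exponential-Euler substeps at the sampling interval.
    """
    dt = protocol.dt_ms
    eq = equilibrium_state(protocol.holding_mv, p)
    sweeps: list[Sweep] = []
    for idx in range(protocol.n_sweeps):
        state = (eq.m, eq.h, eq.s)
        t_parts, v_parts, i_parts = [], [], []
        t0 = 0.0
        for seg, n in zip(protocol.realize(idx), protocol.segment_samples(idx)):
            if seg.mode == "step":
                v_arr, gates, state = _relax_step(seg, state, n, dt, p)
            elif seg.mode == "ramp":
                v_arr, gates, state = _relax_ramp(seg, state, n, dt, p)
            else:  # pragma: no cover - Segment already validates
                raise ValueError(f"unknown segment mode {seg.mode!r}")
            m, h, s = gates
            t_parts.append(t0 + np.arange(n) * dt)
            v_parts.append(v_arr)
            i_parts.append(p.g_max * m * h * s * (v_arr - p.e_rev))
            t0 += seg.duration_ms
        sweeps.append(
            Sweep(
                index=idx,
                value=float(protocol.sweep_values[idx]),
                time_ms=np.concatenate(t_parts),
                command_mv=np.concatenate(v_parts),
                current_pa=np.concatenate(i_parts),
            )
        )
    full_meta = {"group": p.label, "noiseless": True, "cell_id": p.label, "seed": None}
    if meta:
        full_meta.update(meta)
    return SweepSet(protocol=protocol, sweeps=sweeps, meta=full_meta)
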