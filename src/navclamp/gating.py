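"""NaV1.7 gating model: equilibrium curves, relaxation kinetics, ionic current.

The channel is described by three independent first-order gates — activation
(``m``), fast inactivation (``h``) and slow inactivation (``s``).  Each gate
relaxes exponentially toward a voltage-dependent steady state; the steady
states are single Boltzmann curves (the slow gate carries an additive
"resistant" fraction ``R_in`` as its lower asymptote).  Membrane current is

    I(V) = g_max * m * h * s * (V - E_rev)

with unit gate exponents, so the model's equilibrium conductance-voltage
relation is itself a Boltzmann curve and round-trips exactly through the
Boltzmann fitting pipeline in :mod:`navclamp.fitting`.

Fast-inactivation kinetics are anchored at two measured points — the decay
time constant of the macroscopic current at a depolarized step (-25 mV) and
the recovery time constant at the holding potential (-100 mV) — and
log-linearly interpolated in voltage between them.  Activation and
slow-inactivation time constants are voltage independent by default
(activation is much faster than inactivation on these protocols; slow
inactivation is probed only with 30-s conditioning pulses).

Parameter sets for the wild-type channel and the M1852T and T1596I variants
are packaged as JSON files and loaded with :func:`load_params`.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = [
    "GatingParameterSet",
    "GateState",
    "PACKAGED_LABELS",
    "TAU_H_ANCHOR_HYPER_MV",
    "TAU_H_ANCHOR_DEPOL_MV",
    "nernst_reversal",
    "m_inf",
    "h_inf",
    "s_inf",
    "tau_h",
    "equilibrium_state",
    "current",
    "load_params",
]

GAS_CONSTANT = 8.31446261815324  # J / (mol K)
FARADAY = 96485.33212  # C / mol

#: Voltages (mV) at which the two fast-inactivation time-constant anchors
#: are measured: recovery at the holding potential, decay at a depolarized
#: step.
TAU_H_ANCHOR_HYPER_MV = -100.0
TAU_H_ANCHOR_DEPOL_MV = -25.0

PACKAGED_LABELS = ("WT", "M1852T", "T1596I")


def nernst_reversal(na_out: float, na_in: float, temp_c: float = 21.0) -> float:
    """Sodium Nernst potential in mV.

    Parameters
    ----------
    na_out, na_in
        External / internal Na+ concentrations (mM). Must be positive.
    temp_c
        Bath temperature in Celsius (default 21 C, room temperature).
    """
    if na_out <= 0 or na_in <= 0:
        raise ValueError("concentrations must be positive")
    t_kelvin = temp_c + 273.15
    return 1e3 * GAS_CONSTANT * t_kelvin / FARADAY * math.log(na_out / na_in)


#: Default reversal potential from the recording solutions
#: (140 mM Na+ external / 10 mM internal, 21 C): about +66.9 mV.
DEFAULT_E_REV_MV = nernst_reversal(140.0, 10.0, 21.0)


@dataclass(frozen=True)
class GatingParameterSet:
    """All gating parameters for one channel group (WT or a variant).

    Voltages in mV, time constants in ms, conductance in nS.  ``slow_r_in``
    is the fraction of channels resistant to slow inactivation (the lower
    asymptote of the slow-inactivation curve).  ``tau_h_depol`` and
    ``tau_h_hyper`` anchor the fast-inactivation time constant at
    -25 mV and -100 mV respectively.
    """

    label: str
    act_v_half: float
    act_k: float
    fast_v_half: float
    fast_k: float
    slow_v_half: float
    slow_k: float
    tau_h_depol: float
    tau_h_hyper: float
    slow_r_in: float = 0.2
    g_max: float = 100.0
    e_rev: float = DEFAULT_E_REV_MV
    tau_m: float = 0.1
    tau_h_floor: float = 0.05
    tau_s: float = 5000.0

    def __post_init__(self) -> None:
        if not (self.act_k > 0 and self.fast_k > 0 and self.slow_k > 0):
            raise ValueError("slope factors must be strictly positive")
        if not 0.0 <= self.slow_r_in <= 1.0:
            raise ValueError("slow_r_in must lie in [0, 1]")
        for name in ("tau_m", "tau_h_depol", "tau_h_hyper", "tau_h_floor", "tau_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.tau_h_depol < self.tau_h_hyper:
            raise ValueError("tau_h_depol must be smaller than tau_h_hyper")
        if self.g_max <= 0:
            raise ValueError("g_max must be positive")

    def replace(self, **changes) -> "GatingParameterSet":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GatingParameterSet":
        d = dict(d)
        if d.get("e_rev") is None:
            d.pop("e_rev", None)
        return cls(**d)


@dataclass(frozen=True)
class GateState:
    """Instantaneous open fractions of the three gates."""

    m: float
    h: float
    s: float

    def __post_init__(self) -> None:
        for name in ("m", "h", "s"):
            x = getattr(self, name)
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"gate {name}={x} outside [0, 1]")


def _maybe_scalar(x: np.ndarray, scalar: bool):
    return float(x) if scalar else x


def m_inf(v, p: GatingParameterSet):
    """Steady-state activation: 1 / (1 + exp((V1/2 - V) / k)).

    Strictly increasing in ``v``, 0.5 at ``act_v_half``.
    """
    v_arr = np.asarray(v, dtype=float)
    out = 1.0 / (1.0 + np.exp((p.act_v_half - v_arr) / p.act_k))
    return _maybe_scalar(out, np.ndim(v) == 0)


def h_inf(v, p: GatingParameterSet):
    """Steady-state fast inactivation: 1 / (1 + exp((V - V1/2) / k)).

    Strictly decreasing in ``v``, 0.5 at ``fast_v_half``.
    """
    v_arr = np.asarray(v, dtype=float)
    out = 1.0 / (1.0 + np.exp((v_arr - p.fast_v_half) / p.fast_k))
    return _maybe_scalar(out, np.ndim(v) == 0)


def s_inf(v, p: GatingParameterSet):
    """Steady-state slow inactivation with a resistant floor.

    R_in + (1 - R_in) / (1 + exp((V - V1/2) / k)); decreases from 1 to
    ``slow_r_in``.
    """
    v_arr = np.asarray(v, dtype=float)
    boltz = 1.0 / (1.0 + np.exp((v_arr - p.slow_v_half) / p.slow_k))
    out = p.slow_r_in + (1.0 - p.slow_r_in) * boltz
    return _maybe_scalar(out, np.ndim(v) == 0)


def tau_h(v, p: GatingParameterSet):
    """Fast-inactivation time constant (ms), log-linear between anchors.

    Passes exactly through (``-100 mV``, ``tau_h_hyper``) and
    (``-25 mV``, ``tau_h_depol``); clamped to the anchor values outside
    that range and floored at ``tau_h_floor``.
    """
    v_arr = np.asarray(v, dtype=float)
    frac = (v_arr - TAU_H_ANCHOR_HYPER_MV) / (
        TAU_H_ANCHOR_DEPOL_MV - TAU_H_ANCHOR_HYPER_MV
    )
    frac = np.clip(frac, 0.0, 1.0)
    log_tau = math.log(p.tau_h_hyper) + frac * (
        math.log(p.tau_h_depol) - math.log(p.tau_h_hyper)
    )
    out = np.maximum(np.exp(log_tau), p.tau_h_floor)
    return _maybe_scalar(out, np.ndim(v) == 0)


def equilibrium_state(v: float, p: GatingParameterSet) -> GateState:
    """Gate state after infinitely long conditioning at voltage ``v``."""
    return GateState(m=m_inf(v, p), h=h_inf(v, p), s=s_inf(v, p))


def current(v, g: GateState, p: GatingParameterSet):
    """Instantaneous current I = g_max * m * h * s * (V - E_rev), in pA.

    With ``g_max`` in nS and voltages in mV the product is directly in pA.
    Inward current is negative (V below E_rev with open gates).
    """
    v_arr = np.asarray(v, dtype=float)
    out = p.g_max * g.m * g.h * g.s * (v_arr - p.e_rev)
    return _maybe_scalar(out, np.ndim(v) == 0)


def load_params(label: str) -> GatingParameterSet:
    """Load a packaged parameter set by group label (case-insensitive).

    Available labels: ``WT``, ``M1852T``, ``T1596I``.
    """
    key = label.strip().upper()
    if key not in PACKAGED_LABELS:
        raise KeyError(f"no packaged parameter set {label!r}; have {PACKAGED_LABELS}")
    fname = key.lower() + ".json"
    text = resources.files("navclamp").joinpath("params", fname).read_text()
    return GatingParameterSet.from_dict(json.loads(text))
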