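"""Curve-fitting analysis of voltage-clamp sweeps.

Implements the standard whole-cell characterization pipeline: peak-current
extraction, the combined Boltzmann-ohmic I-V fit, normalized
conductance-voltage (activation) and availability (fast / slow
inactivation) Boltzmann fits, single-exponential decay and recovery
kinetics, window-current metrics from the fitted activation /
fast-inactivation overlap, and ramp-current metrics.

Model forms
-----------
I-V:              I(V) = g_max * (V - E_rev) / (1 + exp((V1/2 - V) / k))
activation:       G/G_max = a / (1 + exp((V1/2 - V) / k))
fast inact.:      I/I_max = a / (1 + exp((V - V1/2) / k))
slow inact.:      I/I_max = a * (R_in + (1 - R_in) / (1 + exp((V - V1/2) / k)))
decay:            I(t) = A * exp(-(t - t0) / tau) + C
recovery:         R(dt) = 1 - A * exp(-dt / tau)

The normalized fits carry a free amplitude ``a`` so that normalization to
the maximum observed point (rather than an asymptote) does not bias V1/2
or k.  All fits are nonlinear least squares with heuristic initialization
and bounds k in (0.1, 50] mV, R_in in [0, 1], tau in (0.01, 1e4] ms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .protocols import SweepSet

__all__ = [
    "BoltzmannFit",
    "ExponentialFit",
    "extract_peaks",
    "fit_iv",
    "conductance_transform",
    "fit_activation",
    "fit_fast_inact",
    "fit_slow_inact",
    "availability_table",
    "fit_decay_tau",
    "fit_recovery",
    "window_metrics",
    "ramp_metrics",
    "characterize_cell",
]

K_BOUNDS = (0.1, 50.0)
TAU_BOUNDS = (0.01, 1.0e4)


@dataclass
class BoltzmannFit:
    """Fitted Boltzmann parameters with diagnostics."""

    v_half: float
    k: float
    g_max: float = np.nan  # I-V fit only (nS)
    e_rev: float = np.nan  # I-V fit only (mV)
    r_in: float = np.nan  # slow-inactivation fit only
    amplitude: float = np.nan  # normalized fits
    rss: float = np.nan
    converged: bool = False
    n_points: int = 0


@dataclass
class ExponentialFit:
    """Single-exponential fit (decay or recovery) with diagnostics."""

    tau: float
    amplitude: float
    offset: float = np.nan
    fit_window: tuple[float, float] = (np.nan, np.nan)
    rss: float = np.nan
    converged: bool = False
    n_points: int = 0
    monotonic: bool = True  # recovery only: R(dt) non-decreasing within tol


def extract_peaks(ss: SweepSet, segment: int, settle_ms: float = 0.2) -> pd.DataFrame:
    """Peak current per sweep within one segment.

    The peak is the extremum of largest magnitude after skipping an initial
    settle margin (default 0.2 ms); inward peaks are negative.  Returns an
    IV table with columns ``voltage_mv`` (the sweep variable), ``peak_pa``
    and ``t_peak_ms``, sorted by voltage.
    """
    dt = ss.protocol.dt_ms
    skip = int(round(settle_ms / dt))
    rows = []
    for sw in ss.sweeps:
        i0, i1 = ss.segment_bounds(sw.index)[segment]
        lo = min(i0 + skip, i1 - 1)
        seg_i = sw.current_pa[lo:i1]
        k = int(np.argmax(np.abs(seg_i)))
        rows.append(
            {
                "voltage_mv": sw.value,
                "peak_pa": float(seg_i[k]),
                "t_peak_ms": float(sw.time_ms[lo + k]),
            }
        )
    df = pd.DataFrame(rows).sort_values("voltage_mv", ignore_index=True)
    if df["voltage_mv"].duplicated().any():
        raise ValueError("duplicate sweep voltages in IV table")
    return df


def _finite_pcov(pcov) -> bool:
    return pcov is not None and np.all(np.isfinite(pcov))


def _iv_model(v, g, e, vh, k):
    return g * (v - e) / (1.0 + np.exp((vh - v) / k))


def fit_iv(iv: pd.DataFrame) -> BoltzmannFit:
    """Combined Boltzmann-ohmic fit of a peak I-V table."""
    v = iv["voltage_mv"].to_numpy(dtype=float)
    i = iv["peak_pa"].to_numpy(dtype=float)
    if len(v) < 6:
        raise ValueError("need at least 6 I-V points")
    abs_i = np.abs(i)
    i_pk = int(np.argmax(abs_i))
    # reversal initializer: zero crossing beyond the peak, else linear
    # extrapolation through the last two points
    e0 = None
    for j in range(i_pk, len(v) - 1):
        if i[j] != 0 and np.sign(i[j]) != np.sign(i[j + 1]):
            e0 = v[j] - i[j] * (v[j + 1] - v[j]) / (i[j + 1] - i[j])
            break
    if e0 is None:
        slope = (i[-1] - i[-2]) / (v[-1] - v[-2])
        e0 = v[-1] - i[-1] / slope if slope != 0 else v[-1] + 20.0
    e0 = float(np.clip(e0, v[i_pk] + 5.0, 150.0))
    # half-activation initializer: rising-limb half-magnitude crossing
    half = abs_i[i_pk] / 2.0
    vh0 = v[i_pk] - 10.0
    for j in range(i_pk):
        if abs_i[j] <= half <= abs_i[j + 1]:
            frac = (half - abs_i[j]) / max(abs_i[j + 1] - abs_i[j], 1e-30)
            vh0 = v[j] + frac * (v[j + 1] - v[j])
            break
    k0 = 0.0625 * (v[-1] - v[0])
    g0 = abs_i[i_pk] / max(e0 - v[i_pk], 5.0)
    p0 = [g0, e0, vh0, np.clip(k0, *K_BOUNDS)]
    bounds = ([1e-9, v[i_pk] + 1.0, -120.0, K_BOUNDS[0]], [1e6, 200.0, 60.0, K_BOUNDS[1]])
    try:
        popt, pcov = curve_fit(_iv_model, v, i, p0=p0, bounds=bounds, maxfev=20000)
        rss = float(np.sum((_iv_model(v, *popt) - i) ** 2))
        return BoltzmannFit(
            v_half=float(popt[2]),
            k=float(popt[3]),
            g_max=float(popt[0]),
            e_rev=float(popt[1]),
            rss=rss,
            converged=_finite_pcov(pcov),
            n_points=len(v),
        )
    except RuntimeError:
        return BoltzmannFit(v_half=np.nan, k=np.nan, converged=False, n_points=len(v))


def conductance_transform(iv: pd.DataFrame, e_rev: float, exclude_mv: float = 1.0) -> pd.DataFrame:
    """Normalized conductance-voltage table: G = I / (V - E_rev), G/G_max.

    Voltages within ``exclude_mv`` of the reversal potential are dropped
    (the division is ill-conditioned there).  Negative conductances are
    clipped to zero and flagged in the ``clipped`` column, never silently
    removed.
    """
    v = iv["voltage_mv"].to_numpy(dtype=float)
    i = iv["peak_pa"].to_numpy(dtype=float)
    keep = np.abs(v - e_rev) >= exclude_mv
    v, i = v[keep], i[keep]
    g = i / (v - e_rev)
    clipped = g < 0
    g = np.where(clipped, 0.0, g)
    g_max = g.max()
    if g_max <= 0:
        raise ValueError("no positive conductance values")
    return pd.DataFrame(
        {"voltage_mv": v, "g_norm": g / g_max, "clipped": clipped}
    )


def _rising_boltzmann(v, a, vh, k):
    return a / (1.0 + np.exp((vh - v) / k))


def _falling_boltzmann(v, a, vh, k):
    return a / (1.0 + np.exp((v - vh) / k))


def _slow_boltzmann(v, a, r, vh, k):
    return a * (r + (1.0 - r) / (1.0 + np.exp((v - vh) / k)))


def _half_crossing(v, y, rising: bool) -> float:
    """Voltage where a normalized curve crosses half of its range."""
    half = (y.max() + y.min()) / 2.0
    yy = y if rising else y[::-1]
    vv = v if rising else v[::-1]
    for j in range(len(vv) - 1):
        if (yy[j] - half) * (yy[j + 1] - half) <= 0:
            frac = (half - yy[j]) / max(abs(yy[j + 1] - yy[j]), 1e-30) * np.sign(
                yy[j + 1] - yy[j]
            )
            return float(vv[j] + frac * (vv[j + 1] - vv[j]))
    return float(np.median(v))


def _fit_norm_boltzmann(v, y, model, p0, bounds, n_extra=0) -> BoltzmannFit:
    if len(v) < 6:
        raise ValueError("need at least 6 points")
    if np.any(y < -0.01) or np.any(y > 1.05):
        raise ValueError("normalized values must lie in [0, 1.05]")
    try:
        popt, pcov = curve_fit(model, v, y, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError:
        return BoltzmannFit(v_half=np.nan, k=np.nan, converged=False, n_points=len(v))
    rss = float(np.sum((model(v, *popt) - y) ** 2))
    if n_extra:  # slow fit: (a, r, vh, k)
        return BoltzmannFit(
            v_half=float(popt[2]),
            k=float(popt[3]),
            r_in=float(popt[1]),
            amplitude=float(popt[0]),
            rss=rss,
            converged=_finite_pcov(pcov),
            n_points=len(v),
        )
    return BoltzmannFit(
        v_half=float(popt[1]),
        k=float(popt[2]),
        amplitude=float(popt[0]),
        rss=rss,
        converged=_finite_pcov(pcov),
        n_points=len(v),
    )


def fit_activation(gv: pd.DataFrame) -> BoltzmannFit:
    """Boltzmann fit of a normalized G-V table (columns voltage_mv, g_norm)."""
    v = gv["voltage_mv"].to_numpy(dtype=float)
    y = gv["g_norm"].to_numpy(dtype=float)
    p0 = [1.0, _half_crossing(v, y, rising=True), 5.0]
    bounds = ([0.2, -120.0, K_BOUNDS[0]], [1.5, 60.0, K_BOUNDS[1]])
    return _fit_norm_boltzmann(v, y, _rising_boltzmann, p0, bounds)


def fit_fast_inact(avail: pd.DataFrame) -> BoltzmannFit:
    """Boltzmann fit of normalized availability after 500-ms prepulses
    (columns voltage_mv, availability)."""
    v = avail["voltage_mv"].to_numpy(dtype=float)
    y = avail["availability"].to_numpy(dtype=float)
    p0 = [1.0, _half_crossing(v, y, rising=False), 6.0]
    bounds = ([0.2, -150.0, K_BOUNDS[0]], [1.5, 20.0, K_BOUNDS[1]])
    return _fit_norm_boltzmann(v, y, _falling_boltzmann, p0, bounds)


def fit_slow_inact(avail: pd.DataFrame) -> BoltzmannFit:
    """Boltzmann-with-resistant-fraction fit of availability after 30-s
    prepulses; estimates R_in jointly."""
    v = avail["voltage_mv"].to_numpy(dtype=float)
    y = avail["availability"].to_numpy(dtype=float)
    r0 = float(np.clip(y.min(), 0.0, 0.9))
    p0 = [1.0, r0, _half_crossing(v, y, rising=False), 12.0]
    bounds = ([0.2, 0.0, -150.0, K_BOUNDS[0]], [1.5, 1.0, 40.0, K_BOUNDS[1]])
    return _fit_norm_boltzmann(v, y, _slow_boltzmann, p0, bounds, n_extra=1)


def availability_table(ss: SweepSet, test_segment: int, settle_ms: float = 0.2) -> pd.DataFrame:
    """Test-pulse peaks normalized to the maximum across sweeps."""
    peaks = extract_peaks(ss, segment=test_segment, settle_ms=settle_ms)
    mag = np.abs(peaks["peak_pa"].to_numpy())
    norm = mag.max()
    if norm <= 0:
        raise ValueError("all test-pulse peaks are zero")
    return pd.DataFrame(
        {"voltage_mv": peaks["voltage_mv"], "availability": mag / norm}
    )


def _decay_model(t, a, tau, c):
    return a * np.exp(-t / tau) + c


def fit_decay_tau(
    ss: SweepSet,
    voltages,
    segment: int = 0,
    post_peak_ms: float = 0.5,
    settle_ms: float = 0.2,
) -> dict[float, ExponentialFit]:
    """Single-exponential (with offset) fits of the current decay after the
    peak, at the requested step voltages.

    The fit window runs from 0.5 ms after the peak to the segment end.
    """
    dt = ss.protocol.dt_ms
    out: dict[float, ExponentialFit] = {}
    values = np.array([sw.value for sw in ss.sweeps])
    for v_target in np.atleast_1d(voltages):
        idx = int(np.argmin(np.abs(values - v_target)))
        if abs(values[idx] - v_target) > 1e-6:
            raise KeyError(f"no sweep at {v_target} mV")
        sw = ss.sweeps[idx]
        i0, i1 = ss.segment_bounds(idx)[segment]
        skip = int(round(settle_ms / dt))
        seg_i = sw.current_pa[i0:i1]
        pk_rel = int(np.argmax(np.abs(seg_i[skip:]))) + skip
        start = i0 + pk_rel + int(round(post_peak_ms / dt))
        t = sw.time_ms[start:i1]
        y = sw.current_pa[start:i1]
        if len(t) < 20:
            raise ValueError("decay segment needs >= 20 samples after the peak")
        window = (float(t[0]), float(t[-1]))
        rng_y = float(y.max() - y.min())
        if rng_y < 1e-12:
            out[float(v_target)] = ExponentialFit(
                tau=np.nan, amplitude=np.nan, offset=float(y.mean()),
                fit_window=window, converged=False, n_points=len(t),
            )
            continue
        t_rel = t - t[0]
        c0 = float(np.mean(y[-max(len(y) // 10, 1):]))
        a0 = float(y[0] - c0)
        # time for the decay to shrink by 1/e of its initial range
        target = c0 + a0 / np.e
        crossings = np.nonzero((y[:-1] - target) * (y[1:] - target) <= 0)[0]
        tau0 = float(t_rel[crossings[0]]) if len(crossings) else float(t_rel[-1] / 3)
        tau0 = float(np.clip(tau0, TAU_BOUNDS[0] * 2, TAU_BOUNDS[1] / 2))
        lo = [-np.inf, TAU_BOUNDS[0], -np.inf]
        hi = [np.inf, TAU_BOUNDS[1], np.inf]
        try:
            popt, pcov = curve_fit(
                _decay_model, t_rel, y, p0=[a0, tau0, c0], bounds=(lo, hi), maxfev=20000
            )
            rss = float(np.sum((_decay_model(t_rel, *popt) - y) ** 2))
            out[float(v_target)] = ExponentialFit(
                tau=float(popt[1]), amplitude=float(popt[0]), offset=float(popt[2]),
                fit_window=window, rss=rss, converged=_finite_pcov(pcov),
                n_points=len(t),
            )
        except RuntimeError:
            out[float(v_target)] = ExponentialFit(
                tau=np.nan, amplitude=np.nan, offset=np.nan,
                fit_window=window, converged=False, n_points=len(t),
            )
    return out


def _recovery_model(dt_ms, a, tau):
    return 1.0 - a * np.exp(-dt_ms / tau)


def fit_recovery(ss: SweepSet, settle_ms: float = 0.2, monotonic_tol: float = 0.02) -> ExponentialFit:
    """Exponential fit of the recovery fraction from a two-pulse protocol.

    The recovery fraction is the second-pulse peak divided by the
    first-pulse peak, clipped to [0, 1.05], fitted with
    R(dt) = 1 - A * exp(-dt / tau).  A violation of monotonicity beyond
    ``monotonic_tol`` sets ``monotonic=False`` and emits a warning.
    """
    if ss.protocol.n_sweeps < 6:
        raise ValueError("need at least 6 interpulse durations")
    p1 = extract_peaks(ss, segment=0, settle_ms=settle_ms)
    p2 = extract_peaks(ss, segment=2, settle_ms=settle_ms)
    # extract_peaks sorts by the sweep variable (the interpulse duration)
    dts = p1["voltage_mv"].to_numpy(dtype=float)
    r = np.abs(p2["peak_pa"].to_numpy()) / np.abs(p1["peak_pa"].to_numpy())
    r = np.clip(r, 0.0, 1.05)
    monotonic = bool(np.all(np.diff(r) >= -monotonic_tol))
    if not monotonic:
        warnings.warn("recovery fraction is non-monotone beyond tolerance", stacklevel=2)
    a0 = float(np.clip(1.0 - r.min(), 0.05, 1.0))
    # interpulse duration at which ~63% of the recovery has occurred
    target = 1.0 - a0 / np.e
    above = np.nonzero(r >= target)[0]
    tau0 = float(dts[above[0]]) if len(above) else float(dts[-1] / 3)
    try:
        popt, pcov = curve_fit(
            _recovery_model, dts, r, p0=[a0, tau0],
            bounds=([0.0, TAU_BOUNDS[0]], [1.5, TAU_BOUNDS[1]]), maxfev=20000,
        )
        rss = float(np.sum((_recovery_model(dts, *popt) - r) ** 2))
        return ExponentialFit(
            tau=float(popt[1]), amplitude=float(popt[0]), offset=1.0,
            fit_window=(float(dts[0]), float(dts[-1])), rss=rss,
            converged=_finite_pcov(pcov), n_points=len(dts), monotonic=monotonic,
        )
    except RuntimeError:
        return ExponentialFit(
            tau=np.nan, amplitude=np.nan, converged=False,
            n_points=len(dts), monotonic=monotonic,
        )


def window_metrics(
    act: BoltzmannFit,
    fast: BoltzmannFit,
    v_min: float = -100.0,
    v_max: float = 40.0,
    dv: float = 0.1,
) -> dict[str, float]:
    """Window-current metrics from fitted activation / fast-inactivation
    curves (unit-amplitude Boltzmanns).

    Returns the overlap area integral min(act, fast) dV (mV * fraction,
    trapezoid on a 0.1-mV grid), the peak of the product act*fast, and the
    voltage at that peak.
    """
    v = np.arange(v_min, v_max + dv / 2, dv)
    act_curve = 1.0 / (1.0 + np.exp((act.v_half - v) / act.k))
    fast_curve = 1.0 / (1.0 + np.exp((v - fast.v_half) / fast.k))
    overlap = float(np.trapezoid(np.minimum(act_curve, fast_curve), v))
    product = act_curve * fast_curve
    j = int(np.argmax(product))
    return {
        "overlap_area": overlap,
        "peak_product": float(product[j]),
        "v_at_peak": float(v[j]),
    }


def ramp_metrics(ramp_ss: SweepSet, reference_imax: float) -> dict[str, float]:
    """Peak inward ramp current as a percentage of the maximal peak inward
    current of the step protocol, and the voltage at that peak."""
    if reference_imax == 0:
        raise ValueError("reference_imax must be nonzero")
    sw = ramp_ss.sweeps[0]
    j = int(np.argmin(sw.current_pa))
    peak = sw.current_pa[j]
    pct = 100.0 * max(-peak, 0.0) / abs(reference_imax)
    return {"peak_pct": float(pct), "v_at_peak": float(sw.command_mv[j])}


def characterize_cell(
    sweepsets: dict[str, SweepSet],
    decay_voltages=(-25.0,),
) -> dict[str, float]:
    """Run the full fitting pipeline on whichever protocols are present.

    ``sweepsets`` maps protocol names (``step_iv``, ``fast_inactivation``,
    ``slow_inactivation``, ``recovery``, ``ramp``) to their SweepSets.
    Returns a flat dict of fitted quantities.
    """
    out: dict[str, float] = {}
    iv_fit = None
    peaks = None
    if "step_iv" in sweepsets:
        ss = sweepsets["step_iv"]
        peaks = extract_peaks(ss, segment=0)
        iv_fit = fit_iv(peaks)
        out.update(
            iv_v_half=iv_fit.v_half, iv_k=iv_fit.k,
            iv_g_max=iv_fit.g_max, iv_e_rev=iv_fit.e_rev,
        )
        gv = conductance_transform(peaks, e_rev=iv_fit.e_rev)
        act = fit_activation(gv)
        out.update(act_v_half=act.v_half, act_k=act.k)
        for v_dec, f in fit_decay_tau(ss, decay_voltages).items():
            out[f"decay_tau_{v_dec:g}mV"] = f.tau
    fast = None
    if "fast_inactivation" in sweepsets:
        avail = availability_table(sweepsets["fast_inactivation"], test_segment=1)
        fast = fit_fast_inact(avail)
        out.update(fast_v_half=fast.v_half, fast_k=fast.k)
    if "slow_inactivation" in sweepsets:
        avail = availability_table(sweepsets["slow_inactivation"], test_segment=2)
        slow = fit_slow_inact(avail)
        out.update(slow_v_half=slow.v_half, slow_k=slow.k, slow_r_in=slow.r_in)
    if "recovery" in sweepsets:
        rec = fit_recovery(sweepsets["recovery"])
        out.update(recovery_tau=rec.tau, recovery_amp=rec.amplitude)
    if "step_iv" in sweepsets and fast is not None:
        gv = conductance_transform(peaks, e_rev=iv_fit.e_rev)
        act = fit_activation(gv)
        wm = window_metrics(act, fast)
        out.update(
            window_overlap=wm["overlap_area"],
            window_peak_product=wm["peak_product"],
            window_v_peak=wm["v_at_peak"],
        )
    if "ramp" in sweepsets and peaks is not None:
        ref = float(peaks["peak_pa"].min())
        rm = ramp_metrics(sweepsets["ramp"], reference_imax=ref)
        out.update(ramp_peak_pct=rm["peak_pct"], ramp_v_peak=rm["v_at_peak"])
    return out
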