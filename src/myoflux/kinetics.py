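"""Per-transient kinetics: amplitudes, mono-exponential decay rates and APD.

The decay of both the systolic and the caffeine-evoked Ca transient is
described by a single exponential ``A*exp(-k*t) + C``; the SR-dependent
removal rate is obtained per cell by subtraction, k_SR = k_sys - k_caff
(SERCA removal is what the systolic decay has over and above sarcolemmal
extrusion). Fits are least squares with an explicit acceptance gate: k must
be positive and the residual RMSE below a configured fraction of the fitted
amplitude, otherwise the fit is flagged rather than used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

log = logging.getLogger(__name__)


class KineticsError(ValueError):
    pass


@dataclass
class DecayFit:
    """Result of a mono-exponential decay fit."""

    k: float  # 1/s
    amplitude: float  # fitted A, signal units
    offset: float  # fitted C, signal units
    rmse: float
    window: tuple  # (t_start, t_end), s
    ok: bool = True
    reason: str = ""


@dataclass
class TransientMetrics:
    diastolic_ca: float  # nmol/l
    peak_ca: float  # nmol/l
    amplitude: float  # nmol/l
    k_decay: Optional[float]  # 1/s, None if the decay fit was rejected
    fit_rmse: Optional[float]
    fit_window: Optional[tuple]
    flags: list = field(default_factory=list)


@dataclass
class RateDecomposition:
    k_sys: float
    k_caff: float
    k_sr: float
    k_pmca: Optional[float] = None
    flags: list = field(default_factory=list)


def _mono_exp(t, a, k, c):
    return a * np.exp(-k * t) + c


def fit_mono_exponential_decay(t, y, window: Optional[tuple] = None,
                               rmse_frac_max: float = 0.10,
                               min_samples: int = 20) -> DecayFit:
    """Least-squares fit of ``A*exp(-k*t) + C`` to a decay phase.

    ``window`` restricts the fit to t in [t0, t1]. Degenerate inputs
    (flat or non-decreasing series) and poor fits are returned flagged,
    never silently accepted; fewer than ``min_samples`` samples raises.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if window is not None:
        m = (t >= window[0]) & (t <= window[1])
        t, y = t[m], y[m]
    m = np.isfinite(y)
    t, y = t[m], y[m]
    if t.size < min_samples:
        raise KineticsError(f"decay fit needs >= {min_samples} samples, got {t.size}")
    win = (float(t[0]), float(t[-1]))
    rng_y = float(np.max(y) - np.min(y))
    scale = max(abs(float(np.mean(y))), 1.0)
    if rng_y < 1e-9 * scale or y[-1] >= y[0]:
        return DecayFit(k=np.nan, amplitude=0.0, offset=float(np.mean(y)),
                        rmse=float(np.std(y)), window=win, ok=False,
                        reason="signal not decreasing")

    ts = t - t[0]
    c0 = float(y[-1]) - 0.05 * rng_y
    a0 = float(y[0]) - c0
    # log-linear initial slope estimate on the upper part of the decay
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.log(np.maximum(y - c0, 1e-12 * rng_y))
    k0 = max(-np.polyfit(ts, z, 1)[0], 1e-3)
    try:
        popt, _ = curve_fit(_mono_exp, ts, y, p0=(a0, k0, c0), maxfev=20000)
    except RuntimeError as exc:
        return DecayFit(k=np.nan, amplitude=np.nan, offset=np.nan, rmse=np.nan,
                        window=win, ok=False, reason=f"non-convergence: {exc}")
    a, k, c = (float(v) for v in popt)
    rmse = float(np.sqrt(np.mean((_mono_exp(ts, *popt) - y) ** 2)))
    fit = DecayFit(k=k, amplitude=a, offset=c, rmse=rmse, window=win)
    if k <= 0:
        fit.ok, fit.reason = False, "non-positive rate constant"
    elif a <= 0:
        fit.ok, fit.reason = False, "non-positive amplitude"
    elif rmse > rmse_frac_max * abs(a):
        fit.ok, fit.reason = False, f"rmse {rmse:.3g} > {rmse_frac_max:.2f} x amplitude"
    return fit


def decay_window(t, y, peak_idx: int, hi_frac: float = 0.90, lo_frac: float = 0.10,
                 baseline: Optional[float] = None) -> tuple:
    """Fit window from where the signal has fallen to ``hi_frac`` of its
    amplitude above baseline down to ``lo_frac`` (avoids the release tail
    and the noisy plateau)."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if baseline is None:
        baseline = float(np.nanmin(y[peak_idx:]))
    amp = float(y[peak_idx]) - baseline
    post = y[peak_idx:]
    hi_level = baseline + hi_frac * amp
    lo_level = baseline + lo_frac * amp
    below_hi = np.flatnonzero(post <= hi_level)
    i0 = peak_idx + (int(below_hi[0]) if below_hi.size else 0)
    below_lo = np.flatnonzero(post <= lo_level)
    i1 = peak_idx + (int(below_lo[0]) if below_lo.size else post.size - 1)
    return float(t[i0]), float(t[max(i1, i0 + 1)])


def transient_metrics(t, ca, stim_times: Sequence[float],
                      pre_window_s: float = 0.2, post_window_s: float = 0.3,
                      fit_hi_frac: float = 0.90, fit_lo_frac: float = 0.10,
                      rmse_frac_max: float = 0.10,
                      fit_start_min_s: float = 0.0) -> list:
    """Amplitude, diastolic level and decay rate for each stimulated beat.

    diastolic = mean over the pre-stimulus window; peak = max within the
    post-stimulus window; amplitude = difference. The decay fit runs from
    the 90% to the 10% amplitude level after the peak;
    ``fit_start_min_s`` (relative to the stimulus) additionally delays the
    fit start, e.g. past the depolarising step so the decay is not
    contaminated by ongoing L-type entry.
    """
    t = np.asarray(t, dtype=float)
    ca = np.asarray(ca, dtype=float)
    if len(stim_times) < 1:
        raise KineticsError("at least one stimulus time is required")
    out = []
    for ts in stim_times:
        if ts < t[0] or ts > t[-1]:
            raise KineticsError(f"stimulus at t={ts}s lies outside the trace")
        pre = (t >= ts - pre_window_s) & (t < ts)
        post = (t >= ts) & (t <= ts + post_window_s)
        if not pre.any() or not post.any():
            raise KineticsError(f"empty analysis window around stimulus t={ts}s")
        dia = float(np.nanmean(ca[pre]))
        ipk = int(np.flatnonzero(post)[np.nanargmax(ca[post])])
        peak = float(ca[ipk])
        amp = peak - dia
        flags = []
        k = rmse = win = None
        if amp <= 0:
            flags.append("non-positive amplitude")
            amp = max(amp, 0.0)
        else:
            try:
                win = decay_window(t, ca, ipk, fit_hi_frac, fit_lo_frac, baseline=dia)
                win = (max(win[0], ts + fit_start_min_s), win[1])
                fit = fit_mono_exponential_decay(t, ca, window=win,
                                                 rmse_frac_max=rmse_frac_max)
                if fit.ok:
                    k, rmse = fit.k, fit.rmse
                else:
                    flags.append(f"decay fit rejected: {fit.reason}")
                    rmse = fit.rmse
            except KineticsError as exc:
                flags.append(f"decay fit unavailable: {exc}")
        out.append(TransientMetrics(diastolic_ca=dia, peak_ca=peak, amplitude=amp,
                                    k_decay=k, fit_rmse=rmse, fit_window=win,
                                    flags=flags))
    return out


def decompose_rates(k_sys: float, k_caff: float,
                    k_pmca: Optional[float] = None) -> RateDecomposition:
    """SR-dependent removal rate by subtraction: k_SR = k_sys - k_caff.

    A negative k_SR is flagged, not clamped — it indicates inconsistent
    fits, which the caller should inspect rather than hide.
    """
    k_sr = k_sys - k_caff
    flags = []
    if k_sr < 0:
        flags.append("negative k_SR (k_caff exceeds k_sys)")
    return RateDecomposition(k_sys=k_sys, k_caff=k_caff, k_sr=k_sr,
                             k_pmca=k_pmca, flags=flags)


def apd(t, vm, fraction: float = 0.9) -> float:
    """Action-potential duration (ms) at the given repolarisation fraction.

    Measured from the point of maximum upstroke velocity to the first
    crossing of ``peak - fraction*(peak - baseline)``, with linear
    interpolation between samples.
    """
    t = np.asarray(t, dtype=float)
    vm = np.asarray(vm, dtype=float)
    if not (0.0 < fraction < 1.0):
        raise KineticsError("fraction must lie in (0, 1)")
    if vm.size < 3:
        raise KineticsError("trace too short for APD measurement")
    dv = np.diff(vm)
    iup = int(np.argmax(dv)) + 1  # first sample at/after the fastest upstroke
    baseline = float(np.median(vm[:max(iup - 1, 1)]))
    ipk = iup + int(np.argmax(vm[iup:]))
    peak = float(vm[ipk])
    level = peak - fraction * (peak - baseline)
    below = np.flatnonzero(vm[ipk:] <= level)
    if below.size == 0:
        raise KineticsError(f"repolarisation never crosses the {fraction:.0%} level")
    j = ipk + int(below[0])
    if j == ipk:
        t_cross = t[j]
    else:
        # linear interpolation between (j-1, j)
        f = (vm[j - 1] - level) / (vm[j - 1] - vm[j])
        t_cross = t[j - 1] + f * (t[j] - t[j - 1])
    return float((t_cross - t[iup]) * 1e3)
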