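"""Volumetric Ca fluxes from membrane currents.

SR Ca content is quantified by integrating the inward NCX current evoked by
rapid caffeine application: the exchanger extrudes one Ca2+ per 3 Na+, so it
carries one net elementary charge per extruded ion and the extruded amount
is Q/F mol. L-type Ca entry uses two charges per ion, Q/(2F). All amounts
are referenced to total cell volume V = Cm / (SA:V ratio) and expressed in
umol/l.

Because caffeine renders SERCA uptake futile, the sarcolemmal current does
not relax back to its pre-caffeine baseline (SERCA no longer removes its
share of the background Ca influx). The charge integral therefore uses the
post-caffeine plateau as baseline; the residual error from the pre/post
shift in diastolic free Ca is removed, when a calibrated Ca trace and a
buffering estimate are available, by adding ``beta * d[Ca]_free / 1000``.
Extrusion by PMCA (not electrogenic here) is folded in through a
multiplicative correction 1/(1 - pmca_share).

The cytosolic buffering power is estimated from the same caffeine transient:
the total Ca remaining at each instant of the decay is the outstanding
extrusion integral, and its linear regression on free Ca has slope beta.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import cumulative_trapezoid, trapezoid
from scipy.stats import linregress

from .simulator import FARADAY

log = logging.getLogger(__name__)


class FluxError(ValueError):
    pass


@dataclass(frozen=True)
class CellGeometry:
    """Capacitance-derived cell geometry."""

    cm: float  # pF
    sa_to_vol: float  # pF/pl

    def __post_init__(self) -> None:
        if self.cm <= 0 or self.sa_to_vol <= 0:
            raise FluxError("cm and sa_to_vol must be > 0")

    @property
    def volume(self) -> float:
        """Cell volume, pl."""
        return self.cm / self.sa_to_vol


@dataclass
class SRContentResult:
    sr_content: float  # umol/l of cell volume
    ncx_charge: float  # pC (transient charge above the plateau baseline)
    pmca_correction_factor: float  # >= 1
    baseline_current: float  # pA, median of the pre-caffeine window
    baseline_shift_correction: float = 0.0  # umol/l added for the pre/post baseline shift
    flagged: bool = False
    reason: str = ""


@dataclass
class BufferFit:
    beta: float  # dimensionless slope, d[Ca]_total/d[Ca]_free
    intercept: float  # umol/l
    r_squared: float
    ca_range_used: tuple  # (nmol/l, nmol/l)
    n_points: int
    flagged: bool = False
    reason: str = ""


@dataclass
class NCXSlopeFit:
    slope: float  # pA/pF per nmol/l (extrusion-positive convention)
    intercept: float  # pA/pF
    r_squared: float
    n_points: int


def cell_volume_from_capacitance(cm: float, sa_to_vol: float) -> float:
    """Cell volume (pl) from membrane capacitance and the SA:V ratio."""
    if cm <= 0 or sa_to_vol <= 0:
        raise FluxError("cm and sa_to_vol must be > 0")
    return cm / sa_to_vol


def charge_to_umol_per_l(charge_pc: float, volume_pl: float, n_charges: float = 1.0) -> float:
    """Convert a charge (pC) moved by an n-charge-per-Ca pathway to umol/l."""
    return 1e6 * charge_pc / (n_charges * FARADAY * volume_pl)


def _window_mask(t, lo, hi):
    return (t >= lo) & (t <= hi)


def integrate_ncx_sr_content(t, i_ncx, caffeine_onset_s: float,
                             geometry: CellGeometry, *,
                             window_end_s: Optional[float] = None,
                             pre_baseline_s: float = 2.0,
                             plateau_s: float = 0.5,
                             pmca_share: float = 0.0,
                             beta: Optional[float] = None,
                             ca_free=None,
                             snr_min: float = 3.0) -> SRContentResult:
    """SR Ca content (umol/l of cell volume) from the caffeine-evoked NCX charge.

    ``pmca_share`` is the fraction of sarcolemmal extrusion carried by
    non-NCX pathways; the NCX-derived amount is multiplied by
    1/(1 - pmca_share). When ``beta`` and the calibrated ``ca_free`` trace
    are given, the pre/post baseline-shift correction is applied as well.
    Uniform baseline shifts of the current trace cancel by construction.
    """
    t = np.asarray(t, dtype=float)
    i = np.asarray(i_ncx, dtype=float)
    if not (0 <= pmca_share < 1):
        raise FluxError("pmca_share must lie in [0, 1)")
    end = float(t[-1]) if window_end_s is None else float(window_end_s)
    if caffeine_onset_s < t[0] or end > t[-1] + 1e-9 or end <= caffeine_onset_s:
        raise FluxError("caffeine window lies outside the trace")

    pre = _window_mask(t, caffeine_onset_s - pre_baseline_s, caffeine_onset_s - 1e-12)
    if not pre.any():
        raise FluxError("no pre-caffeine baseline samples available")
    baseline_pre = float(np.median(i[pre]))

    win = _window_mask(t, caffeine_onset_s, end)
    plateau = _window_mask(t, end - plateau_s, end)
    baseline_plateau = float(np.median(i[plateau & win])) if (plateau & win).any() else baseline_pre

    defl = baseline_plateau - i[win]  # extrusion-positive deflection, pA
    charge_pc = float(trapezoid(defl, t[win]))  # pA*s = pC
    if charge_pc < 0:
        raise FluxError(f"negative integrated NCX charge ({charge_pc:.3g} pC)")

    flagged, reason = False, ""
    noise_sd = float(np.std(i[pre] - baseline_pre))
    peak_defl = float(np.max(defl)) if defl.size else 0.0
    if noise_sd > 0 and peak_defl < snr_min * noise_sd:
        flagged, reason = True, (
            f"no clear inward deflection (peak {peak_defl:.3g} pA < "
            f"{snr_min:.1f} x noise {noise_sd:.3g} pA)")
    elif noise_sd == 0 and peak_defl <= 0:
        flagged, reason = True, "no inward deflection"

    factor = 1.0 / (1.0 - pmca_share)
    content = charge_to_umol_per_l(charge_pc, geometry.volume, n_charges=1.0) * factor

    shift = 0.0
    if beta is not None and ca_free is not None:
        ca = np.asarray(ca_free, dtype=float)
        d_ca = float(np.nanmean(ca[plateau & win]) - np.nanmean(ca[pre]))
        shift = beta * d_ca / 1000.0  # nmol/l free -> umol/l total
        content += shift

    return SRContentResult(sr_content=content, ncx_charge=charge_pc,
                           pmca_correction_factor=factor,
                           baseline_current=baseline_pre,
                           baseline_shift_correction=shift,
                           flagged=flagged, reason=reason)


def integrate_cal_entry(t, i_cal, step_window: tuple, geometry: CellGeometry,
                        baseline_pre_s: float = 0.05) -> float:
    """Integrated L-type Ca entry over a depolarising step, umol/l of cell volume.

    The current is baseline-subtracted (median over ``baseline_pre_s``
    before the step); two charges per Ca ion.
    """
    t = np.asarray(t, dtype=float)
    i = np.asarray(i_cal, dtype=float)
    t0, t1 = step_window
    if t0 < t[0] - 1e-9 or t1 > t[-1] + 1e-9 or t1 <= t0:
        raise FluxError("step window lies outside the trace")
    pre = _window_mask(t, t0 - baseline_pre_s, t0 - 1e-12)
    baseline = float(np.median(i[pre])) if pre.any() else 0.0
    win = _window_mask(t, t0, t1)
    charge_pc = float(trapezoid(baseline - i[win], t[win]))  # inward-positive
    return charge_to_umol_per_l(charge_pc, geometry.volume, n_charges=2.0)


def buffer_power_fit(t, ca_free, i_ncx, caffeine_onset_s: float,
                     geometry: CellGeometry, *,
                     window_end_s: Optional[float] = None,
                     pre_baseline_s: float = 2.0,
                     plateau_s: float = 0.5,
                     pmca_share: float = 0.0,
                     range_lo_frac: float = 0.10,
                     range_hi_frac: float = 0.10,
                     r2_floor: float = 0.90,
                     min_points: int = 10) -> BufferFit:
    """Cytosolic buffering power from the caffeine transient.

    At each instant of the decay the total Ca still to be extruded is the
    outstanding (PMCA-corrected) extrusion-current integral; regressing it
    on free Ca over the central part of the transient (between
    end + ``range_lo_frac`` and peak - ``range_hi_frac`` of the free-Ca
    excursion, past the peak) yields slope beta.
    """
    t = np.asarray(t, dtype=float)
    ca = np.asarray(ca_free, dtype=float)
    i = np.asarray(i_ncx, dtype=float)
    end = float(t[-1]) if window_end_s is None else float(window_end_s)
    win = _window_mask(t, caffeine_onset_s, end)
    if win.sum() < min_points:
        raise FluxError("caffeine window too short for a buffering fit")

    plateau = _window_mask(t, end - plateau_s, end)
    baseline = float(np.median(i[plateau & win])) if (plateau & win).any() else float(
        np.median(i[_window_mask(t, caffeine_onset_s - pre_baseline_s, caffeine_onset_s)]))

    tw = t[win]
    defl = baseline - i[win]
    factor = 1.0 / (1.0 - pmca_share)
    # outstanding extrusion from each sample to the end of the window
    cum = cumulative_trapezoid(defl, tw, initial=0.0)
    remaining_pc = (cum[-1] - cum) * factor
    total_umol = 1e6 * remaining_pc / (FARADAY * geometry.volume)

    caw = ca[win]
    ipk = int(np.nanargmax(caw))
    ca_end = float(np.nanmean(caw[_window_mask(tw, end - plateau_s, end)]))
    ca_peak = float(caw[ipk])
    span = ca_peak - ca_end
    lo = ca_end + range_lo_frac * span
    hi = ca_peak - range_hi_frac * span
    sel = np.zeros(caw.shape, dtype=bool)
    sel[ipk:] = True
    sel &= (caw >= lo) & (caw <= hi) & np.isfinite(caw)
    if span <= 0 or sel.sum() < min_points:
        return BufferFit(beta=np.nan, intercept=np.nan, r_squared=np.nan,
                         ca_range_used=(lo, hi), n_points=int(sel.sum()),
                         flagged=True, reason="degenerate free-Ca excursion")

    res = linregress(caw[sel], total_umol[sel])
    beta = float(res.slope) * 1000.0  # umol/l per nmol/l -> dimensionless
    fit = BufferFit(beta=beta, intercept=float(res.intercept),
                    r_squared=float(res.rvalue ** 2), ca_range_used=(lo, hi),
                    n_points=int(sel.sum()))
    if fit.r_squared < r2_floor:
        fit.flagged, fit.reason = True, f"r^2 {fit.r_squared:.3f} below floor {r2_floor}"
    if beta < 1.0:
        fit.flagged = True
        fit.reason = (fit.reason + "; " if fit.reason else "") + "beta < 1"
    return fit


def ncx_ca_slope(ca_free, i_ncx_density, min_points: int = 10) -> NCXSlopeFit:
    """OLS slope of NCX current density on free Ca over the caffeine decay.

    ``i_ncx_density`` should be extrusion-positive (baseline-subtracted
    deflection / Cm, pA/pF) so the slope is the positive NCX coefficient.
    """
    ca = np.asarray(ca_free, dtype=float)
    dens = np.asarray(i_ncx_density, dtype=float)
    m = np.isfinite(ca) & np.isfinite(dens)
    if m.sum() < min_points:
        raise FluxError(f"NCX-Ca fit needs >= {min_points} paired samples, got {int(m.sum())}")
    res = linregress(ca[m], dens[m])
    return NCXSlopeFit(slope=float(res.slope), intercept=float(res.intercept),
                       r_squared=float(res.rvalue ** 2), n_points=int(m.sum()))
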