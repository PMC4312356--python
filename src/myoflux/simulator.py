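"""Synthetic voltage-clamped atrial myocyte.

A two-pool (cytosol + sarcoplasmic reticulum) calcium model of a single
atrial myocyte under voltage clamp, designed so that every quantity the
analysis pipeline estimates has a known closed-form ground truth:

* L-type Ca current: a square depolarising step gates an inward current
  ``i_CaL(t) = -g_CaL_peak * cm * exp(-k_inact * t)`` (pA, inward negative).
* SR release: an instantaneous fractional dump of SR content at each
  stimulus, scaled linearly by the normalised trigger amplitude
  (``g_CaL_peak / 2.27 pA/pF``), so decay phases are clean
  mono-exponentials.
* Removal fluxes are linear in free Ca above the resting level, with
  constant cytosolic buffering power ``beta`` (d[Ca]_free = d[Ca]_total/beta).
* Caffeine holds the SR release channel open (first-order dump at
  ``K_CAFF_OPEN``) and renders SERCA uptake futile; Ni2+ additionally
  blocks NCX (``caffeine_ni`` mode).

Unit conventions: free Ca in nmol/l, SR content and all volumetric fluxes in
umol/l of *total* cell volume, currents in pA, time in s. Removal-rate
parameters (``k_serca``, ``k_pmca_flux`` and the NCX equivalent) are
"total-Ca" rate constants: a flux of ``k * (ca_free - ca_rest) / 1000``
umol/l/s. The closed forms the analysis can target are::

    K_ncx  = 1e9 * g_ncx * sa_to_vol / F        # NCX total-Ca rate, 1/s
    k_caff = (K_ncx + k_pmca_flux) / beta       # caffeine-decay rate of free Ca
    k_sys  = (k_serca + K_ncx + k_pmca_flux)/beta   # systolic-decay rate

so that the fitted caffeine decay is mono-exponential with rate ``k_caff``
(equivalently ``(g_ncx*cm/(F*V) * 1e9 + k_pmca_flux)/beta`` since
``cm/V = sa_to_vol``).

A small constant background Ca influx ``j_leak`` closes the per-beat flux
balance: without it a linear cell paced at 0.5 Hz cannot simultaneously show
an 83 nmol/l transient, a sarcolemmal removal share k_caff/k_sys ~ 8% and an
integrated L-type entry of only ~0.74 umol/l per beat. Preset builders solve
for ``j_leak`` (and the inactivation rate and NCX coefficient) from the
target observables; see :func:`control_preset` / :func:`hf_preset`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.optimize import brentq

log = logging.getLogger(__name__)

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


FARADAY = 96485.0  # C per mol of elementary charge
SIM_DT = 1e-4  # fixed RK4 integration step, s (0.1 ms)
TRIGGER_REF_PA_PER_PF = 2.27  # control peak I_CaL density normalising the release trigger
K_CAFF_OPEN = 50.0  # 1/s; first-order SR dump while caffeine holds RyRs open

#: Multiplicative factors applied by :func:`apply_condition`.
CONDITION_FACTORS = {
    "none": {},
    # dihydropyridine block: peak I_CaL reduced ~30%
    "nicardipine": {"g_CaL_peak": 0.70},
    # beta-adrenergic stimulation: I_CaL 2.27->4.26 pA/pF, SERCA rate ~x2.9
    "isoprenaline": {"g_CaL_peak": 4.26 / 2.27, "k_serca": 5.19 / 1.80},
}


class SimulationError(RuntimeError):
    """Integration blow-up, negative SR content or invalid model input."""


# ---------------------------------------------------------------------------
# parameter and protocol containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimParams:
    """Full generative parameter set (ground truth for recovery tests)."""

    g_CaL_peak: float  # peak L-type current density, pA/pF
    k_inact: float  # L-type inactivation rate, 1/s
    frac_release: float  # SR fraction released per unit normalised trigger
    k_serca: float  # SERCA total-Ca rate constant on free Ca, 1/s
    g_ncx: float  # NCX coefficient, pA/pF per nmol/l free Ca above rest
    k_pmca_flux: float  # PMCA total-Ca rate constant on free Ca, 1/s
    beta: float  # buffering power, d[Ca]_total/d[Ca]_free
    ca_rest: float  # resting free Ca, nmol/l
    sr_init: float  # initial SR content, umol/l cell volume
    cm: float  # membrane capacitance, pF
    sa_to_vol: float  # surface-area-to-volume ratio, pF/pl
    j_leak: float = 0.0  # constant background Ca influx, umol/l/s
    noise_sd_current: float = 0.0  # additive Gaussian SD on current channels, pA
    noise_sd_fluo: float = 0.0  # fractional (of resting emission) SD on optical channels
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("g_CaL_peak", "k_inact", "frac_release", "k_serca", "g_ncx",
                     "k_pmca_flux", "noise_sd_current", "noise_sd_fluo"):
            if getattr(self, name) < 0:
                raise SimulationError(f"SimParams.{name} must be >= 0")
        if self.beta < 1:
            raise SimulationError("SimParams.beta must be >= 1")
        if self.ca_rest <= 0 or self.cm <= 0 or self.sa_to_vol <= 0:
            raise SimulationError("ca_rest, cm and sa_to_vol must be > 0")
        if self.sr_init < 0:
            raise SimulationError("sr_init must be >= 0")

    # -- derived ground-truth quantities ------------------------------------

    @property
    def volume_pl(self) -> float:
        return self.cm / self.sa_to_vol

    @property
    def k_ncx_total(self) -> float:
        """NCX total-Ca removal rate constant on free Ca, 1/s."""
        return 1e9 * self.g_ncx * self.sa_to_vol / FARADAY

    @property
    def k_caff_true(self) -> float:
        """Mono-exponential rate of the caffeine-transient free-Ca decay, 1/s."""
        return (self.k_ncx_total + self.k_pmca_flux) / self.beta

    @property
    def k_sys_true(self) -> float:
        """Mono-exponential rate of the systolic free-Ca decay, 1/s."""
        return (self.k_serca + self.k_ncx_total + self.k_pmca_flux) / self.beta

    @property
    def k_pmca_true(self) -> float:
        """Free-Ca decay rate with NCX blocked (Ni2+ protocol), 1/s."""
        return self.k_pmca_flux / self.beta

    @property
    def pmca_share_true(self) -> float:
        """PMCA share of sarcolemmal extrusion."""
        denom = self.k_ncx_total + self.k_pmca_flux
        return self.k_pmca_flux / denom if denom > 0 else 0.0

    @property
    def diastolic_ca_true(self) -> float:
        """Quiescent free-Ca fixed point (leak balanced by removal), nmol/l."""
        k_tot = self.k_serca + self.k_ncx_total + self.k_pmca_flux
        if k_tot == 0:
            return self.ca_rest
        return self.ca_rest + 1000.0 * self.j_leak / k_tot

    def entry_per_beat_true(self, step_dur_s: float = 0.1) -> float:
        """Integrated L-type Ca entry per stimulus, umol/l of cell volume."""
        if self.k_inact > 0:
            q_pc = self.g_CaL_peak * self.cm * (1.0 - math.exp(-self.k_inact * step_dur_s)) / self.k_inact
        else:
            q_pc = self.g_CaL_peak * self.cm * step_dur_s
        return 1e6 * q_pc / (2.0 * FARADAY * self.volume_pl)

    def with_(self, **changes) -> "SimParams":
        return replace(self, **changes)


@dataclass(frozen=True)
class Protocol:
    """Stimulation protocol emulating steady-state pacing, caffeine and AP clamp."""

    mode: str = "voltage_step"  # voltage_step | ap_clamp | caffeine | caffeine_ni
    hold_mV: float = -40.0
    step_mV: float = 50.0
    step_dur_s: float = 0.1
    freq_hz: float = 0.5
    n_beats: int = 20
    waveform: Optional[np.ndarray] = None  # command potential for one beat (ap_clamp)
    waveform_dt_s: float = 1e-3
    condition: str = "none"
    quiet_s: float = 1.0  # pre-stimulation rest recorded for baselines
    caffeine_delay_s: float = 2.0  # gap between last beat period and caffeine
    post_caffeine_s: float = 12.0
    record_dt_s: float = 1e-3

    def __post_init__(self) -> None:
        modes = ("voltage_step", "ap_clamp", "caffeine", "caffeine_ni")
        if self.mode not in modes:
            raise SimulationError(f"unknown protocol mode {self.mode!r}; expected one of {modes}")
        if self.n_beats < 1:
            raise SimulationError("n_beats must be >= 1")
        if self.mode == "voltage_step" and self.step_dur_s <= 0:
            raise SimulationError("step_dur_s must be > 0 for voltage_step")
        if (self.waveform is not None) != (self.mode == "ap_clamp"):
            raise SimulationError("waveform must be supplied iff mode == 'ap_clamp'")
        if self.record_dt_s < SIM_DT:
            raise SimulationError("record_dt_s must be >= the integration step")


@dataclass
class SimOutput:
    """Recorded trajectories plus embedded ground truth.

    ``ca_free``/``ca_sr`` are the noiseless state (truth); the current and
    optical channels carry the configured measurement noise.
    """

    time: np.ndarray  # s
    ca_free: np.ndarray  # nmol/l (truth)
    ca_sr: np.ndarray  # umol/l cell volume (truth)
    i_cal: np.ndarray  # pA
    i_ncx: np.ndarray  # pA
    i_total: np.ndarray  # pA
    fluo: np.ndarray  # a.u., single-wavelength
    fura_ratio: np.ndarray  # dimensionless
    vm: np.ndarray  # mV command potential
    truth: SimParams
    protocol: Protocol
    stim_times: np.ndarray  # s
    caffeine_onset_s: Optional[float] = None
    sr_at_caffeine_onset: Optional[float] = None

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


# ---------------------------------------------------------------------------
# dye emission models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FluoDye:
    """Single-wavelength dye, F = f_max * ca / (ca + kd)."""

    kd: float = 1035.0  # nmol/l
    f_max: float = 1000.0  # a.u.


@dataclass(frozen=True)
class FuraDye:
    """Ratiometric dye, R = (r_min*k_eff + r_max*ca) / (k_eff + ca)."""

    r_min: float = 0.30
    r_max: float = 3.00
    k_eff: float = 1800.0  # nmol/l


def emit_fluorescence(ca_free, dye, noise_sd: float = 0.0, seed: Optional[int] = None):
    """Map a free-Ca series (nmol/l) to the dye's emitted signal.

    ``noise_sd`` is the additive Gaussian SD as a fraction of the resting
    (first-sample) emission. Noiseless emission composed with the matching
    calibration inverse returns the input exactly.
    """
    ca = np.asarray(ca_free, dtype=float)
    if np.any(ca <= 0):
        raise ValueError("ca_free must be > 0 throughout")
    if isinstance(dye, FluoDye):
        sig = dye.f_max * ca / (ca + dye.kd)
    elif isinstance(dye, FuraDye):
        sig = (dye.r_min * dye.k_eff + dye.r_max * ca) / (dye.k_eff + ca)
    else:
        raise TypeError(f"unknown dye model {type(dye).__name__}")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sig = sig + rng.normal(0.0, noise_sd * sig.flat[0], size=sig.shape)
    return sig


# ---------------------------------------------------------------------------
# conditions
# ---------------------------------------------------------------------------


def apply_condition(params: SimParams, condition: str, factors: Optional[dict] = None) -> SimParams:
    """Return a new parameter set with the drug condition's scale factors applied.

    ``factors`` overrides the default table (maps field name -> multiplier).
    """
    table = CONDITION_FACTORS if factors is None else {**CONDITION_FACTORS, condition: factors}
    if condition not in table:
        raise SimulationError(
            f"unknown condition {condition!r}; valid: {sorted(CONDITION_FACTORS)}")
    changes = {name: getattr(params, name) * fac for name, fac in table[condition].items()}
    return params.with_(**changes) if changes else params


# ---------------------------------------------------------------------------
# RK4 core (numba-compiled when available)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _deriv(t, ca, sr, last_stim_t, step_dur, peak_pa, k_inact, k_serca, k_ncx,
           k_pmca, beta, ca_rest, j_leak, jcal_coeff, caff, ni_block, k_open):
    ts = t - last_stim_t
    ical = 0.0
    if 0.0 <= ts <= step_dur and not caff:
        ical = -peak_pa * np.exp(-k_inact * ts)
    d = ca - ca_rest
    j_serca = 0.0 if caff else 1e-3 * k_serca * d
    j_ncx = 0.0 if (caff and ni_block) else 1e-3 * k_ncx * d
    j_pmca = 1e-3 * k_pmca * d
    j_cal = jcal_coeff * (-ical)
    j_rel = k_open * sr if caff else 0.0
    dtot = j_cal + j_rel + j_leak - j_serca - j_ncx - j_pmca
    return 1000.0 * dtot / beta, j_serca - j_rel


@njit(cache=True)
def _core(dt, n_steps, stim_steps, step_dur, peak_pa, k_inact, rel_eff,
          k_serca, k_ncx, k_pmca, beta, ca_rest, j_leak, jcal_coeff,
          caff_step, ni_block, k_open, ca0, sr0, stride, n_rec):
    rec_ca = np.empty(n_rec)
    rec_sr = np.empty(n_rec)
    rec_ical = np.empty(n_rec)
    ca = ca0
    sr = sr0
    ptr = 0
    last_stim_t = -1.0e18
    ri = 0
    status = 0
    bad = -1
    for i in range(n_steps + 1):
        t = i * dt
        if ptr < stim_steps.shape[0] and i == stim_steps[ptr]:
            rel = rel_eff * sr
            if rel > sr:
                rel = sr
            sr -= rel
            ca += 1000.0 * rel / beta
            last_stim_t = t
            ptr += 1
        caff = caff_step >= 0 and i >= caff_step
        if i % stride == 0 and ri < n_rec:
            ts = t - last_stim_t
            ical = 0.0
            if 0.0 <= ts <= step_dur and not caff:
                ical = -peak_pa * np.exp(-k_inact * ts)
            rec_ca[ri] = ca
            rec_sr[ri] = sr
            rec_ical[ri] = ical
            ri += 1
        if not (np.isfinite(ca) and np.isfinite(sr)) or sr < -1e-9:
            status = 1
            bad = i
            break
        if i == n_steps:
            break
        h = dt
        k1c, k1s = _deriv(t, ca, sr, last_stim_t, step_dur, peak_pa, k_inact,
                          k_serca, k_ncx, k_pmca, beta, ca_rest, j_leak,
                          jcal_coeff, caff, ni_block, k_open)
        k2c, k2s = _deriv(t + 0.5 * h, ca + 0.5 * h * k1c, sr + 0.5 * h * k1s,
                          last_stim_t, step_dur, peak_pa, k_inact, k_serca,
                          k_ncx, k_pmca, beta, ca_rest, j_leak, jcal_coeff,
                          caff, ni_block, k_open)
        k3c, k3s = _deriv(t + 0.5 * h, ca + 0.5 * h * k2c, sr + 0.5 * h * k2s,
                          last_stim_t, step_dur, peak_pa, k_inact, k_serca,
                          k_ncx, k_pmca, beta, ca_rest, j_leak, jcal_coeff,
                          caff, ni_block, k_open)
        k4c, k4s = _deriv(t + h, ca + h * k3c, sr + h * k3s,
                          last_stim_t, step_dur, peak_pa, k_inact, k_serca,
                          k_ncx, k_pmca, beta, ca_rest, j_leak, jcal_coeff,
                          caff, ni_block, k_open)
        ca += h * (k1c + 2.0 * k2c + 2.0 * k3c + k4c) / 6.0
        sr += h * (k1s + 2.0 * k2s + 2.0 * k3s + k4s) / 6.0
    return status, bad, rec_ca, rec_sr, rec_ical


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------


def _build_vm(time: np.ndarray, protocol: Protocol, stim_times: np.ndarray,
              caffeine_onset: Optional[float]) -> np.ndarray:
    vm = np.full(time.shape, protocol.hold_mV)
    if protocol.mode == "ap_clamp":
        wf = np.asarray(protocol.waveform, dtype=float)
        t_wf = np.arange(wf.size) * protocol.waveform_dt_s
        for ts in stim_times:
            rel = time - ts
            m = (rel >= 0) & (rel < t_wf[-1])
            vm[m] = np.interp(rel[m], t_wf, wf)
    else:
        for ts in stim_times:
            m = (time >= ts) & (time < ts + protocol.step_dur_s)
            vm[m] = protocol.hold_mV + protocol.step_mV
    return vm


def simulate(params: SimParams, protocol: Protocol) -> SimOutput:
    """Integrate the myocyte model under ``protocol``.

    Fixed-step classical RK4 at 0.1 ms; recorded channels are decimated to
    ``protocol.record_dt_s``. With both noise SDs zero the output is fully
    deterministic given (params, protocol).
    """
    p = apply_condition(params, protocol.condition)
    dt = SIM_DT
    period = 1.0 / protocol.freq_hz
    stride = int(round(protocol.record_dt_s / dt))
    if abs(stride * dt - protocol.record_dt_s) > 1e-12:
        raise SimulationError("record_dt_s must be an integer multiple of the 0.1 ms step")

    stim_times = protocol.quiet_s + period * np.arange(protocol.n_beats)
    duration = protocol.quiet_s + period * protocol.n_beats
    caffeine_onset: Optional[float] = None
    if protocol.mode in ("caffeine", "caffeine_ni"):
        caffeine_onset = duration + protocol.caffeine_delay_s
        duration = caffeine_onset + protocol.post_caffeine_s

    # align events to the record grid
    n_steps = int(round(duration / dt))
    stim_steps = np.round(stim_times / dt).astype(np.int64)
    caff_step = -1 if caffeine_onset is None else int(round(caffeine_onset / dt))
    n_rec = n_steps // stride + 1

    trigger = p.g_CaL_peak / TRIGGER_REF_PA_PER_PF
    rel_eff = p.frac_release * trigger
    jcal_coeff = 1e6 / (2.0 * FARADAY * p.volume_pl)
    ni_block = protocol.mode == "caffeine_ni"

    status, bad, ca, sr, ical = _core(
        dt, n_steps, stim_steps, protocol.step_dur_s,
        p.g_CaL_peak * p.cm, p.k_inact, rel_eff,
        p.k_serca, p.k_ncx_total, p.k_pmca_flux, p.beta, p.ca_rest,
        p.j_leak, jcal_coeff, caff_step, ni_block, K_CAFF_OPEN,
        p.diastolic_ca_true, p.sr_init, stride, n_rec)
    if status != 0:
        raise SimulationError(
            f"integration aborted at t={bad * dt:.4f}s (non-finite state or negative SR)")
    if np.any(ca <= 0):
        raise SimulationError("free Ca fell to <= 0; invalid parameter set")

    # build the time base from the nominal record step so that a CSV
    # round trip reconstructs bit-identical sample times
    time = np.arange(n_rec) * protocol.record_dt_s
    defl = p.g_ncx * p.cm * (ca - p.ca_rest)
    i_ncx = -defl
    if ni_block and caffeine_onset is not None:
        i_ncx = np.where(time >= caffeine_onset, 0.0, i_ncx)
    i_total = ical + i_ncx

    rng = np.random.default_rng(p.seed)
    if p.noise_sd_current > 0:
        ical = ical + rng.normal(0.0, p.noise_sd_current, n_rec)
        i_ncx = i_ncx + rng.normal(0.0, p.noise_sd_current, n_rec)
        i_total = i_total + rng.normal(0.0, p.noise_sd_current, n_rec)
    fluo = emit_fluorescence(ca, FluoDye(), p.noise_sd_fluo,
                             seed=int(rng.integers(2 ** 31)) if p.noise_sd_fluo > 0 else None)
    fura = emit_fluorescence(ca, FuraDye(), p.noise_sd_fluo,
                             seed=int(rng.integers(2 ** 31)) if p.noise_sd_fluo > 0 else None)

    sr_onset = None
    if caffeine_onset is not None:
        sr_onset = float(sr[int(round(caffeine_onset / protocol.record_dt_s))])

    return SimOutput(
        time=time, ca_free=ca, ca_sr=sr, i_cal=ical, i_ncx=i_ncx, i_total=i_total,
        fluo=fluo, fura_ratio=fura,
        vm=_build_vm(time, protocol, stim_times, caffeine_onset),
        truth=p, protocol=protocol, stim_times=stim_times,
        caffeine_onset_s=caffeine_onset, sr_at_caffeine_onset=sr_onset)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------


def _solve_k_inact(peak_density: float, entry_umol: float, cm: float,
                   volume_pl: float, step_dur_s: float) -> float:
    # peak*(1-exp(-k*T))/k = charge-per-pF implied by the target entry
    q_per_pf = entry_umol * 2.0 * FARADAY * volume_pl / (1e6 * cm)  # pC/pF
    tau = q_per_pf / peak_density
    if tau >= step_dur_s:
        raise SimulationError("target entry not reachable within the step duration")

    def f(k):
        return (1.0 - math.exp(-k * step_dur_s)) / k - tau

    return float(brentq(f, 1e-3, 1e4))


def build_preset(*, cm: float, sa_to_vol: float, ca_rest: float, beta: float,
                 k_sys: float, k_caff: float, pmca_share: float,
                 g_CaL_peak: float, entry_umol: float, sr_ss: float,
                 frac_release_eff: float, freq_hz: float = 0.5,
                 noise_sd_current: float = 0.0, noise_sd_fluo: float = 0.0,
                 seed: int = 0) -> SimParams:
    """Construct a parameter set from target steady-state observables.

    Targets: buffering power ``beta``, systolic and caffeine decay rates,
    PMCA share of sarcolemmal extrusion, peak L-type density and integrated
    entry per beat, steady-state SR content ``sr_ss`` and the effective
    fraction of SR content released per beat ``frac_release_eff``
    (at this preset's own trigger amplitude). The NCX coefficient, SERCA and
    PMCA rates, inactivation rate and background influx are solved so the
    paced 0.5 Hz steady state lands on those targets.
    """
    k_x = k_caff * beta
    k_pmca = pmca_share * k_x
    k_ncx = k_x - k_pmca
    g_ncx = k_ncx * FARADAY / (1e9 * sa_to_vol)
    k_serca = (k_sys - k_caff) * beta
    trigger = g_CaL_peak / TRIGGER_REF_PA_PER_PF
    frac_release = frac_release_eff / trigger
    # per-beat balance: background influx makes extrusion = entry attainable
    release = frac_release_eff * sr_ss
    sigma = 1.0 - k_caff / k_sys  # SERCA share of total removal
    lt = ((1.0 - sigma) * (entry_umol + release) - entry_umol) / sigma
    if lt < 0:
        lt = 0.0
    k_inact = _solve_k_inact(g_CaL_peak, entry_umol, cm, cm / sa_to_vol, 0.1)
    return SimParams(
        g_CaL_peak=g_CaL_peak, k_inact=k_inact, frac_release=frac_release,
        k_serca=k_serca, g_ncx=g_ncx, k_pmca_flux=k_pmca, beta=beta,
        ca_rest=ca_rest, sr_init=sr_ss, cm=cm, sa_to_vol=sa_to_vol,
        j_leak=lt * freq_hz, noise_sd_current=noise_sd_current,
        noise_sd_fluo=noise_sd_fluo, seed=seed)


#: Target observables of the two cohort presets (configuration, not hard truth).
PRESET_TARGETS = {
    "control": dict(cm=59.6, sa_to_vol=5.06, ca_rest=60.7, beta=565.0,
                    k_sys=8.99, k_caff=0.745, pmca_share=0.10,
                    g_CaL_peak=2.27, entry_umol=0.74, sr_ss=84.0,
                    frac_release_eff=0.55),
    "hf": dict(cm=125.9, sa_to_vol=4.89, ca_rest=37.3, beta=318.0,
               k_sys=6.55, k_caff=0.933, pmca_share=0.10,
               g_CaL_peak=1.45, entry_umol=0.86, sr_ss=100.1,
               frac_release_eff=18.2 / 100.1),
}


def control_preset(seed: int = 0, noise_sd_current: float = 0.0,
                   noise_sd_fluo: float = 0.0) -> SimParams:
    """Healthy sheep atrial myocyte phenotype."""
    return build_preset(**PRESET_TARGETS["control"], seed=seed,
                        noise_sd_current=noise_sd_current, noise_sd_fluo=noise_sd_fluo)


def hf_preset(seed: int = 0, noise_sd_current: float = 0.0,
              noise_sd_fluo: float = 0.0) -> SimParams:
    """Tachypacing-induced heart-failure atrial myocyte phenotype."""
    return build_preset(**PRESET_TARGETS["hf"], seed=seed,
                        noise_sd_current=noise_sd_current, noise_sd_fluo=noise_sd_fluo)


def ap_waveform(apd90_ms: float, dt_s: float = 1e-3, rest_mV: float = -75.0,
                peak_mV: float = 25.0, pre_ms: float = 20.0,
                pad_ms: float = 100.0) -> np.ndarray:
    """Triangular action-potential command waveform with an exact APD90.

    Single-sample upstroke, then linear repolarisation over ``apd90/0.9`` so
    the 90%-repolarisation time measured from the upstroke is ``apd90_ms``.
    """
    repol_ms = apd90_ms / 0.9
    n_pre = int(round(pre_ms / (dt_s * 1e3)))
    n_rep = int(round(repol_ms / (dt_s * 1e3)))
    n_pad = int(round(pad_ms / (dt_s * 1e3)))
    wf = np.concatenate([
        np.full(n_pre, rest_mV),
        np.linspace(peak_mV, rest_mV, n_rep + 1),
        np.full(n_pad, rest_mV),
    ])
    return wf


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

#: parameters perturbed cell-to-cell / animal-to-animal (multiplicative lognormal)
_PERTURBED_FIELDS = ("g_CaL_peak", "k_inact", "frac_release", "k_serca", "g_ncx",
                     "k_pmca_flux", "beta", "ca_rest", "cm", "j_leak")


def _perturb(params: SimParams, factors: dict) -> SimParams:
    changes = {k: getattr(params, k) * v for k, v in factors.items()}
    return params.with_(**changes)


def default_cohort_protocols(record_dt_s: float = 1e-3) -> dict:
    """The per-cell recordings the analysis pipeline expects."""
    return {
        "pacing": Protocol(mode="voltage_step", n_beats=12, record_dt_s=record_dt_s),
        "caffeine": Protocol(mode="caffeine", n_beats=12, post_caffeine_s=12.0,
                             record_dt_s=record_dt_s),
        # PMCA-only decay is slow; record longer and sparser
        "caffeine_ni": Protocol(mode="caffeine_ni", n_beats=6, post_caffeine_s=35.0,
                                record_dt_s=5e-3),
    }


def make_cohort(control_params: SimParams, hf_params: Optional[SimParams],
                n_animals: int, cells_per_animal: int,
                cv_animal: float = 0.08, cv_cell: float = 0.05,
                seed: int = 0, protocols: Optional[dict] = None) -> list:
    """Simulate a two-level (animal, cell) cohort of :class:`CellRecord`.

    Each arm gets ``n_animals`` animals with ``cells_per_animal`` cells;
    parameters are perturbed by independent lognormal animal then cell
    factors with the given coefficients of variation. If ``hf_params`` is
    None only the control arm is generated. Ground truth is embedded per cell.
    """
    from .io import CellRecord, Recording, Trace  # deferred: io must not import simulator

    if n_animals < 1 or cells_per_animal < 1:
        raise ValueError("counts must be >= 1")
    if cv_animal < 0 or cv_cell < 0:
        raise ValueError("coefficients of variation must be >= 0")
    protocols = protocols or default_cohort_protocols()
    rng = np.random.default_rng(seed)
    sig_a = math.sqrt(math.log(1.0 + cv_animal ** 2))
    sig_c = math.sqrt(math.log(1.0 + cv_cell ** 2))
    arms = [("control", control_params)] + ([("hf", hf_params)] if hf_params is not None else [])

    records = []
    for group, base in arms:
        for a in range(n_animals):
            animal_id = f"{group}_A{a + 1:02d}"
            afac = {k: math.exp(rng.normal(-0.5 * sig_a ** 2, sig_a)) for k in _PERTURBED_FIELDS}
            for c in range(cells_per_animal):
                cfac = {k: afac[k] * math.exp(rng.normal(-0.5 * sig_c ** 2, sig_c))
                        for k in _PERTURBED_FIELDS}
                cell_seed = int(rng.integers(2 ** 31))
                p = _perturb(base, cfac).with_(seed=cell_seed)
                cell_id = f"{animal_id}_C{c + 1:02d}"
                recs = {}
                meta = {"sr_at_caffeine_onset": {}, "caffeine_onset_s": {},
                        "stim_times_s": {}}
                for name, proto in protocols.items():
                    out = simulate(p, proto)
                    recs[name] = _recording_from_output(out, Recording, Trace)
                    meta["stim_times_s"][name] = [float(t) for t in out.stim_times]
                    if out.caffeine_onset_s is not None:
                        meta["caffeine_onset_s"][name] = float(out.caffeine_onset_s)
                        meta["sr_at_caffeine_onset"][name] = out.sr_at_caffeine_onset
                meta["ca_rest_anchor_nM"] = p.diastolic_ca_true
                records.append(CellRecord(
                    cell_id=cell_id, animal_id=animal_id, group=group,
                    condition="none", cm=p.cm, sa_to_vol=p.sa_to_vol,
                    traces=recs, truth=p, seed=cell_seed, meta=meta))
    return records


_SIGNAL_UNITS = {"vm_mV": "mV", "i_total_pA": "pA", "i_ncx_pA": "pA",
                 "i_cal_pA": "pA", "fluo_au": "a.u.", "fura_ratio": "",
                 "ca_free_nM": "nmol/l"}


def _recording_from_output(out: SimOutput, Recording, Trace):
    sig = {
        "vm_mV": out.vm, "i_total_pA": out.i_total, "i_ncx_pA": out.i_ncx,
        "i_cal_pA": out.i_cal, "fluo_au": out.fluo, "fura_ratio": out.fura_ratio,
        "ca_free_nM": out.ca_free,
    }
    traces = {k: Trace(name=k, data=np.asarray(v, dtype=float), dt=out.dt,
                       units=_SIGNAL_UNITS.get(k, "")) for k, v in sig.items()}
    return Recording(dt=out.dt, signals=traces)
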