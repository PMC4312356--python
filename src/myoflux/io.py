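"""File formats, configuration and cohort orchestration.

Per cell the pipeline expects up to three recordings, each stored as one
CSV (columns ``time_s, vm_mV, i_total_pA, i_ncx_pA, i_cal_pA, fluo_au,
fura_ratio[, ca_free_nM]``) plus one JSON sidecar per cell carrying
geometry, stimulus times, caffeine onsets, the seed and (for synthetic
cells) the ground-truth parameters:

* ``pacing``       — steady-state 0.5 Hz voltage-clamp stimulation
                     (transient amplitude, k_sys, integrated/peak I_CaL);
* ``caffeine``     — rapid 10 mM caffeine after steady-state pacing
                     (k_caff, SR content, buffering power, NCX-Ca slope);
* ``caffeine_ni``  — caffeine with NCX blocked by Ni2+ (k_PMCA).

``run_pipeline`` orchestrates calibration -> kinetics -> flux -> economy per
cell, isolates per-cell failures, and emits a deterministic JSON results
object in which every reported number is a named intermediate.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import economy as econ
from .calibration import CalibrationError, FluoSelfRatioCalibration, fluo_selfratio_to_ca
from .kinetics import (KineticsError, decay_window, decompose_rates,
                       fit_mono_exponential_decay, transient_metrics)
from .sr_flux import (CellGeometry, FluxError, buffer_power_fit,
                      integrate_cal_entry, integrate_ncx_sr_content, ncx_ca_slope)

log = logging.getLogger(__name__)

SCHEMA_COLUMNS = ("time_s", "vm_mV", "i_total_pA", "i_ncx_pA", "i_cal_pA",
                  "fluo_au", "fura_ratio")


class TraceFormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class Trace:
    """Uniformly sampled time series of one signal."""

    name: str
    data: np.ndarray
    dt: float  # s
    t0: float = 0.0
    units: str = ""

    @property
    def time(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(len(self.data))


@dataclass
class Recording:
    """A set of simultaneously sampled traces sharing one time base."""

    dt: float
    signals: dict  # name -> Trace
    t0: float = 0.0

    def __post_init__(self) -> None:
        for tr in self.signals.values():
            if abs(tr.dt - self.dt) > 1e-9:
                raise TraceFormatError(
                    f"trace {tr.name!r} sampling ({tr.dt}) differs from the recording ({self.dt})")

    @property
    def time(self) -> np.ndarray:
        n = len(next(iter(self.signals.values())).data)
        return self.t0 + self.dt * np.arange(n)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.signals[name].data


@dataclass
class CellRecord:
    """Everything known about one cell: traces, geometry, provenance."""

    cell_id: str
    animal_id: str
    group: str  # control | hf
    condition: str
    cm: float  # pF
    sa_to_vol: float  # pF/pl
    traces: dict  # protocol name -> Recording
    truth: Optional[object] = None  # SimParams for synthetic cells
    seed: Optional[int] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.animal_id:
            raise TraceFormatError("animal_id must be present")

    @property
    def geometry(self) -> CellGeometry:
        return CellGeometry(cm=self.cm, sa_to_vol=self.sa_to_vol)


@dataclass
class GroupSummary:
    variable: str
    group: str
    cell_mean: float
    cell_sem: float
    animal_mean: float
    animal_sem: float
    n_cells: int
    n_animals: int
    log10_transformed: bool = False


# ---------------------------------------------------------------------------
# trace CSV round trip
# ---------------------------------------------------------------------------


def write_trace_csv(recording: Recording, path) -> None:
    """Write a recording as CSV (full double precision, lossless round trip)."""
    cols = {"time_s": recording.time}
    for name, tr in recording.signals.items():
        cols[name] = tr.data
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


_UNIT_BY_COLUMN = {"vm_mV": "mV", "i_total_pA": "pA", "i_ncx_pA": "pA",
                   "i_cal_pA": "pA", "fluo_au": "a.u.", "fura_ratio": "",
                   "ca_free_nM": "nmol/l"}


def read_trace_csv(path) -> Recording:
    """Read a trace CSV, validating the schema and the uniform time base.

    Unknown extra columns are accepted and preserved as additional traces.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ("time_s",) if c not in df.columns]
    if missing:
        raise TraceFormatError(f"{path}: missing required column(s) {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise TraceFormatError(f"{path}: need at least two samples")
    steps = np.diff(t)
    if np.any(steps <= 0):
        raise TraceFormatError(f"{path}: time column is not strictly increasing")
    dt = float(np.median(steps))
    if np.max(np.abs(steps - dt)) > 1e-6:
        raise TraceFormatError(f"{path}: time step is not uniform within 1e-6 s")
    # canonicalise away float ulp wobble in the parsed diffs so a write/read
    # cycle reproduces the original nominal step exactly
    dt = float(f"{dt:.9g}")
    signals = {}
    for col in df.columns:
        if col == "time_s":
            continue
        signals[col] = Trace(name=col, data=df[col].to_numpy(dtype=float), dt=dt,
                             t0=float(t[0]), units=_UNIT_BY_COLUMN.get(col, ""))
    return Recording(dt=dt, signals=signals, t0=float(t[0]))


# ---------------------------------------------------------------------------
# cohort persistence
# ---------------------------------------------------------------------------


def write_cohort(records, out_dir) -> None:
    """One CSV per cell per protocol plus one JSON sidecar per cell."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rec in records:
        files = {}
        for proto, recording in rec.traces.items():
            fname = f"{rec.cell_id}__{proto}.csv"
            write_trace_csv(recording, out / fname)
            files[proto] = fname
        sidecar = {
            "cell_id": rec.cell_id, "animal_id": rec.animal_id,
            "group": rec.group, "condition": rec.condition,
            "cm_pF": rec.cm, "sa_to_vol_pF_per_pl": rec.sa_to_vol,
            "seed": rec.seed, "files": files, "meta": rec.meta,
            "truth": dataclasses.asdict(rec.truth) if rec.truth is not None else None,
        }
        (out / f"{rec.cell_id}.json").write_text(
            json.dumps(sidecar, indent=1, sort_keys=True))


def read_cohort(cohort_dir) -> list:
    """Load every cell sidecar (and its trace CSVs) from a directory."""
    from .simulator import SimParams  # deferred import; simulator imports io types

    d = Path(cohort_dir)
    records = []
    for sc_path in sorted(d.glob("*.json")):
        sc = json.loads(sc_path.read_text())
        traces = {proto: read_trace_csv(d / fname)
                  for proto, fname in sc.get("files", {}).items()}
        truth = SimParams(**sc["truth"]) if sc.get("truth") else None
        records.append(CellRecord(
            cell_id=sc["cell_id"], animal_id=sc["animal_id"], group=sc["group"],
            condition=sc.get("condition", "none"), cm=sc["cm_pF"],
            sa_to_vol=sc["sa_to_vol_pF_per_pl"], traces=traces, truth=truth,
            seed=sc.get("seed"), meta=sc.get("meta", {})))
    return records


# ---------------------------------------------------------------------------
# analysis configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnalysisConfig:
    """All tunables of the per-cell analysis, JSON-serialisable and hashed."""

    dye_kd: float = 1035.0  # nmol/l, single-wavelength self-ratio calibration
    pre_stim_window_s: float = 0.2
    post_stim_window_s: float = 0.3
    decay_hi_frac: float = 0.90
    decay_lo_frac: float = 0.10
    # the PMCA-only (Ni2+) decay is slow; stop the fit higher up the transient
    pmca_decay_lo_frac: float = 0.30
    rmse_frac_max: float = 0.10
    step_dur_s: float = 0.1
    pre_caffeine_baseline_s: float = 2.0
    plateau_s: float = 0.5
    buffer_range_lo_frac: float = 0.10
    buffer_range_hi_frac: float = 0.10
    r2_floor: float = 0.90
    pmca_share: Optional[float] = None  # None -> derive from k_pmca/k_caff when available
    baseline_shift_correction: bool = True

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisConfig":
        return cls(**json.loads(text))

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# per-cell analysis
# ---------------------------------------------------------------------------


def _calibrate(recording: Recording, stim_times, anchor_ca_rest: float,
               cfg: AnalysisConfig) -> np.ndarray:
    """Self-ratio calibration of the single-wavelength channel, anchored to
    the cell's measured resting free Ca; f_rest from the pre-stimulus quiet
    period."""
    t = recording.time
    f = recording["fluo_au"]
    t_first = stim_times[0] if len(stim_times) else t[-1]
    pre = t < t_first
    if not pre.any():
        raise CalibrationError("no pre-stimulus samples to establish f_rest")
    f_rest = float(np.median(f[pre]))
    calib = FluoSelfRatioCalibration(kd=cfg.dye_kd, ca_rest=anchor_ca_rest, f_rest=f_rest)
    return fluo_selfratio_to_ca(f, calib)


def analyze_cell(record: CellRecord, cfg: AnalysisConfig) -> dict:
    """Run the full per-cell analysis; returns a JSON-able result dict."""
    geom = record.geometry
    anchor = record.meta.get("ca_rest_anchor_nM")
    if anchor is None:
        raise CalibrationError(f"{record.cell_id}: no resting-Ca anchor in metadata")
    res: dict = {"cell_id": record.cell_id, "animal_id": record.animal_id,
                 "group": record.group, "condition": record.condition,
                 "cm_pF": geom.cm, "sa_to_vol_pF_per_pl": geom.sa_to_vol,
                 "volume_pl": geom.volume}
    flags: list = []

    # ---- PMCA rate first (needed for the correction share) ----
    k_pmca = None
    if "caffeine_ni" in record.traces:
        rec = record.traces["caffeine_ni"]
        stim = record.meta["stim_times_s"]["caffeine_ni"]
        onset = record.meta["caffeine_onset_s"]["caffeine_ni"]
        ca = _calibrate(rec, stim, anchor, cfg)
        t = rec.time
        ipk = int(np.nanargmax(np.where(t >= onset, ca, -np.inf)))
        win = decay_window(t, ca, ipk, cfg.decay_hi_frac, cfg.pmca_decay_lo_frac)
        fit = fit_mono_exponential_decay(t, ca, window=win, rmse_frac_max=cfg.rmse_frac_max)
        if fit.ok:
            k_pmca = fit.k
        else:
            flags.append(f"k_PMCA fit rejected: {fit.reason}")
    res["k_pmca_per_s"] = k_pmca

    # ---- systolic pacing recording ----
    amplitude = diastolic = peak = k_sys = int_ical = peak_ical_density = None
    if "pacing" in record.traces:
        rec = record.traces["pacing"]
        stim = record.meta["stim_times_s"]["pacing"]
        t = rec.time
        ca = _calibrate(rec, stim, anchor, cfg)
        last = stim[-1]
        tm = transient_metrics(t, ca, [last], pre_window_s=cfg.pre_stim_window_s,
                               post_window_s=cfg.post_stim_window_s,
                               fit_hi_frac=cfg.decay_hi_frac,
                               fit_lo_frac=cfg.decay_lo_frac,
                               rmse_frac_max=cfg.rmse_frac_max,
                               # the decay is only free of L-type entry once
                               # the depolarising step has ended
                               fit_start_min_s=cfg.step_dur_s + 0.005)[0]
        diastolic, peak, amplitude = tm.diastolic_ca, tm.peak_ca, tm.amplitude
        k_sys = tm.k_decay
        flags.extend(f"pacing: {f}" for f in tm.flags)
        int_ical = integrate_cal_entry(t, rec["i_cal_pA"],
                                       (last, last + cfg.step_dur_s + 0.02), geom)
        icall = rec["i_cal_pA"]
        pre = (t >= last - 0.05) & (t < last)
        base = float(np.median(icall[pre])) if pre.any() else 0.0
        # step onset is the instant of maximal L-type driving; reading the
        # onset sample avoids the upward bias of a max over noisy samples
        i_on = int(np.searchsorted(t, last))
        peak_ical_density = float(base - icall[i_on]) / geom.cm
    res.update(diastolic_ca_nM=diastolic, peak_ca_nM=peak, amplitude_nM=amplitude,
               k_sys_per_s=k_sys, int_ical_umol_per_l=int_ical,
               peak_ical_pA_per_pF=peak_ical_density)

    # ---- caffeine recording ----
    k_caff = sr_content = beta = ncx_slope = None
    if "caffeine" in record.traces:
        rec = record.traces["caffeine"]
        stim = record.meta["stim_times_s"]["caffeine"]
        onset = record.meta["caffeine_onset_s"]["caffeine"]
        t = rec.time
        ca = _calibrate(rec, stim, anchor, cfg)
        ipk = int(np.nanargmax(np.where(t >= onset, ca, -np.inf)))
        win = decay_window(t, ca, ipk, cfg.decay_hi_frac, cfg.decay_lo_frac)
        fit = fit_mono_exponential_decay(t, ca, window=win, rmse_frac_max=cfg.rmse_frac_max)
        if fit.ok:
            k_caff = fit.k
        else:
            flags.append(f"k_caff fit rejected: {fit.reason}")

        share = cfg.pmca_share
        if share is None:
            share = (k_pmca / k_caff) if (k_pmca is not None and k_caff) else 0.0
        share = min(max(share, 0.0), 0.95)
        res["pmca_share"] = share

        bf = buffer_power_fit(t, ca, rec["i_ncx_pA"], onset, geom,
                              pre_baseline_s=cfg.pre_caffeine_baseline_s,
                              plateau_s=cfg.plateau_s, pmca_share=share,
                              range_lo_frac=cfg.buffer_range_lo_frac,
                              range_hi_frac=cfg.buffer_range_hi_frac,
                              r2_floor=cfg.r2_floor)
        if bf.flagged:
            flags.append(f"buffer fit: {bf.reason}")
        else:
            beta = bf.beta
        res["buffer_r_squared"] = bf.r_squared

        sc = integrate_ncx_sr_content(
            t, rec["i_ncx_pA"], onset, geom,
            pre_baseline_s=cfg.pre_caffeine_baseline_s, plateau_s=cfg.plateau_s,
            pmca_share=share,
            beta=beta if cfg.baseline_shift_correction else None,
            ca_free=ca if cfg.baseline_shift_correction else None)
        if sc.flagged:
            flags.append(f"SR content: {sc.reason}")
        sr_content = sc.sr_content
        res.update(ncx_charge_pC=sc.ncx_charge,
                   pmca_correction_factor=sc.pmca_correction_factor,
                   baseline_current_pA=sc.baseline_current,
                   baseline_shift_umol_per_l=sc.baseline_shift_correction)

        # NCX-Ca relationship over the decay phase, extrusion-positive density
        plateau_m = (t >= win[1] - cfg.plateau_s) & (t <= win[1])
        i_base = float(np.median(rec["i_ncx_pA"][plateau_m])) if plateau_m.any() else 0.0
        decay_m = (t >= win[0]) & (t <= win[1])
        dens = (i_base - rec["i_ncx_pA"][decay_m]) / geom.cm
        try:
            nf = ncx_ca_slope(ca[decay_m], dens)
            ncx_slope = nf.slope
            res["ncx_slope_r_squared"] = nf.r_squared
        except FluxError as exc:
            flags.append(f"NCX slope: {exc}")
    res.update(k_caff_per_s=k_caff, sr_content_umol_per_l=sr_content, beta=beta,
               ncx_slope_pA_pF_per_nM=ncx_slope)

    # ---- rate decomposition and economy ----
    if k_sys is not None and k_caff is not None:
        dec = decompose_rates(k_sys, k_caff, k_pmca)
        flags.extend(dec.flags)
        res["k_sr_per_s"] = dec.k_sr
    else:
        res["k_sr_per_s"] = None

    if None not in (amplitude, beta, int_ical, sr_content):
        table = econ.EconomyTable.from_measurements(
            d_sys_ca=amplitude, beta=beta, int_ical=int_ical, sr_content=sr_content)
        flags.extend(f"economy: {f}" for f in table.flags)
        res.update(total_transient_umol_per_l=table.total_transient,
                   d_sr_systole_umol_per_l=table.d_sr_systole,
                   fractional_release=table.fractional_release,
                   ec_gain=table.ec_gain)
    else:
        res.update(total_transient_umol_per_l=None, d_sr_systole_umol_per_l=None,
                   fractional_release=None, ec_gain=None)

    res["flags"] = flags
    return res


def run_pipeline(cohort: Union[str, Path, list], cfg: Optional[AnalysisConfig] = None) -> dict:
    """Analyse a cohort (directory of CSV+sidecar files, or CellRecords).

    Per-cell failures are isolated: the cell's result carries an ``error``
    field and the pipeline continues. The output is deterministic given
    inputs and configuration, and embeds the configuration hash.
    """
    cfg = cfg or AnalysisConfig()
    records = read_cohort(cohort) if isinstance(cohort, (str, Path)) else cohort
    cells = []
    n_failed = 0
    for rec in records:
        try:
            cells.append(analyze_cell(rec, cfg))
        except (CalibrationError, KineticsError, FluxError, TraceFormatError,
                econ.EconomyError) as exc:
            log.warning("cell %s failed: %s", rec.cell_id, exc)
            n_failed += 1
            cells.append({"cell_id": rec.cell_id, "animal_id": rec.animal_id,
                          "group": rec.group, "condition": rec.condition,
                          "error": str(exc), "flags": [f"analysis failed: {exc}"],
                          "amplitude_nM": None, "k_sys_per_s": None,
                          "k_caff_per_s": None, "k_sr_per_s": None, "beta": None,
                          "sr_content_umol_per_l": None, "int_ical_umol_per_l": None,
                          "total_transient_umol_per_l": None,
                          "d_sr_systole_umol_per_l": None,
                          "fractional_release": None, "ec_gain": None})
    flagged = [{"cell_id": c["cell_id"], "flags": c["flags"]}
               for c in cells if c.get("flags")]
    return {"config_hash": cfg.config_hash, "config": json.loads(cfg.to_json()),
            "n_cells": len(cells), "n_failed": n_failed,
            "cells": cells, "flagged": flagged}


def results_to_json(results: dict) -> str:
    """Canonical (byte-stable) JSON serialisation of a results object."""
    return json.dumps(results, sort_keys=True, indent=1)


# ---------------------------------------------------------------------------
# group summaries
# ---------------------------------------------------------------------------


def _sem(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return 0.0
    return float(np.std(x, ddof=1) / np.sqrt(x.size))


def group_summary(results: dict, variable: str, group: Optional[str] = None,
                  log10: bool = False) -> GroupSummary:
    """Cell-level and animal-nested mean +/- SEM of one variable.

    The animal-nested summary averages cells within each animal first, then
    averages the animal means (each animal counts once regardless of its
    cell count). ``log10=True`` transforms values before summarising, as is
    common for continuous-scale cellular data.
    """
    rows = [(c["animal_id"], c.get(variable)) for c in results["cells"]
            if (group is None or c.get("group") == group)]
    rows = [(a, v) for a, v in rows if v is not None and np.isfinite(v)]
    if len(rows) < 2:
        raise ValueError(f"fewer than 2 usable cells for {variable!r} in group {group!r}")
    animals = np.array([a for a, _ in rows])
    vals = np.array([v for _, v in rows], dtype=float)
    if log10:
        if np.any(vals <= 0):
            raise ValueError("log10 transform requires strictly positive values")
        vals = np.log10(vals)
    animal_means = np.array([vals[animals == a].mean() for a in np.unique(animals)])
    return GroupSummary(variable=variable, group=group or "all",
                        cell_mean=float(vals.mean()), cell_sem=_sem(vals),
                        animal_mean=float(animal_means.mean()),
                        animal_sem=_sem(animal_means),
                        n_cells=int(vals.size), n_animals=int(animal_means.size),
                        log10_transformed=log10)


#: Table-shaped report rows: (results variable, printed label)
REPORT_ROWS = [
    ("amplitude_nM", "Delta systolic [Ca]i (nmol/l)"),
    ("beta", "Ca buffering power (beta)"),
    ("total_transient_umol_per_l", "Total Ca transient (umol/l)"),
    ("int_ical_umol_per_l", "Integrated I_CaL (umol/l)"),
    ("sr_content_umol_per_l", "SR Ca content (umol/l)"),
    ("d_sr_systole_umol_per_l", "Delta SR Ca systole (umol/l)"),
    ("fractional_release", "SR fractional release"),
    ("ec_gain", "EC coupling gain"),
]


def economy_report(results: dict) -> pd.DataFrame:
    """Ca-economy table: one row per quantity, one column pair per group."""
    groups = sorted({c.get("group") for c in results["cells"] if c.get("group")})
    rows = []
    for var, label in REPORT_ROWS:
        row: dict = {"quantity": label}
        for g in groups:
            try:
                s = group_summary(results, var, group=g)
                row[f"{g}_mean"] = s.cell_mean
                row[f"{g}_sem"] = s.cell_sem
                row[f"{g}_n"] = s.n_cells
            except ValueError:
                row[f"{g}_mean"] = row[f"{g}_sem"] = np.nan
                row[f"{g}_n"] = 0
        rows.append(row)
    return pd.DataFrame(rows)
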