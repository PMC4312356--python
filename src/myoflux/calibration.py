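"""Fluorescence-to-calcium calibration.

Two calibration routes are supported, matching common practice for atrial
myocyte photometry:

* ratiometric (Fura-2): the standard two-wavelength saturation equation
  ``ca = k_eff * (R - r_min) / (r_max - R)``;
* single-wavelength self-ratio (Fluo-5F): when Ca-saturated fluorescence
  cannot be obtained in situ, the signal is expressed as a pseudo-ratio
  ``R = F / F_rest`` and anchored to an independently measured resting
  [Ca2+]i, giving ``ca = kd * R / (kd / ca_rest + 1 - R)``.

Both maps are strictly monotone on their valid domains and are exact
inverses of the simulator's emission models. Out-of-range samples are
reported, never silently clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class CalibrationError(ValueError):
    """Signal outside the calibration's valid domain."""


@dataclass(frozen=True)
class FuraCalibration:
    """Ratiometric constants. Defaults mirror the synthetic Fura emission model;
    real rigs supply their own in-vitro values (they are configuration, the
    study system's constants are not published)."""

    r_min: float = 0.30  # ratio at zero Ca
    r_max: float = 3.00  # ratio at saturating Ca
    k_eff: float = 1800.0  # effective dissociation constant x beta-ratio, nmol/l

    def __post_init__(self) -> None:
        if not (self.r_max > self.r_min > 0):
            raise CalibrationError("require r_max > r_min > 0")
        if self.k_eff <= 0:
            raise CalibrationError("k_eff must be > 0")


@dataclass(frozen=True)
class FluoSelfRatioCalibration:
    """Self-ratio constants for a single-wavelength dye."""

    kd: float = 1035.0  # dye dissociation constant, nmol/l
    ca_rest: float = 100.0  # resting free Ca anchor, nmol/l
    f_rest: float = 1.0  # resting fluorescence, a.u.

    def __post_init__(self) -> None:
        if self.kd <= 0 or self.ca_rest <= 0 or self.f_rest <= 0:
            raise CalibrationError("kd, ca_rest and f_rest must all be > 0")


def fura_ratio_to_ca(ratio, calib: FuraCalibration):
    """Convert a ratio series to free Ca (nmol/l).

    Returns ``(ca, flagged_idx)``: samples with ratio outside
    (r_min, r_max) are NaN in ``ca`` and their indices reported in
    ``flagged_idx`` — they are never clipped.
    """
    r = np.asarray(ratio, dtype=float)
    bad = ~((r > calib.r_min) & (r < calib.r_max))
    flagged = np.flatnonzero(bad)
    ca = np.full(r.shape, np.nan)
    ok = ~bad
    ca[ok] = calib.k_eff * (r[ok] - calib.r_min) / (calib.r_max - r[ok])
    return ca, flagged


def fluo_selfratio_to_ca(f, calib: FluoSelfRatioCalibration):
    """Convert single-wavelength fluorescence to free Ca (nmol/l).

    Uses the pseudo-ratio R = f/f_rest; R = 1 maps exactly to the resting
    anchor. Saturated samples (denominator <= 0) raise, naming the first
    offending index.
    """
    f = np.asarray(f, dtype=float)
    r = f / calib.f_rest
    denom = calib.kd / calib.ca_rest + 1.0 - r
    bad = np.flatnonzero(denom <= 0)
    if bad.size:
        raise CalibrationError(
            f"saturated fluorescence at sample index {bad[0]} "
            f"(pseudo-ratio {r.flat[bad[0]]:.3f} >= {calib.kd / calib.ca_rest + 1.0:.3f})")
    return calib.kd * r / denom
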