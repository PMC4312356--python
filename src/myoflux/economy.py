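"""Cellular Ca2+ economy: the per-cell bookkeeping of a beat.

Definitions (free Ca in nmol/l, everything volumetric in umol/l of cell
volume):

* total Ca transient      = beta * d[Ca]_i / 1000
* systolic dSR Ca         = total Ca transient - integrated I_CaL entry
* SR fractional release   = systolic dSR / SR content
* EC coupling gain        = systolic dSR / integrated I_CaL entry

The implemented systolic-dSR form (total minus entry) is the one that
reproduces a consistent economy table; the alternative literal reading
"SR content - (total - entry)" yields the post-release SR content instead
and is exposed as :func:`sr_content_after_release` for comparison — the two
disagree by exactly the SR content, and the discrepancy is documented, not
resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class EconomyError(ValueError):
    pass


@dataclass
class EconomyTable:
    """Table of per-cell Ca-economy quantities."""

    d_sys_ca: float  # nmol/l
    beta: float
    total_transient: float  # umol/l
    int_ical: float  # umol/l
    sr_content: float  # umol/l
    d_sr_systole: float  # umol/l
    fractional_release: float
    ec_gain: float
    flags: list = field(default_factory=list)

    @classmethod
    def from_measurements(cls, d_sys_ca: float, beta: float, int_ical: float,
                          sr_content: float) -> "EconomyTable":
        total = total_ca_transient(beta, d_sys_ca)
        d_sr = delta_sr_systole(total, int_ical)
        flags = []
        if total < int_ical:
            flags.append("total transient smaller than I_CaL entry")
        frac = fractional_release(d_sr, sr_content)
        if not (0.0 <= frac <= 1.0):
            flags.append("fractional release outside [0, 1]")
        gain = ec_gain(d_sr, int_ical)
        return cls(d_sys_ca=d_sys_ca, beta=beta, total_transient=total,
                   int_ical=int_ical, sr_content=sr_content, d_sr_systole=d_sr,
                   fractional_release=frac, ec_gain=gain, flags=flags)


def total_ca_transient(beta: float, d_sys_ca: float) -> float:
    """Total cytosolic Ca needed for the systolic rise, umol/l.

    ``beta`` dimensionless, ``d_sys_ca`` in nmol/l free Ca.
    """
    if beta <= 0:
        raise EconomyError("beta must be > 0")
    if d_sys_ca < 0:
        raise EconomyError("d_sys_ca must be >= 0")
    return beta * d_sys_ca / 1000.0


def delta_sr_systole(total_transient: float, int_ical: float) -> float:
    """SR contribution to the systolic rise: total minus L-type entry, umol/l."""
    return total_transient - int_ical


def sr_content_after_release(sr_content: float, total_transient: float,
                             int_ical: float) -> float:
    """SR content immediately after release: content - (total - entry), umol/l."""
    return sr_content - (total_transient - int_ical)


def fractional_release(d_sr_systole: float, sr_content: float) -> float:
    """Fraction of the SR content released per beat."""
    if sr_content == 0:
        raise EconomyError("sr_content must be non-zero")
    return d_sr_systole / sr_content


def ec_gain(d_sr_systole: float, int_ical: float) -> float:
    """Excitation-contraction coupling gain: SR Ca released per unit trigger entry."""
    if int_ical == 0:
        raise EconomyError("int_ical must be non-zero")
    return d_sr_systole / int_ical


def percent_change(reference_mean: float, comparison_mean: float) -> float:
    """Signed percent change, 100*(ref - comp)/ref.

    Positive values are reductions relative to the reference (the convention
    used for group contrasts such as "reduced by 28%"); increases come out
    negative.
    """
    if reference_mean == 0:
        raise EconomyError("reference mean must be non-zero")
    return 100.0 * (reference_mean - comparison_mean) / reference_mean
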