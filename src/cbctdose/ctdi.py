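"""Cone-beam CT dose indices from axial dose profiles.

The quantities computed here are the standard wide-beam CT dosimetry
statistics:

* ``dpi`` — dose profile integral, DPI_l = ∫_{-l/2}^{l/2} D(z) dz,
* ``ctdi_a`` — aperture-normalized index CTDI_a,l = DPI_l / T with T
  the *actual* (physical) beam width; constant across apertures once
  the integration range captures the scatter tails,
* ``ctdi_w`` — weighted CTDI combining the central-axis value with the
  mean of four peripheral values (default weights 1/2, 1/2),
* ``mean_ctdi_w`` / ``dlp`` — the scan-level mean weighted index and
  the dose-length product DLP = mean CTDIw × T,
* ``ctdi_truncated`` — the pencil-chamber variants CTDI100, D̄100 and
  CTDI300 with their fixed ±50 / ±150 mm integration ranges,
* ``f0`` — the central ray dose D(0),
* ``percent_difference`` — the reporting comparison between a
  point-dose estimate and the fully integrated index.

Integrals use the trapezoid rule with linear endpoint interpolation
when ±l/2 falls between samples; all arithmetic is done in cGy·mm and
converted to cGy·cm only for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .profiles import DoseProfile

__all__ = [
    "CtdiConfig",
    "dpi",
    "ctdi_a",
    "ctdi_w",
    "mean_ctdi_w",
    "dlp",
    "ctdi_truncated",
    "f0",
    "percent_difference",
]


@dataclass(frozen=True)
class CtdiConfig:
    """Configuration of the index calculations.

    ``weights`` are the (center, periphery) combination weights — the
    1/2, 1/2 choice by default; the conventional 1/3, 2/3 is available
    for cross-checks.  ``nominal_collimation_nT_mm`` is the n·T divisor
    of the truncated pencil-chamber indices.  ``rounding`` is the
    number of decimals used in report output (internal arithmetic stays
    at full precision).
    """

    integration_range_l_mm: float = 600.0
    weights: tuple[float, float] = (0.5, 0.5)
    nominal_collimation_nT_mm: float | None = None
    rounding: int = 2

    def __post_init__(self) -> None:
        w_c, w_p = self.weights
        if w_c < 0 or w_p < 0 or abs(w_c + w_p - 1.0) > 1e-9:
            raise ValueError(f"weights must be nonnegative and sum to 1, got {self.weights}")
        if self.integration_range_l_mm <= 0:
            raise ValueError("integration_range_l_mm must be > 0")


def _interp_dose(profile: DoseProfile, z: float) -> float:
    return float(np.interp(z, profile.z_mm, profile.dose_cgy))


def dpi(profile: DoseProfile, l_mm: float) -> float:
    """Dose profile integral over [-l/2, +l/2], in cGy·mm.

    Trapezoid rule on the samples inside the range, with the endpoint
    values obtained by linear interpolation when ±l/2 falls between
    grid points.
    """
    if l_mm <= 0:
        raise ValueError("integration range l must be > 0")
    if not profile.covers(l_mm):
        raise ValueError(
            f"profile grid [{profile.z_mm[0]:g}, {profile.z_mm[-1]:g}] mm does not "
            f"cover the integration range ±{l_mm / 2:g} mm"
        )
    lo, hi = -l_mm / 2.0, l_mm / 2.0
    z, d = profile.z_mm, profile.dose_cgy
    inner = (z > lo) & (z < hi)
    zs = np.concatenate(([lo], z[inner], [hi]))
    ds = np.concatenate(([_interp_dose(profile, lo)], d[inner], [_interp_dose(profile, hi)]))
    return float(np.trapezoid(ds, zs))


def ctdi_a(profile: DoseProfile, T_mm: float, l_mm: float) -> float:
    """Aperture-normalized index CTDI_a,l = DPI_l / T, in cGy.

    The divisor is the *actual* beam width T at isocenter, not the
    nominal reconstruction width.
    """
    if T_mm <= 0:
        raise ValueError("actual beam width T must be > 0")
    return dpi(profile, l_mm) / T_mm


def ctdi_w(
    center_val: float,
    periphery_vals: float | Sequence[float],
    config: CtdiConfig | None = None,
) -> float:
    """Weighted CTDI: w_c·center + w_p·mean(periphery), in cGy.

    ``periphery_vals`` is the four peripheral values, or a single
    pre-averaged peripheral value.
    """
    config = config or CtdiConfig()
    vals = np.atleast_1d(np.asarray(periphery_vals, dtype=float))
    if vals.size not in (1, 4):
        raise ValueError(
            f"expected 4 peripheral values or 1 pre-averaged value, got {vals.size}"
        )
    w_c, w_p = config.weights
    return w_c * float(center_val) + w_p * float(vals.mean())


def mean_ctdi_w(ctdi_w_values: Sequence[float]) -> tuple[float, float]:
    """Mean and sample (n-1) standard deviation of per-width CTDIw values."""
    vals = np.asarray(ctdi_w_values, dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 CTDIw values to average")
    return float(vals.mean()), float(vals.std(ddof=1))


def dlp(mean_ctdi_w_cgy: float, T_mm: float) -> float:
    """Dose-length product DLP = mean CTDIw × T, in cGy·cm."""
    if mean_ctdi_w_cgy < 0 or T_mm < 0:
        raise ValueError("DLP inputs must be nonnegative")
    return mean_ctdi_w_cgy * (T_mm / 10.0)


_TRUNCATED_RANGES = {"ctdi100": 100.0, "d100": 100.0, "ctdi300": 300.0}


def ctdi_truncated(
    profile: DoseProfile,
    config: CtdiConfig,
    variant: Literal["ctdi100", "d100", "ctdi300"],
) -> float:
    """Pencil-chamber indices with fixed truncated integration ranges.

    ``ctdi100`` = DPI(100 mm) / nT, ``ctdi300`` = DPI(300 mm) / nT, and
    ``d100`` = DPI(100 mm) / 100 mm, the average absorbed dose within a
    100 mm chamber.  The nT-divided variants need
    ``config.nominal_collimation_nT_mm``.
    """
    if variant not in _TRUNCATED_RANGES:
        raise ValueError(f"unknown variant {variant!r}")
    l_mm = _TRUNCATED_RANGES[variant]
    integral = dpi(profile, l_mm)
    if variant == "d100":
        return integral / 100.0
    nT = config.nominal_collimation_nT_mm
    if nT is None or nT <= 0:
        raise ValueError("nominal_collimation_nT_mm must be set for nT-divided variants")
    return integral / nT


def f0(profile: DoseProfile) -> float:
    """Central ray dose D(0), in cGy (linear interpolation off-grid)."""
    return _interp_dose(profile, 0.0)


def percent_difference(reference: float, other: float, decimals: int = 1) -> float:
    """|other - reference| / reference × 100, rounded for reporting."""
    if reference <= 0:
        raise ValueError("reference value must be > 0")
    return round(abs(other - reference) / reference * 100.0, decimals)
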