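"""Synthetic axial dose profiles for cone-beam CT dosimetry.

A wide cone beam's axial dose profile can be built up as the
superposition of narrow-beam responses: the profile is the physical
aperture (a rectangle of width T) convolved with a narrow-beam line
spread function (LSF).  This module implements the simplest LSF with
the three behaviours wide-beam phantom dosimetry exhibits:

* a primary impulse (optionally Gaussian-blurred penumbra) carrying
  fraction ``1 - eta`` of the energy,
* an exponential scatter tail with decay length ``d`` carrying
  fraction ``eta``, broader at the phantom center than the periphery,
* an equilibrium (infinitely-wide-beam) plateau dose ``h``.

Because the LSF has unit area, the profile integral is exactly h*T for
any aperture — the aperture-normalized dose index is constant — and the
central dose saturates as f(0) = h*(1 - eta*exp(-T/2d)).  Both closed
forms are exposed as oracles for testing the numerical pipeline.

The kernel is a *model*, declared as such: the default parameters are
illustrative of a 125 kVp head/body technique, not fitted to any
measured system.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal, stats

from .profiles import PERIPHERAL_POSITIONS, POSITIONS, DoseProfile, ProfileSet
from .protocols import BeamCollimation, FanMode, ScanProtocol, collimation_for

__all__ = [
    "ScatterModelParams",
    "GridTruncationError",
    "narrow_beam_lsf",
    "generate_profile",
    "analytic_f0",
    "analytic_area",
    "generate_profile_set",
    "default_grid",
    "DEFAULT_PARAMS",
]


class GridTruncationError(ValueError):
    """The z grid is too short to contain the scatter tails."""


@dataclass(frozen=True)
class ScatterModelParams:
    """Parameters of the narrow-beam scatter kernel at one position.

    Parameters
    ----------
    equilibrium_dose_h : float
        Plateau dose (cGy) an infinitely wide beam would deposit at
        this position.
    scatter_fraction_eta : float
        Fraction of the kernel area in the exponential tail, in [0, 1).
    scatter_range_d : float
        Exponential decay length of the tail, mm (> 0).
    penumbra_sigma : float
        Gaussian blur (mm) of the aperture edges; 0 means a sharp edge
        (impulse primary core).
    noise_cv : float
        Coefficient of variation of multiplicative Gaussian noise
        applied per sample; 0 means noiseless.
    """

    equilibrium_dose_h: float
    scatter_fraction_eta: float
    scatter_range_d: float
    penumbra_sigma: float = 0.0
    noise_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.equilibrium_dose_h <= 0:
            raise ValueError("equilibrium_dose_h must be > 0")
        if not 0.0 <= self.scatter_fraction_eta < 1.0:
            raise ValueError("scatter_fraction_eta must lie in [0, 1)")
        if self.scatter_range_d <= 0:
            raise ValueError("scatter_range_d must be > 0")
        if self.penumbra_sigma < 0:
            raise ValueError("penumbra_sigma must be >= 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


#: Illustrative defaults (cGy, -, mm) per fan mode: (center, periphery).
#: Chosen to land in the qualitative range of a 125 kVp head/body CBCT
#: technique; no quantitative claim depends on them.  The 1% noise CV
#: mirrors the sub-percent statistical uncertainty of a well-converged
#: Monte Carlo profile.
DEFAULT_PARAMS: dict[FanMode, tuple[ScatterModelParams, ScatterModelParams]] = {
    FanMode.FULL_FAN: (
        ScatterModelParams(8.8, 0.60, 60.0, noise_cv=0.01),
        ScatterModelParams(8.8, 0.45, 40.0, noise_cv=0.01),
    ),
    FanMode.HALF_FAN: (
        ScatterModelParams(3.1, 0.75, 90.0, noise_cv=0.01),
        ScatterModelParams(5.5, 0.50, 60.0, noise_cv=0.01),
    ),
}


def default_grid(half_length_mm: float = 450.0, spacing_mm: float = 0.5) -> np.ndarray:
    """Uniform symmetric z grid, default +/-450 mm at 0.5 mm spacing."""
    n = int(round(half_length_mm / spacing_mm))
    return np.arange(-n, n + 1) * spacing_mm


def narrow_beam_lsf(z_mm: np.ndarray, params: ScatterModelParams) -> np.ndarray:
    """Evaluate the unit-area narrow-beam kernel (per mm).

    kernel(z) = (1 - eta) * g(z; sigma) + (eta / 2d) * exp(-|z| / d)

    with g a unit-area Gaussian.  For sigma = 0 the primary core is a
    Dirac impulse: it is represented discretely as 1/dz at z = 0, so the
    sampled kernel still integrates to one on a uniform grid.  The
    kernel is even in z.
    """
    z = np.asarray(z_mm, dtype=float)
    eta, d, sigma = (
        params.scatter_fraction_eta,
        params.scatter_range_d,
        params.penumbra_sigma,
    )
    tail = (eta / (2.0 * d)) * np.exp(-np.abs(z) / d)
    if sigma > 0:
        core = (1.0 - eta) * stats.norm.pdf(z, scale=sigma)
    else:
        core = np.zeros_like(z)
        at_zero = np.isclose(z, 0.0)
        if at_zero.any():
            dz = np.min(np.abs(np.diff(np.unique(z)))) if z.size > 1 else 1.0
            core[at_zero] = (1.0 - eta) / dz
    return core + tail


def analytic_f0(T_mm: float, params: ScatterModelParams) -> float:
    """Closed-form central ray dose f(0) for a sharp-edged beam.

    f(0) = h * (1 - eta * exp(-T / 2d)); monotone nondecreasing in T and
    tending to the equilibrium dose h as T grows.  Only defined for
    penumbra_sigma = 0.
    """
    if params.penumbra_sigma != 0:
        raise ValueError("no closed form for f(0) with penumbra_sigma > 0")
    if T_mm <= 0:
        raise ValueError("beam width T must be > 0")
    h, eta, d = (
        params.equilibrium_dose_h,
        params.scatter_fraction_eta,
        params.scatter_range_d,
    )
    return h * (1.0 - eta * math.exp(-T_mm / (2.0 * d)))


def analytic_area(T_mm: float, params: ScatterModelParams) -> float:
    """Closed-form profile integral over (-inf, inf): h * T (cGy mm).

    The kernel has unit area, so convolution preserves the rectangle's
    area regardless of eta, d or sigma.
    """
    return params.equilibrium_dose_h * T_mm


def _closed_form_profile(z: np.ndarray, T: float, params: ScatterModelParams) -> np.ndarray:
    """Sharp-edge (sigma = 0) profile: rect(T) convolved with the kernel.

    Piecewise-exact integration of the exponential tail across the
    aperture; the primary core contributes (1 - eta) inside |z| < T/2
    (1/2 exactly at the edge, the convention that keeps the sampled
    step trapezoid-exact when the edge lands on a grid point).
    """
    h, eta, d = (
        params.equilibrium_dose_h,
        params.scatter_fraction_eta,
        params.scatter_range_d,
    )
    az = np.abs(z)
    half = T / 2.0
    core = np.where(az < half, 1.0, 0.0)
    core[np.isclose(az, half)] = 0.5
    inside = az <= half
    scatter = np.empty_like(az)
    scatter[inside] = 1.0 - 0.5 * (
        np.exp(-(half - az[inside]) / d) + np.exp(-(half + az[inside]) / d)
    )
    out = ~inside
    scatter[out] = 0.5 * (
        np.exp(-(az[out] - half) / d) - np.exp(-(az[out] + half) / d)
    )
    return h * ((1.0 - eta) * core + eta * scatter)


def generate_profile(
    T_mm: float,
    params: ScatterModelParams,
    z_grid: np.ndarray | None = None,
    position: str = "center",
    rng: np.random.Generator | None = None,
) -> DoseProfile:
    """Generate one axial dose profile for an aperture of width T.

    dose(z) = h * (unit rectangle of width T) convolved with the
    narrow-beam LSF, sampled on ``z_grid``.  With ``penumbra_sigma = 0``
    the convolution is evaluated in closed form; otherwise numerically.
    Multiplicative Gaussian noise with CV ``params.noise_cv`` is applied
    per sample when an ``rng`` is given and the CV is positive; doses
    are clipped at zero to preserve nonnegativity.

    Raises
    ------
    GridTruncationError
        If the grid half-length is below 3*d + T, i.e. the scatter
        tails would be visibly truncated.
    """
    if T_mm <= 0:
        raise ValueError("beam width T must be > 0")
    z = default_grid() if z_grid is None else np.asarray(z_grid, dtype=float)
    half_length = min(-z[0], z[-1])
    required = 3.0 * params.scatter_range_d + T_mm
    if half_length < required:
        raise GridTruncationError(
            f"grid half-length {half_length:.0f} mm truncates the scatter tails; "
            f"need >= 3*d + T = {required:.0f} mm"
        )
    if params.penumbra_sigma == 0:
        dose = _closed_form_profile(z, T_mm, params)
    else:
        dz = z[1] - z[0]
        rect = np.where(np.abs(z) < T_mm / 2.0, 1.0, 0.0)
        rect[np.isclose(np.abs(z), T_mm / 2.0)] = 0.5
        kernel = narrow_beam_lsf(z, params)
        dose = params.equilibrium_dose_h * signal.fftconvolve(
            rect, kernel, mode="same"
        ) * dz
        dose = np.clip(dose, 0.0, None)
    if rng is not None and params.noise_cv > 0:
        dose = dose * (1.0 + params.noise_cv * rng.standard_normal(dose.shape))
        dose = np.clip(dose, 0.0, None)
    return DoseProfile(z_mm=z, dose_cgy=dose, position=position, beam_width_T_mm=T_mm)


def generate_profile_set(
    protocol: ScanProtocol,
    collimation: BeamCollimation | int,
    center_params: ScatterModelParams | None = None,
    periphery_params: ScatterModelParams | None = None,
    seed: int = 0,
    noise_cv: float | None = None,
    z_grid: np.ndarray | None = None,
) -> ProfileSet:
    """Generate the five-position profile bundle for one beam width.

    The four peripheral positions share one parameter set and differ
    only by their (independent) noise realizations.  The random stream
    is position-major in the order center, 12, 3, 6, 9 o'clock, so a
    given seed yields a bit-reproducible set.  ``noise_cv`` overrides
    the parameter sets' own noise level when given.
    """
    if isinstance(collimation, int):
        collimation = collimation_for(protocol, collimation)
    if center_params is None or periphery_params is None:
        dflt_c, dflt_p = DEFAULT_PARAMS[protocol.fan_mode]
        center_params = center_params or dflt_c
        periphery_params = periphery_params or dflt_p
    if (
        center_params.scatter_fraction_eta < periphery_params.scatter_fraction_eta
        or center_params.scatter_range_d < periphery_params.scatter_range_d
    ):
        raise ValueError(
            "center profiles must be at least as broad as peripheral ones "
            "(eta and d at the center must be >= the periphery's)"
        )
    if noise_cv is not None:
        center_params = replace(center_params, noise_cv=noise_cv)
        periphery_params = replace(periphery_params, noise_cv=noise_cv)
    T = collimation.actual_width_T_mm
    rng = np.random.default_rng(seed)
    profiles = {}
    for pos in POSITIONS:
        params = center_params if pos == "center" else periphery_params
        profiles[pos] = generate_profile(T, params, z_grid, position=pos, rng=rng)
    return ProfileSet(
        protocol=protocol, collimation=collimation, profiles=profiles, seed=seed
    )
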