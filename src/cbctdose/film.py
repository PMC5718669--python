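"""Radiochromic film dosimetry: scans, calibration, profile extraction.

Film strips exposed in a CTDI phantom are digitized on a flatbed
scanner (reflective RGB, 16 bit/channel, 72 dpi).  Radiochromic film is
most sensitive in the red, so only the red channel is used (the channel
remains configurable).  The chain is

    pixel value (PV) --calibration--> exposure (R) --0.869--> dose (cGy)

with the PV-to-exposure map built from ion-chamber calibration points
as a shape-preserving monotone piecewise-cubic interpolant; film
darkens with exposure, so PV decreases monotonically and the fitted
curve is refused outside the calibrated PV range rather than
extrapolated.  Net optical density follows the reflective-densitometry
convention NOD = log10(PV_unexposed / PV).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .profiles import DoseProfile

__all__ = [
    "ROENTGEN_TO_RAD",
    "DOSE_TO_FILM",
    "CalibrationPoint",
    "CalibrationCurve",
    "FilmStrip",
    "roi_mean_red",
    "net_optical_density",
    "build_calibration",
    "pv_to_exposure",
    "exposure_to_dose",
    "extract_normalized_profile",
    "measure_beam_width_fwhm",
    "render_film_strip",
]

logger = logging.getLogger(__name__)

#: Exposure-in-air to absorbed-dose-in-air conversion, rad per roentgen.
ROENTGEN_TO_RAD = 0.869
#: Dose-to-air to dose-to-film conversion factor.
DOSE_TO_FILM = 1.00

MM_PER_INCH = 25.4


@dataclass(frozen=True)
class CalibrationPoint:
    """One (scanner pixel value, ion-chamber exposure) calibration pair."""

    pixel_value: float
    exposure_R: float

    def __post_init__(self) -> None:
        if self.pixel_value <= 0:
            raise ValueError("pixel_value must be > 0")
        if self.exposure_R < 0:
            raise ValueError("exposure must be >= 0")


class CalibrationCurve:
    """Monotone PV <-> exposure mapping through the calibration points.

    The interpolant is shape-preserving piecewise cubic (PCHIP), so a
    monotone point set yields a monotone curve that passes through
    every knot exactly.  Evaluation outside the calibrated PV range is
    refused: clamping or extrapolating a dosimetric calibration
    silently biases profile tails.
    """

    def __init__(self, points: Sequence[CalibrationPoint]):
        pts = sorted(points, key=lambda p: p.exposure_R)
        if len(pts) < 3:
            raise ValueError("calibration needs at least 3 points")
        exposures = np.array([p.exposure_R for p in pts])
        pvs = np.array([p.pixel_value for p in pts])
        if np.any(np.diff(exposures) <= 0):
            raise ValueError("duplicate or non-increasing exposures in calibration")
        if np.any(np.diff(pvs) >= 0):
            raise ValueError(
                "pixel values must strictly decrease with exposure (darkening film)"
            )
        self.points = tuple(pts)
        # PCHIP needs ascending x: PV ascends as exposure descends.
        self._pv_to_exp = PchipInterpolator(pvs[::-1], exposures[::-1])
        self._exp_to_pv = PchipInterpolator(exposures, pvs)
        self.pv_min = float(pvs[-1])
        self.pv_max = float(pvs[0])
        self.exposure_max = float(exposures[-1])

    def __call__(self, pv):
        return self.exposure(pv)

    def exposure(self, pv):
        """Exposure (R) at the given pixel value(s); no extrapolation."""
        pv_arr = np.asarray(pv, dtype=float)
        bad = (pv_arr < self.pv_min) | (pv_arr > self.pv_max)
        if np.any(bad):
            offending = np.atleast_1d(pv_arr)[np.atleast_1d(bad)]
            raise ValueError(
                "extrapolation refused: pixel value(s) outside calibrated range "
                f"[{self.pv_min:g}, {self.pv_max:g}]: {offending[:10].tolist()}"
            )
        out = np.clip(self._pv_to_exp(pv_arr), 0.0, None)
        return float(out) if np.isscalar(pv) else out

    def pixel_value(self, exposure_R):
        """Inverse map: pixel value at the given exposure(s)."""
        e = np.asarray(exposure_R, dtype=float)
        if np.any(e < 0) or np.any(e > self.exposure_max):
            raise ValueError(
                f"exposure outside calibrated range [0, {self.exposure_max:g}] R"
            )
        out = self._exp_to_pv(e)
        return float(out) if np.isscalar(exposure_R) else out

    @classmethod
    def from_csv(cls, path: str | Path) -> "CalibrationCurve":
        """Read a two-column CSV: pixel_value, exposure_R."""
        df = pd.read_csv(path)
        return build_calibration(
            list(zip(df["pixel_value"], df["exposure_R"]))
        )


@dataclass(frozen=True)
class FilmStrip:
    """A digitized film strip: RGB image, scan resolution, z axis.

    ``z_axis`` names the image axis that runs along the rotation axis
    (0 = rows, 1 = columns).  16-bit scans are expected; 8-bit input is
    accepted with a warning.
    """

    image: np.ndarray
    dpi: float = 72.0
    z_axis: int = 1

    def __post_init__(self) -> None:
        img = np.asarray(self.image)
        if img.ndim != 3 or img.shape[2] != 3 or img.size == 0:
            raise ValueError("image must be a nonempty (H, W, 3) RGB array")
        if self.dpi <= 0:
            raise ValueError("dpi must be > 0")
        if self.z_axis not in (0, 1):
            raise ValueError("z_axis must be 0 (rows) or 1 (columns)")
        if img.dtype == np.uint8:
            logger.warning("8-bit film scan: quantization will limit dose precision")
        object.__setattr__(self, "image", img)

    @property
    def pixel_pitch_mm(self) -> float:
        return MM_PER_INCH / self.dpi

    @classmethod
    def from_tiff(cls, path: str | Path, dpi: float = 72.0, z_axis: int = 1) -> "FilmStrip":
        import tifffile

        return cls(image=tifffile.imread(str(path)), dpi=dpi, z_axis=z_axis)

    def to_tiff(self, path: str | Path) -> Path:
        import tifffile

        path = Path(path)
        tifffile.imwrite(str(path), self.image)
        return path


def roi_mean_red(strip: FilmStrip, roi: tuple[int, int, int, int]) -> float:
    """Mean red-channel pixel value over a rectangular ROI.

    ``roi`` is (row_start, row_stop, col_start, col_stop) in pixels,
    half-open.  Out-of-bounds or empty ROIs are refused.
    """
    r0, r1, c0, c1 = roi
    h, w = strip.image.shape[:2]
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError(f"ROI {roi} empty or outside image bounds {(h, w)}")
    return float(strip.image[r0:r1, c0:c1, 0].astype(float).mean())


def net_optical_density(pv: float, pv_unexposed: float) -> float:
    """Net optical density log10(PV_unexposed / PV).

    Zero for unexposed film; increases as the film darkens.  A PV above
    the unexposed value means a negative NOD and flags miscalibration.
    """
    if pv <= 0 or pv_unexposed <= 0:
        raise ValueError("pixel values must be > 0")
    if pv > pv_unexposed:
        raise ValueError(
            f"negative NOD: pv {pv:g} exceeds unexposed pv {pv_unexposed:g} "
            "(miscalibrated or swapped arguments)"
        )
    return float(np.log10(pv_unexposed / pv))


def build_calibration(
    points: Sequence[CalibrationPoint] | Sequence[tuple[float, float]],
) -> CalibrationCurve:
    """Build the monotone PV-to-exposure calibration curve."""
    pts = [
        p if isinstance(p, CalibrationPoint) else CalibrationPoint(*p)
        for p in points
    ]
    return CalibrationCurve(pts)


def pv_to_exposure(curve: CalibrationCurve, pv):
    """Interpolated exposure (R) for pixel value(s) in the calibrated range."""
    return curve.exposure(pv)


def exposure_to_dose(exposure_R) -> float | np.ndarray:
    """Absorbed dose (cGy) from exposure (R): dose = R × 0.869 × 1.00."""
    e = np.asarray(exposure_R, dtype=float)
    if np.any(e < 0):
        raise ValueError("exposure must be >= 0")
    out = e * ROENTGEN_TO_RAD * DOSE_TO_FILM
    return float(out) if np.isscalar(exposure_R) else out


def extract_normalized_profile(
    strip: FilmStrip,
    curve: CalibrationCurve,
    pv_unexposed: float | None = None,
    lane: tuple[int, int] | None = None,
) -> DoseProfile:
    """Extract the axial dose profile from a film strip, normalized to f(0)=1.

    The lane (a band of pixels across the strip, perpendicular to z) is
    averaged in the red channel per z sample, converted PV -> exposure
    -> dose, placed on a z grid with pitch 25.4/dpi mm centered at the
    dose-weighted centroid of the beam core (samples at or above half
    maximum), and divided by the interpolated central (z = 0) dose.
    """
    img = strip.image if strip.z_axis == 1 else np.transpose(strip.image, (1, 0, 2))
    n_lane, n_z = img.shape[:2]
    if lane is None:
        lane = (0, n_lane)
    l0, l1 = lane
    if not (0 <= l0 < l1 <= n_lane):
        raise ValueError(f"lane {lane} outside strip (height {n_lane})")
    pv = img[l0:l1, :, 0].astype(float).mean(axis=0)
    bad = (pv < curve.pv_min) | (pv > curve.pv_max)
    if np.any(bad):
        raise ValueError(
            "pixel values outside the calibrated range at z indices "
            f"{np.flatnonzero(bad)[:10].tolist()} (saturated or unexposed film?)"
        )
    dose = exposure_to_dose(curve.exposure(pv))
    pitch = strip.pixel_pitch_mm
    z = np.arange(n_z, dtype=float) * pitch
    core = dose >= 0.5 * dose.max()
    center = float(np.average(z[core], weights=dose[core]))
    z = z - center
    d0 = float(np.interp(0.0, z, dose))
    if d0 <= 0:
        raise ValueError("central dose is zero; cannot normalize the profile")
    return DoseProfile(z_mm=z, dose_cgy=dose / d0, position="center")


def measure_beam_width_fwhm(profile: DoseProfile) -> float:
    """Beam width as full width at half maximum, in mm.

    The outermost crossings of half the profile maximum are located
    with linear sub-sample interpolation.  Profiles that never fall
    below half maximum on both sides of the peak are refused.
    """
    d = profile.dose_cgy
    z = profile.z_mm
    half = d.max() / 2.0
    above = d > half
    if not above.any() or above[0] or above[-1]:
        raise ValueError("profile does not cross half maximum on both sides")
    i_first = int(np.argmax(above))
    i_last = int(len(above) - 1 - np.argmax(above[::-1]))

    def _cross(i_lo: int, i_hi: int) -> float:
        # linear interpolation of the half-max crossing between samples
        frac = (half - d[i_lo]) / (d[i_hi] - d[i_lo])
        return float(z[i_lo] + frac * (z[i_hi] - z[i_lo]))

    left = _cross(i_first - 1, i_first)
    right = _cross(i_last + 1, i_last)
    return right - left


def render_film_strip(
    profile: DoseProfile,
    curve: CalibrationCurve,
    dpi: float = 72.0,
    lane_px: int = 10,
    peak_dose_cgy: float | None = None,
) -> FilmStrip:
    """Render a dose profile to a synthetic 16-bit film-strip scan.

    Inverse of :func:`extract_normalized_profile`: the profile (scaled
    so its peak equals ``peak_dose_cgy`` when given) is resampled at
    the scanner pitch, converted dose -> exposure -> PV through the
    inverted calibration, and written into every row of a
    ``lane_px``-high RGB image.  Used to close the synthesis/analysis
    round trip in tests and demonstrations.
    """
    pitch = MM_PER_INCH / dpi
    z = np.arange(profile.z_mm[0], profile.z_mm[-1] + pitch / 2, pitch)
    dose = np.interp(z, profile.z_mm, profile.dose_cgy)
    if peak_dose_cgy is not None:
        dose = dose * (peak_dose_cgy / dose.max())
    exposure = dose / (ROENTGEN_TO_RAD * DOSE_TO_FILM)
    pv = np.round(curve.pixel_value(exposure)).astype(np.uint16)
    image = np.empty((lane_px, pv.size, 3), dtype=np.uint16)
    image[..., :] = pv[None, :, None]
    return FilmStrip(image=image, dpi=dpi, z_axis=1)
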