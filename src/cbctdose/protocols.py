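"""Scan-protocol and collimation bookkeeping for CBCT dosimetry.

A linac-mounted kV cone-beam imager acquires either a *full-fan* scan
(head technique, 16 cm PMMA phantom, full bowtie) or a *half-fan* scan
(body technique, 32 cm PMMA phantom, half bowtie).  The console nominal
beam width (1-10 cm at isocenter) maps to a wider physical collimation;
that mapping is a measured lookup table, not a geometric model, so
unknown nominal settings are refused rather than interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping

__all__ = [
    "FanMode",
    "Phantom",
    "ScanProtocol",
    "BeamCollimation",
    "actual_beam_width",
    "make_protocol",
    "HEAD_ACTUAL_WIDTHS_MM",
    "BODY_ACTUAL_WIDTHS_MM",
]


class FanMode(str, Enum):
    FULL_FAN = "full_fan"
    HALF_FAN = "half_fan"


class Phantom(str, Enum):
    HEAD_16CM = "head_16cm"
    BODY_32CM = "body_32cm"

    @property
    def diameter_mm(self) -> float:
        return 160.0 if self is Phantom.HEAD_16CM else 320.0


#: Console-reported physical beam width at isocenter (mm) per nominal
#: width (cm), head (full-fan) technique.  The system collimates 1-3 cm
#: wider than the nominal reconstruction width.
HEAD_ACTUAL_WIDTHS_MM: Mapping[int, float] = {
    1: 20.0, 2: 34.0, 3: 46.0, 4: 60.0, 5: 72.0,
    6: 84.0, 7: 98.0, 8: 110.0, 9: 124.0, 10: 136.0,
}

#: Same lookup for the body (half-fan) technique.
BODY_ACTUAL_WIDTHS_MM: Mapping[int, float] = {
    1: 22.0, 2: 38.0, 3: 52.0, 4: 66.0, 5: 80.0,
    6: 96.0, 7: 110.0, 8: 124.0, 9: 138.0, 10: 154.0,
}


@dataclass(frozen=True)
class ScanProtocol:
    """Acquisition settings for one CBCT scan technique.

    Parameters
    ----------
    fan_mode
        Full-fan (head) or half-fan (body) acquisition.
    phantom
        CTDI phantom the dose profiles are scored in.
    tube_potential_kvp, tube_current_ma
        X-ray technique factors.
    projections
        Number of projections in the 360-degree rotation.
    integration_range_l_mm
        Longitudinal integration range *l* for the dose profile
        integral: 600 mm (head) or 900 mm (body) by default.
    peripheral_depth_mm
        Depth of the four peripheral measurement points below the
        phantom surface (CTDI-phantom convention: 10 mm).
    """

    fan_mode: FanMode
    phantom: Phantom
    tube_potential_kvp: float = 125.0
    tube_current_ma: float = 80.0
    projections: int = 660
    integration_range_l_mm: float = 600.0
    peripheral_depth_mm: float = 10.0

    def __post_init__(self) -> None:
        if self.projections <= 0:
            raise ValueError(f"projections must be > 0, got {self.projections}")
        if self.integration_range_l_mm <= 0:
            raise ValueError(
                f"integration_range_l_mm must be > 0, got {self.integration_range_l_mm}"
            )
        if self.tube_potential_kvp <= 0 or self.tube_current_ma <= 0:
            raise ValueError("tube technique factors must be positive")
        if self.peripheral_depth_mm < 0:
            raise ValueError("peripheral_depth_mm must be >= 0")

    def to_dict(self) -> dict:
        return {
            "fan_mode": self.fan_mode.value,
            "phantom": self.phantom.value,
            "tube_potential_kvp": self.tube_potential_kvp,
            "tube_current_ma": self.tube_current_ma,
            "projections": self.projections,
            "integration_range_l_mm": self.integration_range_l_mm,
            "peripheral_depth_mm": self.peripheral_depth_mm,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScanProtocol":
        d = dict(d)
        d["fan_mode"] = FanMode(d["fan_mode"])
        d["phantom"] = Phantom(d["phantom"])
        return cls(**d)


@dataclass(frozen=True)
class BeamCollimation:
    """Nominal console setting paired with the physical aperture.

    ``actual_width_T_mm`` is the Eq.-style aperture *T* used as the
    divisor in aperture-normalized dose indices.
    """

    nominal_width_cm: int
    actual_width_T_mm: float

    def __post_init__(self) -> None:
        if self.actual_width_T_mm <= 0:
            raise ValueError("actual_width_T_mm must be > 0")
        if self.actual_width_T_mm < 10.0 * self.nominal_width_cm:
            raise ValueError(
                "physical collimation narrower than nominal width: "
                f"{self.actual_width_T_mm} mm < {10 * self.nominal_width_cm} mm"
            )


def actual_beam_width(protocol: ScanProtocol, nominal_width_cm: int) -> float:
    """Look up the physical beam width at isocenter, in mm.

    Raises
    ------
    KeyError
        If the nominal width has no calibration entry.  The table is a
        measured calibration; no interpolation or extrapolation is done.
    """
    table = (
        HEAD_ACTUAL_WIDTHS_MM
        if protocol.fan_mode is FanMode.FULL_FAN
        else BODY_ACTUAL_WIDTHS_MM
    )
    try:
        if float(nominal_width_cm) != int(nominal_width_cm):
            raise KeyError
        return table[int(nominal_width_cm)]
    except (KeyError, ValueError, TypeError):
        raise KeyError(
            f"no calibration entry for nominal width {nominal_width_cm!r} cm "
            f"({protocol.fan_mode.value}); valid settings are 1-10 cm"
        ) from None


def collimation_for(protocol: ScanProtocol, nominal_width_cm: int) -> BeamCollimation:
    """Convenience: build a :class:`BeamCollimation` from the lookup table."""
    return BeamCollimation(
        nominal_width_cm=int(nominal_width_cm),
        actual_width_T_mm=actual_beam_width(protocol, nominal_width_cm),
    )


_DEFAULTS = {
    FanMode.FULL_FAN: dict(phantom=Phantom.HEAD_16CM, integration_range_l_mm=600.0),
    FanMode.HALF_FAN: dict(phantom=Phantom.BODY_32CM, integration_range_l_mm=900.0),
}


def make_protocol(fan_mode: FanMode | str, **overrides) -> ScanProtocol:
    """Build a protocol with technique defaults for the given fan mode.

    Defaults: 125 kVp, 80 mA, 660 projections; head pairs with the 16 cm
    phantom and l = 600 mm, body with the 32 cm phantom and l = 900 mm.
    Any field can be overridden by keyword.
    """
    mode = FanMode(fan_mode)
    settings = dict(_DEFAULTS[mode])
    if "phantom" in overrides:
        overrides["phantom"] = Phantom(overrides["phantom"])
    settings.update(overrides)
    return ScanProtocol(fan_mode=mode, **settings)
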