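"""Axial dose-profile containers and their CSV serialization.

The elementary datum of this package is the axial dose profile D(z):
dose (cGy) sampled on a uniform z grid (mm) along the axis of rotation,
at one of five phantom positions (center + four peripheral points at
12/3/6/9 o'clock, 10 mm below the surface).  A :class:`ProfileSet`
bundles the five profiles for one beam width under one scan protocol.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .protocols import BeamCollimation, ScanProtocol

__all__ = ["POSITIONS", "DoseProfile", "ProfileSet"]

#: Measurement positions, position-major generator order.
POSITIONS: tuple[str, ...] = (
    "center",
    "periphery_12",
    "periphery_3",
    "periphery_6",
    "periphery_9",
)

PERIPHERAL_POSITIONS: tuple[str, ...] = POSITIONS[1:]


@dataclass(frozen=True)
class DoseProfile:
    """Sampled axial dose profile at one phantom position.

    ``z_mm`` must be uniformly spaced and symmetric about z = 0; dose is
    in cGy and nonnegative.  ``beam_width_T_mm`` records the physical
    aperture the profile was acquired with.
    """

    z_mm: np.ndarray
    dose_cgy: np.ndarray
    position: str = "center"
    beam_width_T_mm: float | None = None

    def __post_init__(self) -> None:
        z = np.asarray(self.z_mm, dtype=float)
        d = np.asarray(self.dose_cgy, dtype=float)
        object.__setattr__(self, "z_mm", z)
        object.__setattr__(self, "dose_cgy", d)
        if z.ndim != 1 or d.shape != z.shape:
            raise ValueError("z_mm and dose_cgy must be matching 1-D arrays")
        if z.size < 2:
            raise ValueError("profile needs at least 2 samples")
        dz = np.diff(z)
        if not np.all(dz > 0):
            raise ValueError("z grid must be strictly increasing")
        if not np.allclose(dz, dz[0], rtol=1e-9, atol=1e-9):
            raise ValueError("z grid must be uniformly spaced")
        if np.any(d < 0):
            raise ValueError("dose must be nonnegative everywhere")
        if self.position not in POSITIONS:
            raise ValueError(f"unknown position {self.position!r}")

    @property
    def spacing_mm(self) -> float:
        return float(self.z_mm[1] - self.z_mm[0])

    @property
    def half_length_mm(self) -> float:
        return float(min(-self.z_mm[0], self.z_mm[-1]))

    def covers(self, l_mm: float) -> bool:
        """Whether the grid spans the integration range [-l/2, +l/2]."""
        return self.z_mm[0] <= -l_mm / 2 and self.z_mm[-1] >= l_mm / 2

    def scaled(self, factor: float) -> "DoseProfile":
        return DoseProfile(self.z_mm, self.dose_cgy * factor,
                           self.position, self.beam_width_T_mm)


@dataclass(frozen=True)
class ProfileSet:
    """Center + four peripheral profiles for one beam width.

    All five profiles share one z grid and one beam width.
    """

    protocol: ScanProtocol
    collimation: BeamCollimation
    profiles: Mapping[str, DoseProfile]
    seed: int | None = None

    def __post_init__(self) -> None:
        missing = set(POSITIONS) - set(self.profiles)
        if missing:
            raise ValueError(f"profile set missing positions: {sorted(missing)}")
        ref = self.profiles["center"]
        for pos, prof in self.profiles.items():
            if prof.z_mm.shape != ref.z_mm.shape or not np.array_equal(
                prof.z_mm, ref.z_mm
            ):
                raise ValueError(f"profile {pos!r} not on the shared z grid")
            if prof.beam_width_T_mm != ref.beam_width_T_mm:
                raise ValueError(f"profile {pos!r} has a different beam width")

    @property
    def center(self) -> DoseProfile:
        return self.profiles["center"]

    @property
    def peripherals(self) -> list[DoseProfile]:
        return [self.profiles[p] for p in PERIPHERAL_POSITIONS]

    @property
    def beam_width_T_mm(self) -> float:
        return self.collimation.actual_width_T_mm

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: z_mm, dose_cGy, position, beam_width_mm."""
        parts = []
        for pos in POSITIONS:
            prof = self.profiles[pos]
            parts.append(
                pd.DataFrame(
                    {
                        "z_mm": prof.z_mm,
                        "dose_cGy": prof.dose_cgy,
                        "position": pos,
                        "beam_width_mm": self.beam_width_T_mm,
                    }
                )
            )
        return pd.concat(parts, ignore_index=True)

    def write_csv(self, path: str | Path, sidecar: bool = True) -> Path:
        """Write the long-format CSV plus a JSON sidecar with metadata."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        if sidecar:
            meta = {
                "protocol": self.protocol.to_dict(),
                "nominal_width_cm": self.collimation.nominal_width_cm,
                "actual_width_T_mm": self.collimation.actual_width_T_mm,
                "seed": self.seed,
            }
            path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
        return path

    @classmethod
    def read_csv(cls, path: str | Path) -> "ProfileSet":
        """Read a profile-set CSV written by :meth:`write_csv`."""
        path = Path(path)
        df = pd.read_csv(path)
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise FileNotFoundError(f"missing metadata sidecar {sidecar}")
        meta = json.loads(sidecar.read_text())
        protocol = ScanProtocol.from_dict(meta["protocol"])
        collimation = BeamCollimation(
            nominal_width_cm=meta["nominal_width_cm"],
            actual_width_T_mm=meta["actual_width_T_mm"],
        )
        profiles = {}
        for pos, grp in df.groupby("position", sort=False):
            profiles[str(pos)] = DoseProfile(
                z_mm=grp["z_mm"].to_numpy(),
                dose_cgy=grp["dose_cGy"].to_numpy(),
                position=str(pos),
                beam_width_T_mm=float(grp["beam_width_mm"].iloc[0]),
            )
        return cls(
            protocol=protocol,
            collimation=collimation,
            profiles=profiles,
            seed=meta.get("seed"),
        )
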