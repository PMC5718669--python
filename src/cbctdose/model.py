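"""Model/results objects for the per-scan CTDI and DLP report.

:class:`CbctDoseIndexModel` is built from a list of five-position
profile sets (one per beam width) and a :class:`~cbctdose.ctdi.CtdiConfig`;
:meth:`~CbctDoseIndexModel.fit` integrates every profile, combines the
positional indices into the weighted CTDI per beam width, and returns a
:class:`CbctDoseIndexResults` carrying the per-width table (DPI, CTDIw,
DLP, f(0)), the scan-level mean CTDIw with its sample standard
deviation, and a ``summary()`` in the layout of a per-collimation dose
report.

Report conventions
------------------
* The reported per-width DPI is the weighted quantity CTDIw,l × T (the
  positionally combined integral); per-position integrals remain
  available in ``results.per_position``.
* DLP = mean CTDIw × T uses the mean *rounded to the report precision*
  (2 decimals by default), matching how such tables are printed; full
  precision is kept in ``results.mean_ctdi_w``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from . import ctdi
from .ctdi import CtdiConfig
from .profiles import PERIPHERAL_POSITIONS, ProfileSet
from .protocols import ScanProtocol

__all__ = ["CtdiRow", "CbctDoseIndexModel", "CbctDoseIndexResults", "build_report"]


class CtdiRow(NamedTuple):
    """One beam width's report line (units: mm, cGy·cm, cGy, cGy·cm, cGy)."""

    beam_width_T_mm: float
    dpi_l_cgycm: float
    ctdi_w_l_cgy: float
    dlp_cgycm: float
    f0_cgy: float


class CbctDoseIndexModel:
    """Weighted-CTDI model over a family of beam widths.

    Parameters
    ----------
    profile_sets
        One :class:`ProfileSet` per beam width; all must share one scan
        protocol.
    config
        Index configuration.  When omitted, the integration range is
        taken from the shared protocol and the 1/2, 1/2 weights apply.
    """

    def __init__(
        self,
        profile_sets: Sequence[ProfileSet],
        config: CtdiConfig | None = None,
    ) -> None:
        sets = list(profile_sets)
        if not sets:
            raise ValueError("need at least one profile set")
        proto = sets[0].protocol
        for s in sets[1:]:
            if s.protocol.to_dict() != proto.to_dict():
                raise ValueError("all profile sets must share one scan protocol")
        self.profile_sets = sorted(sets, key=lambda s: s.beam_width_T_mm)
        self.protocol = proto
        self.config = config or CtdiConfig(
            integration_range_l_mm=proto.integration_range_l_mm
        )

    @classmethod
    def from_csv_dir(
        cls, directory: str | Path, config: CtdiConfig | None = None
    ) -> "CbctDoseIndexModel":
        """Build from a directory of profile-set CSVs (with sidecars)."""
        directory = Path(directory)
        paths = sorted(directory.glob("*.csv"))
        if not paths:
            raise FileNotFoundError(f"no profile CSVs in {directory}")
        return cls([ProfileSet.read_csv(p) for p in paths], config=config)

    def fit(self) -> "CbctDoseIndexResults":
        """Integrate, weight and tabulate the dose indices."""
        l = self.config.integration_range_l_mm
        per_position = []
        widths, ctdi_ws, f0s = [], [], []
        for pset in self.profile_sets:
            T = pset.beam_width_T_mm
            center = ctdi.ctdi_a(pset.center, T, l)
            periph = [ctdi.ctdi_a(p, T, l) for p in pset.peripherals]
            for pos, val, prof in zip(
                ("center",) + PERIPHERAL_POSITIONS,
                [center] + periph,
                [pset.center] + pset.peripherals,
            ):
                per_position.append(
                    {
                        "beam_width_mm": T,
                        "position": pos,
                        "dpi_cGymm": ctdi.dpi(prof, l),
                        "ctdi_a_cGy": val,
                        "f0_cGy": ctdi.f0(prof),
                    }
                )
            widths.append(T)
            ctdi_ws.append(ctdi.ctdi_w(center, periph, self.config))
            f0s.append(ctdi.f0(pset.center))
        mean, sd = (
            ctdi.mean_ctdi_w(ctdi_ws) if len(ctdi_ws) >= 2 else (ctdi_ws[0], 0.0)
        )
        mean_rounded = round(mean, self.config.rounding)
        rows = [
            CtdiRow(
                beam_width_T_mm=T,
                dpi_l_cgycm=w * T / 10.0,
                ctdi_w_l_cgy=w,
                dlp_cgycm=ctdi.dlp(mean_rounded, T),
                f0_cgy=f,
            )
            for T, w, f in zip(widths, ctdi_ws, f0s)
        ]
        return CbctDoseIndexResults(
            model=self,
            rows=rows,
            mean_ctdi_w=mean,
            mean_ctdi_w_sd=sd,
            per_position=pd.DataFrame(per_position),
        )


@dataclass(frozen=True)
class CbctDoseIndexResults:
    """Fitted per-scan dose-index report."""

    model: CbctDoseIndexModel
    rows: list[CtdiRow]
    mean_ctdi_w: float
    mean_ctdi_w_sd: float
    per_position: pd.DataFrame

    @property
    def protocol(self) -> ScanProtocol:
        return self.model.protocol

    @property
    def config(self) -> CtdiConfig:
        return self.model.config

    def to_frame(self, rounded: bool = False) -> pd.DataFrame:
        """Per-width table; ``rounded`` applies the report precision."""
        df = pd.DataFrame(self.rows, columns=CtdiRow._fields)
        df = df.rename(
            columns={
                "beam_width_T_mm": "beam_width_mm",
                "dpi_l_cgycm": "dpi_cGycm",
                "ctdi_w_l_cgy": "ctdi_w_cGy",
                "dlp_cgycm": "dlp_cGycm",
                "f0_cgy": "f0_cGy",
            }
        )
        if rounded:
            dec = self.config.rounding
            for col in ("dpi_cGycm", "ctdi_w_cGy", "dlp_cGycm", "f0_cGy"):
                df[col] = df[col].round(dec)
        return df

    def summary(self) -> str:
        """Human-readable per-collimation dose report."""
        l = int(self.config.integration_range_l_mm)
        df = self.to_frame(rounded=True)
        dec = self.config.rounding
        lines = [
            f"Cone-beam CT dose index report ({self.protocol.fan_mode.value}, "
            f"{self.protocol.phantom.value}, l = {l} mm)",
            "=" * 78,
            f"{'T (mm)':>8} {'DPI_%d (cGy cm)' % l:>18} {'CTDIw_%d (cGy)' % l:>16} "
            f"{'DLP (cGy cm)':>14} {'f(0) (cGy)':>12}",
            "-" * 78,
        ]
        for _, r in df.iterrows():
            lines.append(
                f"{r.beam_width_mm:>8.0f} {r.dpi_cGycm:>18.{dec}f} "
                f"{r.ctdi_w_cGy:>16.{dec}f} {r.dlp_cGycm:>14.{dec}f} "
                f"{r.f0_cGy:>12.{dec}f}"
            )
        lines += [
            "-" * 78,
            f"Mean CTDIw,{l} = {self.mean_ctdi_w:.{dec}f} "
            f"+/- {self.mean_ctdi_w_sd:.{dec}f} cGy (sample sd over beam widths)",
        ]
        return "\n".join(lines)

    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame(rounded=True).to_csv(path, index=False)
        return path

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol.to_dict(),
            "mean_ctdi_w_cGy": self.mean_ctdi_w,
            "mean_ctdi_w_sd_cGy": self.mean_ctdi_w_sd,
            "rows": self.to_frame().to_dict(orient="records"),
        }

    def plot(self, ax=None):
        """CTDIw and DLP against beam width (quick diagnostic plot)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.to_frame()
        ax.plot(df.beam_width_mm, df.ctdi_w_cGy, "o-", label="CTDIw (cGy)")
        ax2 = ax.twinx()
        ax2.plot(df.beam_width_mm, df.dlp_cGycm, "s--", color="C1", label="DLP (cGy cm)")
        ax.set_xlabel("actual beam width T (mm)")
        ax.set_ylabel("CTDIw (cGy)")
        ax2.set_ylabel("DLP (cGy cm)")
        ax.figure.legend(loc="upper left")
        return ax


def build_report(
    profile_sets: Sequence[ProfileSet], config: CtdiConfig | None = None
) -> CbctDoseIndexResults:
    """One-call report: fit the dose-index model over the given sets."""
    return CbctDoseIndexModel(profile_sets, config=config).fit()
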