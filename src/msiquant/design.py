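"""Calibration-design and slide-layout tables.

The on-tissue calibration design mirrors the study layout: a dilution
series (0.2, 2, 5, 20, 40 ng/uL budesonide, 500 nL drops, i.e. 0.1-20 ng
deposited) spotted in four replicates on homogenate sections at three
surfactant (poractant alfa) levels: 0, 4 and 8 mg/g.  Each design row
describes one expected spot; ``row_hint``/``col_hint`` give its
approximate image position for automated annotation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import List, Optional

import pandas as pd

__all__ = ["CalibrationDesign", "SectionRole", "default_concentrations"]

SPOT_COLUMNS = [
    "spot_id",
    "row_hint",
    "col_hint",
    "conc_ng_per_ul",
    "drop_volume_ul",
    "lipid_mg_per_g",
    "replicate",
]

#: Dilution series of the study, ng/uL.
def default_concentrations() -> List[float]:
    return [0.2, 2.0, 5.0, 20.0, 40.0]


@dataclass
class SectionRole:
    """Expected tissue section: role plus approximate image position."""

    role: str  # sample | control-2.5ng | control-10ng | untreated | calibration
    row_hint: float
    col_hint: float


@dataclass
class CalibrationDesign:
    """Spot design table plus optional section-role layout."""

    spots: pd.DataFrame
    sections: List[SectionRole] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in SPOT_COLUMNS if c not in self.spots.columns]
        if missing:
            raise ValueError(f"design table missing columns: {missing}")
        if (self.spots["conc_ng_per_ul"] < 0).any():
            raise ValueError("concentrations must be >= 0")
        if (self.spots["drop_volume_ul"] <= 0).any():
            raise ValueError("drop volumes must be > 0")

    @property
    def amounts_ng(self) -> pd.Series:
        """Deposited amount per spot: concentration x drop volume."""
        return self.spots["conc_ng_per_ul"] * self.spots["drop_volume_ul"]

    def with_amounts(self) -> pd.DataFrame:
        df = self.spots.copy()
        df["amount_ng"] = self.amounts_ng
        return df

    def to_csv(self, path: os.PathLike) -> None:
        self.with_amounts().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: os.PathLike) -> "CalibrationDesign":
        df = pd.read_csv(path)
        return cls(spots=df[[c for c in df.columns if c in SPOT_COLUMNS]])

    @classmethod
    def grid_layout(
        cls,
        centers,  # iterable of (row, col) per spot
        concentrations: Optional[List[float]] = None,
        n_replicates: int = 4,
        lipid_levels: Optional[List[float]] = None,
        drop_volume_ul: float = 0.5,
    ) -> "CalibrationDesign":
        """Design for a replicate x concentration grid repeated per lipid level.

        ``centers`` must enumerate spots lipid-major, then replicate
        (rows), then concentration (columns) — the order the synthetic
        slide generator uses.
        """
        concentrations = concentrations or default_concentrations()
        lipid_levels = lipid_levels if lipid_levels is not None else [0.0, 4.0, 8.0]
        rows = []
        centers = list(centers)
        expect = len(lipid_levels) * n_replicates * len(concentrations)
        if len(centers) != expect:
            raise ValueError(f"expected {expect} centers, got {len(centers)}")
        i = 0
        for lipid in lipid_levels:
            for rep in range(1, n_replicates + 1):
                for conc in concentrations:
                    r, c = centers[i]
                    rows.append(
                        dict(
                            spot_id=f"L{lipid:g}-R{rep}-C{conc:g}",
                            row_hint=float(r),
                            col_hint=float(c),
                            conc_ng_per_ul=float(conc),
                            drop_volume_ul=float(drop_volume_ul),
                            lipid_mg_per_g=float(lipid),
                            replicate=rep,
                        )
                    )
                    i += 1
        return cls(spots=pd.DataFrame(rows))
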