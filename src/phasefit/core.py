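"""Shared domain types for the phase-separation fitness framework.

The experimental system is a pair of otherwise isogenic yeast strains
expressing a Ura3p-GFP fusion: one soluble (SOL) and one carrying an
aggregation-prone tag that drives the protein into stable intracellular
deposits (AGG, foci-forming).  Fitness is probed by growing the strains
in media where Ura3p activity is dispensable (+uracil), essential
(-uracil) or toxic (+5FOA, where Ura3p converts 5-fluoroorotic acid into
5-fluorouracil).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Medium",
    "Strain",
    "EnvironmentCondition",
    "CELL_COLUMNS",
    "validate_cells",
    "cells_to_csv",
    "cells_from_csv",
]


class Medium(enum.Enum):
    """Growth-medium role of Ura3p activity."""

    PLUS_URA = "PLUS_URA"   # uracil supplied: activity dispensable
    MINUS_URA = "MINUS_URA"  # no uracil: activity essential
    FOA = "FOA"             # 5FOA present: activity toxic

    @classmethod
    def parse(cls, value: "Medium | str") -> "Medium":
        if isinstance(value, Medium):
            return value
        try:
            return cls[str(value).upper().replace("-", "_").replace("+", "PLUS_")]
        except KeyError:
            allowed = ", ".join(m.name for m in cls)
            raise ValueError(f"unknown medium {value!r}; allowed: {allowed}") from None


class Strain(enum.Enum):
    SOL = "SOL"  # soluble Ura3p, homogeneous cytoplasmic fluorescence
    AGG = "AGG"  # aggregation-prone Ura3p, forms foci

    @classmethod
    def parse(cls, value: "Strain | str") -> "Strain":
        if isinstance(value, Strain):
            return value
        try:
            return cls[str(value).upper()]
        except KeyError:
            raise ValueError(f"unknown strain {value!r}; allowed: SOL, AGG") from None


@dataclass
class EnvironmentCondition:
    """One growth environment (e.g. "30C", "37C", "0.5M NaCl") in one medium.

    Parameters
    ----------
    label : str
        Short environment label, unique within an environment table.
    medium : Medium
        Role of Ura3p activity in this medium.
    tau_sol : float
        Doubling time of the soluble strain in hours; must be positive.
    S : float, optional
        Selection coefficient of AGG relative to SOL, per hour.  May be
        left unset until estimated from a competition assay.
    """

    label: str
    medium: Medium = Medium.PLUS_URA
    tau_sol: float = 2.7
    S: float | None = None

    def __post_init__(self) -> None:
        self.medium = Medium.parse(self.medium)
        if not np.isfinite(self.tau_sol) or self.tau_sol <= 0:
            raise ValueError(f"tau_sol must be > 0 h, got {self.tau_sol}")
        if self.S is not None and not np.isfinite(self.S):
            raise ValueError("S must be finite when set")


#: canonical per-cell table schema shared by the generator and the
#: image-analysis pipeline, so downstream modules are source-agnostic
CELL_COLUMNS = ("cell_id", "strain", "area_um2", "f_total", "f_foci", "f_cyto")


def validate_cells(cells: pd.DataFrame) -> pd.DataFrame:
    """Check a per-cell fluorescence table against its invariants.

    Requires the canonical columns, positive areas, non-negative
    fluorescence and exact conservation f_cyto + f_foci == f_total.
    Returns the table unchanged for chaining.
    """
    missing = [c for c in CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise ValueError(f"cell table missing columns: {missing}")
    if len(cells) == 0:
        return cells
    if (cells["area_um2"] <= 0).any():
        raise ValueError("cell areas must be positive")
    if (cells["f_foci"] < 0).any() or (cells["f_cyto"] < 0).any():
        raise ValueError("fluorescence values must be non-negative")
    resid = cells["f_total"] - (cells["f_foci"] + cells["f_cyto"])
    if not np.allclose(resid, 0.0, atol=1e-9 * max(1.0, float(cells["f_total"].abs().max()))):
        raise ValueError("conservation violated: f_cyto + f_foci != f_total")
    return cells


def cells_to_csv(cells: pd.DataFrame, path) -> None:
    validate_cells(cells).to_csv(path, index=False)


def cells_from_csv(path) -> pd.DataFrame:
    return validate_cells(pd.read_csv(path))
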