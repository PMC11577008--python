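"""In-memory containers for simulated tissue: 3D cell fields and 2D sections.

A :class:`CellField` is the source of truth for simulations — a marked 3D
point set (cell type, centre, soma radius) in a bounded box.  A section
table is its 2D counterpart, one row per cell with the columns produced by
confocal ROI quantification (``cell_id, cell_type, x_um, y_um,
soma_area_um2``), stored as a plain :class:`pandas.DataFrame`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SECTION_COLUMNS = ["cell_id", "cell_type", "x_um", "y_um", "soma_area_um2"]
SECTION_CELL_TYPES = frozenset({"ChI", "pSPN", "PV", "astrocyte"})


@dataclass(frozen=True)
class CellField:
    """Marked 3D point set of somata in a box.

    ``cells`` has columns ``cell_type`` (str), ``x``, ``y``, ``z`` (um) and
    ``radius`` (um).  ``box`` is the (Lx, Ly, Lz) extent; all centres lie
    inside it.  ``process`` records how the points were placed.
    """

    box: tuple[float, float, float]
    cells: pd.DataFrame
    process: str = "poisson"
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"cell_type", "x", "y", "z", "radius"}
        missing = required - set(self.cells.columns)
        if missing:
            raise ValueError(f"cells table missing columns: {sorted(missing)}")
        for axis, extent in zip("xyz", self.box):
            vals = self.cells[axis]
            if len(vals) and (vals.min() < 0 or vals.max() > extent):
                raise ValueError(f"cell {axis}-coordinates fall outside box")

    def counts(self) -> dict[str, int]:
        return self.cells["cell_type"].value_counts().to_dict()


def validate_section_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a section table's schema and invariants; returns the table."""
    missing = set(SECTION_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"section table missing columns: {sorted(missing)}")
    if table["cell_id"].duplicated().any():
        raise ValueError("cell_id values must be unique")
    if not (table["soma_area_um2"] > 0).all():
        raise ValueError("soma_area_um2 must be positive")
    if not np.isfinite(table[["x_um", "y_um"]].to_numpy()).all():
        raise ValueError("coordinates must be finite")
    bad = set(table["cell_type"].unique()) - SECTION_CELL_TYPES
    if bad:
        raise ValueError(f"unknown cell types: {sorted(bad)}")
    return table


def read_section_table(path) -> pd.DataFrame:
    """Read a delimited section table (comma or tab separated)."""
    table = pd.read_csv(path, sep=None, engine="python")
    return validate_section_table(table)


def write_section_table(table: pd.DataFrame, path) -> None:
    validate_section_table(table).to_csv(path, index=False)
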