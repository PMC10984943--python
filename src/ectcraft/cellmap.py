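"""Pseudo-single-cell maps from deconvolved abundances.

Abundance rows are discretised to integer cell counts — rounding up per
cell type, down for cancer cells (the asymmetry avoids inflating the
visually dominant cancer compartment) — and each counted cell is placed
at its spot center plus a uniform random offset within a 40 µm jitter
disc, giving the single-cell-like section maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import AbundanceMatrix, Section

__all__ = [
    "CellMap",
    "DEFAULT_JITTER_UM",
    "discretize_abundance",
    "place_pseudocells",
    "plot_cellmap",
]

#: Default jitter radius for pseudo-cell placement, µm.
DEFAULT_JITTER_UM = 40.0


@dataclass
class CellMap:
    """Discretised pseudo-cells of one section."""

    section_id: str
    cells: pd.DataFrame  # columns: cell_type, x_um, y_um, spot_id
    jitter_radius: float = DEFAULT_JITTER_UM

    def __post_init__(self) -> None:
        required = {"cell_type", "x_um", "y_um", "spot_id"}
        missing = required - set(self.cells.columns)
        if missing:
            raise ValueError(f"cell table missing columns {sorted(missing)}")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def counts_by_type(self) -> pd.Series:
        return self.cells["cell_type"].value_counts()

    def to_tsv(self, path: str | Path) -> None:
        self.cells.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, section_id: str,
                 jitter_radius: float = DEFAULT_JITTER_UM) -> "CellMap":
        return cls(section_id, pd.read_csv(path, sep="\t"), jitter_radius)


def discretize_abundance(
    abundance: AbundanceMatrix, cancer_types: Iterable[str] = ()
) -> np.ndarray:
    """Integer spot x cell-type counts: ceiling, floor for cancer types.

    Exact integers are fixed points of both rules, so zeros stay zero.
    """
    cancer = set(cancer_types)
    unknown = cancer - set(abundance.cell_types)
    if unknown:
        raise ValueError(f"unknown cancer types: {sorted(unknown)}")
    is_cancer = np.array([t in cancer for t in abundance.cell_types])
    counts = np.where(
        is_cancer[None, :],
        np.floor(abundance.values),
        np.ceil(abundance.values),
    )
    return counts.astype(np.int64)


def place_pseudocells(
    counts: np.ndarray,
    section: Section,
    jitter_radius: float = DEFAULT_JITTER_UM,
    seed: int | np.random.Generator | None = 0,
) -> CellMap:
    """Place ``counts[i, j]`` pseudo-cells of type j inside spot i.

    Offsets are uniform over a disc of ``jitter_radius`` around the spot
    center, so every pseudo-cell stays within the spot footprint when
    the radius does not exceed the spot diameter.  Deterministic under a
    fixed seed.
    """
    counts = np.asarray(counts)
    if counts.shape != (section.n_spots, len(section.cell_types)):
        raise ValueError(
            f"counts shape {counts.shape} does not match section "
            f"({section.n_spots} spots x {len(section.cell_types)} types)"
        )
    if np.any(counts < 0):
        raise ValueError("negative pseudo-cell count")
    if jitter_radius < 0 or jitter_radius > section.spot_diameter:
        raise ValueError(
            "jitter_radius must be in [0, spot_diameter] so placement "
            "stays within the spot footprint"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spot_idx, type_idx = np.nonzero(counts)
    reps = counts[spot_idx, type_idx]
    spot_rep = np.repeat(spot_idx, reps)
    type_rep = np.repeat(type_idx, reps)
    n = spot_rep.size
    r = jitter_radius * np.sqrt(rng.random(n))
    theta = 2.0 * np.pi * rng.random(n)
    xy = section.coords[spot_rep] + np.column_stack(
        [r * np.cos(theta), r * np.sin(theta)]
    )
    types = np.asarray(section.cell_types, dtype=object)
    spot_ids = np.asarray(section.spot_ids, dtype=object)
    cells = pd.DataFrame(
        {
            "cell_type": types[type_rep],
            "x_um": xy[:, 0],
            "y_um": xy[:, 1],
            "spot_id": spot_ids[spot_rep],
        }
    )
    return CellMap(section.section_id, cells, jitter_radius)


def plot_cellmap(
    cellmap: CellMap,
    path: str | Path,
    cell_types: Sequence[str] | None = None,
    point_size: float = 2.0,
) -> None:
    """Basic scatter export of a pseudo-single-cell map (PNG/SVG by suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = cellmap.cells
    if cell_types is not None:
        df = df[df["cell_type"].isin(cell_types)]
    fig, ax = plt.subplots(figsize=(7, 7))
    for name, grp in df.groupby("cell_type", sort=True):
        ax.scatter(grp["x_um"], grp["y_um"], s=point_size, label=str(name),
                   linewidths=0)
    ax.invert_yaxis()  # image convention: y grows downward
    ax.set_aspect("equal")
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    ax.set_title(cellmap.section_id)
    if df["cell_type"].nunique() <= 20:
        ax.legend(markerscale=3, fontsize=6, loc="center left",
                  bbox_to_anchor=(1.0, 0.5))
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
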