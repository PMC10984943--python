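"""Spatial statistics on pseudo-single-cell maps.

Nearest-distance tables between cell types (per section, never pooled),
median-distance rankings around an anchor type, Shannon diversity of
cell-type fractions, transfer of pathologist compartment polygons onto
spots, and one-versus-all enrichment tests of cell states per
compartment.
"""

from __future__ import annotations

import itertools
import math
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from scipy.spatial import cKDTree
from shapely.geometry import Point
from shapely.ops import unary_union

from .cellmap import CellMap
from .io import AnnotationLayer, Section

__all__ = [
    "nearest_distance_table",
    "rank_by_median_distance",
    "shannon_index",
    "transfer_annotations",
    "compartment_enrichment",
    "rank_sum_test",
]


def nearest_distance_table(
    cellmaps: CellMap | Sequence[CellMap],
) -> pd.DataFrame:
    """Nearest-neighbour distance from every pseudo-cell to every other type.

    For each reference cell and each *other* cell type present in the
    same section, the Euclidean distance (µm) to the nearest pseudo-cell
    of that type is kept.  Sections are processed independently; a
    target type absent from a section simply emits no row.

    Returns a DataFrame with columns section_id, reference_index (row
    position in the section's cell table), reference_type, target_type,
    nearest_distance.
    """
    if isinstance(cellmaps, CellMap):
        cellmaps = [cellmaps]
    if not cellmaps or all(cm.n_cells == 0 for cm in cellmaps):
        raise ValueError("no pseudo-cells to measure")
    columns = [
        "section_id",
        "reference_index",
        "reference_type",
        "target_type",
        "nearest_distance",
    ]
    frames = []
    for cm in cellmaps:
        cells = cm.cells
        xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
        types = cells["cell_type"].to_numpy()
        for target in sorted(pd.unique(types)):
            mask = types == target
            tree = cKDTree(xy[mask])
            ref = ~mask
            if not ref.any():
                continue
            d, _ = tree.query(xy[ref], k=1)
            frames.append(
                pd.DataFrame(
                    {
                        "section_id": cm.section_id,
                        "reference_index": np.flatnonzero(ref),
                        "reference_type": types[ref],
                        "target_type": target,
                        "nearest_distance": d,
                    }
                )
            )
    if not frames:
        return pd.DataFrame(columns=columns)
    return pd.concat(frames, ignore_index=True).sort_values(
        ["section_id", "reference_index", "target_type"], ignore_index=True
    )


def rank_by_median_distance(
    table: pd.DataFrame, anchor_type: str
) -> pd.DataFrame:
    """Reference types ranked by median nearest distance to the anchor.

    Rows of all sections with ``target_type == anchor_type`` are pooled
    (unweighted); the median is taken per reference type and the result
    sorted ascending, ties broken by type name.
    """
    rows = table[table["target_type"] == anchor_type]
    if rows.empty:
        raise ValueError(f"anchor type {anchor_type!r} absent from the table")
    med = (
        rows.groupby("reference_type")["nearest_distance"]
        .median()
        .rename("median_distance")
        .reset_index()
    )
    return med.sort_values(
        ["median_distance", "reference_type"], ignore_index=True
    )


def shannon_index(fractions: Sequence[float]) -> float:
    """Shannon diversity H = -sum p_i ln p_i of a composition.

    Non-negative inputs are renormalised; zero entries contribute
    nothing.  All-zero input is an error.
    """
    p = np.asarray(fractions, dtype=float)
    if np.any(p < 0) or not np.all(np.isfinite(p)):
        raise ValueError("fractions must be finite and non-negative")
    total = p.sum()
    if total <= 0:
        raise ValueError("all-zero composition has no diversity")
    p = p[p > 0] / total
    return float(-(p * np.log(p)).sum())


def transfer_annotations(
    layer: AnnotationLayer,
    section: Section,
    cancer_label: str = "Cancer cells",
    cancer_threshold: float = 0.30,
) -> pd.Series:
    """Assign a compartment label to each spot from annotation polygons.

    Each spot is modeled as a disc of the section's spot diameter.  If
    the cancer compartment covers more than ``cancer_threshold`` of the
    disc the spot is labeled cancer; otherwise the label with the
    largest covered area wins (majority-area rule), lexicographically
    smallest label on ties; spots not covered by any polygon are
    "unassigned".
    """
    if not 0 < cancer_threshold < 1:
        raise ValueError("cancer_threshold must be in (0, 1)")
    merged: dict[str, object] = {}
    for label in layer.labels():
        geoms = [g for lbl, g in layer.polygons if lbl == label]
        merged[label] = unary_union(geoms)
    radius = section.spot_diameter / 2.0
    disc_area = math.pi * radius**2
    labels = []
    for x, y in section.coords:
        disc = Point(x, y).buffer(radius, quad_segs=32)
        fracs = {
            label: disc.intersection(geom).area / disc_area
            for label, geom in merged.items()
        }
        if fracs.get(cancer_label, 0.0) > cancer_threshold:
            labels.append(cancer_label)
            continue
        positive = {lbl: f for lbl, f in fracs.items() if f > 0}
        if not positive:
            labels.append("unassigned")
            continue
        best = max(positive.values())
        winners = sorted(lbl for lbl, f in positive.items() if f == best)
        labels.append(winners[0])
    return pd.Series(labels, index=section.spot_ids, name="compartment")


def rank_sum_test(x: Sequence[float], y: Sequence[float],
                  exact_max: int = 20) -> float:
    """Two-sided Wilcoxon rank-sum p value with midranks for ties.

    Exhaustive enumeration of all group assignments when the pooled
    sample size is at most ``exact_max``; otherwise the normal
    approximation with tie-corrected variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    nx, n = x.size, pooled.size
    w_obs = ranks[:nx].sum()
    mu = nx * (n + 1) / 2.0
    if n <= exact_max:
        count = 0
        total = 0
        dev = abs(w_obs - mu)
        for comb in itertools.combinations(range(n), nx):
            w = ranks[list(comb)].sum()
            total += 1
            if abs(w - mu) >= dev - 1e-12:
                count += 1
        return count / total
    # normal approximation with tie correction
    _, tie_counts = np.unique(pooled, return_counts=True)
    ny = n - nx
    var = nx * ny * (n + 1) / 12.0 * (
        1.0 - (tie_counts**3 - tie_counts).sum() / (n**3 - n)
    )
    if var <= 0:
        return 1.0
    z = (w_obs - mu) / math.sqrt(var)
    return float(2.0 * scipy.stats.norm.sf(abs(z)))


def compartment_enrichment(
    cellmaps: Mapping[str, CellMap],
    spot_annotations: Mapping[str, pd.Series],
    member_states: Sequence[str],
    min_sections: int = 2,
) -> pd.DataFrame:
    """One-versus-all enrichment of cell states within compartments.

    ``member_states`` are the states of one parent cell type (e.g. the
    CAF clusters).  Per section and compartment, the proportion of each
    state among the parent's pseudo-cells is computed; each state's
    per-section proportions are compared against the pooled per-section
    proportions of all other member states with a two-sided Wilcoxon
    rank-sum test (exact by enumeration for pooled n <= 20).  Direction
    is called by median comparison.  A pooled Fisher's exact test of
    state counts (state vs rest, compartment vs rest; sections pooled)
    is emitted alongside, as is a Benjamini-Hochberg adjusted column.
    """
    states = list(member_states)
    rows = []
    counts = {}  # (section, compartment, state) -> count
    compartments: set[str] = set()
    for sid, cm in cellmaps.items():
        ann = spot_annotations[sid]
        cells = cm.cells
        cells = cells[cells["cell_type"].isin(states)]
        comp = cells["spot_id"].map(ann)
        for (c, t), k in cells.groupby([comp, cells["cell_type"]], observed=True).size().items():
            counts[(sid, c, t)] = k
            compartments.add(c)
    compartments.discard("unassigned")

    # per-section proportions
    props: dict[tuple[str, str], dict[str, float]] = {}
    for sid in cellmaps:
        for c in compartments:
            total = sum(counts.get((sid, c, t), 0) for t in states)
            if total == 0:
                continue
            props[(sid, c)] = {
                t: counts.get((sid, c, t), 0) / total for t in states
            }

    grand_total = sum(counts.get((sid, c, t), 0)
                      for sid in cellmaps for c in compartments for t in states)
    results = []
    for c in sorted(compartments):
        per_section = [v for (sid, cc), v in props.items() if cc == c]
        if len(per_section) < min_sections:
            warnings.warn(
                f"compartment {c!r} has parent-type cells in "
                f"{len(per_section)} section(s); state rows omitted",
                RuntimeWarning,
            )
            continue
        for t in states:
            x = np.array([p[t] for p in per_section])
            y = np.concatenate(
                [[p[u] for p in per_section] for u in states if u != t]
            )
            p_val = rank_sum_test(x, y)
            direction = "enriched" if np.median(x) > np.median(y) else "depleted"
            # pooled 2x2 Fisher: state vs others, this compartment vs others
            a = sum(counts.get((sid, c, t), 0) for sid in cellmaps)
            b = sum(counts.get((sid, c, u), 0) for sid in cellmaps
                    for u in states if u != t)
            a_out = sum(counts.get((sid, cc, t), 0) for sid in cellmaps
                        for cc in compartments if cc != c)
            b_out = grand_total - a - b - a_out
            _, fisher_p = scipy.stats.fisher_exact([[a, b], [a_out, b_out]])
            results.append(
                {
                    "state": t,
                    "compartment": c,
                    "n_sections": len(per_section),
                    "median_proportion": float(np.median(x)),
                    "p_value": p_val,
                    "direction": direction,
                    "fisher_p": float(fisher_p),
                }
            )
    out = pd.DataFrame(results)
    if not out.empty:
        out["p_bh"] = scipy.stats.false_discovery_control(out["p_value"], method="bh")
    return out
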