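"""EcoCellTypes: groups of cell types that co-occur across niches.

The niche x cell-type mean-composition matrix is centered and scaled per
cell type (across niches), then cell-type profiles are clustered
hierarchically (Euclidean distance, Ward linkage — Ward.D2 semantics,
i.e. squared distances inside the merge criterion).  The dendrogram is
cut either at an explicit group count or at the count maximising the
mean silhouette.  Each resulting group of co-occurring cell types is an
EcoCellType (ECT); bulk cell-type fractions can be aggregated to ECT
fractions by summing member columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from sklearn.metrics import silhouette_score

from .io import Section

__all__ = [
    "ECTModel",
    "niche_composition",
    "scale_composition",
    "cluster_ect",
    "build_ect_model",
    "ect_fractions",
]


def niche_composition(
    niche_labels: np.ndarray, sections: Sequence[Section]
) -> pd.DataFrame:
    """Mean spot composition per niche, spots pooled across sections.

    ``niche_labels`` aligns with the concatenation of the sections'
    spots (the order produced by the niche pipeline).  Entry (n, t) is
    the mean over niche-n spots of the spot proportion of cell type t.
    """
    labels = np.asarray(niche_labels)
    props = np.vstack([s.abundance.proportions() for s in sections])
    if labels.shape[0] != props.shape[0]:
        raise ValueError(
            f"{labels.shape[0]} labels for {props.shape[0]} spots"
        )
    cell_types = sections[0].cell_types
    niches = np.unique(labels)
    rows = []
    for n in niches:
        members = props[labels == n]
        if members.size == 0:
            raise ValueError(f"niche {n} has no spots")
        rows.append(members.mean(axis=0))
    return pd.DataFrame(rows, index=pd.Index(niches, name="niche"),
                        columns=cell_types)


def scale_composition(matrix: pd.DataFrame) -> pd.DataFrame:
    """Center and scale the niche-mean matrix per cell type.

    Each cell type's profile across niches gets mean 0 and sample
    standard deviation 1; cell types constant across niches are set to
    all-zero with a warning.
    """
    if matrix.shape[0] < 2:
        raise ValueError("scaling needs at least 2 niches")
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        names = [matrix.columns[j] for j in np.flatnonzero(constant)]
        warnings.warn(
            f"cell types constant across niches set to zero: {names}",
            RuntimeWarning,
        )
    scaled = np.where(constant[None, :], 0.0, (values - mean) / np.where(constant, 1.0, sd))
    return pd.DataFrame(scaled, index=matrix.index, columns=matrix.columns)


def _leaf_ordered_ids(linkage: np.ndarray, flat: np.ndarray) -> dict[int, int]:
    """Map raw fcluster ids to ids ordered by dendrogram leaf order."""
    leaves = sch.leaves_list(linkage)
    seen: dict[int, int] = {}
    for leaf in leaves:
        c = int(flat[leaf])
        if c not in seen:
            seen[c] = len(seen) + 1
    return seen


def cluster_ect(
    scaled: pd.DataFrame, k: int | str = "auto"
) -> tuple[dict[str, int], np.ndarray]:
    """Cut the Ward dendrogram of cell-type profiles into ECTs.

    ``k`` may be an integer group count or ``"auto"``, which maximises
    the mean silhouette over k in [2, min(15, D-1)].  Returns the
    membership (cell type -> ECT id, ids numbered 1.. in dendrogram leaf
    order) and the linkage matrix.
    """
    profiles = scaled.to_numpy(dtype=float).T  # cell types x niches
    d = profiles.shape[0]
    if d < 2:
        raise ValueError("need at least 2 cell types")
    linkage = sch.linkage(profiles, method="ward", metric="euclidean")
    if k == "auto":
        best_k, best_score = None, -np.inf
        for kk in range(2, min(15, d - 1) + 1):
            flat = sch.fcluster(linkage, kk, criterion="maxclust")
            if len(np.unique(flat)) < 2:
                continue
            score = silhouette_score(profiles, flat, metric="euclidean")
            if score > best_score:
                best_k, best_score = kk, score
        k = best_k
    else:
        k = int(k)
        if not 1 <= k <= d:
            raise ValueError(f"k={k} outside [1, {d}]")
    flat = sch.fcluster(linkage, k, criterion="maxclust")
    remap = _leaf_ordered_ids(linkage, flat)
    membership = {
        str(name): remap[int(c)] for name, c in zip(scaled.columns, flat)
    }
    return membership, linkage


@dataclass
class ECTModel:
    """Niche-composition matrices and the derived ECT membership."""

    niche_mean_matrix: pd.DataFrame  # niche x cell type
    scaled_matrix: pd.DataFrame
    linkage: np.ndarray
    ect_membership: dict[str, int]
    linkage_method: str = "ward"
    distance_metric: str = "euclidean"

    @property
    def n_ect(self) -> int:
        return len(set(self.ect_membership.values()))

    def membership_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.ect_membership.items()),
            columns=["cell_type", "ect_id"],
        )


def build_ect_model(
    niche_labels: np.ndarray,
    sections: Sequence[Section],
    k: int | str = "auto",
) -> ECTModel:
    """Full ECT derivation from labeled spots."""
    mean = niche_composition(niche_labels, sections)
    scaled = scale_composition(mean)
    membership, linkage = cluster_ect(scaled, k=k)
    return ECTModel(mean, scaled, linkage, membership)


def ect_fractions(
    fractions: pd.DataFrame, ect_membership: Mapping[str, int]
) -> pd.DataFrame:
    """Aggregate per-sample cell-type fractions into ECT fractions.

    Each ECT fraction is the sum of its member cell-type columns, so row
    sums are preserved exactly; in particular compositional rows stay
    compositional.  A member cell type missing from the table is an
    error naming it.
    """
    missing = [t for t in ect_membership if t not in fractions.columns]
    if missing:
        raise ValueError(f"missing cell-type columns: {missing}")
    ects = sorted(set(ect_membership.values()))
    out = pd.DataFrame(index=fractions.index)
    for e in ects:
        members = [t for t, ee in ect_membership.items() if ee == e]
        out[f"ECT{e}"] = fractions[members].sum(axis=1)
    return out
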