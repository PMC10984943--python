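"""Cross-section niche identification.

Spot compositions are mapped to isometric log-ratio (ILR) coordinates, a
batch-balanced k-nearest-neighbour graph is built over all sections
(each spot takes its k nearest neighbours within *every* section, which
absorbs rigid per-section shifts in log-ratio space), and Leiden
community detection at a configurable resolution yields the niches —
communities of spots sharing a similar cell-type composition across
sections.  A fitted model can label new sections by nearest niche
centroid in the same ILR coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import igraph as ig
import leidenalg as la
import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse
from sklearn.neighbors import NearestNeighbors

from .io import Section

__all__ = [
    "NicheModel",
    "ilr_basis",
    "ilr_transform",
    "batch_balanced_knn",
    "detect_niches",
    "fit_niches",
    "map_niches",
]

#: Pseudocount factor: fraction of the row-mean abundance added to every
#: entry before closure, so zero abundances have a defined log-ratio.
PSEUDOCOUNT_FACTOR = 1e-3


def ilr_basis(n_parts: int) -> np.ndarray:
    """Orthonormal Helmert-type sequential-binary contrast basis.

    Returns a ``(D-1, D)`` matrix whose rows are orthonormal and sum to
    zero, so ``basis @ log(p)`` equals ``basis @ clr(p)``: the isometric
    log-ratio coordinates of the composition ``p``.
    """
    if n_parts < 2:
        raise ValueError("ILR needs at least 2 parts")
    return scipy.linalg.helmert(n_parts)


def ilr_transform(
    values: np.ndarray,
    pseudocount: float | None = None,
    basis: np.ndarray | None = None,
) -> np.ndarray:
    """ILR coordinates of non-negative abundance rows.

    Each row gets ``pseudocount`` added to every entry (default:
    ``PSEUDOCOUNT_FACTOR`` x the row mean), is closed to proportions and
    projected on the contrast basis.  Output has ``D - 1`` columns.
    """
    x = np.atleast_2d(np.asarray(values, dtype=float))
    d = x.shape[1]
    if d < 2:
        raise ValueError("ILR needs at least 2 cell types")
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise ValueError("abundances must be finite and non-negative")
    if basis is None:
        basis = ilr_basis(d)
    if pseudocount is None:
        pc = PSEUDOCOUNT_FACTOR * x.mean(axis=1, keepdims=True)
        pc = np.where(pc > 0, pc, PSEUDOCOUNT_FACTOR)
    else:
        if pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        pc = pseudocount
    p = x + pc
    p = p / p.sum(axis=1, keepdims=True)
    return np.log(p) @ basis.T


def batch_balanced_knn(
    embedding: np.ndarray,
    batch_labels: Sequence[object],
    k_within_batch: int = 3,
) -> scipy.sparse.csr_matrix:
    """Symmetrised batch-balanced kNN graph over embedded spots.

    Every spot is connected to its ``k_within_batch`` nearest neighbours
    (Euclidean) within each batch, its own included (self excluded);
    the directed edge set is symmetrised by union.  Batches smaller than
    the requested k contribute all their members, with a warning.
    Returns a boolean symmetric sparse adjacency matrix.
    """
    emb = np.asarray(embedding, dtype=float)
    labels = np.asarray(batch_labels)
    if emb.ndim != 2 or emb.shape[0] != labels.shape[0]:
        raise ValueError("embedding rows and batch labels must align")
    if k_within_batch < 1:
        raise ValueError("k_within_batch must be >= 1")
    n = emb.shape[0]
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    for batch in np.unique(labels):
        members = np.flatnonzero(labels == batch)
        k = k_within_batch
        if members.size < k + 1:
            warnings.warn(
                f"batch {batch!r} has {members.size} members; "
                f"capping k_within_batch={k_within_batch}",
                RuntimeWarning,
            )
            k = max(members.size - 1, 1)
        nn = NearestNeighbors(n_neighbors=min(k + 1, members.size))
        nn.fit(emb[members])
        _, idx = nn.kneighbors(emb)
        nbr = members[idx]  # (n, k+1) global indices
        src = np.repeat(np.arange(n), nbr.shape[1])
        dst = nbr.ravel()
        keep = src != dst
        src, dst = src[keep], dst[keep]
        # own-batch queries returned self + k others; foreign queries
        # returned k+1 real neighbours: trim each source to k edges.
        order = np.argsort(src, kind="stable")
        src, dst = src[order], dst[order]
        first = np.searchsorted(src, np.arange(n))
        take = (first[:, None] + np.arange(k)[None, :]).ravel()
        counts = np.diff(np.append(first, src.size))
        valid = (np.arange(k)[None, :] < np.minimum(counts, k)[:, None]).ravel()
        take = take[valid]
        rows.append(src[take])
        cols.append(dst[take])
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    adj = scipy.sparse.csr_matrix(
        (np.ones(r.size, dtype=bool), (r, c)), shape=(n, n)
    )
    adj = adj + adj.T  # union symmetrisation
    adj.data[:] = True
    return adj


def _graph_from_adjacency(adj: scipy.sparse.spmatrix) -> ig.Graph:
    coo = scipy.sparse.triu(adj, k=1).tocoo()
    g = ig.Graph(n=adj.shape[0], edges=list(zip(coo.row.tolist(), coo.col.tolist())))
    return g


def detect_niches(
    graph: scipy.sparse.spmatrix | ig.Graph,
    resolution: float = 0.6,
    seed: int = 0,
    n_restarts: int = 10,
) -> np.ndarray:
    """Leiden community labels of the spot graph.

    Optimises RBConfiguration modularity at the given resolution;
    ``n_restarts`` seeded runs are performed and the best-quality
    partition kept, so the result is deterministic under ``seed``.
    Labels are renumbered by descending community size (ties broken by
    first occurrence).
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if not isinstance(graph, ig.Graph):
        graph = _graph_from_adjacency(graph)
    if graph.vcount() == 0:
        raise ValueError("empty graph")
    best = None
    best_q = -np.inf
    ss = np.random.SeedSequence(seed)
    for child_seed in ss.generate_state(n_restarts):
        part = la.find_partition(
            graph,
            la.RBConfigurationVertexPartition,
            resolution_parameter=resolution,
            seed=int(child_seed % (2**31 - 1)),
            n_iterations=2,
        )
        if part.quality() > best_q:
            best_q = part.quality()
            best = part
    labels = np.asarray(best.membership)
    # renumber by descending size
    ids, counts = np.unique(labels, return_counts=True)
    order = ids[np.argsort(-counts, kind="stable")]
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[v] for v in labels], dtype=int)


@dataclass
class NicheModel:
    """A fitted niche model: embedding, labels and centroids."""

    cell_types: list[str]
    basis: np.ndarray  # (D-1, D) ILR contrast matrix
    pseudocount: float | None
    k_within_batch: int
    resolution: float
    spot_index: pd.DataFrame  # columns: section_id, spot_id
    embedding: np.ndarray  # (n_spots, D-1)
    niche_labels: np.ndarray  # (n_spots,)
    niche_centroids: np.ndarray  # (n_niches, D-1)

    @property
    def n_niches(self) -> int:
        return self.niche_centroids.shape[0]

    def labels_frame(self) -> pd.DataFrame:
        out = self.spot_index.copy()
        out["niche"] = self.niche_labels
        return out


def _stack_sections(sections: Sequence[Section], cell_types: Sequence[str] | None = None):
    if not sections:
        raise ValueError("no sections")
    if cell_types is None:
        cell_types = sections[0].cell_types
    for s in sections:
        if s.cell_types != list(cell_types):
            diff = set(s.cell_types) ^ set(cell_types)
            raise ValueError(
                f"section {s.section_id} cell types differ; "
                f"symmetric difference: {sorted(diff)}"
            )
    values = np.vstack([s.abundance.values for s in sections])
    batch = np.concatenate([[s.section_id] * s.n_spots for s in sections])
    index = pd.DataFrame(
        {
            "section_id": batch,
            "spot_id": np.concatenate([s.spot_ids for s in sections]),
        }
    )
    return values, batch, index, list(cell_types)


def fit_niches(
    sections: Sequence[Section],
    k_within_batch: int = 3,
    resolution: float = 0.6,
    seed: int = 0,
    pseudocount: float | None = None,
    n_restarts: int = 10,
) -> NicheModel:
    """Run the full niche pipeline on a list of sections.

    ILR transform of per-spot compositions, batch-balanced kNN graph
    with sections as batches, Leiden at the given resolution, then
    per-niche centroid of the member embeddings.
    """
    values, batch, index, cell_types = _stack_sections(sections)
    basis = ilr_basis(len(cell_types))
    emb = ilr_transform(values, pseudocount=pseudocount, basis=basis)
    adj = batch_balanced_knn(emb, batch, k_within_batch)
    labels = detect_niches(adj, resolution=resolution, seed=seed,
                           n_restarts=n_restarts)
    n_niches = labels.max() + 1
    centroids = np.vstack([emb[labels == i].mean(axis=0) for i in range(n_niches)])
    return NicheModel(
        cell_types=cell_types,
        basis=basis,
        pseudocount=pseudocount,
        k_within_batch=k_within_batch,
        resolution=resolution,
        spot_index=index,
        embedding=emb,
        niche_labels=labels,
        niche_centroids=centroids,
    )


def map_niches(
    model: NicheModel, new_sections: Sequence[Section]
) -> pd.DataFrame:
    """Label new sections' spots by nearest niche centroid.

    New spots are ILR-transformed with the model's basis and pseudocount
    rule, then assigned the label of the closest centroid (Euclidean);
    the assignment distance is reported as a confidence proxy.
    """
    values, _, index, _ = _stack_sections(new_sections, model.cell_types)
    emb = ilr_transform(values, pseudocount=model.pseudocount, basis=model.basis)
    d = np.linalg.norm(emb[:, None, :] - model.niche_centroids[None, :, :], axis=2)
    out = index.copy()
    out["niche"] = d.argmin(axis=1)
    out["centroid_distance"] = d.min(axis=1)
    return out
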