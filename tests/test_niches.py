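"""ILR geometry, batch-balanced kNN, Leiden niches and reference mapping."""

import math

import numpy as np
import pytest
import scipy.sparse
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from ectcraft.niches import (
    batch_balanced_knn,
    detect_niches,
    fit_niches,
    ilr_basis,
    ilr_transform,
    map_niches,
)


# --- ILR -----------------------------------------------------------------


@pytest.mark.parametrize("d", [2, 3, 10, 37])
def test_basis_orthonormal_zero_sum(d):
    basis = ilr_basis(d)
    assert basis.shape == (d - 1, d)
    assert np.allclose(basis @ basis.T, np.eye(d - 1), atol=1e-10)
    assert np.allclose(basis.sum(axis=1), 0.0, atol=1e-10)


def test_two_part_closed_form():
    assert ilr_transform(np.array([[0.5, 0.5]]), pseudocount=1e-12)[0, 0] == (
        pytest.approx(0.0, abs=1e-10)
    )
    p = math.e / (1 + math.e)
    got = ilr_transform(np.array([[p, 1 - p]]), pseudocount=1e-15)[0, 0]
    assert got == pytest.approx(1 / math.sqrt(2), abs=1e-10)
    for q in [0.1, 0.37, 0.9]:
        got = ilr_transform(np.array([[q, 1 - q]]), pseudocount=1e-15)[0, 0]
        assert got == pytest.approx(math.log(q / (1 - q)) / math.sqrt(2),
                                    abs=1e-10)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(0, 10_000))
def test_ilr_isometry_matches_aitchison(seed):
    """The ILR embedding is an isometry of the Aitchison geometry: ILR
    Euclidean distance equals the clr-difference norm."""
    rng = np.random.default_rng(seed)
    d = rng.integers(3, 12)
    x = rng.dirichlet(np.ones(d), size=2)
    coords = ilr_transform(x, pseudocount=1e-15)
    clr = np.log(x) - np.log(x).mean(axis=1, keepdims=True)
    aitchison = np.linalg.norm(clr[0] - clr[1])
    assert np.linalg.norm(coords[0] - coords[1]) == pytest.approx(
        aitchison, abs=1e-8
    )


def test_perturbation_shifts_by_constant():
    rng = np.random.default_rng(4)
    x = rng.dirichlet(np.ones(6), size=5)
    g = rng.uniform(0.5, 2.0, size=6)
    y = x * g
    y /= y.sum(axis=1, keepdims=True)
    shift = ilr_transform(y, pseudocount=1e-15) - ilr_transform(x, pseudocount=1e-15)
    assert np.allclose(shift, shift[0], atol=1e-8)


def test_ilr_input_validation():
    with pytest.raises(ValueError):
        ilr_transform(np.array([[1.0]]))
    with pytest.raises(ValueError):
        ilr_transform(np.array([[1.0, -1.0]]))
    with pytest.raises(ValueError):
        ilr_transform(np.array([[1.0, 1.0]]), pseudocount=0.0)


# --- batch-balanced kNN --------------------------------------------------


def test_single_batch_reduces_to_knn():
    rng = np.random.default_rng(6)
    pts = rng.normal(size=(100, 4))
    k = 3
    adj = batch_balanced_knn(pts, ["b"] * 100, k)
    # brute-force directed kNN, then union-symmetrise
    dist = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    np.fill_diagonal(dist, np.inf)
    expected = np.zeros((100, 100), dtype=bool)
    for i in range(100):
        expected[i, np.argsort(dist[i])[:k]] = True
    expected |= expected.T
    assert (adj.toarray().astype(bool) == expected).all()


def test_each_node_reaches_every_batch():
    rng = np.random.default_rng(7)
    pts = np.vstack([rng.normal(0, 1, (40, 3)), rng.normal(5, 1, (40, 3))])
    batches = ["a"] * 40 + ["b"] * 40
    adj = batch_balanced_knn(pts, batches, 1)
    adj = adj.toarray()
    for i in range(80):
        assert adj[i, :40].sum() >= 1
        assert adj[i, 40:].sum() >= 1


def test_duplicated_batch_links_duplicates():
    rng = np.random.default_rng(8)
    pts = rng.normal(size=(30, 3))
    dup = np.vstack([pts, pts])
    batches = ["a"] * 30 + ["b"] * 30
    adj = batch_balanced_knn(dup, batches, 1).toarray()
    for i in range(30):
        assert adj[i, i + 30]  # cross-batch neighbour is the duplicate


def test_small_batch_capped_with_warning():
    pts = np.random.default_rng(9).normal(size=(12, 2))
    batches = ["a"] * 10 + ["b"] * 2
    with pytest.warns(RuntimeWarning, match="capping"):
        adj = batch_balanced_knn(pts, batches, 3)
    assert adj.shape == (12, 12)


def test_k_validation():
    with pytest.raises(ValueError):
        batch_balanced_knn(np.zeros((3, 2)), ["a"] * 3, 0)


# --- Leiden --------------------------------------------------------------


def _clique_adj(sizes):
    import scipy.linalg

    blocks = [np.ones((s, s)) - np.eye(s) for s in sizes]
    return scipy.sparse.csr_matrix(scipy.linalg.block_diag(*blocks))


def test_two_disjoint_cliques():
    adj = _clique_adj([10, 15])
    labels = detect_niches(adj, resolution=0.6, seed=0)
    assert len(np.unique(labels)) == 2
    assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
    # labels renumbered by descending size: the 15-clique is community 0
    assert labels[10] == 0


def test_single_clique_single_community():
    adj = _clique_adj([12])
    labels = detect_niches(adj, resolution=0.6, seed=0)
    assert len(np.unique(labels)) == 1


def test_detect_validation():
    with pytest.raises(ValueError):
        detect_niches(_clique_adj([5]), resolution=0.0)
    with pytest.raises(ValueError):
        detect_niches(scipy.sparse.csr_matrix((0, 0)), resolution=0.6)


def test_detect_deterministic_under_seed():
    adj = _clique_adj([8, 8, 8])
    a = detect_niches(adj, seed=42)
    b = detect_niches(adj, seed=42)
    assert np.array_equal(a, b)


# --- end-to-end pipeline -------------------------------------------------


def test_pipeline_recovers_planted_niches(small_config, small_sections,
                                          small_truth_labels):
    """ILR -> batch-balanced kNN -> Leiden at 0.6 recovers the planted
    niche count with high agreement on the scaled-down study."""
    model = fit_niches(small_sections, seed=0)
    assert model.n_niches == small_config.n_niches
    assert adjusted_rand_score(small_truth_labels, model.niche_labels) >= 0.9
    # centroids are the means of member embeddings
    for i in range(model.n_niches):
        np.testing.assert_allclose(
            model.niche_centroids[i],
            model.embedding[model.niche_labels == i].mean(axis=0),
        )


def test_labels_invariant_to_spot_order(small_sections):
    model = fit_niches(small_sections, seed=0)
    model_r = fit_niches(list(reversed(small_sections)), seed=0)
    # map reordered labels back into original spot order: with sections
    # reversed, section j's block starts at sum of later sections' sizes
    n = [s.n_spots for s in small_sections]
    new_pos = np.concatenate(
        [sum(n[j + 1 :]) + np.arange(n[j]) for j in range(len(n))]
    )
    restored = model_r.niche_labels[new_pos]
    assert adjusted_rand_score(model.niche_labels, restored) == pytest.approx(1.0)


def test_map_niches_identity_and_centroid(small_sections):
    model = fit_niches(small_sections, seed=0)
    mapped = map_niches(model, small_sections)
    agree = (mapped["niche"].to_numpy() == model.niche_labels).mean()
    # nearest-centroid reassignment of training spots matches Leiden labels
    # wherever spots are not on community boundaries
    assert agree >= 0.85
    # a pseudo-section whose single spot sits exactly at a centroid
    from ectcraft.io import AbundanceMatrix, Section

    # invert the ILR of centroid 0 back to a composition
    comp = np.exp(model.basis.T @ model.niche_centroids[0])
    comp /= comp.sum()
    sec = Section(
        section_id="new",
        spot_ids=["n0"],
        coords=np.array([[0.0, 0.0]]),
        abundance=AbundanceMatrix(model.cell_types, comp[None, :]),
    )
    out = map_niches(model, [sec])
    assert out.loc[0, "niche"] == 0
    assert out.loc[0, "centroid_distance"] < 0.15


def test_map_niches_holdout_recovery(small_config):
    """Held-out sections are labeled consistently with the planted niches."""
    from ectcraft.synthetic import generate_sections

    study = generate_sections(small_config)
    train = [s for s, _ in study[:2]]
    test_sec, test_truth = study[2]
    model = fit_niches(train, seed=0)
    mapped = map_niches(model, [test_sec])
    assert adjusted_rand_score(
        test_truth.spot_niche_labels, mapped["niche"].to_numpy()
    ) >= 0.85


def test_map_niches_cell_type_mismatch(small_sections):
    from ectcraft.io import AbundanceMatrix, Section

    model = fit_niches(small_sections, seed=0)
    bad = Section(
        section_id="bad",
        spot_ids=["x"],
        coords=np.zeros((1, 2)),
        abundance=AbundanceMatrix(["Zeta"], np.ones((1, 1))),
    )
    with pytest.raises(ValueError, match="symmetric difference"):
        map_niches(model, [bad])
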