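"""Distance tables, diversity, annotation transfer and enrichment tests."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from shapely.geometry import Polygon, box

from ectcraft.cellmap import CellMap
from ectcraft.io import AbundanceMatrix, AnnotationLayer, Section
from ectcraft.spatial import (
    compartment_enrichment,
    nearest_distance_table,
    rank_by_median_distance,
    rank_sum_test,
    shannon_index,
    transfer_annotations,
)


def _cellmap(types, xy, section_id="S"):
    xy = np.asarray(xy, dtype=float)
    return CellMap(
        section_id,
        pd.DataFrame(
            {
                "cell_type": list(types),
                "x_um": xy[:, 0],
                "y_um": xy[:, 1],
                "spot_id": [f"s{i}" for i in range(len(types))],
            }
        ),
    )


def test_three_four_five_symmetry():
    cm = _cellmap(["A", "B"], [[0, 0], [3, 4]])
    table = nearest_distance_table(cm)
    d = table.set_index(["reference_type", "target_type"])["nearest_distance"]
    assert d[("A", "B")] == pytest.approx(5.0)
    assert d[("B", "A")] == pytest.approx(5.0)


def test_single_type_empty_table():
    cm = _cellmap(["A", "A", "A"], [[0, 0], [1, 0], [2, 0]])
    table = nearest_distance_table(cm)
    assert table.empty


def test_matches_brute_force_oracle():
    rng = np.random.default_rng(12)
    n = 200
    xy = rng.uniform(0, 1000, size=(n, 2))
    types = rng.choice(["A", "B", "C", "D"], size=n)
    table = nearest_distance_table(_cellmap(types, xy))
    # O(n^2) oracle
    dist = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=2)
    for _, row in table.iterrows():
        i = int(row["reference_index"])
        mask = types == row["target_type"]
        assert row["nearest_distance"] == pytest.approx(dist[i, mask].min())
    # every (cell, other type present) pair has exactly one row
    expected_rows = sum(
        (types != t).sum() for t in np.unique(types)
    )
    assert len(table) == expected_rows


def test_ranking_orders_by_median():
    cm = _cellmap(
        ["Anchor", "Near", "Far"], [[0, 0], [0, 10], [0, 20]]
    )
    table = nearest_distance_table(cm)
    ranking = rank_by_median_distance(table, "Anchor")
    assert ranking["reference_type"].tolist() == ["Near", "Far"]
    assert ranking["median_distance"].tolist() == [10.0, 20.0]


def test_ranking_row_order_invariant():
    rng = np.random.default_rng(5)
    xy = rng.uniform(0, 500, size=(60, 2))
    types = rng.choice(["X", "Y", "Z"], size=60)
    table = nearest_distance_table(_cellmap(types, xy))
    shuffled = table.sample(frac=1.0, random_state=1)
    a = rank_by_median_distance(table, "X")
    b = rank_by_median_distance(shuffled, "X")
    assert a.equals(b)


def test_ranking_planted_rings():
    """Three rings of cells around anchor cells rank in ring order."""
    rng = np.random.default_rng(7)
    records = [("Anchor", 0.0, 0.0)]
    for name, radius in [("Ring1", 50), ("Ring2", 120), ("Ring3", 300)]:
        for theta in rng.uniform(0, 2 * math.pi, 30):
            records.append((name, radius * math.cos(theta),
                            radius * math.sin(theta)))
    types = [r[0] for r in records]
    xy = [(r[1], r[2]) for r in records]
    table = nearest_distance_table(_cellmap(types, xy))
    ranking = rank_by_median_distance(table, "Anchor")
    assert ranking["reference_type"].tolist() == ["Ring1", "Ring2", "Ring3"]


def test_anchor_absent_is_error():
    cm = _cellmap(["A", "B"], [[0, 0], [1, 1]])
    table = nearest_distance_table(cm)
    with pytest.raises(ValueError, match="absent"):
        rank_by_median_distance(table, "Z")


# --- Shannon index -------------------------------------------------------


def test_shannon_closed_forms():
    assert shannon_index([1.0]) == 0.0
    assert shannon_index([0.25] * 4) == pytest.approx(math.log(4), abs=1e-12)
    assert shannon_index([0.5, 0.25, 0.25]) == pytest.approx(1.03972, abs=1e-5)
    # renormalisation: counts give the same index as fractions
    assert shannon_index([2, 1, 1]) == pytest.approx(shannon_index([0.5, 0.25, 0.25]))


def test_shannon_uniform_is_maximal():
    rng = np.random.default_rng(1)
    uniform = shannon_index(np.full(6, 1 / 6))
    for _ in range(1000):
        assert shannon_index(rng.dirichlet(np.ones(6))) <= uniform + 1e-12


def test_shannon_rejects_bad_input():
    with pytest.raises(ValueError):
        shannon_index([0.0, 0.0])
    with pytest.raises(ValueError):
        shannon_index([-0.1, 1.1])


# --- annotation transfer -------------------------------------------------


def _one_spot_section(diameter=50.0):
    return Section(
        section_id="S",
        spot_ids=["s0"],
        coords=np.array([[0.0, 0.0]]),
        abundance=AbundanceMatrix(["T"], np.array([[1.0]])),
        spot_diameter=diameter,
    )


def test_cancer_rule_precedence():
    """A spot ~40% covered by cancer and ~60% by stroma is labeled cancer:
    the >30% cancer rule precedes the majority rule."""
    section = _one_spot_section()
    cancer = box(-30, -30, -6.35, 30)  # left part of the disc, ~40%
    stroma = box(-6.35, -30, 30, 30)
    layer = AnnotationLayer(
        [("Cancer cells", cancer), ("Intratumor stroma", stroma)]
    )
    out = transfer_annotations(layer, section)
    assert out["s0"] == "Cancer cells"


def test_majority_rule_below_cancer_threshold():
    """~20% cancer / ~60% stroma / ~20% uncovered -> stroma by majority."""
    section = _one_spot_section()
    # chord at x = -12.5 cuts ~20% of a radius-25 disc
    cancer = box(-30, -30, -12.4, 30)
    stroma = box(-12.4, -30, 11.0, 30)
    layer = AnnotationLayer(
        [("Cancer cells", cancer), ("Intratumor stroma", stroma)]
    )
    out = transfer_annotations(layer, section)
    assert out["s0"] == "Intratumor stroma"


def test_uncovered_spot_unassigned():
    section = _one_spot_section()
    far = box(1000, 1000, 1100, 1100)
    layer = AnnotationLayer([("Peritumor stroma", far)])
    out = transfer_annotations(layer, section)
    assert out["s0"] == "unassigned"


def test_threshold_validated():
    section = _one_spot_section()
    layer = AnnotationLayer([("Cancer cells", box(-30, -30, 30, 30))])
    with pytest.raises(ValueError):
        transfer_annotations(layer, section, cancer_threshold=1.5)


def test_transfer_invariant_to_vertex_order():
    section = _one_spot_section()
    ring = [(-30, -30), (30, -30), (30, 30), (-30, 30)]
    a = AnnotationLayer([("Peritumor stroma", Polygon(ring))])
    b = AnnotationLayer([("Peritumor stroma", Polygon(ring[::-1]))])
    assert transfer_annotations(a, section).equals(
        transfer_annotations(b, section)
    )


# --- rank-sum test and enrichment ---------------------------------------


def test_rank_sum_exact_matches_scipy_enumeration():
    rng = np.random.default_rng(2)
    for _ in range(10):
        x = rng.normal(size=5)
        y = rng.normal(size=6)
        ours = rank_sum_test(x, y)
        ref = scipy.stats.mannwhitneyu(x, y, alternative="two-sided",
                                       method="exact").pvalue
        assert ours == pytest.approx(ref, abs=1e-12)


def test_rank_sum_asymptotic_matches_scipy():
    rng = np.random.default_rng(3)
    x = rng.normal(size=20)
    y = rng.normal(0.5, size=25)
    ours = rank_sum_test(x, y)
    ref = scipy.stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic",
        use_continuity=False
    ).pvalue
    assert ours == pytest.approx(ref, rel=1e-10)


def _enrichment_setup(props_by_state):
    """Five sections, one compartment; planted per-state proportions."""
    cellmaps = {}
    annotations = {}
    n_per_section = 100
    for s in range(5):
        types = []
        for state, prop in props_by_state.items():
            types += [state] * int(round(prop * n_per_section))
        xy = np.zeros((len(types), 2))
        cm = _cellmap(types, xy, section_id=f"S{s}")
        cm.cells["spot_id"] = "spot0"
        cellmaps[f"S{s}"] = cm
        annotations[f"S{s}"] = pd.Series({"spot0": "Intratumor stroma"})
    return cellmaps, annotations


def test_enrichment_extreme_state():
    cellmaps, annotations = _enrichment_setup({"only": 1.0, "other": 0.0})
    out = compartment_enrichment(cellmaps, annotations, ["only", "other"])
    row = out[out["state"] == "only"].iloc[0]
    assert row["direction"] == "enriched"
    # smallest attainable two-sided exact p for 5 vs 5 observations
    assert row["p_value"] == pytest.approx(2 / math.comb(10, 5), rel=1e-9)


def test_enrichment_identical_states_null():
    cellmaps, annotations = _enrichment_setup({"a": 0.5, "b": 0.5})
    out = compartment_enrichment(cellmaps, annotations, ["a", "b"])
    assert np.allclose(out["p_value"], 1.0)


def test_enrichment_matches_exact_enumeration():
    """Hand-listed per-section proportions: the reported p equals the
    exhaustive rank-sum enumeration (via the exact reference test)."""
    cellmaps, annotations = _enrichment_setup({"a": 0.7, "b": 0.3})
    out = compartment_enrichment(cellmaps, annotations, ["a", "b"])
    x = np.full(5, 0.7)
    y = np.full(5, 0.3)
    ref = rank_sum_test(x, y)
    row = out[out["state"] == "a"].iloc[0]
    assert row["p_value"] == pytest.approx(ref, abs=1e-12)
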