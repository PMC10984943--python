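"""Synthetic multi-section deconvolution data with known ground truth.

The generator emulates the downstream-analysis inputs of a Visium-style
breast-cancer study: ~17 sections of ~2,000 spots on a 55 µm-spot
hexagonal lattice, ~37 cell types, spatially contiguous niche domains
with niche-specific compositional centers, per-section batch shifts,
pathologist-style compartment polygons and a bulk cohort whose
EcoCellType (ECT) fractions carry a planted survival effect.

Generative model, per spot:

* the spot's niche is a nearest-seed Voronoi domain, with boundaries
  perturbed by a smooth Gaussian random displacement field so domains
  stay contiguous but irregular;
* the niche's compositional center is built from per-block enrichment
  profiles (cell types in the same planted ECT block share their niche
  enrichment pattern, up to a small per-type wiggle);
* the spot composition is Dirichlet-distributed around the center with
  concentration ``niche_center_concentration``;
* the abundance row is composition x a Gamma total (mean
  ``total_cells_per_spot``, variance equal to the mean, a non-negative
  real mimicking a posterior-quantile export) x a per-section,
  per-cell-type log-normal batch factor.

Because the batch factor multiplies the composition elementwise, it acts
as an Aitchison perturbation: each section is rigidly translated in
log-ratio space, exactly the kind of shift a batch-balanced kNN graph is
meant to absorb.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .io import COMPARTMENTS, AbundanceMatrix, AnnotationLayer, Section

__all__ = [
    "DEFAULT_CELL_TYPES",
    "SimConfig",
    "GroundTruth",
    "ConfigError",
    "generate_sections",
    "generate_annotations",
    "generate_cohort",
    "default_compartment_mapping",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


#: 37 cell types and states of a breast-tumor microenvironment:
#: cancer and normal epithelium, CAF and perivascular (CAP) states,
#: endothelial, myeloid and lymphoid populations.
DEFAULT_CELL_TYPES = (
    "Cancer cells",
    "Normal epithelial",
    "Myoepithelial",
    "Detox-iCAF",
    "IL-iCAF",
    "IFNg-iCAF",
    "ECM-myCAF",
    "TGFb-myCAF",
    "Wound-myCAF",
    "IFNab-myCAF",
    "Universal fibroblasts",
    "Contractile-CAP",
    "Ag-CAP",
    "ECM-CAP",
    "Angio-EC",
    "ap-EC",
    "Adipo-EC",
    "Lymphatic-EC",
    "FOLR2+ TAM",
    "TREM2+ TAM",
    "SPP1+ TAM",
    "Mo-DC",
    "cDC1",
    "cDC2",
    "pDC",
    "Monocytes",
    "Mast cells",
    "Neutrophils",
    "B cells",
    "Plasma cells",
    "SELL+ CD4+ T",
    "FOXP3+ CD4+ Treg",
    "GZMK+ CD8+ T",
    "XCL1+ CD8+ T",
    "Cytotoxic CD8+ T",
    "NKG2A+ NKreg",
    "Cytotoxic NK",
)

#: Center-to-center spacing of adjacent spots on the lattice, µm.
LATTICE_PITCH_UM = 100.0

#: Scale (s.d., in log-abundance units) of the per-block niche-enrichment
#: profiles, and of the per-type wiggle around its block profile.
_BLOCK_PROFILE_SD = 1.25
_TYPE_WIGGLE_SD = 0.15

#: Amplitude (µm) of the boundary-perturbing displacement field.
_BOUNDARY_AMPLITUDE_UM = 150.0


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic generator.

    Defaults replicate the spatial study design: 17 sections of ~2,000
    spots (55 µm spots), 37 cell types, 11 niches, 10 co-occurrence
    blocks, ~15 cells per spot.
    """

    n_sections: int = 17
    spots_per_section: int = 2000
    spot_diameter: float = 55.0
    n_cell_types: int = 37
    cell_type_names: tuple[str, ...] | None = None
    cancer_type_names: tuple[str, ...] = ("Cancer cells",)
    n_niches: int = 11
    niche_center_concentration: float = 150.0
    batch_shift_sd: float = 0.3
    spatial_smoothness: float = 400.0
    total_cells_per_spot: float = 15.0
    n_ect_blocks: int = 10
    seed: int = 0

    def cell_types(self) -> tuple[str, ...]:
        if self.cell_type_names is not None:
            names = tuple(self.cell_type_names)
        elif self.n_cell_types <= len(DEFAULT_CELL_TYPES):
            names = DEFAULT_CELL_TYPES[: self.n_cell_types]
        else:
            extra = tuple(
                f"Cell type {i + 1}"
                for i in range(len(DEFAULT_CELL_TYPES), self.n_cell_types)
            )
            names = DEFAULT_CELL_TYPES + extra
        return names

    def validate(self) -> None:
        names = self.cell_types()
        if len(names) != self.n_cell_types:
            raise ConfigError(
                f"{len(names)} cell_type_names for n_cell_types={self.n_cell_types}"
            )
        if len(set(names)) != len(names):
            raise ConfigError("duplicate cell-type names")
        if self.n_niches < 1:
            raise ConfigError("n_niches must be >= 1")
        if self.n_niches > self.spots_per_section:
            raise ConfigError("n_niches exceeds spots_per_section")
        if not 1 <= self.n_ect_blocks <= self.n_cell_types:
            raise ConfigError("n_ect_blocks must be in [1, n_cell_types]")
        missing = set(self.cancer_type_names) - set(names)
        if missing:
            raise ConfigError(f"cancer types not among cell types: {sorted(missing)}")
        if self.spot_diameter <= 0:
            raise ConfigError("spot_diameter must be positive")
        if self.niche_center_concentration <= 0:
            raise ConfigError("niche_center_concentration must be positive")
        if self.batch_shift_sd < 0 or self.spatial_smoothness < 0:
            raise ConfigError("batch_shift_sd and spatial_smoothness must be >= 0")
        if self.total_cells_per_spot <= 0:
            raise ConfigError("total_cells_per_spot must be positive")

    def as_dict(self) -> dict[str, object]:
        return {
            "n_sections": self.n_sections,
            "spots_per_section": self.spots_per_section,
            "spot_diameter": self.spot_diameter,
            "n_cell_types": self.n_cell_types,
            "cancer_type_names": ",".join(self.cancer_type_names),
            "n_niches": self.n_niches,
            "niche_center_concentration": self.niche_center_concentration,
            "batch_shift_sd": self.batch_shift_sd,
            "spatial_smoothness": self.spatial_smoothness,
            "total_cells_per_spot": self.total_cells_per_spot,
            "n_ect_blocks": self.n_ect_blocks,
            "seed": self.seed,
        }


@dataclass
class GroundTruth:
    """Planted structure of one generated section (pipeline never reads it)."""

    spot_niche_labels: np.ndarray  # (n_spots,) int niche ids
    ect_membership: dict[str, int]  # cell type -> planted block id
    annotation_polygons: AnnotationLayer | None = None
    cohort_effect: np.ndarray | None = None  # per-ECT log-hazard coefficient

    def to_frame(self, section: Section) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "spot_id": section.spot_ids,
                "section_id": section.section_id,
                "niche": self.spot_niche_labels,
            }
        )


def _hex_lattice(n_spots: int) -> np.ndarray:
    """Hexagonally packed spot centers (µm), roughly square overall."""
    n_cols = int(np.ceil(np.sqrt(n_spots)))
    n_rows = int(np.ceil(n_spots / n_cols))
    rows, cols = np.divmod(np.arange(n_rows * n_cols), n_cols)
    x = cols * LATTICE_PITCH_UM + (rows % 2) * (LATTICE_PITCH_UM / 2.0)
    y = rows * LATTICE_PITCH_UM * (np.sqrt(3.0) / 2.0)
    return np.column_stack([x, y])[:n_spots]


def _smooth_field(coords: np.ndarray, length: float, rng: np.random.Generator,
                  n_centers: int = 40) -> np.ndarray:
    """A zero-mean smooth 2-D displacement field with unit variance per axis."""
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    centers = rng.uniform(lo, hi, size=(n_centers, 2))
    weights = rng.standard_normal((n_centers, 2))
    d2 = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    k = np.exp(-d2 / (2.0 * max(length, 1e-9) ** 2))
    disp = k @ weights
    sd = disp.std(axis=0)
    sd[sd == 0] = 1.0
    return disp / sd


def _niche_labels(coords: np.ndarray, n_niches: int, smoothness: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Contiguous niche domains: perturbed nearest-seed Voronoi labels."""
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    seeds = rng.uniform(lo, hi, size=(n_niches, 2))
    pts = coords
    if smoothness > 0:
        pts = coords + _BOUNDARY_AMPLITUDE_UM * _smooth_field(coords, smoothness, rng)
    d2 = ((pts[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)


def _block_assignment(names: Sequence[str], n_blocks: int,
                      rng: np.random.Generator) -> dict[str, int]:
    """Round-robin assignment of shuffled cell types to planted blocks."""
    order = rng.permutation(len(names))
    return {names[j]: int(i % n_blocks) for i, j in enumerate(order)}


def _niche_centers(config: SimConfig, membership: Mapping[str, int],
                   rng: np.random.Generator) -> np.ndarray:
    """(n_niches, D) compositional centers realising the block structure."""
    names = config.cell_types()
    block = np.array([membership[t] for t in names])
    profiles = rng.normal(0.0, _BLOCK_PROFILE_SD,
                          size=(config.n_niches, config.n_ect_blocks))
    wiggle = rng.normal(0.0, _TYPE_WIGGLE_SD,
                        size=(config.n_niches, config.n_cell_types))
    log_alpha = profiles[:, block] + wiggle
    alpha = np.exp(log_alpha)
    return alpha / alpha.sum(axis=1, keepdims=True)


def generate_sections(config: SimConfig) -> list[tuple[Section, GroundTruth]]:
    """Generate all sections of a synthetic study with their ground truth.

    Deterministic: the same config (including seed) gives byte-identical
    output.  Every ground truth carries the same global ECT membership.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    names = config.cell_types()
    membership = _block_assignment(names, config.n_ect_blocks, rng)
    centers = _niche_centers(config, membership, rng)

    out: list[tuple[Section, GroundTruth]] = []
    for s in range(config.n_sections):
        coords = _hex_lattice(config.spots_per_section)
        labels = _niche_labels(coords, config.n_niches,
                               config.spatial_smoothness, rng)
        alphas = config.niche_center_concentration * centers[labels]
        comp = rng.gamma(np.maximum(alphas, 1e-12))
        comp /= comp.sum(axis=1, keepdims=True)
        totals = rng.gamma(config.total_cells_per_spot, 1.0,
                           size=config.spots_per_section)
        batch = np.exp(rng.normal(0.0, config.batch_shift_sd,
                                  size=config.n_cell_types))
        batch /= batch.mean()  # keep expected spot totals on target
        values = totals[:, None] * comp * batch[None, :]
        sid = f"S{s + 1:02d}"
        section = Section(
            section_id=sid,
            spot_ids=[f"{sid}_spot{i:05d}" for i in range(config.spots_per_section)],
            coords=coords,
            abundance=AbundanceMatrix(list(names), values),
            spot_diameter=config.spot_diameter,
        )
        out.append((section, GroundTruth(labels, dict(membership))))
    return out


def default_compartment_mapping(n_niches: int) -> dict[int, str]:
    """Cycle the 5-compartment vocabulary over niche ids."""
    return {i: COMPARTMENTS[i % len(COMPARTMENTS)] for i in range(n_niches)}


def _spot_hexagon(center: np.ndarray, pitch: float) -> Polygon:
    """The Voronoi hexagon of a lattice spot (circumradius pitch/sqrt(3))."""
    r = pitch / np.sqrt(3.0)
    ang = np.deg2rad(30.0 + 60.0 * np.arange(6))
    verts = center + r * np.column_stack([np.cos(ang), np.sin(ang)])
    return Polygon(verts)


def generate_annotations(
    section: Section,
    truth: GroundTruth,
    mapping: Mapping[int, str] | None = None,
) -> AnnotationLayer:
    """Pathologist-style compartment polygons from the planted niches.

    Each mapped compartment is the union of the Voronoi hexagons of its
    spots, so the true compartment of every interior spot is recoverable
    by the annotation-transfer rule.
    """
    labels = np.asarray(truth.spot_niche_labels)
    niche_ids = np.unique(labels)
    if mapping is None:
        mapping = default_compartment_mapping(int(niche_ids.max()) + 1)
    unmapped = [int(n) for n in niche_ids if int(n) not in mapping]
    if unmapped:
        raise ConfigError(f"niches without a compartment mapping: {unmapped}")
    bad = set(mapping.values()) - set(COMPARTMENTS)
    if bad:
        raise ConfigError(f"compartment labels outside vocabulary: {sorted(bad)}")

    if section.n_spots > 1:
        from scipy.spatial import cKDTree

        d, _ = cKDTree(section.coords).query(section.coords, k=2)
        pitch = float(np.min(d[:, 1]))
    else:
        pitch = LATTICE_PITCH_UM

    polygons: list[tuple[str, object]] = []
    spot_labels = np.array([mapping[int(n)] for n in labels])
    for compartment in sorted(set(spot_labels)):
        hexes = [
            _spot_hexagon(section.coords[i], pitch)
            for i in np.flatnonzero(spot_labels == compartment)
        ]
        geom = unary_union(hexes)
        polygons.append((compartment, geom))
    layer = AnnotationLayer(polygons)
    truth.annotation_polygons = layer
    return layer


def generate_cohort(
    config: SimConfig,
    n_samples: int,
    effect: Sequence[float] | None = None,
    censor_rate: float = 0.005,
    n_archetypes: int = 4,
    baseline_rate: float = 0.01,
    max_followup: float = 120.0,
    archetype_concentration: float = 30.0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Bulk cohort with planted archetypes and an ECT-linked hazard.

    Each sample draws an archetype (a Dirichlet center over the planted
    ECT blocks), its ECT fractions around that center, then splits each
    block's fraction uniformly-Dirichlet among the member cell types.
    Survival times are exponential with log-hazard
    ``log(baseline_rate) + effect . ect_fractions``; censoring is
    independent exponential (rate ``censor_rate``) truncated at
    ``max_followup`` (time units: months).

    Returns the cohort table (sample_id, per-cell-type fraction columns,
    time, event, subtype, group=archetype) and a ground-truth sidecar
    holding the planted ECT membership and effect.
    """
    config.validate()
    if n_samples < 2:
        raise ConfigError("n_samples must be >= 2")
    if censor_rate < 0:
        raise ConfigError("censor_rate must be >= 0")
    if effect is None:
        effect = np.zeros(config.n_ect_blocks)
    effect = np.asarray(effect, dtype=float)
    if effect.shape != (config.n_ect_blocks,):
        raise ConfigError(
            f"effect must have one coefficient per ECT block "
            f"({config.n_ect_blocks}), got shape {effect.shape}"
        )
    rng = np.random.default_rng(config.seed if seed is None else seed)
    names = config.cell_types()
    membership = _block_assignment(names, config.n_ect_blocks, rng)
    block = np.array([membership[t] for t in names])

    # Archetype centers over ECT blocks: distinct Dirichlet draws.
    arch_centers = rng.dirichlet(np.full(config.n_ect_blocks, 0.8), size=n_archetypes)
    archetype = rng.integers(n_archetypes, size=n_samples)
    alphas = archetype_concentration * np.maximum(arch_centers[archetype], 1e-4)
    g = rng.gamma(alphas)
    ect_frac = g / g.sum(axis=1, keepdims=True)

    # Split each block fraction among its member types.
    frac = np.zeros((n_samples, config.n_cell_types))
    for b in range(config.n_ect_blocks):
        members = np.flatnonzero(block == b)
        w = rng.gamma(np.ones((n_samples, members.size)))
        w /= w.sum(axis=1, keepdims=True)
        frac[:, members] = ect_frac[:, [b]] * w

    rate = baseline_rate * np.exp(ect_frac @ effect)
    event_time = rng.exponential(1.0 / rate)
    censor_time = np.full(n_samples, max_followup)
    if censor_rate > 0:
        censor_time = np.minimum(censor_time, rng.exponential(1.0 / censor_rate,
                                                              size=n_samples))
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    subtypes = np.array(["LumA", "LumB", "HER2", "Basal"])
    subtype = subtypes[rng.integers(len(subtypes), size=n_samples)]

    df = pd.DataFrame(frac, columns=list(names))
    df.insert(0, "sample_id", [f"P{i + 1:04d}" for i in range(n_samples)])
    df["time"] = time
    df["event"] = event
    df["subtype"] = subtype
    df["group"] = [f"A{a + 1}" for a in archetype]
    truth = GroundTruth(
        spot_niche_labels=np.empty(0, dtype=int),
        ect_membership=dict(membership),
        cohort_effect=effect.copy(),
    )
    if df.filter(items=names).sum(axis=1).sub(1).abs().max() > 1e-9:
        warnings.warn("cohort fraction rows do not sum to 1", RuntimeWarning)
    return df, truth
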