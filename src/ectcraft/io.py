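"""Reading, writing and validation of on-disk artifacts.

All tabular artifacts are tab-delimited UTF-8 text with a header row and
'.' as decimal separator.  Abundance matrices may alternatively be stored
as Matrix Market coordinate files with two sidecar TSVs listing row
(spot) and column (cell type) names.  Pathologist annotations are GeoJSON
FeatureCollections whose features carry a ``label`` property.

Coordinates are micrometres in the image frame of the section (y grows
downward); this convention is recorded in every run manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from shapely.geometry import mapping as geom_mapping, shape as geom_shape
from shapely.geometry.base import BaseGeometry
from shapely.validation import make_valid

__all__ = [
    "COMPARTMENTS",
    "AbundanceMatrix",
    "AnnotationLayer",
    "Section",
    "ValidationError",
    "read_abundance",
    "read_annotations",
    "read_section",
    "read_spot_table",
    "write_abundance",
    "write_annotations",
    "write_results",
    "write_section",
]

#: Pathological compartment vocabulary used for annotations.
COMPARTMENTS = (
    "Cancer cells",
    "Intratumor stroma",
    "Peritumor stroma",
    "Lymphocyte aggregates",
    "Normal ducts and lobules",
)


class ValidationError(ValueError):
    """An on-disk artifact violates the data model."""


@dataclass
class AbundanceMatrix:
    """Spot x cell-type non-negative abundance estimates for one section.

    ``values[i, j]`` is the estimated abundance (expected number of cells,
    a non-negative real) of cell type ``cell_types[j]`` in spot ``i``.
    This is the shape of a deconvolution posterior-quantile export such as
    cell2location's ``q05_cell_abundance_w_sf``.
    """

    cell_types: list[str]
    values: np.ndarray  # (n_spots, n_types) float64

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("abundance values must be a 2-D matrix")
        if self.values.shape[1] != len(self.cell_types):
            raise ValidationError(
                f"{self.values.shape[1]} columns for "
                f"{len(self.cell_types)} cell types"
            )
        if len(set(self.cell_types)) != len(self.cell_types):
            raise ValidationError("duplicate cell-type names")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("abundance values must be finite")
        if np.any(self.values < 0):
            raise ValidationError("abundance values must be non-negative")

    @property
    def n_spots(self) -> int:
        return self.values.shape[0]

    def proportions(self) -> np.ndarray:
        """Row-normalised abundances (rows with zero total stay zero)."""
        totals = self.values.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            props = np.where(totals > 0, self.values / totals, 0.0)
        return props


@dataclass
class AnnotationLayer:
    """Labeled compartment polygons for one section, in µm coordinates."""

    polygons: list[tuple[str, BaseGeometry]]
    vocabulary: tuple[str, ...] = COMPARTMENTS

    def __post_init__(self) -> None:
        for label, geom in self.polygons:
            if label not in self.vocabulary:
                raise ValidationError(
                    f"annotation label {label!r} not in vocabulary "
                    f"{sorted(self.vocabulary)}"
                )
            if geom.is_empty:
                raise ValidationError(f"empty geometry for label {label!r}")

    def labels(self) -> list[str]:
        return sorted({label for label, _ in self.polygons})


@dataclass
class Section:
    """One tissue section: spots, coordinates and their abundance matrix."""

    section_id: str
    spot_ids: list[str]
    coords: np.ndarray  # (n_spots, 2) µm
    abundance: AbundanceMatrix
    spot_diameter: float = 55.0
    annotations: AnnotationLayer | None = field(default=None)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.spot_ids)
        if len(set(self.spot_ids)) != n:
            raise ValidationError(f"duplicate spot ids in {self.section_id}")
        if self.coords.shape != (n, 2):
            raise ValidationError("coords must be (n_spots, 2)")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("non-finite spot coordinates")
        if self.abundance.n_spots != n:
            raise ValidationError(
                f"abundance has {self.abundance.n_spots} rows for {n} spots"
            )
        if self.spot_diameter <= 0:
            raise ValidationError("spot_diameter must be positive")

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)

    @property
    def cell_types(self) -> list[str]:
        return self.abundance.cell_types


# ---------------------------------------------------------------------------
# readers


def read_spot_table(path: str | Path) -> pd.DataFrame:
    """Read a spot table TSV with columns spot_id, x_um, y_um, section_id."""
    df = pd.read_csv(path, sep="\t", dtype={"spot_id": str, "section_id": str})
    required = {"spot_id", "x_um", "y_um", "section_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"spot table {path} missing columns {sorted(missing)}")
    if df["spot_id"].duplicated().any():
        dup = df.loc[df["spot_id"].duplicated(), "spot_id"].iloc[0]
        raise ValidationError(f"duplicate spot id {dup!r} in {path}")
    return df


def read_abundance(path: str | Path) -> pd.DataFrame:
    """Read an abundance matrix, dense TSV or Matrix Market + sidecars.

    Dense TSVs have a leading ``spot_id`` column and one column per cell
    type.  A path ending in ``.mtx`` is read as a Matrix Market coordinate
    file with sidecars ``<stem>.rows.tsv`` (spot ids) and
    ``<stem>.cols.tsv`` (cell types), one name per line with a header.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        rows = pd.read_csv(path.with_suffix(".rows.tsv"), sep="\t", dtype=str)
        cols = pd.read_csv(path.with_suffix(".cols.tsv"), sep="\t", dtype=str)
        df = pd.DataFrame(
            np.asarray(mat, dtype=float),
            index=rows.iloc[:, 0].tolist(),
            columns=cols.iloc[:, 0].tolist(),
        )
    else:
        df = pd.read_csv(path, sep="\t", index_col="spot_id")
        df.index = df.index.astype(str)
    if df.index.duplicated().any():
        raise ValidationError(f"duplicate spot id in abundance {path}")
    values = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValidationError(f"non-finite abundance value in {path}")
    if (values < 0).any():
        raise ValidationError(f"negative abundance value in {path}")
    return df


def read_annotations(path: str | Path, vocabulary: Sequence[str] = COMPARTMENTS) -> AnnotationLayer:
    """Read a GeoJSON FeatureCollection of labeled compartment polygons."""
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValidationError(f"{path}: expected a GeoJSON FeatureCollection")
    polygons: list[tuple[str, BaseGeometry]] = []
    for feat in doc.get("features", []):
        label = (feat.get("properties") or {}).get("label")
        if label is None:
            raise ValidationError(f"{path}: feature without a 'label' property")
        geom = geom_shape(feat["geometry"])
        if not geom.is_valid:
            geom = make_valid(geom)
        polygons.append((str(label), geom))
    return AnnotationLayer(polygons, vocabulary=tuple(vocabulary))


def read_section(
    spot_path: str | Path,
    abundance_path: str | Path,
    annotation_path: str | Path | None = None,
    spot_diameter: float = 55.0,
    cell_types: Sequence[str] | None = None,
) -> Section:
    """Assemble and validate a :class:`Section` from its on-disk parts.

    Abundance rows are re-indexed to the spot-table order, so the two
    files may list spots in different orders.  A spot present in the
    abundance matrix but absent from the spot table (or vice versa) is a
    structural error naming the spot.
    """
    spots = read_spot_table(spot_path)
    section_ids = spots["section_id"].unique()
    if len(section_ids) != 1:
        raise ValidationError(
            f"spot table {spot_path} mixes sections {sorted(section_ids)}"
        )
    ab = read_abundance(abundance_path)
    spot_ids = spots["spot_id"].tolist()
    missing = set(ab.index) - set(spot_ids)
    if missing:
        raise ValidationError(
            f"abundance spot {sorted(missing)[0]!r} absent from spot table"
        )
    missing = set(spot_ids) - set(ab.index)
    if missing:
        raise ValidationError(
            f"spot {sorted(missing)[0]!r} has no abundance row"
        )
    ab = ab.loc[spot_ids]
    if cell_types is not None and list(ab.columns) != list(cell_types):
        raise ValidationError(
            f"abundance columns of {abundance_path} do not match the "
            f"declared cell-type list"
        )
    annotations = None
    if annotation_path is not None:
        annotations = read_annotations(annotation_path)
    return Section(
        section_id=str(section_ids[0]),
        spot_ids=spot_ids,
        coords=spots[["x_um", "y_um"]].to_numpy(dtype=float),
        abundance=AbundanceMatrix(list(ab.columns), ab.to_numpy(dtype=float)),
        spot_diameter=spot_diameter,
        annotations=annotations,
    )


# ---------------------------------------------------------------------------
# writers


def write_spot_table(section: Section, path: str | Path) -> None:
    pd.DataFrame(
        {
            "spot_id": section.spot_ids,
            "x_um": section.coords[:, 0],
            "y_um": section.coords[:, 1],
            "section_id": section.section_id,
        }
    ).to_csv(path, sep="\t", index=False)


def write_abundance(section: Section, path: str | Path, sparse: bool = False) -> None:
    path = Path(path)
    ab = section.abundance
    if sparse:
        scipy.io.mmwrite(path, scipy.sparse.csr_matrix(ab.values))
        pd.DataFrame({"spot_id": section.spot_ids}).to_csv(
            path.with_suffix(".rows.tsv"), sep="\t", index=False
        )
        pd.DataFrame({"cell_type": ab.cell_types}).to_csv(
            path.with_suffix(".cols.tsv"), sep="\t", index=False
        )
    else:
        df = pd.DataFrame(ab.values, columns=ab.cell_types)
        df.insert(0, "spot_id", section.spot_ids)
        df.to_csv(path, sep="\t", index=False)


def write_annotations(layer: AnnotationLayer, path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"label": label},
            "geometry": geom_mapping(geom),
        }
        for label, geom in layer.polygons
    ]
    doc = {"type": "FeatureCollection", "features": features}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


def write_section(section: Section, out_dir: str | Path, sparse: bool = False) -> dict[str, Path]:
    """Write one section's spot table, abundance and annotations.

    Returns a dict of artifact name -> path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sid = section.section_id
    paths: dict[str, Path] = {}
    paths["spots"] = out_dir / f"{sid}.spots.tsv"
    write_spot_table(section, paths["spots"])
    paths["abundance"] = out_dir / (
        f"{sid}.abundance.mtx" if sparse else f"{sid}.abundance.tsv"
    )
    write_abundance(section, paths["abundance"], sparse=sparse)
    if section.annotations is not None:
        paths["annotations"] = out_dir / f"{sid}.annotations.geojson"
        write_annotations(section.annotations, paths["annotations"])
    return paths


def config_hash(config: Mapping[str, object]) -> str:
    """Stable SHA-256 over a flat key=value rendering of the config."""
    lines = sorted(f"{k}={config[k]!r}" for k in config)
    return hashlib.sha256("\n".join(lines).encode("utf-8")).hexdigest()


def write_results(
    run_dir: str | Path,
    config: Mapping[str, object],
    artifacts: Mapping[str, pd.DataFrame] | None = None,
    seed: int | None = None,
) -> dict[str, object]:
    """Write analysis artifacts as TSVs plus a run manifest.

    The manifest lists every written file, the SHA-256 of the flattened
    config, the seed, and the coordinate convention.  Returns the
    manifest as a dict (also written as ``manifest.tsv``).
    """
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    artifacts = artifacts or {}
    files = []
    for name, df in artifacts.items():
        out = run_dir / f"{name}.tsv"
        df.to_csv(out, sep="\t", index=False)
        files.append(out.name)
    manifest: dict[str, object] = {
        "config_hash": config_hash(config),
        "seed": "" if seed is None else seed,
        "coordinate_frame": "um,image(y-down)",
        "files": ";".join(files),
    }
    pd.DataFrame([manifest]).to_csv(run_dir / "manifest.tsv", sep="\t", index=False)
    return manifest
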