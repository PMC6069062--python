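"""Buffer-based GIS predictor engineering.

Turns feature layers plus site locations into a sites x predictors matrix:
point counts, clipped polyline lengths and polygon areas within discs of
fixed radii, nearest distances with inverse-distance transforms, and raster
buffer means.

Conventions (declared, deterministic):

* the buffer disc is closed — features whose distance to the site equals the
  radius exactly count as inside;
* raster cell membership is by cell centre in the closed disc;
* inverse distances use a 1 m floor so sites sitting on a feature remain
  finite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely import STRtree

from .errors import (
    DuplicatePredictorError,
    EmptyLayerError,
    EmptyMatrixError,
    GeometryAggregationError,
    MissingLayerError,
    RasterCoverageError,
)
from .geodata import FeatureLayer, Raster, site_points

#: Buffer radii used for vector aggregations (metres).
VECTOR_RADII = (25, 50, 100, 300, 500, 1000)
#: Buffer radii used for raster (vegetation-index) means (metres).
RASTER_RADII = (30, 100, 150, 200, 500, 750)
#: Lower bound applied before inverting a distance (metres).
DISTANCE_FLOOR = 1.0
#: Quadrant segments for polygonal disc approximation (64 -> 256-gon,
#: relative area deficit ~1e-4).
BUFFER_QUAD_SEGS = 64

AGGREGATIONS = (
    "count",
    "length",
    "area",
    "raster_mean",
    "distance",
    "inverse_distance",
    "inverse_sq_distance",
)

_GEOM_FOR_AGG = {"count": "point", "length": "line", "area": "polygon"}


@dataclass(frozen=True)
class PredictorSpec:
    """One engineered predictor column.

    ``buffer_radius`` is required for count/length/area/raster_mean and
    ignored for the distance transforms.  ``expected_sign`` is the a-priori
    direction of effect used by the supervised selection.
    """

    name: str
    source_category: str
    aggregation: str
    buffer_radius: float | None = None
    expected_sign: str = "+"

    def __post_init__(self) -> None:
        if self.aggregation not in AGGREGATIONS:
            raise GeometryAggregationError(
                f"{self.name}: unknown aggregation {self.aggregation!r}"
            )
        if self.expected_sign not in ("+", "-"):
            raise ValueError(f"{self.name}: expected_sign must be '+' or '-'")
        if self.aggregation in ("count", "length", "area", "raster_mean"):
            if self.buffer_radius is None or self.buffer_radius <= 0:
                raise ValueError(f"{self.name}: positive buffer_radius required")

    @property
    def sign_value(self) -> int:
        return 1 if self.expected_sign == "+" else -1

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PredictorSpec":
        return cls(
            name=d["name"],
            source_category=d["source_category"],
            aggregation=d["aggregation"],
            buffer_radius=d.get("buffer_radius"),
            expected_sign=d.get("expected_sign", "+"),
        )


@dataclass
class PredictorMatrix:
    """Sites x predictors values plus per-column spec metadata."""

    frame: pd.DataFrame
    specs: dict[str, PredictorSpec]

    @property
    def site_ids(self) -> list:
        return list(self.frame.index)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    def values_for(self, names: Sequence[str]) -> np.ndarray:
        return self.frame.loc[:, list(names)].to_numpy(dtype=float)

    def to_csv(self, matrix_path: str | Path, meta_path: str | Path | None = None) -> None:
        self.frame.to_csv(matrix_path, index_label="site_id")
        if meta_path is not None:
            meta = {name: spec.to_dict() for name, spec in self.specs.items()}
            Path(meta_path).write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_csv(cls, matrix_path: str | Path, meta_path: str | Path) -> "PredictorMatrix":
        frame = pd.read_csv(matrix_path, index_col="site_id")
        meta = json.loads(Path(meta_path).read_text())
        specs = {name: PredictorSpec.from_dict(d) for name, d in meta.items()}
        return cls(frame=frame, specs=specs)


def _discs(sites: pd.DataFrame, radius: float) -> np.ndarray:
    pts = site_points(sites)
    return shapely.buffer(pts, radius, quad_segs=BUFFER_QUAD_SEGS)


def buffer_aggregate(
    layer: FeatureLayer,
    sites: pd.DataFrame,
    radius: float,
    aggregation: str,
) -> np.ndarray:
    """Aggregate one layer within the closed disc of ``radius`` around each site.

    count: points with distance <= radius; length: clipped polyline length;
    area: clipped polygon area.
    """
    if aggregation not in _GEOM_FOR_AGG:
        raise GeometryAggregationError(f"{aggregation!r} is not a buffer aggregation")
    if radius <= 0:
        raise ValueError("radius must be positive")
    expected = _GEOM_FOR_AGG[aggregation]
    if layer.geom_type != expected:
        raise GeometryAggregationError(
            f"layer {layer.category!r} is {layer.geom_type}; "
            f"{aggregation} requires {expected} geometry"
        )
    n = len(sites)
    if len(layer) == 0:
        return np.zeros(n)

    if aggregation == "count":
        pts = site_points(sites)
        geoms = layer.array
        # pairwise distances via broadcasting; closed-disc rule is <=
        d = shapely.distance(geoms[None, :], pts[:, None])
        return (d <= radius).sum(axis=1).astype(float)

    discs = _discs(sites, radius)
    tree = STRtree(layer.geometries)
    out = np.zeros(n)
    for i, disc in enumerate(discs):
        idx = tree.query(disc)
        if idx.size == 0:
            continue
        clipped = shapely.intersection(layer.array[idx], disc)
        if aggregation == "length":
            out[i] = shapely.length(clipped).sum()
        else:
            out[i] = shapely.area(clipped).sum()
    return out


def nearest_distance(layer: FeatureLayer, sites: pd.DataFrame) -> np.ndarray:
    """Minimum Euclidean distance from each site to any feature of ``layer``."""
    if len(layer) == 0:
        raise EmptyLayerError(f"layer {layer.category!r} has no features")
    pts = site_points(sites)
    d = shapely.distance(layer.array[None, :], pts[:, None])
    return d.min(axis=1)


def distance_transforms(
    d: np.ndarray | float, floor: float = DISTANCE_FLOOR
) -> tuple[np.ndarray, np.ndarray]:
    """Return (1/max(d, floor), 1/max(d, floor)^2)."""
    if floor <= 0:
        raise ValueError("floor must be positive")
    d = np.maximum(np.asarray(d, dtype=float), floor)
    inv = 1.0 / d
    return inv, inv * inv


def raster_buffer_mean(raster: Raster, sites: pd.DataFrame, radius: float) -> np.ndarray:
    """Mean of raster cells whose centres lie in the closed disc around each site."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    cx, cy = raster.cell_centers()
    cx = cx.ravel()
    cy = cy.ravel()
    vals = raster.values.ravel()
    xmin, ymin, xmax, ymax = raster.bounds
    out = np.zeros(len(sites))
    xs = np.asarray(sites["x"], dtype=float)
    ys = np.asarray(sites["y"], dtype=float)
    ids = list(sites.index)
    for i, (x, y) in enumerate(zip(xs, ys)):
        if x - radius < xmin or x + radius > xmax or y - radius < ymin or y + radius > ymax:
            raise RasterCoverageError(
                f"buffer of {radius} m around site {ids[i]!r} exits the raster extent"
            )
        inside = (cx - x) ** 2 + (cy - y) ** 2 <= radius**2
        cell_vals = vals[inside]
        cell_vals = cell_vals[np.isfinite(cell_vals)]
        if cell_vals.size == 0:
            raise RasterCoverageError(
                f"no raster cell centres inside the {radius} m buffer of site {ids[i]!r}"
            )
        out[i] = cell_vals.mean()
    return out


def build_matrix(
    specs: Sequence[PredictorSpec],
    layers: Mapping[str, FeatureLayer],
    sites: pd.DataFrame,
    raster: Raster | None = None,
    floor: float = DISTANCE_FLOOR,
) -> PredictorMatrix:
    """Dispatch each spec to its aggregation and assemble the matrix.

    Distance columns are cached per source layer so that the three transforms
    (d, 1/d, 1/d^2) share one nearest-distance computation.
    """
    names = [s.name for s in specs]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise DuplicatePredictorError(f"duplicate predictor names: {sorted(dupes)}")
    if len(sites) == 0:
        raise EmptyMatrixError("no sites provided")

    dist_cache: dict[str, np.ndarray] = {}
    columns: dict[str, np.ndarray] = {}
    for spec in specs:
        if spec.aggregation == "raster_mean":
            if raster is None:
                raise MissingLayerError(f"{spec.name}: no raster provided")
            columns[spec.name] = raster_buffer_mean(raster, sites, spec.buffer_radius)
            continue
        layer = layers.get(spec.source_category)
        if layer is None:
            raise MissingLayerError(
                f"{spec.name}: layer category {spec.source_category!r} not provided"
            )
        if spec.aggregation in ("count", "length", "area"):
            columns[spec.name] = buffer_aggregate(layer, sites, spec.buffer_radius, spec.aggregation)
        else:
            if spec.source_category not in dist_cache:
                dist_cache[spec.source_category] = nearest_distance(layer, sites)
            d = dist_cache[spec.source_category]
            if spec.aggregation == "distance":
                columns[spec.name] = d.copy()
            else:
                inv, inv_sq = distance_transforms(d, floor)
                columns[spec.name] = inv if spec.aggregation == "inverse_distance" else inv_sq

    frame = pd.DataFrame(columns, index=sites.index)
    return PredictorMatrix(frame=frame, specs={s.name: s for s in specs})


def standard_specs(
    point_layers: Mapping[str, str] | None = None,
    line_layers: Mapping[str, str] | None = None,
    polygon_layers: Mapping[str, str] | None = None,
    raster_sign: str | None = "-",
    vector_radii: Sequence[float] = VECTOR_RADII,
    raster_radii: Sequence[float] = RASTER_RADII,
) -> list[PredictorSpec]:
    """Generate the standard predictor battery for a set of layers.

    Each mapping is ``category -> expected sign``.  Point layers yield counts
    at each radius plus inverse (squared) distance; line layers yield clipped
    lengths plus the distance transforms; polygon layers yield clipped areas.
    A raster entry yields buffer means at the raster radii.
    """
    specs: list[PredictorSpec] = []
    for cat, sign in (point_layers or {}).items():
        up = cat.upper()
        for r in vector_radii:
            specs.append(PredictorSpec(f"{up}_{r:g}", cat, "count", r, sign))
        specs.append(PredictorSpec(f"{up}_INVD", cat, "inverse_distance", None, sign))
        specs.append(PredictorSpec(f"{up}_INVD2", cat, "inverse_sq_distance", None, sign))
    for cat, sign in (line_layers or {}).items():
        up = cat.upper()
        for r in vector_radii:
            specs.append(PredictorSpec(f"{up}_{r:g}", cat, "length", r, sign))
        specs.append(PredictorSpec(f"{up}_INVD", cat, "inverse_distance", None, sign))
        specs.append(PredictorSpec(f"{up}_INVD2", cat, "inverse_sq_distance", None, sign))
    for cat, sign in (polygon_layers or {}).items():
        up = cat.upper()
        for r in vector_radii:
            specs.append(PredictorSpec(f"{up}_{r:g}", cat, "area", r, sign))
    if raster_sign is not None:
        for r in raster_radii:
            specs.append(PredictorSpec(f"NDVI_{r:g}", "ndvi", "raster_mean", r, raster_sign))
    return specs
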