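"""Geospatial containers and plain-text I/O (GeoJSON, ESRI ASCII grid).

Coordinates are a local planar Cartesian system in metres.  All geometry is
Euclidean; no CRS or geodesy is involved anywhere in the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .errors import ConfigError

NODATA = -9999.0


@dataclass
class FeatureLayer:
    """A named collection of homogeneous geometries.

    Parameters
    ----------
    category:
        Layer key used by predictor specs (e.g. ``"major_road"``).
    geom_type:
        One of ``"point"``, ``"line"``, ``"polygon"``.
    geometries:
        Shapely geometries, all of the declared type.
    names:
        Optional per-feature labels; autogenerated when omitted.
    """

    category: str
    geom_type: str
    geometries: list[BaseGeometry]
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.geom_type not in ("point", "line", "polygon"):
            raise ConfigError(f"unknown geometry type {self.geom_type!r}")
        if not self.names:
            self.names = [f"{self.category}_{i}" for i in range(len(self.geometries))]

    def __len__(self) -> int:
        return len(self.geometries)

    @property
    def array(self) -> np.ndarray:
        """Geometries as a shapely object array (vectorised ops)."""
        return np.asarray(self.geometries, dtype=object)

    def total_length(self) -> float:
        return float(sum(g.length for g in self.geometries))


def write_geojson(layer: FeatureLayer, path: str | Path) -> None:
    """Write a layer as a GeoJSON FeatureCollection (``category``/``name`` properties)."""
    features = [
        {
            "type": "Feature",
            "geometry": mapping(geom),
            "properties": {"category": layer.category, "name": name},
        }
        for geom, name in zip(layer.geometries, layer.names)
    ]
    payload = {
        "type": "FeatureCollection",
        "lur:geom_type": layer.geom_type,
        "features": features,
    }
    Path(path).write_text(json.dumps(payload))


_GEOJSON_TYPE = {
    "Point": "point",
    "MultiPoint": "point",
    "LineString": "line",
    "MultiLineString": "line",
    "Polygon": "polygon",
    "MultiPolygon": "polygon",
}


def read_geojson(path: str | Path) -> FeatureLayer:
    payload = json.loads(Path(path).read_text())
    feats = payload.get("features", [])
    geoms = [shape(f["geometry"]) for f in feats]
    names = [f.get("properties", {}).get("name", f"f{i}") for i, f in enumerate(feats)]
    category = Path(path).stem
    if feats:
        category = feats[0].get("properties", {}).get("category", category)
    geom_type = payload.get("lur:geom_type")
    if geom_type is None:
        if not geoms:
            raise ConfigError(f"{path}: empty collection without declared geometry type")
        geom_type = _GEOJSON_TYPE[geoms[0].geom_type]
    return FeatureLayer(category=category, geom_type=geom_type, geometries=geoms, names=names)


def write_layers(layers: dict[str, FeatureLayer], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for key, layer in layers.items():
        write_geojson(layer, directory / f"{key}.geojson")


def read_layers(directory: str | Path) -> dict[str, FeatureLayer]:
    layers = {}
    for path in sorted(Path(directory).glob("*.geojson")):
        layer = read_geojson(path)
        layers[layer.category] = layer
    return layers


@dataclass
class Raster:
    """A regular grid of cell values on the local metric plane.

    ``values[0, :]`` is the northernmost (top) row, matching the ESRI ASCII
    grid convention.  ``xll``/``yll`` locate the lower-left corner.
    """

    values: np.ndarray
    xll: float
    yll: float
    cell_size: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ConfigError("raster values must be a 2-D array")
        if self.cell_size <= 0:
            raise ConfigError("raster cell size must be positive")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return (
            self.xll,
            self.yll,
            self.xll + self.ncols * self.cell_size,
            self.yll + self.nrows * self.cell_size,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) arrays of all cell centres, shaped like ``values``."""
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        x = self.xll + (cols + 0.5) * self.cell_size
        y = self.yll + (self.nrows - rows - 0.5) * self.cell_size
        return np.meshgrid(x, y)


def write_ascii_grid(raster: Raster, path: str | Path) -> None:
    """Write an ESRI ASCII grid (plain text, NODATA for NaN cells)."""
    values = np.where(np.isfinite(raster.values), raster.values, NODATA)
    header = (
        f"ncols {raster.ncols}\n"
        f"nrows {raster.nrows}\n"
        f"xllcorner {float(raster.xll)!r}\n"
        f"yllcorner {float(raster.yll)!r}\n"
        f"cellsize {float(raster.cell_size)!r}\n"
        f"NODATA_value {NODATA!r}\n"
    )
    body = "\n".join(" ".join(repr(float(v)) for v in row) for row in values)
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(path: str | Path) -> Raster:
    lines = Path(path).read_text().splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in (
        "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
    ):
        key, val = lines[i].split()
        header[key.lower()] = float(val)
        i += 1
    values = np.array([[float(v) for v in line.split()] for line in lines[i:] if line.strip()])
    nodata = header.get("nodata_value", NODATA)
    values = np.where(values == nodata, np.nan, values)
    return Raster(
        values=values,
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cell_size=header["cellsize"],
    )


def site_points(sites) -> np.ndarray:
    """Shapely point array from a table with ``x``/``y`` columns."""
    return shapely.points(np.asarray(sites["x"]), np.asarray(sites["y"]))
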