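"""Exposure surfaces: apply a fitted model at receptor points or over a grid.

Predictor values at receptors are recomputed with the same buffer machinery
used at the training sites — nothing is interpolated from a precomputed
surface.  Negative predictions clamp to 0 (physical floor); there is no upper
truncation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, MissingLayerError
from .features import DISTANCE_FLOOR, PredictorSpec, build_matrix
from .geodata import FeatureLayer, Raster
from .selection import LurFit


@dataclass
class PredictionGrid:
    """A regular grid of predicted concentrations (row 0 is the top row)."""

    origin: tuple[float, float]
    cell_size: float
    values: np.ndarray
    pollutant: str
    season: str
    truncated_cells: int

    def to_raster(self) -> Raster:
        return Raster(
            values=self.values,
            xll=self.origin[0],
            yll=self.origin[1],
            cell_size=self.cell_size,
        )


def _fit_specs(fit: LurFit, layers: Mapping[str, FeatureLayer], raster: Raster | None) -> list[PredictorSpec]:
    specs = []
    for term in fit.terms:
        if not term.spec:
            raise MissingLayerError(f"term {term.name!r} carries no predictor spec")
        spec = PredictorSpec.from_dict(term.spec)
        if spec.aggregation == "raster_mean":
            if raster is None:
                raise MissingLayerError(f"term {term.name!r} needs a raster, none provided")
        elif spec.source_category not in layers:
            raise MissingLayerError(
                f"term {term.name!r} needs layer {spec.source_category!r}, not provided"
            )
        specs.append(spec)
    return specs


def predict_points(
    fit: LurFit,
    receptors: pd.DataFrame,
    layers: Mapping[str, FeatureLayer],
    raster: Raster | None = None,
    floor: float = DISTANCE_FLOOR,
) -> pd.DataFrame:
    """Model predictions at arbitrary receptor locations.

    ``receptors`` needs ``x``/``y`` columns; the index is the receptor id.
    Returns a frame with ``value_ugm3`` and a ``clamped`` flag.
    """
    specs = _fit_specs(fit, layers, raster)
    if specs:
        pm = build_matrix(specs, layers, receptors, raster, floor=floor)
        X = pm.values_for(fit.term_names)
    else:
        X = np.empty((len(receptors), 0))
    raw = fit.predict(X)
    clamped = raw < 0
    out = receptors[["x", "y"]].copy()
    out["pollutant"] = fit.pollutant
    out["season"] = fit.season
    out["value_ugm3"] = np.where(clamped, 0.0, raw)
    out["clamped"] = clamped
    return out


def predict_grid(
    fit: LurFit,
    layers: Mapping[str, FeatureLayer],
    raster: Raster | None,
    cell_size: float,
    bounds: tuple[float, float, float, float],
    floor: float = DISTANCE_FLOOR,
) -> PredictionGrid:
    """Evaluate :func:`predict_points` at every cell centre of a regular grid.

    ``bounds`` is (xmin, ymin, xmax, ymax) of the study area; the default
    25 m cell size mirrors the smallest buffer radius.
    """
    xmin, ymin, xmax, ymax = bounds
    if cell_size <= 0:
        raise ConfigError("cell_size must be positive")
    if cell_size > (xmax - xmin) or cell_size > (ymax - ymin):
        raise ConfigError("cell_size exceeds the study-area extent")
    ncols = int(np.floor((xmax - xmin) / cell_size))
    nrows = int(np.floor((ymax - ymin) / cell_size))
    cols = xmin + (np.arange(ncols) + 0.5) * cell_size
    rows = ymin + (nrows - np.arange(nrows) - 0.5) * cell_size  # top row first
    xx, yy = np.meshgrid(cols, rows)
    receptors = pd.DataFrame({"x": xx.ravel(), "y": yy.ravel()})
    receptors.index = [f"cell_{i}" for i in range(len(receptors))]
    preds = predict_points(fit, receptors, layers, raster, floor=floor)
    values = preds["value_ugm3"].to_numpy().reshape(nrows, ncols)
    return PredictionGrid(
        origin=(xmin, ymin),
        cell_size=cell_size,
        values=values,
        pollutant=fit.pollutant,
        season=fit.season,
        truncated_cells=int(preds["clamped"].sum()),
    )


def write_receptor_csv(preds: pd.DataFrame, path) -> None:
    out = preds.reset_index(names="receptor_id")
    out = out[["receptor_id", "x", "y", "pollutant", "season", "value_ugm3", "clamped"]]
    out.to_csv(path, index=False)


def plot_grid(grid: PredictionGrid, path) -> None:
    """Render the surface as an image (no cartographic styling)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xmin, ymin = grid.origin
    extent = (
        xmin,
        xmin + grid.values.shape[1] * grid.cell_size,
        ymin,
        ymin + grid.values.shape[0] * grid.cell_size,
    )
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(grid.values, extent=extent, origin="upper", cmap="viridis")
    fig.colorbar(im, ax=ax, label=f"{grid.pollutant.upper()} ({grid.season}) ug/m3")
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
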