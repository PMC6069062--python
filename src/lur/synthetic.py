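"""Synthetic study generation.

Produces a complete, fully seeded study on a local metric plane: GIS layers
(grid-aligned road network, bus routes as a subset of roads, rail, informal
point sources, dwellings, a non-overlapping land-use tiling), a smooth
vegetation-index raster in [-1, 1], stratified measurement sites, an hourly
reference-station series, and weekly measurements drawn from a known linear
ground truth.  Because the generative model is known, downstream stages can
assert exact recovery.

Randomness is split into one independent stream per layer, derived from the
master seed, so adding a layer never perturbs the others.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Point, box

from . import temporal
from .errors import ConfigError, SchedulingError, SiteGenerationError
from .features import PredictorSpec, build_matrix
from .geodata import FeatureLayer, Raster
from .temporal import SeasonWindow

# fixed sub-stream ids: adding a stream must not renumber existing ones
_STREAMS = {
    "major_road": 1,
    "minor_road": 2,
    "bus_route": 3,
    "rail": 4,
    "bus_stop": 5,
    "grill": 6,
    "waste_burn": 7,
    "construction": 8,
    "refuse_station": 9,
    "dwelling": 10,
    "landuse": 11,
    "ndvi": 12,
    "sites": 13,
    "reference": 14,
    "measurements": 15,
    "schedule": 16,
}

POINT_CATEGORIES = ("bus_stop", "grill", "waste_burn", "construction", "refuse_station", "dwelling")
LANDUSE_CLASSES = ("residential", "commercial", "industrial", "open_space", "vegetation")

#: line layers in km per km^2 (grid spacing = 2000 / intensity metres),
#: rail in number of lines, point layers in points per km^2.
DEFAULT_INTENSITIES = {
    "major_road": 4.0,
    "minor_road": 20.0,
    "rail": 1.0,
    "bus_stop": 15.0,
    "grill": 20.0,
    "waste_burn": 12.0,
    "construction": 6.0,
    "refuse_station": 3.0,
    "dwelling": 300.0,
}

DEFAULT_SEASONS = {
    "warm": SeasonWindow("warm", "2015-11-02", "2016-03-27"),
    "cold": SeasonWindow("cold", "2016-06-06", "2016-09-25"),
}

DEFAULT_REF_PARAMS = {
    "pm10_mean": {"warm": 25.0, "cold": 29.0},
    "pm10_ar": 0.6,
    "pm10_day_sd": 5.0,
    "pm10_hour_sd": 2.0,
    "solar_amp": {"warm": 800.0, "cold": 450.0},
    "no2_model": (5.0, 0.6, -0.01),  # intercept, pm10 coef, solar coef
    "no2_noise_sd": 2.0,
    "temp_mean": {"warm": 22.0, "cold": 13.0},
}


@dataclass(frozen=True)
class TrueTerm:
    spec: PredictorSpec
    coefficient: float


@dataclass
class TrueModel:
    """Ground-truth linear exposure model used to generate measurements."""

    intercepts: dict[str, float]
    terms: list[TrueTerm]

    def coefficient_map(self) -> dict[str, float]:
        return {t.spec.name: t.coefficient for t in self.terms}


def default_true_model() -> TrueModel:
    return TrueModel(
        intercepts={"warm": 14.0, "cold": 24.0},
        terms=[
            TrueTerm(PredictorSpec("GRILL_300", "grill", "count", 300, "+"), 0.8),
            TrueTerm(PredictorSpec("WASTE_BURN_500", "waste_burn", "count", 500, "+"), 0.5),
            TrueTerm(PredictorSpec("NDVI_200", "ndvi", "raster_mean", 200, "-"), -4.0),
        ],
    )


@dataclass
class StudyConfig:
    """All knobs of the synthetic study.

    ``road_proximity_fractions`` stratify sites into <50 m / 50-100 m /
    >100 m distance to a major road.  ``true_model`` defines the linear
    ground truth; ``noise_sd`` is the iid measurement noise in ug/m3.
    """

    area_width: float = 2000.0
    area_height: float = 1500.0
    seed: int = 0
    n_sites: int = 95
    road_proximity_fractions: tuple[float, float, float] = (0.6, 0.3, 0.1)
    layer_intensities: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_INTENSITIES))
    season_windows: dict[str, SeasonWindow] = field(default_factory=lambda: dict(DEFAULT_SEASONS))
    weekly_capacity: int = 10
    true_model: TrueModel = field(default_factory=default_true_model)
    noise_sd: float = 1.0
    ref_gap_fraction: float = 0.02
    pollutant: str = "no2"
    drop_fraction: float = 0.0
    no2_cutover: str | None = "2016-01-15"
    bus_route_fraction: float = 0.3
    landuse_tile: float = 250.0
    ndvi_cell_size: float = 30.0
    ndvi_pad: float = 800.0
    ref_params: dict = field(default_factory=lambda: json.loads(json.dumps(DEFAULT_REF_PARAMS)))

    def __post_init__(self) -> None:
        if self.area_width <= 0 or self.area_height <= 0:
            raise ConfigError("study area must have positive width and height")
        if abs(sum(self.road_proximity_fractions) - 1.0) > 1e-9:
            raise ConfigError("road proximity fractions must sum to 1")
        if any(f < 0 for f in self.road_proximity_fractions):
            raise ConfigError("road proximity fractions must be non-negative")
        for cat, lam in self.layer_intensities.items():
            if lam < 0:
                raise ConfigError(f"layer intensity for {cat!r} is negative")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if not 0 <= self.ref_gap_fraction < 1:
            raise ConfigError("ref_gap_fraction must lie in [0, 1)")
        if not 0 <= self.drop_fraction < 1:
            raise ConfigError("drop_fraction must lie in [0, 1)")
        windows = list(self.season_windows.values())
        for i, a in enumerate(windows):
            for b in windows[i + 1 :]:
                if a.start <= b.end and b.start <= a.end:
                    raise ConfigError(f"season windows {a.label!r} and {b.label!r} overlap")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])


@dataclass
class SyntheticTruth:
    """Ground truth retained for recovery tests."""

    true_coefficients: dict[str, float]
    intercepts: dict[str, float]
    true_site_means: pd.DataFrame  # index site_id, one column per season
    predictor_values: pd.DataFrame  # true-model predictors at the sites
    ref_deviations: dict[tuple[str, str], float] = field(default_factory=dict)


def _grid_lines(width: float, height: float, spacing: float, rng: np.random.Generator) -> list[LineString]:
    ox = rng.uniform(0, spacing)
    oy = rng.uniform(0, spacing)
    lines = []
    x = ox
    while x < width:
        lines.append(LineString([(x, 0.0), (x, height)]))
        x += spacing
    y = oy
    while y < height:
        lines.append(LineString([(0.0, y), (width, y)]))
        y += spacing
    return lines


def _poisson_points(width: float, height: float, per_km2: float, rng: np.random.Generator) -> list[Point]:
    area_km2 = width * height / 1e6
    n = rng.poisson(per_km2 * area_km2)
    xs = rng.uniform(0, width, n)
    ys = rng.uniform(0, height, n)
    return [Point(x, y) for x, y in zip(xs, ys)]


def _ndvi_raster(config: StudyConfig) -> Raster:
    rng = config.rng("ndvi")
    pad = config.ndvi_pad
    cs = config.ndvi_cell_size
    ncols = math.ceil((config.area_width + 2 * pad) / cs)
    nrows = math.ceil((config.area_height + 2 * pad) / cs)
    raster = Raster(np.zeros((nrows, ncols)), xll=-pad, yll=-pad, cell_size=cs)
    x, y = raster.cell_centers()
    field_vals = np.zeros_like(x)
    for _ in range(4):
        wavelength = rng.uniform(300.0, 1500.0)
        theta = rng.uniform(0, 2 * np.pi)
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.5, 1.0)
        k = 2 * np.pi / wavelength
        field_vals += amp * np.sin(k * (np.cos(theta) * x + np.sin(theta) * y) + phase)
    lo, hi = field_vals.min(), field_vals.max()
    raster.values = -1.0 + 2.0 * (field_vals - lo) / (hi - lo)
    return raster


def generate_layers(config: StudyConfig) -> tuple[dict[str, FeatureLayer], Raster]:
    """Generate all vector layers plus the vegetation-index raster."""
    w, h = config.area_width, config.area_height
    lam = {**DEFAULT_INTENSITIES, **config.layer_intensities}
    layers: dict[str, FeatureLayer] = {}

    major = _grid_lines(w, h, 2000.0 / lam["major_road"], config.rng("major_road"))
    minor = _grid_lines(w, h, 2000.0 / lam["minor_road"], config.rng("minor_road"))
    layers["major_road"] = FeatureLayer("major_road", "line", major)
    layers["minor_road"] = FeatureLayer("minor_road", "line", minor)
    layers["road"] = FeatureLayer("road", "line", list(major) + list(minor))

    rng = config.rng("bus_route")
    all_roads = list(major) + list(minor)
    keep = rng.random(len(all_roads)) < config.bus_route_fraction
    routes = [g for g, k in zip(all_roads, keep) if k] or [major[0]]
    layers["bus_route"] = FeatureLayer("bus_route", "line", routes)

    rng = config.rng("rail")
    n_rail = max(1, int(round(lam["rail"])))
    rails = [LineString([(0.0, yy), (w, yy)]) for yy in sorted(rng.uniform(0, h, n_rail))]
    layers["rail"] = FeatureLayer("rail", "line", rails)

    for cat in POINT_CATEGORIES:
        pts = _poisson_points(w, h, lam[cat], config.rng(cat))
        layers[cat] = FeatureLayer(cat, "point", pts)

    rng = config.rng("landuse")
    t = config.landuse_tile
    tiles: dict[str, list] = {c: [] for c in LANDUSE_CLASSES}
    nx, ny = math.ceil(w / t), math.ceil(h / t)
    for i in range(nx):
        for j in range(ny):
            tile = box(i * t, j * t, min((i + 1) * t, w), min((j + 1) * t, h))
            cls = LANDUSE_CLASSES[rng.integers(0, len(LANDUSE_CLASSES))]
            tiles[cls].append(tile)
    for cls, polys in tiles.items():
        layers[f"lu_{cls}"] = FeatureLayer(f"lu_{cls}", "polygon", polys)

    return layers, _ndvi_raster(config)


def _allocate(n: int, fractions: Sequence[float]) -> np.ndarray:
    raw = np.asarray(fractions, dtype=float) * n
    base = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - base))[: n - base.sum()]:
        base[i] += 1
    return base


#: distance-to-major-road class bands (lower inclusive, upper inclusive)
CLASS_BANDS = {"near": (0.0, 50.0), "intermediate": (50.0, 100.0), "background": (100.0, np.inf)}


def classify_distance(d: np.ndarray) -> np.ndarray:
    """Proximity class from distance to the nearest major road."""
    d = np.asarray(d, dtype=float)
    out = np.where(d < 50.0, "near", np.where(d <= 100.0, "intermediate", "background"))
    return out.astype(object)


def sample_sites(config: StudyConfig, layers: Mapping[str, FeatureLayer]) -> pd.DataFrame:
    """Sample stratified sites; index ``site_id``, columns x, y, class, dist_major."""
    if "major_road" not in layers or len(layers["major_road"]) == 0:
        raise SiteGenerationError("a non-empty major_road layer is required")
    rng = config.rng("sites")
    roads = layers["major_road"].array
    targets = dict(zip(("near", "intermediate", "background"), _allocate(config.n_sites, config.road_proximity_fractions)))
    got: dict[str, list[tuple[float, float, float]]] = {c: [] for c in targets}
    batch = max(200, 4 * config.n_sites)
    for _ in range(200):
        if all(len(got[c]) >= targets[c] for c in targets):
            break
        xs = rng.uniform(0, config.area_width, batch)
        ys = rng.uniform(0, config.area_height, batch)
        pts = shapely.points(xs, ys)
        d = shapely.distance(pts[:, None], roads[None, :]).min(axis=1)
        cls = classify_distance(d)
        for x, y, dd, c in zip(xs, ys, d, cls):
            if len(got[c]) < targets[c]:
                got[c].append((x, y, dd))
    unmet = {c: targets[c] - len(got[c]) for c in targets if len(got[c]) < targets[c]}
    if unmet:
        lo, hi = CLASS_BANDS[next(iter(unmet))]
        raise SiteGenerationError(
            f"could not place sites for classes {unmet} (distance band [{lo}, {hi}] m "
            "unreachable in this area/road layout)"
        )
    rows = []
    k = 0
    for c in ("near", "intermediate", "background"):
        for x, y, dd in got[c][: targets[c]]:
            rows.append((f"S{k:03d}", x, y, c, dd))
            k += 1
    sites = pd.DataFrame(rows, columns=["site_id", "x", "y", "class", "dist_major"])
    return sites.set_index("site_id")


def generate_reference_series(config: StudyConfig) -> pd.DataFrame:
    """Hourly reference-station series: pm10, no2, solar, temp with gaps.

    PM10 carries a seasonal level plus AR(1) day-to-day deviations; solar
    radiation follows a clear-sky half-sine that is exactly 0 at night; NO2 is
    a configured linear function of PM10 and solar plus noise.  A fraction of
    hours is deleted per variable, and NO2 stops entirely at the cut-over
    date when one is configured.
    """
    rng = config.rng("reference")
    p = config.ref_params
    start = min(wnd.start for wnd in config.season_windows.values())
    end = max(wnd.end for wnd in config.season_windows.values()) + pd.Timedelta(hours=23)
    idx = pd.date_range(start, end, freq="h")
    days = pd.date_range(start.normalize(), end.normalize(), freq="D")

    cold = config.season_windows.get("cold")
    is_cold_day = np.array([cold is not None and cold.start <= d for d in days])
    pm10_base = np.where(is_cold_day, p["pm10_mean"]["cold"], p["pm10_mean"]["warm"])
    ar, dsd = p["pm10_ar"], p["pm10_day_sd"]
    dev = np.zeros(len(days))
    eps = rng.normal(0, 1, len(days))
    dev[0] = dsd * eps[0]
    for t in range(1, len(days)):
        dev[t] = ar * dev[t - 1] + dsd * math.sqrt(1 - ar * ar) * eps[t]
    day_level = pd.Series(pm10_base + dev, index=days)

    hours = idx.hour.to_numpy()
    level = day_level.reindex(idx.normalize()).to_numpy()
    pm10 = np.maximum(level + rng.normal(0, p["pm10_hour_sd"], len(idx)), 0.0)

    day_is_cold = pd.Series(is_cold_day, index=days).reindex(idx.normalize()).to_numpy()
    # per-day cloud factor so daily solar means vary (needed by the gap-fill fit)
    cloud = pd.Series(rng.uniform(0.6, 1.0, len(days)), index=days).reindex(idx.normalize()).to_numpy()
    amp = cloud * np.where(day_is_cold, p["solar_amp"]["cold"], p["solar_amp"]["warm"])
    frac = (hours - 6) / 12.0
    solar = np.where((hours >= 6) & (hours <= 18), amp * np.maximum(np.sin(np.pi * frac), 0.0), 0.0)

    a, b, c = p["no2_model"]
    no2 = a + b * pm10 + c * solar + rng.normal(0, p["no2_noise_sd"], len(idx))

    tmean = np.where(day_is_cold, p["temp_mean"]["cold"], p["temp_mean"]["warm"])
    temp = tmean + 6.0 * np.sin(np.pi * (hours - 9) / 12.0)

    df = pd.DataFrame({"pm10": pm10, "no2": no2, "solar": solar, "temp": temp}, index=idx)
    df.index.name = "timestamp"
    if config.ref_gap_fraction > 0:
        for col in df.columns:
            mask = rng.random(len(df)) < config.ref_gap_fraction
            df.loc[mask, col] = np.nan
    if config.no2_cutover is not None:
        df.loc[df.index >= pd.Timestamp(config.no2_cutover), "no2"] = np.nan
    return df


def make_truth(
    config: StudyConfig,
    layers: Mapping[str, FeatureLayer],
    sites: pd.DataFrame,
    raster: Raster | None,
) -> SyntheticTruth:
    """Evaluate the true model at the sites; clamp negative means to 0."""
    model = config.true_model
    for term in model.terms:
        if term.coefficient * term.spec.sign_value <= 0:
            raise ConfigError(
                f"true coefficient for {term.spec.name} contradicts its expected sign"
            )
    specs = [t.spec for t in model.terms]
    pm = build_matrix(specs, layers, sites, raster)
    coefs = np.array([t.coefficient for t in model.terms])
    means = {}
    for season, intercept in model.intercepts.items():
        vals = intercept + pm.frame.to_numpy(dtype=float) @ coefs
        means[season] = np.maximum(vals, 0.0)
    true_means = pd.DataFrame(means, index=sites.index)
    return SyntheticTruth(
        true_coefficients=model.coefficient_map(),
        intercepts=dict(model.intercepts),
        true_site_means=true_means,
        predictor_values=pm.frame,
    )


def season_weeks(window: SeasonWindow) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Monday-start weeks fully contained in the window."""
    days = pd.date_range(window.start, window.end, freq="D")
    weeks = []
    for d in days[days.weekday == 0]:
        if d + pd.Timedelta(days=6) <= window.end:
            weeks.append((d, d + pd.Timedelta(days=6)))
    return weeks


def generate_measurements(
    sites: pd.DataFrame,
    truth: SyntheticTruth,
    config: StudyConfig,
    ref_daily: pd.Series,
) -> pd.DataFrame:
    """Weekly measurement records under the capacity-limited schedule.

    Each record value = true seasonal site mean + that week's reference
    deviation from the seasonal mean + iid noise.  Noise draws and deviations
    are kept as columns so values regenerate exactly from the parts.
    """
    rng_sched = config.rng("schedule")
    rng_meas = config.rng("measurements")
    rows = []
    for season, window in config.season_windows.items():
        weeks = season_weeks(window)
        needed = math.ceil(len(sites) / config.weekly_capacity)
        if needed > len(weeks):
            raise SchedulingError(
                f"season {season!r}: {len(sites)} sites at capacity "
                f"{config.weekly_capacity} need {needed} weeks but only {len(weeks)} are available"
            )
        season_ref = ref_daily.loc[window.start : window.end]
        season_mean = float(season_ref.mean())
        order = rng_sched.permutation(sites.index.to_numpy())
        for k in range(needed):
            week_start, week_end = weeks[k]
            dev = float(ref_daily.loc[week_start:week_end].mean()) - season_mean
            truth.ref_deviations[(season, week_start.date().isoformat())] = dev
            for site in order[k * config.weekly_capacity : (k + 1) * config.weekly_capacity]:
                noise = float(rng_meas.normal(0, config.noise_sd)) if config.noise_sd > 0 else 0.0
                true_mean = float(truth.true_site_means.loc[site, season])
                rows.append(
                    (site, config.pollutant, season, week_start.date().isoformat(),
                     week_end.date().isoformat(), true_mean + dev + noise, true_mean, dev, noise)
                )
    records = pd.DataFrame(
        rows,
        columns=["site_id", "pollutant", "season", "start_date", "end_date",
                 "value_ugm3", "true_mean", "ref_deviation", "noise"],
    )
    if config.drop_fraction > 0:
        keep = rng_meas.random(len(records)) >= config.drop_fraction
        records = records[keep].reset_index(drop=True)
    return records


@dataclass
class SimulationResult:
    config: StudyConfig
    layers: dict[str, FeatureLayer]
    raster: Raster
    sites: pd.DataFrame
    reference: pd.DataFrame
    ref_daily: pd.Series
    truth: SyntheticTruth
    measurements: pd.DataFrame


def simulate_study(config: StudyConfig, gap_fill="fit") -> SimulationResult:
    """Run every generator in sequence and bundle the results."""
    layers, raster = generate_layers(config)
    sites = sample_sites(config, layers)
    reference = generate_reference_series(config)
    ref_daily = temporal.reference_daily(reference, config.pollutant, gap_fill=gap_fill)
    truth = make_truth(config, layers, sites, raster)
    measurements = generate_measurements(sites, truth, config, ref_daily)
    return SimulationResult(config, layers, raster, sites, reference, ref_daily, truth, measurements)


# ---------------------------------------------------------------- plain-text IO

def write_sites(sites: pd.DataFrame, path) -> None:
    out = sites.reset_index()[["site_id", "x", "y", "class"]]
    out.to_csv(path, index=False)


def read_sites(path) -> pd.DataFrame:
    return pd.read_csv(path).set_index("site_id")


def write_measurements(records: pd.DataFrame, path) -> None:
    cols = ["site_id", "pollutant", "season", "start_date", "end_date", "value_ugm3"]
    records[cols].to_csv(path, index=False)


def read_measurements(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_reference(reference: pd.DataFrame, path) -> None:
    reference.to_csv(path, index_label="timestamp")


def read_reference(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="timestamp", parse_dates=True)


def write_truth(truth: SyntheticTruth, means_path, model_path) -> None:
    truth.true_site_means.to_csv(means_path, index_label="site_id")
    payload = {
        "intercepts": truth.intercepts,
        "coefficients": truth.true_coefficients,
        "ref_deviations": {f"{s}:{d}": v for (s, d), v in truth.ref_deviations.items()},
    }
    Path(model_path).write_text(json.dumps(payload, indent=1))
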