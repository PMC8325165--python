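"""Synthetic swath/tract scenario generator with planted structure.

Generates a complete, fully known test scenario for the pipeline: a ground
truth NO2 column surface (regional background + Gaussian urban plumes +
exponential near-road enhancements), primary-road polylines radiating from
city centers, a Voronoi tract tessellation that is denser near cities (so a
tunable share of tracts is smaller than one 0.01 degree grid cell), tract
demographics spatially linked to road proximity, and daily satellite swaths
of ~3.5 x 5 km quadrilateral footprints with multiplicative retrieval noise
and a QA flag.

The exposure disparity between the least- and most-White tract deciles is
planted at a configurable ratio by a closed-form calibration of the field
(see :func:`calibrate_excess_scale`), so recovery of that ratio by the full
pipeline is a quantitative end-to-end check.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import Voronoi
from scipy.stats import rankdata
from shapely.geometry import LineString, Polygon, box

from ._geo import explode_polylines, km_factors, min_dist_to_lines_km, point_edge_dist_km
from .disparity import partition_deciles

__all__ = [
    "ScenarioConfig",
    "TrueField",
    "Scenario",
    "generate_roads",
    "generate_true_field",
    "generate_tracts",
    "generate_swath",
    "calibrate_excess_scale",
    "generate_scenario",
    "PERIOD_START",
]

PERIOD_START = {
    "baseline": dt.date(2019, 3, 13),
    "lockdown": dt.date(2020, 3, 13),
}
_PERIOD_CODE = {"baseline": 1, "lockdown": 2}

# rng stream ids, so stages draw independent, reproducible streams
_STREAM_CITIES = 11
_STREAM_ROADS = 12
_STREAM_TRACTS = 13
_STREAM_DEMOG = 14
_STREAM_SWATH = 15


class ConfigError(ValueError):
    """Invalid scenario configuration."""


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one synthetic scenario.

    Column amounts are molecules/cm^2. ``pixel_noise_cv`` is the coefficient
    of variation of multiplicative single-retrieval noise (real single-pixel
    uncertainties run 40-60% of the column; 0.5 is the default).
    ``planted_disparity_ratio`` is the target baseline exposure ratio between
    the least-White and most-White tract deciles; 1.0 plants no
    demographic-exposure association at all.
    """

    domain_bbox: tuple = (-101.0, 39.0, -99.0, 41.0)  # lon_min, lat_min, lon_max, lat_max
    n_tracts: int = 5000
    n_cities: int = 2
    plume_amplitudes: tuple = (3.0e15, 2.0e15)
    plume_sigma_km: float = 14.0
    background_column: float = 1.5e15
    road_enhancement: float = 0.2e15   # at d=0 next to a city center
    road_decay_km: float = 2.5
    road_taper_km: float = 30.0        # traffic falloff with distance from city
    roads_per_city: int = 5
    lockdown_drop_fraction_near_road: float = 0.35
    lockdown_drop_fraction_background: float = 0.15
    pixel_noise_cv: float = 0.5
    qa_good_fraction: float = 0.9
    planted_disparity_ratio: float = 2.6
    demog_noise_sd: float = 0.05
    demog_link_strength: float = 3.0
    cluster_fraction: float = 0.15     # share of tract seeds packed around cities
    cluster_sigma_deg: float = 0.035   # tuned so ~8% of tracts lack a colocated cell
    urban_radius_deg: float = 0.45
    msa_radius_deg: float = 0.75
    pixel_size_km: tuple = (5.0, 3.5)  # (along-lon, along-lat)
    n_days: int = 60
    swath_gap_fraction: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        lon_min, lat_min, lon_max, lat_max = self.domain_bbox
        if not (lon_max > lon_min and lat_max > lat_min):
            raise ConfigError(f"degenerate bbox {self.domain_bbox}")
        for name in (
            "lockdown_drop_fraction_near_road",
            "lockdown_drop_fraction_background",
            "pixel_noise_cv",
            "qa_good_fraction",
            "cluster_fraction",
            "swath_gap_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.background_column < 0 or any(a < 0 for a in self.plume_amplitudes):
            raise ConfigError("column amplitudes must be >= 0")
        if self.planted_disparity_ratio <= 0:
            raise ConfigError("planted_disparity_ratio must be > 0")
        if self.n_cities < 1:
            raise ConfigError("need at least one city")
        if self.n_tracts < 20:
            raise ConfigError("need at least 20 tracts for decile partitions")

    def rng(self, stream: int, *extra: int) -> np.random.Generator:
        return np.random.default_rng([self.rng_seed, stream, *extra])

    @property
    def center(self):
        lon_min, lat_min, lon_max, lat_max = self.domain_bbox
        return (0.5 * (lon_min + lon_max), 0.5 * (lat_min + lat_max))


def _city_centers(config: ScenarioConfig) -> np.ndarray:
    """City centers, drawn in the central 60% of the domain; (n_cities, 2)."""
    lon_min, lat_min, lon_max, lat_max = config.domain_bbox
    rng = config.rng(_STREAM_CITIES)
    u = rng.uniform(0.2, 0.8, size=(config.n_cities, 2))
    return np.column_stack(
        [lon_min + u[:, 0] * (lon_max - lon_min), lat_min + u[:, 1] * (lat_max - lat_min)]
    )


def generate_roads(config: ScenarioConfig) -> pd.DataFrame:
    """Primary-road polylines: radial highways per city plus intercity links.

    Returns a DataFrame (segment_id, geometry) of LineStrings in lon/lat.
    Each radial road starts at its city center and runs to the domain edge
    with mild heading wiggle; consecutive cities are joined by a connector.
    Deterministic given the config seed.
    """
    lon_min, lat_min, lon_max, lat_max = config.domain_bbox
    cities = _city_centers(config)
    rng = config.rng(_STREAM_ROADS)
    half_diag = math.hypot(lon_max - lon_min, lat_max - lat_min)
    dom = box(lon_min, lat_min, lon_max, lat_max)

    seg_ids, geoms = [], []
    for c, (cx, cy) in enumerate(cities):
        base = rng.uniform(0, 2 * math.pi)
        for r in range(config.roads_per_city):
            theta = base + 2 * math.pi * r / config.roads_per_city
            verts = [(cx, cy)]
            x, y = cx, cy
            heading = theta
            step = half_diag / 10
            for _ in range(12):
                heading += rng.normal(0, 0.08)
                x += step * math.cos(heading)
                y += step * math.sin(heading)
                verts.append((x, y))
            line = LineString(verts).intersection(dom)
            if line.is_empty:
                continue
            if line.geom_type == "MultiLineString":
                line = max(line.geoms, key=lambda g: g.length)
            seg_ids.append(f"c{c}_r{r}")
            geoms.append(line)
    for c in range(len(cities) - 1):
        (x0, y0), (x1, y1) = cities[c], cities[c + 1]
        mid = (0.5 * (x0 + x1) + rng.normal(0, 0.05), 0.5 * (y0 + y1) + rng.normal(0, 0.05))
        seg_ids.append(f"link{c}")
        geoms.append(LineString([(x0, y0), mid, (x1, y1)]))
    return pd.DataFrame({"segment_id": seg_ids, "geometry": geoms})


@dataclass
class TrueField:
    """Noise-free NO2 column surface with baseline and lockdown states.

    baseline(x) = B + s * [sum_k A_k exp(-r_k^2 / (2 sigma^2))
                           + E exp(-d_city/taper) exp(-d_road/L)]

    where s is the calibrated excess scale. The lockdown state multiplies
    the road term by (1 - drop_near_road) and everything else by
    (1 - drop_background).
    """

    background: float
    cities: np.ndarray          # (n, 2) lon/lat
    amplitudes: np.ndarray
    sigma_km: float
    road_edges: tuple           # exploded polylines (x1, y1, x2, y2, idx)
    road_enhancement: float
    road_decay_km: float
    road_taper_km: float
    drop_near_road: float
    drop_background: float
    lat_ref: float
    excess_scale: float = 1.0

    def _components(self, lon, lat):
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        kx, ky = km_factors(self.lat_ref)
        dx = (lon[:, None] - self.cities[None, :, 0]) * kx
        dy = (lat[:, None] - self.cities[None, :, 1]) * ky
        r2 = dx * dx + dy * dy
        plume = (self.amplitudes[None, :] * np.exp(-r2 / (2 * self.sigma_km**2))).sum(axis=1)
        d_city = np.sqrt(r2.min(axis=1))
        ex1, ey1, ex2, ey2, _ = self.road_edges
        if ex1.size:
            d_road = np.empty(lon.shape[0])
            for s in range(0, lon.shape[0], 50_000):
                sl = slice(s, s + 50_000)
                d_road[sl] = point_edge_dist_km(
                    lon[sl], lat[sl], ex1, ey1, ex2, ey2, self.lat_ref
                ).min(axis=1)
        else:
            d_road = np.full(lon.shape[0], np.inf)
        road = (
            self.road_enhancement
            * np.exp(-d_city / self.road_taper_km)
            * np.exp(-d_road / self.road_decay_km)
        )
        return plume, road

    def evaluate(self, lon, lat, period: str = "baseline") -> np.ndarray:
        if period not in _PERIOD_CODE:
            raise ValueError(f"unknown period {period!r}")
        plume, road = self._components(lon, lat)
        s = self.excess_scale
        if period == "baseline":
            return self.background + s * (plume + road)
        f_bg = 1.0 - self.drop_background
        f_rd = 1.0 - self.drop_near_road
        return (self.background + s * plume) * f_bg + s * road * f_rd

    def excess(self, lon, lat) -> np.ndarray:
        """Unscaled above-background baseline component (plume + road)."""
        plume, road = self._components(lon, lat)
        return plume + road


def generate_true_field(config: ScenarioConfig, roads: pd.DataFrame) -> TrueField:
    cities = _city_centers(config)
    amps = np.resize(np.asarray(config.plume_amplitudes, dtype=float), config.n_cities)
    return TrueField(
        background=config.background_column,
        cities=cities,
        amplitudes=amps,
        sigma_km=config.plume_sigma_km,
        road_edges=explode_polylines(roads["geometry"].tolist()),
        road_enhancement=config.road_enhancement,
        road_decay_km=config.road_decay_km,
        road_taper_km=config.road_taper_km,
        drop_near_road=config.lockdown_drop_fraction_near_road,
        drop_background=config.lockdown_drop_fraction_background,
        lat_ref=config.center[1],
    )


def _voronoi_tessellation(points: np.ndarray, bbox) -> list[Polygon]:
    """Bounded Voronoi cells of ``points`` clipped to ``bbox``.

    Implemented by mirroring the points across all four box edges so every
    interior region is finite, then clipping for numerical safety.
    """
    lon_min, lat_min, lon_max, lat_max = bbox
    x, y = points[:, 0], points[:, 1]
    mirrored = np.vstack(
        [
            points,
            np.column_stack([2 * lon_min - x, y]),
            np.column_stack([2 * lon_max - x, y]),
            np.column_stack([x, 2 * lat_min - y]),
            np.column_stack([x, 2 * lat_max - y]),
        ]
    )
    vor = Voronoi(mirrored)
    dom = box(lon_min, lat_min, lon_max, lat_max)
    polys = []
    for i in range(len(points)):
        region = vor.regions[vor.point_region[i]]
        poly = Polygon(vor.vertices[region])
        if not poly.is_valid:
            poly = poly.buffer(0)
        polys.append(poly.intersection(dom))
    return polys


def _invlogit(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_tracts(config: ScenarioConfig, roads: pd.DataFrame) -> pd.DataFrame:
    """Voronoi tract tessellation with road-linked demographics.

    Tract seed points mix a uniform component with tight Gaussian clusters
    around each city, so near-city tracts are small (some below one grid
    cell, exercising the centroid-interpolation path). Demographics follow a
    logistic link on the rank of distance-to-nearest-road: White share,
    income, vehicle ownership and college attainment rise with distance,
    Hispanic share falls. With planted_disparity_ratio == 1 the link slope
    is zero and demographics are pure noise. Race shares sum to one exactly.
    """
    lon_min, lat_min, lon_max, lat_max = config.domain_bbox
    cities = _city_centers(config)
    rng = config.rng(_STREAM_TRACTS)

    n_cluster = int(round(config.cluster_fraction * config.n_tracts))
    n_uniform = config.n_tracts - n_cluster
    pts_u = np.column_stack(
        [rng.uniform(lon_min, lon_max, n_uniform), rng.uniform(lat_min, lat_max, n_uniform)]
    )
    city_for = rng.integers(0, config.n_cities, n_cluster)
    pts_c = cities[city_for] + rng.normal(0, config.cluster_sigma_deg, size=(n_cluster, 2))
    pts_c[:, 0] = np.clip(pts_c[:, 0], lon_min + 1e-6, lon_max - 1e-6)
    pts_c[:, 1] = np.clip(pts_c[:, 1], lat_min + 1e-6, lat_max - 1e-6)
    points = np.vstack([pts_u, pts_c])
    # drop (rare) duplicate seeds that would break the tessellation
    points = np.unique(np.round(points, 12), axis=0)

    polys = _voronoi_tessellation(points, config.domain_bbox)
    cent = shapely.centroid(np.asarray(polys, dtype=object))
    clon = shapely.get_x(cent)
    clat = shapely.get_y(cent)

    d_road = min_dist_to_lines_km(clon, clat, roads["geometry"].tolist(), lat0=config.center[1])
    kx, ky = km_factors(config.center[1])
    d_city_deg = np.sqrt(
        ((clon[:, None] - cities[None, :, 0])) ** 2 + ((clat[:, None] - cities[None, :, 1])) ** 2
    ).min(axis=1)
    nearest_city = np.argmin(
        (clon[:, None] - cities[None, :, 0]) ** 2 + (clat[:, None] - cities[None, :, 1]) ** 2,
        axis=1,
    )

    n = len(polys)
    rank = (rankdata(d_road, method="average") - 0.5) / n  # in (0, 1), 0 = nearest road
    slope = 0.0 if config.planted_disparity_ratio == 1.0 else config.demog_link_strength
    drng = config.rng(_STREAM_DEMOG)
    sd = config.demog_noise_sd

    def noisy(x, lo=0.02, hi=0.98):
        return np.clip(x + drng.normal(0, sd, n), lo, hi)

    frac_white = noisy(_invlogit(1.1 + slope * (rank - 0.5)))
    black_share = np.clip(0.5 + drng.normal(0, 0.15, n), 0.05, 0.95)
    frac_black = (1.0 - frac_white) * black_share
    frac_other = 1.0 - frac_white - frac_black
    frac_hispanic = noisy(_invlogit(-1.5 - 0.8 * slope * (rank - 0.5)), lo=0.0)
    median_income = np.clip(
        30_000 + 65_000 * _invlogit(-0.3 + 0.8 * slope * (rank - 0.5))
        + drng.normal(0, 4_000, n),
        12_000,
        None,
    )
    frac_no_vehicle = noisy(_invlogit(-1.8 - 0.9 * slope * (rank - 0.5)), lo=0.0, hi=0.85)
    frac_graduate = noisy(_invlogit(-2.0 + 0.6 * slope * (rank - 0.5)), lo=0.01, hi=0.5)
    frac_college = noisy(_invlogit(-0.8 + 0.5 * slope * (rank - 0.5)), lo=0.02, hi=0.7)
    frac_college = np.minimum(frac_college, 0.98 - frac_graduate)
    frac_highschool = np.clip(
        0.9 - frac_college - frac_graduate + drng.normal(0, 0.02, n), 0.02, None
    )
    frac_highschool = np.minimum(frac_highschool, 1.0 - frac_college - frac_graduate)

    return pd.DataFrame(
        {
            "tract_id": [f"T{i:05d}" for i in range(n)],
            "geometry": polys,
            "centroid_lon": clon,
            "centroid_lat": clat,
            "area_deg2": shapely.area(np.asarray(polys, dtype=object)),
            "dist_road_km": d_road,
            "urban": d_city_deg < config.urban_radius_deg,
            "msa_key": np.where(
                d_city_deg < config.msa_radius_deg,
                np.char.add("city", nearest_city.astype(str)),
                None,
            ),
            "frac_white": frac_white,
            "frac_black": frac_black,
            "frac_other": frac_other,
            "frac_hispanic": frac_hispanic,
            "median_income": median_income,
            "frac_highschool": frac_highschool,
            "frac_college": frac_college,
            "frac_graduate": frac_graduate,
            "frac_no_vehicle": frac_no_vehicle,
        }
    )


def calibrate_excess_scale(
    field: TrueField, tracts: pd.DataFrame, target_ratio: float
) -> TrueField:
    """Scale the above-background field so the planted decile ratio holds.

    With B the background and e the unscaled excess at tract centroids, the
    baseline exposure ratio between the least-White (marginalized, mean
    excess e1) and most-White (mean excess e0) deciles is

        R = (B + s e1) / (B + s e0)   =>   s = B (R - 1) / (e1 - R e0),

    solved exactly on the noise-free surface with the same decile partition
    the estimator uses. Requires e1 > R e0, i.e. the geography must put the
    marginalized decile in the more polluted excess field; raises
    ConfigError otherwise. With target 1.0 the field is returned unchanged
    (demographics then carry no spatial link).
    """
    if target_ratio == 1.0:
        return replace(field, excess_scale=1.0)
    e = field.excess(tracts["centroid_lon"].to_numpy(), tracts["centroid_lat"].to_numpy())
    part = partition_deciles(
        pd.Series(tracts["frac_white"].to_numpy(), index=tracts["tract_id"]),
        variable="frac_white",
    )
    ids = pd.Index(tracts["tract_id"])
    e1 = e[ids.get_indexer(part.marginalized_ids)].mean()
    e0 = e[ids.get_indexer(part.nonmarginalized_ids)].mean()
    denom = e1 - target_ratio * e0
    if denom <= 0:
        raise ConfigError(
            f"cannot plant ratio {target_ratio}: excess contrast e1={e1:.3g}, e0={e0:.3g}"
        )
    s = field.background * (target_ratio - 1.0) / denom
    return replace(field, excess_scale=float(s))


def generate_swath(
    field: TrueField,
    config: ScenarioConfig,
    period: str = "baseline",
    n_days: int | None = None,
) -> pd.DataFrame:
    """Daily swaths of quadrilateral footprints sampling the true field.

    One full tiling of the domain per synthetic day, with the tiling origin
    jittered and the footprint grid slightly rotated from day to day (as
    successive real overpasses are). The retrieved column is the field at
    the footprint center times (1 + eps), eps ~ N(0, pixel_noise_cv). QA
    values are uniform on (0.75, 1] for the good fraction and on [0, 0.75]
    otherwise. Returns the standard pixel table.
    """
    if period not in _PERIOD_CODE:
        raise ValueError(f"unknown period {period!r}")
    if n_days is None:
        n_days = config.n_days
    lon_min, lat_min, lon_max, lat_max = config.domain_bbox
    lat_c = config.center[1]
    kx, ky = km_factors(lat_c)
    wx, wy = config.pixel_size_km
    dlon = wx / kx
    dlat = wy / ky
    rng = config.rng(_STREAM_SWATH, _PERIOD_CODE[period])
    start = PERIOD_START[period]

    frames = []
    for day in range(n_days):
        ox = rng.uniform(0, dlon)
        oy = rng.uniform(0, dlat)
        theta = rng.uniform(-0.06, 0.06)  # swath-axis rotation, radians
        xs = np.arange(lon_min - dlon + ox, lon_max + dlon, dlon)
        ys = np.arange(lat_min - dlat + oy, lat_max + dlat, dlat)
        cx, cy = np.meshgrid(xs, ys)
        cx = cx.ravel()
        cy = cy.ravel()
        # rotated rectangle corners (rotation applied in km space)
        hx = np.array([-0.5, 0.5, 0.5, -0.5]) * wx
        hy = np.array([-0.5, -0.5, 0.5, 0.5]) * wy
        rx = hx * math.cos(theta) - hy * math.sin(theta)
        ry = hx * math.sin(theta) + hy * math.cos(theta)
        corner_lon = cx[:, None] + rx[None, :] / kx
        corner_lat = cy[:, None] + ry[None, :] / ky

        keep = np.ones(cx.size, dtype=bool)
        if config.swath_gap_fraction > 0:
            keep = rng.random(cx.size) >= config.swath_gap_fraction
        truth = field.evaluate(cx[keep], cy[keep], period)
        if config.pixel_noise_cv > 0:
            col = truth * (1.0 + rng.normal(0, config.pixel_noise_cv, truth.size))
        else:
            col = truth
        good = rng.random(truth.size) < config.qa_good_fraction
        u = rng.random(truth.size)
        # good: (0.75, 1] strictly above the cut; bad: [0, 0.75)
        qa = np.where(good, 0.75 + 0.25 * (1.0 - u), 0.75 * u)

        df = pd.DataFrame(
            {f"corner_lon_{i + 1}": corner_lon[keep, i] for i in range(4)}
            | {f"corner_lat_{i + 1}": corner_lat[keep, i] for i in range(4)}
        )
        df["center_lon"] = cx[keep]
        df["center_lat"] = cy[keep]
        df["no2_column"] = col
        df["qa_value"] = qa
        df["day"] = day
        df["date"] = (start + dt.timedelta(days=day)).isoformat()
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


@dataclass
class Scenario:
    """A complete synthetic scenario bundle."""

    config: ScenarioConfig
    roads: pd.DataFrame
    tracts: pd.DataFrame
    field: TrueField
    pixels: dict = dc_field(default_factory=dict)  # period -> pixel table


def generate_scenario(config: ScenarioConfig, periods=("baseline", "lockdown"),
                      with_swaths: bool = True) -> Scenario:
    """Roads -> true field -> tracts -> calibration -> swaths, in one call."""
    roads = generate_roads(config)
    field = generate_true_field(config, roads)
    tracts = generate_tracts(config, roads)
    field = calibrate_excess_scale(field, tracts, config.planted_disparity_ratio)
    pixels = {}
    if with_swaths:
        for period in periods:
            pixels[period] = generate_swath(field, config, period)
    return Scenario(config=config, roads=roads, tracts=tracts, field=field, pixels=pixels)
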