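"""Synthetic study generator: layouts, predictors, responses, level series.

Emulates an informal-settlement measurement campaign end to end with known
ground truth, so every pipeline stage can be tested without the (unreleased)
field data:

* a settlement *layout* — random road segments in four traffic classes,
  households clustered around the sites, a land-use mosaic, community point
  features and a smooth vegetation-index field;
* a *response* — per-site ``L_den`` values generated from a linear model
  on named feature columns with Gaussian noise;
* raw 1-second *level series* with diurnal structure, optional isolated
  spikes (outliers) and contiguous gaps (battery failures), constructed so
  the cleaned period levels hit prescribed targets to within 0.1 dB.

Each component draws from its own child seed stream, so reconfiguring one
never perturbs the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import LineString, box

from .acoustics import (
    AnalysisWindow,
    EVENING,
    DAY,
    NIGHT,
    SoundLevelSeries,
    lden_from_components,
)
from .gis import (
    FeatureMatrix,
    HouseholdLayer,
    LandUseLayer,
    PointFeatureSet,
    RasterGrid,
    RoadNetwork,
    Site,
    StudyLayers,
)
from .variables import LANDUSE_CLASSES, POINT_CATEGORIES

__all__ = [
    "LayoutConfig",
    "TruthModel",
    "SeriesConfig",
    "SimulatedSeries",
    "generate_layout",
    "generate_response",
    "generate_series",
    "series_config_for_lden",
    "DEFAULT_WINDOW_START",
]

#: A Wednesday 06:00 inside the 2015-16 southern-summer campaign season.
DEFAULT_WINDOW_START = "2015-11-11 06:00:00"

LN10_OVER_20 = math.log(10.0) / 20.0


@dataclass(frozen=True)
class LayoutConfig:
    """Parameters of one synthetic settlement layout.

    The 3 km square extent comfortably contains the largest (1000 m) buffer;
    sites are inset from the border so their buffers stay mostly inside the
    mapped layers. Densities are sized to an informal settlement: many short
    neighbourhood roads, few arterials, households strongly clustered around
    the dwellings where loggers hang.
    """

    extent_m: float = 3000.0
    n_sites: int = 134
    site_inset_m: float = 300.0
    roads_per_class: Mapping[str, int] = field(
        default_factory=lambda: {"large": 3, "medium": 8, "small": 18, "very_small": 30}
    )
    road_length_range_m: tuple[float, float] = (600.0, 2500.0)
    n_households: int = 3000
    household_cluster_sd_m: float = 150.0
    household_background_fraction: float = 0.3
    landuse_cell_m: float = 100.0
    landuse_weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "residential": 0.50,
            "commercial": 0.10,
            "industrial": 0.10,
            "buildings": 0.15,
            "nature": 0.15,
        }
    )
    point_counts: Mapping[str, int] = field(
        default_factory=lambda: {
            "airport": 1,
            "railway_active": 2,
            "railway_any": 4,
            "church": 5,
            "police": 3,
            "hospital": 2,
        }
    )
    ndvi_cell_m: float = 30.0
    ndvi_smooth_cells: float = 4.0
    ndvi_mean: float = 0.25
    ndvi_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.extent_m < 2000.0:
            raise ValueError("extent must be at least twice the largest buffer (1000 m)")
        if self.n_sites <= 0 or self.n_households < 0:
            raise ValueError("counts must be non-negative (n_sites positive)")


@dataclass(frozen=True)
class TruthModel:
    """Ground-truth linear model for the synthetic ``L_den`` surface.

    Default coefficients mirror the shape of a traffic-and-density noise
    model — positive effects of household density (50 m), medium-road length
    (25 m), large-road length (200 m), and commercial / industrial land use
    (50 m) — with magnitudes scaled so each predictor moves the response by
    a few dB across its realistic range (weak-noise regime for recovery
    experiments).
    """

    beta0: float = 61.3
    beta: Mapping[str, float] = field(
        default_factory=lambda: {
            "hh_density_50m": 12000.0,  # dB per (households/m^2)
            "road_medium_25m": 0.15,  # dB per m
            "road_large_200m": 0.015,  # dB per m
            "landuse_commercial_50m": 0.0009,  # dB per m^2
            "landuse_industrial_50m": 0.0010,  # dB per m^2
        }
    )
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


@dataclass(frozen=True)
class SeriesConfig:
    """Targets and artefacts for one site's simulated 1-s level series.

    Default period targets follow typical measured settlement levels
    (day 60.0, evening 60.7, night 52.9 dB(A)); the within-period spread is
    a Gaussian on the dB scale whose mean is offset so the *energetic* mean
    hits the target.
    """

    l_day: float = 60.0
    l_evening: float = 60.7
    l_night: float = 52.9
    within_period_sd: float = 3.0
    missing_fraction: float = 0.0
    spikes_per_hour: float = 0.0
    spike_magnitude_db: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must be in [0, 1)")
        if self.spike_magnitude_db <= 0:
            raise ValueError("spike magnitude must be positive")


@dataclass
class SimulatedSeries:
    """A generated series plus the injection bookkeeping tests rely on."""

    series: SoundLevelSeries
    spike_timestamps: pd.DatetimeIndex
    n_missing_seconds: int


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_layout(config: LayoutConfig = LayoutConfig()) -> tuple[list[Site], StudyLayers]:
    """Build sites and all predictor layers, reproducibly from the seed."""
    rng_sites, rng_roads, rng_hh, rng_lu, rng_pts, rng_veg = _child_rngs(config.seed, 6)
    E = config.extent_m
    inset = config.site_inset_m

    xy = rng_sites.uniform(inset, E - inset, size=(config.n_sites, 2))
    half = E / 2.0
    sites = [
        Site(
            site_id=f"site_{i:03d}",
            x=float(x),
            y=float(y),
            area_label=f"area_{1 + (x >= half) + 2 * (y >= half)}",
        )
        for i, (x, y) in enumerate(xy)
    ]

    segments: dict[str, list[LineString]] = {}
    for cls in ("large", "medium", "small", "very_small"):
        n = int(config.roads_per_class.get(cls, 0))
        lines = []
        for _ in range(n):
            mid = rng_roads.uniform(0, E, size=2)
            theta = rng_roads.uniform(0, np.pi)
            length = rng_roads.uniform(*config.road_length_range_m)
            d = np.array([np.cos(theta), np.sin(theta)]) * length / 2.0
            lines.append(LineString([mid - d, mid + d]))
        segments[cls] = lines
    roads = RoadNetwork(segments)

    n_bg = int(round(config.n_households * config.household_background_fraction))
    n_cl = config.n_households - n_bg
    pts = []
    if n_bg:
        pts.append(rng_hh.uniform(0, E, size=(n_bg, 2)))
    if n_cl and len(sites):
        centers = xy[rng_hh.integers(0, len(sites), size=n_cl)]
        pts.append(centers + rng_hh.normal(0, config.household_cluster_sd_m, size=(n_cl, 2)))
    households = HouseholdLayer(np.vstack(pts) if pts else np.empty((0, 2)))

    ncell = int(np.ceil(E / config.landuse_cell_m))
    classes = list(LANDUSE_CLASSES)
    weights = np.array([config.landuse_weights.get(c, 0.0) for c in classes], dtype=float)
    weights = weights / weights.sum()
    polys: dict[str, list] = {c: [] for c in classes}
    for i in range(ncell):
        for j in range(ncell):
            cls = classes[rng_lu.choice(len(classes), p=weights)]
            x0, y0 = i * config.landuse_cell_m, j * config.landuse_cell_m
            polys[cls].append(box(x0, y0, x0 + config.landuse_cell_m, y0 + config.landuse_cell_m))
    landuse = LandUseLayer(polys)

    point_features: dict[str, PointFeatureSet] = {}
    active_pts: np.ndarray | None = None
    for cat in POINT_CATEGORIES:
        n = int(config.point_counts.get(cat, 0))
        coords = rng_pts.uniform(0, E, size=(n, 2))
        if cat == "railway_active":
            active_pts = coords
        if cat == "railway_any" and active_pts is not None:
            # tracks in activity are a subset of all tracks
            coords = np.vstack([active_pts, coords]) if n else active_pts
        point_features[cat] = PointFeatureSet(cat, coords)

    ngrid = int(np.ceil(E / config.ndvi_cell_m))
    fieldvals = ndimage.gaussian_filter(
        rng_veg.standard_normal((ngrid, ngrid)), sigma=config.ndvi_smooth_cells
    )
    sd = fieldvals.std()
    if sd > 0:
        fieldvals = fieldvals / sd
    ndvi_vals = np.clip(config.ndvi_mean + config.ndvi_sd * fieldvals, -1.0, 1.0)
    ndvi = RasterGrid(x0=0.0, y0=0.0, cell_size=config.ndvi_cell_m, values=ndvi_vals)

    layers = StudyLayers(
        roads=roads,
        point_features=point_features,
        households=households,
        landuse=landuse,
        ndvi=ndvi,
    )
    return sites, layers


def generate_response(
    features: FeatureMatrix, truth: TruthModel, seed: int
) -> pd.Series:
    """``L_den = beta0 + X beta + Normal(0, sigma)`` per site, seeded."""
    unknown = set(truth.beta) - set(features.df.columns)
    if unknown:
        raise KeyError(f"truth coefficients reference unknown columns: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    y = np.full(len(features.df), truth.beta0, dtype=float)
    for name, b in truth.beta.items():
        y += b * features.df[name].to_numpy()
    y += rng.normal(0.0, truth.sigma, size=len(y))
    return pd.Series(y, index=features.df.index, name="l_den")


def series_config_for_lden(target_lden: float, base: SeriesConfig = SeriesConfig()) -> SeriesConfig:
    """Shift the base diurnal profile so its ``L_den`` equals the target."""
    current = lden_from_components(base.l_day, base.l_evening, base.l_night)
    delta = target_lden - current
    return SeriesConfig(
        l_day=base.l_day + delta,
        l_evening=base.l_evening + delta,
        l_night=base.l_night + delta,
        within_period_sd=base.within_period_sd,
        missing_fraction=base.missing_fraction,
        spikes_per_hour=base.spikes_per_hour,
        spike_magnitude_db=base.spike_magnitude_db,
        seed=base.seed,
    )


def generate_series(
    config: SeriesConfig,
    window: AnalysisWindow,
    site_id: str = "synthetic",
) -> SimulatedSeries:
    """Simulate one site's 1-s series over the five-day window.

    Within each clock period, levels are i.i.d. Gaussian on the dB scale
    with the configured SD and a mean offset of ``-sd^2 ln10/20`` below the
    target, so the energetic mean equals the target level (lognormal energy
    correction). Spikes are isolated single-second excursions of the given
    magnitude; gaps are contiguous blocks totalling the missing fraction.
    """
    rng = np.random.default_rng(config.seed)
    idx = pd.date_range(window.start, window.end, freq="s", inclusive="left")
    hours = idx.hour.to_numpy()
    sd = config.within_period_sd
    offset = sd * sd * LN10_OVER_20
    mu = np.empty(len(idx))
    mu[DAY.contains_hour(hours)] = config.l_day - offset
    mu[EVENING.contains_hour(hours)] = config.l_evening - offset
    mu[NIGHT.contains_hour(hours)] = config.l_night - offset
    levels = rng.normal(mu, sd)

    n = len(idx)
    n_spikes = int(rng.poisson(config.spikes_per_hour * (n / 3600.0)))
    spike_pos = np.array([], dtype=int)
    if n_spikes > 0:
        # isolated seconds: sample on a coarse lattice so no two are adjacent
        lattice = np.arange(1, n - 1, 3)
        n_spikes = min(n_spikes, len(lattice))
        spike_pos = np.sort(rng.choice(lattice, size=n_spikes, replace=False))
        levels[spike_pos] += config.spike_magnitude_db

    keep = np.ones(n, dtype=bool)
    n_missing = int(round(config.missing_fraction * n))
    if n_missing > 0:
        n_blocks = min(3, n_missing)
        cuts = np.sort(rng.integers(1, n_missing, size=n_blocks - 1)) if n_blocks > 1 else np.array([], dtype=int)
        sizes = np.diff(np.concatenate([[0], cuts, [n_missing]])).astype(int)
        for size in sizes:
            if size <= 0:
                continue
            for _ in range(200):  # find a start not clobbering earlier gaps
                start = int(rng.integers(0, n - size))
                if keep[start : start + size].all():
                    keep[start : start + size] = False
                    break

    levels = np.clip(levels, 0.0, 140.0)
    series = SoundLevelSeries(site_id, pd.Series(levels[keep], index=idx[keep]))
    return SimulatedSeries(
        series=series,
        spike_timestamps=idx[spike_pos[keep[spike_pos]]] if len(spike_pos) else idx[:0],
        n_missing_seconds=int((~keep).sum()),
    )
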