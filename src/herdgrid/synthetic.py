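"""Synthetic-archipelago generator.

Builds a fully self-consistent study area on which every stage of the
disaggregation pipeline can be exercised with known ground truth: a
spatially autocorrelated true cattle-density surface (Gaussian random field
with exponential covariance, simulated by circulant embedding), a
Voronoi municipality tessellation, a 10-class land-cover layer whose
suitable classes co-vary with density, point/line infrastructure features,
and seasonal per-pixel time series with known harmonic structure.

Ground-truth bookkeeping:

* municipal ``true_counts`` equal the rounded integral of the density
  surface over each municipality's suitable pixels;
* urban municipalities are fully unsuitable (their polygons double as
  exclusion zones) and their census count is assembled by taking heads from
  each non-urban neighbour proportionally to shared-border length — the
  exact inverse of the urban-redistribution rule, so redistribution can be
  evaluated against the truth;
* one predictor family (NDVI mean) is a strong monotone transform of the
  density field while others are driven by independent noise fields, so the
  true variable-importance ranking is known by construction.

Default conditions: density rescaled to [0, 0.65] head/ha, autocorrelation
range 6 750 m (30 pixels at 225 m), urban fraction 0.15, urban uptake 0.5,
five years of 46 observations/year per time series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint
from shapely.ops import voronoi_diagram

from .census_prep import adjacency_from_polygons
from .landscape import (
    GridSpec,
    MunicipalCensus,
    RasterLayer,
    ReclassTable,
    build_suitability_mask,
    municipality_raster,
)

__all__ = ["SyntheticScene", "generate_synthetic_scene", "gaussian_random_field"]

#: land-cover classes; the first five are suitable for cattle keeping
LANDCOVER_CLASSES = (
    "breeding_area",
    "grassland",
    "agricultural",
    "fallow",
    "home_garden",
    "forest",
    "dense_forest",
    "wetland",
    "bare_soil",
    "built",
)
SUITABLE_CLASSES = LANDCOVER_CLASSES[:5]

DEFAULT_RECLASS = ReclassTable(
    {c: ("suitable" if c in SUITABLE_CLASSES else "unsuitable") for c in LANDCOVER_CLASSES}
)


@dataclass
class SyntheticScene:
    """A generated study area plus its ground truth."""

    grid: GridSpec
    true_density: RasterLayer
    municipalities: MunicipalCensus
    true_counts: np.ndarray
    suitability: RasterLayer
    dem: RasterLayer
    landcover: list  # (polygon, class_label) pairs
    reclass: ReclassTable
    exclusions: list
    features: dict  # name -> list of geometries (barns, ponds, roads, rivers)
    timeseries: dict  # name -> (times_days, array (T, n_rows, n_cols))
    true_harmonics: dict = field(default_factory=dict)
    rng_seed: int = 0


def gaussian_random_field(
    shape: tuple[int, int], range_pixels: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary zero-mean, unit-variance GRF with exponential covariance
    ``exp(-d / range_pixels)``, simulated by circulant embedding on a torus
    twice the grid size."""
    m, n = shape
    big_m, big_n = 2 * m, 2 * n
    di = np.minimum(np.arange(big_m), big_m - np.arange(big_m))
    dj = np.minimum(np.arange(big_n), big_n - np.arange(big_n))
    dist = np.hypot(di[:, None], dj[None, :])
    cov = np.exp(-dist / range_pixels)
    lam = np.fft.fft2(cov).real
    lam = np.clip(lam, 0, None)  # embedding may be slightly indefinite
    noise = rng.standard_normal((big_m, big_n)) + 1j * rng.standard_normal((big_m, big_n))
    fld = np.fft.fft2(np.sqrt(lam) * noise) / np.sqrt(big_m * big_n)
    return fld.real[:m, :n] / np.sqrt(2)


def _rescale(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    vmin, vmax = values.min(), values.max()
    return lo + (hi - lo) * (values - vmin) / (vmax - vmin)


def _tessellate(
    grid: GridSpec, n_municipalities: int, rng: np.random.Generator
) -> list:
    """Voronoi tessellation of the grid rectangle from well-separated seeds."""
    x0, y0, x1, y1 = grid.bounds()
    domain = shapely.box(x0, y0, x1, y1)
    min_sep = 0.35 * np.sqrt(domain.area / n_municipalities)
    pts: list[tuple[float, float]] = []
    for _ in range(10_000):
        if len(pts) == n_municipalities:
            break
        cand = (rng.uniform(x0, x1), rng.uniform(y0, y1))
        if all(np.hypot(cand[0] - p[0], cand[1] - p[1]) >= min_sep for p in pts):
            pts.append(cand)
    if len(pts) < n_municipalities:
        raise ValueError(
            f"could not place {n_municipalities} municipality seeds in the grid"
        )
    cells = voronoi_diagram(MultiPoint(pts), envelope=domain)
    polys = []
    for pt in pts:
        owner = None
        for cell in cells.geoms:
            if cell.contains(shapely.Point(pt)):
                owner = cell.intersection(domain)
                break
        if owner is None or owner.is_empty:
            raise ValueError("degenerate Voronoi tessellation")
        polys.append(owner)
    return polys


def _pixel_landcover(
    grid: GridSpec, density_rank: np.ndarray, noise_rank: np.ndarray
) -> list:
    """Classify each pixel into one of 10 classes from a blend of the density
    rank and an independent noise rank, then emit one square polygon per
    pixel. High scores map to the suitable classes, so suitability co-varies
    with true density (about half the territory ends up suitable)."""
    score = 0.6 * density_rank + 0.4 * noise_rank
    # deciles -> class index 0..9, class 0 = highest score
    flat = score.ravel()
    order = np.argsort(np.argsort(flat))
    deciles = (order * 10) // len(flat)
    class_idx = 9 - deciles
    boxes = grid.pixel_boxes()
    return [(boxes[k], LANDCOVER_CLASSES[class_idx[k]]) for k in range(len(flat))]


def _random_lines(
    grid: GridSpec, n_lines: int, rng: np.random.Generator
) -> list:
    x0, y0, x1, y1 = grid.bounds()
    lines = []
    for _ in range(n_lines):
        xs = rng.uniform(x0, x1, 3)
        ys = rng.uniform(y0, y1, 3)
        lines.append(shapely.LineString(np.column_stack([xs, ys])))
    return lines


def generate_synthetic_scene(
    seed: int,
    n_municipalities: int = 16,
    grid: GridSpec | None = None,
    autocorr_range: float = 6750.0,
    urban_fraction: float = 0.15,
    density_range: tuple[float, float] = (0.0, 0.65),
    urban_uptake: float = 0.5,
    n_years: int = 5,
    obs_per_year: int = 46,
) -> SyntheticScene:
    """Generate a seeded synthetic study area (see module docstring).

    Parameters
    ----------
    seed
        Seeds every random draw; identical seeds give bit-identical scenes.
    n_municipalities
        Number of Voronoi municipalities (>= 4).
    grid
        Analysis grid; default 100 x 100 pixels of 225 m.
    autocorr_range
        Range (m) of the exponential covariance of the density field.
    urban_fraction
        Fraction of municipalities flagged urban (at least one, at most
        n - 2 so rural neighbours remain).
    density_range
        (lo, hi) head/ha interval the density field is rescaled to.
    urban_uptake
        Intensity of the urban count inflation, in (0, 1).
    """
    if n_municipalities < 4:
        raise ValueError("need at least 4 municipalities")
    if grid is None:
        grid = GridSpec(0.0, 22_500.0, 225.0, 100, 100, crs_id="synthetic")
    rng = np.random.default_rng(seed)

    range_px = autocorr_range / grid.pixel_size
    dens_field = gaussian_random_field(grid.shape, range_px, rng)
    noise_field = gaussian_random_field(grid.shape, range_px, rng)
    dem_noise = gaussian_random_field(grid.shape, range_px, rng)
    lc_field = gaussian_random_field(grid.shape, range_px, rng)
    density = _rescale(dens_field, *density_range)
    true_density = RasterLayer(grid, "true_density", density)

    polys = _tessellate(grid, n_municipalities, rng)
    n_urban = max(1, min(n_municipalities - 2, round(urban_fraction * n_municipalities)))

    # urban municipalities need at least one rural neighbour; choose them
    # greedily among non-adjacent candidates so no rural area is orphaned
    probe = MunicipalCensus(
        pd.DataFrame(
            {
                "id": [f"m{k:02d}" for k in range(n_municipalities)],
                "geometry": polys,
                "count": 0,
                "urban": False,
            }
        )
    )
    adjacency = adjacency_from_polygons(probe)
    ids = probe.ids
    candidates = list(rng.permutation(n_municipalities))
    urban_set: set[int] = set()
    for k in candidates:
        if len(urban_set) == n_urban:
            break
        nbrs = {ids.index(nid) for nid, _ in adjacency.neighbours(ids[k])}
        if nbrs and not (nbrs & urban_set):  # keep urban municipalities apart
            urban_set.add(k)
    urban = np.array([k in urban_set for k in range(n_municipalities)])

    def rank01(a: np.ndarray) -> np.ndarray:
        flat = a.ravel()
        r = np.argsort(np.argsort(flat)) / (len(flat) - 1)
        return r.reshape(a.shape)

    landcover = _pixel_landcover(grid, rank01(density), rank01(lc_field))
    exclusions = [polys[k] for k in sorted(urban_set)]
    suitability = build_suitability_mask(landcover, DEFAULT_RECLASS, exclusions, grid)

    # infrastructure: barns cluster where density is high (informative
    # distance layer); ponds/roads/rivers are uninformative
    xx, yy = grid.centre_coords()
    p = (density.ravel() ** 2) / (density.ravel() ** 2).sum()
    barn_idx = rng.choice(density.size, size=30, replace=False, p=p)
    barns = list(shapely.points(xx.ravel()[barn_idx], yy.ravel()[barn_idx]))
    pond_idx = rng.choice(density.size, size=20, replace=False)
    ponds = list(shapely.points(xx.ravel()[pond_idx], yy.ravel()[pond_idx]))
    features = {
        "barns": barns,
        "ponds": ponds,
        "roads": _random_lines(grid, 6, rng),
        "rivers": _random_lines(grid, 4, rng),
    }

    dem = _rescale(-0.8 * dens_field + 0.6 * dem_noise, 0.0, 900.0)

    # seasonal series: NDVI mean tracks density (strong predictor), the
    # others are driven by independent noise fields or are flat
    times = np.arange(n_years * obs_per_year) * (365.25 / obs_per_year)
    harmonics = {
        "ndvi": {"base": _rescale(0.9 * dens_field + 0.1 * noise_field, 0.15, 0.85),
                 "amp": (0.08, 0.02, 0.0), "pha": (0.5, -1.0, 0.0), "noise_sd": 0.01},
        "evi": {"base": _rescale(noise_field, 0.1, 0.6),
                "amp": (0.05, 0.0, 0.0), "pha": (1.2, 0.0, 0.0), "noise_sd": 0.01},
        "dlst": {"base": _rescale(dem_noise, 22.0, 32.0),
                 "amp": (3.0, 1.0, 0.3), "pha": (-2.0, 0.7, 2.5), "noise_sd": 0.2},
        "nlst": {"base": _rescale(-dem_noise, 15.0, 24.0),
                 "amp": (2.0, 0.5, 0.0), "pha": (-2.3, 1.5, 0.0), "noise_sd": 0.2},
    }
    timeseries = {}
    w = 2 * np.pi * times / 365.25
    for name, harm in harmonics.items():
        cycle = sum(
            a * np.cos(k * w - ph)
            for k, (a, ph) in enumerate(zip(harm["amp"], harm["pha"]), start=1)
        )
        series = (
            harm["base"][None, :, :]
            + cycle[:, None, None]
            + rng.normal(0.0, harm["noise_sd"], (len(times),) + grid.shape)
        )
        timeseries[name] = (times, series)

    # municipal true counts: rounded integral of density over suitable pixels
    census0 = MunicipalCensus(
        pd.DataFrame(
            {
                "id": ids,
                "geometry": polys,
                "count": 0,
                "urban": urban,
            }
        )
    )
    member = municipality_raster(census0, grid)
    suit = suitability.values == 1.0
    true_counts = np.zeros(n_municipalities)
    for k in range(n_municipalities):
        sel = (member == k) & suit
        true_counts[k] = np.round(density[sel].sum() * grid.pixel_area_ha)

    # urban inflation: each urban municipality takes heads from its rural
    # neighbours proportionally to border length (inverse of redistribution)
    census_counts = true_counts.copy()
    for k in sorted(urban_set):
        rural = [
            (ids.index(nid), length)
            for nid, length in adjacency.neighbours(ids[k])
            if ids.index(nid) not in urban_set
        ]
        if not rural:
            raise ValueError("urban municipality lacks a rural neighbour")
        total_l = sum(length for _, length in rural)
        take_total = urban_uptake * sum(census_counts[i] for i, _ in rural)
        for i, length in rural:
            take = min(np.round(take_total * length / total_l), census_counts[i])
            census_counts[i] -= take
            census_counts[k] += take

    table = pd.DataFrame(
        {
            "id": ids,
            "geometry": polys,
            "count": census_counts,
            "urban": urban,
        }
    )
    return SyntheticScene(
        grid=grid,
        true_density=true_density,
        municipalities=MunicipalCensus(table),
        true_counts=true_counts,
        suitability=suitability,
        dem=RasterLayer(grid, "dem", dem),
        landcover=landcover,
        reclass=DEFAULT_RECLASS,
        exclusions=exclusions,
        features=features,
        timeseries=timeseries,
        true_harmonics={
            name: {k: v for k, v in h.items() if k != "base"}
            for name, h in harmonics.items()
        },
        rng_seed=seed,
    )
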