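"""Environmental predictor engineering.

The predictor stack mirrors the covariates conventionally used in livestock
census downscaling: terrain derivatives of a DEM (slope, ruggedness),
Euclidean distance to infrastructure and water features, per-class land-cover
fractions, and temporal-Fourier summaries (mean, annual extremes, SD, and the
amplitude/phase of the annual, biannual and triannual harmonics) of
vegetation-index and land-surface-temperature time series.

The full stack ("model I") holds 57 layers: 3 topographic + 10 land-cover +
4 distance + 4 indices x 10 Fourier metrics. The reduced stack ("model II",
45 layers) drops the layers that require a high-resolution land-cover product
(the 10 class fractions plus barn and pond distances), for territories where
no such product exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import stats
from shapely.geometry.base import BaseGeometry
from shapely.strtree import STRtree

from .landscape import NODATA, GridSpec, MunicipalCensus, RasterLayer, municipality_raster

__all__ = [
    "TFASummary",
    "PredictorStack",
    "slope",
    "tri",
    "distance_raster",
    "tfa_summary",
    "landcover_class_layers",
    "spearman_screen",
    "assemble_stack",
]

TFA_METRICS = (
    "mean",
    "min",
    "max",
    "sd",
    "amp1",
    "amp2",
    "amp3",
    "pha1",
    "pha2",
    "pha3",
)


@dataclass
class PredictorStack:
    """Ordered, named, tagged predictor layers sharing one grid.

    Each entry carries a provenance tag (topographic | landcover | distance |
    tfa) and a flag marking layers derived from the high-resolution land-cover
    product, which the reduced predictor set excludes.
    """

    grid: GridSpec
    layers: list[RasterLayer] = field(default_factory=list)
    tags: list[str] = field(default_factory=list)
    landcover_derived: list[bool] = field(default_factory=list)

    _TAGS = ("topographic", "landcover", "distance", "tfa")

    def add(self, layer: RasterLayer, tag: str, landcover_derived: bool = False) -> None:
        if tag not in self._TAGS:
            raise ValueError(f"unknown provenance tag '{tag}'")
        if layer.grid != self.grid:
            raise ValueError(f"layer '{layer.name}' is not on the stack grid")
        if layer.name in self.names:
            raise ValueError(f"duplicate layer name '{layer.name}'")
        self.layers.append(layer)
        self.tags.append(tag)
        self.landcover_derived.append(bool(landcover_derived))

    @property
    def names(self) -> list[str]:
        return [lyr.name for lyr in self.layers]

    def __len__(self) -> int:
        return len(self.layers)

    def subset(self, predictor_set: str = "model_I") -> "PredictorStack":
        """'model_I' keeps everything; 'model_II' drops land-cover-derived layers."""
        if predictor_set == "model_I":
            keep = [True] * len(self.layers)
        elif predictor_set == "model_II":
            keep = [not lc for lc in self.landcover_derived]
        else:
            raise ValueError(f"unknown predictor set '{predictor_set}'")
        out = PredictorStack(self.grid)
        for k, lyr, tag, lc in zip(keep, self.layers, self.tags, self.landcover_derived):
            if k:
                out.add(lyr, tag, lc)
        return out

    def matrix(self) -> np.ndarray:
        """(n_pixels, n_layers) array, row-major pixels, NaN for missing."""
        return np.column_stack([lyr.masked().ravel() for lyr in self.layers])


def _padded(dem: RasterLayer) -> np.ndarray:
    vals = dem.masked()
    if np.isnan(vals).all():
        raise ValueError("DEM has no valid cells")
    return np.pad(vals, 1, mode="edge")


def slope(dem: RasterLayer) -> RasterLayer:
    """Slope in degrees by Horn's 3x3 method, edge rows/cols replicated."""
    z = _padded(dem)
    cell = dem.grid.pixel_size
    a, b, c = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    d, f = z[1:-1, :-2], z[1:-1, 2:]
    g, h, i = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * cell)
    dzdy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8 * cell)
    out = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    out[np.isnan(out)] = NODATA
    return RasterLayer(dem.grid, "slope", out)


def tri(dem: RasterLayer) -> RasterLayer:
    """Terrain Ruggedness Index: per-pixel root-sum-square of the elevation
    differences to the 8 neighbours (Riley's formulation), edges replicated."""
    z = _padded(dem)
    centre = z[1:-1, 1:-1]
    ssq = np.zeros_like(centre)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            nb = z[1 + dr : z.shape[0] - 1 + dr, 1 + dc : z.shape[1] - 1 + dc]
            ssq += (centre - nb) ** 2
    out = np.sqrt(ssq)
    out[np.isnan(out)] = NODATA
    return RasterLayer(dem.grid, "tri", out)


def distance_raster(
    features: Sequence[BaseGeometry], grid: GridSpec, name: str = "distance"
) -> RasterLayer:
    """Euclidean distance (m) from each pixel centre to the nearest feature."""
    feats = [f for f in features if f is not None and not f.is_empty]
    if not feats:
        raise ValueError("feature layer is empty")
    xx, yy = grid.centre_coords()
    pts = shapely.points(xx.ravel(), yy.ravel())
    union = shapely.union_all(feats)
    dist = shapely.distance(pts, union)
    return RasterLayer(grid, name, dist.reshape(grid.shape))


@dataclass
class TFASummary:
    """Ten harmonic-regression metrics of a seasonal series, per pixel.

    Arrays share the shape of the input's spatial axes. Amplitudes are
    non-negative; phases follow atan2(B, A) in (-pi, pi] for the model
    a0 + sum_k A_k cos(2 pi k t / period) + B_k sin(2 pi k t / period).
    """

    mean: np.ndarray
    annual_min: np.ndarray
    annual_max: np.ndarray
    sd: np.ndarray
    amp: tuple[np.ndarray, np.ndarray, np.ndarray]
    pha: tuple[np.ndarray, np.ndarray, np.ndarray]

    def metric(self, key: str) -> np.ndarray:
        if key in ("mean", "sd"):
            return getattr(self, key)
        if key == "min":
            return self.annual_min
        if key == "max":
            return self.annual_max
        kind, k = key[:3], int(key[3:])
        return {"amp": self.amp, "pha": self.pha}[kind][k - 1]


def tfa_summary(
    series: np.ndarray,
    times_days: np.ndarray,
    period: float = 365.25,
    extrema: str = "reconstructed",
) -> TFASummary:
    """Temporal Fourier Analysis by least-squares harmonic regression.

    Fits ``y(t) = a0 + sum_{k=1..3} A_k cos(2 pi k t/period) + B_k sin(...)``
    to each pixel's series, tolerating irregular timestamps. The annual
    minimum and maximum are the extremes of the reconstructed mean annual
    cycle sampled daily (``extrema='raw'`` switches to the raw series
    extremes); the SD is that of the raw series.

    Parameters
    ----------
    series
        Array of shape (T,) or (T, ...) — time first.
    times_days
        Observation times in days; must span the fitted harmonics, with at
        least 12 observations.
    """
    series = np.asarray(series, dtype=float)
    t = np.asarray(times_days, dtype=float)
    if series.shape[0] != t.shape[0]:
        raise ValueError("series and timestamps must align on the time axis")
    if t.shape[0] < 12:
        raise ValueError("TFA needs at least 12 observations per pixel")
    if extrema not in ("reconstructed", "raw"):
        raise ValueError("extrema must be 'reconstructed' or 'raw'")

    spatial = series.shape[1:]
    y = series.reshape(series.shape[0], -1)

    w = 2 * np.pi * t / period
    design = np.column_stack(
        [np.ones_like(t)]
        + [f(k * w) for k in (1, 2, 3) for f in (np.cos, np.sin)]
    )
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    a0 = coef[0]
    amps, phas = [], []
    for k in (1, 2, 3):
        a_k, b_k = coef[2 * k - 1], coef[2 * k]
        amps.append(np.hypot(a_k, b_k))
        phas.append(np.arctan2(b_k, a_k))

    if extrema == "reconstructed":
        td = np.arange(int(np.ceil(period)))
        wd = 2 * np.pi * td / period
        cycle_design = np.column_stack(
            [np.ones_like(wd)] + [f(k * wd) for k in (1, 2, 3) for f in (np.cos, np.sin)]
        )
        cycle = cycle_design @ coef
        ann_min, ann_max = cycle.min(axis=0), cycle.max(axis=0)
    else:
        ann_min, ann_max = y.min(axis=0), y.max(axis=0)

    rs = lambda a: np.asarray(a).reshape(spatial)
    return TFASummary(
        mean=rs(a0),
        annual_min=rs(ann_min),
        annual_max=rs(ann_max),
        sd=rs(y.std(axis=0)),
        amp=tuple(rs(a) for a in amps),
        pha=tuple(rs(p) for p in phas),
    )


def landcover_class_layers(
    landcover: Sequence[tuple[BaseGeometry, str]],
    classes: Sequence[str],
    grid: GridSpec,
) -> list[RasterLayer]:
    """Per-class fraction of pixel area covered, in [0, 1], one layer per class."""
    known = {label for _, label in landcover}
    for cls in classes:
        if cls not in known:
            raise ValueError(f"class '{cls}' not present in the land-cover layer")
    boxes = grid.pixel_boxes()
    area = grid.pixel_size**2
    out = []
    for cls in classes:
        geoms = [g for g, label in landcover if label == cls]
        frac = np.zeros(boxes.shape[0])
        tree = STRtree(geoms)
        box_idx, geom_idx = tree.query(boxes, predicate="intersects")
        if len(box_idx):
            geom_arr = np.asarray(geoms, dtype=object)
            inter = shapely.area(
                shapely.intersection(boxes[box_idx], geom_arr[geom_idx])
            )
            np.add.at(frac, box_idx, inter / area)
        out.append(RasterLayer(grid, f"lc_{cls}", np.clip(frac, 0, 1).reshape(grid.shape)))
    return out


def spearman_screen(
    stack: PredictorStack, census: MunicipalCensus
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank-correlation screening of the predictor stack.

    Returns ``(pred_vs_pred, pred_vs_density)``: Spearman rho between
    predictor pairs on pixel values, and between municipal predictor means
    and adjusted densities (columns rho, p_value). Constant predictors give
    NaN. Average-rank tie handling throughout (scipy default).
    """
    if len(census) < 5:
        raise ValueError("need at least 5 municipalities for screening")
    mat = stack.matrix()
    names = stack.names
    valid = ~np.isnan(mat).any(axis=1)
    p = mat.shape[1]
    with np.errstate(invalid="ignore"):
        if p == 1:
            rho = np.ones((1, 1))
        elif p == 2:
            r, _ = stats.spearmanr(mat[valid, 0], mat[valid, 1])
            rho = np.array([[1.0, r], [r, 1.0]])
        else:
            rho, _ = stats.spearmanr(mat[valid], axis=0)
    pvp = pd.DataFrame(rho, index=names, columns=names)

    member = municipality_raster(census, stack.grid).ravel()
    dens = census.table["adjusted_density"].to_numpy(dtype=float)
    rows = []
    for j, name in enumerate(names):
        means = np.array(
            [np.nanmean(mat[(member == k) & valid, j]) if ((member == k) & valid).any() else np.nan
             for k in range(len(census))]
        )
        ok = ~np.isnan(means) & ~np.isnan(dens)
        if ok.sum() >= 3 and np.std(means[ok]) > 0 and np.std(dens[ok]) > 0:
            r, p = stats.spearmanr(means[ok], dens[ok])
        else:
            r, p = np.nan, np.nan
        rows.append((name, r, p))
    pvd = pd.DataFrame(rows, columns=["predictor", "rho", "p_value"]).set_index("predictor")
    return pvp, pvd


def assemble_stack(
    dem: RasterLayer,
    landcover: Sequence[tuple[BaseGeometry, str]],
    classes: Sequence[str],
    features: dict,
    timeseries: dict,
    grid: GridSpec,
    period: float = 365.25,
    extrema: str = "reconstructed",
) -> PredictorStack:
    """Build the full predictor stack from raw sources.

    Layer composition (full stack, 57 layers when 10 classes and 4 indices
    are supplied): dem/slope/tri, one fraction layer per land-cover class,
    distance to barns/ponds/roads/rivers, and 10 Fourier metrics per time
    series. Land-cover class layers and barn/pond distances are flagged as
    derived from the high-resolution land-cover product; ``subset("model_II")``
    drops them.

    Parameters
    ----------
    features
        Mapping with keys 'barns', 'ponds', 'roads', 'rivers' to geometry
        sequences (any key may be absent).
    timeseries
        Mapping index name -> (times_days, array of shape (T, n_rows, n_cols)).
    """
    stack = PredictorStack(grid)
    stack.add(dem.copy_with(dem.values, "dem"), "topographic")
    stack.add(slope(dem), "topographic")
    stack.add(tri(dem), "topographic")
    for layer in landcover_class_layers(landcover, classes, grid):
        stack.add(layer, "landcover", landcover_derived=True)
    for name in ("barns", "ponds", "roads", "rivers"):
        if name in features:
            from_lc = name in ("barns", "ponds")
            stack.add(
                distance_raster(features[name], grid, name=f"dist_{name}"),
                "distance",
                landcover_derived=from_lc,
            )
    for idx_name, (times, series) in timeseries.items():
        summ = tfa_summary(series, times, period=period, extrema=extrema)
        for metric in TFA_METRICS:
            stack.add(
                RasterLayer(grid, f"{idx_name}_{metric}", summ.metric(metric)),
                "tfa",
            )
    return stack
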