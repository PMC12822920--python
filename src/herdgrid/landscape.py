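"""Gridded data model and suitability masking.

The analysis grid is a regular raster of square pixels in a projected CRS
(metres). Row 0 is the northernmost row and pixel (0, 0) is anchored at the
upper-left corner ``(origin_x, origin_y)``; pixel extents are half-open so
every point belongs to exactly one pixel. All vector layers (municipality
polygons, land-cover polygons, exclusion zones, linear features) are shapely
geometries in the same CRS — no reprojection is performed.

The suitability mask is the binary raster that restricts both training
responses and prediction extent: a pixel is suitable (1) when it overlaps at
least one land-cover polygon reclassified as suitable and overlaps no
exclusion polygon.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry
from shapely.strtree import STRtree

__all__ = [
    "GridSpec",
    "RasterLayer",
    "MunicipalCensus",
    "ReclassTable",
    "build_suitability_mask",
    "suitable_area_per_municipality",
    "municipality_raster",
]

NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the analysis raster.

    Parameters
    ----------
    origin_x, origin_y
        Projected coordinates (m) of the upper-left corner of pixel (0, 0).
    pixel_size
        Side of a square pixel in metres (default 225).
    n_rows, n_cols
        Raster dimensions.
    crs_id
        Identifier of the projected CRS all layers share (informational;
        no reprojection engine is provided).
    """

    origin_x: float
    origin_y: float
    pixel_size: float = 225.0
    n_rows: int = 1
    n_cols: int = 1
    crs_id: str = "local"

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def pixel_area_ha(self) -> float:
        """Pixel area in hectares (225 m -> 5.0625 ha)."""
        return self.pixel_size**2 / 10_000.0

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def x_centres(self) -> np.ndarray:
        return self.origin_x + (np.arange(self.n_cols) + 0.5) * self.pixel_size

    def y_centres(self) -> np.ndarray:
        return self.origin_y - (np.arange(self.n_rows) + 0.5) * self.pixel_size

    def centre_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) arrays of shape (n_rows, n_cols) of pixel centres."""
        xx, yy = np.meshgrid(self.x_centres(), self.y_centres())
        return xx, yy

    def pixel_box(self, row: int, col: int) -> BaseGeometry:
        x0 = self.origin_x + col * self.pixel_size
        y1 = self.origin_y - row * self.pixel_size
        return shapely.box(x0, y1 - self.pixel_size, x0 + self.pixel_size, y1)

    def pixel_boxes(self) -> np.ndarray:
        """Flat (row-major) array of all pixel squares as shapely geometries."""
        cols, rows = np.meshgrid(np.arange(self.n_cols), np.arange(self.n_rows))
        x0 = self.origin_x + cols.ravel() * self.pixel_size
        y1 = self.origin_y - rows.ravel() * self.pixel_size
        return shapely.box(x0, y1 - self.pixel_size, x0 + self.pixel_size, y1)

    def bounds(self) -> tuple[float, float, float, float]:
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.pixel_size,
            self.origin_x + self.n_cols * self.pixel_size,
            self.origin_y,
        )


@dataclass
class RasterLayer:
    """A single named band on an analysis grid.

    ``values`` is float with :data:`NODATA` as the missing sentinel;
    operations propagate missingness.
    """

    grid: GridSpec
    name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"layer '{self.name}': array shape {self.values.shape} "
                f"does not match grid {self.grid.shape}"
            )

    @property
    def missing(self) -> np.ndarray:
        return self.values == NODATA

    def masked(self) -> np.ndarray:
        """Values with the sentinel replaced by NaN."""
        out = self.values.copy()
        out[self.missing] = np.nan
        return out

    def copy_with(self, values: np.ndarray, name: str | None = None) -> "RasterLayer":
        return RasterLayer(self.grid, name or self.name, values)


class MunicipalCensus:
    """Municipality polygons with counts, urban flags and derived quantities.

    Backed by a DataFrame with columns ``id`` (str), ``geometry`` (shapely
    polygon), ``count`` (head), ``urban`` (bool), and the columns filled by
    downstream steps: ``suitable_area`` (ha), ``adjusted_count`` (head,
    fractional after urban redistribution) and ``adjusted_density`` (head/ha).
    """

    _FILLED = ("suitable_area", "adjusted_count", "adjusted_density")

    def __init__(self, table: pd.DataFrame):
        required = {"id", "geometry", "count", "urban"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"census table missing columns: {sorted(missing)}")
        table = table.reset_index(drop=True).copy()
        table["id"] = table["id"].astype(str)
        table["count"] = table["count"].astype(float)
        table["urban"] = table["urban"].astype(bool)
        if (table["count"] < 0).any():
            raise ValueError("municipal counts must be non-negative")
        if table["id"].duplicated().any():
            raise ValueError("municipality ids must be unique")
        for geom in table["geometry"]:
            if geom is None or geom.is_empty:
                raise ValueError("municipality polygons must be non-empty")
        for col in self._FILLED:
            if col not in table.columns:
                table[col] = np.nan
        self.table = table

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> list[str]:
        return list(self.table["id"])

    @property
    def geometries(self) -> np.ndarray:
        return self.table["geometry"].to_numpy()

    def copy(self) -> "MunicipalCensus":
        return MunicipalCensus(self.table.copy())

    def total_count(self) -> float:
        return float(self.table["count"].sum())


@dataclass(frozen=True)
class ReclassTable:
    """Binary reclassification of land-cover classes into suitable/unsuitable."""

    mapping: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, status in self.mapping.items():
            if status not in ("suitable", "unsuitable"):
                raise ValueError(
                    f"class '{label}': suitability must be 'suitable' or "
                    f"'unsuitable', got '{status}'"
                )

    def is_suitable(self, label: str) -> bool:
        if label not in self.mapping:
            raise KeyError(f"land-cover class '{label}' has no reclassification entry")
        return self.mapping[label] == "suitable"


def _positive_area_pairs(
    boxes: np.ndarray, geoms: Sequence[BaseGeometry]
) -> np.ndarray:
    """Flat pixel indices whose square shares interior area with any geometry."""
    if len(geoms) == 0:
        return np.empty(0, dtype=int)
    tree = STRtree(list(geoms))
    box_idx, geom_idx = tree.query(boxes, predicate="intersects")
    if len(box_idx) == 0:
        return np.empty(0, dtype=int)
    geom_arr = np.asarray(list(geoms), dtype=object)
    inter = shapely.intersection(boxes[box_idx], geom_arr[geom_idx])
    hit = shapely.area(inter) > 0
    return np.unique(box_idx[hit])


def build_suitability_mask(
    landcover: Sequence[tuple[BaseGeometry, str]],
    reclass: ReclassTable,
    exclusions: Sequence[BaseGeometry],
    grid: GridSpec,
) -> RasterLayer:
    """Rasterise land-cover suitability onto the analysis grid.

    A pixel gets value 1 when its square overlaps (positive-area
    intersection) at least one polygon whose class is suitable and overlaps
    no exclusion polygon; exclusion always wins. Boundary-only contact does
    not count as overlap.

    Parameters
    ----------
    landcover
        Iterable of ``(polygon, class_label)`` pairs.
    reclass
        Suitable/unsuitable mapping covering every class present.
    exclusions
        Polygons (e.g., protected areas, urban zones) that veto suitability.
    """
    suitable_geoms = []
    for geom, label in landcover:
        if reclass.is_suitable(label):  # raises on unmapped class
            suitable_geoms.append(geom)

    boxes = grid.pixel_boxes()
    mask = np.zeros(grid.n_rows * grid.n_cols, dtype=float)
    mask[_positive_area_pairs(boxes, suitable_geoms)] = 1.0
    mask[_positive_area_pairs(boxes, list(exclusions))] = 0.0
    return RasterLayer(grid, "suitability", mask.reshape(grid.shape))


def municipality_raster(census: MunicipalCensus, grid: GridSpec) -> np.ndarray:
    """Integer raster of municipality membership by pixel-centre containment.

    Returns an int array of shape ``grid.shape`` holding the row index of the
    containing municipality in ``census.table``, or -1 where the pixel centre
    falls outside every polygon. Each pixel is assigned to at most one
    municipality; if polygons overlap (they should not beyond boundaries) the
    lowest table index wins.
    """
    xx, yy = grid.centre_coords()
    out = np.full(grid.shape, -1, dtype=int)
    # iterate in reverse so the lowest index has priority on (degenerate) overlap
    for idx in range(len(census) - 1, -1, -1):
        geom = census.geometries[idx]
        inside = shapely.contains_xy(geom, xx, yy)
        out[inside] = idx
    return out


def suitable_area_per_municipality(
    mask: RasterLayer, census: MunicipalCensus
) -> MunicipalCensus:
    """Fill ``suitable_area`` (ha) from the suitability mask.

    The area of a municipality is the summed area of suitable pixels whose
    centre falls inside its polygon; pixels outside all municipalities are
    dropped.
    """
    vals = mask.values
    if not np.isin(vals[vals != NODATA], (0.0, 1.0)).all():
        raise ValueError("suitability mask must be binary (0/1/nodata)")
    member = municipality_raster(census, mask.grid)
    out = census.copy()
    area = mask.grid.pixel_area_ha
    suitable = vals == 1.0
    counts = np.bincount(member[suitable & (member >= 0)], minlength=len(census))
    out.table["suitable_area"] = counts * area
    return out
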