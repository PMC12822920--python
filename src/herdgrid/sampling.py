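"""Training-set construction.

Two strategies turn municipal densities plus the predictor stack into
regression samples:

* **average** — one sample per municipality: the mean of every predictor
  over the municipality's pixels, response = adjusted density, located at
  the polygon centroid. Deterministic, so it is run once.
* **random** — points scattered uniformly inside each municipality at a
  fixed density (default 50 points per 10 000 ha, the count rounded per
  municipality so sample size is a deterministic function of geometry).
  Each point reads the predictors of its pixel; its response is the
  municipal adjusted density when the pixel is suitable and 0 otherwise,
  which injects within-municipality heterogeneity into the training data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

from .landscape import GridSpec, MunicipalCensus, RasterLayer, municipality_raster
from .predictors import PredictorStack

__all__ = ["TrainingSet", "average_sample", "random_sample", "replicate_sampling"]

logger = logging.getLogger(__name__)


@dataclass
class TrainingSet:
    """Samples ready for forest fitting.

    ``frame`` columns: x, y, municipality_id, response, then one column per
    predictor in stack order. ``predictor_names`` preserves that order for
    layer-alignment checks at prediction time.
    """

    frame: pd.DataFrame
    predictor_names: list[str]
    strategy: str
    replicate_id: int = 0
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def X(self) -> np.ndarray:
        return self.frame[self.predictor_names].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame["response"].to_numpy(dtype=float)

    @property
    def coords(self) -> np.ndarray:
        return self.frame[["x", "y"]].to_numpy(dtype=float)


def _require_density(census: MunicipalCensus) -> np.ndarray:
    dens = census.table["adjusted_density"].to_numpy(dtype=float)
    if np.isnan(dens).any():
        raise ValueError("census must carry adjusted_density before sampling")
    return dens


def average_sample(stack: PredictorStack, census: MunicipalCensus) -> TrainingSet:
    """One municipal-mean sample per municipality (deterministic)."""
    dens = _require_density(census)
    member = municipality_raster(census, stack.grid).ravel()
    mat = stack.matrix()
    rows = []
    for k, mid in enumerate(census.ids):
        sel = member == k
        if not sel.any():
            raise ValueError(f"municipality '{mid}' contains no pixel centre")
        means = np.nanmean(mat[sel], axis=0)
        centroid = census.geometries[k].centroid
        rows.append([centroid.x, centroid.y, mid, dens[k], *means])
    frame = pd.DataFrame(
        rows, columns=["x", "y", "municipality_id", "response", *stack.names]
    )
    return TrainingSet(frame, stack.names, strategy="average")


def _points_in_polygon(
    geom, n: int, rng: np.random.Generator, max_tries: int = 1000
) -> np.ndarray:
    """Uniform points inside a polygon by seeded rejection sampling."""
    x0, y0, x1, y1 = geom.bounds
    got: list[tuple[float, float]] = []
    for _ in range(max_tries):
        if len(got) >= n:
            break
        m = max(4 * (n - len(got)), 16)
        xs = rng.uniform(x0, x1, m)
        ys = rng.uniform(y0, y1, m)
        inside = shapely.contains_xy(geom, xs, ys)
        got.extend(zip(xs[inside], ys[inside]))
    if len(got) < n:
        raise ValueError("rejection sampling failed; is the polygon degenerate?")
    return np.asarray(got[:n])


def random_sample(
    stack: PredictorStack,
    census: MunicipalCensus,
    mask: RasterLayer,
    density_per_10k_ha: float = 50.0,
    seed: int = 0,
    replicate_id: int = 0,
    suitable_only: bool = False,
) -> TrainingSet:
    """Scatter seeded random points at a fixed areal density.

    Per municipality the point count is ``round(area_ha * density / 10 000)``
    (deterministic given geometry); points landing on unsuitable pixels get
    response 0. With ``suitable_only=True`` points are instead drawn until
    they land on suitable pixels and all carry the municipal density.
    """
    if density_per_10k_ha <= 0:
        raise ValueError("point density must be positive")
    dens = _require_density(census)
    rng = np.random.default_rng(seed)
    grid = stack.grid
    mat = stack.matrix()
    suit = mask.values.ravel()
    rows = []
    for k, mid in enumerate(census.ids):
        geom = census.geometries[k]
        area_ha = geom.area / 10_000.0
        n_pts = int(round(area_ha * density_per_10k_ha / 10_000.0))
        if n_pts == 0:
            logger.info("municipality %s too small for any point", mid)
            continue
        pts = _points_in_polygon(geom, n_pts, rng)
        col = np.floor((pts[:, 0] - grid.origin_x) / grid.pixel_size).astype(int)
        row = np.floor((grid.origin_y - pts[:, 1]) / grid.pixel_size).astype(int)
        col = np.clip(col, 0, grid.n_cols - 1)
        row = np.clip(row, 0, grid.n_rows - 1)
        flat = row * grid.n_cols + col
        if suitable_only:
            keep = suit[flat] == 1.0
            tries = 0
            while not keep.all() and tries < 1000:
                bad = ~keep
                repl = _points_in_polygon(geom, int(bad.sum()), rng)
                pts[bad] = repl
                col = np.floor((pts[:, 0] - grid.origin_x) / grid.pixel_size).astype(int)
                row = np.floor((grid.origin_y - pts[:, 1]) / grid.pixel_size).astype(int)
                col = np.clip(col, 0, grid.n_cols - 1)
                row = np.clip(row, 0, grid.n_rows - 1)
                flat = row * grid.n_cols + col
                keep = suit[flat] == 1.0
                tries += 1
            response = np.full(n_pts, dens[k])
        else:
            response = np.where(suit[flat] == 1.0, dens[k], 0.0)
        for j in range(n_pts):
            rows.append([pts[j, 0], pts[j, 1], mid, response[j], *mat[flat[j]]])
    frame = pd.DataFrame(
        rows, columns=["x", "y", "municipality_id", "response", *stack.names]
    )
    return TrainingSet(
        frame, stack.names, strategy="random", replicate_id=replicate_id, seed=seed
    )


def replicate_sampling(
    stack: PredictorStack,
    census: MunicipalCensus,
    mask: RasterLayer,
    strategy: str = "random",
    n_replicates: int = 30,
    base_seed: int = 0,
    density_per_10k_ha: float = 50.0,
    suitable_only: bool = False,
) -> list[TrainingSet]:
    """Replicated training sets: replicate r uses seed ``base_seed + r``.

    The average strategy is deterministic, so its single set is reused across
    replicates (model seeds still differ downstream); the random strategy
    redraws points every replicate.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    if strategy == "average":
        base = average_sample(stack, census)
        out = []
        for r in range(n_replicates):
            ts = TrainingSet(
                base.frame, base.predictor_names, "average", replicate_id=r,
                seed=base_seed + r,
            )
            out.append(ts)
        return out
    if strategy == "random":
        return [
            random_sample(
                stack, census, mask,
                density_per_10k_ha=density_per_10k_ha,
                seed=base_seed + r, replicate_id=r, suitable_only=suitable_only,
            )
            for r in range(n_replicates)
        ]
    raise ValueError(f"unknown sampling strategy '{strategy}'")
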