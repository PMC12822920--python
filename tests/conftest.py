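import numpy as np
import pandas as pd
import pytest
import shapely

import herdgrid as hg
from herdgrid.synthetic import LANDCOVER_CLASSES


@pytest.fixture(scope="session")
def tiny_scene():
    """9-municipality archipelago on a 40x40 grid of 225 m pixels."""
    grid = hg.GridSpec(0.0, 40 * 225.0, 225.0, 40, 40, "synthetic")
    return hg.generate_synthetic_scene(7, n_municipalities=9, grid=grid)


@pytest.fixture(scope="session")
def tiny_stack(tiny_scene):
    return hg.assemble_stack(
        tiny_scene.dem,
        tiny_scene.landcover,
        list(LANDCOVER_CLASSES),
        tiny_scene.features,
        tiny_scene.timeseries,
        tiny_scene.grid,
    )


@pytest.fixture(scope="session")
def tiny_prepared(tiny_scene):
    """Census of the tiny scene after suitable areas, redistribution, densities."""
    adj = hg.adjacency_from_polygons(tiny_scene.municipalities)
    cen = hg.suitable_area_per_municipality(
        tiny_scene.suitability, tiny_scene.municipalities
    )
    cen = hg.redistribute_urban(cen, adj)
    cen = hg.adjusted_density(cen)
    return cen, adj


@pytest.fixture(scope="session")
def tiny_random_train(tiny_stack, tiny_prepared, tiny_scene):
    cen, _ = tiny_prepared
    return hg.random_sample(tiny_stack, cen, tiny_scene.suitability, seed=3)


@pytest.fixture(scope="session")
def big_scene():
    """Default study conditions: 16 municipalities on a 100x100 grid."""
    return hg.generate_synthetic_scene(3, n_municipalities=16)


@pytest.fixture(scope="session")
def big_stack(big_scene):
    return hg.assemble_stack(
        big_scene.dem,
        big_scene.landcover,
        list(LANDCOVER_CLASSES),
        big_scene.features,
        big_scene.timeseries,
        big_scene.grid,
    )


@pytest.fixture(scope="session")
def big_prepared(big_scene):
    adj = hg.adjacency_from_polygons(big_scene.municipalities)
    cen = hg.suitable_area_per_municipality(
        big_scene.suitability, big_scene.municipalities
    )
    cen = hg.redistribute_urban(cen, adj)
    cen = hg.adjusted_density(cen)
    return cen, adj


def square_grid(n: int, pixel: float = 225.0) -> hg.GridSpec:
    return hg.GridSpec(0.0, n * pixel, pixel, n, n, "test")


def census_from_rects(rects, counts, urban):
    """MunicipalCensus from (x0, y0, x1, y1) rectangles."""
    return hg.MunicipalCensus(
        pd.DataFrame(
            {
                "id": [f"m{k}" for k in range(len(rects))],
                "geometry": [shapely.box(*r) for r in rects],
                "count": counts,
                "urban": urban,
            }
        )
    )
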