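"""Plain-text I/O for rasters, vectors and tables.

Rasters travel as single-band ESRI ASCII grids (``.asc``) with the nodata
tag set; vector layers as GeoJSON (a ``class`` property carries land-cover
labels); the census as CSV with columns ``municipality_id, count, urban``;
the reclassification table as two-column CSV; adjacency as a CSV edge list.
All coordinates are assumed to share one projected CRS.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .census_prep import AdjacencyGraph
from .landscape import NODATA, GridSpec, MunicipalCensus, RasterLayer, ReclassTable

__all__ = [
    "write_ascii_grid",
    "read_ascii_grid",
    "write_geojson",
    "read_geojson",
    "write_census_csv",
    "read_census_csv",
    "read_reclass_csv",
    "write_reclass_csv",
    "write_adjacency_csv",
    "read_adjacency_csv",
]


def write_ascii_grid(layer: RasterLayer, path: str | Path) -> None:
    g = layer.grid
    header = (
        f"ncols {g.n_cols}\n"
        f"nrows {g.n_rows}\n"
        f"xllcorner {g.origin_x!r}\n"
        f"yllcorner {g.origin_y - g.n_rows * g.pixel_size!r}\n"
        f"cellsize {g.pixel_size!r}\n"
        f"NODATA_value {NODATA!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, layer.values, fmt="%.10g")


def read_ascii_grid(
    path: str | Path, name: str | None = None, crs_id: str = "local"
) -> RasterLayer:
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh, ndmin=2)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    cell = header["cellsize"]
    grid = GridSpec(
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + n_rows * cell,
        pixel_size=cell,
        n_rows=n_rows,
        n_cols=n_cols,
        crs_id=crs_id,
    )
    nod = header.get("nodata_value", NODATA)
    values[values == nod] = NODATA
    return RasterLayer(grid, name or path.stem, values)


def write_geojson(
    geoms, path: str | Path, properties: list[dict] | None = None
) -> None:
    feats = []
    for k, geom in enumerate(geoms):
        props = properties[k] if properties else {}
        feats.append(
            {"type": "Feature", "geometry": mapping(geom), "properties": props}
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": feats})
    )


def read_geojson(path: str | Path) -> tuple[list, list[dict]]:
    data = json.loads(Path(path).read_text())
    geoms = [shape(f["geometry"]) for f in data["features"]]
    props = [f.get("properties") or {} for f in data["features"]]
    return geoms, props


def write_census_csv(census: MunicipalCensus, path: str | Path) -> None:
    t = census.table
    out = pd.DataFrame(
        {
            "municipality_id": t["id"],
            "count": t["count"],
            "urban": t["urban"].astype(int),
        }
    )
    for col in ("suitable_area", "adjusted_count", "adjusted_density"):
        if t[col].notna().any():
            out[col] = t[col]
    out.to_csv(path, index=False)


def read_census_csv(path: str | Path, geometries) -> MunicipalCensus:
    """Join the census CSV with polygon geometries (same order)."""
    t = pd.read_csv(path, dtype={"municipality_id": str})
    if len(t) != len(geometries):
        raise ValueError("census rows and geometries do not align")
    frame = pd.DataFrame(
        {
            "id": t["municipality_id"],
            "geometry": list(geometries),
            "count": t["count"],
            "urban": t["urban"].astype(bool),
        }
    )
    census = MunicipalCensus(frame)
    for col in ("suitable_area", "adjusted_count", "adjusted_density"):
        if col in t.columns:
            census.table[col] = t[col].to_numpy()
    return census


def write_reclass_csv(reclass: ReclassTable, path: str | Path) -> None:
    pd.DataFrame(
        sorted(reclass.mapping.items()), columns=["class_label", "suitability"]
    ).to_csv(path, index=False)


def read_reclass_csv(path: str | Path) -> ReclassTable:
    t = pd.read_csv(path)
    return ReclassTable(dict(zip(t["class_label"].astype(str), t["suitability"])))


def write_adjacency_csv(graph: AdjacencyGraph, path: str | Path) -> None:
    rows = [
        (*sorted(pair), length) for pair, length in sorted(
            graph.edges.items(), key=lambda kv: sorted(kv[0])
        )
    ]
    pd.DataFrame(rows, columns=["id_a", "id_b", "border_length_m"]).to_csv(
        path, index=False
    )


def read_adjacency_csv(path: str | Path) -> AdjacencyGraph:
    t = pd.read_csv(path, dtype={"id_a": str, "id_b": str})
    nodes = sorted(set(t["id_a"]) | set(t["id_b"]))
    graph = AdjacencyGraph(nodes=nodes)
    for _, row in t.iterrows():
        graph.add_edge(row["id_a"], row["id_b"], float(row["border_length_m"]))
    return graph
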