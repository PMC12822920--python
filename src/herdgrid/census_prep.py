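"""Response-variable preparation.

Municipal censuses attach animals to the breeder's residence, which inflates
counts in urban municipalities where breeders live but do not keep animals.
Counts of each urban municipality are therefore reallocated to its non-urban
neighbours proportionally to shared-border length, and densities are then
computed over the suitable area only. Global Moran's I quantifies the spatial
autocorrelation of the municipal densities that motivates the geographical
(local) modelling downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .landscape import MunicipalCensus

__all__ = [
    "AdjacencyGraph",
    "MoranResult",
    "adjacency_from_polygons",
    "redistribute_urban",
    "adjusted_density",
    "morans_i",
]


@dataclass
class AdjacencyGraph:
    """Symmetric municipality contiguity with shared-border lengths (m)."""

    nodes: list[str]
    edges: dict[frozenset, float] = field(default_factory=dict)

    def add_edge(self, a: str, b: str, length: float) -> None:
        if a == b:
            raise ValueError("self-loops are not allowed")
        if length <= 0:
            raise ValueError("border length must be positive")
        self.edges[frozenset((a, b))] = float(length)

    def neighbours(self, node: str) -> list[tuple[str, float]]:
        out = []
        for pair, length in self.edges.items():
            if node in pair:
                (other,) = pair - {node}
                out.append((other, length))
        return sorted(out)

    def border_length(self, a: str, b: str) -> float:
        return self.edges.get(frozenset((a, b)), 0.0)


def adjacency_from_polygons(census: MunicipalCensus) -> AdjacencyGraph:
    """Derive contiguity from polygons: edge iff shared boundary length > 0."""
    graph = AdjacencyGraph(nodes=census.ids)
    geoms = census.geometries
    ids = census.ids
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            inter = geoms[i].intersection(geoms[j])
            if not inter.is_empty and inter.length > 0:
                graph.add_edge(ids[i], ids[j], inter.length)
    return graph


def redistribute_urban(
    census: MunicipalCensus, adjacency: AdjacencyGraph
) -> MunicipalCensus:
    """Reallocate urban counts to non-urban neighbours by border length.

    For each urban municipality c with count C_c and non-urban neighbours i
    sharing border length L_ci, the neighbour receives C_c * L_ci / sum_j L_cj.
    Ratios are applied exactly (no intermediate rounding), so the archipelago
    total is conserved to machine precision; urban adjusted counts are 0.
    Fills ``adjusted_count``.
    """
    out = census.copy()
    t = out.table
    adjusted = t["count"].to_numpy(dtype=float).copy()
    pos = {mid: k for k, mid in enumerate(t["id"])}
    urban_ids = list(t.loc[t["urban"], "id"])
    for uid in urban_ids:
        c_c = float(t.loc[t["id"] == uid, "count"].iloc[0])
        rural = [
            (nid, length)
            for nid, length in adjacency.neighbours(uid)
            if nid in pos and not t["urban"].iloc[pos[nid]]
        ]
        if not rural:
            raise ValueError(
                f"urban municipality '{uid}' has no non-urban neighbour to "
                "receive its animals"
            )
        total_border = sum(length for _, length in rural)
        for nid, length in rural:
            adjusted[pos[nid]] += c_c * length / total_border
        adjusted[pos[uid]] -= c_c
    t["adjusted_count"] = adjusted
    return out


def adjusted_density(census: MunicipalCensus) -> MunicipalCensus:
    """Fill ``adjusted_density`` = adjusted_count / suitable_area (head/ha).

    Municipalities with no suitable area and no animals get density 0; a
    positive count with zero suitable area is an error (animals with nowhere
    to live).
    """
    out = census.copy()
    t = out.table
    if t["suitable_area"].isna().any():
        raise ValueError("suitable_area must be filled before computing densities")
    if t["adjusted_count"].isna().any():
        raise ValueError("urban redistribution must be applied before densities")
    area = t["suitable_area"].to_numpy(dtype=float)
    cnt = t["adjusted_count"].to_numpy(dtype=float)
    bad = (area == 0) & (cnt > 0)
    if bad.any():
        ids = ", ".join(t.loc[bad, "id"])
        raise ValueError(f"positive count but zero suitable area in: {ids}")
    with np.errstate(invalid="ignore", divide="ignore"):
        dens = np.where(area > 0, cnt / np.where(area > 0, area, 1.0), 0.0)
    t["adjusted_density"] = dens
    return out


@dataclass
class MoranResult:
    """Global Moran's I with its permutation-test p-value."""

    I: float
    expected_I: float
    p_value: float
    n_permutations: int
    warnings: list[str] = field(default_factory=list)


def morans_i(
    values: np.ndarray,
    adjacency: AdjacencyGraph,
    ids: list[str] | None = None,
    n_permutations: int = 999,
    seed: int = 0,
) -> MoranResult:
    """Global Moran's I under row-standardised binary contiguity weights.

    The permutation p-value is two-sided:
    ``(1 + #{|I_perm| >= |I_obs|}) / (1 + n_permutations)``. Nodes with no
    neighbour carry no weight and are excluded, recorded as a warning in the
    result.
    """
    ids = list(ids) if ids is not None else list(adjacency.nodes)
    values = np.asarray(values, dtype=float)
    if len(values) != len(ids):
        raise ValueError("values and ids must align")
    if len(values) < 3:
        raise ValueError("Moran's I needs at least 3 observations")

    pos = {mid: k for k, mid in enumerate(ids)}
    w = np.zeros((len(ids), len(ids)))
    for pair, _ in adjacency.edges.items():
        a, b = tuple(pair)
        if a in pos and b in pos:
            w[pos[a], pos[b]] = 1.0
            w[pos[b], pos[a]] = 1.0

    warn_list = []
    connected = w.sum(axis=1) > 0
    if not connected.all():
        isolated = [ids[k] for k in np.flatnonzero(~connected)]
        msg = f"excluded municipalities with no neighbours: {', '.join(isolated)}"
        warn_list.append(msg)
        warnings.warn(msg, stacklevel=2)
        w = w[np.ix_(connected, connected)]
        values = values[connected]

    n = len(values)
    if n < 3:
        raise ValueError("fewer than 3 connected observations")
    if np.var(values) == 0:
        raise ValueError("Moran's I is undefined for constant values")

    w = w / w.sum(axis=1, keepdims=True)  # row-standardise
    s0 = w.sum()

    def stat(v: np.ndarray) -> float:
        z = v - v.mean()
        return float(n / s0 * (z @ w @ z) / (z @ z))

    i_obs = stat(values)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        if abs(stat(rng.permutation(values))) >= abs(i_obs):
            hits += 1
    return MoranResult(
        I=i_obs,
        expected_I=-1.0 / (n - 1),
        p_value=(1 + hits) / (1 + n_permutations),
        n_permutations=n_permutations,
        warnings=warn_list,
    )
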