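"""Map products and validation.

Predicted density maps are converted to per-pixel animal counts, aggregated
back to municipalities for goodness-of-fit scoring (RMSE and Pearson
correlation against the redistributed census), ensembled across replicates
(per-pixel mean and SD), and finally rescaled so the map total equals the
census total — the territory-level pycnophylactic constraint.

`run_experiment` drives the full factorial design: {average, random}
sampling x {RF, GRF} x {full, reduced} predictor set, with replicated
sampling/model seeds, and `compare_runs` summarises the per-replicate
goodness-of-fit distributions with a one-way ANOVA and Tukey HSD compact
letter display.
"""

from __future__ import annotations

import itertools
import logging
import string
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .landscape import GridSpec, MunicipalCensus, RasterLayer, municipality_raster
from .models import (
    bandwidth_search,
    fit_grf,
    fit_rf,
    hyperparams,
    predict_grf,
    predict_rf,
)
from .predictors import PredictorStack
from .sampling import replicate_sampling

__all__ = [
    "RunReport",
    "EnsembleProduct",
    "ExperimentConfig",
    "density_to_counts",
    "aggregate_to_municipality",
    "gof",
    "minmax_standardise",
    "ensemble",
    "adjust_counts",
    "compare_runs",
    "run_experiment",
]

logger = logging.getLogger(__name__)


@dataclass
class RunReport:
    """Per-replicate goodness of fit for one method combination."""

    replicate_id: int
    strategy: str
    model_type: str
    predictor_set: str
    rmse: float
    pcc: float

    @property
    def group(self) -> str:
        return f"{self.strategy}-{self.model_type}-{self.predictor_set}"


@dataclass
class EnsembleProduct:
    """Ensemble mean/SD count maps and the census-conserving adjusted map."""

    mean_map: RasterLayer
    sd_map: RasterLayer
    adjusted_map: RasterLayer
    census_total: float


def density_to_counts(density: RasterLayer, grid: GridSpec | None = None) -> RasterLayer:
    """head/ha -> head/pixel (multiply by pixel area in ha)."""
    grid = grid or density.grid
    return RasterLayer(grid, "counts", density.values * grid.pixel_area_ha)


def aggregate_to_municipality(
    counts: RasterLayer, census: MunicipalCensus
) -> np.ndarray:
    """Sum pixel counts into municipalities by pixel-centre containment."""
    member = municipality_raster(census, counts.grid).ravel()
    vals = counts.values.ravel()
    out = np.zeros(len(census))
    inside = member >= 0
    np.add.at(out, member[inside], vals[inside])
    return out


def gof(observed: np.ndarray, predicted: np.ndarray) -> tuple[float, float]:
    """(RMSE, Pearson r) between observed and predicted municipal counts.

    Pearson r is NaN (reported missing) when either side has zero variance.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.ndim != 1:
        raise ValueError("observed and predicted must be 1-D and aligned")
    if len(observed) < 3:
        raise ValueError("goodness of fit needs at least 3 municipalities")
    rmse = float(np.sqrt(np.mean((observed - predicted) ** 2)))
    if np.std(observed) == 0 or np.std(predicted) == 0:
        return rmse, float("nan")
    pcc = float(stats.pearsonr(observed, predicted).statistic)
    return rmse, pcc


def minmax_standardise(values: np.ndarray) -> np.ndarray:
    """Affine rescale to [0, 1]; constant input is an error."""
    values = np.asarray(values, dtype=float)
    vmin, vmax = np.nanmin(values), np.nanmax(values)
    if vmax == vmin:
        raise ValueError("min-max standardisation undefined for constant input")
    return (values - vmin) / (vmax - vmin)


def ensemble(maps: list[RasterLayer]) -> tuple[RasterLayer, RasterLayer]:
    """Per-pixel mean and population SD across replicate count maps."""
    if len(maps) < 2:
        raise ValueError("ensemble needs at least 2 maps")
    grid = maps[0].grid
    for m in maps[1:]:
        if m.grid != grid:
            raise ValueError("ensemble maps must share one grid")
    cube = np.stack([m.values for m in maps])
    return (
        RasterLayer(grid, "ensemble_mean", cube.mean(axis=0)),
        RasterLayer(grid, "ensemble_sd", cube.std(axis=0)),  # population SD
    )


def adjust_counts(mean_map: RasterLayer, census_total: float) -> RasterLayer:
    """Rescale pixel counts so the map total equals the census total.

    X_i = C * x_i / sum(x); zero pixels stay zero; ratio-invariant to any
    positive rescaling of the input.
    """
    if census_total < 0:
        raise ValueError("census total must be non-negative")
    total = float(mean_map.values.sum())
    if total <= 0:
        if census_total == 0:
            return mean_map.copy_with(np.zeros_like(mean_map.values), "adjusted")
        raise ValueError("cannot adjust an all-zero map to a positive total")
    return mean_map.copy_with(
        mean_map.values * (census_total / total), "adjusted"
    )


def _compact_letters(groups: list[str], not_different: set[frozenset]) -> dict[str, str]:
    """Compact letter display: groups share a letter iff not significantly
    different. Letters are the maximal cliques of the 'not different' graph."""
    g = nx.Graph()
    g.add_nodes_from(groups)
    g.add_edges_from(tuple(pair) for pair in not_different)
    cliques = sorted(nx.find_cliques(g), key=lambda c: sorted(groups.index(m) for m in c))
    letters: dict[str, list[str]] = {grp: [] for grp in groups}
    for letter, clique in zip(string.ascii_lowercase, cliques):
        for member in clique:
            letters[member].append(letter)
    return {grp: "".join(sorted(ls)) for grp, ls in letters.items()}


def compare_runs(reports: list[RunReport], alpha: float = 0.05) -> dict:
    """One-way ANOVA + Tukey HSD across method combinations, per metric.

    Returns ``{metric: {"F", "p", "letters", "tukey"}}`` where ``letters`` is
    a compact letter display (groups sharing a letter are not significantly
    different at ``alpha``) and ``tukey`` the pairwise summary frame.
    """
    frame = pd.DataFrame(
        {
            "group": [r.group for r in reports],
            "rmse": [r.rmse for r in reports],
            "pcc": [r.pcc for r in reports],
        }
    )
    groups = list(dict.fromkeys(frame["group"]))
    if len(groups) < 2:
        raise ValueError("need at least two method combinations to compare")
    if (frame.groupby("group").size() < 2).any():
        raise ValueError("need at least two replicates per combination")
    out = {}
    for metric in ("rmse", "pcc"):
        samples = [frame.loc[frame["group"] == g, metric].to_numpy() for g in groups]
        f_stat, p = stats.f_oneway(*samples)
        tukey = pairwise_tukeyhsd(frame[metric], frame["group"], alpha=alpha)
        tuk = pd.DataFrame(
            tukey.summary().data[1:], columns=tukey.summary().data[0]
        )
        nd = {
            frozenset((row["group1"], row["group2"]))
            for _, row in tuk.iterrows()
            if not row["reject"]
        }
        out[metric] = {
            "F": float(f_stat),
            "p": float(p),
            "letters": _compact_letters(groups, nd),
            "tukey": tuk,
        }
    return out


@dataclass
class ExperimentConfig:
    """Factorial design and seeds for a full disaggregation experiment."""

    n_replicates: int = 30
    strategies: tuple[str, ...] = ("average", "random")
    model_types: tuple[str, ...] = ("rf", "grf")
    predictor_sets: tuple[str, ...] = ("model_I", "model_II")
    base_seed: int = 0
    density_per_10k_ha: float = 50.0
    w_global: float = 0.75
    bandwidth: int | None = None  # None -> five-step search per combination
    adjust_per_replicate: bool = False


def run_experiment(
    stack: PredictorStack,
    census: MunicipalCensus,
    mask: RasterLayer,
    config: ExperimentConfig = ExperimentConfig(),
) -> tuple[pd.DataFrame, dict[str, EnsembleProduct], list[RunReport]]:
    """Run the full sampling x model x predictor-set grid.

    ``census`` must carry adjusted counts and densities. Observed municipal
    counts for validation are the redistributed counts. Returns the report
    table, one ensemble product per combination (count maps adjusted to the
    census total), and the raw report list.
    """
    t = census.table
    if t["adjusted_count"].isna().any() or t["adjusted_density"].isna().any():
        raise ValueError("census must be prepared (redistribution + densities)")
    observed = t["adjusted_count"].to_numpy(dtype=float)
    census_total = census.total_count()

    reports: list[RunReport] = []
    ensembles: dict[str, EnsembleProduct] = {}
    for strategy, pset in itertools.product(config.strategies, config.predictor_sets):
        sub = stack.subset(pset)
        trains = replicate_sampling(
            sub,
            census,
            mask,
            strategy=strategy,
            n_replicates=config.n_replicates,
            base_seed=config.base_seed,
            density_per_10k_ha=config.density_per_10k_ha,
        )
        hp = hyperparams(len(trains[0]), len(sub))
        bandwidths: dict[str, int] = {}
        for model_type in config.model_types:
            if model_type == "grf":
                if config.bandwidth is not None:
                    bw = config.bandwidth
                else:
                    search = bandwidth_search(
                        trains[0], hp, seed=config.base_seed, w_global=config.w_global
                    )
                    bw = search.selected
                    logger.info(
                        "%s/%s bandwidth search: %s -> %d",
                        strategy, pset, search.candidates, bw,
                    )
                bandwidths[model_type] = bw
            count_maps = []
            for r, train in enumerate(trains):
                seed = config.base_seed + r
                if model_type == "rf":
                    model = fit_rf(train, hp, seed)
                    dens_map = predict_rf(model, sub, mask)
                else:
                    model = fit_grf(
                        train, hp, bandwidths[model_type],
                        w_global=config.w_global, seed=seed,
                    )
                    dens_map = predict_grf(model, sub, mask)
                counts = density_to_counts(dens_map)
                if config.adjust_per_replicate:
                    counts = adjust_counts(counts, census_total)
                predicted = aggregate_to_municipality(counts, census)
                rmse, pcc = gof(observed, predicted)
                reports.append(
                    RunReport(r, strategy, model_type, pset, rmse, pcc)
                )
                count_maps.append(counts)
            if len(count_maps) >= 2:
                mean_map, sd_map = ensemble(count_maps)
            else:
                mean_map = count_maps[0]
                sd_map = count_maps[0].copy_with(
                    np.zeros_like(count_maps[0].values), "ensemble_sd"
                )
            adjusted = adjust_counts(mean_map, census_total)
            key = f"{strategy}-{model_type}-{pset}"
            ensembles[key] = EnsembleProduct(mean_map, sd_map, adjusted, census_total)
            logger.info("finished combination %s", key)

    table = pd.DataFrame(
        {
            "replicate_id": [r.replicate_id for r in reports],
            "strategy": [r.strategy for r in reports],
            "model_type": [r.model_type for r in reports],
            "predictor_set": [r.predictor_set for r in reports],
            "rmse": [r.rmse for r in reports],
            "pcc": [r.pcc for r in reports],
        }
    )
    return table, ensembles, reports
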