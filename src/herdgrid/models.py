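"""Global and geographical random-forest regression.

The global model is an ordinary regression forest. The geographical variant
(GRF) additionally fits one *local* forest per training location on that
location's K nearest training samples (adaptive kernel, K = "bandwidth"),
and predicts as a fixed-weight blend of the global forest and the local
forest whose centre is nearest the prediction point — 0.75 global / 0.25
local by default. The bandwidth is tuned by a five-step grid search between
n/3 and 2n/3 neighbours, keeping the candidate with the highest r².

Hyperparameters follow simple census-downscaling rules of thumb driven by
the training-set size: ntree = max(100, n/20), node size = max(3, n/1000),
mtry = max(3, p/3) capped at p.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.ensemble import RandomForestRegressor

from .landscape import GridSpec, RasterLayer
from .predictors import PredictorStack
from .sampling import TrainingSet

__all__ = [
    "HyperParams",
    "hyperparams",
    "RFModel",
    "GRFModel",
    "BandwidthSearchResult",
    "fit_rf",
    "bandwidth_candidates",
    "bandwidth_search",
    "fit_grf",
    "predict_rf",
    "predict_grf",
    "permutation_importance",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class HyperParams:
    ntree: int
    node_size: int
    mtry: int

    def __post_init__(self) -> None:
        if self.ntree < 100:
            raise ValueError("ntree must be at least 100")
        if self.node_size < 3:
            raise ValueError("node_size must be at least 3")
        if self.mtry < 1:
            raise ValueError("mtry must be positive")


def hyperparams(n_samples: int, n_predictors: int) -> HyperParams:
    """Size-driven hyperparameter rules (see module docstring)."""
    if n_samples < 3 or n_predictors < 1:
        raise ValueError("need at least 3 samples and 1 predictor")
    return HyperParams(
        ntree=max(100, n_samples // 20),
        node_size=max(3, n_samples // 1000),
        mtry=min(n_predictors, max(3, n_predictors // 3)),
    )


def _make_forest(hp: HyperParams, n_predictors: int, seed: int) -> RandomForestRegressor:
    return RandomForestRegressor(
        n_estimators=hp.ntree,
        min_samples_split=max(2, hp.node_size),
        max_features=min(hp.mtry, n_predictors),
        random_state=seed,
        bootstrap=True,
        n_jobs=1,
    )


def _oob_mask(forest: RandomForestRegressor, n: int) -> np.ndarray:
    """(n_trees, n) boolean matrix marking out-of-bag samples per tree.

    Reconstructs each tree's bootstrap draw from its random_state, matching
    the forest's own index generation (verified against oob_prediction_ in
    the test suite).
    """
    out = np.zeros((len(forest.estimators_), n), dtype=bool)
    for t, est in enumerate(forest.estimators_):
        rs = np.random.RandomState(est.random_state)
        idx = rs.randint(0, n, n)
        oob = np.ones(n, dtype=bool)
        oob[idx] = False
        out[t] = oob
    return out


def _oob_predict(forest: RandomForestRegressor, X: np.ndarray) -> np.ndarray:
    """Out-of-bag predictions; samples never OOB fall back to the full-forest
    prediction (vanishingly rare at >= 100 trees)."""
    n = X.shape[0]
    oob = _oob_mask(forest, n)
    preds = np.array([est.predict(X) for est in forest.estimators_])
    counts = oob.sum(axis=0)
    sums = (preds * oob).sum(axis=0)
    out = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    never = counts == 0
    if never.any():
        out[never] = forest.predict(X[never])
    return out


@dataclass
class RFModel:
    """A fitted global regression forest plus its training context."""

    forest: RandomForestRegressor
    predictor_names: list[str]
    hp: HyperParams
    seed: int
    train_X: np.ndarray = field(repr=False, default=None)
    train_y: np.ndarray = field(repr=False, default=None)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forest.predict(X)

    def oob_predictions(self) -> np.ndarray:
        return _oob_predict(self.forest, self.train_X)


def fit_rf(train: TrainingSet, hp: HyperParams, seed: int) -> RFModel:
    """Fit the global forest; reproducible per seed, rejects missing values."""
    X, y = train.X, train.y
    if np.isnan(X).any():
        raise ValueError("training predictors contain missing values")
    if len(y) < hp.node_size:
        raise ValueError("fewer samples than the node size")
    forest = _make_forest(hp, X.shape[1], seed).fit(X, y)
    return RFModel(forest, list(train.predictor_names), hp, seed, X, y)


@dataclass
class GRFModel:
    """Global forest plus one local forest per training location."""

    global_model: RFModel
    centres: np.ndarray  # (n, 2) training coordinates
    local_forests: list[RandomForestRegressor]
    bandwidth: int
    w_global: float = 0.75
    w_local: float = 0.25
    seed: int = 0

    @property
    def predictor_names(self) -> list[str]:
        return self.global_model.predictor_names

    def __post_init__(self) -> None:
        if abs(self.w_global + self.w_local - 1.0) > 1e-12:
            raise ValueError("global and local weights must sum to 1")
        if len(self.local_forests) != len(self.centres):
            raise ValueError("one local forest per training location required")


def _knn_indices(coords: np.ndarray, centre_idx: int, k: int) -> np.ndarray:
    """Indices of the k nearest samples to a centre (self included); distance
    ties break on the lower sample index via stable sort."""
    d = np.hypot(
        coords[:, 0] - coords[centre_idx, 0], coords[:, 1] - coords[centre_idx, 1]
    )
    order = np.argsort(d, kind="stable")
    return order[:k]


def fit_grf(
    train: TrainingSet,
    hp: HyperParams,
    bandwidth: int,
    w_global: float = 0.75,
    seed: int = 0,
) -> GRFModel:
    """Fit global + per-location local forests with an adaptive KNN kernel."""
    n = len(train)
    if not 1 <= bandwidth <= n:
        raise ValueError("bandwidth must be between 1 and the sample size")
    global_model = fit_rf(train, hp, seed)
    coords = train.coords
    X, y = train.X, train.y
    locals_: list[RandomForestRegressor] = []
    for i in range(n):
        nbr = _knn_indices(coords, i, bandwidth)
        lf = _make_forest(hp, X.shape[1], seed + i + 1)
        lf.fit(X[nbr], y[nbr])
        locals_.append(lf)
    return GRFModel(
        global_model,
        coords.copy(),
        locals_,
        bandwidth,
        w_global=w_global,
        w_local=1.0 - w_global,
        seed=seed,
    )


@dataclass
class BandwidthSearchResult:
    candidates: list[int]
    r2_per_candidate: list[float]
    selected: int


def bandwidth_candidates(n: int) -> list[int]:
    """Five evenly spaced integer bandwidths spanning [ceil(n/3), floor(2n/3)]."""
    if n < 9:
        raise ValueError("bandwidth search needs at least 9 samples")
    lo = int(np.ceil(n / 3))
    hi = int(np.floor(2 * n / 3))
    return [int(np.rint(v)) for v in np.linspace(lo, hi, 5)]


def _r2(obs: np.ndarray, pred: np.ndarray) -> float:
    ss_tot = float(((obs - obs.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("zero-variance responses: r² undefined")
    return 1.0 - float(((obs - pred) ** 2).sum()) / ss_tot


def _grf_training_predictions(model: GRFModel) -> np.ndarray:
    """Blend of global OOB predictions and each point's own local forest."""
    X = model.global_model.train_X
    g = model.global_model.oob_predictions()
    loc = np.array(
        [model.local_forests[i].predict(X[i : i + 1])[0] for i in range(len(X))]
    )
    return model.w_global * g + model.w_local * loc


def bandwidth_search(
    train: TrainingSet, hp: HyperParams, seed: int = 0, w_global: float = 0.75
) -> BandwidthSearchResult:
    """Five-step adaptive-bandwidth grid search between n/3 and 2n/3.

    Candidates are 5 evenly spaced integers spanning [ceil(n/3), floor(2n/3)];
    each candidate GRF is scored by r² between the observed responses and the
    blended training-point predictions (OOB for the global part); ties keep
    the smallest bandwidth.
    """
    candidates = bandwidth_candidates(len(train))
    scores = []
    for k in candidates:
        model = fit_grf(train, hp, k, w_global=w_global, seed=seed)
        scores.append(_r2(train.y, _grf_training_predictions(model)))
    best = int(np.argmax(scores))  # first max -> smallest bandwidth on ties
    return BandwidthSearchResult(candidates, scores, candidates[best])


def _stack_matrix_checked(model_names: list[str], stack: PredictorStack) -> np.ndarray:
    if stack.names != model_names:
        raise ValueError(
            "predictor stack layers do not match the training order: "
            f"{stack.names} vs {model_names}"
        )
    return stack.matrix()


def predict_rf(model: RFModel, stack: PredictorStack, mask: RasterLayer) -> RasterLayer:
    """Density map from the global forest alone; unsuitable pixels are 0."""
    X = _stack_matrix_checked(model.predictor_names, stack)
    grid = stack.grid
    out = np.zeros(grid.n_rows * grid.n_cols)
    suit = mask.values.ravel() == 1.0
    if suit.any():
        Xs = X[suit]
        if np.isnan(Xs).any():
            raise ValueError("missing predictor values on suitable pixels")
        out[suit] = model.predict(Xs)
    return RasterLayer(grid, "density_rf", out.reshape(grid.shape))


def predict_grf(
    model: GRFModel, stack: PredictorStack, mask: RasterLayer
) -> RasterLayer:
    """Blended GRF density map on suitable pixels (0 elsewhere).

    Each suitable pixel is scored by the global forest and by the local
    forest whose centre is nearest the pixel centre (ties on the lower
    sample index), combined with the stored weights.
    """
    X = _stack_matrix_checked(model.predictor_names, stack)
    grid = stack.grid
    out = np.zeros(grid.n_rows * grid.n_cols)
    suit = mask.values.ravel() == 1.0
    if suit.any():
        Xs = X[suit]
        if np.isnan(Xs).any():
            raise ValueError("missing predictor values on suitable pixels")
        g = model.global_model.predict(Xs)
        xx, yy = grid.centre_coords()
        pix = np.column_stack([xx.ravel()[suit], yy.ravel()[suit]])
        nearest = np.argmin(cdist(pix, model.centres), axis=1)
        loc = np.empty(len(Xs))
        for c in np.unique(nearest):
            sel = nearest == c
            loc[sel] = model.local_forests[c].predict(Xs[sel])
        out[suit] = model.w_global * g + model.w_local * loc
    return RasterLayer(grid, "density_grf", out.reshape(grid.shape))


def permutation_importance(
    model: RFModel | GRFModel,
    train: TrainingSet,
    n_repeats: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation variable importance on the global forest's OOB error.

    Importance of a predictor is the mean increase in OOB mean squared error
    after permuting its column, averaged over ``n_repeats`` seeded
    permutations. Returns a DataFrame (importance, se) sorted descending.
    """
    rf = model.global_model if isinstance(model, GRFModel) else model
    X, y = train.X, train.y
    forest = rf.forest
    n = len(y)
    oob = _oob_mask(forest, n)
    counts = np.maximum(oob.sum(axis=0), 1)

    def oob_mse(Xe: np.ndarray) -> float:
        preds = np.array([est.predict(Xe) for est in forest.estimators_])
        pbar = (preds * oob).sum(axis=0) / counts
        return float(np.mean((y - pbar) ** 2))

    base = oob_mse(X)
    rng = np.random.default_rng(seed)
    rows = []
    for j, name in enumerate(rf.predictor_names):
        deltas = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            deltas.append(oob_mse(Xp) - base)
        deltas = np.asarray(deltas)
        rows.append((name, deltas.mean(), deltas.std(ddof=1) / np.sqrt(n_repeats)))
    out = pd.DataFrame(rows, columns=["predictor", "importance", "se"])
    return out.set_index("predictor").sort_values("importance", ascending=False)


def save_model(model: RFModel | GRFModel, directory: str | Path) -> None:
    """Persist a model as a binary artefact directory with a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if isinstance(model, GRFModel):
        manifest = {
            "kind": "grf",
            "predictor_names": model.predictor_names,
            "bandwidth": model.bandwidth,
            "w_global": model.w_global,
            "w_local": model.w_local,
            "seed": model.seed,
            "hyperparams": vars(model.global_model.hp),
        }
    else:
        manifest = {
            "kind": "rf",
            "predictor_names": model.predictor_names,
            "seed": model.seed,
            "hyperparams": vars(model.hp),
        }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    joblib.dump(model, directory / "model.joblib")


def load_model(directory: str | Path) -> RFModel | GRFModel:
    return joblib.load(Path(directory) / "model.joblib")
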