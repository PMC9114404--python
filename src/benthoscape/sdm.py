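"""Per-morphotype presence/absence random forests and spatial prediction.

One classification forest is fitted per morphotype on image-level
environmental predictors and used to predict a probability-of-occurrence
grid: the probability at a cell is the fraction of trees voting
presence.  Settings are pinned to the classic randomForest defaults (500
trees, mtry = floor(sqrt(p)), bootstrap sampling with replacement, no
class weighting) and the out-of-bag error is the internal performance
estimate.  Point-sampled environmental variables (boxcores) are carried
to grids with a random-forest regression on the same covariates.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .grids import Grid, GridStack


class DegenerateResponseError(ValueError):
    """Response contains a single class; no forest can be fitted."""


@dataclass
class RFConfig:
    n_trees: int = 500
    mtry: int | None = None      # None -> floor(sqrt(p))
    seed: int = 0
    balanced: bool = False       # sensitivity analysis only


@dataclass
class MorphotypeModel:
    morphotype_id: str
    forest: RandomForestClassifier
    predictor_names: list
    oob_error: float
    n_presence: int
    seed: int


@dataclass
class ProbabilityStack:
    """Per-morphotype probability grids plus their model registry."""

    grids: GridStack
    models: dict = field(default_factory=dict)  # morphotype_id -> MorphotypeModel

    @property
    def names(self) -> list:
        return self.grids.names

    def __getitem__(self, name: str) -> Grid:
        return self.grids[name]

    def __len__(self) -> int:
        return len(self.grids)

    def registry(self) -> pd.DataFrame:
        rows = [{"morphotype_id": m.morphotype_id, "oob_error": m.oob_error,
                 "n_presence": m.n_presence, "seed": m.seed}
                for m in self.models.values()]
        return pd.DataFrame(rows)


def derive_seed(global_seed: int, key: str) -> int:
    """Deterministic per-item seed below 2^31, order-independent."""
    return (int(global_seed) * 1000003 + zlib.crc32(key.encode())) % (2 ** 31)


def build_predictor_table(images: pd.DataFrame, env: GridStack):
    """Environmental predictors sampled at each image's cell.

    Returns (table, dropped_ids): images landing on nodata cells are
    dropped and reported, not fatal.  Column order follows the stack and
    is the fixed predictor order for fitting and prediction.
    """
    xs = images["x"].to_numpy(float)
    ys = images["y"].to_numpy(float)
    data = {n: env[n].sample(xs, ys) for n in env.names}
    table = pd.DataFrame(data, index=images.index)
    ok = np.isfinite(table.to_numpy()).all(axis=1)
    dropped = images.loc[~ok, "image_id"].tolist()
    return table.loc[ok], dropped


def fit_morphotype_model(presence, predictors: pd.DataFrame,
                         config: RFConfig | None = None,
                         morphotype_id: str = "") -> MorphotypeModel:
    """Fit one presence/absence forest; OOB error is its error estimate."""
    config = config or RFConfig()
    y = np.asarray(presence).astype(int)
    if len(y) != len(predictors):
        raise ValueError("presence vector length must match predictor rows")
    classes = np.unique(y)
    if len(classes) < 2:
        raise DegenerateResponseError(
            f"morphotype {morphotype_id or '?'}: single-class response")
    p = predictors.shape[1]
    mtry = config.mtry if config.mtry is not None else max(1, int(np.sqrt(p)))
    forest = RandomForestClassifier(
        n_estimators=config.n_trees, max_features=mtry, bootstrap=True,
        oob_score=True, random_state=config.seed,
        class_weight="balanced" if config.balanced else None, n_jobs=1)
    forest.fit(predictors.to_numpy(), y)
    return MorphotypeModel(
        morphotype_id=morphotype_id, forest=forest,
        predictor_names=list(predictors.columns),
        oob_error=float(1.0 - forest.oob_score_),
        n_presence=int(y.sum()), seed=config.seed)


def predict_probability(model: MorphotypeModel, env: GridStack) -> Grid:
    """Probability-of-occurrence grid: fraction of trees voting presence."""
    for name in model.predictor_names:
        if name not in env:
            raise KeyError(f"predictor layer {name!r} missing from stack")
    mask = env.subset(model.predictor_names).joint_valid_mask
    rows, cols = np.nonzero(mask)
    X = np.column_stack([env[n].values[rows, cols]
                         for n in model.predictor_names])
    proba = model.forest.predict_proba(X)
    p_present = proba[:, list(model.forest.classes_).index(1)]
    ref = env.reference
    out = np.full(ref.values.shape, np.nan)
    out[rows, cols] = p_present
    return Grid(out, ref.cell_size_m, ref.origin_x, ref.origin_y,
                name=model.morphotype_id, units="probability")


def fit_all(matrix, predictors: pd.DataFrame, env: GridStack,
            config: RFConfig | None = None):
    """Fit and predict every (prevalence-filtered) morphotype.

    Per-morphotype seeds derive deterministically from the global seed and
    the morphotype id, so results do not depend on column order.  Returns
    (ProbabilityStack, failures) where failures maps morphotype id to the
    reason it was skipped.
    """
    config = config or RFConfig()
    stack = GridStack()
    models: dict = {}
    failures: dict = {}
    for mtp in matrix.morphotype_ids:
        y = matrix.values[mtp].to_numpy()
        sub_config = RFConfig(config.n_trees, config.mtry,
                              derive_seed(config.seed, mtp), config.balanced)
        try:
            model = fit_morphotype_model(y, predictors, sub_config, mtp)
        except DegenerateResponseError as exc:
            failures[mtp] = str(exc)
            continue
        stack.add(mtp, predict_probability(model, env))
        models[mtp] = model
    return ProbabilityStack(stack, models), failures


def interpolate_point_samples(points: pd.DataFrame, covariates: GridStack,
                              config: RFConfig | None = None):
    """Predict a point-sampled variable (e.g. boxcore nodule abundance) to a grid.

    ``points`` needs columns x, y, value.  A random-forest regression of
    value on the covariate layers at the point cells is predicted to every
    jointly valid cell.  Returns (grid, oob_r2, excluded_point_indices).
    """
    config = config or RFConfig()
    xs = points["x"].to_numpy(float)
    ys = points["y"].to_numpy(float)
    X = np.column_stack([covariates[n].sample(xs, ys) for n in covariates.names])
    ok = np.isfinite(X).all(axis=1)
    excluded = list(points.index[~ok])
    X, y = X[ok], points["value"].to_numpy(float)[ok]
    if len(y) < 10:
        raise ValueError(f"need >= 10 on-grid points, have {len(y)}")
    forest = RandomForestRegressor(
        n_estimators=config.n_trees,
        max_features=max(1, covariates.names.__len__() // 3),
        oob_score=True, random_state=config.seed, n_jobs=1)
    forest.fit(X, y)
    mask = covariates.joint_valid_mask
    rows, cols = np.nonzero(mask)
    Xg = np.column_stack([covariates[n].values[rows, cols]
                          for n in covariates.names])
    ref = covariates.reference
    out = np.full(ref.values.shape, np.nan)
    out[rows, cols] = forest.predict(Xg)
    grid = Grid(out, ref.cell_size_m, ref.origin_x, ref.origin_y,
                name="interpolated", units="")
    return grid, float(forest.oob_score_), excluded
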