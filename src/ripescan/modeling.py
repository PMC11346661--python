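"""Decision-tree and random-forest regression with leave-one-out validation.

The modeling protocol follows the study design of small-cohort fruit
quality work: every sample is predicted once by a model trained on the
other n-1 samples (LOOCV); hyperparameters are tuned by exhaustive grid
search minimising the validation RMSE; and the feature subset is chosen by
ranking the full-pool impurity importances and evaluating the nested top-k
subsets (k = 1..p), re-tuning on each, again by validation RMSE.

Hyperparameter grids default to the conventional small-data settings:
decision trees over max depth {1,3,5,7,9}, min samples per leaf
{2,4,6,8,10} and max leaf nodes {None,10,20,30,40,50}; random forests over
1..25 trees and 1..p features per split.

Note that tuning and feature selection reuse the same LOOCV that is
reported, so validation metrics carry optimistic selection bias — this
reproduces the historical protocol.  ``nested=True`` adds an outer LOOCV
around the whole selection for an honest error estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "ModelConfig",
    "CVResult",
    "rmse",
    "r2",
    "default_dt_grid",
    "default_rf_grid",
    "make_estimator",
    "loocv_evaluate",
    "tune",
    "select_features",
    "run_study",
]

DT_MD_VALUES = (1, 3, 5, 7, 9)
DT_MS_VALUES = (2, 4, 6, 8, 10)
DT_MLN_VALUES = (None, 10, 20, 30, 40, 50)
RF_NTREE_RANGE = tuple(range(1, 26))


@dataclass(frozen=True)
class ModelConfig:
    """One hyperparameter setting for a DT or RF regressor.

    DT uses (max_depth Md, min_samples_leaf Ms, max_leaf_nodes Mln;
    Mln=None means unlimited leaves).  RF uses (ntree, mtry).
    """

    model: str
    max_depth: int | None = None
    min_samples_leaf: int = 2
    max_leaf_nodes: int | None = None
    ntree: int = 10
    mtry: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("DT", "RF"):
            raise ValueError(f"model must be 'DT' or 'RF', got {self.model!r}")

    def label(self) -> str:
        if self.model == "DT":
            mln = "None" if self.max_leaf_nodes is None else self.max_leaf_nodes
            return f"({self.max_depth}, {self.min_samples_leaf}, {mln})"
        return f"({self.ntree}, {self.mtry})"


@dataclass
class CVResult:
    """Training and leave-one-out validation metrics for one configuration."""

    config: ModelConfig
    features: list[str]
    train_r2: float
    train_rmse: float
    val_r2: float
    val_rmse: float
    predictions: np.ndarray = field(repr=False, default=None)


def rmse(y_act, y_p) -> float:
    """Root mean square error, sqrt(mean((y_act - y_p)^2))."""
    a = np.asarray(y_act, dtype=float)
    p = np.asarray(y_p, dtype=float)
    if a.shape != p.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {p.shape}")
    if a.size == 0:
        raise ValueError("need at least one observation")
    return float(np.sqrt(np.mean((a - p) ** 2)))


def r2(y_act, y_p) -> float:
    """Coefficient of determination, 1 - SSres/SStot.

    Requires a non-constant ``y_act`` (otherwise the total sum of squares
    is zero and the statistic is undefined).
    """
    a = np.asarray(y_act, dtype=float)
    p = np.asarray(y_p, dtype=float)
    if a.shape != p.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {p.shape}")
    sstot = float(np.sum((a - a.mean()) ** 2))
    if sstot == 0:
        raise ValueError("y_act is constant; R2 is undefined")
    ssres = float(np.sum((a - p) ** 2))
    return 1.0 - ssres / sstot


def default_dt_grid(seed: int = 0) -> list[ModelConfig]:
    """DT grid in simplicity order (shallow first, large leaves first)."""
    return [
        ModelConfig("DT", max_depth=md, min_samples_leaf=ms, max_leaf_nodes=mln, seed=seed)
        for md in DT_MD_VALUES
        for ms in sorted(DT_MS_VALUES, reverse=True)
        for mln in sorted((v for v in DT_MLN_VALUES if v is not None)) + [None]
    ]


def default_rf_grid(p: int, seed: int = 0) -> list[ModelConfig]:
    """RF grid over ntree 1..25 and mtry 1..p, simplest first."""
    return [
        ModelConfig("RF", ntree=nt, mtry=mt, seed=seed)
        for nt in RF_NTREE_RANGE
        for mt in range(1, p + 1)
    ]


def make_estimator(config: ModelConfig, seed_offset: int = 0):
    """Instantiate the sklearn regressor for a configuration.

    ``seed_offset`` derives a distinct deterministic random state (used to
    reseed RF fits per LOOCV fold).
    """
    rs = (config.seed * 100_003 + seed_offset) % (2**31 - 1)
    if config.model == "DT":
        return DecisionTreeRegressor(
            criterion="squared_error",
            max_depth=config.max_depth,
            min_samples_leaf=config.min_samples_leaf,
            max_leaf_nodes=config.max_leaf_nodes,
            random_state=rs,
        )
    return RandomForestRegressor(
        n_estimators=config.ntree,
        max_features=config.mtry,
        criterion="squared_error",
        bootstrap=True,
        random_state=rs,
    )


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return np.ascontiguousarray(X.to_numpy(dtype=float)), [str(c) for c in X.columns]
    arr = np.ascontiguousarray(np.asarray(X, dtype=float))
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"x{i}" for i in range(arr.shape[1])]


def loocv_evaluate(config: ModelConfig, X, y, _sse_cap: float | None = None):
    """Leave-one-out evaluation of one configuration.

    For each sample i the model is fit on the other n-1 samples and
    predicts sample i; validation R2/RMSE are computed from the n held-out
    predictions only.  Training metrics come from a final fit on all data.
    RF fits are reseeded deterministically per fold from the config seed.

    ``_sse_cap`` supports exact early abandonment during grid search: once
    the accumulated held-out squared error strictly exceeds the cap the
    configuration cannot be the grid optimum and ``None`` is returned.
    """
    Xm, names = _as_matrix(X)
    ya = np.asarray(y, dtype=float)
    n = Xm.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples for LOOCV")
    if ya.shape[0] != n:
        raise ValueError("X and y length mismatch")
    if not (np.all(np.isfinite(Xm)) and np.all(np.isfinite(ya))):
        raise ValueError("X and y must be finite")

    preds = np.empty(n)
    mask = np.ones(n, dtype=bool)
    is_dt = config.model == "DT"
    # the tree code path with validation disabled requires float32 features
    X32 = np.ascontiguousarray(Xm, dtype=np.float32) if is_dt else Xm
    sse = 0.0
    for i in range(n):
        mask[i] = False
        est = make_estimator(config, seed_offset=i + 1)
        if is_dt:
            est.fit(X32[mask], ya[mask], check_input=False)
            preds[i] = est.tree_.predict(X32[i : i + 1])[0, 0]
        else:
            est.fit(Xm[mask], ya[mask])
            preds[i] = est.predict(Xm[i : i + 1])[0]
        mask[i] = True
        sse += (preds[i] - ya[i]) ** 2
        if _sse_cap is not None and sse > _sse_cap:
            return None

    final = make_estimator(config, seed_offset=0)
    final.fit(Xm, ya)
    train_pred = final.predict(Xm)
    return CVResult(
        config=config,
        features=names,
        train_r2=r2(ya, train_pred),
        train_rmse=rmse(ya, train_pred),
        val_r2=r2(ya, preds),
        val_rmse=rmse(ya, preds),
        predictions=preds,
    )


def tune(model: str, X, y, grid: list[ModelConfig] | None = None, seed: int = 0,
         _initial_cap: float | None = None):
    """Exhaustive grid search minimising validation RMSE.

    Grids are traversed in simplicity order and only a strict improvement
    replaces the incumbent, so ties resolve to the simpler, first-seen
    configuration.

    ``_initial_cap`` (a held-out SSE bound from an outer search) lets every
    configuration be abandoned exactly when it cannot beat the outer
    incumbent; in that case ``None`` is returned instead of raising.
    """
    if grid is None:
        p = X.shape[1] if hasattr(X, "shape") else len(X[0])
        grid = default_dt_grid(seed) if model == "DT" else default_rf_grid(p, seed)
    if not grid:
        raise ValueError("empty hyperparameter grid")
    n = X.shape[0] if hasattr(X, "shape") else len(X)
    best: CVResult | None = None
    errors = []
    for config in grid:
        if config.model != model:
            raise ValueError(f"grid config {config} does not match model {model}")
        # exact early abandonment: a config whose partial held-out SSE
        # already exceeds the incumbent's total cannot become the optimum
        cap = _initial_cap if best is None else best.val_rmse**2 * n
        try:
            res = loocv_evaluate(config, X, y, _sse_cap=cap)
        except ValueError as exc:  # e.g. mtry > p
            errors.append(exc)
            continue
        if res is not None and (best is None or res.val_rmse < best.val_rmse):
            best = res
    if best is None:
        if errors:
            raise ValueError(f"all grid configurations failed; first error: {errors[0]}")
        if _initial_cap is not None:
            return None  # every config provably worse than the outer incumbent
        raise ValueError("empty hyperparameter grid")
    return best


def _importance_order(model: str, pool: pd.DataFrame, y, grid, seed: int) -> list[str]:
    """Rank features by impurity importance of the tuned full-pool model."""
    tuned = tune(model, pool, y, grid=grid, seed=seed)
    est = make_estimator(tuned.config, seed_offset=0)
    Xm, names = _as_matrix(pool)
    est.fit(Xm, np.asarray(y, dtype=float))
    imp = est.feature_importances_
    # stable sort: ties in importance resolve to column order
    order = np.argsort(-imp, kind="stable")
    return [names[i] for i in order]


def select_features(
    model: str,
    pool: pd.DataFrame,
    y,
    grid: list[ModelConfig] | None = None,
    seed: int = 0,
    max_subset: int | None = None,
) -> CVResult:
    """Importance-ranked nested feature-subset selection.

    1. Tune the model on the full pool and rank features by impurity-based
       variable importance (ties break by column order).
    2. For k = 1..p evaluate the top-k subset, re-tuning the
       hyperparameters on each subset.
    3. Return the subset minimising validation RMSE; ties prefer fewer
       features.  The winning subset is reported in importance order.

    ``max_subset`` caps the largest k examined (default: the full pool).
    """
    if not isinstance(pool, pd.DataFrame):
        pool = pd.DataFrame(np.asarray(pool, dtype=float))
        pool.columns = [f"x{i}" for i in range(pool.shape[1])]
    p = pool.shape[1]
    if p == 0:
        raise ValueError("feature pool is empty")
    ranked = _importance_order(model, pool, y, grid, seed)
    kmax = p if max_subset is None else min(max_subset, p)
    n = len(pool)
    best: CVResult | None = None
    for k in range(1, kmax + 1):
        subset = ranked[:k]
        cap = None if best is None else best.val_rmse**2 * n
        res = tune(model, pool[subset], y, grid=grid, seed=seed, _initial_cap=cap)
        if res is None:  # nothing in this subset can beat the incumbent
            continue
        res.features = subset
        if best is None or res.val_rmse < best.val_rmse:
            best = res
    return best


def nested_loocv(
    model: str,
    pool: pd.DataFrame,
    y,
    grid: list[ModelConfig] | None = None,
    seed: int = 0,
    max_subset: int | None = None,
) -> CVResult:
    """Outer LOOCV around the entire selection pipeline (honest error).

    The default protocol tunes hyperparameters and selects features on the
    same LOOCV it reports, which is optimistically biased.  Here, for each
    held-out sample the full ``select_features`` pipeline runs on the
    remaining n-1 samples and then predicts the held-out one, so the
    reported validation error is free of selection bias.  This is
    expensive (the whole grid search runs n times); intended for small
    grids/pools.
    """
    if not isinstance(pool, pd.DataFrame):
        pool = pd.DataFrame(np.asarray(pool, dtype=float))
        pool.columns = [f"x{i}" for i in range(pool.shape[1])]
    ya = np.asarray(y, dtype=float)
    n = len(pool)
    preds = np.empty(n)
    for i in range(n):
        inner_pool = pool.drop(pool.index[i])
        inner = select_features(
            model, inner_pool, np.delete(ya, i), grid=grid, seed=seed, max_subset=max_subset
        )
        est = make_estimator(inner.config, seed_offset=i + 1)
        est.fit(inner_pool[inner.features].to_numpy(float), np.delete(ya, i))
        preds[i] = est.predict(pool.iloc[[i]][inner.features].to_numpy(float))[0]
    inner_full = select_features(model, pool, ya, grid=grid, seed=seed, max_subset=max_subset)
    return CVResult(
        config=inner_full.config,
        features=inner_full.features,
        train_r2=inner_full.train_r2,
        train_rmse=inner_full.train_rmse,
        val_r2=r2(ya, preds),
        val_rmse=rmse(ya, preds),
        predictions=preds,
    )


def run_study(
    traits: pd.DataFrame,
    sri_pool: pd.DataFrame,
    rgbi_pool: pd.DataFrame,
    trait_names: list[str] | None = None,
    models: tuple[str, ...] = ("DT", "RF"),
    pools: tuple[str, ...] = ("SRI", "RGBI", "HV"),
    dt_grid: list[ModelConfig] | None = None,
    rf_grid: list[ModelConfig] | None = None,
    seed: int = 0,
    max_subset: int | None = None,
) -> pd.DataFrame:
    """Full trait x model x feature-pool selection study.

    For every combination of trait, model kind and variable pool (spectral
    indices, RGB indices, or their hybrid union HV) the feature subset and
    hyperparameters are selected by LOOCV and the chosen configuration's
    training/validation metrics are reported — one row per combination,
    shaped like the study summary tables (variable, model, pool, suggested
    features, parameters, train/validation R2 and RMSE).
    """
    if trait_names is None:
        trait_names = [
            c for c in traits.columns
            if c not in ("sample_id", "species", "stage")
        ]
    hv = pd.concat([sri_pool, rgbi_pool.drop(columns=rgbi_pool.columns.intersection(sri_pool.columns))], axis=1)
    pool_map = {"SRI": sri_pool, "RGBI": rgbi_pool, "HV": hv}
    rows = []
    for trait in trait_names:
        y = traits[trait].to_numpy(dtype=float)
        for model in models:
            grid = dt_grid if model == "DT" else rf_grid
            for pool_name in pools:
                pool = pool_map[pool_name]
                res = select_features(
                    model, pool, y, grid=grid, seed=seed, max_subset=max_subset
                )
                rows.append(
                    {
                        "variable": trait,
                        "model": model,
                        "pool": pool_name,
                        "n_features": len(res.features),
                        "suggested_features": ", ".join(res.features),
                        "parameters": res.config.label(),
                        "train_r2": res.train_r2,
                        "train_rmse": res.train_rmse,
                        "val_r2": res.val_r2,
                        "val_rmse": res.val_rmse,
                    }
                )
    return pd.DataFrame(rows)
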