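"""Driver ranking by regression-forest impurity importance.

A random forest regresses per-lake maximum bloom extent on the seven
buffer-zone driver summaries, separately per buffer distance.  The model
exists to rank covariates, not to predict: variable importance is the
residual-sum-of-squares (RSS) metric — for each covariate, the total
decrease in node RSS over every split made on it, summed across all trees
— and is reported as a percentage of the total over covariates.

Hyperparameters follow the common regression-forest defaults the source
analysis fixed: ntree = 200 and mtry = one third of the predictors
(floored, minimum 1); bootstrap resampling of the rows per tree; minimum
leaf size 5; no depth cap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .types import COVARIATE_NAMES
from .zonal import summary_column

__all__ = [
    "ForestConfig",
    "ImportanceResult",
    "fit_importance",
    "relative_importance",
    "sensitivity_rerun",
    "raw_rss_importance",
]

DEFAULT_PREDICTORS = tuple(summary_column(n) for n in COVARIATE_NAMES)
MIN_ROWS = 30


def default_mtry(n_predictors: int) -> int:
    return max(1, math.floor(n_predictors / 3))


@dataclass
class ForestConfig:
    n_trees: int = 200
    mtry: int | None = None          # None -> floor(p/3), min 1
    seed: int = 0
    min_leaf: int = 5
    min_rows: int = MIN_ROWS

    def resolved_mtry(self, n_predictors: int) -> int:
        m = self.mtry if self.mtry is not None else default_mtry(n_predictors)
        if not 1 <= m <= n_predictors:
            raise ValueError(f"mtry must be in [1, {n_predictors}], got {m}")
        return m


@dataclass
class ImportanceResult:
    distance_m: float
    raw_importance: dict[str, float]
    relative_importance: dict[str, float]
    ranking: list[str]
    n_rows: int
    seed: int
    config: dict = field(default_factory=dict)

    def top(self) -> str:
        return self.ranking[0]


def raw_rss_importance(forest: RandomForestRegressor, n_predictors: int) -> np.ndarray:
    """Split-wise RSS decrease per predictor, summed over nodes and trees.

    For a node t with (bootstrap-weighted) sample count N_t and mean
    squared error I_t, the RSS decrease of its split is
    N_t*I_t - N_l*I_l - N_r*I_r, credited to the split variable.
    """
    raw = np.zeros(n_predictors)
    for est in forest.estimators_:
        t = est.tree_
        internal = t.children_left != -1
        for node in np.nonzero(internal)[0]:
            left, right = t.children_left[node], t.children_right[node]
            dec = (
                t.weighted_n_node_samples[node] * t.impurity[node]
                - t.weighted_n_node_samples[left] * t.impurity[left]
                - t.weighted_n_node_samples[right] * t.impurity[right]
            )
            raw[t.feature[node]] += dec
    return raw


def relative_importance(raw: dict[str, float]) -> dict[str, float]:
    """Normalize raw scores to percentages (full precision; round for display)."""
    if any(v < 0 for v in raw.values()):
        raise ValueError("raw importance scores must be nonnegative")
    total = sum(raw.values())
    if total == 0:
        raise ValueError("all-zero importance scores cannot be normalized")
    return {k: 100.0 * v / total for k, v in raw.items()}


def fit_importance(
    rows: pd.DataFrame,
    config: ForestConfig | None = None,
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS,
    response: str = "mbe_km2",
    distance_m: float | None = None,
) -> ImportanceResult:
    """Fit the regression forest and rank predictors by RSS importance.

    ``rows`` is the (lake x buffer distance) covariate table restricted to
    one distance (pass ``distance_m`` to filter, or pre-filter yourself).
    Deterministic given the seed; ties in raw importance break
    alphabetically.
    """
    config = config or ForestConfig()
    df = rows
    if distance_m is not None and "distance_m" in df.columns:
        df = df[df["distance_m"] == distance_m]
    missing = [c for c in (*predictors, response) if c not in df.columns]
    if missing:
        raise KeyError(f"covariate table lacks column(s): {missing}")
    n = len(df)
    if n < config.min_rows:
        raise ValueError(f"need at least {config.min_rows} rows, got {n}")
    y = df[response].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("constant response: no variance to explain")
    X = df[list(predictors)].to_numpy(dtype=float)
    if all(np.ptp(X[:, j]) == 0 for j in range(X.shape[1])):
        raise ValueError("all predictors constant: no valid splits")

    mtry = config.resolved_mtry(len(predictors))
    forest = RandomForestRegressor(
        n_estimators=config.n_trees,
        max_features=mtry,
        min_samples_leaf=config.min_leaf,
        bootstrap=True,
        random_state=config.seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    raw = dict(zip(predictors, raw_rss_importance(forest, len(predictors))))
    if sum(raw.values()) == 0:
        raise ValueError(
            f"forest made no splits ({n} rows with min_leaf={config.min_leaf}); "
            "more rows or a smaller min_leaf are needed"
        )
    rel = relative_importance(raw)
    ranking = sorted(raw, key=lambda k: (-raw[k], k))
    dist = float(distance_m) if distance_m is not None else float("nan")
    return ImportanceResult(
        distance_m=dist,
        raw_importance=raw,
        relative_importance=rel,
        ranking=ranking,
        n_rows=n,
        seed=config.seed,
        config={
            "n_trees": config.n_trees,
            "mtry": mtry,
            "min_leaf": config.min_leaf,
            "response": response,
            "predictors": list(predictors),
        },
    )


def sensitivity_rerun(
    rows: pd.DataFrame,
    config: ForestConfig | None = None,
    drop: set[str] = frozenset(),
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS,
    **kwargs,
) -> ImportanceResult:
    """Refit with covariates removed (e.g. phosphorus, or slope+elevation).

    ``drop`` names covariates (``'phosphorus'``) or summary columns
    (``'phosphorus_mean'``).  mtry is recomputed as floor(p'/3), minimum 1.
    """
    drop_cols = {d if d in predictors else summary_column(d) for d in drop}
    unknown = drop_cols - set(predictors)
    if unknown:
        raise ValueError(f"cannot drop unknown predictor(s): {sorted(unknown)}")
    kept = tuple(p for p in predictors if p not in drop_cols)
    if len(kept) < 2:
        raise ValueError(f"dropping {sorted(drop_cols)} leaves fewer than 2 predictors")
    config = config or ForestConfig()
    if config.mtry is not None:
        config = ForestConfig(
            n_trees=config.n_trees, mtry=None, seed=config.seed,
            min_leaf=config.min_leaf, min_rows=config.min_rows,
        )
    return fit_importance(rows, config, predictors=kept, **kwargs)
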