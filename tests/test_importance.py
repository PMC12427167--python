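"""Regression-forest RSS importance: normalization, determinism, recovery."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from lakebloom import ForestConfig, fit_importance, relative_importance, sensitivity_rerun
from lakebloom.importance import DEFAULT_PREDICTORS, default_mtry


@pytest.mark.parametrize(
    "raw,expected",
    [
        ({"a": 2.0, "b": 1.0, "c": 1.0}, {"a": 50.0, "b": 25.0, "c": 25.0}),
        ({"a": 3.5}, {"a": 100.0}),
        ({k: 1.0 for k in "abcdefg"}, {k: 100.0 / 7 for k in "abcdefg"}),
    ],
)
def test_relative_importance_normalizes_to_percent(raw, expected):
    rel = relative_importance(raw)
    assert rel == pytest.approx(expected)
    assert sum(rel.values()) == pytest.approx(100.0, abs=1e-9)


def test_relative_importance_rejects_all_zero():
    with pytest.raises(ValueError):
        relative_importance({"a": 0.0, "b": 0.0})


def test_default_mtry_is_one_third_floored():
    assert default_mtry(7) == 2
    assert default_mtry(6) == 2
    assert default_mtry(2) == 1


def _table(n, seed=0, response=None):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({c: rng.normal(size=n) for c in DEFAULT_PREDICTORS})
    df["erosion_sum"] = np.abs(df["erosion_sum"]) * 100
    df["mbe_km2"] = response if response is not None else rng.normal(size=n)
    return df


def test_response_equal_to_one_covariate_dominates():
    # with the full candidate set every greedy split lands on the true
    # covariate, so its RSS credit is near-total
    df = _table(200, seed=1)
    df["mbe_km2"] = df["temperature_mean"]
    res = fit_importance(df, ForestConfig(seed=0, mtry=7))
    assert res.top() == "temperature_mean"
    assert res.relative_importance["temperature_mean"] > 90.0


def test_importance_is_seed_deterministic():
    df = _table(120, seed=2)
    a = fit_importance(df, ForestConfig(seed=7))
    b = fit_importance(df, ForestConfig(seed=7))
    assert a.ranking == b.ranking
    assert a.raw_importance == b.raw_importance
    assert a.relative_importance == b.relative_importance


def test_matches_sklearn_normalized_importance_ordering():
    # same forest, independently normalized importances: the dominant
    # covariate must agree between the raw RSS route and sklearn's
    # per-tree-normalized feature_importances_
    from sklearn.ensemble import RandomForestRegressor

    df = _table(200, seed=3)
    df["mbe_km2"] = 2.0 * df["nitrogen_mean"] + 0.1 * np.random.default_rng(3).normal(size=200)
    res = fit_importance(df, ForestConfig(seed=5))
    skl = RandomForestRegressor(n_estimators=200, max_features=2, min_samples_leaf=5,
                                random_state=5, n_jobs=1)
    skl.fit(df[list(DEFAULT_PREDICTORS)].to_numpy(), df["mbe_km2"].to_numpy())
    assert res.top() == DEFAULT_PREDICTORS[int(np.argmax(skl.feature_importances_))]


def test_ranger_cross_implementation_agreement(tmp_path):
    """An independent forest implementation (R ranger, impurity mode) must
    agree on the dominant covariate of a strongly planted dataset."""
    df = _table(200, seed=4)
    rng = np.random.default_rng(4)
    df["mbe_km2"] = (df["erosion_sum"] - df["erosion_sum"].mean()) / df["erosion_sum"].std() \
        + 0.1 * rng.normal(size=200)
    res = fit_importance(df, ForestConfig(seed=0))
    assert res.top() == "erosion_sum"

    csv = tmp_path / "rows.csv"
    df.to_csv(csv, index=False)
    script = textwrap.dedent(f"""
        suppressMessages(library(ranger))
        d <- read.csv("{csv}")
        preds <- setdiff(names(d), "mbe_km2")
        fit <- ranger(mbe_km2 ~ ., data = d[, c(preds, "mbe_km2")],
                      num.trees = 200, mtry = 2, importance = "impurity", seed = 1)
        cat(names(which.max(fit$variable.importance)))
    """)
    out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True, timeout=120)
    assert out.returncode == 0, out.stderr
    assert out.stdout.strip() == "erosion_sum"


def test_errors_on_degenerate_inputs():
    df = _table(100, seed=5)
    with pytest.raises(ValueError, match="constant response"):
        fit_importance(df.assign(mbe_km2=1.0), ForestConfig(seed=0))
    const = df.copy()
    for c in DEFAULT_PREDICTORS:
        const[c] = 3.0
    with pytest.raises(ValueError, match="predictors constant"):
        fit_importance(const, ForestConfig(seed=0))
    with pytest.raises(ValueError, match="at least 30"):
        fit_importance(df.head(10), ForestConfig(seed=0))


def test_sensitivity_rerun_reduces_predictors():
    df = _table(120, seed=6)
    r1 = sensitivity_rerun(df, ForestConfig(seed=0), drop={"phosphorus"})
    assert len(r1.raw_importance) == 6
    assert "phosphorus_mean" not in r1.raw_importance
    assert sum(r1.relative_importance.values()) == pytest.approx(100.0, abs=1e-9)
    assert r1.config["mtry"] == 2  # floor(6/3)

    r2 = sensitivity_rerun(df, ForestConfig(seed=0), drop={"slope", "elevation"})
    assert len(r2.raw_importance) == 5
    assert r2.config["mtry"] == 1  # floor(5/3)

    with pytest.raises(ValueError, match="fewer than 2"):
        sensitivity_rerun(df, ForestConfig(seed=0), drop=set(n.rsplit("_", 1)[0] for n in DEFAULT_PREDICTORS[:6]))
    with pytest.raises(ValueError, match="unknown"):
        sensitivity_rerun(df, ForestConfig(seed=0), drop={"rainfall"})
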