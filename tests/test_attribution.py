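"""Shapley and local-surrogate attributions: exactness and signal recovery."""

import numpy as np
import pandas as pd
import pytest

from edcrowd.attribution import shapley_importance, surrogate_importance
from edcrowd.forecaster import fit_classifier, prepare_features

from oracles import shapley_enumeration

FAST = {"n_estimators": 10, "num_leaves": 4, "min_child_samples": 10}


def planted_frame(n: int, seed: int, n_noise: int = 5) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    f = pd.DataFrame(
        rng.standard_normal((n, n_noise)), columns=[f"noise{i}" for i in range(n_noise)]
    )
    f["signal"] = rng.standard_normal(n)
    f["crowding"] = (f["signal"] > 0).astype(int)
    return f


@pytest.fixture(scope="module")
def planted_model():
    frame = planted_frame(600, seed=0)
    cols = [c for c in frame.columns if c != "crowding"]
    return fit_classifier(frame, cols, hyperparameters=FAST, seed=0), frame, cols


def test_unused_features_have_zero_attribution(planted_model):
    model, frame, cols = planted_model
    booster = model.booster
    unused = [c for c, imp in zip(cols, booster.feature_importance()) if imp == 0]
    assert unused  # perfectly separable target leaves the noise unsplit
    res = shapley_importance(model, frame.head(50))
    for c in unused:
        assert (res.per_row[c] == 0).all()


def test_local_accuracy_on_every_row(planted_model):
    model, frame, cols = planted_model
    sub = frame.head(100)
    res = shapley_importance(model, sub)
    X = prepare_features(sub, model.feature_columns, model.categorical_columns)
    raw = model.model.predict_proba(X, raw_score=True)
    total = res.per_row.sum(axis=1).to_numpy() + res.base_values
    assert np.allclose(total, raw, atol=1e-9)


def test_ranking_is_permutation_sorted_desc(planted_model):
    model, frame, cols = planted_model
    res = shapley_importance(model, frame.head(50))
    assert sorted(res.ranking) == sorted(cols)
    imp = res.global_importance.to_numpy()
    assert (np.diff(imp) <= 1e-15).all()


@pytest.mark.parametrize("seed", range(3))
def test_tree_exact_shapley_matches_subset_enumeration(seed):
    # |N| <= 8 so the 2^|N| enumeration of the weighted-marginal formula
    # is feasible; tree-exact values must agree to numerical precision
    rng = np.random.default_rng(seed)
    n, nf = 300, 4
    frame = pd.DataFrame(
        rng.standard_normal((n, nf)), columns=[f"x{i}" for i in range(nf)]
    )
    frame["crowding"] = (
        (frame["x0"] + 0.6 * frame["x1"] + 0.3 * rng.standard_normal(n)) > 0
    ).astype(int)
    cols = [f"x{i}" for i in range(nf)]
    model = fit_classifier(frame, cols, hyperparameters=FAST, seed=seed)
    res = shapley_importance(model, frame.head(5))
    for i in range(5):
        phi, base = shapley_enumeration(model.booster, frame[cols].iloc[i].to_numpy())
        assert np.allclose(res.per_row.iloc[i].to_numpy(), phi, atol=1e-9)
        assert res.base_values[i] == pytest.approx(base, abs=1e-9)


def test_schema_mismatch_is_error(planted_model):
    model, frame, _ = planted_model
    with pytest.raises(ValueError, match="lack model features"):
        shapley_importance(model, frame[["noise0", "crowding"]])


def test_planted_signal_recovered_by_both_methods(planted_model):
    model, frame, cols = planted_model
    shap_res = shapley_importance(model, frame.head(100))
    assert shap_res.ranking[0] == "signal"
    lime_res = surrogate_importance(model, frame.head(20), n_samples=300, seed=0)
    assert lime_res.ranking[0] == "signal"
    # per-row: the planted feature dominates nearly everywhere
    top_per_row = lime_res.per_row.idxmax(axis=1)
    assert (top_per_row == "signal").mean() >= 0.95


def test_subgroup_and_weekday_signal_recovered():
    # label driven by subgroup and weekday categoricals -> both in top 5
    rng = np.random.default_rng(1)
    n = 800
    frame = pd.DataFrame(
        {
            "subgroup": rng.integers(0, 4, n),
            "weekday": rng.integers(0, 7, n),
            "origin": rng.integers(8, 14, n),
        }
    )
    for i in range(6):
        frame[f"noise{i}"] = rng.standard_normal(n)
    p = 0.15 + 0.5 * (frame["subgroup"] == 2) + 0.3 * (frame["weekday"] >= 5)
    frame["crowding"] = (rng.random(n) < np.clip(p, 0, 1)).astype(int)
    cols = [c for c in frame.columns if c != "crowding"]
    model = fit_classifier(frame, cols, hyperparameters={"n_estimators": 40,
                                                         "min_child_samples": 10},
                           seed=0)
    res = shapley_importance(model, frame.head(200))
    assert {"subgroup", "weekday"} <= set(res.ranking[:5])


def test_surrogate_determinism_and_constant_model():
    frame = planted_frame(200, seed=2)
    cols = [c for c in frame.columns if c != "crowding"]
    model = fit_classifier(frame, cols, hyperparameters=FAST, seed=0)
    r1 = surrogate_importance(model, frame.head(5), n_samples=100, seed=9)
    r2 = surrogate_importance(model, frame.head(5), n_samples=100, seed=9)
    assert r1.ranking == r2.ranking
    assert np.allclose(r1.per_row.to_numpy(), r2.per_row.to_numpy())
    # constant-probability model: all importances ~ 0
    frame1 = frame.copy()
    frame1["crowding"] = 1
    const = fit_classifier(frame1, cols)
    rc = surrogate_importance(const, frame.head(3), n_samples=100, seed=0)
    assert float(rc.global_importance.max()) < 1e-12


def test_zero_perturbation_variance_is_error():
    frame = planted_frame(100, seed=3)
    cols = [c for c in frame.columns if c != "crowding"]
    model = fit_classifier(frame, cols, hyperparameters=FAST, seed=0)
    flat = frame.head(5).copy()
    for c in cols:
        flat[c] = 1.0
    with pytest.raises(ValueError, match="zero perturbation variance"):
        surrogate_importance(model, flat, n_samples=50, seed=0)
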