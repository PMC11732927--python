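"""Classifier contract and expanding-window protocol properties."""

import logging

import numpy as np
import pandas as pd
import pytest

from edcrowd.features import DesignMatrix
from edcrowd.forecaster import (
    ConstantModel,
    SplitConfig,
    default_split,
    expanding_window_forecast,
    fit_classifier,
)
from edcrowd.metrics import auroc

FAST = {"n_estimators": 25, "min_child_samples": 5}

CALENDAR = ["holiday", "after_holiday", "before_holiday", "weekday", "month",
            "subgroup", "origin"]


def toy_frame(n: int, seed: int, informative: bool = True) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    f = pd.DataFrame(rng.standard_normal((n, 6)), columns=[f"x{i}" for i in range(6)])
    f["flag"] = rng.integers(0, 2, n)
    if informative:
        f["crowding"] = f["flag"]
    else:
        f["crowding"] = rng.integers(0, 2, n)
    return f


def test_separable_training_set_reaches_auroc_one():
    frame = toy_frame(300, seed=0)
    model = fit_classifier(frame, feature_columns=[f"x{i}" for i in range(6)] + ["flag"],
                           hyperparameters=FAST)
    p = model.predict(frame)
    assert auroc(p, frame["crowding"]) == 1.0


def test_same_data_and_seed_identical_predictions():
    frame = toy_frame(300, seed=1)
    cols = [f"x{i}" for i in range(6)] + ["flag"]
    p1 = fit_classifier(frame, cols, hyperparameters=FAST, seed=5).predict(frame)
    p2 = fit_classifier(frame, cols, hyperparameters=FAST, seed=5).predict(frame)
    assert np.array_equal(p1, p2)


def test_single_class_training_falls_back_to_constant(caplog):
    frame = toy_frame(50, seed=2)
    frame["crowding"] = 1
    with caplog.at_level(logging.WARNING):
        model = fit_classifier(frame, [f"x{i}" for i in range(6)])
    assert isinstance(model.model, ConstantModel)
    assert "single-class" in caplog.text
    assert (model.predict(frame) == 1.0).all()


def test_permuted_labels_give_chance_level_auroc():
    # permutation null: held-out AUROC concentrates around 0.5
    aucs = []
    for seed in range(5):
        rng = np.random.default_rng(seed)
        frame = toy_frame(1200, seed=seed, informative=False)
        cols = [f"x{i}" for i in range(6)] + ["flag"]
        train, test = frame.iloc[:800], frame.iloc[800:]
        model = fit_classifier(train, cols, hyperparameters=FAST, seed=seed)
        aucs.append(auroc(model.predict(test), test["crowding"]))
    assert abs(np.mean(aucs) - 0.5) < 0.08


def test_expanding_window_bookkeeping(sim_150):
    matrix = sim_150["matrix"]
    dates = sorted(set(matrix.frame["date"]))
    split = SplitConfig(initial_train_end=dates[139], test_end=dates[149],
                        retrain_stride_days=1)
    run = expanding_window_forecast(matrix, split, hyperparameters=FAST, seed=0)
    run.validate()
    assert run.metadata["n_refits"] == 10
    ends = run.frame.groupby("date")["train_window_end"].first()
    assert list(ends.index) == sorted(ends.index)
    assert all(a < b for a, b in zip(ends.to_numpy()[:-1], ends.to_numpy()[1:]))
    # expanding property: training size never shrinks
    sizes = run.metadata["train_sizes"]
    assert all(a <= b for a, b in zip(sizes[:-1], sizes[1:]))
    # every test day predicted for all 4 subgroups x 6 origins
    assert len(run.frame) == 10 * 24


def test_full_stride_equals_static_split(sim_150):
    matrix = sim_150["matrix"]
    dates = sorted(set(matrix.frame["date"]))
    split = SplitConfig(initial_train_end=dates[139], test_end=dates[149],
                        retrain_stride_days=10)
    run = expanding_window_forecast(matrix, split, hyperparameters=FAST, seed=0)
    assert run.metadata["n_refits"] == 1
    assert (run.frame["train_window_end"] == dates[139]).all()


def test_empty_test_range_is_error(sim_150):
    matrix = sim_150["matrix"]
    dates = sorted(set(matrix.frame["date"]))
    split = SplitConfig(initial_train_end=dates[-1], test_end=dates[-1].replace(
        year=dates[-1].year + 1))
    with pytest.raises(ValueError, match="zero rows"):
        expanding_window_forecast(matrix, split)


def test_label_leak_drives_test_auroc_to_one(sim_150):
    matrix = sim_150["matrix"]
    leaky = matrix.frame.copy()
    leaky["beds_all"] = leaky["crowding"] * 100
    dm = DesignMatrix(frame=leaky, origins=matrix.origins)
    split = default_split(dm, initial_train_days=100, retrain_stride_days=50)
    run = expanding_window_forecast(dm, split, hyperparameters=FAST, seed=0)
    assert auroc(run.frame["probability"], run.frame["label"]) == 1.0


def test_run_roundtrip(tmp_path, run_150):
    run_150.write(tmp_path / "run")
    back = type(run_150).read(tmp_path / "run")
    assert np.allclose(back.frame["probability"], run_150.frame["probability"])
    assert back.metadata["n_refits"] == run_150.metadata["n_refits"]
    back.validate()


def test_full_features_beat_calendar_only_baseline():
    # ablation on the shipped generator: history features add real signal
    from edcrowd.crowding import crowding_labels
    from edcrowd.features import build_design_matrix
    from edcrowd.sim_ed import calibrate_default_config, replace_config, simulate_panel

    wins = []
    for seed in (0, 1, 2):
        cfg = replace_config(calibrate_default_config(), n_days=300, seed=seed)
        panel, cov = simulate_panel(cfg)
        labels = crowding_labels(panel)
        dm = build_design_matrix(panel, cov, labels)
        split = default_split(dm, initial_train_days=200, retrain_stride_days=50)
        full = expanding_window_forecast(dm, split, seed=0)
        cal = DesignMatrix(
            frame=dm.frame[["date"] + CALENDAR + ["crowding"]], origins=dm.origins
        )
        base = expanding_window_forecast(cal, split, seed=0)
        wins.append(
            auroc(full.frame["probability"], full.frame["label"])
            > auroc(base.frame["probability"], base.frame["label"])
        )
    assert all(wins)
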