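"""Gradient-boosted tree forecaster under expanding-window retraining.

One LightGBM binary classifier serves all four subgroups and six forecast
origins (both are categorical features).  Following the daily-retraining
protocol, the model is refit at the start of each test day on all rows
dated strictly before that day and predicts that day's rows; an optional
stride groups several test days per refit (stride 1 is the reference
protocol, a stride equal to the test length degenerates to a static
train/test split).

Hyperparameters default to the library defaults with a fixed seed and
single-threaded deterministic mode — reproducibility over tuning.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import lightgbm as lgb
import numpy as np
import pandas as pd

from edcrowd.features import DesignMatrix

log = logging.getLogger(__name__)

#: LightGBM defaults plus determinism settings; everything is overridable.
DEFAULT_HYPERPARAMETERS: dict = {
    "n_estimators": 100,
    "learning_rate": 0.1,
    "num_leaves": 31,
    "min_child_samples": 20,
    "num_threads": 1,
    "deterministic": True,
    "force_row_wise": True,
    "verbosity": -1,
}


@dataclass(frozen=True)
class SplitConfig:
    """Expanding-window split boundaries (dates are inclusive)."""

    initial_train_end: dt.date
    test_end: dt.date
    retrain_stride_days: int = 1

    def validate(self) -> None:
        if self.initial_train_end >= self.test_end:
            raise ValueError("initial_train_end must precede test_end")
        if self.retrain_stride_days < 1:
            raise ValueError("retrain_stride_days must be >= 1")


def default_split(matrix: DesignMatrix, initial_train_days: int = 365,
                  retrain_stride_days: int = 1) -> SplitConfig:
    """365-day initial training window, test to the end of the matrix."""
    dates = sorted(set(matrix.frame["date"]))
    if len(dates) <= initial_train_days:
        raise ValueError(
            f"matrix spans {len(dates)} days; need more than {initial_train_days}"
        )
    return SplitConfig(
        initial_train_end=dates[initial_train_days - 1],
        test_end=dates[-1],
        retrain_stride_days=retrain_stride_days,
    )


class ConstantModel:
    """Degenerate-fit fallback when a training window has a single class."""

    def __init__(self, probability: float):
        self.probability = float(probability)

    def predict_proba(self, X) -> np.ndarray:
        p = np.full(len(X), self.probability)
        return np.column_stack([1 - p, p])


@dataclass
class FittedModel:
    """A fitted probabilistic classifier plus its feature schema."""

    model: object
    feature_columns: list[str]
    categorical_columns: list[str]
    hyperparameters: dict
    seed: int

    def predict(self, frame: pd.DataFrame) -> np.ndarray:
        X = prepare_features(frame, self.feature_columns, self.categorical_columns)
        return self.model.predict_proba(X)[:, 1]

    @property
    def booster(self) -> lgb.Booster | None:
        return getattr(self.model, "booster_", None)


def prepare_features(
    frame: pd.DataFrame, feature_columns: list[str], categorical_columns: list[str]
) -> pd.DataFrame:
    """Select feature columns and declare categoricals to the learner.

    Categorical codes are small nonnegative integers package-wide, so a
    fixed global category range keeps codes consistent across refits.
    """
    X = frame[feature_columns].copy()
    for c in categorical_columns:
        if c in X.columns:
            X[c] = pd.Categorical(X[c].astype(int), categories=range(32))
    return X


def fit_classifier(
    frame: pd.DataFrame,
    feature_columns: list[str],
    label_column: str = "crowding",
    categorical_columns: tuple[str, ...] = ("weekday", "month", "subgroup", "origin"),
    hyperparameters: dict | None = None,
    seed: int = 0,
) -> FittedModel:
    """Fit the binary classifier on the given rows.

    Missing feature values and categorical codes are handled natively by
    the learner.  A single-class training set triggers a constant-
    probability fallback with a logged warning.
    """
    if len(frame) == 0:
        raise ValueError("empty training set")
    params = dict(DEFAULT_HYPERPARAMETERS)
    if hyperparameters:
        params.update(hyperparameters)
    params["random_state"] = seed
    y = frame[label_column].to_numpy(int)
    cats = [c for c in categorical_columns if c in feature_columns]
    if len(np.unique(y)) < 2:
        log.warning(
            "single-class training set (all labels %d); constant fallback", y[0]
        )
        return FittedModel(
            model=ConstantModel(float(y[0])),
            feature_columns=list(feature_columns),
            categorical_columns=cats,
            hyperparameters=params,
            seed=seed,
        )
    X = prepare_features(frame, list(feature_columns), cats)
    clf = lgb.LGBMClassifier(**params)
    clf.fit(X, y, categorical_feature=cats)
    return FittedModel(
        model=clf,
        feature_columns=list(feature_columns),
        categorical_columns=cats,
        hyperparameters=params,
        seed=seed,
    )


@dataclass
class ForecastRun:
    """Per-row predicted crowding probabilities for the test range.

    ``frame`` columns: date, subgroup, origin, probability, label,
    train_window_end.  ``metadata``: hyperparameters, seed, n_refits.
    """

    frame: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        f = self.frame
        if not ((f["probability"] >= 0) & (f["probability"] <= 1)).all():
            raise ValueError("probabilities outside [0, 1]")
        if not (f["train_window_end"] < f["date"]).all():
            raise ValueError("temporal leakage: train_window_end >= row date")

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_csv(out / "forecast.csv")
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.metadata, fh, indent=1, default=str)

    @classmethod
    def read(cls, in_dir) -> "ForecastRun":
        out = Path(in_dir)
        frame = pd.read_csv(out / "forecast.csv", parse_dates=["date", "train_window_end"])
        frame["date"] = frame["date"].dt.date
        frame["train_window_end"] = frame["train_window_end"].dt.date
        with open(out / "manifest.json") as fh:
            metadata = json.load(fh)
        return cls(frame=frame, metadata=metadata)


def expanding_window_forecast(
    matrix: DesignMatrix,
    split: SplitConfig,
    hyperparameters: dict | None = None,
    seed: int = 0,
) -> ForecastRun:
    """Run the retraining protocol and collect out-of-sample probabilities.

    For each test block starting at day d (stepped by the stride), the
    model is fit on all rows dated < d and predicts rows dated in
    [d, d + stride); all subgroups and origins of a block share one refit.
    """
    split.validate()
    frame = matrix.frame
    dates = np.asarray(sorted(set(frame["date"])))
    test_dates = dates[(dates > split.initial_train_end) & (dates <= split.test_end)]
    if len(test_dates) == 0:
        raise ValueError("test range contains zero rows")

    stride = split.retrain_stride_days
    n_refits = math.ceil(len(test_dates) / stride)
    date_col = frame["date"].to_numpy()
    pieces = []
    train_sizes = []
    for i in range(n_refits):
        block = test_dates[i * stride : (i + 1) * stride]
        d0 = block[0]
        train = frame[date_col < d0]
        train_sizes.append(len(train))
        model = fit_classifier(
            train,
            feature_columns=matrix.feature_columns,
            label_column=matrix.label_column,
            categorical_columns=matrix.categorical_columns,
            hyperparameters=hyperparameters,
            seed=seed,
        )
        test = frame[np.isin(date_col, block)]
        probs = model.predict(test)
        pieces.append(
            pd.DataFrame(
                {
                    "date": test["date"].to_numpy(),
                    "subgroup": test["subgroup"].to_numpy(int),
                    "origin": test["origin"].to_numpy(int),
                    "probability": probs,
                    "label": test[matrix.label_column].to_numpy(int),
                    "train_window_end": max(
                        d for d in dates if d < d0
                    ),
                }
            )
        )
    out = pd.concat(pieces, ignore_index=True)
    run = ForecastRun(
        frame=out,
        metadata={
            "hyperparameters": dict(DEFAULT_HYPERPARAMETERS, **(hyperparameters or {})),
            "seed": seed,
            "n_refits": n_refits,
            "train_sizes": train_sizes,
            "initial_train_end": str(split.initial_train_end),
            "test_end": str(split.test_end),
            "retrain_stride_days": stride,
        },
    )
    run.validate()
    return run
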