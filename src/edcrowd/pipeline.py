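"""End-to-end pipeline driver.

Runs simulate → targets → features → train → evaluate → attribute, where
each stage reads only the previous stage's serialized outputs, so every
intermediate is inspectable and any stage can be re-run from disk.  A
single global seed fans out to per-stage seeds through
``numpy.random.SeedSequence(global_seed).spawn``, so stages are
independently reproducible; the run manifest records the config hash,
derived seeds and a checksum per stage output.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from edcrowd import crowding, features, forecaster, metrics, sim_ed
from edcrowd.attribution import shapley_importance, surrogate_importance

log = logging.getLogger(__name__)

STAGES = ("simulate", "targets", "features", "train", "evaluate", "attribute")


@dataclass
class PipelineConfig:
    """Human-readable configuration of a full run.

    All protocol constants are explicit: EDOR threshold 0.90, >=3 crowded
    hours, origins 8-13, 168-hour lookback, lags 7/14 days, bootstrap
    n=200, decision threshold 0.5, 365-day initial training window.
    """

    out_dir: str = "edcrowd_run"
    start_date: dt.date = dt.date(2018, 1, 1)
    n_days: int = 790
    seed: int = 0
    edor_threshold: float = 0.90
    min_crowded_hours: int = 3
    origins: tuple[int, ...] = features.DEFAULT_ORIGINS
    initial_train_days: int = 365
    retrain_stride_days: int = 1
    bootstrap_resamples: int = 200
    decision_threshold: float = 0.5
    hyperparameters: dict = field(default_factory=dict)
    attribution_rows: int = 200
    surrogate_rows: int = 20
    surrogate_samples: int = 500
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.n_days < 2:
            raise ValueError("n_days must be >= 2")
        if not 0 < self.initial_train_days < self.n_days:
            raise ValueError(
                "initial_train_days must be positive and smaller than n_days"
            )
        if self.retrain_stride_days < 1:
            raise ValueError("retrain_stride_days must be >= 1")
        crowding.CrowdingConfig(self.edor_threshold, self.min_crowded_hours).validate()
        metrics.BootstrapConfig(n_resamples=self.bootstrap_resamples).validate()
        for o in self.origins:
            if not 0 <= o <= 23:
                raise ValueError(f"origin {o} outside 0..23")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["start_date"] = str(self.start_date)
        d["origins"] = list(self.origins)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "start_date" in d and isinstance(d["start_date"], str):
            d["start_date"] = dt.date.fromisoformat(d["start_date"])
        if "origins" in d:
            d["origins"] = tuple(d["origins"])
        return cls(**d)

    def config_hash(self) -> str:
        d = asdict(self)
        d["start_date"] = str(self.start_date)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def stage_seeds(global_seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds below 2**31."""
    children = np.random.SeedSequence(global_seed).spawn(len(STAGES))
    return {
        name: int(child.generate_state(1)[0] % 2**31)
        for name, child in zip(STAGES, children)
    }


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all six stages; returns (and writes) the run manifest."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "global_seed": config.seed,
        "stage_seeds": seeds,
        "outputs": {},
    }
    config.to_yaml(out / "pipeline.yaml")

    def record(stage: str, *paths: Path) -> None:
        manifest["outputs"][stage] = {p.name: _checksum(p) for p in paths}
        log.info("stage %s done: %s", stage, [p.name for p in paths])

    try:
        # 1. simulate ----------------------------------------------------
        sim_cfg = sim_ed.replace_config(
            sim_ed.calibrate_default_config(
                start_date=config.start_date, n_days=config.n_days
            ),
            seed=seeds["simulate"],
        )
        panel, covariates = sim_ed.simulate_panel(sim_cfg)
        panel.to_csv(out / "panel.csv")
        covariates.to_csv(out / "covariates.csv")
        record("simulate", out / "panel.csv", out / "covariates.csv")

        # 2. targets -----------------------------------------------------
        panel2 = sim_ed.HourlyOccupancyPanel.read_csv(out / "panel.csv")
        ccfg = crowding.CrowdingConfig(config.edor_threshold, config.min_crowded_hours)
        labels = crowding.crowding_labels(panel2, ccfg)
        labels.to_csv(out / "labels.csv")
        record("targets", out / "labels.csv")

        # 3. features ----------------------------------------------------
        panel3 = sim_ed.HourlyOccupancyPanel.read_csv(out / "panel.csv")
        cov3 = sim_ed.CovariatePanel.read_csv(out / "covariates.csv")
        hourly3 = crowding.hourly_crowding(panel3, ccfg)
        labels3 = crowding.CrowdingLabels.read_csv(out / "labels.csv", hourly=hourly3)
        dm = features.build_design_matrix(panel3, cov3, labels3, config.origins)
        dm.write(out / "matrix")
        record("features", out / "matrix" / "matrix.parquet",
               out / "matrix" / "schema.json")

        # 4. train -------------------------------------------------------
        dm4 = features.DesignMatrix.read(out / "matrix")
        split = forecaster.default_split(
            dm4, config.initial_train_days, config.retrain_stride_days
        )
        run = forecaster.expanding_window_forecast(
            dm4, split, config.hyperparameters, seed=seeds["train"]
        )
        run.write(out / "run")
        record("train", out / "run" / "forecast.csv", out / "run" / "manifest.json")

        # 5. evaluate ----------------------------------------------------
        run5 = forecaster.ForecastRun.read(out / "run")
        bcfg = metrics.BootstrapConfig(
            n_resamples=config.bootstrap_resamples, seed=seeds["evaluate"]
        )
        table = metrics.metrics_table(run5, bcfg, config.decision_threshold)
        (out / "eval").mkdir(exist_ok=True)
        table.to_csv(out / "eval" / "metrics.csv", index=False)
        cal = []
        for o in sorted(set(run5.frame["origin"])):
            cal.append(metrics.calendar_outcomes(run5, o, config.decision_threshold))
        import pandas as pd

        pd.concat(cal, ignore_index=True).to_csv(
            out / "eval" / "calendar_outcomes.csv", index=False
        )
        record("evaluate", out / "eval" / "metrics.csv",
               out / "eval" / "calendar_outcomes.csv")

        # 6. attribute ---------------------------------------------------
        dm6 = features.DesignMatrix.read(out / "matrix")
        split6 = forecaster.default_split(
            dm6, config.initial_train_days, config.retrain_stride_days
        )
        train_rows = dm6.frame[dm6.frame["date"] <= split6.initial_train_end]
        model = forecaster.fit_classifier(
            train_rows,
            feature_columns=dm6.feature_columns,
            label_column=dm6.label_column,
            categorical_columns=dm6.categorical_columns,
            hyperparameters=config.hyperparameters,
            seed=seeds["train"],
        )
        test_rows = dm6.frame[dm6.frame["date"] > split6.initial_train_end]
        rng = np.random.default_rng(seeds["attribute"])
        k = min(config.attribution_rows, len(test_rows))
        pick = np.sort(rng.choice(len(test_rows), size=k, replace=False))
        sample = test_rows.iloc[pick]
        (out / "attr").mkdir(exist_ok=True)
        shap_res = shapley_importance(model, sample)
        shap_res.to_csv(out / "attr" / "shapley.csv")
        k2 = min(config.surrogate_rows, len(sample))
        lime_res = surrogate_importance(
            model, sample.head(k2), n_samples=config.surrogate_samples,
            seed=seeds["attribute"],
        )
        lime_res.to_csv(out / "attr" / "surrogate.csv")
        record("attribute", out / "attr" / "shapley.csv",
               out / "attr" / "surrogate.csv")
    except Exception as exc:  # halt with the stage name and cause
        done = set(manifest["outputs"])
        stage = next((s for s in STAGES if s not in done), "unknown")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
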