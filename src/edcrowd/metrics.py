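"""Binary-metric panel with percentile-bootstrap confidence intervals.

Implements the full evaluation protocol: confusion-count metrics at a
probability threshold (default 0.5, prediction = probability >= threshold),
rank metrics (AUROC with Mann-Whitney tie handling, AUPRC as step-wise
average precision), percentile bootstrap intervals (default 200 resamples)
and the per-(subgroup, origin) metrics table.  Ratios with zero
denominators propagate as NaN, never as a silent 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from edcrowd.forecaster import ForecastRun
from edcrowd.subgroups import CODE_TO_SUBGROUP, EVALUATED_SUBGROUPS, SUBGROUP_CODES

UNDEFINED = float("nan")


@dataclass(frozen=True)
class BootstrapConfig:
    n_resamples: int = 200
    alpha: float = 0.05
    seed: int = 0
    max_redraws: int = 10_000

    def validate(self) -> None:
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class MetricRecord:
    """One evaluation cell: counts, ratio metrics and rank metrics."""

    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float
    f1: float
    tpr: float
    tnr: float
    ppv: float
    npv: float
    fpr: float
    fnr: float
    acc: float
    auroc: float
    auprc: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else UNDEFINED


def binary_metrics(
    probabilities: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> MetricRecord:
    """Confusion-count metric panel at the given probability cutoff."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.size == 0:
        raise ValueError("empty input")
    if p.shape != y.shape:
        raise ValueError("probabilities and labels differ in length")
    pred = p >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tpr = _ratio(tp, tp + fn)
    tnr = _ratio(tn, tn + fp)
    ppv = _ratio(tp, tp + fp)
    npv = _ratio(tn, tn + fn)
    fpr = _ratio(fp, fp + tn)
    fnr = _ratio(fn, fn + tp)
    acc = _ratio(tp + tn, tp + tn + fp + fn)
    if np.isnan(ppv) or np.isnan(tpr) or (ppv + tpr) == 0:
        f1 = UNDEFINED
    else:
        f1 = 2 * ppv * tpr / (ppv + tpr)
    return MetricRecord(
        tp=tp, fp=fp, tn=tn, fn=fn, threshold=threshold,
        f1=f1, tpr=tpr, tnr=tnr, ppv=ppv, npv=npv, fpr=fpr, fnr=fnr, acc=acc,
        auroc=auroc(p, y), auprc=auprc(p, y),
    )


def f1_from_rates(tpr: float, ppv: float) -> float:
    """Harmonic mean of precision and recall."""
    if tpr + ppv == 0:
        return UNDEFINED
    return 2 * ppv * tpr / (ppv + tpr)


def auroc(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Probability a random positive outranks a random negative (ties ½)."""
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        warnings.warn("single-class labels: AUROC undefined", stacklevel=2)
        return UNDEFINED
    return float(roc_auc_score(y, np.asarray(probabilities, dtype=float)))


def auprc(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Step-wise average precision; guess level equals positive prevalence."""
    y = np.asarray(labels, dtype=int)
    if (y == 1).sum() == 0:
        warnings.warn("no positive labels: AUPRC undefined", stacklevel=2)
        return UNDEFINED
    return float(average_precision_score(y, np.asarray(probabilities, dtype=float)))


_METRIC_FUNCS = {
    "auroc": auroc,
    "auprc": auprc,
    "f1": lambda p, y, threshold=0.5: binary_metrics(p, y, threshold).f1,
    "acc": lambda p, y, threshold=0.5: binary_metrics(p, y, threshold).acc,
    "tpr": lambda p, y, threshold=0.5: binary_metrics(p, y, threshold).tpr,
}


def bootstrap_ci(
    metric: str,
    probabilities: np.ndarray,
    labels: np.ndarray,
    config: BootstrapConfig = BootstrapConfig(),
    threshold: float = 0.5,
) -> tuple[float, float]:
    """Percentile bootstrap interval over row resamples with replacement.

    Resamples that lose a class (making rank metrics undefined) are redrawn;
    the number of redraws is capped, and exceeding the cap raises.
    Row order does not affect the interval for a fixed seed.
    """
    config.validate()
    if metric not in _METRIC_FUNCS:
        raise ValueError(f"unknown metric {metric!r}")
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    # canonical order so the interval is invariant to input row order
    order = np.lexsort((y, p))
    p, y = p[order], y[order]
    fn = _METRIC_FUNCS[metric]
    needs_both = metric in ("auroc", "auprc")
    rng = np.random.default_rng(config.seed)
    n = len(p)
    stats = []
    redraws = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        while len(stats) < config.n_resamples:
            idx = rng.integers(0, n, size=n)
            yb = y[idx]
            if needs_both and len(np.unique(yb)) < 2:
                redraws += 1
                if redraws > config.max_redraws:
                    raise RuntimeError(
                        f"bootstrap degenerate: {redraws} resamples lost a class"
                    )
                continue
            if metric in ("auroc", "auprc"):
                stats.append(fn(p[idx], yb))
            else:
                stats.append(fn(p[idx], yb, threshold=threshold))
    lo, hi = np.nanquantile(stats, [config.alpha / 2, 1 - config.alpha / 2])
    return float(lo), float(hi)


def metrics_table(
    run: ForecastRun,
    config: BootstrapConfig = BootstrapConfig(),
    threshold: float = 0.5,
    subgroups: tuple[str, ...] = EVALUATED_SUBGROUPS,
) -> pd.DataFrame:
    """Per-(subgroup, origin) metric panel with AUROC/F1/AUPRC intervals.

    Critical is excluded from evaluation by default (it serves as an
    explanatory variable only).  Output row order is fixed: subgroups in
    the given order, origins ascending.
    """
    if len(run.frame) == 0:
        raise ValueError("empty forecast run")
    f = run.frame
    rows = []
    origins = sorted(set(f["origin"]))
    for s in subgroups:
        code = SUBGROUP_CODES[s]
        for o in origins:
            cell = f[(f["subgroup"] == code) & (f["origin"] == o)]
            cell = cell.sort_values(["date"])
            p = cell["probability"].to_numpy()
            y = cell["label"].to_numpy(int)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rec = binary_metrics(p, y, threshold)
                single_class = len(np.unique(y)) < 2
                if single_class:
                    auroc_ci = f1_ci = auprc_ci = (UNDEFINED, UNDEFINED)
                else:
                    cell_cfg = BootstrapConfig(
                        n_resamples=config.n_resamples,
                        alpha=config.alpha,
                        seed=config.seed,
                        max_redraws=config.max_redraws,
                    )
                    auroc_ci = bootstrap_ci("auroc", p, y, cell_cfg)
                    f1_ci = bootstrap_ci("f1", p, y, cell_cfg, threshold)
                    auprc_ci = bootstrap_ci("auprc", p, y, cell_cfg)
            row = {"target": s, "origin": o}
            row.update(rec.as_dict())
            row["auroc_ci_low"], row["auroc_ci_high"] = auroc_ci
            row["f1_ci_low"], row["f1_ci_high"] = f1_ci
            row["auprc_ci_low"], row["auprc_ci_high"] = auprc_ci
            row["prevalence"] = float(y.mean()) if len(y) else UNDEFINED
            row["ci_method"] = "percentile-bootstrap"
            rows.append(row)
    return pd.DataFrame(rows)


def calendar_outcomes(
    run: ForecastRun, origin: int, threshold: float = 0.5
) -> pd.DataFrame:
    """Map each test date to TP/FP/TN/FN per subgroup at one origin."""
    f = run.frame
    sel = f[f["origin"] == origin]
    if len(sel) == 0:
        raise ValueError(f"origin {origin} not present in run")
    pred = sel["probability"].to_numpy() >= threshold
    y = sel["label"].to_numpy(int) == 1
    cls = np.where(
        pred & y, "TP", np.where(pred & ~y, "FP", np.where(~pred & ~y, "TN", "FN"))
    )
    return pd.DataFrame(
        {
            "date": sel["date"].to_numpy(),
            "subgroup": [CODE_TO_SUBGROUP[c] for c in sel["subgroup"].to_numpy(int)],
            "origin": origin,
            "outcome": cls,
        }
    ).sort_values(["subgroup", "date"], ignore_index=True)
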