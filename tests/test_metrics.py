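"""Metric identities, rank-metric oracles, bootstrap and table behaviour."""

import numpy as np
import pandas as pd
import pytest

from edcrowd.forecaster import ForecastRun
from edcrowd.metrics import (
    BootstrapConfig,
    auprc,
    auroc,
    binary_metrics,
    bootstrap_ci,
    calendar_outcomes,
    f1_from_rates,
    metrics_table,
)

from oracles import auprc_threshold_sweep, auroc_pair_counting


def random_scores(seed: int, n: int = 30):
    rng = np.random.default_rng(seed)
    p = rng.random(n)
    y = rng.integers(0, 2, n)
    if y.min() == y.max():  # ensure both classes
        y[0], y[1] = 0, 1
    return p, y


@pytest.mark.parametrize("seed", range(8))
def test_metric_record_identities(seed):
    p, y = random_scores(seed, n=80)
    rec = binary_metrics(p, y, threshold=0.5)
    assert rec.tpr + rec.fnr == pytest.approx(1.0)
    assert rec.tnr + rec.fpr == pytest.approx(1.0)
    assert rec.acc == pytest.approx(
        (rec.tp + rec.tn) / (rec.tp + rec.tn + rec.fp + rec.fn)
    )
    if not np.isnan(rec.f1):
        assert rec.f1 == pytest.approx(f1_from_rates(rec.tpr, rec.ppv))


def test_perfect_predictions():
    y = np.array([0, 1, 0, 1, 1])
    rec = binary_metrics(y.astype(float), y)
    assert rec.f1 == rec.acc == 1.0
    assert rec.fpr == rec.fnr == 0.0
    assert auroc(y.astype(float), y) == 1.0
    assert auprc(y.astype(float), y) == 1.0


def test_zero_denominators_are_undefined_not_zero():
    p = np.zeros(10)
    y = np.array([1, 1] + [0] * 8)
    rec = binary_metrics(p, y)
    assert np.isnan(rec.ppv)
    assert rec.tpr == 0.0
    with pytest.raises(ValueError, match="empty"):
        binary_metrics(np.array([]), np.array([]))


def test_single_class_rank_metrics_undefined():
    with pytest.warns(UserWarning, match="single-class"):
        assert np.isnan(auroc(np.array([0.2, 0.4]), np.array([1, 1])))
    with pytest.warns(UserWarning, match="no positive"):
        assert np.isnan(auprc(np.array([0.2, 0.4]), np.array([0, 0])))


def test_all_tied_scores_give_half_auroc_and_prevalence_auprc():
    p = np.full(40, 0.3)
    y = np.array([1] * 10 + [0] * 30)
    assert auroc(p, y) == 0.5
    assert auprc(p, y) == pytest.approx(0.25)


@pytest.mark.parametrize("seed", range(20))
def test_rank_metrics_match_brute_force_oracles(seed):
    p, y = random_scores(seed)
    assert auroc(p, y) == pytest.approx(auroc_pair_counting(p, y), abs=1e-12)
    assert auprc(p, y) == pytest.approx(auprc_threshold_sweep(p, y), abs=1e-12)


def test_bootstrap_degenerate_and_deterministic():
    y = np.array([0, 1] * 25)
    p = y.astype(float)
    cfg = BootstrapConfig(n_resamples=100, seed=4)
    assert bootstrap_ci("auroc", p, y, cfg) == (1.0, 1.0)
    p2, y2 = random_scores(3, n=100)
    ci_a = bootstrap_ci("auroc", p2, y2, cfg)
    ci_b = bootstrap_ci("auroc", p2, y2, cfg)
    assert ci_a == ci_b
    # row order invariance
    order = np.random.default_rng(0).permutation(len(p2))
    assert bootstrap_ci("auroc", p2[order], y2[order], cfg) == ci_a


def test_bootstrap_interval_converges_with_resamples():
    p, y = random_scores(7, n=500)
    lo1, hi1 = bootstrap_ci("auroc", p, y, BootstrapConfig(n_resamples=200, seed=0))
    lo2, hi2 = bootstrap_ci("auroc", p, y, BootstrapConfig(n_resamples=10_000, seed=1))
    assert abs(lo1 - lo2) < 0.03
    assert abs(hi1 - hi2) < 0.03


def _synthetic_run(seed: int = 0, n_days: int = 60) -> ForecastRun:
    rng = np.random.default_rng(seed)
    rows = []
    for d in range(n_days):
        for sub in (0, 1, 2, 3):
            for o in (8, 9, 10, 11, 12, 13):
                y = int(rng.random() < 0.3)
                p = np.clip(0.3 * y + rng.random() * 0.7, 0, 1)
                rows.append((d, sub, o, p, y, -1))
    f = pd.DataFrame(rows, columns=["date", "subgroup", "origin", "probability",
                                    "label", "train_window_end"])
    return ForecastRun(frame=f, metadata={})


def test_metrics_table_shape_and_order_invariance():
    run = _synthetic_run()
    cfg = BootstrapConfig(n_resamples=30, seed=1)
    tab = metrics_table(run, cfg)
    assert len(tab) == 18  # 3 evaluated subgroups x 6 origins
    assert set(tab["target"]) == {"bedoccupying", "medical", "surgical"}
    assert (tab["ci_method"] == "percentile-bootstrap").all()
    tab12 = metrics_table(run, cfg, subgroups=("medical", "surgical"))
    assert len(tab12) == 12
    shuffled = ForecastRun(
        frame=run.frame.sample(frac=1.0, random_state=2).reset_index(drop=True),
        metadata={},
    )
    tab2 = metrics_table(shuffled, cfg)
    pd.testing.assert_frame_equal(tab, tab2)


def test_calendar_outcomes_reconcile_with_confusion_counts():
    run = _synthetic_run(seed=5)
    out = calendar_outcomes(run, origin=11, threshold=0.5)
    sel = run.frame[run.frame["origin"] == 11]
    rec = binary_metrics(sel["probability"], sel["label"], 0.5)
    counts = out["outcome"].value_counts()
    assert counts.get("TP", 0) == rec.tp
    assert counts.get("FP", 0) == rec.fp
    assert counts.get("TN", 0) == rec.tn
    assert counts.get("FN", 0) == rec.fn
    # each (date, subgroup) maps to exactly one outcome
    assert out.groupby(["date", "subgroup"]).size().max() == 1


def test_label_flip_swaps_outcome_classes():
    run = _synthetic_run(seed=6)
    flipped = ForecastRun(frame=run.frame.assign(label=1 - run.frame["label"]),
                          metadata={})
    a = calendar_outcomes(run, 9)["outcome"].value_counts()
    b = calendar_outcomes(flipped, 9)["outcome"].value_counts()
    assert a.get("TP", 0) == b.get("FP", 0)
    assert a.get("FP", 0) == b.get("TP", 0)
    assert a.get("TN", 0) == b.get("FN", 0)
    assert a.get("FN", 0) == b.get("TN", 0)


def test_missing_origin_is_error():
    run = _synthetic_run()
    with pytest.raises(ValueError, match="origin"):
        calendar_outcomes(run, origin=5)
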