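"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation paths they check: rank metrics
are computed by exhaustive pair counting / threshold sweeps, and Shapley
values by direct subset enumeration of the weighted-marginal formula over
tree expectations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def auroc_pair_counting(probabilities, labels) -> float:
    """P(random positive outranks random negative), ties counted 1/2."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos = p[y == 1]
    neg = p[y == 0]
    wins = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def auprc_threshold_sweep(probabilities, labels) -> float:
    """Average precision from an exhaustive sweep over distinct scores."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int(y.sum())
    thresholds = np.unique(p)[::-1]
    ap = 0.0
    prev_recall = 0.0
    for t in thresholds:
        pred = p >= t
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        precision = tp / (tp + fp)
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


# ---------------------------------------------------------------------------
# tree-model Shapley enumeration
# ---------------------------------------------------------------------------


def _node_count(node: dict) -> int:
    return node["leaf_count"] if "leaf_value" in node else node["internal_count"]


def _expected_value(node: dict, x: np.ndarray, known: set[int]) -> float:
    """Expected tree output when only features in ``known`` are observed;
    unknown splits average children weighted by training cover."""
    if "leaf_value" in node:
        return node["leaf_value"]
    f = node["split_feature"]
    left, right = node["left_child"], node["right_child"]
    if f in known:
        child = left if x[f] <= node["threshold"] else right
        return _expected_value(child, x, known)
    cl, cr = _node_count(left), _node_count(right)
    return (
        cl * _expected_value(left, x, known) + cr * _expected_value(right, x, known)
    ) / (cl + cr)


def shapley_enumeration(booster, x: np.ndarray) -> tuple[np.ndarray, float]:
    """Shapley values phi_i by direct enumeration of all feature subsets.

    phi_i = sum over S subseteq N\\{i} of |S|!(|N|-|S|-1)!/|N|! *
    [v(S u {i}) - v(S)], with v(S) the cover-weighted tree expectation.
    Only feasible for |N| <= ~8.  Returns (phi, v(empty set)).
    """
    dump = booster.dump_model()
    trees = [t["tree_structure"] for t in dump["tree_info"]]
    nf = len(x)

    def v(S: set[int]) -> float:
        return sum(_expected_value(t, x, S) for t in trees)

    phi = np.zeros(nf)
    for i in range(nf):
        rest = [j for j in range(nf) if j != i]
        for k in range(nf):
            w = math.factorial(k) * math.factorial(nf - k - 1) / math.factorial(nf)
            for S in itertools.combinations(rest, k):
                s = set(S)
                phi[i] += w * (v(s | {i}) - v(s))
    return phi, v(set())
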