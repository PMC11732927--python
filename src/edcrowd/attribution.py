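"""Feature attribution: tree-exact Shapley values and local surrogates.

Global importance is the mean absolute per-row attribution over the
evaluated rows.  Shapley values come from the learner's built-in tree-exact
algorithm (polynomial in tree size; no subset enumeration), which satisfies
local accuracy: base value + sum of per-feature attributions equals the
model's raw (log-odds) output for every row.  The locality-weighted linear
surrogate perturbs features around each row, weights perturbed samples by
an exponential proximity kernel and reads absolute coefficients off a
ridge fit — a per-instance linear approximation of the model's decision
surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logit
from sklearn.linear_model import Ridge

from edcrowd.forecaster import ConstantModel, FittedModel, prepare_features


@dataclass
class AttributionResult:
    method: str  # "shapley" | "local-surrogate"
    global_importance: pd.Series  # feature -> mean |attribution|, desc order
    per_row: pd.DataFrame  # one column per feature
    base_values: np.ndarray | None = None  # Shapley only

    @property
    def ranking(self) -> list[str]:
        return list(self.global_importance.index)

    def to_csv(self, path) -> None:
        out = pd.DataFrame(
            {
                "feature": self.global_importance.index,
                "method": self.method,
                "importance": self.global_importance.to_numpy(),
                "rank": np.arange(1, len(self.global_importance) + 1),
            }
        )
        out.to_csv(path, index=False)


def _global_from_rows(per_row: pd.DataFrame) -> pd.Series:
    imp = per_row.abs().mean(axis=0)
    # stable order: importance descending, feature name as tie-break
    return imp.sort_index().sort_values(ascending=False, kind="stable")


def shapley_importance(model: FittedModel, frame: pd.DataFrame) -> AttributionResult:
    """Tree-exact Shapley attributions for the given rows.

    Raises on a feature-schema mismatch.  Features the trees never split
    on receive exactly zero attribution on every row (null player).
    """
    missing = [c for c in model.feature_columns if c not in frame.columns]
    if missing:
        raise ValueError(f"rows lack model features: {missing[:5]}")
    X = prepare_features(frame, model.feature_columns, model.categorical_columns)
    if isinstance(model.model, ConstantModel):
        contrib = np.zeros((len(X), len(model.feature_columns)))
        base = np.full(len(X), logit(np.clip(model.model.probability, 1e-9, 1 - 1e-9)))
    else:
        raw = model.model.predict_proba(X, pred_contrib=True)
        contrib, base = raw[:, :-1], raw[:, -1]
    per_row = pd.DataFrame(contrib, columns=model.feature_columns, index=frame.index)
    return AttributionResult(
        method="shapley",
        global_importance=_global_from_rows(per_row),
        per_row=per_row,
        base_values=np.asarray(base, dtype=float),
    )


def surrogate_importance(
    model: FittedModel,
    frame: pd.DataFrame,
    n_samples: int = 500,
    seed: int = 0,
    kernel_width: float | None = None,
    ridge_alpha: float = 1.0,
) -> AttributionResult:
    """Locality-weighted linear surrogate attributions (LIME-style).

    For each row: perturb numeric features with Gaussian noise at the
    empirical scale of ``frame`` (categoricals resample from their
    empirical distribution), query the model, weight samples by
    exp(−d²/width²) on standardized distance, and fit a ridge regression
    to the predicted probability.  Per-row attribution is the absolute
    standardized coefficient.
    """
    missing = [c for c in model.feature_columns if c not in frame.columns]
    if missing:
        raise ValueError(f"rows lack model features: {missing[:5]}")
    rng = np.random.default_rng(seed)
    feats = model.feature_columns
    cats = set(model.categorical_columns)
    ref = frame[feats]

    med = ref.median(numeric_only=False)
    sd = ref.std().fillna(0.0)
    if float(sd.sum()) == 0 and not cats:
        raise ValueError("zero perturbation variance: all features constant")
    n_feat = len(feats)
    d = len(frame)
    width = kernel_width if kernel_width is not None else 0.75 * np.sqrt(n_feat)

    coefs = np.zeros((d, n_feat))
    for i, (_, row) in enumerate(frame.iterrows()):
        x0 = row[feats].astype(float)
        x0 = x0.fillna(med.astype(float))
        Z = np.tile(x0.to_numpy(dtype=float), (n_samples, 1))
        for j, c in enumerate(feats):
            if c in cats:
                pool = ref[c].dropna().to_numpy()
                if len(pool):
                    Z[:, j] = rng.choice(pool, size=n_samples)
            else:
                Z[:, j] = Z[:, j] + rng.standard_normal(n_samples) * float(sd[c])
        Z[0] = x0.to_numpy(dtype=float)  # anchor at the instance itself
        zframe = pd.DataFrame(Z, columns=feats)
        fz = model.predict(zframe)
        scale = sd.to_numpy(dtype=float).copy()
        scale[scale == 0] = 1.0
        Zs = (Z - x0.to_numpy(dtype=float)) / scale
        dist = np.sqrt((Zs**2).sum(axis=1))
        w = np.exp(-(dist**2) / width**2)
        reg = Ridge(alpha=ridge_alpha)
        reg.fit(Zs, fz, sample_weight=w)
        coefs[i] = np.abs(reg.coef_)
    per_row = pd.DataFrame(coefs, columns=feats, index=frame.index)
    return AttributionResult(
        method="local-surrogate",
        global_importance=_global_from_rows(per_row),
        per_row=per_row,
        base_values=None,
    )
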