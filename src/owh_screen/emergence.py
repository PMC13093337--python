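"""Detection of emergent combination-treatment transcriptomic effects.

Per-transcript combination-group expression is predicted from the four
single-condition group means with a tree-ensemble regressor using 10-fold
pre-validated (out-of-fold) predictions; an OLS regression of measured on
predicted then yields 95%/99% prediction intervals, and transcripts outside
them are flagged as candidate emergent effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.model_selection import KFold

PREDICTOR_GROUPS = ("control", "OGD", "Az", "Epo")
TARGET_GROUP = "AzEpo"
SCOPES = ("global", "cortex", "white matter", "deep gray")


@dataclass
class EmergenceInput:
    predictors: pd.DataFrame  # transcripts x 4 group means
    target: pd.Series         # transcript -> combination-group mean
    scope: str


def build_emergence_input(matrix: pd.DataFrame, meta: pd.DataFrame,
                          scope: str = "global") -> EmergenceInput:
    """Group means per transcript within a regional scope ('global' pools)."""
    m = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    if scope != "global":
        m = m[m["region"] == scope]
        if len(m) == 0:
            raise ValueError(f"scope {scope!r} has no samples")
    means = {}
    for g in PREDICTOR_GROUPS + (TARGET_GROUP,):
        cols = m.index[m["group"] == g]
        if len(cols) == 0:
            raise ValueError(f"missing group {g!r} in scope {scope!r}")
        means[g] = matrix[cols].mean(axis=1)
    predictors = pd.DataFrame({g: means[g] for g in PREDICTOR_GROUPS})
    return EmergenceInput(predictors=predictors, target=means[TARGET_GROUP],
                          scope=scope)


def cv_predict(inp: EmergenceInput, folds: int = 10, seed: int = 0,
               n_estimators: int = 200) -> pd.Series:
    """Pre-validated predictions: each transcript's prediction comes from a
    gradient-boosted additive-regression-tree model trained on the other
    folds only."""
    X = inp.predictors.to_numpy(dtype=float)
    y = inp.target.to_numpy(dtype=float)
    if len(y) < folds:
        raise ValueError(f"need >= {folds} transcripts for {folds}-fold CV")
    preds = np.empty(len(y))
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for train_idx, test_idx in kf.split(X):
        model = GradientBoostingRegressor(n_estimators=n_estimators,
                                          random_state=seed)
        model.fit(X[train_idx], y[train_idx])
        preds[test_idx] = model.predict(X[test_idx])
    return pd.Series(preds, index=inp.target.index, name="predicted")


def prediction_interval_flags(predicted: pd.Series, measured: pd.Series,
                              levels: tuple = (0.95, 0.99),
                              scope: str = "global") -> pd.DataFrame:
    """OLS of measured on predicted with per-point prediction intervals.

    Flags each transcript outside the interval at each level; z_diff is the
    absolute measured-predicted difference in SD units of the measured
    expression distribution within scope.
    """
    pred = np.asarray(predicted, dtype=float)
    meas = np.asarray(measured, dtype=float)
    if len(pred) < 10:
        raise ValueError("need >= 10 transcripts")
    if np.std(pred) == 0:
        raise ValueError("zero variance in predictions")
    X = sm.add_constant(pred)
    fit = sm.OLS(meas, X).fit()
    out = pd.DataFrame({"predicted": pred, "measured": meas,
                        "residual": meas - fit.predict(X)},
                       index=predicted.index)
    tol = 1e-9 * (1.0 + np.abs(meas))  # exact fits must not flag
    for level in levels:
        frame = fit.get_prediction(X).summary_frame(alpha=1.0 - level)
        outside = ((meas < frame["obs_ci_lower"].to_numpy() - tol)
                   | (meas > frame["obs_ci_upper"].to_numpy() + tol))
        out[f"flag{int(round(level * 100))}"] = outside
    sd = float(np.std(meas))
    out["z_diff"] = np.abs(meas - pred) / sd if sd > 0 else 0.0
    out["direction"] = np.where(meas >= pred, "over", "under")
    out["scope"] = scope
    return out


def emergence_report(matrix: pd.DataFrame, meta: pd.DataFrame,
                     scope: str = "global", folds: int = 10,
                     seed: int = 0) -> pd.DataFrame:
    """Full per-scope pipeline: inputs -> CV predictions -> interval flags."""
    inp = build_emergence_input(matrix, meta, scope)
    predicted = cv_predict(inp, folds=folds, seed=seed)
    return prediction_interval_flags(predicted, inp.target, scope=scope)


def emergence_summary(reports: dict) -> pd.DataFrame:
    """Flagged transcripts across scopes, sorted by z_diff within scope.

    ``reports`` maps scope -> report frame.  Rows carry the 95/99 tier and
    over/under direction; the 99% tier is always a subset of the 95% tier.
    """
    rows = []
    for scope, rep in reports.items():
        flagged = rep[rep["flag95"]]
        for transcript, row in flagged.sort_values(
                "z_diff", ascending=False).iterrows():
            rows.append({"scope": scope, "transcript": transcript,
                         "z_diff": row["z_diff"],
                         "direction": row["direction"],
                         "tier": "99" if row["flag99"] else "95",
                         "predicted": row["predicted"],
                         "measured": row["measured"]})
    return pd.DataFrame(rows, columns=["scope", "transcript", "z_diff",
                                       "direction", "tier", "predicted",
                                       "measured"])
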