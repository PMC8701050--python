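"""Feature engineering and screening for the minute-level modelling table.

Candidate predictors are transforms of the per-minute signal aggregates
(polynomials, logs, interactions and trailing rolling statistics).  They are
screened in two stages: multicollinearity filtering by variance inflation
factor (VIF > 5 excluded, removed one at a time), then backward elimination
on ordinary-least-squares p-values (drop the least significant predictor
until all p <= alpha), with a univariate F ranking available as a
cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "FeatureSpec",
    "engineer_features",
    "default_feature_specs",
    "compute_vif",
    "filter_vif",
    "backward_select",
    "rank_univariate_f",
]

TRANSFORMS = (
    "identity",
    "poly2",
    "poly3",
    "log",
    "rolling_mean",
    "rolling_min",
    "rolling_max",
    "rolling_median",
    "rolling_sd",
    "interaction",
)


@dataclass(frozen=True)
class FeatureSpec:
    """One engineered predictor: a transform of a source aggregate column."""

    name: str
    source: str
    transform: str = "identity"
    window: Optional[int] = None  # minutes, rolling transforms only
    partner: Optional[str] = None  # second column, interaction only

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.transform.startswith("rolling"):
            if self.window is None or self.window < 1:
                raise ValueError(f"{self.name}: rolling transform needs window >= 1")
        if self.transform == "interaction" and not self.partner:
            raise ValueError(f"{self.name}: interaction needs a partner column")


def default_feature_specs() -> list[FeatureSpec]:
    """The package's default candidate set.

    Mean/min/max/SD of every signal, squares of heart rate and skin
    temperature, their interaction, and 5-min trailing rolling means of the
    physiological channels.
    """
    specs: list[FeatureSpec] = []
    for sig in ("hr", "skin_temp", "skin_rh", "amb_temp", "amb_rh", "step_rate"):
        for agg in ("mean", "min", "max", "sd"):
            specs.append(FeatureSpec(f"{sig}_{agg}", f"{sig}_{agg}"))
    specs.append(FeatureSpec("hr_mean_sq", "hr_mean", "poly2"))
    specs.append(FeatureSpec("skin_temp_mean_sq", "skin_temp_mean", "poly2"))
    specs.append(FeatureSpec("hr_x_skin_temp", "hr_mean", "interaction", partner="skin_temp_mean"))
    for sig in ("hr", "skin_temp", "skin_rh"):
        specs.append(FeatureSpec(f"{sig}_roll5", f"{sig}_mean", "rolling_mean", window=5))
    return specs


def _rolling(series: pd.Series, kind: str, window: int) -> pd.Series:
    roll = series.rolling(window, min_periods=window)
    if kind == "rolling_mean":
        return roll.mean()
    if kind == "rolling_min":
        return roll.min()
    if kind == "rolling_max":
        return roll.max()
    if kind == "rolling_median":
        return roll.median()
    if kind == "rolling_sd":
        return roll.std(ddof=1)
    raise AssertionError(kind)


def engineer_features(frame: pd.DataFrame, specs: Sequence[FeatureSpec]) -> pd.DataFrame:
    """Evaluate feature specs against a minute table, one column per spec.

    Rolling transforms are trailing (real-time deployment cannot look
    ahead) and computed within each trial, with NaN for the first
    window - 1 minutes.  Log of a non-positive value yields NaN with a
    warning.
    """
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("feature names must be unique")
    out = pd.DataFrame(index=frame.index)
    by_trial = frame.groupby("trial_id", sort=False) if "trial_id" in frame else None
    for spec in specs:
        if spec.source not in frame.columns:
            raise ValueError(f"{spec.name}: source column {spec.source!r} not in frame")
        x = frame[spec.source].astype(float)
        if spec.transform == "identity":
            col = x
        elif spec.transform == "poly2":
            col = x**2
        elif spec.transform == "poly3":
            col = x**3
        elif spec.transform == "log":
            bad = x <= 0
            if bad.any():
                warnings.warn(f"{spec.name}: log of non-positive value masked ({int(bad.sum())} rows)")
            col = pd.Series(np.where(bad, np.nan, np.log(np.where(bad, 1.0, x))), index=x.index)
        elif spec.transform == "interaction":
            if spec.partner not in frame.columns:
                raise ValueError(f"{spec.name}: partner column {spec.partner!r} not in frame")
            col = x * frame[spec.partner].astype(float)
        else:  # rolling_*
            if by_trial is not None:
                col = by_trial[spec.source].transform(
                    lambda s: _rolling(s.astype(float), spec.transform, spec.window)
                )
            else:
                col = _rolling(x, spec.transform, spec.window)
        out[spec.name] = col
    return out


def compute_vif(matrix: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per feature.

    VIF_j = 1 / (1 - R^2_j) with R^2_j from regressing feature j on all the
    other features plus an intercept.  Perfectly collinear or constant
    features report +inf.
    """
    matrix = matrix.dropna()
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 features for VIF")
    if matrix.shape[0] <= matrix.shape[1]:
        raise ValueError("need more rows than features for VIF")
    out = {}
    for col in matrix.columns:
        y = matrix[col].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            warnings.warn(f"constant feature {col!r}: VIF undefined, reporting +inf")
            out[col] = np.inf
            continue
        x = sm.add_constant(matrix.drop(columns=[col]).to_numpy(dtype=float))
        r2 = sm.OLS(y, x).fit().rsquared
        out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def filter_vif(matrix: pd.DataFrame, threshold: float = 5.0) -> pd.DataFrame:
    """Iteratively drop the highest-VIF feature until all VIF <= threshold.

    Ties on VIF are broken by feature-name order (the alphabetically first
    of the tied features is removed), so the result is reproducible.
    """
    cols = list(matrix.columns)
    while len(cols) >= 2:
        vif = compute_vif(matrix[cols])
        worst = max(vif.max(), 0.0)
        if worst <= threshold:
            break
        tied = sorted(vif.index[vif == worst])
        cols = [c for c in cols if c != tied[0]]
    return matrix[cols]


def backward_select(
    matrix: pd.DataFrame, target: pd.Series, alpha: float = 0.05
) -> tuple[list[str], pd.DataFrame]:
    """Backward elimination on OLS p-values.

    Fits OLS of the target on all features plus an intercept, repeatedly
    drops the largest-p feature with p > alpha, and stops when every
    remaining feature has p <= alpha.  The intercept is never dropped.

    Returns (selected feature names, report of coefficient/p per feature at
    its final fit, with a ``selected`` flag).
    """
    data = pd.concat([matrix, target.rename("__target__")], axis=1).dropna()
    y = data["__target__"].to_numpy(dtype=float)
    cols = list(matrix.columns)
    report_rows = {}
    while cols:
        x = sm.add_constant(data[cols].to_numpy(dtype=float))
        fit = sm.OLS(y, x).fit()
        pvals = pd.Series(fit.pvalues[1:], index=cols)
        coefs = pd.Series(fit.params[1:], index=cols)
        worst = pvals.idxmax()
        if pvals[worst] <= alpha:
            for c in cols:
                report_rows[c] = {"coef": coefs[c], "pvalue": pvals[c], "selected": True}
            break
        report_rows[worst] = {"coef": coefs[worst], "pvalue": pvals[worst], "selected": False}
        cols.remove(worst)
    if not cols:
        warnings.warn("backward selection eliminated every feature")
    report = pd.DataFrame.from_dict(report_rows, orient="index").reindex(matrix.columns)
    report["selected"] = report["selected"].fillna(False).astype(bool)
    return cols, report


def rank_univariate_f(
    matrix: pd.DataFrame, target: pd.Series, k: int
) -> tuple[list[str], pd.Series]:
    """Top-k features by the univariate linear-regression F statistic.

    F_j = r_j^2 (n - 2) / (1 - r_j^2), with r_j the Pearson correlation of
    feature j with the target.  Zero-variance features have undefined F and
    rank last.  Returns (top-k names, F per feature).
    """
    if k > matrix.shape[1]:
        raise ValueError(f"k={k} exceeds feature count {matrix.shape[1]}")
    data = pd.concat([matrix, target.rename("__target__")], axis=1).dropna()
    y = data["__target__"].to_numpy(dtype=float)
    n = len(y)
    fstats = {}
    for col in matrix.columns:
        x = data[col].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            fstats[col] = np.nan
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        fstats[col] = np.inf if abs(r) >= 1.0 else r * r * (n - 2) / (1.0 - r * r)
    f = pd.Series(fstats)
    order = f.sort_values(ascending=False, na_position="last", kind="stable")
    return list(order.index[:k]), f
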