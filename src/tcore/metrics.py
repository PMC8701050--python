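"""Accuracy statistics for estimated vs. reference core temperature.

All statistics follow the trial-then-overall averaging convention: each
metric is computed on a trial's one-minute residuals, then the per-trial
values are averaged *unweighted* across trials (so a 40-min trial counts the
same as a 107-min trial).  Binned analyses assign each minute to a bin
(reference-Tc band, heart-rate zone, ambient-temperature band, reference
device, or sex), compute metrics per trial within the bin, and average
across trials within the bin.

Errors are estimated minus reference, so a positive mean bias means the
estimator overestimates.  Note the "SEM" here is defined as the standard
deviation of a trial's residuals (the definition used in this validation
literature), not the classical standard-error-of-measurement formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import tanaka_hr_max, SubjectProfile

__all__ = [
    "MetricsReport",
    "BinSpec",
    "BlandAltmanData",
    "trial_metrics",
    "aggregate_metrics",
    "hr_zone",
    "binned_metrics",
    "bland_altman",
    "error_histogram",
    "default_bin_specs",
    "HR_ZONE_LABELS",
]

HR_ZONE_LABELS = ("Lighter", "Light", "Moderate", "Vigorous")


@dataclass(frozen=True)
class MetricsReport:
    mae: float  # deg C
    rmse: float  # deg C
    sem: float  # deg C: SD of the residuals
    mape: float  # %
    pearson_r: float  # NaN when undefined (constant series)
    bias: float  # deg C, estimated - reference
    loa_halfwidth: float  # deg C, 1.96 * SD of errors
    n_minutes: int
    n_trials: int = 1
    n_r_defined: int = 1  # trials contributing to the r average

    def as_dict(self) -> dict:
        return {
            "mae": self.mae,
            "rmse": self.rmse,
            "sem": self.sem,
            "mape": self.mape,
            "pearson_r": self.pearson_r,
            "bias": self.bias,
            "loa_halfwidth": self.loa_halfwidth,
            "n_minutes": self.n_minutes,
            "n_trials": self.n_trials,
            "n_r_defined": self.n_r_defined,
        }


@dataclass(frozen=True)
class BinSpec:
    """One binning axis: numeric edges with labels, or a categorical column.

    For numeric axes, bin i covers (edges[i], edges[i+1]] (half-open upward,
    upper endpoint inclusive), matching boundary conventions like
    "<=57", ">57 to <=64".  Values outside every bin fall into an
    ``out_of_range`` bucket when enabled, else are dropped.
    """

    axis: str  # one of gt_tc, hr_zone, ambient_ta, gt_device, sex
    column: str  # column of the prediction table holding the axis value
    edges: Optional[tuple[float, ...]] = None
    labels: tuple[str, ...] = ()
    categorical: bool = False
    out_of_range_bucket: bool = True

    def assign(self, values: pd.Series) -> pd.Series:
        if self.categorical:
            return values.astype(str)
        edges = np.asarray(self.edges, dtype=float)
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        idx = np.searchsorted(edges, values.to_numpy(dtype=float), side="left") - 1
        labels = np.asarray(self.labels, dtype=object)
        out = np.where((idx >= 0) & (idx < len(labels)), labels[np.clip(idx, 0, len(labels) - 1)], None)
        # left edge of the first bin is inclusive
        out = np.where(values.to_numpy(dtype=float) == edges[0], labels[0], out)
        if self.out_of_range_bucket:
            out = np.where(pd.isna(out), "out_of_range", out)
        return pd.Series(out, index=values.index)


@dataclass(frozen=True)
class BlandAltmanData:
    """Modified Bland-Altman data: errors against the reference value."""

    reference: np.ndarray
    errors: np.ndarray
    bias: float
    loa_lower: float
    loa_upper: float


def _core_metrics(pred: np.ndarray, gt: np.ndarray) -> dict:
    """All metric fields over one set of paired minutes; NaN where undefined."""
    err = pred - gt
    n = len(err)
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    bias = float(np.mean(err))
    sem = float(np.std(err, ddof=1)) if n > 1 else np.nan
    mape = float(np.mean(np.abs(err) / gt) * 100.0)
    loa = 1.96 * float(np.std(err, ddof=1)) if n > 1 else np.nan
    if n > 1 and np.ptp(pred) > 0 and np.ptp(gt) > 0:
        r = float(stats.pearsonr(gt, pred).statistic)
    else:
        r = np.nan
    return {
        "mae": mae,
        "rmse": rmse,
        "sem": sem,
        "mape": mape,
        "pearson_r": r,
        "bias": bias,
        "loa_halfwidth": loa,
        "n_minutes": n,
    }


def _paired(df: pd.DataFrame) -> pd.DataFrame:
    """Rows with valid estimate/reference pairs, exclusion flag honoured."""
    ok = np.isfinite(df["tc_hat"]) & np.isfinite(df["tc_gt"])
    if "excluded" in df:
        ok &= ~df["excluded"].astype(bool)
    return df.loc[ok]


def trial_metrics(predictions: pd.DataFrame) -> MetricsReport:
    """Metrics for one trial from its (tc_hat, tc_gt) minute pairs."""
    paired = _paired(predictions)
    if len(paired) < 2:
        raise ValueError("need at least 2 paired minutes for trial metrics")
    vals = _core_metrics(paired["tc_hat"].to_numpy(float), paired["tc_gt"].to_numpy(float))
    return MetricsReport(**vals, n_trials=1, n_r_defined=int(np.isfinite(vals["pearson_r"])))


def aggregate_metrics(reports: Sequence[MetricsReport]) -> MetricsReport:
    """Unweighted mean of each metric across trials; minutes are summed.

    Pearson r is averaged over the trials where it is defined, with that
    count reported in ``n_r_defined``.
    """
    if len(reports) == 0:
        raise ValueError("need at least one trial report")

    def mean_of(name: str) -> float:
        vals = np.array([getattr(r, name) for r in reports], dtype=float)
        vals = vals[np.isfinite(vals)]
        return float(np.mean(vals)) if len(vals) else np.nan

    rs = np.array([r.pearson_r for r in reports], dtype=float)
    return MetricsReport(
        mae=mean_of("mae"),
        rmse=mean_of("rmse"),
        sem=mean_of("sem"),
        mape=mean_of("mape"),
        pearson_r=float(np.mean(rs[np.isfinite(rs)])) if np.any(np.isfinite(rs)) else np.nan,
        bias=mean_of("bias"),
        loa_halfwidth=mean_of("loa_halfwidth"),
        n_minutes=int(sum(r.n_minutes for r in reports)),
        n_trials=len(reports),
        n_r_defined=int(np.sum(np.isfinite(rs))),
    )


def hr_zone(hr_mean: float, age: float) -> str:
    """Heart-rate zone from the percentage of age-predicted maximum HR.

    Lighter <= 57 %, Light > 57 to <= 64 %, Moderate > 64 to <= 75 %,
    Vigorous > 75 % (upper endpoints inclusive).
    """
    if hr_mean <= 0:
        raise ValueError("hr_mean must be positive")
    pct = 100.0 * hr_mean / tanaka_hr_max(age)
    if pct <= 57:
        return "Lighter"
    if pct <= 64:
        return "Light"
    if pct <= 75:
        return "Moderate"
    return "Vigorous"


def default_bin_specs() -> dict[str, BinSpec]:
    """The standard report axes: reference-Tc bands, HR zones, ambient bands,
    reference device, and sex."""
    return {
        "gt_tc": BinSpec(
            axis="gt_tc",
            column="tc_gt",
            edges=(36.2, 37.0, 38.0, 39.0, 40.2),
            labels=("36.2-37.0", ">37.0-38.0", ">38.0-39.0", ">39.0-40.2"),
        ),
        "hr_zone": BinSpec(axis="hr_zone", column="hr_zone", categorical=True),
        "ambient_ta": BinSpec(
            axis="ambient_ta",
            column="amb_temp_mean",
            edges=(-np.inf, 20.0, 30.0, np.inf),
            labels=("<=20.0", "20.1-30.0", ">30.1"),
        ),
        "gt_device": BinSpec(axis="gt_device", column="gt_device", categorical=True),
        "sex": BinSpec(axis="sex", column="sex", categorical=True),
    }


def binned_metrics(predictions: pd.DataFrame, spec: BinSpec) -> pd.DataFrame:
    """Per-bin metrics table with the trial-then-overall averaging rule.

    Each minute is assigned to a bin by its axis value (independent of
    trial); within a bin, metrics are computed per trial over that trial's
    minutes in the bin (single-minute contributions provide MAE/bias/MAPE
    but no r/SD-based metrics), then averaged unweighted across trials.
    Bins with no minutes are emitted with n = 0 and null metrics.
    """
    paired = _paired(predictions)
    if spec.column not in paired.columns:
        raise ValueError(f"bin column {spec.column!r} not in prediction table")
    bins = spec.assign(paired[spec.column])
    if spec.categorical:
        labels = tuple(sorted(bins.dropna().unique()))
    else:
        labels = spec.labels + (("out_of_range",) if spec.out_of_range_bucket else ())
    rows = []
    for label in labels:
        sub = paired.loc[bins == label]
        if len(sub) == 0:
            rows.append({"bin": label, "n_minutes": 0})
            continue
        per_trial = []
        for _, grp in sub.groupby("trial_id", sort=True):
            vals = _core_metrics(grp["tc_hat"].to_numpy(float), grp["tc_gt"].to_numpy(float))
            per_trial.append(
                MetricsReport(**vals, n_trials=1, n_r_defined=int(np.isfinite(vals["pearson_r"])))
            )
        agg = aggregate_metrics(per_trial)
        rows.append({"bin": label, **agg.as_dict()})
    out = pd.DataFrame(rows)
    out["n_minutes"] = out["n_minutes"].fillna(0).astype(int)
    return out


def bland_altman(predictions: pd.DataFrame) -> BlandAltmanData:
    """Modified Bland-Altman data: per-minute errors against the reference Tc
    (not the pair mean), with bias and 95 % limits of agreement pooled over
    all minutes."""
    paired = _paired(predictions)
    if len(paired) < 2:
        raise ValueError("need at least 2 paired minutes")
    gt = paired["tc_gt"].to_numpy(float)
    err = paired["tc_hat"].to_numpy(float) - gt
    bias = float(np.mean(err))
    half = 1.96 * float(np.std(err, ddof=1))
    return BlandAltmanData(
        reference=gt, errors=err, bias=bias, loa_lower=bias - half, loa_upper=bias + half
    )


def error_histogram(predictions: pd.DataFrame) -> tuple[pd.Series, float]:
    """Distribution of per-minute errors rounded to one decimal place.

    Returns (counts per 0.1 deg C bucket, fraction of minutes with
    |error| <= 0.30 deg C).  Rounding is numpy's round-half-even.
    """
    paired = _paired(predictions)
    if len(paired) == 0:
        raise ValueError("need at least one paired minute")
    err = paired["tc_hat"].to_numpy(float) - paired["tc_gt"].to_numpy(float)
    buckets = np.round(err, 1) + 0.0  # normalise -0.0
    counts = pd.Series(buckets).value_counts().sort_index()
    frac = float(np.mean(np.abs(err) <= 0.30 + 1e-12))
    return counts, frac


def add_bin_columns(
    predictions: pd.DataFrame,
    minute_frame: pd.DataFrame,
    profiles: Mapping[str, SubjectProfile],
) -> pd.DataFrame:
    """Join the axis columns needed for binned reports onto predictions.

    Adds hr-zone labels (from each minute's mean HR and the subject's age),
    the minute's ambient temperature, the reference device and the
    subject's sex.
    """
    cols = ["trial_id", "minute", "hr_mean", "amb_temp_mean", "gt_device"]
    merged = predictions.merge(minute_frame[cols], on=["trial_id", "minute"], how="left")
    ages = {sid: p.age for sid, p in profiles.items()}
    sexes = {sid: p.sex for sid, p in profiles.items()}
    merged["sex"] = merged["subject_id"].map(sexes)
    merged["hr_zone"] = [
        hr_zone(hr, ages[sid]) if np.isfinite(hr) else None
        for hr, sid in zip(merged["hr_mean"], merged["subject_id"])
    ]
    return merged
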