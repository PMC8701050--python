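"""Cross-validated training, coefficient averaging and final evaluation.

Models are trained with leave-one-out splitting at either the trial level
(LOOCV: one fold per trial) or the participant level (LOPO: one fold per
subject, holding out all of that subject's trials).  For each fold the
seed regression, observation model and process noise are refitted on the
training trials only, the held-out trial(s) are predicted, and per-trial
metrics recorded.  The overall cross-validated accuracy is the unweighted
mean of the held-out per-trial MAE (and bias).  The final deployed model is
the element-wise average of the per-fold coefficients, then applied to all
trials for the full binned evaluation.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .ekf import EKFModelSpec, EKFParams, ObsChannel, SeedModel, fit_ekf_params, predict_trial
from .metrics import MetricsReport, aggregate_metrics, trial_metrics
from .simulate import SubjectProfile

__all__ = [
    "Fold",
    "CVResult",
    "EKFCandidate",
    "LinearBaseline",
    "split_folds",
    "run_cv",
    "average_params",
    "select_model",
    "evaluate_final",
]


@dataclass
class Fold:
    held_out: tuple[str, ...]  # trial ids in the test set
    params: object = None
    reports: dict[str, MetricsReport] = field(default_factory=dict)
    train_fingerprint: str = ""  # sha256 over the training trial ids
    failed: bool = False
    error: str = ""


@dataclass
class CVResult:
    mode: str
    candidate: str
    folds: list[Fold]
    final_params: object
    overall_mae: float
    overall_bias: float
    overall_rmse: float

    @property
    def held_out_reports(self) -> list[MetricsReport]:
        return [r for f in self.folds if not f.failed for r in f.reports.values()]


def split_folds(frame: pd.DataFrame, mode: str = "loocv_trial") -> list[tuple[str, ...]]:
    """Deterministic fold plan: held-out trial-id groups, ordered by id.

    ``loocv_trial`` leaves out one trial per fold; ``lopo_subject`` leaves
    out all trials of one subject per fold.  Every trial appears in exactly
    one held-out set.
    """
    if mode == "loocv_trial":
        groups = [(tid,) for tid in sorted(frame["trial_id"].unique())]
    elif mode == "lopo_subject":
        bysub = frame.groupby("subject_id")["trial_id"].unique()
        groups = [tuple(sorted(bysub[s])) for s in sorted(bysub.index)]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to cross-validate")
    return groups


# ---------------------------------------------------------------------------
# candidates


class EKFCandidate:
    """The extended Kalman filter candidate: fit, predict, average."""

    def __init__(self, spec: EKFModelSpec):
        self.spec = spec
        self.name = spec.name

    def fit(self, frame: pd.DataFrame, profiles: Mapping[str, SubjectProfile]) -> EKFParams:
        return fit_ekf_params(frame, profiles, self.spec)

    def predict(
        self, frame: pd.DataFrame, profiles: Mapping[str, SubjectProfile], params: EKFParams
    ) -> pd.DataFrame:
        out = []
        for tid, grp in frame.groupby("trial_id", sort=True):
            out.append(predict_trial(grp, params, profiles[grp["subject_id"].iloc[0]]))
        return pd.concat(out, ignore_index=True)

    @staticmethod
    def average(params_list: Sequence[EKFParams]) -> EKFParams:
        return average_params(params_list)


class LinearBaseline:
    """Plain multiple linear regression of Tc on minute features.

    Kept as the reference point in the model-selection harness; predicts
    each minute independently with no state.
    """

    def __init__(self, feature_cols: Sequence[str], name: str = "linear_baseline"):
        self.feature_cols = tuple(feature_cols)
        self.name = name

    def fit(self, frame: pd.DataFrame, profiles=None) -> np.ndarray:
        valid = frame.loc[np.isfinite(frame["tc_gt"])]
        x = valid[list(self.feature_cols)].to_numpy(dtype=float)
        ok = np.all(np.isfinite(x), axis=1)
        x = np.column_stack([np.ones(ok.sum()), x[ok]])
        y = valid["tc_gt"].to_numpy(dtype=float)[ok]
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        return beta

    def predict(self, frame: pd.DataFrame, profiles, params: np.ndarray) -> pd.DataFrame:
        x = frame[list(self.feature_cols)].to_numpy(dtype=float)
        tc_hat = params[0] + x @ params[1:]
        return pd.DataFrame(
            {
                "trial_id": frame["trial_id"].to_numpy(),
                "subject_id": frame["subject_id"].to_numpy(),
                "minute": frame["minute"].to_numpy(),
                "tc_hat": tc_hat,
                "variance": np.nan,
                "tc_gt": frame["tc_gt"].to_numpy(),
                "excluded": frame["excluded"].to_numpy() if "excluded" in frame else False,
            }
        )

    @staticmethod
    def average(params_list: Sequence[np.ndarray]) -> np.ndarray:
        return np.mean(np.vstack(params_list), axis=0)


# ---------------------------------------------------------------------------
# cross-validation


def _fingerprint(trial_ids: Sequence[str]) -> str:
    return hashlib.sha256("|".join(sorted(trial_ids)).encode()).hexdigest()


def run_cv(
    frame: pd.DataFrame,
    profiles: Mapping[str, SubjectProfile],
    candidate,
    plan: Sequence[tuple[str, ...]],
    mode: str = "loocv_trial",
) -> CVResult:
    """Fit/test the candidate on every fold and average the coefficients.

    Per fold: fit on the training trials only (the held-out trials never
    touch the fitted parameters; the training-set fingerprint is recorded so
    leakage is checkable), predict the held-out trial(s), record per-trial
    metrics.  Overall accuracy = unweighted mean of held-out per-trial MAE
    and bias.  Failed folds are excluded from the coefficient average with a
    warning.
    """
    all_ids = set(frame["trial_id"].unique())
    folds: list[Fold] = []
    for held in plan:
        train_ids = sorted(all_ids - set(held))
        fold = Fold(held_out=tuple(held), train_fingerprint=_fingerprint(train_ids))
        train = frame.loc[frame["trial_id"].isin(train_ids)]
        try:
            fold.params = candidate.fit(train, profiles)
            test = frame.loc[frame["trial_id"].isin(held)]
            preds = candidate.predict(test, profiles, fold.params)
            for tid, grp in preds.groupby("trial_id", sort=True):
                fold.reports[str(tid)] = trial_metrics(grp)
        except Exception as exc:  # noqa: BLE001 - fold failures are surfaced, not fatal
            fold.failed = True
            fold.error = str(exc)
            warnings.warn(f"fold {held} failed: {exc}")
        folds.append(fold)

    good = [f for f in folds if not f.failed]
    if not good:
        raise RuntimeError("every cross-validation fold failed")
    reports = [r for f in good for r in f.reports.values()]
    final = candidate.average([f.params for f in good])
    return CVResult(
        mode=mode,
        candidate=candidate.name,
        folds=folds,
        final_params=final,
        overall_mae=float(np.mean([r.mae for r in reports])),
        overall_bias=float(np.mean([r.bias for r in reports])),
        overall_rmse=float(np.mean([r.rmse for r in reports])),
    )


def average_params(params_list: Sequence[EKFParams]) -> EKFParams:
    """Element-wise arithmetic mean of every coefficient across folds.

    All folds must share the same structure (channel names and polynomial
    degrees, drift feature names); a mismatch is an error.
    """
    if len(params_list) == 0:
        raise ValueError("nothing to average")
    first = params_list[0]
    for p in params_list[1:]:
        if p.structure() != first.structure():
            raise ValueError("cannot average structurally different parameter sets")
    n = len(params_list)
    seed = SeedModel(
        b0=sum(p.seed.b0 for p in params_list) / n,
        b_female=sum(p.seed.b_female for p in params_list) / n,
    )
    channels = []
    for i, ch in enumerate(first.channels):
        coeffs = tuple(
            sum(p.channels[i].coeffs[k] for p in params_list) / n for k in range(len(ch.coeffs))
        )
        r = sum(p.channels[i].r for p in params_list) / n
        channels.append(ObsChannel(name=ch.name, coeffs=coeffs, r=r))
    drift = {k: sum(p.drift[k] for p in params_list) / n for k in first.drift}
    return EKFParams(
        seed=seed,
        channels=tuple(channels),
        drift=drift,
        q=sum(p.q for p in params_list) / n,
        bias_offset=sum(p.bias_offset for p in params_list) / n,
        init_variance=sum(p.init_variance for p in params_list) / n,
    )


def select_model(
    candidates: Sequence,
    frame: pd.DataFrame,
    profiles: Mapping[str, SubjectProfile],
    mode: str = "loocv_trial",
    mae_criterion: float = 0.3,
) -> tuple[pd.DataFrame, CVResult]:
    """Rank candidates by cross-validated MAE; the best model has the lowest.

    Ties are broken by RMSE, then by candidate name.  Candidates meeting the
    MAE <= 0.3 deg C design criterion are flagged.  Returns the ranking
    table and the winning candidate's CVResult.
    """
    if len(candidates) == 0:
        raise ValueError("need at least one candidate")
    plan = split_folds(frame, mode)
    results = {c.name: run_cv(frame, profiles, c, plan, mode) for c in candidates}
    rows = [
        {
            "candidate": name,
            "cv_mae": res.overall_mae,
            "cv_rmse": res.overall_rmse,
            "cv_bias": res.overall_bias,
            "meets_mae_criterion": res.overall_mae <= mae_criterion,
        }
        for name, res in results.items()
    ]
    table = (
        pd.DataFrame(rows)
        .sort_values(["cv_mae", "cv_rmse", "candidate"], kind="stable")
        .reset_index(drop=True)
    )
    winner = results[table["candidate"].iloc[0]]
    return table, winner


def evaluate_final(
    candidate,
    params,
    frame: pd.DataFrame,
    profiles: Mapping[str, SubjectProfile],
    bin_specs: Optional[dict] = None,
) -> dict:
    """Apply the final (averaged) model to every trial and compute the full
    report: overall metrics, per-axis binned tables, Bland-Altman data and
    the error histogram."""
    preds = candidate.predict(frame, profiles, params)
    per_trial = [trial_metrics(grp) for _, grp in preds.groupby("trial_id", sort=True)]
    overall = aggregate_metrics(per_trial)
    enriched = _metrics.add_bin_columns(preds, frame, profiles)
    specs = bin_specs if bin_specs is not None else _metrics.default_bin_specs()
    binned = {axis: _metrics.binned_metrics(enriched, spec) for axis, spec in specs.items()}
    ba = _metrics.bland_altman(preds)
    hist, frac = _metrics.error_histogram(preds)
    return {
        "predictions": preds,
        "overall": overall,
        "binned": binned,
        "bland_altman": ba,
        "error_histogram": hist,
        "frac_within_0p30": frac,
    }
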