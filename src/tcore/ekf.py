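"""Scalar-state extended Kalman filter for core body temperature.

The hidden state is core temperature Tc (deg C).  Each minute the filter
runs a time update (an optional learned drift on exogenous minute features,
or a pure random walk) followed by sequential scalar measurement updates,
one per observation channel.  Each channel's observation model is a
polynomial in Tc (degree <= 2) fitted to training data, linearized at the
prior estimate; channel noise variances come from the fit residuals.  The
initial estimate is seeded from a separate linear regression in which
biological sex is the sole input, and an optional additive bias offset lets
the deployed estimator deliberately err on the side of overestimation (an
alert that fires slightly early is safer than one that fires late).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .simulate import SubjectProfile

__all__ = [
    "SeedModel",
    "ObsChannel",
    "EKFParams",
    "EKFModelSpec",
    "EKFState",
    "seed_tc",
    "fit_seed_regression",
    "fit_observation_model",
    "fit_process_model",
    "fit_ekf_params",
    "ekf_predict",
    "ekf_update",
    "predict_trial",
    "save_params",
    "load_params",
]

PARAMS_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class SeedModel:
    """Initial-estimate regression: Tc0 = b0 + b_female * 1[sex == female]."""

    b0: float  # deg C
    b_female: float  # deg C


@dataclass(frozen=True)
class ObsChannel:
    """One observation channel: z = poly(Tc) + noise, Var(noise) = r."""

    name: str  # resolves against a minute-table column
    coeffs: tuple[float, ...]  # polynomial coefficients, ascending degree
    r: float  # measurement-noise variance, (channel units)^2

    def __post_init__(self) -> None:
        object.__setattr__(self, "coeffs", tuple(float(c) for c in self.coeffs))
        if not (1 <= len(self.coeffs) <= 3):
            raise ValueError(f"{self.name}: polynomial degree must be <= 2")
        if self.r <= 0:
            raise ValueError(f"{self.name}: measurement-noise variance must be > 0")

    def h(self, tc: float) -> float:
        return float(np.polynomial.polynomial.polyval(tc, np.asarray(self.coeffs)))

    def jacobian(self, tc: float) -> float:
        c = self.coeffs
        out = 0.0
        for k in range(1, len(c)):
            out += k * c[k] * tc ** (k - 1)
        return float(out)


@dataclass(frozen=True)
class EKFParams:
    """Complete coefficient set of the estimator."""

    seed: SeedModel
    channels: tuple[ObsChannel, ...]
    drift: dict[str, float] = field(default_factory=dict)  # degC/min per unit
    q: float = 1e-4  # process-noise variance, degC^2 per minute
    bias_offset: float = 0.0  # deg C added to emitted estimates
    init_variance: float = 0.25  # degC^2

    def __post_init__(self) -> None:
        object.__setattr__(self, "channels", tuple(self.channels))
        object.__setattr__(self, "drift", dict(self.drift))
        if self.q <= 0:
            raise ValueError("process-noise variance q must be > 0")
        if self.init_variance <= 0:
            raise ValueError("init_variance must be > 0")
        if len(self.channels) == 0:
            raise ValueError("need at least one observation channel")

    def structure(self) -> tuple:
        """Hashable structural signature used to check averaging compatibility."""
        return (
            tuple((c.name, len(c.coeffs)) for c in self.channels),
            tuple(sorted(self.drift)),
        )


@dataclass(frozen=True)
class EKFModelSpec:
    """Structural description of an EKF candidate (what to fit, not values)."""

    name: str = "ekf"
    channels: tuple[tuple[str, int], ...] = (
        ("hr_mean", 2),
        ("skin_temp_mean", 1),
        ("skin_rh_mean", 1),
    )
    drift_features: tuple[str, ...] = ()
    bias_offset: float = 0.0
    init_variance: float = 0.25


@dataclass
class EKFState:
    tc_hat: float  # deg C
    variance: float  # degC^2
    minute_index: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.tc_hat):
            raise ValueError("tc_hat must be finite")
        if self.variance <= 0:
            raise ValueError("variance must be > 0")


# ---------------------------------------------------------------------------
# fitting


def seed_tc(profile: SubjectProfile, params: EKFParams) -> float:
    """Initial core-temperature estimate from the sex-only seed regression."""
    return params.seed.b0 + params.seed.b_female * (profile.sex == "female")


def _first_measured_tc(frame: pd.DataFrame) -> pd.DataFrame:
    """Per trial: first valid reference Tc and the subject id."""
    rows = []
    for trial_id, grp in frame.groupby("trial_id", sort=True):
        valid = grp.loc[np.isfinite(grp["tc_gt"])]
        if len(valid):
            rows.append(
                {
                    "trial_id": trial_id,
                    "subject_id": valid["subject_id"].iloc[0],
                    "tc0": float(valid["tc_gt"].iloc[0]),
                }
            )
    return pd.DataFrame(rows)


def fit_seed_regression(
    frame: pd.DataFrame, profiles: Mapping[str, SubjectProfile]
) -> SeedModel:
    """OLS of each trial's first measured reference Tc on a female indicator.

    With a single-sex training set the intercept-only model is fitted and
    b_female set to 0 (with a warning).
    """
    first = _first_measured_tc(frame)
    if len(first) == 0:
        raise ValueError("no trials with valid reference temperature")
    female = np.array(
        [profiles[s].sex == "female" for s in first["subject_id"]], dtype=float
    )
    y = first["tc0"].to_numpy()
    if len(np.unique(female)) < 2:
        warnings.warn("single-sex training set: fitting intercept-only seed model")
        return SeedModel(b0=float(np.mean(y)), b_female=0.0)
    x = np.column_stack([np.ones_like(female), female])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return SeedModel(b0=float(beta[0]), b_female=float(beta[1]))


def fit_observation_model(
    frame: pd.DataFrame, channel_specs: Sequence[tuple[str, int]]
) -> tuple[ObsChannel, ...]:
    """Least-squares polynomial fit of each channel on the reference Tc.

    ``channel_specs`` is a sequence of (minute-table column, polynomial
    degree).  The channel noise variance r is the residual variance of the
    fit (ddof = number of coefficients).
    """
    valid = frame.loc[np.isfinite(frame["tc_gt"])]
    tc = valid["tc_gt"].to_numpy(dtype=float)
    if np.ptp(tc) < 1e-9:
        raise ValueError("degenerate fit: reference Tc range is (near) constant")
    channels = []
    for name, degree in channel_specs:
        if name not in valid.columns:
            raise ValueError(f"channel column {name!r} not in minute table")
        z = valid[name].to_numpy(dtype=float)
        ok = np.isfinite(z)
        coeffs = np.polynomial.polynomial.polyfit(tc[ok], z[ok], degree)
        resid = z[ok] - np.polynomial.polynomial.polyval(tc[ok], coeffs)
        dof = max(len(resid) - (degree + 1), 1)
        r = float(np.sum(resid**2) / dof)
        channels.append(ObsChannel(name=name, coeffs=tuple(coeffs), r=max(r, 1e-12)))
    return tuple(channels)


def fit_process_model(
    frame: pd.DataFrame, drift_features: Sequence[str] = ()
) -> tuple[dict[str, float], float]:
    """Fit the per-minute drift coefficients and process-noise variance.

    Regresses the minute-to-minute change in reference Tc on the named
    exogenous features (current minute's values); with no drift features the
    model is a random walk and q is the variance of the Tc increments.
    """
    dys, us = [], []
    for _, grp in frame.groupby("trial_id", sort=True):
        grp = grp.loc[np.isfinite(grp["tc_gt"])]
        if len(grp) < 2:
            continue
        dy = np.diff(grp["tc_gt"].to_numpy(dtype=float))
        dys.append(dy)
        if drift_features:
            us.append(grp[list(drift_features)].to_numpy(dtype=float)[1:])
    if not dys:
        raise ValueError("not enough data to fit the process model")
    dy = np.concatenate(dys)
    if not drift_features:
        return {}, max(float(np.var(dy)), 1e-8)
    u = np.vstack(us)
    ok = np.all(np.isfinite(u), axis=1) & np.isfinite(dy)
    beta, *_ = np.linalg.lstsq(u[ok], dy[ok], rcond=None)
    resid = dy[ok] - u[ok] @ beta
    q = max(float(np.var(resid)), 1e-8)
    return dict(zip(drift_features, map(float, beta))), q


def fit_ekf_params(
    frame: pd.DataFrame,
    profiles: Mapping[str, SubjectProfile],
    spec: EKFModelSpec,
) -> EKFParams:
    """Fit every component of the estimator on a training minute table."""
    seed = fit_seed_regression(frame, profiles)
    channels = fit_observation_model(frame, spec.channels)
    drift, q = fit_process_model(frame, spec.drift_features)
    return EKFParams(
        seed=seed,
        channels=channels,
        drift=drift,
        q=q,
        bias_offset=spec.bias_offset,
        init_variance=spec.init_variance,
    )


# ---------------------------------------------------------------------------
# filtering


def ekf_predict(state: EKFState, params: EKFParams, exogenous: Mapping[str, float]) -> EKFState:
    """Time update: tc <- tc + a . u, var <- var + q.

    With no drift coefficients the model is a random walk.  A named drift
    feature missing from ``exogenous`` is an error.
    """
    tc = state.tc_hat
    for name, a in params.drift.items():
        if name not in exogenous:
            raise KeyError(f"drift feature {name!r} missing from exogenous inputs")
        u = exogenous[name]
        if np.isfinite(u):
            tc += a * u
    return EKFState(tc_hat=tc, variance=state.variance + params.q, minute_index=state.minute_index)


def ekf_update(state: EKFState, observations: Mapping[str, float], params: EKFParams) -> EKFState:
    """Sequential scalar measurement updates, one per available channel.

    Channels missing (or NaN) are skipped; with every channel missing the
    state passes through unchanged.  For each channel j with linearization
    H = dh/dTc at the current estimate: K = var H / (H^2 var + r),
    tc <- tc + K (z - h(tc)), var <- (1 - K H) var.
    """
    tc, var = state.tc_hat, state.variance
    for ch in params.channels:
        z = observations.get(ch.name, np.nan)
        if not np.isfinite(z):
            continue
        h = ch.h(tc)
        H = ch.jacobian(tc)
        s = H * H * var + ch.r
        k = var * H / s
        tc = tc + k * (z - h)
        var = max((1.0 - k * H) * var, 1e-12)
    return EKFState(tc_hat=tc, variance=var, minute_index=state.minute_index)


def predict_trial(
    frame: pd.DataFrame, params: EKFParams, profile: SubjectProfile
) -> pd.DataFrame:
    """Run the filter over one trial's minute table, causally, one estimate
    per minute.

    The state is initialized from the sex-seeded regression with the
    configured initial variance, then each minute runs a time update
    followed by the measurement update with that minute's aggregates.
    ``bias_offset`` is added to the *emitted* estimates only, leaving the
    internal state untouched.  Carries the reference Tc and exclusion flag
    through for downstream metrics.
    """
    if len(frame) == 0:
        raise ValueError("empty minute table")
    state = EKFState(tc_hat=seed_tc(profile, params), variance=params.init_variance)
    rows = []
    for _, row in frame.sort_values("minute").iterrows():
        obs = {ch.name: row.get(ch.name, np.nan) for ch in params.channels}
        exog = {name: row.get(name, np.nan) for name in params.drift}
        state = ekf_predict(state, params, exog)
        state = ekf_update(state, obs, params)
        state.minute_index = int(row["minute"])
        rows.append(
            {
                "trial_id": row["trial_id"],
                "subject_id": row["subject_id"],
                "minute": int(row["minute"]),
                "tc_hat": state.tc_hat + params.bias_offset,
                "variance": state.variance,
                "tc_gt": row.get("tc_gt", np.nan),
                "excluded": bool(row.get("excluded", False)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# (de)serialization


def params_to_dict(params: EKFParams) -> dict:
    return {
        "schema_version": PARAMS_SCHEMA_VERSION,
        "seed": {"b0": params.seed.b0, "b_female": params.seed.b_female},
        "channels": [
            {"name": c.name, "coeffs": list(c.coeffs), "r": c.r} for c in params.channels
        ],
        "drift": dict(params.drift),
        "q": params.q,
        "bias_offset": params.bias_offset,
        "init_variance": params.init_variance,
    }


def params_from_dict(d: dict) -> EKFParams:
    return EKFParams(
        seed=SeedModel(**d["seed"]),
        channels=tuple(
            ObsChannel(name=c["name"], coeffs=tuple(c["coeffs"]), r=c["r"])
            for c in d["channels"]
        ),
        drift={k: float(v) for k, v in d.get("drift", {}).items()},
        q=d["q"],
        bias_offset=d.get("bias_offset", 0.0),
        init_variance=d.get("init_variance", 0.25),
    )


def save_params(params: EKFParams, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(params_to_dict(params), indent=2))
    return path


def load_params(path: str | Path) -> EKFParams:
    return params_from_dict(json.loads(Path(path).read_text()))
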