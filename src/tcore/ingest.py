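"""Parsing of trial CSVs and one-minute alignment/aggregation.

The wearable's streams arrive at mixed rates (1 Hz for heart rate and step
rate, 0.2 Hz for the temperature/humidity channels) and the reference core
temperature anywhere from every 5 s to every 300 s, so all modelling is done
on a one-minute grid: each complete minute gets the mean/min/max/median/SD/
count of every signal plus a reference core temperature, interpolated to the
minute when the reference instrument is slower than once a minute.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .simulate import RawTrial, STREAM_CADENCE_S, GT_DEVICES

__all__ = [
    "SIGNALS",
    "AGGREGATES",
    "parse_trial",
    "align_and_aggregate",
    "interpolate_ground_truth",
    "aggregate_cohort",
    "write_minutes",
]

SIGNALS = ("hr", "step_rate", "skin_temp", "amb_temp", "skin_rh", "amb_rh")
AGGREGATES = ("mean", "min", "max", "median", "sd", "count")

#: a minute missing more than half of a signal's expected samples is flagged
INCOMPLETE_FRACTION = 0.5


def parse_trial(
    streams_path: str | Path,
    gt_path: str | Path,
    subject_id: Optional[str] = None,
) -> RawTrial:
    """Read the ``*_streams.csv`` / ``*_gt.csv`` pair back into a RawTrial.

    Validates column layout, strictly increasing timestamps per signal, and
    stream cadences.  The trial id is the file stem up to ``_streams``.
    """
    streams_path, gt_path = Path(streams_path), Path(gt_path)
    df = pd.read_csv(streams_path)
    expected = {"t_s", "signal", "value"}
    if set(df.columns) != expected:
        raise ValueError(f"{streams_path}: expected columns {sorted(expected)}, got {list(df.columns)}")
    if df["value"].isna().any():
        bad = int(df.index[df["value"].isna()][0]) + 2  # header + 0-base
        raise ValueError(f"{streams_path}: malformed row at line {bad}")
    streams = {}
    for name, grp in df.groupby("signal", sort=True):
        arr = grp[["t_s", "value"]].to_numpy(dtype=float)
        if np.any(np.diff(arr[:, 0]) <= 0):
            raise ValueError(f"{streams_path}: duplicated or non-monotone timestamps in {name}")
        streams[str(name)] = arr

    gt_df = pd.read_csv(gt_path)
    if not {"t_s", "tc_c", "device"}.issubset(gt_df.columns):
        raise ValueError(f"{gt_path}: expected columns t_s, tc_c, device")
    if len(gt_df) == 0:
        raise ValueError(f"{gt_path}: no ground truth")
    device = str(gt_df["device"].iloc[0])
    if device not in GT_DEVICES:
        raise ValueError(f"{gt_path}: unknown ground-truth device {device!r}")

    trial_id = streams_path.stem.removesuffix("_streams")
    trial = RawTrial(
        trial_id=trial_id,
        subject_id=subject_id if subject_id is not None else trial_id,
        streams=streams,
        ground_truth=gt_df[["t_s", "tc_c"]].to_numpy(dtype=float),
        gt_device=device,
    )
    return trial.validate()


def interpolate_ground_truth(gt: np.ndarray, n_minutes: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-minute reference core temperature from an (n, 2) (t, tc) series.

    When the sampling interval exceeds 60 s, values are linearly interpolated
    at each minute midpoint (t = 60 m + 30); with sampling at or faster than
    once a minute, each minute takes the mean of its samples.  Minutes not
    covered by the reference span are NaN (no extrapolation).

    Returns (tc per minute, interpolated flag per minute).
    """
    gt = np.asarray(gt, dtype=float)
    if len(gt) < 2:
        raise ValueError("need at least 2 ground-truth samples")
    t, tc = gt[:, 0], gt[:, 1]
    interval = float(np.median(np.diff(t)))
    out = np.full(n_minutes, np.nan)
    flags = np.zeros(n_minutes, dtype=bool)
    if interval > 60.0:
        mid = 60.0 * np.arange(n_minutes) + 30.0
        inside = (mid >= t[0]) & (mid <= t[-1])
        out[inside] = np.interp(mid[inside], t, tc)
        flags[:] = inside  # every in-span value is an interpolated one
        flags &= inside
    else:
        for m in range(n_minutes):
            sel = (t >= 60.0 * m) & (t < 60.0 * (m + 1))
            if np.any(sel):
                out[m] = float(np.mean(tc[sel]))
    return out, flags


def align_and_aggregate(trial: RawTrial) -> pd.DataFrame:
    """Build the one-minute modelling table for one trial.

    Minute m covers the half-open window [60 m, 60 (m + 1)) seconds.
    Trailing partial minutes are dropped; a minute missing more than half of
    any signal's expected samples is flagged ``incomplete``; minutes without
    a valid reference temperature are flagged ``excluded`` (kept for
    prediction, ignored by accuracy metrics).
    """
    ends = [arr[-1, 0] + STREAM_CADENCE_S[name] for name, arr in trial.streams.items()]
    n_minutes = int(min(ends) // 60)
    if n_minutes < 1:
        raise ValueError(f"trial {trial.trial_id} shorter than one minute")

    cols: dict[str, np.ndarray] = {}
    incomplete = np.zeros(n_minutes, dtype=bool)
    for name, arr in trial.streams.items():
        t, v = arr[:, 0], arr[:, 1]
        minute = (t // 60).astype(int)
        keep = minute < n_minutes
        minute, v = minute[keep], v[keep]
        expected = 60 // STREAM_CADENCE_S[name]
        agg = {a: np.full(n_minutes, np.nan) for a in AGGREGATES}
        for m in range(n_minutes):
            vals = v[minute == m]
            agg["count"][m] = len(vals)
            if len(vals) == 0:
                incomplete[m] = True
                continue
            agg["mean"][m] = vals.mean()
            agg["min"][m] = vals.min()
            agg["max"][m] = vals.max()
            agg["median"][m] = np.median(vals)
            agg["sd"][m] = vals.std(ddof=1) if len(vals) > 1 else 0.0
            if len(vals) < INCOMPLETE_FRACTION * expected:
                incomplete[m] = True
        for a in AGGREGATES:
            cols[f"{name}_{a}"] = agg[a]

    tc, interp = interpolate_ground_truth(trial.ground_truth, n_minutes)
    frame = pd.DataFrame(cols)
    frame.insert(0, "trial_id", trial.trial_id)
    frame.insert(1, "subject_id", trial.subject_id)
    frame.insert(2, "minute", np.arange(n_minutes))
    frame.insert(3, "elapsed_min", np.arange(n_minutes, dtype=float))
    frame["tc_gt"] = tc
    frame["tc_gt_interpolated"] = interp
    frame["gt_device"] = trial.gt_device
    frame["incomplete"] = incomplete
    frame["excluded"] = ~np.isfinite(tc)
    return frame


def aggregate_cohort(trials, profiles=None) -> pd.DataFrame:
    """Concatenate per-trial minute tables into one cohort-level table."""
    frames = [align_and_aggregate(t) for t in trials]
    return pd.concat(frames, ignore_index=True)


def write_minutes(frame: pd.DataFrame, path: str | Path) -> Path:
    """Serialize a minute table as CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
    return path
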