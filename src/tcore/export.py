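"""Firmware-style coefficient export.

Before a model ships to device firmware its coefficients are reduced to
five decimal places (truncation toward zero by default, ordinary half-even
rounding available), the full accuracy evaluation is re-run with the rounded
coefficients to confirm nothing moved, and the result is written as a flat,
versioned coefficient table a firmware build can consume.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from decimal import ROUND_DOWN, ROUND_HALF_EVEN, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ekf import EKFParams, ObsChannel, SeedModel
from .traincv import evaluate_final

__all__ = [
    "round_params",
    "verify_rounding",
    "write_coefficient_table",
    "read_coefficient_table",
    "TABLE_SCHEMA_VERSION",
]

TABLE_SCHEMA_VERSION = 1

_MODES = {"truncate_toward_zero": ROUND_DOWN, "half_even": ROUND_HALF_EVEN}


def _round_scalar(x: float, places: int, mode: str) -> float:
    quantum = Decimal(1).scaleb(-places)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=_MODES[mode]))


def round_params(
    params: EKFParams, places: int = 5, mode: str = "truncate_toward_zero"
) -> EKFParams:
    """Round every scalar coefficient to ``places`` decimal digits.

    The default mode truncates toward zero ("rounds down" in magnitude);
    ``half_even`` gives ordinary rounding.  Idempotent, structure-preserving.
    """
    if places < 0:
        raise ValueError("places must be >= 0")
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {sorted(_MODES)}")

    def rnd(x: float) -> float:
        return _round_scalar(x, places, mode)

    return EKFParams(
        seed=SeedModel(b0=rnd(params.seed.b0), b_female=rnd(params.seed.b_female)),
        channels=tuple(
            ObsChannel(
                name=c.name,
                coeffs=tuple(rnd(v) for v in c.coeffs),
                r=max(rnd(c.r), 10.0**-places),
            )
            for c in params.channels
        ),
        drift={k: rnd(v) for k, v in params.drift.items()},
        q=max(rnd(params.q), 10.0**-places),
        bias_offset=rnd(params.bias_offset),
        init_variance=max(rnd(params.init_variance), 10.0**-places),
    )


def verify_rounding(
    original: EKFParams,
    rounded: EKFParams,
    candidate,
    frame: pd.DataFrame,
    profiles: Mapping,
    tolerance: float = 0.005,
) -> dict:
    """Re-run the full evaluation with original and rounded coefficients.

    Reports the per-metric deltas (rounded minus original) on the overall
    metrics and flags failure when |delta MAE| exceeds ``tolerance`` deg C.
    """
    if original.structure() != rounded.structure():
        raise ValueError("original and rounded parameter sets differ structurally")
    ev_orig = evaluate_final(candidate, original, frame, profiles)
    ev_round = evaluate_final(candidate, rounded, frame, profiles)
    o, r = ev_orig["overall"].as_dict(), ev_round["overall"].as_dict()
    deltas = {k: r[k] - o[k] for k in o if isinstance(o[k], float)}
    return {
        "original": o,
        "rounded": r,
        "deltas": deltas,
        "tolerance_mae": tolerance,
        "passed": abs(deltas["mae"]) <= tolerance,
    }


def _flatten(params: EKFParams) -> list[tuple[str, float, str]]:
    rows = [
        ("seed.b0", params.seed.b0, "degC"),
        ("seed.b_female", params.seed.b_female, "degC"),
        ("q", params.q, "degC^2"),
        ("bias_offset", params.bias_offset, "degC"),
        ("init_variance", params.init_variance, "degC^2"),
    ]
    for k in sorted(params.drift):
        rows.append((f"drift.{k}", params.drift[k], "degC/min per unit"))
    for ch in params.channels:
        for i, c in enumerate(ch.coeffs):
            rows.append((f"obs.{ch.name}.c{i}", c, f"units/degC^{i}"))
        rows.append((f"obs.{ch.name}.r", ch.r, "units^2"))
    return rows


def write_coefficient_table(params: EKFParams, path: str | Path) -> Path:
    """Flat, deterministic CSV of named coefficients for embedded consumption.

    Columns: name, value, units, schema_version.  Values are written with
    ``repr`` so the table round-trips losslessly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "value", "units", "schema_version"])
        for name, value, units in _flatten(params):
            writer.writerow([name, repr(float(value)), units, TABLE_SCHEMA_VERSION])
    return path


def read_coefficient_table(path: str | Path) -> EKFParams:
    """Reconstruct an EKFParams from a coefficient table CSV."""
    df = pd.read_csv(path)
    vals = dict(zip(df["name"], df["value"].astype(float)))
    drift = {n.removeprefix("drift."): v for n, v in vals.items() if n.startswith("drift.")}
    chans: dict[str, dict] = {}
    order: list[str] = []
    for n, v in vals.items():
        if not n.startswith("obs."):
            continue
        ch_name, part = n.removeprefix("obs.").rsplit(".", 1)
        if ch_name not in chans:
            chans[ch_name] = {}
            order.append(ch_name)  # preserve written channel order
        chans[ch_name][part] = v
    channels = []
    for name in order:
        parts = chans[name]
        coeffs = tuple(parts[f"c{i}"] for i in range(sum(1 for p in parts if p.startswith("c"))))
        channels.append(ObsChannel(name=name, coeffs=coeffs, r=parts["r"]))
    return EKFParams(
        seed=SeedModel(b0=vals["seed.b0"], b_female=vals["seed.b_female"]),
        channels=tuple(channels),
        drift=drift,
        q=vals["q"],
        bias_offset=vals.get("bias_offset", 0.0),
        init_variance=vals.get("init_variance", 0.25),
    )
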