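"""Independent brute-force reimplementations used only as test oracles.

Everything here is written as plain loops over minutes, deliberately
avoiding the package's own metric code paths.
"""

import math

import numpy as np


def naive_trial_metrics(pred, gt):
    errs = [p - g for p, g in zip(pred, gt)]
    n = len(errs)
    mae = sum(abs(e) for e in errs) / n
    rmse = math.sqrt(sum(e * e for e in errs) / n)
    bias = sum(errs) / n
    mape = sum(abs(e) / g for e, g in zip(errs, gt)) / n * 100.0
    if n > 1:
        sd = math.sqrt(sum((e - bias) ** 2 for e in errs) / (n - 1))
    else:
        sd = float("nan")
    # pearson r by the textbook formula
    mp, mg = sum(pred) / n, sum(gt) / n
    sp = math.sqrt(sum((p - mp) ** 2 for p in pred))
    sg = math.sqrt(sum((g - mg) ** 2 for g in gt))
    if n > 1 and sp > 0 and sg > 0:
        r = sum((p - mp) * (g - mg) for p, g in zip(pred, gt)) / (sp * sg)
    else:
        r = float("nan")
    return {
        "mae": mae,
        "rmse": rmse,
        "sem": sd,
        "mape": mape,
        "pearson_r": r,
        "bias": bias,
        "loa_halfwidth": 1.96 * sd if n > 1 else float("nan"),
        "n_minutes": n,
    }


def naive_aggregate(per_trial_dicts):
    keys = ("mae", "rmse", "sem", "mape", "pearson_r", "bias", "loa_halfwidth")
    out = {}
    for k in keys:
        vals = [d[k] for d in per_trial_dicts if not math.isnan(d[k])]
        out[k] = sum(vals) / len(vals) if vals else float("nan")
    out["n_minutes"] = sum(d["n_minutes"] for d in per_trial_dicts)
    return out


def naive_bland_altman(pred, gt):
    errs = [p - g for p, g in zip(pred, gt)]
    n = len(errs)
    bias = sum(errs) / n
    sd = math.sqrt(sum((e - bias) ** 2 for e in errs) / (n - 1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def naive_kalman_filter(x0, p0, z_seq, u_seq, c0, c1, r_diag, a, q):
    """Textbook linear Kalman filter, joint vector measurement update.

    z_seq: (T, m) observations; u_seq: (T, k) exogenous inputs;
    c0, c1: per-channel intercept/slope arrays; a: drift coefficients.
    Returns arrays of posterior means and variances.
    """
    c1 = np.asarray(c1, dtype=float)
    c0 = np.asarray(c0, dtype=float)
    R = np.diag(np.asarray(r_diag, dtype=float))
    x, p = float(x0), float(p0)
    means, variances = [], []
    for t in range(len(z_seq)):
        x = x + float(np.dot(a, u_seq[t])) if len(a) else x
        p = p + q
        H = c1.reshape(-1, 1)  # m x 1
        z = np.asarray(z_seq[t], dtype=float).reshape(-1, 1)
        innov = z - (c0.reshape(-1, 1) + c1.reshape(-1, 1) * x)
        S = H @ H.T * p + R
        K = p * H.T @ np.linalg.inv(S)  # 1 x m
        x = x + (K @ innov).item()
        p = ((1.0 - K @ H) * p).item()
        means.append(x)
        variances.append(p)
    return np.asarray(means), np.asarray(variances)
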