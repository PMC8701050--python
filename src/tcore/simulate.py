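"""Synthetic thermophysiological trial generator.

Generates subjects, environments, exercise protocols and full multi-rate
wearable sensor streams (heart rate and step rate at 1 Hz; skin-side and
ambient-side temperature and relative humidity at 0.2 Hz) together with a
reference core-temperature series, using a two-compartment (core/skin)
heat-balance model integrated at 1 s steps.  Every trial carries its true
state so downstream estimators can be tested against known ground truth.

The generator emulates exercise-lab validation trials: 40-107 min long,
ambient temperatures roughly 13-43 deg C and 11-75 % relative humidity,
exercise intensities from seated rest to sprint intervals, and reference
core temperature sampled every 5-300 s by rectal probe or gastrointestinal
pill.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SubjectProfile",
    "Segment",
    "ActivityProtocol",
    "EnvironmentProfile",
    "SimConfig",
    "RawTrial",
    "Cohort",
    "SimulationError",
    "dubois_bsa",
    "tanaka_hr_max",
    "make_protocol",
    "simulate_trial",
    "sample_ground_truth",
    "simulate_cohort",
    "write_trial",
    "write_cohort",
    "STREAM_CADENCE_S",
]

SEXES = ("male", "female")
MODES = ("rest", "walk", "run", "cycle", "sprint_interval")
CLOTHING = ("minimal", "impermeable")
GT_DEVICES = ("rectal", "gi_pill")

#: sampling period in seconds for each emitted stream
STREAM_CADENCE_S = {
    "hr": 1,
    "step_rate": 1,
    "skin_temp": 5,
    "amb_temp": 5,
    "skin_rh": 5,
    "amb_rh": 5,
}

# cadence step rate in steps/min by locomotion mode (arm-worn accelerometer
# does not register cycling cadence, hence 0 for rest and cycling)
_STEP_RATE_BY_MODE = {
    "rest": 0.0,
    "walk": 112.0,
    "run": 168.0,
    "cycle": 0.0,
    "sprint_interval": 196.0,
}


class SimulationError(RuntimeError):
    """Raised when the heat-balance integration produces a non-finite state."""


def dubois_bsa(mass: float, height: float) -> float:
    """Body surface area (m^2) from mass (kg) and height (cm), DuBois & DuBois.

    BSA = 0.007184 * mass^0.425 * height^0.725
    """
    if mass <= 0 or height <= 0:
        raise ValueError(f"mass and height must be positive, got {mass=}, {height=}")
    return 0.007184 * mass**0.425 * height**0.725


def tanaka_hr_max(age: float) -> float:
    """Age-predicted maximum heart rate (beats/min), Tanaka: 208 - 0.7*age."""
    if age < 0:
        raise ValueError(f"age must be non-negative, got {age}")
    return 208.0 - 0.7 * age


@dataclass(frozen=True)
class SubjectProfile:
    """Anthropometrics entered at onboarding plus derived quantities.

    ``bsa`` (DuBois) and ``hr_max`` (Tanaka) are derived automatically and
    should not normally be passed.
    """

    subject_id: str
    age: float  # years
    sex: str
    height: float  # cm
    mass: float  # kg
    bsa: float = field(default=float("nan"))  # m^2, derived
    hr_max: float = field(default=float("nan"))  # beats/min, derived

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not (18 <= self.age <= 70):
            raise ValueError(f"age must be in [18, 70], got {self.age}")
        if not (140 <= self.height <= 210):
            raise ValueError(f"height must be in [140, 210] cm, got {self.height}")
        if not (45 <= self.mass <= 120):
            raise ValueError(f"mass must be in [45, 120] kg, got {self.mass}")
        if np.isnan(self.bsa):
            object.__setattr__(self, "bsa", dubois_bsa(self.mass, self.height))
        if np.isnan(self.hr_max):
            object.__setattr__(self, "hr_max", tanaka_hr_max(self.age))


@dataclass(frozen=True)
class Segment:
    duration_min: float
    mode: str
    target_intensity: float  # fraction of hr_max
    clothing: str = "minimal"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.clothing not in CLOTHING:
            raise ValueError(f"unknown clothing {self.clothing!r}")
        if not (0.30 <= self.target_intensity <= 1.10):
            raise ValueError(
                f"target_intensity must be in [0.30, 1.10], got {self.target_intensity}"
            )
        if self.duration_min <= 0:
            raise ValueError("duration_min must be positive")


@dataclass(frozen=True)
class ActivityProtocol:
    """Ordered exercise segments; optionally an early-stop core temperature.

    ``stop_when_tc_exceeds`` truncates the trial once the simulated core
    temperature crosses the threshold during a sprint-interval segment
    (used by the sprint-to-criterion protocol).
    """

    segments: tuple[Segment, ...]
    stop_when_tc_exceeds: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        total = self.total_duration_min
        if not (40 <= total <= 107):
            raise ValueError(f"total duration must be in [40, 107] min, got {total}")

    @property
    def total_duration_min(self) -> float:
        return sum(s.duration_min for s in self.segments)


@dataclass(frozen=True)
class EnvironmentProfile:
    ta: float  # ambient temperature, deg C
    rh: float  # ambient relative humidity, %

    def __post_init__(self) -> None:
        if not (13.0 <= self.ta <= 43.5):
            raise ValueError(f"ta must be in [13.0, 43.5] degC, got {self.ta}")
        if not (11 <= self.rh <= 75):
            raise ValueError(f"rh must be in [11, 75] %, got {self.rh}")


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters: two-node thermal model, heart rate, sensor noise.

    Thermal parameters are lumped whole-body values for a reference adult.
    ``k_cs`` is the resting core->skin conductance; it is scaled up with core
    temperature above 37 deg C by ``k_dilation`` to emulate vasodilation,
    without which a two-node model with constant coefficients cannot both
    hold a resting core near 37 deg C in cool air and reach realistic
    exercise equilibria.  Metabolic heat is a piecewise-linear function of
    intensity with M(0) = 0: M = m_rest * i / i_rest for i <= i_rest, then
    m_rest + m_slope * (i - i_rest).
    """

    rng_seed: int = 0
    # thermal params
    c_core: float = 2.1e5  # J/degC
    c_skin: float = 5.0e4  # J/degC
    k_cs: float = 25.0  # W/degC at rest
    k_dilation: float = 1.5  # 1/degC, conductance gain per degC of Tc above 37
    h_env: float = 20.0  # W/degC skin->air
    sweat_gain: float = 400.0  # W/degC above threshold
    sweat_threshold: float = 37.2  # degC
    e_max: float = 600.0  # W, evaporative capacity cap
    eta: float = 0.15  # mechanical efficiency
    m_rest: float = 95.0  # W at i_rest
    i_rest: float = 0.35  # intensity of seated rest
    m_slope: float = 1100.0  # W per unit intensity above i_rest
    clothing_sweat_factor: float = 0.25  # evaporation efficiency, impermeable
    # heart-rate params
    hr_rest: float = 60.0  # beats/min
    k_drift: float = 3.0  # beats/min per degC of Tc above 37
    # initial state
    tc0_male: float = 36.9
    tc0_female: float = 37.1
    tc0_sd: float = 0.12  # between-trial SD of the starting core temperature
    # sensor noise SDs
    noise_hr: float = 2.0  # beats/min
    noise_step: float = 3.0  # steps/min
    noise_temp: float = 0.2  # degC (stated sensor accuracy)
    noise_rh: float = 2.0  # % RH (stated sensor accuracy)
    # ground truth
    gt_interval: int = 60  # s
    gt_device: str = "rectal"
    gt_noise_sd: float = 0.05  # degC
    gi_pill_lag_s: float = 0.0  # first-order lag time constant, 0 = none
    # optional known-coefficient observation mode: channel -> polynomial
    # coefficients (c0, c1, ...) in true core temperature; channels listed
    # here are emitted as poly(Tc) + channel noise instead of the
    # biophysical signal.
    obs_polynomials: Optional[dict[str, tuple[float, ...]]] = None

    def __post_init__(self) -> None:
        for name in ("c_core", "c_skin", "k_cs", "h_env", "sweat_gain", "e_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("noise_hr", "noise_step", "noise_temp", "noise_rh", "gt_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (5 <= self.gt_interval <= 300):
            raise ValueError(f"gt_interval must be in [5, 300] s, got {self.gt_interval}")
        if self.gt_device not in GT_DEVICES:
            raise ValueError(f"gt_device must be one of {GT_DEVICES}")


@dataclass
class RawTrial:
    """One trial's raw multi-rate streams plus the reference series.

    ``streams`` maps signal name to an (n, 2) array of (t seconds from trial
    start, value).  ``ground_truth`` is an (n, 2) array of (t, tc).
    ``true_state`` is populated for simulated trials only.
    """

    trial_id: str
    subject_id: str
    streams: dict[str, np.ndarray]
    ground_truth: np.ndarray
    gt_device: str
    true_state: Optional[dict] = None

    def validate(self) -> "RawTrial":
        for name, arr in self.streams.items():
            t = arr[:, 0]
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"timestamps not strictly increasing in {name}")
            cad = STREAM_CADENCE_S.get(name)
            if cad is not None and len(t) > 1 and not np.allclose(np.diff(t), cad):
                raise ValueError(f"stream {name} violates its {cad}-s cadence")
        hr = self.streams.get("hr")
        if hr is not None and (np.any(hr[:, 1] < 30) or np.any(hr[:, 1] > 230)):
            raise ValueError("hr values outside [30, 230] beats/min")
        if len(self.ground_truth) == 0:
            raise ValueError("no ground truth")
        gt_t = self.ground_truth[:, 0]
        if np.any(np.diff(gt_t) <= 0):
            raise ValueError("ground-truth timestamps not strictly increasing")
        tc = self.ground_truth[:, 1]
        if np.any(tc < 35.0) or np.any(tc > 41.5):
            raise ValueError("ground-truth core temperature outside [35.0, 41.5] degC")
        if self.gt_device not in GT_DEVICES:
            raise ValueError(f"unknown gt device {self.gt_device!r}")
        return self


@dataclass
class Cohort:
    subjects: list[SubjectProfile]
    trials: list[RawTrial]
    config: SimConfig

    @property
    def profiles(self) -> dict[str, SubjectProfile]:
        return {s.subject_id: s for s in self.subjects}


# ---------------------------------------------------------------------------
# protocols


def _study1(rng: np.random.Generator) -> list[Segment]:
    # seated rest, two steady cycling bouts at 50-65 % HRmax, a short
    # high-intensity bout above 76 %, interspersed rests; 100 min total
    i_cycle = float(rng.uniform(0.50, 0.65))
    return [
        Segment(10, "rest", 0.35),
        Segment(25, "cycle", i_cycle),
        Segment(5, "rest", 0.35),
        Segment(25, "cycle", i_cycle),
        Segment(5, "rest", 0.35),
        Segment(15, "cycle", float(rng.uniform(0.78, 0.88))),
        Segment(15, "rest", 0.35),
    ]


def _study2(rng: np.random.Generator) -> list[Segment]:
    # 60 min treadmill run: 45 min steady below threshold, 15 min self-paced
    return [
        Segment(45, "run", float(rng.uniform(0.70, 0.76))),
        Segment(15, "run", float(rng.uniform(0.80, 0.92))),
    ]


def _study3(rng: np.random.Generator) -> list[Segment]:
    # walking at fixed speed/gradient with seated baseline and rests; 105 min
    i_walk = float(rng.uniform(0.50, 0.60))
    return [
        Segment(10, "rest", 0.35),
        Segment(60, "walk", i_walk),
        Segment(10, "rest", 0.35),
        Segment(15, "walk", i_walk),
        Segment(10, "rest", 0.35),
    ]


def _study4(rng: np.random.Generator) -> list[Segment]:
    # impermeable clothing; walk, two moderate runs, then 15 s sprint / 30 s
    # recovery cycles padded to the protocol cap (trial truncates early once
    # the simulated core temperature crosses the stop threshold)
    i_run = float(rng.uniform(0.64, 0.76))
    segs = [
        Segment(5, "walk", 0.45, "impermeable"),
        Segment(15, "run", i_run, "impermeable"),
        Segment(5, "walk", 0.45, "impermeable"),
        Segment(15, "run", i_run, "impermeable"),
    ]
    total = 40.0
    while total + 0.75 <= 107.0:
        segs.append(Segment(0.25, "sprint_interval", 1.05, "impermeable"))
        segs.append(Segment(0.50, "walk", 0.50, "impermeable"))
        total += 0.75
    return segs


#: target core temperature for the sprint-to-criterion protocol; the
#: protocol requires exceeding at least 38.25 degC with a goal of 39.0.
STUDY4_STOP_TC = 39.0

_STUDY_BUILDERS = {1: _study1, 2: _study2, 3: _study3, 4: _study4}

# lab ambient ranges per study template; study 3 is run across the full
# cool-to-hot span so the cohort covers all three ambient bands
_STUDY_ENV_RANGES = {
    1: ((20.0, 35.0), (20.0, 60.0)),
    2: ((16.0, 26.0), (20.0, 60.0)),
    3: ((13.5, 43.0), (11.0, 75.0)),
    4: ((20.0, 30.0), (25.0, 60.0)),
}


def make_protocol(
    study_id: int,
    subject: SubjectProfile,
    rng: Optional[np.random.Generator] = None,
) -> ActivityProtocol:
    """Segment template of one of the four study protocols.

    Intensities are fractions of the subject's age-predicted maximum heart
    rate; intensity draws within the protocol's stated ranges use ``rng``
    (deterministic midpoints when ``rng`` is None).  The sprint protocol
    (study 4) is marked with a stop threshold so simulation truncates once
    core temperature exceeds it.
    """
    if study_id not in _STUDY_BUILDERS:
        raise ValueError(f"unknown study_id {study_id!r}; expected one of 1-4")
    if rng is None:
        rng = np.random.default_rng(12345)  # midpoint-ish deterministic draws
    segments = _STUDY_BUILDERS[study_id](rng)
    stop = STUDY4_STOP_TC if study_id == 4 else None
    return ActivityProtocol(tuple(segments), stop_when_tc_exceeds=stop)


# ---------------------------------------------------------------------------
# trial simulation


def _metabolic_rate(intensity: float, cfg: SimConfig) -> float:
    """Whole-body metabolic heat (W); zero at zero intensity."""
    if intensity <= cfg.i_rest:
        return cfg.m_rest * intensity / cfg.i_rest
    return cfg.m_rest + cfg.m_slope * (intensity - cfg.i_rest)


def _per_second_schedule(protocol: ActivityProtocol) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Expand segments to per-second (intensity, mode, impermeable) arrays."""
    intensity, modes, imperm = [], [], []
    for seg in protocol.segments:
        n = int(round(seg.duration_min * 60))
        intensity.extend([seg.target_intensity] * n)
        modes.extend([seg.mode] * n)
        imperm.extend([seg.clothing == "impermeable"] * n)
    return np.asarray(intensity), modes, np.asarray(imperm, dtype=bool)


def simulate_trial(
    subject: SubjectProfile,
    env: EnvironmentProfile,
    protocol: ActivityProtocol,
    config: SimConfig,
    trial_id: str = "trial",
) -> RawTrial:
    """Integrate the two-node heat-balance model and emit sensor streams.

    Core/skin dynamics at 1 s Euler steps::

        c_core dTc/dt = M(t) (1 - eta) - k(Tc) (Tc - Tsk)
        c_skin dTsk/dt = k(Tc) (Tc - Tsk) - h_env (Tsk - ta) - E_sw(Tc)

    with k(Tc) = k_cs (1 + k_dilation max(0, Tc - 37)) and E_sw a
    saturating sweating term above ``sweat_threshold``, scaled by
    ``clothing_sweat_factor`` under impermeable clothing.  Heart rate is
    hr_rest + (hr_max - hr_rest) * intensity + k_drift * max(0, Tc - 37)
    plus noise.  Deterministic given (subject, env, protocol, config).
    """
    rng = np.random.default_rng(config.rng_seed)
    intensity, modes, imperm = _per_second_schedule(protocol)
    n = len(intensity)
    if n < 60:
        raise ValueError("protocol shorter than one minute")

    tc0 = config.tc0_male if subject.sex == "male" else config.tc0_female
    tc0 = tc0 + float(rng.normal(0.0, config.tc0_sd))
    # quasi-equilibrium skin start (no sweating)
    tsk0 = (config.k_cs * tc0 + config.h_env * env.ta) / (config.k_cs + config.h_env)

    tc = np.empty(n)
    tsk = np.empty(n)
    x_c, x_s = tc0, tsk0
    stop_at = n
    for t in range(n):
        tc[t], tsk[t] = x_c, x_s
        if (
            protocol.stop_when_tc_exceeds is not None
            and modes[t] == "sprint_interval"
            and x_c > protocol.stop_when_tc_exceeds
        ):
            stop_at = t
            break
        m = _metabolic_rate(intensity[t], config)
        k_eff = config.k_cs * (1.0 + config.k_dilation * max(0.0, x_c - 37.0))
        e_sw = min(config.sweat_gain * max(0.0, x_c - config.sweat_threshold), config.e_max)
        if imperm[t]:
            e_sw *= config.clothing_sweat_factor
        flux_cs = k_eff * (x_c - x_s)
        d_c = (m * (1.0 - config.eta) - flux_cs) / config.c_core
        d_s = (flux_cs - config.h_env * (x_s - env.ta) - e_sw) / config.c_skin
        x_c += d_c
        x_s += d_s
        if not (np.isfinite(x_c) and np.isfinite(x_s)):
            raise SimulationError(
                f"non-finite state at t={t}s with thermal params "
                f"k_cs={config.k_cs}, h_env={config.h_env}, "
                f"sweat_gain={config.sweat_gain}, e_max={config.e_max}"
            )
    n_eff = stop_at if stop_at >= 60 else n
    tc, tsk = tc[:n_eff], tsk[:n_eff]
    intensity = intensity[:n_eff]
    modes = modes[:n_eff]

    t_1hz = np.arange(n_eff, dtype=float)
    t_5s = np.arange(0, n_eff, 5, dtype=float)

    # sweating wetness fraction drives skin-side humidity
    wet = np.minimum(config.sweat_gain * np.maximum(tc - config.sweat_threshold, 0.0) / config.e_max, 1.0)

    hr_true = (
        config.hr_rest
        + (subject.hr_max - config.hr_rest) * intensity
        + config.k_drift * np.maximum(tc - 37.0, 0.0)
    )
    step_true = np.asarray([_STEP_RATE_BY_MODE[m] for m in modes])
    skin_temp_true = tsk
    amb_temp_true = np.full(n_eff, env.ta)
    skin_rh_true = env.rh + (95.0 - env.rh) * wet
    amb_rh_true = np.full(n_eff, env.rh)

    truths = {
        "hr": hr_true,
        "step_rate": step_true,
        "skin_temp": skin_temp_true,
        "amb_temp": amb_temp_true,
        "skin_rh": skin_rh_true,
        "amb_rh": amb_rh_true,
    }
    if config.obs_polynomials:
        for name, coeffs in config.obs_polynomials.items():
            if name not in truths:
                raise ValueError(f"unknown observation channel {name!r}")
            truths[name] = np.polynomial.polynomial.polyval(tc, np.asarray(coeffs, dtype=float))

    noise_sd = {
        "hr": config.noise_hr,
        "step_rate": config.noise_step,
        "skin_temp": config.noise_temp,
        "amb_temp": config.noise_temp,
        "skin_rh": config.noise_rh,
        "amb_rh": config.noise_rh,
    }
    streams: dict[str, np.ndarray] = {}
    for name in ("hr", "step_rate", "skin_temp", "amb_temp", "skin_rh", "amb_rh"):
        t_axis = t_1hz if STREAM_CADENCE_S[name] == 1 else t_5s
        vals = truths[name][t_axis.astype(int)] + rng.normal(0.0, noise_sd[name], len(t_axis))
        if name == "hr":
            vals = np.clip(vals, 30.0, 230.0)
        elif name == "step_rate":
            vals = np.maximum(vals, 0.0)
        elif name.endswith("_rh"):
            vals = np.clip(vals, 0.0, 100.0)
        streams[name] = np.column_stack([t_axis, vals])

    gt = sample_ground_truth(
        np.column_stack([t_1hz, tc]), config.gt_interval, config.gt_device, config, rng=rng
    )

    trial = RawTrial(
        trial_id=trial_id,
        subject_id=subject.subject_id,
        streams=streams,
        ground_truth=gt,
        gt_device=config.gt_device,
        true_state={
            "t": t_1hz,
            "tc": tc,
            "tsk": tsk,
            "env": dataclasses.asdict(env),
            "config": dataclasses.asdict(config),
        },
    )
    return trial.validate()


def sample_ground_truth(
    true_tc: np.ndarray,
    interval: int,
    device: str,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Sample the dense core-temperature trajectory as a reference instrument.

    ``true_tc`` is an (n, 2) array of (t seconds, tc).  Samples every
    ``interval`` seconds starting at t = 0, with device noise; the
    gastrointestinal pill optionally applies a first-order lag
    (time constant ``config.gi_pill_lag_s``, default 0 = none).
    """
    if not (5 <= interval <= 300):
        raise ValueError(f"interval must be in [5, 300] s, got {interval}")
    if device not in GT_DEVICES:
        raise ValueError(f"unknown device {device!r}")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    t = true_tc[:, 0]
    tc = true_tc[:, 1]
    if device == "gi_pill" and config.gi_pill_lag_s > 0:
        # first-order response with 1 s steps
        alpha = 1.0 / config.gi_pill_lag_s
        lagged = np.empty_like(tc)
        lagged[0] = tc[0]
        for i in range(1, len(tc)):
            dt = t[i] - t[i - 1]
            a = min(alpha * dt, 1.0)
            lagged[i] = lagged[i - 1] + a * (tc[i] - lagged[i - 1])
        tc = lagged
    sample_t = np.arange(0.0, t[-1] + 0.5, interval)
    sample_tc = np.interp(sample_t, t, tc) + rng.normal(0.0, config.gt_noise_sd, len(sample_t))
    return np.column_stack([sample_t, sample_tc])


# ---------------------------------------------------------------------------
# cohorts


def simulate_cohort(
    n_subjects: int,
    config: SimConfig,
    trials_per_subject: Optional[Sequence[int]] = None,
    studies: Sequence[int] = (1, 2, 3, 4),
) -> Cohort:
    """Generate a cohort of subjects and trials, deterministic under the seed.

    ``trials_per_subject`` gives the trial count for each subject; when None
    counts are drawn from {1, 2, 3} with median 2.  Subjects alternate sex
    so both sexes are always represented (a warning is raised if the
    resulting cohort ends up single-sex).  Ambient conditions are drawn per
    study template so the cohort spans the cool / temperate / hot bands.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    rng = np.random.default_rng(config.rng_seed)
    subjects = []
    for i in range(n_subjects):
        sex = SEXES[i % 2]
        subjects.append(
            SubjectProfile(
                subject_id=f"S{i:03d}",
                age=float(np.round(rng.uniform(20, 62), 1)),
                sex=sex,
                height=float(np.round(rng.uniform(150, 195), 1)),
                mass=float(np.round(rng.uniform(50, 100), 1)),
            )
        )
    if len({s.sex for s in subjects}) < 2:
        warnings.warn("cohort contains a single sex; sex-seeded models will degenerate")

    if trials_per_subject is None:
        counts = rng.choice([1, 2, 3], size=n_subjects, p=[0.3, 0.45, 0.25])
    else:
        counts = np.asarray(trials_per_subject, dtype=int)
        if len(counts) != n_subjects:
            raise ValueError("trials_per_subject length must equal n_subjects")

    gt_options = [(60, "rectal"), (15, "rectal"), (300, "gi_pill"), (120, "gi_pill")]
    trials: list[RawTrial] = []
    k = 0
    for subj, n_tr in zip(subjects, counts):
        for _ in range(int(n_tr)):
            study = int(studies[k % len(studies)])
            (ta_lo, ta_hi), (rh_lo, rh_hi) = _STUDY_ENV_RANGES[study]
            env = EnvironmentProfile(
                ta=float(np.round(rng.uniform(ta_lo, ta_hi), 1)),
                rh=float(np.round(rng.uniform(rh_lo, rh_hi), 1)),
            )
            protocol = make_protocol(study, subj, rng=rng)
            gt_interval, gt_device = gt_options[k % len(gt_options)]
            trial_cfg = dataclasses.replace(
                config,
                rng_seed=int(rng.integers(0, 2**31 - 1)),
                gt_interval=gt_interval,
                gt_device=gt_device,
            )
            trials.append(
                simulate_trial(subj, env, protocol, trial_cfg, trial_id=f"T{k:03d}_study{study}")
            )
            k += 1
    return Cohort(subjects=subjects, trials=trials, config=config)


# ---------------------------------------------------------------------------
# serialization


def write_trial(trial: RawTrial, outdir: str | Path) -> tuple[Path, Path]:
    """Write ``<trial>_streams.csv`` (long format) and ``<trial>_gt.csv``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for name in sorted(trial.streams):
        arr = trial.streams[name]
        rows.append(pd.DataFrame({"t_s": arr[:, 0], "signal": name, "value": arr[:, 1]}))
    streams_path = outdir / f"{trial.trial_id}_streams.csv"
    pd.concat(rows, ignore_index=True).to_csv(streams_path, index=False)
    gt_path = outdir / f"{trial.trial_id}_gt.csv"
    pd.DataFrame(
        {
            "t_s": trial.ground_truth[:, 0],
            "tc_c": trial.ground_truth[:, 1],
            "device": trial.gt_device,
        }
    ).to_csv(gt_path, index=False)
    return streams_path, gt_path


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Write every trial plus a manifest JSON (subjects, trials, config, seed)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for trial in cohort.trials:
        write_trial(trial, outdir)
    manifest = {
        "seed": cohort.config.rng_seed,
        "config": dataclasses.asdict(cohort.config),
        "subjects": [dataclasses.asdict(s) for s in cohort.subjects],
        "trials": [
            {"trial_id": t.trial_id, "subject_id": t.subject_id, "gt_device": t.gt_device}
            for t in cohort.trials
        ],
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
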