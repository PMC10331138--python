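"""Core data containers for the synthetic EMA + passive-sensing study.

All timestamps are float seconds since the study start (midnight before the
first study day). The helpers in :mod:`cravecast.synthdata.io` convert to and
from ISO-8601 UTC wall-clock time for on-disk CSV artifacts.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

DAY_S = 86400.0
MIN_S = 60.0

#: Sensor effect groups recognised by the generator, in canonical order.
SENSOR_GROUPS = ("SCREEN", "AUDIO", "ACC", "LIGHT", "NOTIF")


@dataclass(frozen=True)
class StudyDesign:
    """Sampling plan of the EMA study.

    Six signal-contingent prompts per day at fixed anchors 150 min apart,
    jittered by +/-15 min, for 14 consecutive days (84 prompts), each
    answerable for up to 60 min.
    """

    n_days: int = 14
    anchors_min: tuple = (540, 690, 840, 990, 1140, 1290)  # 09:00 ... 21:30
    jitter_halfwidth_min: float = 15.0
    answer_window_min: float = 60.0
    craving_lo: float = 0.0
    craving_hi: float = 100.0

    def __post_init__(self):
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if any(b <= a for a, b in zip(self.anchors_min, self.anchors_min[1:])):
            raise ValueError("anchors must be strictly increasing")

    @property
    def n_prompts(self) -> int:
        return self.n_days * len(self.anchors_min)

    @property
    def period_s(self) -> float:
        """Length of the simulated sensing period in seconds."""
        return self.n_days * DAY_S


@dataclass(frozen=True)
class EffectConfig:
    """Ground-truth generative model for craving ratings.

    The latent predictor is a sum of four standardized components —
    person intercept, sensor-driven signal, diurnal rhythm, and an AR(1)
    noise process across successive prompts — with standard deviations
    ``sigma_*``. It is mapped to the 0-100 VAS through a calibrated
    exponential skew transform ``clip(c0 + c1*expm1(b*z)/b, 0, 100)``.

    With the default sigmas the latent variance is 1 and the transform
    constants are calibrated so that a default cohort reproduces the
    observed marginal craving moments (pooled mean ~21.9, pooled SD ~26.7,
    mean per-person skewness ~1.28).
    """

    sensor_weights: dict = field(
        default_factory=lambda: {
            "SCREEN": 1.0,
            "AUDIO": 0.6,
            "ACC": 0.5,
            "LIGHT": 0.3,
            "NOTIF": 0.2,
        }
    )
    sigma_person: float = 0.5477225575051661  # sqrt(0.30)
    sigma_sensor: float = 0.6204836822995429  # sqrt(0.385)
    sigma_diurnal: float = 0.2645751311064591  # sqrt(0.07)
    sigma_noise: float = 0.4949747468305833  # sqrt(0.245)
    ar_coef: float = 0.5
    weight_jitter_sd: float = 0.25
    # skew transform constants (frozen calibration; see docs/methods.md)
    transform_c0: float = 10.50587107
    transform_c1: float = 45.74792227
    transform_b: float = -0.15370663
    null_mode: bool = False

    def effective_sigma_sensor(self) -> float:
        return 0.0 if self.null_mode else self.sigma_sensor

    def effective_sigma_noise(self) -> float:
        """Noise SD, absorbing the sensor share under ``null_mode`` so the
        marginal craving distribution keeps its calibration."""
        if not self.null_mode:
            return self.sigma_noise
        return float(np.hypot(self.sigma_noise, self.sigma_sensor))

    def transform(self, z: np.ndarray) -> np.ndarray:
        """Map latent reals to the [0, 100] craving scale."""
        x = self.transform_c0 + self.transform_c1 * np.expm1(self.transform_b * z) / self.transform_b
        return np.clip(x, 0.0, 100.0)


@dataclass(frozen=True)
class PersonProfile:
    """Per-person base levels and rhythms of the five sensor sources."""

    accel_base: float = 0.5            # mean acceleration change, arbitrary units
    accel_diurnal: float = 1.2         # log-scale day/night contrast
    accel_noise_sd: float = 0.6
    audio_base_db: float = 45.0
    audio_diurnal_db: float = 14.0
    audio_noise_sd: float = 6.0
    audio_spread_db: float = 6.0
    light_log_base: float = 0.4        # log10 lux at night
    light_log_diurnal: float = 2.1
    light_log_noise_sd: float = 0.5
    notif_rate_day: float = 4.0        # events per hour at diurnal peak
    notif_rate_floor: float = 0.3
    screen_mean_on_s: float = 120.0
    screen_mean_off_s: float = 900.0
    screen_diurnal: float = 1.0        # 0 disables diurnal gating of off-times
    p_answer: float = 70.0 / 84.0
    availability: float = 0.848


@dataclass
class SensorStreams:
    """Multi-rate passive sensing streams for one participant.

    ``audio_db`` / ``light_lux`` are (n, 3) arrays of (mean, min, max) per
    record; ``screen`` is an (n, 2) array of disjoint, ordered
    (on_time, off_time) intervals.
    """

    accel_t: np.ndarray
    accel_mag: np.ndarray
    audio_t: np.ndarray
    audio_db: np.ndarray
    light_t: np.ndarray
    light_lux: np.ndarray
    notif_t: np.ndarray
    notif_app: np.ndarray
    screen: np.ndarray

    def n_records(self) -> dict:
        return {
            "accel": len(self.accel_t),
            "audio": len(self.audio_t),
            "light": len(self.light_t),
            "notif": len(self.notif_t),
            "screen": len(self.screen),
        }

    def total_records(self) -> int:
        return sum(self.n_records().values())

    def copy(self) -> "SensorStreams":
        return SensorStreams(
            self.accel_t.copy(), self.accel_mag.copy(),
            self.audio_t.copy(), self.audio_db.copy(),
            self.light_t.copy(), self.light_lux.copy(),
            self.notif_t.copy(), self.notif_app.copy(),
            self.screen.copy(),
        )

    def validate(self, period_s: Optional[float] = None) -> None:
        for t in (self.accel_t, self.audio_t, self.light_t, self.notif_t):
            if len(t) > 1 and np.any(np.diff(t) < 0):
                raise ValueError("sensor timestamps must be sorted")
            if period_s is not None and len(t) and (t[0] < 0 or t[-1] > period_s):
                raise ValueError("timestamps outside the study period")
        if len(self.audio_t):
            m, lo, hi = self.audio_db[:, 0], self.audio_db[:, 1], self.audio_db[:, 2]
            if np.any(lo > m) or np.any(m > hi):
                raise ValueError("audio min <= mean <= max violated")
        if len(self.light_t):
            m, lo, hi = self.light_lux[:, 0], self.light_lux[:, 1], self.light_lux[:, 2]
            if np.any(lo > m) or np.any(m > hi) or np.any(lo < 0):
                raise ValueError("light min <= mean <= max (>=0) violated")
        if len(self.screen):
            on, off = self.screen[:, 0], self.screen[:, 1]
            if np.any(off <= on):
                raise ValueError("screen intervals must have off > on")
            if np.any(on[1:] < off[:-1]):
                raise ValueError("screen intervals must be disjoint and ordered")


@dataclass
class EmaRecord:
    """One scheduled EMA prompt, possibly answered with a craving rating."""

    prompt_time: float
    day_index: int
    slot: int
    answer_time: Optional[float] = None
    craving: Optional[float] = None

    @property
    def answered(self) -> bool:
        return self.answer_time is not None

    def validate(self, design: StudyDesign) -> None:
        if (self.answer_time is None) != (self.craving is None):
            raise ValueError("craving must be present iff answer_time is present")
        if self.answer_time is not None:
            delay = self.answer_time - self.prompt_time
            if not (0 <= delay <= design.answer_window_min * MIN_S):
                raise ValueError("answer outside the allowed window")
            if not (design.craving_lo <= self.craving <= design.craving_hi):
                raise ValueError("craving outside the rating scale")


@dataclass
class PersonTruth:
    """Generator-side ground truth kept for recovery tests only."""

    u_person: float
    weights: dict
    p_answer: float
    availability_target: float
    availability_observed: float
    sensor_score: np.ndarray      # standardized sensor signal per answered prompt
    latent: np.ndarray            # latent predictor per answered prompt
    drivers: dict                 # raw per-group span aggregates per answered prompt

    @property
    def top_group(self) -> str:
        return max(self.weights, key=lambda g: abs(self.weights[g]))


@dataclass
class Participant:
    """One synthetic participant: degraded streams, EMA, and hidden truth."""

    id: str
    streams: SensorStreams
    ema: list
    truth: Optional[PersonTruth] = None
    full_streams: Optional[SensorStreams] = None
    profile: Optional[PersonProfile] = None

    @property
    def answered(self) -> list:
        return [e for e in self.ema if e.answered]


def replace_profile(profile: PersonProfile, **kw) -> PersonProfile:
    return replace(profile, **kw)
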