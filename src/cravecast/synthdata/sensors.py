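"""Passive sensor stream simulation and block-wise missingness.

Cadences mirror the on-device preprocessing of the source app: one
acceleration-change summary every 5 min, one (mean, min, max) audio dB and
light record every 15 min, notification events as an inhomogeneous point
process, and screen use as an alternating on/off renewal process.
"""
from __future__ import annotations

import numpy as np

from .types import DAY_S, SensorStreams, PersonProfile, StudyDesign

ACCEL_CADENCE_S = 300.0
AUDIO_CADENCE_S = 900.0
LIGHT_CADENCE_S = 900.0

_APP_POOL = np.array([f"app_{i:02d}" for i in range(12)], dtype=object)


def diurnal01(t_s: np.ndarray) -> np.ndarray:
    """Smooth 0-1 activity rhythm: minimum at 03:00, peak at 15:00."""
    h = (np.asarray(t_s, dtype=float) / 3600.0) % 24.0
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * (h - 3.0) / 24.0))


def simulate_sensor_streams(design: StudyDesign, profile: PersonProfile,
                            rng: np.random.Generator) -> SensorStreams:
    """Simulate one participant's full (pre-dropout) sensing period."""
    end = design.period_s

    # accelerometer: positive change magnitudes, log-scale diurnal modulation
    acc_t = np.arange(0.0, end, ACCEL_CADENCE_S)
    d = diurnal01(acc_t)
    acc = profile.accel_base * np.exp(
        profile.accel_diurnal * (d - 0.5)
        + profile.accel_noise_sd * rng.standard_normal(acc_t.size)
    )

    # audio volume: dB triplets
    au_t = np.arange(0.0, end, AUDIO_CADENCE_S)
    d = diurnal01(au_t)
    au_mean = (profile.audio_base_db + profile.audio_diurnal_db * (d - 0.5)
               + profile.audio_noise_sd * rng.standard_normal(au_t.size))
    au_lo = au_mean - np.abs(rng.normal(0, profile.audio_spread_db, au_t.size)) - 0.5
    au_hi = au_mean + np.abs(rng.normal(0, profile.audio_spread_db, au_t.size)) + 0.5
    audio = np.column_stack([au_mean, au_lo, au_hi])

    # ambient light: log-normal lux triplets, strongly diurnal, >= 0
    li_t = np.arange(0.0, end, LIGHT_CADENCE_S)
    d = diurnal01(li_t)
    lux_mean = 10.0 ** (profile.light_log_base + profile.light_log_diurnal * d
                        + profile.light_log_noise_sd * rng.standard_normal(li_t.size))
    lux_lo = lux_mean * rng.uniform(0.2, 0.95, li_t.size)
    lux_hi = lux_mean * (1.0 + rng.exponential(0.5, li_t.size))
    light = np.column_stack([lux_mean, lux_lo, lux_hi])

    # notifications: thinned inhomogeneous Poisson process on 10-min bins
    bin_s = 600.0
    bins = np.arange(0.0, end, bin_s)
    rate_hr = profile.notif_rate_floor + profile.notif_rate_day * diurnal01(bins + bin_s / 2)
    counts = rng.poisson(rate_hr * bin_s / 3600.0)
    notif_t = np.sort(np.repeat(bins, counts) + rng.uniform(0, bin_s, counts.sum()))
    notif_app = rng.choice(_APP_POOL, size=notif_t.size,
                           p=_zipf_weights(len(_APP_POOL)))

    # screen: alternating exponential off/on renewal, off-times stretched at night
    screen = _simulate_screen(end, profile, rng)

    s = SensorStreams(acc_t, acc, au_t, audio, li_t, light, notif_t, notif_app, screen)
    s.validate(period_s=end)
    return s


def _zipf_weights(k: int) -> np.ndarray:
    w = 1.0 / np.arange(1, k + 1)
    return w / w.sum()


def _simulate_screen(end: float, profile: PersonProfile,
                     rng: np.random.Generator) -> np.ndarray:
    """Alternating off/on renewal process starting in the off state."""
    ons, offs = [], []
    t = 0.0
    while t < end:
        gate = 1.0 + profile.screen_diurnal * (1.0 - float(diurnal01(np.array([t]))[0]))
        t += rng.exponential(profile.screen_mean_off_s * gate)
        if t >= end:
            break
        on = t
        t += rng.exponential(profile.screen_mean_on_s)
        ons.append(on)
        offs.append(min(t, end))
    if not ons:
        return np.empty((0, 2))
    return np.column_stack([ons, offs])


def _run_mask(n: int, target: float, mean_drop_len: float,
              rng: np.random.Generator) -> np.ndarray:
    """Alternating keep/drop runs with geometric lengths.

    Mean drop-run length is ``mean_drop_len`` records; the mean keep-run
    length is scaled so the long-run kept fraction equals ``target``; the
    initial state is drawn from the stationary law, making the expected
    retained fraction exactly ``target``.
    """
    mean_keep_len = mean_drop_len * target / (1.0 - target)
    p_keep = min(1.0, 1.0 / mean_keep_len)
    p_drop = min(1.0, 1.0 / mean_drop_len)
    mask = np.empty(n, dtype=bool)
    pos = 0
    state = rng.random() < target
    while pos < n:
        run = rng.geometric(p_keep if state else p_drop)
        mask[pos:pos + run] = state
        pos += run
        state = not state
    return mask


def apply_missingness(streams: SensorStreams, target_availability: float,
                      rng: np.random.Generator,
                      mean_drop_len: float = 12.0) -> SensorStreams:
    """Drop contiguous blocks of records so that each stream retains an
    expected fraction ``target_availability`` of its records.

    Block (not record-wise i.i.d.) dropout emulates phone-off periods and
    dead sensors. ``target_availability == 1`` returns an unchanged copy.
    """
    if not (0 < target_availability <= 1):
        raise ValueError("target_availability must be in (0, 1]")
    if target_availability == 1.0:
        return streams.copy()
    m_acc = _run_mask(len(streams.accel_t), target_availability, mean_drop_len, rng)
    m_au = _run_mask(len(streams.audio_t), target_availability, mean_drop_len, rng)
    m_li = _run_mask(len(streams.light_t), target_availability, mean_drop_len, rng)
    m_no = _run_mask(len(streams.notif_t), target_availability, mean_drop_len, rng)
    m_sc = _run_mask(len(streams.screen), target_availability, mean_drop_len, rng)
    return SensorStreams(
        streams.accel_t[m_acc], streams.accel_mag[m_acc],
        streams.audio_t[m_au], streams.audio_db[m_au],
        streams.light_t[m_li], streams.light_lux[m_li],
        streams.notif_t[m_no], streams.notif_app[m_no],
        streams.screen[m_sc],
    )


def sensor_availability(original: SensorStreams, degraded: SensorStreams) -> float:
    """Pooled fraction of sensor records retained across all five streams."""
    tot = original.total_records()
    if tot == 0:
        return 1.0
    return degraded.total_records() / tot
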