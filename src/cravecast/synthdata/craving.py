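"""Ground-truth craving simulation on top of simulated sensor streams.

The latent predictor for person *i* at answered prompt *t* is

    z_it = sigma_person * u_i
         + sigma_sensor * S_it      (standardized weighted sensor signal)
         + sigma_diurnal * D_it     (standardized evening-peaking rhythm)
         + sigma_noise * eps_it     (AR(1) across successive prompts)

and craving = clip(c0 + c1*expm1(b*z)/b, 0, 100). The sensor signal S is a
weighted sum of per-person-standardized true window aggregates over the same
lagged [T0-150, T0-30) span the feature pipeline uses, computed on the full
(pre-dropout) streams — so a downstream model sees a noisy, partially
missing view of the true drivers.
"""
from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np

from .. import featurize
from .types import EffectConfig, EmaRecord, SensorStreams, SENSOR_GROUPS


def _standardize(x: np.ndarray) -> np.ndarray:
    x = np.where(np.isfinite(x), x, np.nan)
    mu = np.nanmean(x) if np.any(np.isfinite(x)) else 0.0
    sd = np.nanstd(x) if np.any(np.isfinite(x)) else 0.0
    z = (x - mu) / sd if sd > 0 else np.zeros_like(x)
    return np.where(np.isfinite(z), z, 0.0)


def span_drivers(streams: SensorStreams, t0: float) -> dict:
    """True per-group aggregates over the full lagged span of one prompt.

    Combines the four 30-min windows of the feature pipeline: ACC/AUDIO/LIGHT
    as the mean of window means, NOTIF and SCREEN as window sums — identical
    to what the documented feature schema exposes, which closes the loop for
    signal-recovery tests.
    """
    wins = [featurize.aggregate_window(streams, w) for w in featurize.window_bounds(t0)]
    with np.errstate(invalid="ignore"):
        return {
            "ACC": np.nanmean([w["acc_mean"] for w in wins]),
            "AUDIO": np.nanmean([w["audio_db_mean"] for w in wins]),
            "LIGHT": np.nanmean([w["light_lux_mean"] for w in wins]),
            "NOTIF": float(np.sum([w["notif_count"] for w in wins])),
            "SCREEN": float(np.sum([w["screen_on_sec"] for w in wins])),
        }


def simulate_craving(streams: SensorStreams, ema: List[EmaRecord],
                     effects: EffectConfig, rng: np.random.Generator,
                     u_person: Optional[float] = None,
                     weights: Optional[dict] = None,
                     ) -> Tuple[List[EmaRecord], dict]:
    """Fill in craving ratings for the answered prompts of ``ema``.

    ``u_person`` and ``weights`` are the person-level realizations (drawn
    here if not supplied). Returns the EMA list (modified in place) plus a
    truth dict with the latent components, for recovery tests.

    The random stream is consumed identically regardless of ``null_mode``
    so that null and signal cohorts are exact counterfactuals.
    """
    if u_person is None:
        u_person = float(rng.standard_normal())
    if weights is None:
        jit = np.exp(rng.normal(0.0, effects.weight_jitter_sd, len(SENSOR_GROUPS)))
        weights = {g: effects.sensor_weights.get(g, 0.0) * j
                   for g, j in zip(SENSOR_GROUPS, jit)}

    # AR(1) noise across the full scheduled prompt sequence, stationary var 1
    n_all = len(ema)
    eps = np.empty(n_all)
    innov = rng.standard_normal(n_all)
    phi = effects.ar_coef
    eps[0] = innov[0]
    for k in range(1, n_all):
        eps[k] = phi * eps[k - 1] + np.sqrt(1.0 - phi ** 2) * innov[k]

    answered_idx = [i for i, r in enumerate(ema) if r.answered]
    if not answered_idx:
        return ema, {"u_person": u_person, "weights": weights,
                     "sensor_score": np.empty(0), "latent": np.empty(0),
                     "drivers": {g: np.empty(0) for g in SENSOR_GROUPS}}

    t0s = np.array([ema[i].answer_time for i in answered_idx])
    if np.any(t0s - featurize.LOOKBACK_S < -1e-9):
        raise ValueError("lagged window precedes the sensor stream start")

    drivers = {g: np.empty(len(answered_idx)) for g in SENSOR_GROUPS}
    for j, t0 in enumerate(t0s):
        d = span_drivers(streams, t0)
        for g in SENSOR_GROUPS:
            drivers[g][j] = d[g]

    # Residualize the shared diurnal rhythm out of each driver before
    # weighting: every sensor co-varies with time of day, and without this
    # step the common diurnal factor would accumulate across groups and make
    # the per-group weights unrecoverable. Craving keeps its own separate
    # diurnal term below.
    hour = (t0s / 3600.0) % 24.0
    diurnal_basis = np.column_stack([
        np.ones_like(hour),
        np.sin(2 * np.pi * hour / 24.0), np.cos(2 * np.pi * hour / 24.0),
    ])
    s_raw = np.zeros(len(answered_idx))
    for g in SENSOR_GROUPS:
        zg = _standardize(drivers[g])
        beta, *_ = np.linalg.lstsq(diurnal_basis, zg, rcond=None)
        s_raw = s_raw + weights[g] * _standardize(zg - diurnal_basis @ beta)
    s_score = _standardize(s_raw)

    d_score = _standardize(-np.cos(2 * np.pi * (hour - 17.0) / 24.0))

    z = (effects.sigma_person * u_person
         + effects.effective_sigma_sensor() * s_score
         + effects.sigma_diurnal * d_score
         + effects.effective_sigma_noise() * eps[answered_idx])
    craving = effects.transform(z)
    for j, i in enumerate(answered_idx):
        ema[i].craving = float(craving[j])

    truth = {"u_person": u_person, "weights": weights,
             "sensor_score": s_score, "latent": z, "drivers": drivers}
    return ema, truth
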