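"""Lagged-window feature engineering for event-anchored prediction.

Each answered EMA prompt (anchor time T0, by default the answer time) gets
four half-open 30-min windows [T0-150, T0-120), [T0-120, T0-90),
[T0-90, T0-60), [T0-60, T0-30). Data from [T0-30, T0) are never used: the
model is required to look 30 min into the future, leaving room to deliver a
preventive intervention.

Feature schema (43 columns):

* per window (4): ACC mean change (1); AUDIO mean of dB means, min of dB
  minima, max of dB maxima (3); LIGHT analogous lux triplet (3); NOTIF event
  count (1); SCREEN on-seconds and on-transition count (2);
* time of day (3): prompt slot index (1-6) and sine/cosine of the hour.

Empty windows yield NaN for mean/min/max aggregates (downstream models
impute with training-set means) but 0 for counts and durations.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List

import numpy as np
import pandas as pd

from .synthdata.types import MIN_S, Participant, SensorStreams

WINDOW_LEN_S = 30.0 * MIN_S
N_WINDOWS = 4
CUTOFF_S = 30.0 * MIN_S  # data in [T0-30min, T0) are never used
LOOKBACK_S = N_WINDOWS * WINDOW_LEN_S + CUTOFF_S  # 150 min


@dataclass(frozen=True)
class LagWindow:
    start: float
    end: float
    index: int  # 1..4, ascending in time


def window_bounds(t0: float) -> List[LagWindow]:
    """The four half-open 30-min windows tiling [T0-150min, T0-30min)."""
    out = []
    for k in range(1, N_WINDOWS + 1):
        start = t0 - LOOKBACK_S + (k - 1) * WINDOW_LEN_S
        out.append(LagWindow(start=start, end=start + WINDOW_LEN_S, index=k))
    return out


def accel_change_summary(block: np.ndarray) -> float:
    """Mean absolute acceleration change along the dominant change axis.

    ``block`` is an (n, 3) triaxial series from one 5-min block. Successive
    differences are projected onto their first principal axis (the direction
    of strongest acceleration change, re-identified per block); the mean
    absolute projection is returned. The result is invariant to rigid
    rotations of the device axes. Fewer than 2 samples yield NaN.
    """
    block = np.asarray(block, dtype=float)
    if block.ndim != 2 or block.shape[1] != 3 or block.shape[0] < 2:
        return float("nan")
    diffs = np.diff(block, axis=0)
    centered = diffs - diffs.mean(axis=0, keepdims=True)
    if not np.any(centered):
        # no variation around the mean change: project onto the mean itself
        norm = np.linalg.norm(diffs.mean(axis=0))
        if norm == 0:
            return 0.0
        axis = diffs.mean(axis=0) / norm
    else:
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        axis = vt[0]
    return float(np.mean(np.abs(diffs @ axis)))


def _slice(t: np.ndarray, start: float, end: float) -> slice:
    lo = np.searchsorted(t, start, side="left")
    hi = np.searchsorted(t, end, side="left")
    return slice(lo, hi)


def _screen_overlap(screen: np.ndarray, start: float, end: float):
    """(on-seconds, on-transition count) of screen intervals vs [start, end)."""
    if len(screen) == 0:
        return 0.0, 0
    on, off = screen[:, 0], screen[:, 1]
    i0 = np.searchsorted(off, start, side="right")
    i1 = np.searchsorted(on, end, side="left")
    if i1 <= i0:
        return 0.0, 0
    o, f = on[i0:i1], off[i0:i1]
    sec = np.clip(np.minimum(f, end) - np.maximum(o, start), 0.0, None).sum()
    events = int(np.count_nonzero((o >= start) & (o < end)))
    return float(sec), events


def aggregate_window(streams: SensorStreams, window: LagWindow) -> dict:
    """Per-sensor aggregates of one 30-min window.

    Mean/min/max aggregates of empty windows are NaN; the notification count
    and screen on-time/on-events of empty windows are 0.
    """
    s, e = window.start, window.end
    out = {}

    sl = _slice(streams.accel_t, s, e)
    v = streams.accel_mag[sl]
    out["acc_mean"] = float(v.mean()) if v.size else float("nan")

    sl = _slice(streams.audio_t, s, e)
    a = streams.audio_db[sl]
    if a.shape[0]:
        out["audio_db_mean"] = float(a[:, 0].mean())
        out["audio_db_min"] = float(a[:, 1].min())
        out["audio_db_max"] = float(a[:, 2].max())
    else:
        out["audio_db_mean"] = out["audio_db_min"] = out["audio_db_max"] = float("nan")

    sl = _slice(streams.light_t, s, e)
    a = streams.light_lux[sl]
    if a.shape[0]:
        out["light_lux_mean"] = float(a[:, 0].mean())
        out["light_lux_min"] = float(a[:, 1].min())
        out["light_lux_max"] = float(a[:, 2].max())
    else:
        out["light_lux_mean"] = out["light_lux_min"] = out["light_lux_max"] = float("nan")

    sl = _slice(streams.notif_t, s, e)
    out["notif_count"] = float(sl.stop - sl.start)

    sec, events = _screen_overlap(streams.screen, s, e)
    out["screen_on_sec"] = sec
    out["screen_on_events"] = float(events)
    return out


_WINDOW_STATS = ("acc_mean", "audio_db_mean", "audio_db_min", "audio_db_max",
                 "light_lux_mean", "light_lux_min", "light_lux_max",
                 "notif_count", "screen_on_sec", "screen_on_events")

#: The 43 model-facing feature columns, in canonical order.
FEATURE_COLUMNS = [f"{stat}_w{k}" for k in range(1, N_WINDOWS + 1)
                   for stat in _WINDOW_STATS] + ["slot", "tod_sin", "tod_cos"]

#: Feature groups used for grouped permutation importance; they partition
#: FEATURE_COLUMNS.
FEATURE_GROUPS = {
    "SCREEN": [c for c in FEATURE_COLUMNS if c.startswith("screen_")],
    "AUDIO": [c for c in FEATURE_COLUMNS if c.startswith("audio_")],
    "ACC": [c for c in FEATURE_COLUMNS if c.startswith("acc_")],
    "LIGHT": [c for c in FEATURE_COLUMNS if c.startswith("light_")],
    "NOTIF": [c for c in FEATURE_COLUMNS if c.startswith("notif_")],
    "TIME": ["slot", "tod_sin", "tod_cos"],
}

META_COLUMNS = ["participant_id", "t0", "prompt_time", "day_index", "craving"]


def build_feature_matrix(participant: Participant, anchor: str = "answer") -> pd.DataFrame:
    """One feature row per answered prompt.

    ``anchor`` selects the window anchor T0: the answer event time
    (``"answer"``, the default — windows are defined relative to when the
    questionnaire was answered) or the prompt time (``"prompt"``).
    Missing aggregates are NaN; imputation is deferred to model fitting so
    that only training-set statistics are ever used.
    """
    if anchor not in ("answer", "prompt"):
        raise ValueError("anchor must be 'answer' or 'prompt'")
    rows = []
    answered = participant.answered
    if not answered:
        warnings.warn(f"participant {participant.id}: no answered prompts")
    for rec in answered:
        t0 = rec.answer_time if anchor == "answer" else rec.prompt_time
        row = {
            "participant_id": participant.id,
            "t0": t0,
            "prompt_time": rec.prompt_time,
            "day_index": rec.day_index,
            "craving": rec.craving,
            "slot": float(rec.slot),
        }
        for w in window_bounds(t0):
            for stat, val in aggregate_window(participant.streams, w).items():
                row[f"{stat}_w{w.index}"] = val
        hour = (t0 / 3600.0) % 24.0
        row["tod_sin"] = np.sin(2 * np.pi * hour / 24.0)
        row["tod_cos"] = np.cos(2 * np.pi * hour / 24.0)
        rows.append(row)
    df = pd.DataFrame(rows, columns=META_COLUMNS + FEATURE_COLUMNS)
    return df
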