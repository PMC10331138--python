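"""CSV/JSON writers and readers for synthetic cohorts.

Layout of a cohort directory::

    manifest.json
    p000/accel.csv          timestamp,mean_change
    p000/audio.csv          timestamp,db_mean,db_min,db_max
    p000/light.csv          timestamp,lux_mean,lux_min,lux_max
    p000/notifications.csv  timestamp,app_id
    p000/screen.csv         on_time,off_time
    p000/ema.csv            prompt_time,answer_time,craving,day_index,slot
    ...

Timestamps are ISO-8601 UTC, derived from a configurable study epoch.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from .types import EmaRecord, Participant, SensorStreams

DEFAULT_EPOCH = "2023-01-02T00:00:00+00:00"


def _to_iso(seconds, epoch: str) -> pd.Series:
    base = pd.Timestamp(epoch).tz_convert("UTC").tz_localize(None)
    dt = pd.to_datetime(np.asarray(seconds, dtype=float), unit="s", origin=base)
    return pd.Series(dt.tz_localize("UTC")).dt.strftime("%Y-%m-%dT%H:%M:%S.%f%z")


def _from_iso(series: pd.Series, epoch: str) -> np.ndarray:
    base = pd.Timestamp(epoch)
    dt = pd.to_datetime(series, utc=True, format="ISO8601")
    return ((dt - base).dt.total_seconds().to_numpy()
            if hasattr(dt, "dt") else (dt - base).total_seconds().to_numpy())


def write_participant(p: Participant, outdir: Path, epoch: str = DEFAULT_EPOCH) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    s = p.streams
    pd.DataFrame({"timestamp": _to_iso(s.accel_t, epoch),
                  "mean_change": s.accel_mag}).to_csv(outdir / "accel.csv", index=False)
    pd.DataFrame({"timestamp": _to_iso(s.audio_t, epoch),
                  "db_mean": s.audio_db[:, 0], "db_min": s.audio_db[:, 1],
                  "db_max": s.audio_db[:, 2]}).to_csv(outdir / "audio.csv", index=False)
    pd.DataFrame({"timestamp": _to_iso(s.light_t, epoch),
                  "lux_mean": s.light_lux[:, 0], "lux_min": s.light_lux[:, 1],
                  "lux_max": s.light_lux[:, 2]}).to_csv(outdir / "light.csv", index=False)
    pd.DataFrame({"timestamp": _to_iso(s.notif_t, epoch),
                  "app_id": s.notif_app}).to_csv(outdir / "notifications.csv", index=False)
    pd.DataFrame({"on_time": _to_iso(s.screen[:, 0], epoch) if len(s.screen) else [],
                  "off_time": _to_iso(s.screen[:, 1], epoch) if len(s.screen) else [],
                  }).to_csv(outdir / "screen.csv", index=False)
    ema = pd.DataFrame({
        "prompt_time": _to_iso([e.prompt_time for e in p.ema], epoch),
        "answer_time": [(_to_iso([e.answer_time], epoch)[0] if e.answered else "")
                        for e in p.ema],
        "craving": [e.craving if e.answered else None for e in p.ema],
        "day_index": [e.day_index for e in p.ema],
        "slot": [e.slot for e in p.ema],
    })
    ema.to_csv(outdir / "ema.csv", index=False)


def read_participant(pid: str, pdir: Path, epoch: str = DEFAULT_EPOCH) -> Participant:
    pdir = Path(pdir)
    acc = pd.read_csv(pdir / "accel.csv")
    aud = pd.read_csv(pdir / "audio.csv")
    lig = pd.read_csv(pdir / "light.csv")
    noti = pd.read_csv(pdir / "notifications.csv")
    scr = pd.read_csv(pdir / "screen.csv")
    streams = SensorStreams(
        accel_t=_from_iso(acc["timestamp"], epoch) if len(acc) else np.empty(0),
        accel_mag=acc["mean_change"].to_numpy(dtype=float),
        audio_t=_from_iso(aud["timestamp"], epoch) if len(aud) else np.empty(0),
        audio_db=aud[["db_mean", "db_min", "db_max"]].to_numpy(dtype=float),
        light_t=_from_iso(lig["timestamp"], epoch) if len(lig) else np.empty(0),
        light_lux=lig[["lux_mean", "lux_min", "lux_max"]].to_numpy(dtype=float),
        notif_t=_from_iso(noti["timestamp"], epoch) if len(noti) else np.empty(0),
        notif_app=noti["app_id"].to_numpy(dtype=object),
        screen=(np.column_stack([_from_iso(scr["on_time"], epoch),
                                 _from_iso(scr["off_time"], epoch)])
                if len(scr) else np.empty((0, 2))),
    )
    ema_df = pd.read_csv(pdir / "ema.csv")
    ema: List[EmaRecord] = []
    for _, r in ema_df.iterrows():
        answered = isinstance(r["answer_time"], str) and r["answer_time"] != ""
        ema.append(EmaRecord(
            prompt_time=float(_from_iso(pd.Series([r["prompt_time"]]), epoch)[0]),
            day_index=int(r["day_index"]), slot=int(r["slot"]),
            answer_time=(float(_from_iso(pd.Series([r["answer_time"]]), epoch)[0])
                         if answered else None),
            craving=float(r["craving"]) if answered else None,
        ))
    return Participant(id=pid, streams=streams, ema=ema)


def write_cohort(cohort: List[Participant], outdir: Path, seed: Optional[int] = None,
                 config: Optional[dict] = None, epoch: str = DEFAULT_EPOCH) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for p in cohort:
        write_participant(p, outdir / p.id, epoch=epoch)
    manifest = {
        "participants": [p.id for p in cohort],
        "epoch": epoch,
        "seed": seed,
        "config": config or {},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_cohort(indir: Path) -> List[Participant]:
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    epoch = manifest.get("epoch", DEFAULT_EPOCH)
    return [read_participant(pid, indir / pid, epoch=epoch)
            for pid in manifest["participants"]]
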