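"""Cohort-level orchestration and reporting on top of the analysis modules."""
from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from . import evaluate, featurize, models
from .synthdata.cohort import CALIBRATION_REFERENCE, cohort_descriptives
from .synthdata.types import Participant

log = logging.getLogger("cravecast")

#: Eligibility rule: at least 50% of scheduled prompts answered and a
#: minimal fraction of sensor records present.
MIN_ANSWER_FRACTION = 0.50
MIN_AVAILABILITY = 0.20


def eligible(p: Participant) -> tuple:
    """(is_eligible, reason) under the study's inclusion rule."""
    n_prompts = len(p.ema)
    frac = len(p.answered) / n_prompts if n_prompts else 0.0
    if frac < MIN_ANSWER_FRACTION:
        return False, f"answered {frac:.0%} < {MIN_ANSWER_FRACTION:.0%} of prompts"
    if p.truth is not None and p.truth.availability_observed < MIN_AVAILABILITY:
        return False, (f"sensor availability "
                       f"{p.truth.availability_observed:.0%} < {MIN_AVAILABILITY:.0%}")
    return True, ""


def analyze_cohort(cohort: List[Participant], mode: str = "paper", seed: int = 0,
                   anchor: str = "answer", with_importance: bool = False,
                   apply_eligibility: bool = True) -> dict:
    """Run both arms for every eligible participant and summarize the cohort.

    Returns a dict with the per-participant score table, the cohort summary
    (means, SDs, fraction improved, Mann-Whitney comparison), exclusions,
    and optionally the grouped permutation-importance tables.
    """
    per_participant, exclusions, importances, runs = [], [], {}, {}
    for p in cohort:
        t_start = time.perf_counter()
        if apply_eligibility:
            ok, reason = eligible(p)
            if not ok:
                exclusions.append({"id": p.id, "reason": reason})
                log.info("excluded %s: %s", p.id, reason)
                continue
        try:
            sensor = models.run_participant(p, arm="sensor", mode=mode,
                                            seed=seed, anchor=anchor)
            base = models.run_participant(p, arm="baseline", mode=mode,
                                          seed=seed, anchor=anchor)
        except Exception as exc:  # participant failures are never cohort-fatal
            exclusions.append({"id": p.id, "reason": f"analysis error: {exc}"})
            log.exception("participant %s failed", p.id)
            continue
        if sensor.excluded or base.excluded:
            reason = sensor.reason or base.reason
            exclusions.append({"id": p.id, "reason": reason})
            log.info("excluded %s: %s", p.id, reason)
            continue
        s, b = sensor.selected, base.selected
        per_participant.append({
            "id": p.id,
            "sensor": evaluate.ScorePair(
                s.auc, s.brier,
                evaluate.hanley_mcneil_ci(s.auc, s.n_test_pos, s.n_test_neg)),
            "baseline": evaluate.ScorePair(
                b.auc, b.brier,
                evaluate.hanley_mcneil_ci(b.auc, b.n_test_pos, b.n_test_neg)),
        })
        runs[p.id] = {"sensor": sensor, "baseline": base}
        if with_importance:
            importances[p.id] = evaluate.permutation_importance(
                s.model, sensor.X_test, sensor.y_test, seed=seed)
        log.info("analyzed %s in %.1fs", p.id, time.perf_counter() - t_start)

    out = {"mode": mode, "exclusions": exclusions, "runs": runs,
           "n_analyzed": len(per_participant)}
    if len(per_participant) >= 2:
        table, summary = evaluate.cohort_summary(per_participant)
        out["table"], out["summary"] = table, summary
    else:
        out["table"], out["summary"] = pd.DataFrame(), {}
    if with_importance and importances:
        out["importance"] = mean_importance(importances)
        out["importance_per_participant"] = importances
    return out


def mean_importance(per_participant: dict) -> pd.DataFrame:
    """Cohort-averaged grouped permutation importance."""
    frames = [t["mean_drop"].rename(pid) for pid, t in per_participant.items()]
    mat = pd.concat(frames, axis=1)
    return pd.DataFrame({"mean_drop": mat.mean(axis=1), "sd_drop": mat.std(axis=1)}
                        ).sort_values("mean_drop", ascending=False)


def calibration_report(cohort: List[Participant]) -> pd.DataFrame:
    """Cohort descriptives side by side with the calibration reference."""
    desc = cohort_descriptives(cohort)
    rows = []
    for key, ref in CALIBRATION_REFERENCE.items():
        rows.append({"statistic": key, "cohort": desc.get(key), "reference": ref})
    return pd.DataFrame(rows)


def delta_chart(table: pd.DataFrame, path: Path) -> None:
    """Per-participant sensor-minus-baseline AUC bar chart."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    d = table.sort_values("delta_auc")
    fig, ax = plt.subplots(figsize=(max(6, 0.18 * len(d)), 4))
    ax.bar(range(len(d)), d["delta_auc"],
           color=np.where(d["delta_auc"] > 0, "#2b8cbe", "#d95f0e"))
    ax.axhline(0, color="k", lw=0.8)
    ax.set_xlabel("participant (sorted)")
    ax.set_ylabel("AUC difference (sensor - baseline)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def importance_chart(importance: pd.DataFrame, path: Path) -> None:
    """Cohort-mean grouped permutation-importance bar chart."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    d = importance.sort_values("mean_drop", ascending=False)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(d.index, d["mean_drop"], yerr=d.get("sd_drop"), color="#2b8cbe")
    ax.set_ylabel("mean AUC loss when group permuted")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
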