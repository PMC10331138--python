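"""Scoring, confidence intervals, cohort comparison, and grouped
permutation importance."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .featurize import FEATURE_GROUPS


def auc(labels: Sequence, scores: Sequence[float]) -> float:
    """Area under the ROC curve via the rank-sum (Mann-Whitney) identity.

    Equals the probability that a random positive outscores a random
    negative, with ties credited 0.5. Requires both classes.
    """
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = stats.rankdata(s)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def brier(labels: Sequence, probabilities: Sequence[float]) -> float:
    """Mean squared difference between predicted probability and label."""
    y = np.asarray(labels, dtype=float)
    p = np.asarray(probabilities, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    return float(np.mean((p - y) ** 2))


def hanley_mcneil_ci(a: float, n_pos: int, n_neg: int,
                     level: float = 0.90) -> Tuple[float, float]:
    """Closed-form AUC confidence interval after Hanley & McNeil.

    SE^2 = [A(1-A) + (n_pos-1)(Q1-A^2) + (n_neg-1)(Q2-A^2)] / (n_pos*n_neg)
    with Q1 = A/(2-A) and Q2 = 2A^2/(1+A); the two-sided ``level`` interval
    A +/- z*SE is clipped to [0, 1].
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one case per class")
    if not (0.0 <= a <= 1.0):
        raise ValueError("AUC must lie in [0, 1]")
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (a * (1 - a) + (n_pos - 1) * (q1 - a * a)
           + (n_neg - 1) * (q2 - a * a)) / (n_pos * n_neg)
    se = np.sqrt(max(var, 0.0))
    z = stats.norm.ppf(0.5 + level / 2.0)
    return float(np.clip(a - z * se, 0, 1)), float(np.clip(a + z * se, 0, 1))


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Two-sample Mann-Whitney U test, two-tailed.

    Returns (U, p) with the U statistic of the first sample
    (#{x_i > y_j} + 0.5 * #ties). The p-value uses exact enumeration for
    small tie-free samples (both n <= 8) and the tie-corrected normal
    approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class ScorePair:
    auc: float
    brier: float
    ci90: Tuple[float, float]


def score_pair(labels, scores, probabilities=None, level: float = 0.90) -> ScorePair:
    y = np.asarray(labels, dtype=bool)
    a = auc(y, scores)
    b = brier(y, probabilities if probabilities is not None else scores)
    return ScorePair(auc=a, brier=b,
                     ci90=hanley_mcneil_ci(a, int(y.sum()), int((~y).sum()), level))


def permutation_importance(model, X_test: pd.DataFrame, y_test: Sequence,
                           groups: Optional[Dict[str, List[str]]] = None,
                           n_rep: int = 50, seed: int = 0) -> pd.DataFrame:
    """Grouped permutation importance as mean AUC loss over ``n_rep`` shuffles.

    For each feature group, all its columns are shuffled jointly across the
    test rows (one fresh permutation per repetition), the model is rescored,
    and the AUC drop recorded. Negative drops are kept as-is — the
    construct is a difference of AUCs. Returns a DataFrame indexed by group
    with columns ``mean_drop`` and ``sd_drop``.
    """
    groups = groups or FEATURE_GROUPS
    y = np.asarray(y_test, dtype=bool)
    base = auc(y, model.predict_proba(X_test)[:, 1])
    rng = np.random.default_rng(seed)
    n = len(X_test)
    drops = {g: np.empty(n_rep) for g in groups}
    for rep in range(n_rep):
        for g, cols in groups.items():
            perm = rng.permutation(n)
            Xs = X_test.copy()
            Xs.loc[:, cols] = X_test[cols].to_numpy()[perm]
            drops[g][rep] = base - auc(y, model.predict_proba(Xs)[:, 1])
    return pd.DataFrame({
        "mean_drop": {g: float(d.mean()) for g, d in drops.items()},
        "sd_drop": {g: float(d.std(ddof=1)) for g, d in drops.items()},
    })


def cohort_summary(per_participant: List[dict]) -> Tuple[pd.DataFrame, dict]:
    """Cohort-level comparison of the sensor arm against the baseline arm.

    ``per_participant`` holds dicts with keys ``id``, ``sensor`` and
    ``baseline`` (ScorePair). Returns (per-participant table, summary dict)
    with cohort means/SDs/ranges, the fraction of participants whose sensor
    model beats their baseline, a Mann-Whitney comparison of the two AUC
    samples, and mean-of-bounds average confidence intervals.
    """
    if len(per_participant) < 2:
        raise ValueError("need at least 2 participants")
    rows = []
    for r in per_participant:
        s, b = r["sensor"], r["baseline"]
        rows.append({
            "id": r["id"],
            "sensor_auc": s.auc, "sensor_brier": s.brier,
            "sensor_ci_lo": s.ci90[0], "sensor_ci_hi": s.ci90[1],
            "baseline_auc": b.auc, "baseline_brier": b.brier,
            "baseline_ci_lo": b.ci90[0], "baseline_ci_hi": b.ci90[1],
            "delta_auc": s.auc - b.auc,
        })
    df = pd.DataFrame(rows)
    u, p = mann_whitney(df["sensor_auc"], df["baseline_auc"])

    def _stats(col):
        return {"mean": float(df[col].mean()), "sd": float(df[col].std(ddof=1)),
                "min": float(df[col].min()), "max": float(df[col].max()),
                "median": float(df[col].median())}

    summary = {
        "n": len(df),
        "sensor_auc": _stats("sensor_auc"),
        "baseline_auc": _stats("baseline_auc"),
        "sensor_brier": _stats("sensor_brier"),
        "baseline_brier": _stats("baseline_brier"),
        "delta_auc": _stats("delta_auc"),
        "fraction_sensor_better": float((df["delta_auc"] > 0).mean()),
        "mann_whitney_u": u,
        "mann_whitney_p": p,
        # mean-of-bounds aggregation of the per-person 90% intervals
        "sensor_mean_ci": (float(df["sensor_ci_lo"].mean()), float(df["sensor_ci_hi"].mean())),
        "baseline_mean_ci": (float(df["baseline_ci_lo"].mean()), float(df["baseline_ci_hi"].mean())),
    }
    return df, summary
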