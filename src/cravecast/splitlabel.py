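"""Individual craving binarization, greedy class-balanced day split, and
optional isolation-forest outlier removal.

Because craving distributions are strongly (and individually) skewed, each
participant's ratings are dichotomized at their own empirical 25%, 50% or
75% quantile. The 14 study days are then split day-wise into 10 training
and 4 test days by a greedy algorithm that, at each of 4 steps, adds the
single day minimizing the gap between the growing test set's high-craving
fraction and the full-data fraction — day-wise (not rating-wise) to retain
diurnal structure, and greedily because the last-4-days or random splits
leave most participants with badly imbalanced test sets.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import IsolationForest
from sklearn.impute import SimpleImputer


@dataclass
class LabelSpec:
    quantile_q: float
    threshold: float
    labels: np.ndarray  # boolean, True = high craving
    usable: bool

    def to_dict(self) -> dict:
        return {"quantile_q": self.quantile_q, "threshold": self.threshold,
                "labels": self.labels.astype(int).tolist(), "usable": self.usable}


@dataclass
class SplitSpec:
    test_days: List[int]
    train_days: List[int]
    target_ratio: float
    achieved_ratio: float = float("nan")

    def to_dict(self) -> dict:
        return {"test_days": list(self.test_days), "train_days": list(self.train_days),
                "target_ratio": self.target_ratio, "achieved_ratio": self.achieved_ratio}


def binarize(cravings: Sequence[float], q: float) -> LabelSpec:
    """Dichotomize ratings at the participant's own ``q``-quantile.

    The threshold is the linear-interpolation empirical quantile; a rating
    is *high* iff it is strictly above the threshold (strict, so that a
    zero-inflated majority at the 25% quantile stays in the low class).
    A spec whose classes are not both non-empty is marked unusable.
    """
    vals = np.asarray(cravings, dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 ratings to binarize")
    threshold = float(np.quantile(vals, q))
    labels = vals > threshold
    usable = bool(labels.any() and not labels.all()) and np.unique(vals).size >= 2
    return LabelSpec(quantile_q=q, threshold=threshold, labels=labels, usable=usable)


def day_table(labels: np.ndarray, day_index: Sequence[int]) -> pd.DataFrame:
    """Per-day high/low counts for the days with at least one rating."""
    df = pd.DataFrame({"day": np.asarray(day_index, dtype=int),
                       "high": np.asarray(labels, dtype=bool)})
    tab = df.groupby("day")["high"].agg(n_high="sum", n="count").reset_index()
    tab["n_low"] = tab["n"] - tab["n_high"]
    return tab[["day", "n_high", "n_low", "n"]]


def ratio_gap(table: pd.DataFrame, days: Iterable[int], target: float) -> float:
    """|high-fraction of the given days - target|; inf for an empty selection."""
    sel = table[table["day"].isin(list(days))]
    n = sel["n"].sum()
    if n == 0:
        return float("inf")
    return abs(sel["n_high"].sum() / n - target)


def greedy_test_days(table: pd.DataFrame, k: int = 4) -> SplitSpec:
    """Greedy day-wise selection of ``k`` test days.

    At each step the day (among those not yet selected, scanned in
    ascending day order) that minimizes the absolute difference between the
    growing test set's high fraction and the full-data high fraction is
    added; ties go to the earliest day.
    """
    days = table["day"].tolist()
    if len(days) < k:
        raise ValueError(f"need at least {k} days with ratings, got {len(days)}")
    total_n = table["n"].sum()
    target = table["n_high"].sum() / total_n
    chosen: List[int] = []
    sel_high = sel_n = 0
    counts = {int(r.day): (int(r.n_high), int(r.n)) for r in table.itertuples()}
    for _ in range(k):
        best_day, best_gap = None, np.inf
        for d in sorted(set(days) - set(chosen)):
            h, n = counts[d]
            gap = abs((sel_high + h) / (sel_n + n) - target)
            if gap < best_gap - 1e-12:
                best_day, best_gap = d, gap
        chosen.append(best_day)
        sel_high += counts[best_day][0]
        sel_n += counts[best_day][1]
    train = [d for d in sorted(days) if d not in chosen]
    return SplitSpec(test_days=sorted(chosen), train_days=train,
                     target_ratio=float(target),
                     achieved_ratio=float(sel_high / sel_n))


def remove_outliers(train_X: pd.DataFrame, train_labels: np.ndarray,
                    seed: int = 0, contamination: float = 0.05,
                    mode: str = "features",
                    craving: Optional[np.ndarray] = None) -> np.ndarray:
    """Isolation-forest outlier flagging on *training* rows only.

    Returns a boolean keep-mask over the training rows. ``mode='features'``
    (default) fits the forest on the mean-imputed feature vectors;
    ``mode='craving'`` fits it on the raw craving ratings alone. If removal
    would empty a class, the unfiltered mask is returned with a warning.
    """
    n = len(train_X)
    if n < 10:
        warnings.warn("fewer than 10 training rows; skipping outlier removal")
        return np.ones(n, dtype=bool)
    if mode == "features":
        X = SimpleImputer(strategy="mean", keep_empty_features=True).fit_transform(train_X)
    elif mode == "craving":
        if craving is None:
            raise ValueError("mode='craving' requires the craving values")
        X = np.asarray(craving, dtype=float).reshape(-1, 1)
    else:
        raise ValueError(f"unknown outlier mode {mode!r}")
    forest = IsolationForest(contamination=contamination, random_state=seed)
    keep = forest.fit_predict(X) == 1
    y = np.asarray(train_labels, dtype=bool)
    if not (y[keep].any() and (~y[keep]).any()):
        warnings.warn("outlier removal would empty a class; reverting to unfiltered")
        return np.ones(n, dtype=bool)
    return keep
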