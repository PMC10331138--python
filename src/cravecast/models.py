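"""Per-participant model grids and best-configuration selection.

The sensor arm individualizes along three axes: the craving split quantile
(25/50/75%), whether isolation-forest outlier removal is applied to the
training rows, and the learning algorithm (logistic regression, decision
tree, SVM, AdaBoost, gradient-boosted trees, multi-layer perceptron) —
3 x 2 x 6 = 36 candidate configurations. The baseline arm predicts the
current rating's class from the four immediately preceding answered
ratings, with a fixed median split: 2 x 6 = 12 configurations.

Two selection modes are provided. ``paper`` mode picks the configuration
with the highest *test-set* AUC, reproducing the original selection rule
and its optimism (the resulting score is an upper bound). ``honest`` mode
selects on an inner validation split carved out of the training days and
reports the test AUC of that single pre-registered winner.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from . import featurize
from .evaluate import auc, brier
from .splitlabel import binarize, day_table, greedy_test_days, remove_outliers
from .synthdata.types import EmaRecord, Participant

QUANTILES = (0.25, 0.50, 0.75)
ALGORITHM_ORDER = ("logreg", "tree", "svm", "adaboost", "xgboost", "mlp")
BASELINE_COLUMNS = ["prev1", "prev2", "prev3", "prev4"]


@dataclass(frozen=True)
class CandidateConfig:
    arm: str                 # "sensor" | "baseline"
    quantile_q: float
    outlier_removal: bool
    algorithm: str
    seed: int = 0


@dataclass
class CandidateResult:
    config: CandidateConfig
    auc: float = float("nan")
    brier: float = float("nan")
    n_test_pos: int = 0
    n_test_neg: int = 0
    model: object = None
    usable: bool = False
    note: str = ""


@dataclass
class ParticipantRun:
    participant_id: str
    arm: str
    mode: str
    results: List[CandidateResult] = field(default_factory=list)
    selected: Optional[CandidateResult] = None
    X_test: Optional[pd.DataFrame] = None
    y_test: Optional[np.ndarray] = None
    splits: dict = field(default_factory=dict)   # q -> SplitSpec
    labels: dict = field(default_factory=dict)   # q -> LabelSpec
    excluded: bool = False
    reason: str = ""


def enumerate_configs(arm: str, seed: int = 0) -> List[CandidateConfig]:
    """The candidate grid in deterministic order (q asc, outlier off/on,
    fixed algorithm order): 36 sensor or 12 baseline configurations."""
    if arm == "sensor":
        qs: Sequence[float] = QUANTILES
    elif arm == "baseline":
        qs = (0.50,)
    else:
        raise ValueError(f"unknown arm {arm!r}")
    return [CandidateConfig(arm=arm, quantile_q=q, outlier_removal=out,
                            algorithm=alg, seed=seed)
            for q in qs for out in (False, True) for alg in ALGORITHM_ORDER]


def _make_estimator(name: str, seed: int):
    if name == "logreg":
        return LogisticRegression(max_iter=1000, random_state=seed)
    if name == "tree":
        return DecisionTreeClassifier(random_state=seed)
    if name == "svm":
        return SVC(probability=True, random_state=seed)
    if name == "adaboost":
        return AdaBoostClassifier(random_state=seed)
    if name == "xgboost":
        return XGBClassifier(random_state=seed, n_jobs=1, verbosity=0,
                             eval_metric="logloss")
    if name == "mlp":
        return MLPClassifier(max_iter=500, random_state=seed)
    raise ValueError(f"unknown algorithm {name!r}")


def make_pipeline(algorithm: str, seed: int = 0) -> Pipeline:
    """Imputation (training-column means) + standardization + classifier."""
    return Pipeline([
        ("impute", SimpleImputer(strategy="mean", keep_empty_features=True)),
        ("scale", StandardScaler()),
        ("clf", _make_estimator(algorithm, seed)),
    ])


def fit_candidate(config: CandidateConfig, X_train: pd.DataFrame,
                  y_train: np.ndarray) -> Optional[Pipeline]:
    """Fit one candidate; returns None (unusable) for a one-class train set.

    All preprocessing statistics come from the training rows alone.
    """
    y = np.asarray(y_train, dtype=bool)
    if not (y.any() and (~y).any()):
        return None
    pipe = make_pipeline(config.algorithm, config.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", FutureWarning)
        pipe.fit(X_train, y.astype(int))
    return pipe


def select_best(results: List[CandidateResult]) -> CandidateResult:
    """Highest test AUC; ties by lower Brier, then enumeration order."""
    usable = [(i, r) for i, r in enumerate(results) if r.usable]
    if not usable:
        raise ValueError("no usable candidate results")
    return min(usable, key=lambda ir: (-ir[1].auc, ir[1].brier, ir[0]))[1]


def build_baseline_rows(ema: List[EmaRecord]) -> pd.DataFrame:
    """One row per answered rating with >= 4 answered predecessors.

    Predecessors are the four immediately preceding *answered* ratings in
    prompt order (unanswered prompts in between do not break the sequence,
    and predecessors may come from the previous day), oldest first.
    """
    answered = sorted([e for e in ema if e.answered], key=lambda e: e.prompt_time)
    if len(answered) < 5:
        warnings.warn("fewer than 5 answered ratings; baseline rows empty")
        return pd.DataFrame(columns=BASELINE_COLUMNS + ["craving", "day_index", "t0"])
    vals = [e.craving for e in answered]
    rows = []
    for i in range(4, len(answered)):
        rows.append({
            "prev1": vals[i - 4], "prev2": vals[i - 3],
            "prev3": vals[i - 2], "prev4": vals[i - 1],
            "craving": vals[i],
            "day_index": answered[i].day_index,
            "t0": answered[i].answer_time,
        })
    return pd.DataFrame(rows)


def _score(model: Pipeline, X: pd.DataFrame, y: np.ndarray):
    p = model.predict_proba(X)[:, 1]
    return auc(y, p), brier(y, p)


def run_participant(participant: Participant, arm: str = "sensor",
                    mode: str = "paper", seed: int = 0,
                    anchor: str = "answer", outlier_mode: str = "features",
                    k_test_days: int = 4, k_val_days: int = 3) -> ParticipantRun:
    """Run the full candidate grid for one participant and select a winner.

    ``mode='paper'`` selects by test-set AUC over all candidates;
    ``mode='honest'`` selects by AUC on an inner greedy validation split of
    the training days and then reports the winner's test-set score. In
    honest mode the per-candidate ``auc``/``brier`` stored in ``results``
    are validation scores, while ``selected`` carries test-set scores.
    """
    if mode not in ("paper", "honest"):
        raise ValueError("mode must be 'paper' or 'honest'")
    run = ParticipantRun(participant_id=participant.id, arm=arm, mode=mode)

    if arm == "sensor":
        df = featurize.build_feature_matrix(participant, anchor=anchor)
        feat_cols = featurize.FEATURE_COLUMNS
    elif arm == "baseline":
        df = build_baseline_rows(participant.ema)
        feat_cols = BASELINE_COLUMNS
    else:
        raise ValueError(f"unknown arm {arm!r}")
    if len(df) < 10:
        run.excluded, run.reason = True, "fewer than 10 usable rows"
        return run

    configs = enumerate_configs(arm, seed=seed)
    by_q: dict = {}
    for q in sorted({c.quantile_q for c in configs}):
        by_q[q] = _prepare_q(df, feat_cols, q, k_test_days, k_val_days)
        if by_q[q] is not None:
            run.labels[q] = by_q[q]["labels"]
            run.splits[q] = by_q[q]["split"]

    selected_ctx = None
    for idx, cfg in enumerate(configs):
        ctx = by_q[cfg.quantile_q]
        res = CandidateResult(config=cfg)
        if ctx is None:
            res.note = "unusable label/split for this quantile"
            run.results.append(res)
            continue
        if mode == "paper":
            X_fit, y_fit = ctx["X_train"], ctx["y_train"]
            X_eval, y_eval = ctx["X_test"], ctx["y_test"]
        else:
            if ctx.get("inner") is None:
                res.note = "unusable inner validation split"
                run.results.append(res)
                continue
            X_fit, y_fit = ctx["inner"]["X_train"], ctx["inner"]["y_train"]
            X_eval, y_eval = ctx["inner"]["X_val"], ctx["inner"]["y_val"]
        if cfg.outlier_removal:
            keep = remove_outliers(X_fit, y_fit, seed=cfg.seed, mode=outlier_mode,
                                   craving=ctx["craving_train"] if mode == "paper" else None)
            X_fit, y_fit = X_fit[keep], y_fit[keep]
        model = fit_candidate(cfg, X_fit, y_fit)
        if model is None:
            res.note = "one-class training set"
            run.results.append(res)
            continue
        if not (y_eval.any() and (~y_eval).any()):
            res.note = "one-class evaluation set"
            run.results.append(res)
            continue
        res.auc, res.brier = _score(model, X_eval, y_eval)
        res.n_test_pos = int(y_eval.sum())
        res.n_test_neg = int((~y_eval).sum())
        res.model = model
        res.usable = True
        run.results.append(res)

    usable = [r for r in run.results if r.usable]
    if not usable:
        run.excluded, run.reason = True, "no usable candidate configuration"
        return run

    best = select_best(run.results)
    ctx = by_q[best.config.quantile_q]
    if mode == "paper":
        run.selected = best
    else:
        # refit the pre-registered winner on the full training days and
        # report its test-set score
        X_fit, y_fit = ctx["X_train"], ctx["y_train"]
        if best.config.outlier_removal:
            keep = remove_outliers(X_fit, y_fit, seed=best.config.seed,
                                   mode=outlier_mode, craving=ctx["craving_train"])
            X_fit, y_fit = X_fit[keep], y_fit[keep]
        model = fit_candidate(best.config, X_fit, y_fit)
        y_test = ctx["y_test"]
        if model is None or not (y_test.any() and (~y_test).any()):
            run.excluded, run.reason = True, "winner not scorable on the test days"
            return run
        final = CandidateResult(config=best.config)
        final.auc, final.brier = _score(model, ctx["X_test"], y_test)
        final.n_test_pos = int(y_test.sum())
        final.n_test_neg = int((~y_test).sum())
        final.model = model
        final.usable = True
        final.note = f"validation AUC {best.auc:.3f}"
        run.selected = final
    run.X_test = ctx["X_test"]
    run.y_test = ctx["y_test"]
    return run


def _prepare_q(df: pd.DataFrame, feat_cols: List[str], q: float,
               k_test_days: int, k_val_days: int = 3) -> Optional[dict]:
    """Labels, greedy split, and train/test partitions for one quantile."""
    spec = binarize(df["craving"].to_numpy(), q)
    if not spec.usable:
        return None
    table = day_table(spec.labels, df["day_index"].to_numpy())
    if len(table) < k_test_days + 1:
        return None
    split = greedy_test_days(table, k=k_test_days)
    test_mask = df["day_index"].isin(split.test_days).to_numpy()
    y = spec.labels
    y_test = y[test_mask]
    y_train = y[~test_mask]
    if not (y_test.any() and (~y_test).any()):
        return None
    if not (y_train.any() and (~y_train).any()):
        return None
    ctx = {
        "labels": spec, "split": split,
        "X_train": df.loc[~test_mask, feat_cols],
        "y_train": y_train,
        "X_test": df.loc[test_mask, feat_cols],
        "y_test": y_test,
        "craving_train": df.loc[~test_mask, "craving"].to_numpy(),
    }
    # inner validation split of the training days (for honest mode)
    train_df = df[~test_mask]
    inner_table = day_table(y_train, train_df["day_index"].to_numpy())
    if len(inner_table) >= k_val_days + 1:
        inner_split = greedy_test_days(inner_table, k=k_val_days)
        val_mask = train_df["day_index"].isin(inner_split.test_days).to_numpy()
        y_val = y_train[val_mask]
        y_in = y_train[~val_mask]
        if (y_val.any() and (~y_val).any() and y_in.any() and (~y_in).any()):
            ctx["inner"] = {
                "X_train": train_df.loc[~val_mask, feat_cols],
                "y_train": y_in,
                "X_val": train_df.loc[val_mask, feat_cols],
                "y_val": y_val,
                "split": inner_split,
            }
        else:
            ctx["inner"] = None
    else:
        ctx["inner"] = None
    return ctx
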