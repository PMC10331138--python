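"""Scoring tests: AUC oracle equivalence, Brier, Hanley-McNeil interval,
Mann-Whitney conventions, grouped permutation importance, cohort summary."""
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from cravecast.evaluate import (ScorePair, auc, brier, cohort_summary,
                                hanley_mcneil_ci, mann_whitney,
                                permutation_importance)


def pair_count_auc(labels, scores):
    """Brute-force oracle: fraction of pos-neg pairs correctly ordered."""
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    num = den = 0.0
    for sp in s[y]:
        for sn in s[~y]:
            den += 1
            num += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return num / den


class TestAuc:
    def test_perfect_ranking(self):
        assert auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_ties_give_half(self):
        assert auc([0, 1, 0, 1], [0.5] * 4) == 0.5

    def test_documented_example(self):
        assert auc([0, 1, 0, 1], [0.2, 0.3, 0.4, 0.5]) == 0.75

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_pair_counting_oracle_and_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 50)
        y = rng.random(n) < 0.4
        if not (y.any() and (~y).any()):
            y[0], y[1] = True, False
        s = np.round(rng.random(n), 2)  # rounding forces some ties
        a = auc(y, s)
        assert a == pytest.approx(pair_count_auc(y, s))
        assert a == pytest.approx(roc_auc_score(y, s))

    def test_antisymmetry_for_tie_free_scores(self):
        rng = np.random.default_rng(3)
        y = np.array([0, 1] * 10, dtype=bool)
        s = rng.permutation(20).astype(float)
        assert auc(y, s) == pytest.approx(1.0 - auc(y, -s))

    def test_one_class_is_an_error(self):
        with pytest.raises(ValueError):
            auc([1, 1], [0.1, 0.2])


class TestBrier:
    def test_perfect_and_uninformative(self):
        assert brier([1, 0], [1.0, 0.0]) == 0.0
        assert brier([1, 0, 1, 0], [0.5] * 4) == 0.25

    def test_hand_arithmetic(self):
        assert brier([1, 0], [0.8, 0.4]) == pytest.approx(0.10)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            brier([1], [1.2])


class TestHanleyMcNeil:
    def test_degenerate_perfect_auc(self):
        assert hanley_mcneil_ci(1.0, 10, 10) == (1.0, 1.0)

    def test_hand_computed_chance_interval(self):
        # A=0.5, n=10/10: Q1=Q2=1/3, SE^2=(0.25+18*(1/3-0.25))/100=0.0175
        lo, hi = hanley_mcneil_ci(0.5, 10, 10, level=0.90)
        assert lo == pytest.approx(0.282, abs=0.001)
        assert hi == pytest.approx(0.718, abs=0.001)

    def test_width_shrinks_with_sample_size(self):
        widths = []
        for n in (5, 10, 25, 50, 100):
            lo, hi = hanley_mcneil_ci(0.75, n, n)
            widths.append(hi - lo)
        assert all(a > b for a, b in zip(widths, widths[1:]))

    @pytest.mark.parametrize("target_auc,n", [(0.6, 25), (0.75, 10), (0.9, 25)])
    def test_coverage_on_binormal_scores(self, target_auc, n):
        # the closed-form interval should roughly achieve its nominal level
        from scipy.stats import norm

        rng = np.random.default_rng(42)
        delta = float(np.sqrt(2) * norm.ppf(target_auc))  # AUC = Phi(delta/sqrt 2)
        cover = 0
        reps = 600
        for _ in range(reps):
            neg = rng.standard_normal(n)
            pos = rng.standard_normal(n) + delta
            a = auc([0] * n + [1] * n, np.concatenate([neg, pos]))
            lo, hi = hanley_mcneil_ci(a, n, n, level=0.90)
            cover += lo <= target_auc <= hi
        assert cover / reps >= 0.82  # mildly below nominal at small n is known


class TestMannWhitney:
    def test_complete_separation(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p < 0.2

    def test_identical_samples_symmetry(self):
        u, _ = mann_whitney([5, 5, 5], [5, 5, 5])
        assert u == 9 / 2

    def test_pair_enumeration_example(self):
        u, _ = mann_whitney([1, 3], [2, 4])
        assert u == 1.0  # only 3 > 2

    def test_large_sample_p_value_sane(self):
        rng = np.random.default_rng(0)
        x = rng.normal(1.0, 1, 56)
        y = rng.normal(0.0, 1, 56)
        u, p = mann_whitney(x, y)
        assert 0 <= u <= 56 * 56
        assert p < 1e-4


class _OneFeatureModel:
    """Scores = the value of a single column; perfect ranking feature."""

    def __init__(self, col):
        self.col = col

    def predict_proba(self, X):
        v = X[self.col].to_numpy(dtype=float)
        p = 1 / (1 + np.exp(-v))
        return np.column_stack([1 - p, p])


class TestPermutationImportance:
    def _data(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame({"a": np.linspace(-3, 3, n),
                          "b": rng.standard_normal(n),
                          "c": rng.standard_normal(n)})
        y = X["a"] > 0
        return X, y

    def test_irrelevant_group_has_near_zero_drop(self):
        X, y = self._data()
        imp = permutation_importance(_OneFeatureModel("a"), X, y,
                                     groups={"A": ["a"], "B": ["b"], "C": ["c"]},
                                     n_rep=50, seed=1)
        assert abs(imp.loc["B", "mean_drop"]) < 0.01
        assert abs(imp.loc["C", "mean_drop"]) < 0.01

    def test_single_perfect_feature_drop_approaches_half(self):
        X, y = self._data()
        imp = permutation_importance(_OneFeatureModel("a"), X, y,
                                     groups={"A": ["a"]}, n_rep=50, seed=2)
        # base AUC 1.0; shuffling destroys ranking -> expected drop ~ 0.5
        assert imp.loc["A", "mean_drop"] == pytest.approx(0.5, abs=0.03)

    def test_joint_shuffling_is_column_order_invariant(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(80, 4)), columns=list("abcd"))
        y = (X["a"] + X["b"]) > 0

        class TwoCol:
            def predict_proba(self, Z):
                v = Z["a"].to_numpy() + Z["b"].to_numpy()
                p = 1 / (1 + np.exp(-v))
                return np.column_stack([1 - p, p])

        i1 = permutation_importance(TwoCol(), X, y, groups={"G": ["a", "b"]},
                                    n_rep=20, seed=5)
        i2 = permutation_importance(TwoCol(), X, y, groups={"G": ["b", "a"]},
                                    n_rep=20, seed=5)
        assert i1.loc["G", "mean_drop"] == pytest.approx(i2.loc["G", "mean_drop"])

    def test_negative_drops_are_preserved(self):
        X, y = self._data(n=20, seed=6)
        imp = permutation_importance(_OneFeatureModel("b"), X, y,
                                     groups={"B": ["b"]}, n_rep=50, seed=7)
        assert np.isfinite(imp.loc["B", "mean_drop"])  # may well be < 0


class TestCohortSummary:
    def _pair(self, a, b):
        return {"sensor": ScorePair(a, 0.2, hanley_mcneil_ci(a, 10, 10)),
                "baseline": ScorePair(b, 0.25, hanley_mcneil_ci(b, 10, 10))}

    def test_identical_arms_give_zero_deltas(self):
        rows = [dict(id=i, **self._pair(0.7, 0.7)) for i in range(5)]
        df, summary = cohort_summary(rows)
        assert (df["delta_auc"] == 0).all()
        assert summary["fraction_sensor_better"] == 0.0

    def test_fraction_counts_positive_deltas(self):
        rows = [dict(id=0, **self._pair(0.8, 0.7)),
                dict(id=1, **self._pair(0.9, 0.7)),
                dict(id=2, **self._pair(0.65, 0.7))]
        _, summary = cohort_summary(rows)
        assert summary["fraction_sensor_better"] == pytest.approx(2 / 3)
        assert 0 <= summary["mann_whitney_u"] <= 9
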