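"""Model-grid tests: enumeration, fitting, selection, baseline rows,
leakage freedom, and null calibration."""
import numpy as np
import pandas as pd
import pytest

from cravecast import models
from cravecast.models import (CandidateConfig, CandidateResult,
                              build_baseline_rows, enumerate_configs,
                              fit_candidate, run_participant, select_best)
from cravecast.synthdata import EmaRecord
from conftest import make_full_participant


class TestEnumerateConfigs:
    def test_grid_sizes(self):
        assert len(enumerate_configs("sensor")) == 36
        assert len(enumerate_configs("baseline")) == 12

    def test_ordering_stable_and_documented(self):
        cfgs = enumerate_configs("sensor")
        assert cfgs == enumerate_configs("sensor")
        assert [c.quantile_q for c in cfgs[:12]] == [0.25] * 12
        assert [c.outlier_removal for c in cfgs[:12]] == [False] * 6 + [True] * 6
        assert [c.algorithm for c in cfgs[:6]] == list(models.ALGORITHM_ORDER)

    def test_baseline_uses_median_only(self):
        assert {c.quantile_q for c in enumerate_configs("baseline")} == {0.5}

    def test_unknown_arm_rejected(self):
        with pytest.raises(ValueError):
            enumerate_configs("both")


class TestFitCandidate:
    def _toy(self):
        X = pd.DataFrame({"f1": [0.0, 0.1, 1.0, 1.1] * 5,
                          "f2": [0.0, 0.2, 1.0, 0.9] * 5})
        y = np.array([False, False, True, True] * 5)
        return X, y

    def test_separable_toy_scores_perfectly(self):
        X, y = self._toy()
        cfg = CandidateConfig("sensor", 0.5, False, "logreg", 0)
        model = fit_candidate(cfg, X, y)
        from cravecast.evaluate import auc
        assert auc(y, model.predict_proba(X)[:, 1]) == 1.0

    def test_one_class_training_set_unusable(self):
        X, _ = self._toy()
        cfg = CandidateConfig("sensor", 0.5, False, "tree", 0)
        assert fit_candidate(cfg, X, np.ones(len(X), dtype=bool)) is None

    @pytest.mark.parametrize("algo", models.ALGORITHM_ORDER)
    def test_identical_seeds_give_identical_predictions(self, algo):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(60, 5)))
        X.columns = [f"f{i}" for i in range(5)]
        y = rng.random(60) < 0.5
        cfg = CandidateConfig("sensor", 0.5, False, algo, seed=3)
        p1 = fit_candidate(cfg, X, y).predict_proba(X)[:, 1]
        p2 = fit_candidate(cfg, X, y).predict_proba(X)[:, 1]
        assert np.array_equal(p1, p2)

    def test_shuffled_labels_score_near_chance(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(400, 6)),
                         columns=[f"f{i}" for i in range(6)])
        y_train = rng.random(400) < 0.5
        cfg = CandidateConfig("sensor", 0.5, False, "logreg", 0)
        model = fit_candidate(cfg, X, y_train)
        X2 = pd.DataFrame(rng.normal(size=(400, 6)), columns=X.columns)
        y2 = rng.random(400) < 0.5
        from cravecast.evaluate import auc
        assert auc(y2, model.predict_proba(X2)[:, 1]) == pytest.approx(0.5, abs=0.08)


class TestSelectBest:
    def _res(self, a, b):
        return CandidateResult(config=None, auc=a, brier=b, usable=True)

    def test_argmax_auc(self):
        picked = select_best([self._res(0.6, 0.2), self._res(0.9, 0.2),
                              self._res(0.7, 0.2)])
        assert picked.auc == 0.9

    def test_auc_tie_breaks_on_brier_then_order(self):
        first = self._res(0.8, 0.25)
        second = self._res(0.8, 0.20)
        assert select_best([first, second]) is second
        third = self._res(0.8, 0.20)
        assert select_best([second, third]) is second

    def test_no_usable_results_raises(self):
        with pytest.raises(ValueError):
            select_best([CandidateResult(config=None, usable=False)])


def _ema_seq(values, gap_after=None):
    out = []
    t = 0.0
    for i, v in enumerate(values):
        rec = EmaRecord(prompt_time=t, day_index=int(t // 86400), slot=1,
                        answer_time=t + 60.0, craving=float(v))
        out.append(rec)
        if gap_after is not None and i == gap_after:
            out.append(EmaRecord(prompt_time=t + 4500.0,
                                 day_index=int(t // 86400), slot=2))
        t += 9000.0
    return out


class TestBaselineRows:
    def test_five_ratings_make_one_row(self):
        df = build_baseline_rows(_ema_seq([1, 2, 3, 4, 5]))
        assert len(df) == 1
        assert df.iloc[0][["prev1", "prev2", "prev3", "prev4"]].tolist() == [1, 2, 3, 4]
        assert df.iloc[0]["craving"] == 5

    def test_seventy_ratings_make_sixty_six_rows(self):
        df = build_baseline_rows(_ema_seq(range(70)))
        assert len(df) == 66

    def test_unanswered_prompt_does_not_break_the_sequence(self):
        with_gap = build_baseline_rows(_ema_seq([1, 2, 3, 4, 5], gap_after=3))
        without = build_baseline_rows(_ema_seq([1, 2, 3, 4, 5]))
        pd.testing.assert_frame_equal(with_gap, without)

    def test_too_few_ratings_warns_and_is_empty(self):
        with pytest.warns(UserWarning):
            df = build_baseline_rows(_ema_seq([1, 2, 3]))
        assert df.empty


@pytest.fixture(scope="module")
def participant():
    return make_full_participant(seed=10)


class TestRunParticipant:
    def test_sensor_paper_mode_produces_36_results_one_selected(self, participant):
        run = run_participant(participant, arm="sensor", mode="paper", seed=0)
        assert len(run.results) == 36
        assert run.selected is not None and run.selected.usable
        usable_aucs = [r.auc for r in run.results if r.usable]
        assert run.selected.auc == max(usable_aucs)

    def test_baseline_arm_produces_12_results_median_split(self, participant):
        run = run_participant(participant, arm="baseline", mode="paper", seed=0)
        assert len(run.results) == 12
        assert {r.config.quantile_q for r in run.results} == {0.5}
        assert run.selected is not None

    def test_test_day_counts_partition_test_rows(self, participant):
        run = run_participant(participant, arm="sensor", mode="paper", seed=0)
        s = run.selected
        assert s.n_test_pos + s.n_test_neg == len(run.y_test)
        assert len(run.splits[s.config.quantile_q].test_days) == 4

    def test_perturbing_test_days_never_changes_fitted_parameters(self, participant):
        run1 = run_participant(participant, arm="sensor", mode="paper", seed=0)
        q = run1.selected.config.quantile_q
        test_days = set(run1.splits[q].test_days)

        # corrupt every sensor record falling on the selected test days
        p2 = type(participant)(id=participant.id,
                               streams=participant.streams.copy(),
                               ema=participant.ema, truth=participant.truth)
        s = p2.streams
        day = lambda t: (t // 86400).astype(int)
        s.accel_mag[np.isin(day(s.accel_t), list(test_days))] += 1e5
        s.audio_db[np.isin(day(s.audio_t), list(test_days))] += 1e5
        run2 = run_participant(p2, arm="sensor", mode="paper", seed=0)

        for r1, r2 in zip(run1.results, run2.results):
            assert r1.config == r2.config
            if r1.config.algorithm != "logreg" or not (r1.usable and r2.usable):
                continue
            if r1.config.quantile_q != q:
                continue
            m1 = r1.model
            m2 = r2.model
            assert np.allclose(m1.named_steps["impute"].statistics_,
                               m2.named_steps["impute"].statistics_)
            assert np.allclose(m1.named_steps["clf"].coef_,
                               m2.named_steps["clf"].coef_)

    def test_honest_mode_selects_on_validation_and_reports_test(self, participant):
        run = run_participant(participant, arm="sensor", mode="honest", seed=0)
        assert run.selected is not None
        assert "validation AUC" in run.selected.note

    def test_degenerate_participant_is_excluded_with_reason(self):
        p = make_full_participant(seed=11)
        for e in p.ema:
            if e.answered:
                e.craving = 7.0  # constant ratings: every quantile unusable
        run = run_participant(p, arm="sensor", mode="paper", seed=0)
        assert run.excluded
        assert run.reason
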