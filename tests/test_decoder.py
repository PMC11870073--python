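"""CV2 statistics, snippet features, balanced split and decoder behaviour."""

import numpy as np
import pytest

from licklock.core_io import CellRecording, LickTrain
from licklock.decoder import (
    FeatureWindow,
    balanced_split,
    classify_predictivity,
    cv2_series,
    decode_cell,
    extract_windows,
    train_eval,
)
from licklock.synth import BehaviourSpec, CellSpec, generate_session

FAST_TREES = {"n_estimators": 64}


class TestCv2:
    def test_regular_train_is_zero(self):
        np.testing.assert_array_equal(cv2_series(np.full(50, 0.01)), np.zeros(49))

    def test_printed_formula_example(self):
        assert cv2_series(np.array([0.010, 0.030]))[0] == pytest.approx(1.0)

    def test_values_in_range(self, rng):
        vals = cv2_series(rng.exponential(0.02, size=1000))
        assert np.all(vals >= 0) and np.all(vals < 2)

    def test_poisson_expectation_is_one(self):
        rng = np.random.default_rng(5)
        vals = cv2_series(rng.exponential(0.02, size=100_001))
        assert vals.mean() == pytest.approx(1.0, abs=0.01)

    def test_short_input_empty(self):
        assert cv2_series(np.array([0.01])).size == 0


def _session_windows(duration=1.0, licks=(), ss=(), cs=()):
    train = LickTrain(detect_times=np.asarray(licks, dtype=float),
                      session_duration=duration)
    cell = CellRecording("c", ss_times=np.asarray(ss, dtype=float),
                         cs_times=np.asarray(cs, dtype=float))
    return extract_windows(train, cell)


class TestExtractWindows:
    def test_tiling_arithmetic(self):
        wins = _session_windows(duration=1.0, ss=[0.5, 0.6, 0.7])
        starts = [w.t_start for w in wins]
        np.testing.assert_allclose(starts, [0.0, 0.19, 0.38, 0.57, 0.76])
        assert all(w.t_end - w.t_start == pytest.approx(0.2) for w in wins)

    def test_lick_labels(self):
        wins = _session_windows(duration=1.0, licks=[0.25], ss=[0.5, 0.6, 0.7])
        labels = {round(w.t_start, 2): w.label for w in wins}
        assert labels[0.19] == 1  # window [0.19, 0.39) contains 0.25
        assert labels[0.0] == 0 and labels[0.57] == 0

    def test_features_match_brute_force(self, rng):
        from licklock.decoder import cv2_series as cv2f
        for _ in range(25):
            duration = 20.0
            ss = np.sort(rng.uniform(0, duration, size=int(rng.integers(50, 400))))
            cs = np.sort(rng.uniform(0, duration, size=int(rng.integers(0, 20))))
            lt = np.sort(rng.uniform(0, duration, size=int(rng.integers(5, 60))))
            train = LickTrain(detect_times=lt, session_duration=duration)
            cell = CellRecording("c", ss_times=ss, cs_times=cs)
            wins = extract_windows(train, cell, impute_cv2=False)
            all_cv2 = cv2f(np.diff(ss))
            mid = ss[1:-1]
            for w in wins:
                in_w = lambda t: (t >= w.t_start) & (t < w.t_end)
                assert w.ss_rate == pytest.approx(np.sum(in_w(ss)) / 0.2)
                assert w.cs_rate == pytest.approx(np.sum(in_w(cs)) / 0.2)
                assert w.label == int(np.any(in_w(lt)))
                sel = in_w(mid)
                assert sel.any()  # impute_cv2=False drops undefined windows
                assert w.ss_cv2 == pytest.approx(all_cv2[sel].mean())

    def test_poisson_rate_recovered(self):
        rng = np.random.default_rng(8)
        ss = np.sort(rng.uniform(0, 200, size=12000))  # 60 Hz
        train = LickTrain(detect_times=np.array([1.0]), session_duration=200.0)
        cell = CellRecording("c", ss_times=ss, cs_times=np.array([]))
        wins = extract_windows(train, cell)
        rates = np.array([w.ss_rate for w in wins])
        se = rates.std(ddof=1) / np.sqrt(rates.size)
        assert abs(rates.mean() - 60.0) < 3 * se + 0.1

    def test_undefined_cv2_imputed_and_flagged(self):
        wins = _session_windows(duration=1.0, ss=[0.01, 0.02, 0.03, 0.05, 0.09])
        flagged = [w for w in wins if w.cv2_imputed]
        assert flagged and all(np.isfinite(w.ss_cv2) for w in wins)


class TestBalancedSplit:
    @staticmethod
    def _windows(n_lick, n_nolick):
        mk = lambda lab, i: FeatureWindow(i * 0.19, i * 0.19 + 0.2, 10.0, 1.0, 0.5, lab)
        return [mk(1, i) for i in range(n_lick)] + [mk(0, i) for i in range(n_nolick)]

    def test_two_thirds_of_smaller_class(self):
        train, test = balanced_split(self._windows(30, 90), seed_or_rng=0)
        labels = [w.label for w in train]
        assert labels.count(1) == 20 and labels.count(0) == 20
        assert len(test) == 80

    def test_equal_classes(self):
        m = 33
        train, test = balanced_split(self._windows(m, m), seed_or_rng=1)
        assert len(train) == 2 * int(np.floor(2 * m / 3))
        assert len(train) + len(test) == 2 * m

    @pytest.mark.parametrize("seed", range(5))
    def test_train_always_balanced(self, seed, rng):
        n1, n0 = int(rng.integers(10, 80)), int(rng.integers(10, 80))
        train, _ = balanced_split(self._windows(n1, n0), seed_or_rng=seed)
        labels = [w.label for w in train]
        assert labels.count(0) == labels.count(1)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            balanced_split(self._windows(0, 50), seed_or_rng=0)


class TestPredictivity:
    @pytest.mark.parametrize(
        "acc,expected",
        [
            ((54.0, 80.0), "non_predictive"),
            ((55.0, 55.0), "non_predictive"),  # boundary: strictly greater
            ((56.0, 56.0), "predictive"),
            ((65.0, 66.0), "predictive"),
            ((65.1, 65.1), "strongly_predictive"),
        ],
    )
    def test_boundaries(self, acc, expected):
        assert classify_predictivity(*acc) == expected


class TestTrainEval:
    @staticmethod
    def _separable_windows(n=120):
        out = []
        for i in range(n):
            lab = i % 2
            rate = 50.0 if lab else 10.0
            out.append(FeatureWindow(i * 0.19, i * 0.19 + 0.2, rate, 1.0, 0.5, lab))
        return out

    def test_perfectly_separable_is_perfect(self):
        wins = self._separable_windows()
        train, test = balanced_split(wins, seed_or_rng=0)
        rep = train_eval(train, test, model_params=FAST_TREES, seed=0)
        assert rep.acc_bout == 100.0 and rep.acc_interbout == 100.0
        assert rep.predictivity == "strongly_predictive"

    def test_attribution_follows_the_informative_feature(self):
        # signal only in CV2; rate features constant by construction
        rng = np.random.default_rng(3)
        wins = []
        for i in range(400):
            lab = i % 2
            cv2 = rng.normal(1.2 if lab else 0.6, 0.1)
            wins.append(FeatureWindow(i * 0.19, i * 0.19 + 0.2, 30.0, cv2, 0.5, lab))
        train, test = balanced_split(wins, seed_or_rng=0)
        rep = train_eval(train, test, model_params=FAST_TREES, seed=0)
        assert rep.attribution["ss_cv2"] > rep.attribution["ss_rate"]
        assert rep.attribution["ss_cv2"] > rep.attribution["cs_rate"]

    def test_degenerate_features_flagged(self):
        wins = [FeatureWindow(i * 0.19, i * 0.19 + 0.2, 10.0, 1.0, 0.5, i % 2)
                for i in range(60)]
        train, test = balanced_split(wins, seed_or_rng=0)
        rep = train_eval(train, test, model_params=FAST_TREES, seed=0)
        assert rep.degenerate

    def test_permuted_labels_near_chance(self):
        session, _ = generate_session(
            BehaviourSpec(), [CellSpec(ss_base_rate=50.0, ss_bout_gain=1.8)],
            duration=300.0, seed=2,
        )
        from licklock.decoder import extract_windows as ew
        wins = ew(session.licks, session.cells[0])
        rng = np.random.default_rng(0)
        labels = np.array([w.label for w in wins])
        rng.shuffle(labels)
        for w, lab in zip(wins, labels):
            w.label = int(lab)
        train, test = balanced_split(wins, seed_or_rng=0)
        rep = train_eval(train, test, model_params={"n_estimators": 128}, seed=0)
        assert 40.0 <= rep.acc_bout <= 60.0
        assert 40.0 <= rep.acc_interbout <= 60.0

    def test_strongly_modulated_cell_detected(self):
        session, _ = generate_session(
            BehaviourSpec(), [CellSpec(ss_base_rate=50.0, ss_bout_gain=1.8,
                                       ss_kappa=2.0)],
            duration=300.0, seed=4,
        )
        rep = decode_cell(session.licks, session.cells[0], seed=0,
                          model_params={"n_estimators": 256})
        assert rep.predictivity == "strongly_predictive"
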