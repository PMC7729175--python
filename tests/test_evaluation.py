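"""Cross-validation, permutation testing, ITR, and condition comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orthobci import datasets
from orthobci.controller import AttemptResult
from orthobci.evaluation import (compare_conditions, crossval, itr,
                                 online_report, permutation_test)


def _separable(rng, n=60):
    X = rng.normal(size=(2 * n, 4))
    y = np.repeat([0, 1], n)
    X[:, 0] += 10 * y
    return X, y


def _noise(rng, n=60, p=6):
    return rng.normal(size=(2 * n, p)), np.repeat([0, 1], n)


class TestCrossval:
    def test_separable_fixture_is_perfect(self, rng):
        X, y = _separable(rng)
        report = crossval(X, y, seed=0, method="rlda")
        assert report.acc_weighted == 100.0
        assert report.acc_weighted == pytest.approx(
            0.5 * (report.acc_target + report.acc_nontarget))

    def test_chance_level_on_independent_labels(self):
        rng = np.random.default_rng(4)
        accs = [crossval(*_noise(rng), seed=i, method="rlda").acc_weighted
                for i in range(20)]
        assert np.mean(accs) == pytest.approx(50.0, abs=6.0)

    def test_fold_assignment_deterministic(self, rng):
        X, y = _noise(rng)
        r1 = crossval(X, y, seed=7, method="rlda")
        r2 = crossval(X, y, seed=7, method="rlda")
        assert r1 == r2

    def test_small_class_rejected(self, rng):
        X = rng.normal(size=(8, 2))
        y = np.array([0] * 5 + [1] * 3)
        with pytest.raises(ValueError, match="need"):
            crossval(X, y, k=5, method="rlda")

    def test_weighted_identity_holds_per_report(self, rng):
        X, y = _noise(rng, n=40)
        report = crossval(X, y, seed=3, method="rlda")
        assert report.acc_weighted == pytest.approx(
            0.5 * (report.acc_target + report.acc_nontarget))


class TestPermutationTest:
    def test_separable_data_is_highly_significant(self, rng):
        X, y = _separable(rng, n=30)
        report = permutation_test(X, y, m=199, seed=0, method="rlda")
        assert report.p_value <= 0.005
        assert report.p_value > 0.0

    def test_null_rejection_rate_is_calibrated(self):
        rng = np.random.default_rng(8)
        hits = 0
        for rep in range(50):
            X, y = _noise(rng, n=20, p=4)
            report = permutation_test(X, y, m=99, seed=rep, method="rlda")
            hits += report.p_value <= 0.05
        assert hits / 50 <= 0.11

    def test_zero_permutations_rejected(self, rng):
        X, y = _noise(rng)
        with pytest.raises(ValueError, match="m must"):
            permutation_test(X, y, m=0)


class TestItr:
    @pytest.mark.parametrize("acc,t_avg,expected", [
        (1.00, 5.43, 28.56),
        (0.75, 10.22, 7.01),
        (1.00, 4.33, 35.82),
    ])
    def test_printed_operating_points(self, acc, t_avg, expected):
        _, rate = itr(acc, n_c=6, t_avg=t_avg)
        assert round(rate, 2) == pytest.approx(expected, abs=0.005)

    def test_chance_accuracy_carries_zero_information(self):
        bits, rate = itr(1 / 6, n_c=6, t_avg=9.9)
        assert bits == pytest.approx(0.0, abs=1e-12)
        assert rate == pytest.approx(0.0, abs=1e-12)

    def test_bits_monotone_above_chance(self):
        grid = np.linspace(1 / 6 + 1e-3, 1.0, 50)
        bits = [itr(a, 6, 1.0)[0] for a in grid]
        assert np.all(np.diff(bits) > 0)

    def test_halving_time_doubles_rate(self):
        _, r1 = itr(0.9, 6, 8.0)
        _, r2 = itr(0.9, 6, 4.0)
        assert r2 == pytest.approx(2 * r1)

    def test_boundary_and_validation(self):
        bits0, _ = itr(0.0, 6, 1.0)
        assert bits0 == pytest.approx(np.log2(6) + np.log2(1 / 5))
        with pytest.raises(ValueError):
            itr(1.2, 6, 1.0)
        with pytest.raises(ValueError):
            itr(0.5, 6, 0.0)
        with pytest.raises(ValueError):
            itr(0.5, 1, 1.0)

    @given(st.floats(0.2, 1.0), st.floats(0.5, 30.0))
    @settings(max_examples=50, deadline=None)
    def test_rate_scales_inversely_with_time(self, acc, t_avg):
        bits, rate = itr(acc, 6, t_avg)
        assert rate == pytest.approx(60.0 * bits / t_avg)


class TestOnlineReport:
    def test_simple_accuracy_arithmetic(self):
        attempts = ([AttemptResult(selected=2, selection_time_s=5.0)] * 9
                    + [AttemptResult(selected=None, selection_time_s=30.0,
                                     timed_out=True)] * 3)
        report = online_report(attempts, [2] * 12)
        assert report.acc_online == pytest.approx(75.00)
        assert report.n_sel == 9 and report.n_att == 12
        assert report.t_avg == pytest.approx(5.0)

    def test_all_timeouts(self):
        attempts = [AttemptResult(selected=None, selection_time_s=30.0,
                                  timed_out=True)] * 4
        report = online_report(attempts, [0, 1, 2, 3])
        assert report.acc_online == 0.0
        assert report.t_avg is None and report.itr == 0.0
        assert report.bits == pytest.approx(np.log2(6) + np.log2(1 / 5))

    def test_engineered_triple(self):
        attempts = [AttemptResult(selected=1, selection_time_s=4.0),
                    AttemptResult(selected=5, selection_time_s=6.0),
                    AttemptResult(selected=0, selection_time_s=8.0),
                    AttemptResult(selected=None, selection_time_s=30.0,
                                  timed_out=True)]
        report = online_report(attempts, [1, 5, 2, 0])
        # 2 of 4 correct, successful-correct times 4 and 6 s.
        assert report.acc_online == pytest.approx(50.0)
        assert report.t_avg == pytest.approx(5.0)
        bits, rate = itr(0.5, 6, 5.0)
        assert report.itr == pytest.approx(rate)

    def test_wrong_selection_time_not_averaged(self):
        attempts = [AttemptResult(selected=1, selection_time_s=4.0),
                    AttemptResult(selected=3, selection_time_s=20.0)]
        report = online_report(attempts, [1, 5])
        assert report.t_avg == pytest.approx(4.0)

    def test_empty_attempts_rejected(self):
        with pytest.raises(ValueError, match="attempt"):
            online_report([], [])


class TestCompareConditions:
    def test_identical_columns_give_null_result(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        t, p, extra = compare_conditions(x, x)
        assert (t, p) == (0.0, 1.0)
        assert extra["df"] == 3

    def test_published_paired_selection_times(self):
        without, with_ = datasets.paired_selection_times()
        t, p, extra = compare_conditions(without, with_)
        assert extra["df"] == 21
        assert t == pytest.approx(-3.67, abs=0.01)
        assert p == pytest.approx(0.001, abs=0.001)

    def test_swapping_columns_flips_sign(self, rng):
        a, b = rng.normal(size=(2, 10))
        t1, _, _ = compare_conditions(a, b)
        t2, _, _ = compare_conditions(b, a)
        assert t1 == pytest.approx(-t2)

    def test_ranksum_available(self, rng):
        a = rng.normal(0, 1, 15)
        b = rng.normal(2, 1, 12)
        stat, p, _ = compare_conditions(a, b, method="ranksum")
        assert p < 0.01

    def test_validation(self):
        with pytest.raises(ValueError):
            compare_conditions([1, 2], [1, 2])
        with pytest.raises(ValueError):
            compare_conditions([1, 2, 3], [1, 2], method="paired_t")
        with pytest.raises(ValueError):
            compare_conditions([1, 2, 3], [4], method="ranksum")
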