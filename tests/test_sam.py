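import numpy as np
import pandas as pd
import pytest

from circuc.datatypes import ExprMatrix, ValidationError
from circuc.sam import (
    SamParams,
    _cut_points,
    choose_s0,
    fold_change,
    pooled_se,
    sam_calibrate,
    sam_scores,
)
from circuc.synth import SimulationDesign, sample_table, simulate_feature_matrix


def _expr(values, samples=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExprMatrix(pd.DataFrame(values, index=[f"f{i}" for i in range(len(values))],
                                   columns=samples))


def _brute_force_d(case, control, s0):
    """Independent closed-formula computation of the modified t-score."""
    case, control = np.asarray(case, float), np.asarray(control, float)
    n1, n2 = len(case), len(control)
    ss = ((case - case.mean()) ** 2).sum() + ((control - control.mean()) ** 2).sum()
    s = np.sqrt((1 / n1 + 1 / n2) * ss / (n1 + n2 - 2))
    return (case.mean() - control.mean()) / (s + s0)


class TestScores:
    def test_identical_groups_score_zero(self):
        m = _expr([[5, 6, 5, 6, 5, 6, 5, 6]])
        mask = np.array([True] * 4 + [False] * 4)
        assert sam_scores(m, mask, 0.1)[0] == 0.0

    def test_label_swap_flips_sign(self):
        rng = np.random.default_rng(1)
        m = _expr(rng.normal(size=(5, 8)))
        mask = np.array([True] * 4 + [False] * 4)
        d1 = sam_scores(m, mask, 0.05)
        d2 = sam_scores(m, ~mask, 0.05)
        np.testing.assert_allclose(d2, -d1, atol=1e-12)

    def test_matches_independent_formula(self):
        case, control = [10, 11, 10, 11], [8, 9, 8, 9]
        m = _expr([case + control])
        mask = np.array([True] * 4 + [False] * 4)
        assert sam_scores(m, mask, 0.0)[0] == pytest.approx(
            _brute_force_d(case, control, 0.0), abs=1e-12)
        # and with a nonzero stabilizer
        assert sam_scores(m, mask, 0.3)[0] == pytest.approx(
            _brute_force_d(case, control, 0.3), abs=1e-12)

    def test_small_class_rejected(self):
        m = _expr([[1, 2, 3]])
        with pytest.raises(ValidationError):
            sam_scores(m, np.array([True, False, False]), 0.0)


class TestFoldChange:
    @pytest.mark.parametrize("shift,expected", [
        (0.0, 1.0), (1.0, 2.0), (-0.5, 2 ** -0.5),
    ])
    def test_log2_difference_maps_to_ratio(self, shift, expected):
        base = np.full(4, 7.0)
        m = _expr([np.concatenate([base + shift, base])])
        mask = np.array([True] * 4 + [False] * 4)
        assert fold_change(m, mask)[0] == pytest.approx(expected, abs=1e-12)


class TestChooseS0:
    def test_fixed_mode_bypasses_tuning(self, default_planted):
        _, expr, _, meta = default_planted
        mask = meta.groups_for(expr.sample_ids)
        res = sam_calibrate(expr, mask, SamParams(s0_mode="fixed", s0_value=0.123,
                                                  n_permutations=50, seed=0))
        assert res.s0 == 0.123

    def test_all_zero_variance_falls_back_to_epsilon(self):
        m = _expr(np.tile([[1.0], [2.0]], (1, 8)))
        mask = np.array([True] * 4 + [False] * 4)
        assert choose_s0(m, mask) == 1e-8

    def test_variance_increasing_with_mean_gives_positive_s0(self):
        rng = np.random.default_rng(8)
        base = np.linspace(2, 12, 400)
        sd = 0.05 + 0.08 * base
        X = base[:, None] + rng.normal(size=(400, 20)) * sd[:, None]
        mask = np.array([True] * 10 + [False] * 10)
        assert choose_s0(_expr(X), mask) > 0


class TestCalibration:
    def test_planted_features_called_with_few_false_calls(self, default_planted):
        _, expr, truth, meta = default_planted
        mask = meta.groups_for(expr.sample_ids)
        res = sam_calibrate(expr, mask, SamParams(n_permutations=200, seed=1))
        de = truth["is_de"].to_numpy()
        called = res.table["called"].to_numpy()
        assert (called & de).sum() >= 0.7 * de.sum()
        n_called = max(called.sum(), 1)
        assert (called & ~de).sum() / n_called <= 0.1
        assert (res.table.loc[called, "direction"] == "up").all()

    def test_q_values_bounded_by_target_for_called(self, default_planted):
        _, expr, _, meta = default_planted
        mask = meta.groups_for(expr.sample_ids)
        res = sam_calibrate(expr, mask, SamParams(n_permutations=100, seed=2))
        called = res.table["called"]
        assert (res.table.loc[called, "q_value"] <= res.fdr_target + 1e-12).all()
        assert res.table["q_value"].between(0, 1).all()

    def test_calls_monotone_in_delta(self, default_planted):
        _, expr, _, meta = default_planted
        mask = meta.groups_for(expr.sample_ids)
        res = sam_calibrate(expr, mask, SamParams(n_permutations=100, seed=3))
        d = res.table["score"].to_numpy()
        order = np.argsort(d, kind="stable")
        d_sorted = d[order]
        prev = None
        for delta in (0.2, 0.5, 1.0, 2.0):
            cut_up, cut_low = _cut_points(d_sorted, res.expected_order_scores, delta)
            called = set(np.nonzero((d >= cut_up) | (d <= cut_low))[0])
            if prev is not None:
                assert called <= prev
            prev = called

    def test_relabeling_invariance(self, small_planted):
        _, expr, _, meta = small_planted
        mask = meta.groups_for(expr.sample_ids)
        params = SamParams(n_permutations=100, seed=5)
        res_a = sam_calibrate(expr, mask, params)
        rng = np.random.default_rng(0)
        perm = rng.permutation(expr.shape[1])
        shuffled = ExprMatrix(expr.data.iloc[:, perm])
        res_b = sam_calibrate(shuffled, mask[perm], params)
        pd.testing.assert_series_equal(res_a.table["called"], res_b.table["called"])
        np.testing.assert_allclose(res_a.table["score"], res_b.table["score"],
                                   atol=1e-10)

    def test_exact_null_space_enumerated_when_small(self):
        rng = np.random.default_rng(4)
        m = _expr(rng.normal(size=(30, 8)))
        mask = np.array([True] * 4 + [False] * 4)
        res = sam_calibrate(m, mask, SamParams(n_permutations=1000, seed=0))
        assert res.n_permutations_used == 70  # C(8,4)

    def test_expected_order_scores_sorted(self, small_planted):
        _, expr, _, meta = small_planted
        mask = meta.groups_for(expr.sample_ids)
        res = sam_calibrate(expr, mask, SamParams(n_permutations=100, seed=6))
        assert np.all(np.diff(res.expected_order_scores) >= -1e-12)
        assert 0 < res.pi0 <= 1
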