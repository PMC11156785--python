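"""Combination algorithms: closed-form oracles, invariants, parameter search."""

import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from liverdwi.combine import (
    COMBINERS,
    OutlierExclusionParams,
    QtotalGridSearch,
    exception_set,
    grid_search,
    outlier_exclusion,
    p_mean,
    percentile_combine,
    weighted_average,
)
from liverdwi.floss import mip
from liverdwi.qscore import trace_reference

stack_strategy = arrays(
    np.float64,
    (3, 4, 6),
    elements=st.floats(min_value=0.0, max_value=10.0, allow_nan=False),
)


class TestWeightedAverage:
    def test_beta_zero_is_plain_mean(self):
        rng = np.random.default_rng(0)
        stack = rng.uniform(0, 2, (5, 5, 12))
        np.testing.assert_allclose(weighted_average(stack, 0.0), stack.mean(axis=2))

    def test_hand_arithmetic(self):
        stack = np.array([[[1.0, 3.0]]])
        assert weighted_average(stack, 1.0)[0, 0] == pytest.approx(2.5)

    def test_large_beta_approaches_max(self):
        stack = np.array([[[1.0, 3.0]]])
        assert weighted_average(stack, 50.0)[0, 0] == pytest.approx(3.0, abs=1e-6)

    def test_all_zero_voxel_yields_zero(self):
        stack = np.zeros((1, 1, 4))
        assert weighted_average(stack, 2.0)[0, 0] == 0.0

    def test_negative_beta_rejected(self):
        with pytest.raises(ValueError):
            weighted_average(np.ones((1, 1, 2)), -1.0)


class TestPMean:
    def test_p_one_is_mean(self):
        rng = np.random.default_rng(1)
        stack = rng.uniform(0, 2, (4, 4, 12))
        np.testing.assert_allclose(p_mean(stack, 1.0), stack.mean(axis=2))

    def test_hand_arithmetic(self):
        stack = np.array([[[1.0, 2.0, 3.0]]])
        assert p_mean(stack, 2.0)[0, 0] == pytest.approx(np.sqrt(14 / 3))

    def test_large_p_approaches_max(self):
        stack = np.array([[[1.0, 2.0, 3.0]]])
        assert p_mean(stack, 200.0)[0, 0] == pytest.approx(3.0, rel=1e-2)

    def test_p_below_one_rejected(self):
        with pytest.raises(ValueError):
            p_mean(np.ones((1, 1, 2)), 0.5)


class TestPercentile:
    def test_median_odd_n(self):
        rng = np.random.default_rng(2)
        stack = rng.uniform(0, 1, (3, 3, 5))
        np.testing.assert_allclose(
            percentile_combine(stack, 50), np.median(stack, axis=2)
        )

    def test_q100_is_mip(self):
        rng = np.random.default_rng(3)
        stack = rng.uniform(0, 1, (3, 3, 7))
        np.testing.assert_allclose(percentile_combine(stack, 100), mip(stack))

    def test_linear_interpolation(self):
        stack = np.array([[[1.0, 2.0, 3.0, 4.0]]])
        assert percentile_combine(stack, 75)[0, 0] == pytest.approx(3.25)


class TestOutlierExclusion:
    def test_k_zero_is_plain_mean(self):
        rng = np.random.default_rng(4)
        stack = rng.uniform(0, 2, (6, 6, 12))
        params = OutlierExclusionParams(k=0, ks2=3, thr=0.0)
        np.testing.assert_allclose(outlier_exclusion(stack, params), stack.mean(axis=2))

    def test_huge_threshold_is_plain_mean(self):
        rng = np.random.default_rng(5)
        stack = rng.uniform(0, 2, (6, 6, 12))
        params = OutlierExclusionParams(k=5, ks2=3, thr=1e6)
        np.testing.assert_allclose(outlier_exclusion(stack, params), stack.mean(axis=2))

    def test_hand_traced_exclusion(self):
        # voxel values (1, 1, 1, 0.1): 0.1 < mean - std = 0.385 -> excluded
        # at iteration 1; retained (1, 1, 1) has std 0 so iteration 2 stops
        stack = np.tile(np.array([1.0, 1.0, 1.0, 0.1]), (3, 3, 1))
        params = OutlierExclusionParams(k=2, ks2=1, thr=0.3)
        np.testing.assert_allclose(outlier_exclusion(stack, params), 1.0)

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            outlier_exclusion(np.ones((2, 2, 4)), OutlierExclusionParams(k=3))

    def test_equals_p_mean_one_without_exclusions(self):
        rng = np.random.default_rng(6)
        stack = rng.uniform(0.5, 1.5, (4, 4, 12))
        a = outlier_exclusion(stack, OutlierExclusionParams(k=0, ks2=3, thr=0.0))
        np.testing.assert_array_equal(a, p_mean(stack, 1.0))


def _naive_exception_set_voxel(values, max_excl, sf_min):
    """Stepwise enumeration oracle: try every single removal, pick the one
    with the lowest resulting variance, apply the smoothing-factor rule."""
    retained = list(values)
    for step in range(1, max_excl + 1):
        var_cur = statistics.pvariance(retained)
        candidates = [
            (statistics.pvariance(retained[:i] + retained[i + 1 :]), i)
            for i in range(len(retained))
        ]
        best_var, best_i = min(candidates)
        sf = (var_cur - best_var) * (len(retained) - 1) / step
        if sf > sf_min:
            retained.pop(best_i)
        else:
            break
    return sum(retained) / len(retained)


class TestExceptionSet:
    def test_equal_values_untouched(self):
        stack = np.full((2, 2, 6), 1.3)
        np.testing.assert_allclose(exception_set(stack, 2, 0.0), 1.3)

    def test_infinite_threshold_is_plain_mean(self):
        rng = np.random.default_rng(7)
        stack = rng.uniform(0, 2, (3, 3, 6))
        np.testing.assert_allclose(
            exception_set(stack, 2, np.inf), stack.mean(axis=2)
        )

    def test_single_dark_outlier_removed(self):
        stack = np.tile(np.array([1.0, 1.0, 1.0, 1.0, 1.0, 0.2]), (2, 2, 1))
        np.testing.assert_allclose(exception_set(stack, 2, 0.0), 1.0)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(8)
        stack = rng.uniform(0, 3, (25, 40, 6))  # 1000 voxels
        for sf_min in (0.0, 0.02):
            fast = exception_set(stack, 2, sf_min)
            flat = stack.reshape(-1, 6)
            slow = np.array(
                [_naive_exception_set_voxel(list(v), 2, sf_min) for v in flat]
            ).reshape(25, 40)
            np.testing.assert_allclose(fast, slow, rtol=1e-10)


class TestSharedInvariants:
    @pytest.mark.parametrize(
        "fn",
        [
            lambda s: weighted_average(s, 2.0),
            lambda s: p_mean(s, 3.0),
            lambda s: percentile_combine(s, 70),
            lambda s: outlier_exclusion(s, OutlierExclusionParams(k=2, ks2=3, thr=0.1)),
            lambda s: exception_set(s, 2, 0.0),
        ],
        ids=list(COMBINERS),
    )
    @given(stack=stack_strategy)
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_permutation_invariant_and_bounded(self, fn, stack):
        out = fn(stack)
        perm = np.random.default_rng(0).permutation(stack.shape[2])
        np.testing.assert_allclose(fn(stack[:, :, perm]), out, rtol=1e-9, atol=1e-12)
        assert (out >= stack.min(axis=2) - 1e-9).all()
        assert (out <= stack.max(axis=2) + 1e-9).all()


@pytest.fixture(scope="module")
def tiny_dataset():
    from liverdwi.phantom import PhantomConfig, generate_dataset

    cfg = PhantomConfig(height=64, width=64)
    return [(s.stack, s.rois) for s in generate_dataset(2, 2, cfg, seed=21)]


class TestGridSearch:

    def test_single_point_grid_returned(self, tiny_dataset):
        best, score, table = grid_search(tiny_dataset, "p_mean", [{"p": 2.0}])
        assert best == {"p": 2.0}
        assert len(table) == 1

    def test_argmax_and_table_consistency(self, tiny_dataset):
        grid = [{"q": 50.0}, {"q": 75.0}, {"q": 90.0}]
        gs = QtotalGridSearch(algorithm="percentile", grid=grid).fit(tiny_dataset)
        assert gs.best_score_ == pytest.approx(gs.results_["qtotal"].max())
        assert gs.best_params_ == grid[int(gs.results_["qtotal"].argmax())]
        assert len(gs.results_) == 3

    def test_dropout_correction_beats_plain_mean(self, tiny_dataset):
        # beta > 0 up-weights bright repetitions, filling left-lobe dropouts
        grid = [{"beta": 0.0}, {"beta": 3.0}]
        best, score, table = grid_search(tiny_dataset, "weighted_average", grid)
        assert best == {"beta": 3.0}
        assert score > table["qtotal"].min()

    def test_empty_grid_rejected(self, tiny_dataset):
        with pytest.raises(ValueError, match="grid"):
            grid_search(tiny_dataset, "p_mean", [])

    def test_unknown_algorithm_rejected(self, tiny_dataset):
        with pytest.raises(ValueError, match="unknown algorithm"):
            grid_search(tiny_dataset, "nope", [{}])
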