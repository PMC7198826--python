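import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dynconn.errors import DegenerateCorrelationWarning, DimensionError
from dynconn.networks import (
    build_cfcn,
    build_ho_dfcn,
    build_lo_dfcn,
    pearson,
    sliding_windows,
)

from conftest import random_dynnet


class TestPearson:
    def test_self_correlation(self, rng):
        x = rng.standard_normal(20)
        assert pearson(x, x) == pytest.approx(1.0)

    def test_sign_flip(self, rng):
        x = rng.standard_normal(20)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        assert pearson([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_zero_variance_returns_zero_with_warning(self):
        with pytest.warns(DegenerateCorrelationWarning):
            assert pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(DimensionError):
            pearson([1, 2], [1, 2, 3])

    def test_too_short(self):
        with pytest.raises(DimensionError):
            pearson([1.0], [2.0])


class TestStaticNetwork:
    def test_identical_columns_give_unit_correlation(self, rng):
        col = rng.standard_normal(30)
        data = np.column_stack([col, col, rng.standard_normal(30)])
        c = build_cfcn(data).values
        assert c[0, 1] == pytest.approx(1.0)

    def test_matches_pairwise_pearson(self, rng):
        data = rng.standard_normal((25, 3))
        c = build_cfcn(data).values
        for i in range(3):
            for j in range(i):
                assert c[i, j] == pytest.approx(pearson(data[:, i], data[:, j]))

    def test_full_scale_shape(self, rng):
        c = build_cfcn(rng.standard_normal((170, 116)))
        assert c.values.shape == (116, 116)

    def test_matrix_invariants(self, rng):
        c = build_cfcn(rng.standard_normal((40, 6))).values
        assert np.allclose(c, c.T, atol=1e-12)
        assert np.allclose(np.diag(c), 1.0)
        assert (np.abs(c) <= 1.0).all()


class TestSlidingWindows:
    def test_published_optimum(self):
        spans = sliding_windows(170, 60, 2)
        assert len(spans) == 56
        assert spans[0] == (0, 60)
        assert spans[-1] == (110, 170)

    def test_single_window_limit(self):
        assert sliding_windows(10, 10, 1) == [(0, 10)]

    def test_hand_enumeration(self):
        assert sliding_windows(10, 4, 3) == [(0, 4), (3, 7), (6, 10)]

    @pytest.mark.parametrize(
        "m,t,s", [(10, 11, 1), (10, 1, 1), (10, 4, 0)]
    )
    def test_invalid_parameters(self, m, t, s):
        with pytest.raises(DimensionError):
            sliding_windows(m, t, s)

    def test_count_formula_exhaustive(self):
        for m in range(2, 201, 7):
            for t in range(2, m + 1, 5):
                for s in range(1, 13, 3):
                    spans = sliding_windows(m, t, s)
                    assert len(spans) == (m - t) // s + 1
                    assert all(b - a == t for a, b in spans)
                    assert spans[-1][1] <= m


class TestLowOrderDynamicNetwork:
    def test_equals_slice_then_static(self, rng):
        data = rng.standard_normal((60, 5))
        dyn = build_lo_dfcn(data, 20, 20)
        assert dyn.n_windows == 3
        for k, (a, b) in enumerate(sliding_windows(60, 20, 20)):
            np.testing.assert_array_equal(dyn.windows[k], build_cfcn(data[a:b]).values)

    def test_static_limit(self, rng):
        data = rng.standard_normal((30, 4))
        dyn = build_lo_dfcn(data, 30, 1)
        assert dyn.n_windows == 1
        np.testing.assert_array_equal(dyn.windows[0], build_cfcn(data).values)

    def test_constant_roi_zeroed_in_every_window(self, rng):
        data = rng.standard_normal((40, 4))
        data[:, 2] = 7.0
        with pytest.warns(DegenerateCorrelationWarning):
            dyn = build_lo_dfcn(data, 20, 10)
        off = np.ones(4, dtype=bool)
        off[2] = False
        assert (dyn.windows[:, 2, off] == 0).all()
        assert (dyn.windows[:, 2, 2] == 1).all()


def _trim_then_pearson(c, i, j):
    keep = np.ones(c.shape[0], dtype=bool)
    keep[[i, j]] = False
    return pearson(c[i, keep], c[j, keep])


class TestHighOrderDynamicNetwork:
    def test_hand_oracle_on_four_rois(self, rng):
        dyn = random_dynnet(rng, n_windows=3, n_roi=4)
        ho = build_ho_dfcn(dyn)
        for k in range(3):
            for i in range(4):
                for j in range(i):
                    expected = _trim_then_pearson(dyn.windows[k], i, j)
                    assert ho.windows[k, i, j] == pytest.approx(expected)

    def test_identical_trimmed_profiles_give_unit_entry(self):
        # rows 0 and 1 agree on the trimmed positions {2, 3, 4}
        c = np.eye(5)
        prof = np.array([0.2, -0.4, 0.6])
        c[0, 2:] = prof
        c[1, 2:] = prof
        c[0, 1] = c[1, 0] = 0.1
        c = (c + c.T) / 2
        np.fill_diagonal(c, 1.0)
        dyn = random_dynnet(np.random.default_rng(0), 1, 5)
        dyn.windows[0] = c
        ho = build_ho_dfcn(dyn)
        assert ho.windows[0, 0, 1] == pytest.approx(1.0)

    def test_window_count_preserved(self, rng):
        dyn = random_dynnet(rng, n_windows=7, n_roi=5)
        assert build_ho_dfcn(dyn).n_windows == 7

    def test_too_few_rois(self, rng):
        with pytest.raises(DimensionError):
            build_ho_dfcn(random_dynnet(rng, 2, 3))

    def test_full_profile_mode(self, rng):
        dyn = random_dynnet(rng, 2, 5)
        ho = build_ho_dfcn(dyn, trim="full_profile")
        for k in range(2):
            expected = np.corrcoef(dyn.windows[k])
            np.testing.assert_allclose(
                ho.windows[k], expected, atol=1e-12
            )

    def test_matrix_invariants(self, rng):
        ho = build_ho_dfcn(random_dynnet(rng, 4, 6))
        for k in range(4):
            w = ho.windows[k]
            assert np.allclose(w, w.T, atol=1e-12)
            assert np.allclose(np.diag(w), 1.0)
            assert (np.abs(w) <= 1.0).all()

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(4, 7))
    def test_permutation_equivariance(self, seed, n):
        rng = np.random.default_rng(seed)
        dyn = random_dynnet(rng, 3, n)
        perm = rng.permutation(n)
        permuted = random_dynnet(rng, 3, n)
        permuted.windows = dyn.windows[:, perm][:, :, perm]
        ho = build_ho_dfcn(dyn).windows
        ho_perm = build_ho_dfcn(permuted).windows
        np.testing.assert_allclose(ho_perm, ho[:, perm][:, :, perm], atol=1e-12)
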