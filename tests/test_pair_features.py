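"""Pair assembly, min-max scaling, correlation/F-value selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from triface.pair_features import (
    PAIR_WIDTH,
    RESIDUE_DESCRIPTOR_WIDTH,
    NormalizationParams,
    SelectionResult,
    apply_minmax,
    assemble_pair,
    default_preserved_columns,
    f_value,
    fit_minmax,
    pair_columns,
    pearson_r,
    residue_descriptor_columns,
    select_features,
)


class TestAssemble:
    def test_dimensions(self):
        v = np.arange(RESIDUE_DESCRIPTOR_WIDTH, dtype=float)
        pair = assemble_pair(v, v + 100)
        assert pair.shape == (PAIR_WIDTH,) == (128,)
        assert np.all(pair[:64] == v) and np.all(pair[64:] == v + 100)

    def test_identical_descriptors_give_equal_halves(self):
        v = np.random.default_rng(0).normal(size=64)
        pair = assemble_pair(v, v)
        assert np.all(pair[:64] == pair[64:])

    def test_wrong_width_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            assemble_pair(np.zeros(63), np.zeros(64))

    def test_manifests(self):
        assert len(residue_descriptor_columns()) == 64
        assert len(pair_columns()) == 128
        preserved = default_preserved_columns()
        assert len(preserved) == 24
        names = pair_columns()
        assert all(
            names[i].split("_", 1)[1].startswith(("basic_",))
            or names[i].split("_", 1)[1]
            in ("asa_bound", "rasa", "eca", "ica", "eva")
            for i in preserved
        )


class TestMinMax:
    def test_direct_formula(self):
        col = np.array([[2.0], [4.0], [6.0]])
        out = apply_minmax(col, fit_minmax(col))
        assert out.ravel().tolist() == [0.0, 0.5, 1.0]

    def test_constant_column_maps_to_zero(self):
        col = np.full((3, 1), 5.0)
        assert np.all(apply_minmax(col, fit_minmax(col)) == 0.0)

    def test_test_time_clipping(self):
        params = fit_minmax(np.array([[0.0], [5.0]]))
        assert apply_minmax(np.array([[10.0]]), params)[0, 0] == 1.0
        assert apply_minmax(np.array([[-3.0]]), params)[0, 0] == 0.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            fit_minmax(np.empty((0, 4)))

    def test_json_roundtrip(self):
        params = fit_minmax(np.random.default_rng(1).normal(size=(5, 3)))
        back = NormalizationParams.from_json(params.to_json())
        assert np.allclose(back.minima, params.minima)
        assert np.allclose(back.maxima, params.maxima)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        arrays(
            float,
            st.tuples(st.integers(1, 12), st.integers(1, 6)),
            elements=st.floats(-1e6, 1e6),
        )
    )
    def test_training_output_always_in_unit_interval(self, X):
        out = apply_minmax(X, fit_minmax(X))
        assert np.all((out >= 0.0) & (out <= 1.0))


class TestPearson:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 2, 3], [1, 2, 3], 1.0),
            ([1, 2, 3], [3, 2, 1], -1.0),
            ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),
        ],
    )
    def test_hand_values(self, x, y, expected):
        assert pearson_r(np.array(x, float), np.array(y, float)) == pytest.approx(
            expected
        )

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            pearson_r(np.array([1.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0]))

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        arrays(float, 8, elements=st.floats(-100, 100)),
        arrays(float, 8, elements=st.floats(-100, 100)),
        st.floats(-5, 5).filter(lambda a: abs(a) > 1e-3),
        st.floats(-10, 10),
    )
    def test_symmetry_and_affine_invariance(self, x, y, a, b):
        if x.std() < 1e-6 or y.std() < 1e-6 or (a * x).std() < 1e-9:
            return
        r = pearson_r(x, y)
        assert pearson_r(y, x) == pytest.approx(r, abs=1e-9)
        assert pearson_r(a * x + b, y) == pytest.approx(
            np.sign(a) * r, rel=1e-6, abs=1e-6
        )


class TestFValue:
    def test_hand_value(self):
        assert f_value(np.array([2.0, 4.0]), np.array([0.0, 2.0])) == 1.0

    def test_identical_groups_zero(self):
        g = np.array([1.0, 5.0, 2.0])
        assert f_value(g, g.copy()) == 0.0

    def test_perfect_split_is_infinite(self):
        assert f_value(np.array([5.0, 5.0]), np.array([1.0, 1.0])) == np.inf

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            f_value(np.array([]), np.array([1.0]))


def _random_labelled_matrix(seed, n=20, p=30):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = np.zeros(n, bool)
    y[: n // 2] = True
    return X, y


class TestSelection:
    def test_uncorrelated_columns_all_retained(self):
        X, y = _random_labelled_matrix(0, n=40, p=10)
        res = select_features(X, y, r_threshold=0.95)
        assert res.retained == list(range(10))
        assert res.groups == []

    def test_duplicate_keeps_larger_f(self):
        rng = np.random.default_rng(5)
        n = 40
        y = np.zeros(n, bool)
        y[:20] = True
        strong = rng.normal(size=n) + 2.0 * y  # high F
        weak = rng.normal(size=n) + 0.2 * y  # low F
        X = np.column_stack([strong, strong.copy(), weak])
        res = select_features(X, y)
        assert 0 in res.retained and 1 not in res.retained
        assert [0, 1] in res.groups

    def test_preserved_column_survives_any_group(self):
        rng = np.random.default_rng(6)
        n = 40
        y = np.zeros(n, bool)
        y[:20] = True
        strong = rng.normal(size=n) + 2.0 * y
        X = np.column_stack([strong, strong.copy()])
        res = select_features(X, y, preserved=[1])
        assert 1 in res.retained

    def test_single_class_rejected(self):
        X = np.random.default_rng(1).normal(size=(10, 3))
        with pytest.raises(ValueError, match="both classes"):
            select_features(X, np.ones(10, bool))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_idempotence(self, seed):
        rng = np.random.default_rng(seed)
        n, p = 60, 15
        y = np.zeros(n, bool)
        y[:30] = True
        base = rng.normal(size=(n, 5))
        # build correlated clusters: each base column plus noisy copies
        X = np.column_stack(
            [base[:, i % 5] + 0.1 * rng.normal(size=n) for i in range(p)]
        )
        first = select_features(X, y)
        second = select_features(X[:, first.retained], y)
        assert second.retained == list(range(len(first.retained)))

    def test_retained_bounds(self):
        X, y = _random_labelled_matrix(3)
        preserved = [0, 1, 2]
        res = select_features(X, y, preserved=preserved)
        assert set(preserved) <= set(res.retained)
        assert len(res.retained) <= X.shape[1]

    def test_json_roundtrip(self):
        X, y = _random_labelled_matrix(4)
        res = select_features(X, y, preserved=[2])
        back = SelectionResult.from_json(res.to_json())
        assert back.retained == res.retained
        assert back.groups == res.groups
        assert back.preserved == res.preserved


class TestBruteForceOracles:
    """The vectorised operations against naive reimplementations."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_minmax_pearson_f_selection_vs_naive(self, seed):
        rng = np.random.default_rng(seed)
        n, p = 20, 30
        X = rng.normal(size=(n, p))
        X[:, 7] = X[:, 3] * 2.0 + 0.01 * rng.normal(size=n)  # planted correlation
        y = np.zeros(n, bool)
        y[: n // 2] = True

        # min-max by explicit loops
        params = fit_minmax(X)
        Xn = apply_minmax(X, params)
        for j in range(p):
            lo, hi = X[:, j].min(), X[:, j].max()
            for i in range(n):
                want = 0.0 if hi == lo else (X[i, j] - lo) / (hi - lo)
                assert Xn[i, j] == pytest.approx(min(1.0, max(0.0, want)))

        # pearson by the covariance formula
        for _ in range(10):
            a, b = rng.integers(0, p, size=2)
            if a == b or Xn[:, a].std() == 0 or Xn[:, b].std() == 0:
                continue
            xa, xb = Xn[:, a], Xn[:, b]
            want = ((xa - xa.mean()) * (xb - xb.mean())).mean() / (
                xa.std() * xb.std()
            )
            assert pearson_r(xa, xb) == pytest.approx(want)

        # F-value by group statistics
        for j in range(p):
            pos, neg = Xn[y, j], Xn[~y, j]
            want = abs(pos.mean() - neg.mean()) / (pos.std() + neg.std())
            assert f_value(pos, neg) == pytest.approx(want)

        # selection against a naive union-find over the |r| graph
        res = select_features(Xn, y, r_threshold=0.5)
        parent = list(range(p))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for a in range(p):
            for b in range(a + 1, p):
                if Xn[:, a].std() == 0 or Xn[:, b].std() == 0:
                    continue
                if abs(pearson_r(Xn[:, a], Xn[:, b])) > 0.5:
                    parent[find(a)] = find(b)
        expected = set()
        for root in {find(i) for i in range(p)}:
            members = [i for i in range(p) if find(i) == root]
            fvals = [
                f_value(Xn[y, m], Xn[~y, m]) for m in members
            ]
            expected.add(members[int(np.argmax(fvals))])
        assert set(res.retained) == expected
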