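"""JMI ranking, MI estimation, length selection, polynomial-kernel GDA, SJGDA."""

import numpy as np
import pytest

from riemannmi.classifiers import KNNClassifier
from riemannmi.sjgda import (
    GDAModel,
    discretize,
    gda_fit,
    gda_transform,
    jmi_rank,
    mutual_information,
    poly_kernel,
    select_length,
    sjgda_fit,
    sjgda_transform,
)
from riemannmi.spd import UNLABELLED


class TestDiscretize:
    def test_quartiles_balanced(self):
        X = np.arange(1, 101, dtype=float)[:, None]
        codes, _ = discretize(X, bins=4)
        counts = np.bincount(codes[:, 0])
        np.testing.assert_array_equal(counts, [25, 25, 25, 25])

    def test_constant_feature_single_bin(self):
        with pytest.warns(UserWarning, match="constant"):
            codes, _ = discretize(np.ones((10, 1)), bins=4)
        assert np.all(codes == 0)

    def test_gaussian_equal_frequency(self, rng):
        X = rng.standard_normal((800, 1))
        codes, _ = discretize(X, bins=8)
        counts = np.bincount(codes[:, 0], minlength=8)
        assert counts.max() - counts.min() <= 1

    def test_transform_is_monotone(self, rng):
        X = rng.standard_normal((200, 1))
        codes, disc = discretize(X, bins=8)
        order = np.argsort(X[:, 0])
        assert np.all(np.diff(codes[order, 0]) >= 0)


class TestMutualInformation:
    def test_independent_coins_vanishing(self):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 2, 100_000)
        b = rng.integers(0, 2, 100_000)
        assert mutual_information(a, b) <= 0.01

    def test_self_information_is_entropy(self, rng):
        a = rng.integers(0, 4, 500)
        p = np.bincount(a) / a.size
        H = -np.sum(p[p > 0] * np.log2(p[p > 0]))
        np.testing.assert_allclose(mutual_information(a, a), H, atol=1e-12)

    def test_hand_computed_joint_table(self):
        # counts [[2,1,0],[0,2,1],[1,0,2]] over 9 samples, terms by hand
        a = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2])
        b = np.array([0, 0, 1, 1, 1, 2, 0, 2, 2])
        joint = np.array([[2, 1, 0], [0, 2, 1], [1, 0, 2]]) / 9.0
        pa = joint.sum(axis=1)
        pb = joint.sum(axis=0)
        expected = sum(
            joint[i, j] * np.log2(joint[i, j] / (pa[i] * pb[j]))
            for i in range(3)
            for j in range(3)
            if joint[i, j] > 0
        )
        np.testing.assert_allclose(mutual_information(a, b), expected, atol=1e-12)

    def test_symmetry_nonnegativity_bounds(self, rng):
        for _ in range(20):
            a = rng.integers(0, 3, 50)
            b = rng.integers(0, 4, 50)
            iab = mutual_information(a, b)
            iba = mutual_information(b, a)
            np.testing.assert_allclose(iab, iba, atol=1e-12)
            assert iab >= 0
            assert iab <= min(mutual_information(a, a), mutual_information(b, b)) + 1e-12

    def test_exhaustive_binary_tables(self):
        # all pairs of binary sequences of length 5 vs a direct p log p sum
        seqs = [np.array([(i >> k) & 1 for k in range(5)]) for i in range(32)]
        for a in seqs[:16]:
            for b in seqs:
                expected = 0.0
                for va in (0, 1):
                    for vb in (0, 1):
                        p = np.mean((a == va) & (b == vb))
                        if p > 0:
                            pa, pb = np.mean(a == va), np.mean(b == vb)
                            expected += p * np.log2(p / (pa * pb))
                np.testing.assert_allclose(
                    mutual_information(a, b), max(expected, 0.0), atol=1e-12
                )


def exhaustive_jmi_order(Xd, y):
    """Independent greedy JMI: naive loops, recomputing every score."""
    n = Xd.shape[1]
    rel = [mutual_information(Xd[:, k], y) for k in range(n)]
    order = [int(np.argmax(rel))]
    while len(order) < n:
        best_k, best_s = None, -np.inf
        for k in range(n):
            if k in order:
                continue
            s = sum(
                mutual_information(np.column_stack([Xd[:, k], Xd[:, j]]), y)
                for j in order
            )
            if s > best_s + 1e-12:
                best_k, best_s = k, s
        order.append(best_k)
    return order


class TestJMIRank:
    def test_planted_relevant_feature_ranked_first(self):
        rng = np.random.default_rng(6)
        n = 2000
        y = rng.integers(0, 2, n)
        X = rng.standard_normal((n, 6))
        X[:, 3] = y + 0.1 * rng.standard_normal(n)
        ranking = jmi_rank(X, y)
        assert ranking.order[0] == 3

    def test_matches_exhaustive_greedy_oracle(self):
        rng = np.random.default_rng(42)
        n = 300
        y = rng.integers(0, 2, n)
        X = rng.standard_normal((n, 8))
        X[:, 0] += 0.8 * y
        X[:, 1] += 0.8 * y  # duplicate of the same signal
        X[:, 2] -= 0.6 * y
        Xd, _ = discretize(X, bins=4)
        ranking = jmi_rank(X, y, bins=4)
        assert list(ranking.order) == exhaustive_jmi_order(Xd, y)

    def test_redundant_duplicate_ranks_below_complementary(self):
        rng = np.random.default_rng(10)
        n = 3000
        bits = rng.integers(0, 2, (n, 2))
        y = bits[:, 0] * 2 + bits[:, 1]  # two complementary bits define y
        X = np.column_stack([
            bits[:, 0] + 0.05 * rng.standard_normal(n),
            bits[:, 0] + 0.05 * rng.standard_normal(n),  # duplicate
            bits[:, 1] + 0.05 * rng.standard_normal(n),  # complementary
            rng.standard_normal(n),
        ])
        ranking = jmi_rank(X, y, bins=4)
        order = list(ranking.order)
        # the complementary feature (2) must precede the duplicate of
        # whichever copy of bit 0 was taken first
        first = order[0]
        assert first in (0, 1)
        dup = 1 - first
        assert order.index(2) < order.index(dup)

    def test_empty_unlabelled_pool_identical_to_plain(self, rng):
        X = rng.standard_normal((200, 6))
        y = rng.integers(0, 2, 200)
        r1 = jmi_rank(X, y, use_unlabelled=False)
        r2 = jmi_rank(X, y, use_unlabelled=True)
        np.testing.assert_array_equal(r1.order, r2.order)
        np.testing.assert_array_equal(r1.scores, r2.scores)

    def test_semi_path_uses_unlabelled_rows(self, rng):
        X = rng.standard_normal((300, 5))
        y = rng.integers(0, 2, 300)
        X[:, 1] += 1.2 * y
        y_semi = y.copy()
        y_semi[200:] = UNLABELLED
        ranking = jmi_rank(X, y_semi, use_unlabelled=True)
        assert ranking.order[0] == 1

    def test_no_labelled_rows_rejected(self, rng):
        X = rng.standard_normal((10, 3))
        with pytest.raises(ValueError):
            jmi_rank(X, np.full(10, UNLABELLED))


class TestSelectLength:
    def test_planted_dimension_recovered(self):
        rng = np.random.default_rng(8)
        n = 400
        y = rng.integers(0, 2, n)
        X = rng.standard_normal((n, 20))
        X[:, :5] += 0.9 * np.outer(y, np.ones(5))  # 5 informative features
        ranking = jmi_rank(X, y)
        m = select_length(
            X, y, ranking, lambda: KNNClassifier(k=5), grid=range(1, 21),
            folds=5, seed=8,
        )
        assert 3 <= m <= 12

    def test_full_grid_single_value(self, rng):
        X = rng.standard_normal((60, 6))
        y = rng.integers(0, 2, 60)
        ranking = jmi_rank(X, y)
        m = select_length(X, y, ranking, lambda: KNNClassifier(k=5), grid=[6], folds=5)
        assert m == 6

    def test_all_noise_picks_smallest_by_tie_rule(self):
        # chance-level accuracy everywhere is not an exact tie, but the
        # smallest grid value must win when it is at least as good
        rng = np.random.default_rng(0)
        X = np.repeat(rng.standard_normal((4, 4)), 15, axis=0)  # duplicated rows
        y = np.tile([0, 1], 30)
        ranking = jmi_rank(X + 1e-9 * rng.standard_normal(X.shape), y)
        m = select_length(X, y, ranking, lambda: KNNClassifier(k=5),
                          grid=[2, 3, 4], folds=5, seed=0)
        assert m == 2

    def test_oversized_grid_truncated_with_warning(self, rng):
        X = rng.standard_normal((40, 4))
        y = rng.integers(0, 2, 40)
        ranking = jmi_rank(X, y)
        with pytest.warns(UserWarning, match="grid"):
            m = select_length(X, y, ranking, lambda: KNNClassifier(k=5),
                              grid=[2, 99], folds=5)
        assert m == 2


class TestPolyKernel:
    def test_degree_one_is_dot_product(self, rng):
        x, y = rng.standard_normal(5), rng.standard_normal(5)
        np.testing.assert_allclose(
            poly_kernel(x, y, degree=1, coef0=0.0, scale=1.0), x @ y
        )

    def test_zero_vectors_with_offset(self):
        z = np.zeros(4)
        for degree in (1, 2, 3):
            assert poly_kernel(z, z, degree=degree, coef0=1.0, scale=1.0) == 1.0

    def test_degree_two_explicit_feature_map(self, rng):
        # (x.y + 1)^2 equals the inner product of the explicit quadratic map
        x, y = rng.standard_normal(4), rng.standard_normal(4)

        def phi(v):
            sq = v**2
            cross = [np.sqrt(2) * v[i] * v[j] for i in range(4) for j in range(i + 1, 4)]
            return np.concatenate([sq, cross, np.sqrt(2) * v, [1.0]])

        np.testing.assert_allclose(
            poly_kernel(x, y, degree=2, coef0=1.0, scale=1.0),
            phi(x) @ phi(y),
            atol=1e-10,
        )


class TestGDA:
    def test_linearly_separable_projection_orders_classes(self, rng):
        X = np.vstack([rng.standard_normal((30, 3)), rng.standard_normal((30, 3))])
        X[30:, 0] += 8.0
        y = np.repeat([0, 1], 30)
        model = gda_fit(X, y, degree=1, coef0=0.0)
        t = model.train_projections[:, 0]
        assert max(t[:30]) < min(t[30:]) or min(t[:30]) > max(t[30:])

    def test_class_exchange_flips_sign(self, rng):
        X = rng.standard_normal((40, 3))
        X[20:, 1] += 3.0
        y = np.repeat([0, 1], 20)
        t1 = gda_fit(X, y).train_projections[:, 0]
        t2 = gda_fit(X, 1 - y).train_projections[:, 0]
        corr = np.corrcoef(t1, t2)[0, 1]
        assert abs(abs(corr) - 1.0) < 1e-6

    def test_xor_needs_nonlinear_kernel(self):
        rng = np.random.default_rng(17)
        centers = np.array([[1, 1], [-1, -1], [1, -1], [-1, 1]], dtype=float)
        X = np.vstack([c + 0.15 * rng.standard_normal((25, 2)) for c in centers])
        y = np.repeat([0, 0, 1, 1], 25)

        def overlap(model):
            t = model.train_projections[:, 0]
            lo0, hi0 = np.quantile(t[y == 0], [0.025, 0.975])
            inside = np.mean((t[y == 1] >= lo0) & (t[y == 1] <= hi0))
            return inside

        quad = gda_fit(X, y, degree=2, coef0=1.0, scale=1.0)
        lin = gda_fit(X, y, degree=1, coef0=0.0, scale=1.0)
        assert overlap(quad) <= 0.05
        assert overlap(lin) > 0.3

    def test_transform_consistent_with_training(self, rng):
        X = rng.standard_normal((30, 4))
        y = rng.integers(0, 2, 30)
        model = gda_fit(X, y)
        np.testing.assert_allclose(
            gda_transform(model, X), model.train_projections, atol=1e-8
        )

    def test_duplicate_training_point_identical_output(self, rng):
        X = rng.standard_normal((20, 3))
        X[5] = X[4]
        y = np.repeat([0, 1], 10)
        model = gda_fit(X, y)
        np.testing.assert_allclose(
            gda_transform(model, X[4]), gda_transform(model, X[5]), atol=1e-12
        )

    def test_matches_naive_double_loop(self, rng):
        X = rng.standard_normal((25, 3))
        y = rng.integers(0, 2, 25)
        model = gda_fit(X, y, degree=2, coef0=1.0, scale=0.5)
        for _ in range(50):
            q = rng.standard_normal(3)
            expected = np.zeros(model.d)
            for dim in range(model.d):
                s = model.offset[dim]
                for j in range(X.shape[0]):
                    s += model.beta[j, dim] * (0.5 * (X[j] @ q) + 1.0) ** 2
                expected[dim] = s
            np.testing.assert_allclose(gda_transform(model, q), expected, atol=1e-10)

    def test_row_permutation_invariance_up_to_sign(self, rng):
        X = rng.standard_normal((30, 3))
        X[15:, 2] += 2.0
        y = np.repeat([0, 1], 15)
        perm = rng.permutation(30)
        m1 = gda_fit(X, y)
        m2 = gda_fit(X[perm], y[perm])
        q = rng.standard_normal((5, 3))
        t1 = gda_transform(m1, q)[:, 0]
        t2 = gda_transform(m2, q)[:, 0]
        assert min(np.max(np.abs(t1 - t2)), np.max(np.abs(t1 + t2))) < 1e-6


class TestSJGDA:
    def test_output_layout_length(self, rng):
        X = rng.standard_normal((80, 15))
        y = rng.integers(0, 2, 80)
        X[:, 2] += 1.5 * y
        model = sjgda_fit(X, y, grid=[10], folds=5)
        assert model.m == 10
        z = sjgda_transform(model, X[0])
        assert z.shape == (11,)  # d=1 GDA output + 10 ranked features

    def test_determinism(self, rng):
        X = rng.standard_normal((60, 8))
        y = rng.integers(0, 2, 60)
        m1 = sjgda_fit(X, y, grid=[2, 4, 6], folds=5, seed=3)
        m2 = sjgda_fit(X, y, grid=[2, 4, 6], folds=5, seed=3)
        np.testing.assert_array_equal(m1.ranking.order, m2.ranking.order)
        assert m1.m == m2.m
        np.testing.assert_allclose(
            sjgda_transform(m1, X), sjgda_transform(m2, X), atol=0
        )

    def test_bin_count_insensitivity_of_top_feature(self, rng):
        X = rng.standard_normal((500, 6))
        y = rng.integers(0, 2, 500)
        X[:, 4] += 2.0 * y
        for bins in (4, 8, 16):
            assert jmi_rank(X, y, bins=bins).order[0] == 4
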