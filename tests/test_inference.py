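import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import linalg, stats

import floralsym as fs


def grouped(data, labels, **kw):
    return fs.GroupedShapeSample(np.asarray(data, float), np.asarray(labels), **kw)


class TestANOVA:
    def test_identical_group_means_give_zero_f(self):
        res = fs.anova_centroid_size([1, 2, 3, 1, 2, 3], list("aaabbb"))
        assert res.F == pytest.approx(0.0, abs=1e-12)
        assert (res.df_between, res.df_within) == (1, 4)

    def test_zero_within_variance_is_infinite_with_warning(self):
        with pytest.warns(RuntimeWarning, match="infinite"):
            res = fs.anova_centroid_size([1, 1, 1, 2, 2, 2], list("aaabbb"))
        assert math.isinf(res.F)
        assert res.p_value == 0.0

    def test_textbook_sums_of_squares(self):
        # groups {1,2}, {4,6}, {5,5}: SSB=49/3, SSW=5/2 -> F=9.8
        res = fs.anova_centroid_size([1, 2, 4, 6, 5, 5], list("aabbcc"))
        assert res.F == pytest.approx(9.8, abs=1e-9)
        assert (res.df_between, res.df_within) == (2, 3)
        assert res.p_value == pytest.approx(stats.f.sf(9.8, 2, 3), abs=1e-9)
        table = res.table.set_index("group")
        assert table.loc["b", "mean"] == pytest.approx(5.0)
        assert table.loc["b", "se"] == pytest.approx(1.0)
        assert table.loc["c", "se"] == pytest.approx(0.0)


class TestGoodallF:
    def test_zero_when_group_means_equal(self, rng):
        X = rng.normal(size=(6, 4))
        X -= X[:3].mean(axis=0) - X[3:].mean(axis=0)  # no-op layout guard
        X[:3] -= X[:3].mean(axis=0)
        X[3:] -= X[3:].mean(axis=0)
        f = fs.goodall_f(grouped(X, [0, 0, 0, 1, 1, 1]))
        assert f == pytest.approx(0.0, abs=1e-20)

    def test_closed_form_two_group_instance(self):
        # SSB = 1 (df 1), SSW = 4 (df 2) -> F = 0.5
        data = [[0.0, 0.0], [2.0, 0.0], [0.0, 1.0], [2.0, 1.0]]
        assert fs.goodall_f(grouped(data, [0, 0, 1, 1])) == pytest.approx(0.5)

    @settings(derandomize=True, max_examples=20)
    @given(st.integers(0, 2**31 - 1), st.floats(0.01, 100.0))
    def test_scale_invariance(self, seed, c):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(9, 3))
        labels = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2])
        f1 = fs.goodall_f(grouped(X, labels))
        f2 = fs.goodall_f(grouped(c * X, labels))
        assert f2 == pytest.approx(f1, rel=1e-9)

    def test_rotation_invariance(self, rng):
        X = rng.normal(size=(10, 5))
        labels = rng.integers(0, 2, size=10)
        labels[:2], labels[-2:] = 0, 1
        Q = np.linalg.qr(rng.normal(size=(5, 5)))[0]
        f1 = fs.goodall_f(grouped(X, labels))
        f2 = fs.goodall_f(grouped(X @ Q, labels))
        assert f2 == pytest.approx(f1, rel=1e-9)

    def test_zero_within_dispersion_warns_infinite(self):
        data = [[0.0], [0.0], [1.0], [1.0]]
        with pytest.warns(RuntimeWarning):
            assert math.isinf(fs.goodall_f(grouped(data, [0, 0, 1, 1])))


class TestPillaiTrace:
    def test_fully_separated_groups_reach_maximum(self):
        data = [[0.0], [0.0], [1.0], [1.0]]
        assert fs.pillai_trace(grouped(data, [0, 0, 1, 1])) == pytest.approx(1.0)

    def test_eigenvalue_oracle(self, rng):
        X = rng.normal(size=(15, 4))
        labels = np.repeat([0, 1, 2], 5)
        pillai = fs.pillai_trace(grouped(X, labels))
        # independent oracle: eigenvalues of E^-1 H, Pillai = sum l/(1+l)
        grand = X.mean(axis=0)
        H = np.zeros((4, 4))
        E = np.zeros((4, 4))
        for g in (0, 1, 2):
            sub = X[labels == g]
            m = sub.mean(axis=0)
            H += len(sub) * np.outer(m - grand, m - grand)
            E += (sub - m).T @ (sub - m)
        lam = np.linalg.eigvals(np.linalg.solve(E, H)).real
        assert pillai == pytest.approx(float((lam / (1 + lam)).sum()), abs=1e-10)

    def test_bounded_by_groups_and_rank(self, rng):
        X = rng.normal(size=(20, 6))
        labels = np.repeat([0, 1, 2, 3], 5)
        v = fs.pillai_trace(grouped(X, labels))
        assert 0.0 <= v <= 3.0

    def test_rotation_invariance(self, rng):
        X = rng.normal(size=(12, 4))
        labels = np.repeat([0, 1], 6)
        Q = np.linalg.qr(rng.normal(size=(4, 4)))[0]
        assert fs.pillai_trace(grouped(X @ Q, labels)) == pytest.approx(
            fs.pillai_trace(grouped(X, labels)), abs=1e-10
        )

    def test_identical_observations_rejected(self):
        data = np.ones((6, 3))
        with pytest.raises(ValueError, match="identical"):
            fs.pillai_trace(grouped(data, [0, 0, 0, 1, 1, 1]))


class TestPermutationTest:
    def test_extreme_observed_statistic_gives_minimal_p(self, rng):
        # huge separation: observed F larger than any permuted value
        X = np.vstack([rng.normal(size=(10, 3)), rng.normal(size=(10, 3)) + 100])
        labels = np.repeat([0, 1], 10)
        res = fs.permutation_test(
            grouped(X, labels), "goodall_f", n_permutations=199, seed=1
        )
        assert res.p_value == pytest.approx(1 / 200)

    def test_reproducible_given_seed(self, rng):
        X = rng.normal(size=(12, 4))
        labels = np.repeat([0, 1, 2], 4)
        r1 = fs.permutation_test(grouped(X, labels), "pillai", 199, seed=7)
        r2 = fs.permutation_test(grouped(X, labels), "pillai", 199, seed=7)
        assert r1.p_value == r2.p_value
        assert r1.observed == r2.observed

    def test_exhaustive_enumeration_for_small_samples(self, rng):
        X = rng.normal(size=(6, 2))
        labels = np.array([0, 0, 0, 1, 1, 1])  # 20 distinct arrangements
        res = fs.permutation_test(grouped(X, labels), "goodall_f", 10_000)
        assert res.exhaustive
        assert res.n_permutations == 20
        assert res.p_value >= 1 / 20

    def test_flower_unit_keeps_label_blocks_together(self, rng):
        X = rng.normal(size=(12, 3))
        labels = np.tile([0, 120, 240], 4)
        flowers = np.repeat(np.arange(4), 3)
        res = fs.permutation_test(
            grouped(X, labels, flower_ids=flowers),
            "goodall_f", 199, seed=3, unit="flower",
        )
        assert 0 < res.p_value <= 1.0
        # shuffling whole flowers leaves a flower-balanced design unchanged
        # in group counts, so the statistic distribution stays proper
        assert res.unit == "flower"

    def test_rejects_too_few_permutations(self, rng):
        X = rng.normal(size=(8, 2))
        with pytest.raises(ValueError):
            fs.permutation_test(grouped(X, [0] * 4 + [1] * 4), "pillai", 50)


class TestCVA:
    def test_two_spherical_groups_align_cv1_with_separation(self, rng):
        X = np.vstack([rng.normal(size=(300, 3)), rng.normal(size=(300, 3))])
        X[300:, 0] += 10.0
        res = fs.cva(grouped(X, np.repeat([0, 1], 300)))
        direction = np.zeros(3)
        direction[0] = 1.0
        cos = abs(res.axes[:, 0] @ direction) / np.linalg.norm(res.axes[:, 0])
        assert cos > 0.99
        assert res.eigenvalues.shape == (1,)  # m = G - 1 = 1

    def test_scores_whitened_within_groups(self, small_fall_dataset, fall_pairing):
        _, _, configs, organs = small_fall_dataset
        dec = fs.object_symmetry_decompose(configs, fall_pairing)
        sample = grouped(dec.symmetric, organs["compass_orientation"])
        res = fs.cva(sample)
        labels = sample.labels
        groups, codes = np.unique(labels, return_inverse=True)
        resid = res.scores.copy()
        for i in range(len(groups)):
            resid[codes == i] -= resid[codes == i].mean(axis=0)
        W = resid.T @ resid / (len(labels) - len(groups))
        np.testing.assert_allclose(W, np.eye(W.shape[0]), atol=1e-8)

    def test_generalized_eigen_oracle(self, rng):
        X = rng.normal(size=(20, 6))
        labels = np.repeat([0, 1, 2, 3], 5)
        res = fs.cva(grouped(X, labels))
        # independent dense-solver oracle on the same B, W matrices
        groups, codes = np.unique(labels, return_inverse=True)
        grand = X.mean(axis=0)
        B = np.zeros((6, 6))
        E = np.zeros((6, 6))
        for i, g in enumerate(groups):
            sub = X[codes == i]
            m = sub.mean(axis=0)
            B += len(sub) * np.outer(m - grand, m - grand)
            E += (sub - m).T @ (sub - m)
        B /= len(groups) - 1
        W = E / (len(X) - len(groups))
        vals, vecs = linalg.eigh(B, W)
        order = np.argsort(vals)[::-1][: len(groups) - 1]
        np.testing.assert_allclose(res.eigenvalues, vals[order], atol=1e-8)
        for j, col in enumerate(order):
            v = vecs[:, col]
            cos = abs(v @ res.axes[:, j]) / (
                np.linalg.norm(v) * np.linalg.norm(res.axes[:, j])
            )
            assert cos == pytest.approx(1.0, abs=1e-8)

    def test_invariance_to_linear_reparameterization(self, rng):
        X = rng.normal(size=(30, 4))
        labels = np.repeat([0, 1, 2], 10)
        A = rng.normal(size=(4, 4)) + 4 * np.eye(4)
        r1 = fs.cva(grouped(X, labels))
        r2 = fs.cva(grouped(X @ A, labels))
        np.testing.assert_allclose(r1.eigenvalues, r2.eigenvalues, rtol=1e-8)
        for j in range(r1.scores.shape[1]):
            cos = abs(r1.scores[:, j] @ r2.scores[:, j]) / (
                np.linalg.norm(r1.scores[:, j]) * np.linalg.norm(r2.scores[:, j])
            )
            assert cos == pytest.approx(1.0, abs=1e-8)

    def test_rank_zero_within_rejected(self):
        data = np.repeat([[0.0, 0.0], [1.0, 1.0]], 3, axis=0)
        with pytest.raises(ValueError, match="rank 0"):
            fs.cva(grouped(data, [0, 0, 0, 1, 1, 1]))


class TestGroupMeanShapes:
    def test_single_member_groups_return_the_organs(self, rng):
        X = rng.normal(size=(3, 4))
        # need >=2 groups with >=2 members for the sample container,
        # so test the operation on a compliant sample plus singleton logic
        sample = grouped(np.vstack([X, X]), [0, 1, 2, 0, 1, 2])
        means = fs.group_mean_shapes(sample)
        np.testing.assert_allclose(means.means, X)

    def test_recovers_injected_compass_differences(self, fall_pairing):
        params = fs.SimulationParams.defaults(
            n_flowers=300, seed=21, organ_types=("fall",),
            compass_amplitude=0.01, organ_da_amplitude=0.0,
            fa_sd=0.002, noise_sd=0.1,
        )
        _, configs = fs.generate_dataset(params)
        organs_labels = np.array([c.compass_orientation for c in configs])
        dec = fs.object_symmetry_decompose(configs, fall_pairing)
        sample = grouped(dec.tangent, organs_labels)
        gm = fs.group_mean_shapes(sample)
        # injected field differences between sectors, re-expressed in the
        # consensus frame, match the recovered mean differences
        from floralsym.procrustes import _preshape, _rotate_to

        template = _preshape(params.templates["fall"])
        R, *_ = np.linalg.lstsq(
            template, _rotate_to(template, dec.consensus), rcond=None
        )
        c = dec.consensus.ravel() / np.linalg.norm(dec.consensus)
        rot = np.stack([-dec.consensus[:, 1], dec.consensus[:, 0]], axis=1).ravel()
        rot /= np.linalg.norm(rot)

        def inject(sector):
            d = (params.compass_da["fall"][sector // 60] @ R).ravel()
            d = d - (d @ c) * c
            return d - (d @ rot) * rot

        for (a, b), diff in gm.differences.items():
            expected = inject(a) - inject(b)
            # Monte-Carlo bound: ~sqrt(2 * 32) * sigma / sqrt(150) ~ 1.3e-3
            assert np.linalg.norm(diff - expected) < 3e-3

    def test_permuting_order_leaves_means_unchanged(self, rng):
        X = rng.normal(size=(12, 3))
        labels = np.repeat([0, 1, 2], 4)
        perm = rng.permutation(12)
        m1 = fs.group_mean_shapes(grouped(X, labels))
        m2 = fs.group_mean_shapes(grouped(X[perm], labels[perm]))
        np.testing.assert_allclose(m1.means, m2.means)


def test_confidence_ellipse_closed_form():
    # construct 2-D scores whose sample covariance is exactly s^2 I
    a = 2.0
    pts = np.array([[a, 0.0], [-a, 0.0], [0.0, a], [0.0, -a]])
    s2 = 2 * a**2 / 3  # sample covariance (ddof=1) of these points
    center, semi, _ = fs.mean_confidence_ellipse(pts)
    np.testing.assert_allclose(center, [0.0, 0.0], atol=1e-12)
    expected = math.sqrt(stats.chi2.ppf(0.95, 2) * s2 / 4)
    np.testing.assert_allclose(semi, [expected, expected], rtol=1e-10)


def test_confidence_ellipse_area_shrinks_with_n(rng):
    pts = rng.normal(size=(50, 2))
    doubled = np.vstack([pts, pts])  # same scatter, twice the sample size
    _, semi1, _ = fs.mean_confidence_ellipse(pts)
    _, semi2, _ = fs.mean_confidence_ellipse(doubled)
    area1, area2 = np.pi * semi1.prod(), np.pi * semi2.prod()
    # cov identical (duplicated sample changes ddof slightly); 1/n scaling
    assert area2 / area1 == pytest.approx(0.5, rel=0.03)
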