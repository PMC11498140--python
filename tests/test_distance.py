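import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform

from dispersalshare import (
    AsvTable,
    DistanceMatrix,
    bray_curtis,
    distance_matrix,
    hellinger_distance,
    pairwise_permanova,
    pcoa,
    permanova,
    permdisp,
    sorensen,
    spatial_median,
)


def euclid_dm(points):
    d = squareform(pdist(points))
    return DistanceMatrix([f"p{i}" for i in range(len(points))], d)


class TestVectorDistances:
    def test_bray_identity(self):
        assert bray_curtis([2, 1, 0], [2, 1, 0]) == 0.0

    def test_bray_disjoint_is_one(self):
        assert bray_curtis([2, 0], [0, 3]) == 1.0

    def test_bray_worked_example(self):
        assert bray_curtis([2, 1, 0], [0, 1, 3]) == pytest.approx(5 / 7)

    def test_bray_all_zero_raises(self):
        with pytest.raises(ValueError):
            bray_curtis([0, 0], [0, 0])

    def test_sorensen_closed_form(self):
        # {A,B,C} vs {B,C,D}: a=2 shared, b=c=1 -> (1+1)/(4+1+1)
        assert sorensen([1, 1, 1, 0], [0, 1, 1, 1]) == pytest.approx(1 / 3)

    def test_sorensen_ignores_abundance(self):
        assert sorensen([9, 1], [1, 9]) == 0.0

    def test_hellinger_identity_and_range(self):
        assert hellinger_distance([3, 1], [3, 1]) == 0.0
        assert hellinger_distance([1, 0], [0, 1]) == pytest.approx(np.sqrt(2), abs=1e-12)

    def test_hellinger_worked_example(self):
        expected = np.sqrt((np.sqrt(0.5) - 1) ** 2 + 0.5)
        assert hellinger_distance([1, 1], [1, 0]) == pytest.approx(expected, abs=1e-10)

    def test_hellinger_zero_sum_raises(self):
        with pytest.raises(ValueError):
            hellinger_distance([0, 0], [1, 0])

    @given(
        st.lists(st.integers(0, 50), min_size=4, max_size=12),
        st.lists(st.integers(0, 50), min_size=4, max_size=12),
    )
    @settings(max_examples=100, deadline=None)
    def test_sorensen_equals_bray_on_presence(self, x, y):
        m = min(len(x), len(y))
        x, y = np.array(x[:m]), np.array(y[:m])
        if (x + y).sum() == 0:
            return
        assert sorensen(x, y) == bray_curtis(np.sign(x), np.sign(y))

    @given(
        st.lists(st.integers(0, 30), min_size=5, max_size=5),
        st.lists(st.integers(0, 30), min_size=5, max_size=5),
    )
    @settings(max_examples=60, deadline=None)
    def test_symmetry_and_bounds(self, x, y):
        x, y = np.array(x), np.array(y)
        if (x + y).sum() == 0:
            return
        assert bray_curtis(x, y) == pytest.approx(bray_curtis(y, x))
        assert 0 <= bray_curtis(x, y) <= 1
        if x.sum() > 0 and y.sum() > 0:
            d = hellinger_distance(x, y)
            assert 0 <= d <= np.sqrt(2) + 1e-12
            assert d == pytest.approx(hellinger_distance(y, x))


class TestDistanceMatrix:
    def test_matrix_matches_pair_functions(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 20, size=(6, 25))
        counts[counts.sum(axis=1) == 0, 0] = 1
        t = AsvTable([f"s{i}" for i in range(6)], [f"a{j}" for j in range(25)], counts)
        for metric, fn in (
            ("bray", bray_curtis),
            ("sorensen", sorensen),
            ("hellinger", hellinger_distance),
        ):
            D = distance_matrix(t, metric=metric)
            for i in range(6):
                for j in range(i + 1, 6):
                    assert D.values[i, j] == pytest.approx(
                        fn(counts[i], counts[j]), abs=1e-10
                    )

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [0.5, 0.0]]))


class TestPcoa:
    def test_points_on_a_line(self):
        D = euclid_dm(np.array([[0.0], [3.0], [4.0]]))
        ordn = pcoa(D)
        pos = ordn.eigenvalues[ordn.eigenvalues > 0]
        assert len(pos) == 1
        re_d = squareform(pdist(ordn.coordinates))
        assert np.allclose(re_d, D.values, atol=1e-8)

    def test_random_3d_embedding_recovered(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(10, 3))
        D = euclid_dm(pts)
        ordn = pcoa(D)
        pos = ordn.eigenvalues[ordn.eigenvalues > 0]
        assert len(pos) == 3
        re_d = squareform(pdist(ordn.coordinates))
        assert np.allclose(re_d, D.values, atol=1e-8)

    def test_equilateral_triangle_symmetry(self):
        d = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        ordn = pcoa(DistanceMatrix(["a", "b", "c"], d))
        pos = ordn.eigenvalues[ordn.eigenvalues > 0]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1], rel=1e-8)

    def test_axes_sorted_descending(self):
        rng = np.random.default_rng(9)
        D = euclid_dm(rng.normal(size=(12, 4)))
        ordn = pcoa(D)
        assert np.all(np.diff(ordn.eigenvalues) <= 1e-12)

    def test_matches_skbio(self):
        """Independent oracle: scikit-bio's PCoA on a non-Euclidean matrix."""
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(10)
        counts = rng.integers(0, 30, size=(8, 40))
        counts[:, 0] += 1
        t = AsvTable([f"s{i}" for i in range(8)], [f"a{j}" for j in range(40)], counts)
        D = distance_matrix(t, metric="bray")
        ours = pcoa(D)
        theirs = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(D.values, ids=D.ids), number_of_dimensions=3
        )
        n_pos = (ours.eigenvalues > 0).sum()
        assert np.allclose(
            np.abs(ours.coordinates[:, :3]),
            np.abs(theirs.samples.to_numpy()[:, :3]),
            atol=1e-6,
        )
        assert n_pos >= 3


def brute_force_pseudo_f(d, codes):
    """Independent SS computation, straight from the definition."""
    n = len(codes)
    groups = sorted(set(codes))
    ss_total = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_w = 0.0
    for g in groups:
        idx = [i for i in range(n) if codes[i] == g]
        ss_w += sum(
            d[i, j] ** 2 for ii, i in enumerate(idx) for j in idx[ii + 1 :]
        ) / len(idx)
    ss_a = ss_total - ss_w
    return (ss_a / (len(groups) - 1)) / (ss_w / (n - len(groups)))


class TestPermanova:
    def test_matches_brute_force(self):
        rng = np.random.default_rng(11)
        pts = np.vstack([rng.normal(0, 1, (4, 2)), rng.normal(5, 1, (4, 2))])
        D = euclid_dm(pts)
        groups = ["a"] * 4 + ["b"] * 4
        res = permanova(D, groups, n_perm=199, seed=0)
        assert res.statistic == pytest.approx(
            brute_force_pseudo_f(D.values, groups), abs=1e-10
        )
        assert res.permutation_p >= 1 / 200

    def test_min_p_floor(self):
        rng = np.random.default_rng(12)
        pts = np.vstack([rng.normal(0, 0.1, (6, 2)), rng.normal(50, 0.1, (6, 2))])
        res = permanova(euclid_dm(pts), ["a"] * 6 + ["b"] * 6, n_perm=999, seed=1)
        # permutations reproducing the observed partition tie with F_obs, so p
        # can sit slightly above the 1/(n_perm+1) floor but never below it
        assert 1 / 1000 <= res.permutation_p <= 3 / 1000

    def test_identical_points_f_zero(self):
        d = np.zeros((6, 6))
        res = permanova(DistanceMatrix([f"s{i}" for i in range(6)], d),
                        ["a"] * 3 + ["b"] * 3, n_perm=99, seed=0)
        assert res.statistic == 0.0

    def test_invariant_to_relabeling_and_order(self):
        rng = np.random.default_rng(13)
        pts = rng.normal(size=(10, 3))
        D = euclid_dm(pts)
        groups = ["x"] * 5 + ["y"] * 5
        f1 = permanova(D, groups, n_perm=9, seed=0).statistic
        f2 = permanova(D, ["B" if g == "x" else "A" for g in groups], n_perm=9, seed=0).statistic
        perm = rng.permutation(10)
        D2 = DistanceMatrix([D.ids[i] for i in perm], D.values[np.ix_(perm, perm)])
        f3 = permanova(D2, [groups[i] for i in perm], n_perm=9, seed=0).statistic
        assert f1 == pytest.approx(f2, abs=1e-12)
        assert f1 == pytest.approx(f3, abs=1e-10)

    def test_singleton_group_rejected(self):
        d = np.zeros((3, 3))
        with pytest.raises(ValueError, match="singleton"):
            permanova(DistanceMatrix(list("abc"), d), ["x", "x", "y"], n_perm=9, seed=0)


class TestPairwisePermanova:
    def _three_group_dm(self):
        rng = np.random.default_rng(14)
        pts = np.vstack(
            [rng.normal(0, 1, (4, 2)), rng.normal(4, 1, (4, 2)), rng.normal(8, 1, (4, 2))]
        )
        return euclid_dm(pts), ["a"] * 4 + ["b"] * 4 + ["c"] * 4

    def test_three_groups_three_contrasts(self):
        D, groups = self._three_group_dm()
        results = pairwise_permanova(D, groups, n_perm=99, seed=0)
        assert len(results) == 3
        pairs = {r.details["pair"] for r in results}
        assert pairs == {("a", "b"), ("a", "c"), ("b", "c")}

    def test_adjust_none_keeps_raw(self):
        D, groups = self._three_group_dm()
        results = pairwise_permanova(D, groups, n_perm=99, seed=0, adjust="none")
        for r in results:
            assert r.permutation_p == r.details["p_raw"]

    def test_bonferroni_closed_form(self):
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.03], method="bonferroni")[1]
        assert np.allclose(adj, [0.03, 0.06, 0.09])


class TestPermdisp:
    def test_mirror_groups_f_near_zero(self):
        pts = np.array([[1, 0], [-1, 0], [0, 1], [0, -1],
                        [2, 0], [-2, 0], [0, 2], [0, -2]], dtype=float)
        D = euclid_dm(pts)
        groups = ["a", "a", "a", "a", "b", "b", "b", "b"]
        res = permdisp(D, groups, n_perm=99, seed=0)
        # within each group all points are equidistant from the median (origin)
        assert res.f_statistic == pytest.approx(
            (res.ss_groups / res.df_groups) / (res.ss_residual / res.df_residual)
            if res.ss_residual > 0
            else res.f_statistic
        )
        assert np.allclose(res.distances[:4], 1.0, atol=1e-6)
        assert np.allclose(res.distances[4:], 2.0, atol=1e-6)

    def test_1d_hand_computed_anova(self):
        pts = np.array([[0.0], [0.001], [10.0], [10.001], [5.0], [5.001], [4.999], [5.002]])
        D = euclid_dm(pts)
        groups = ["a"] * 4 + ["b"] * 4
        res = permdisp(D, groups, n_perm=49, seed=0)
        # group a: median ~5, distances ~5 each; group b: distances ~0
        assert np.allclose(res.distances[:4], 5.0, atol=0.01)
        assert np.allclose(res.distances[4:], 0.0, atol=0.01)
        # hand-check one-way ANOVA on the exact distances
        z = res.distances
        grand = z.mean()
        ss_b = 4 * (z[:4].mean() - grand) ** 2 + 4 * (z[4:].mean() - grand) ** 2
        ss_w = ((z[:4] - z[:4].mean()) ** 2).sum() + ((z[4:] - z[4:].mean()) ** 2).sum()
        f_hand = (ss_b / 1) / (ss_w / 6)
        assert res.f_statistic == pytest.approx(f_hand, rel=1e-10)

    def test_spatial_median_vs_grid_search(self):
        rng = np.random.default_rng(15)
        pts = rng.normal(size=(9, 2))
        med = spatial_median(pts, tol=1e-10)
        xs = np.linspace(med[0] - 0.02, med[0] + 0.02, 41)
        ys = np.linspace(med[1] - 0.02, med[1] + 0.02, 41)
        best, best_val = None, np.inf
        for x in xs:
            for y in ys:
                val = np.linalg.norm(pts - [x, y], axis=1).sum()
                if val < best_val:
                    best, best_val = (x, y), val
        assert np.allclose(med, best, atol=1e-3)
        med_val = np.linalg.norm(pts - med, axis=1).sum()
        assert med_val <= best_val + 1e-6

    def test_weiszfeld_handles_coincident_points(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        med = spatial_median(pts)
        oracle = min(
            (np.linalg.norm(pts - c, axis=1).sum(), tuple(c))
            for c in np.mgrid[-0.2:1.2:0.01, -0.2:1.2:0.01].reshape(2, -1).T
        )
        assert np.linalg.norm(pts - med, axis=1).sum() <= oracle[0] + 1e-4
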