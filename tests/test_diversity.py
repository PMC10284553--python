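"""Diversity profiles, ANOVA, Bray-Curtis, PERMDISP and IndVal."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.distance import pdist, squareform

from conftest import make_relfreq
from ecoweave.diversity import (
    anova_compare,
    bray_curtis,
    dispersion_test,
    diversity_profile,
    geometric_median,
    indval,
)


class TestDiversityProfile:
    def test_uniform_profile_hill_equals_richness(self):
        rf = make_relfreq([[0.1, 0.1, 0.1, 0.1, 0.0]], ["complexity"])
        t = diversity_profile(rf).table
        assert t["richness"].iloc[0] == 4
        assert t["hill1"].iloc[0] == pytest.approx(4.0, abs=1e-12)

    def test_single_feature(self):
        rf = make_relfreq([[0.0, 0.3]], ["control"])
        t = diversity_profile(rf).table
        assert t["richness"].iloc[0] == 1
        assert t["hill1"].iloc[0] == pytest.approx(1.0)

    def test_skewed_profile_direct_entropy(self):
        # proportions (0.5, 0.25, 0.25): exp(H) = exp(1.5 ln 2) = 2^1.5
        rf = make_relfreq([[0.02, 0.01, 0.01]], ["control"])
        t = diversity_profile(rf).table
        assert t["hill1"].iloc[0] == pytest.approx(2 ** 1.5, rel=1e-12)

    def test_hill_never_exceeds_richness(self):
        rng = np.random.default_rng(42)
        X = rng.random((300, 23)) * (rng.random((300, 23)) < 0.4)
        X[X.sum(axis=1) == 0, 0] = 0.5
        rf = make_relfreq(X, ["control"] * 300)
        t = diversity_profile(rf).table
        assert (t["hill1"] <= t["richness"] + 1e-9).all()
        assert (t["hill1"] >= 1 - 1e-12).all()

    def test_zero_row_rejected(self):
        rf = make_relfreq([[0.0, 0.0], [0.1, 0.0]], ["control", "complexity"])
        with pytest.raises(ValueError, match="drop_featureless"):
            diversity_profile(rf)


class TestAnova:
    def test_worked_example(self):
        res = anova_compare([1, 2, 3, 4, 5, 6], ["a", "a", "a", "b", "b", "b"])
        assert res["F"] == pytest.approx(13.5, rel=1e-12)
        assert (res["df1"], res["df2"]) == (1, 4)

    def test_identical_groups_f_zero(self):
        res = anova_compare([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert res["F"] == pytest.approx(0.0, abs=1e-12)

    def test_single_member_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            anova_compare([1, 2, 3], ["a", "a", "b"])


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        d = bray_curtis(np.array([[0.1, 0.2], [0.1, 0.2]]))
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_one(self):
        d = bray_curtis(np.array([[0.5, 0.0], [0.0, 0.7]]))
        assert d[0, 1] == pytest.approx(1.0)

    def test_direct_formula(self):
        d = bray_curtis(np.array([[0.2, 0.8], [0.8, 0.2]]))
        assert d[0, 1] == pytest.approx(0.6, rel=1e-12)

    def test_zero_row_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis(np.array([[0.0, 0.0], [0.1, 0.2]]))


def brute_force_median_distances(points, groups):
    """Oracle: Euclidean distances to each group's geometric median, found by
    plain fixed-point iteration in the original coordinates (no PCoA)."""
    out = np.zeros(len(points))
    for g in np.unique(groups):
        pts = points[groups == g]
        y = pts.mean(axis=0)
        for _ in range(100000):
            w = 1.0 / np.linalg.norm(pts - y, axis=1)
            y_new = (pts * w[:, None]).sum(axis=0) / w.sum()
            if np.linalg.norm(y_new - y) < 1e-15:
                break
            y = y_new
        # sanity: no cheaper point nearby (convex objective)
        base = np.linalg.norm(pts - y, axis=1).sum()
        assert minimize(
            lambda z: np.linalg.norm(pts - z, axis=1).sum(), y, method="Nelder-Mead"
        ).fun >= base - 1e-8
        out[groups == g] = np.linalg.norm(pts - y, axis=1)
    return out


class TestDispersion:
    def test_euclidean_input_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        pts = np.vstack([rng.normal(0, 1, (9, 3)), rng.normal(2, 2, (11, 3))])
        groups = np.array(["a"] * 9 + ["b"] * 11)
        d = squareform(pdist(pts))
        res = dispersion_test(d, groups)
        oracle = brute_force_median_distances(pts, groups)
        assert np.abs(res.distances.to_numpy() - oracle).max() < 1e-8
        anova = anova_compare(oracle, groups)
        assert res.F == pytest.approx(anova["F"], rel=1e-9)

    def test_mirror_image_groups_have_equal_dispersion(self):
        pts_a = np.array([[0.0, 0], [1, 0], [0, 1], [1, 1], [0.5, 2]])
        pts_b = pts_a * np.array([-1.0, 1.0]) + np.array([10.0, 0.0])
        pts = np.vstack([pts_a, pts_b])
        groups = np.array(["a"] * 5 + ["b"] * 5)
        res = dispersion_test(squareform(pdist(pts)), groups)
        assert res.F == pytest.approx(0.0, abs=1e-18)
        means = res.group_stats["mean"]
        assert means["a"] == pytest.approx(means["b"], rel=1e-10)

    def test_identical_point_group_zero_distances(self):
        pts = np.array([[0.0, 0], [0, 0], [0, 0], [5, 5], [6, 5], [5, 6]])
        groups = np.array(["same"] * 3 + ["other"] * 3)
        res = dispersion_test(squareform(pdist(pts)), groups)
        assert np.allclose(res.distances.to_numpy()[:3], 0.0, atol=1e-10)

    def test_all_identical_points_rejected(self):
        d = np.zeros((6, 6))
        with pytest.raises(ValueError, match="zero dispersion"):
            dispersion_test(d, ["a"] * 3 + ["b"] * 3)

    def test_semimetric_bray_curtis_distances_finite_nonnegative(self):
        rng = np.random.default_rng(3)
        X = rng.random((20, 6)) * (rng.random((20, 6)) < 0.6)
        X[X.sum(axis=1) == 0, 0] = 0.1
        res = dispersion_test(bray_curtis(X), ["a"] * 10 + ["b"] * 10)
        dist = res.distances.to_numpy()
        assert np.isfinite(dist).all() and (dist >= 0).all()


def test_geometric_median_minimizes_distance_sum():
    rng = np.random.default_rng(0)
    pts = rng.normal(size=(15, 2))
    med = geometric_median(pts)
    best = np.linalg.norm(pts - med, axis=1).sum()
    for _ in range(200):
        other = med + rng.normal(0, 0.1, 2)
        assert np.linalg.norm(pts - other, axis=1).sum() >= best - 1e-9


class TestIndval:
    def test_perfect_indicator(self):
        X = np.zeros((20, 1))
        X[:10, 0] = 0.3
        res = indval(X, ["A"] * 10 + ["B"] * 10, n_perm=999, seed=0)
        row = res.table.iloc[0]
        assert row["stat"] == pytest.approx(1.0)
        # minimal p up to chance permutations reproducing the split: the
        # statistic is label-symmetric, so the complement labeling also
        # attains 1.0 (probability 2/C(20,10) per permutation)
        assert row["p"] <= 3 / 1000
        assert row["group"] == "A"

    def test_uninformative_feature_stat_half(self):
        X = np.full((20, 1), 0.2)
        res = indval(X, ["A"] * 10 + ["B"] * 10, n_perm=199, seed=0)
        row = res.table.iloc[0]
        assert row["A"] == pytest.approx(0.5)
        assert row["B"] == pytest.approx(1.0)
        assert row["stat"] == pytest.approx(0.5)

    def test_absent_feature_flagged(self):
        X = np.zeros((10, 2))
        X[:, 0] = 1.0
        res = indval(X, ["A"] * 5 + ["B"] * 5, n_perm=99, seed=0)
        assert not res.table.iloc[1]["present"]
        assert np.isnan(res.table.iloc[1]["stat"])

    def test_presence_mode_ignores_abundance(self):
        rng = np.random.default_rng(1)
        X = np.zeros((20, 1))
        X[:10, 0] = rng.lognormal(0, 1, 10)  # group A: always present
        X[10:15, 0] = 100.0                  # group B: half present, huge abundance
        res = indval(X, ["A"] * 10 + ["B"] * 10, mode="presence", n_perm=99, seed=0)
        row = res.table.iloc[0]
        # presence: A = (1)/(1+0.5) = 2/3, B = 1 for group A
        assert row["group"] == "A"
        assert row["stat"] == pytest.approx(2 / 3)

    def test_seeded_permutations_reproducible(self):
        rng = np.random.default_rng(5)
        X = rng.random((30, 4))
        g = ["A"] * 15 + ["B"] * 15
        r1 = indval(X, g, n_perm=199, seed=11)
        r2 = indval(X, g, n_perm=199, seed=11)
        assert r1.table["p"].equals(r2.table["p"])

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError, match="99"):
            indval(np.ones((4, 1)), ["A", "A", "B", "B"], n_perm=10)
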