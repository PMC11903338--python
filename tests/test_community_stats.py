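"""Bray-Curtis, PERMANOVA, dispersion, richness and variable pruning."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from epiquant.community_stats import (
    bray_curtis,
    dispersion,
    env_prune,
    observed_richness,
    pairwise_permanova,
    permanova,
)


def _dm(points):
    points = np.asarray(points, dtype=float)
    ids = [f"s{i}" for i in range(len(points))]
    return DistanceMatrix(squareform(pdist(points)), ids=ids)


class TestBrayCurtis:
    def test_identical_rows_have_zero_distance(self):
        df = pd.DataFrame([[1, 2, 3], [1, 2, 3]], index=["a", "b"])
        dm = bray_curtis(df)
        assert dm["a", "b"] == 0.0

    def test_disjoint_supports_have_distance_one(self):
        df = pd.DataFrame([[5, 0], [0, 3]], index=["a", "b"])
        assert bray_curtis(df)["a", "b"] == 1.0

    def test_hand_arithmetic(self):
        df = pd.DataFrame([[2, 2], [1, 3]], index=["x", "y"])
        assert bray_curtis(df)["x", "y"] == pytest.approx(0.25, rel=1e-12)

    def test_axioms_on_random_abundances(self):
        rng = np.random.default_rng(51)
        df = pd.DataFrame(rng.uniform(0, 100, (15, 20)))
        df.index = [f"s{i}" for i in range(15)]
        dm = bray_curtis(df)
        data = dm.data
        assert np.allclose(np.diag(data), 0)
        assert np.allclose(data, data.T)
        assert (data >= 0).all() and (data <= 1).all()
        # identity of indiscernibles on this fixture: off-diagonal positive
        assert (data[np.triu_indices(15, 1)] > 0).all()

    def test_joint_scaling_equivariance(self):
        rng = np.random.default_rng(53)
        df = pd.DataFrame(rng.uniform(0, 10, (6, 8)))
        df.index = [f"s{i}" for i in range(6)]
        np.testing.assert_allclose(bray_curtis(df).data,
                                   bray_curtis(df * 37.5).data, rtol=1e-12)

    def test_zero_total_sample_rejected(self):
        df = pd.DataFrame([[0, 0], [1, 2]], index=["dead", "ok"])
        with pytest.raises(ValueError, match="zero total"):
            bray_curtis(df)


class TestPermanova:
    def test_pseudo_f_matches_independent_implementation(self):
        rng = np.random.default_rng(57)
        x = rng.normal(size=(18, 4))
        x[6:12] += 1.5
        dm = _dm(x)
        groups = ["a"] * 6 + ["b"] * 6 + ["c"] * 6
        ours = permanova(dm, groups, n_perm=99, seed=1)
        ref = skbio_permanova(dm, grouping=np.array(groups), permutations=0)
        assert ours.statistic == pytest.approx(ref["test statistic"], rel=1e-9)
        assert ours.df_between == 2
        assert ours.df_within == 15

    def test_sampled_p_agrees_with_exhaustive_enumeration_n6(self):
        rng = np.random.default_rng(59)
        x = rng.normal(size=(6, 3))
        dm = _dm(x)
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        d2 = dm.data**2
        n = 6

        def f_of(assign):
            ssw = 0.0
            for g in ("a", "b"):
                idx = np.flatnonzero(assign == g)
                ssw += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
            sst = d2.sum() / (2 * n)
            ssb = sst - ssw
            return (ssb / 1) / (ssw / 4)

        f_obs = f_of(labels)
        # exhaustive oracle over all 20 balanced assignments
        fs = []
        for combo in itertools.combinations(range(6), 3):
            assign = np.array(["b"] * 6)
            assign[list(combo)] = "a"
            fs.append(f_of(assign))
        p_exact = np.mean([f >= f_obs - 1e-12 for f in fs])
        res = permanova(dm, list(labels), n_perm=999, seed=7)
        assert res.statistic == pytest.approx(f_obs, rel=1e-9)
        assert abs(res.p_value - p_exact) < 0.06

    def test_planted_clusters_give_large_f_and_smallest_p(self):
        rng = np.random.default_rng(61)
        x = rng.normal(size=(20, 3), scale=0.1)
        x[10:] += 50.0
        dm = _dm(x)
        groups = ["a"] * 10 + ["b"] * 10
        res = permanova(dm, groups, n_perm=999, seed=3)
        assert res.statistic > 100
        assert res.p_value == pytest.approx(1 / 1000)
        assert res.r_squared > 0.9

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(63)
        dm = _dm(rng.normal(size=(12, 3)))
        groups = ["a"] * 6 + ["b"] * 6
        r1 = permanova(dm, groups, n_perm=99, seed=5)
        r2 = permanova(dm, groups, n_perm=99, seed=5)
        assert r1.p_value == r2.p_value

    def test_single_group_rejected(self):
        dm = _dm(np.random.default_rng(0).normal(size=(4, 2)))
        with pytest.raises(ValueError, match="two groups"):
            permanova(dm, ["a"] * 4, n_perm=9, seed=0)

    def test_degenerate_within_variance_warns_infinite_f(self):
        points = np.array([[0.0, 0], [0, 0], [5, 5], [5, 5]])
        dm = _dm(points)
        with pytest.warns(UserWarning, match="infinite"):
            res = permanova(dm, ["a", "a", "b", "b"], n_perm=9, seed=0)
        assert np.isinf(res.statistic)

    def test_p_bounded_below_by_plus_one_convention(self):
        rng = np.random.default_rng(67)
        dm = _dm(rng.normal(size=(10, 2)))
        res = permanova(dm, ["a"] * 5 + ["b"] * 5, n_perm=99, seed=2)
        assert res.p_value >= 1 / 100


class TestPairwisePermanova:
    def test_two_groups_reduce_to_omnibus(self):
        rng = np.random.default_rng(71)
        dm = _dm(rng.normal(size=(12, 3)))
        groups = pd.Series(["a"] * 6 + ["b"] * 6, index=dm.ids)
        omni = permanova(dm, groups, n_perm=99, seed=9)
        pw = pairwise_permanova(dm, groups, n_perm=99, seed=9)
        assert len(pw) == 1
        assert pw.loc[0, "p"] == omni.p_value
        assert pw.loc[0, "p_adjusted"] == pw.loc[0, "p"]

    def test_planted_outlier_group_flagged_in_both_of_its_pairs(self):
        rng = np.random.default_rng(73)
        x = rng.normal(size=(30, 3))
        x[20:] += 40.0  # group c far away
        dm = _dm(x)
        groups = pd.Series(["a"] * 10 + ["b"] * 10 + ["c"] * 10, index=dm.ids)
        pw = pairwise_permanova(dm, groups, n_perm=999, seed=11)
        pw = pw.set_index(["group_a", "group_b"])
        assert pw.loc[("a", "c"), "p_adjusted"] < 0.05
        assert pw.loc[("b", "c"), "p_adjusted"] < 0.05
        assert pw.loc[("a", "b"), "p_adjusted"] > 0.05


class TestDispersion:
    def test_identical_samples_have_zero_dispersion(self):
        points = np.zeros((6, 2))
        dm = _dm(points)
        res = dispersion(dm, ["a"] * 3 + ["b"] * 3, n_perm=9, seed=0)
        assert (res.distances == 0).all()

    def test_matches_planar_closed_form(self):
        rng = np.random.default_rng(77)
        points = rng.normal(size=(14, 2))
        dm = _dm(points)
        groups = ["a"] * 7 + ["b"] * 7
        res = dispersion(dm, groups, n_perm=9, seed=1)
        for label, idx in (("a", slice(0, 7)), ("b", slice(7, 14))):
            centroid = points[idx].mean(axis=0)
            direct = np.linalg.norm(points[idx] - centroid, axis=1)
            np.testing.assert_allclose(
                res.distances.iloc[idx].to_numpy(), direct, atol=1e-8)

    def test_scaling_one_group_raises_its_mean_dispersion(self):
        rng = np.random.default_rng(79)
        base = rng.normal(size=(8, 2))
        tight = np.vstack([base, base * 0.1 + 10])
        dm = _dm(tight)
        res = dispersion(dm, ["wide"] * 8 + ["tight"] * 8, n_perm=9, seed=0)
        assert res.group_means["wide"] > res.group_means["tight"]

    def test_non_euclidean_distances_still_yield_real_dispersions(self):
        # Bray-Curtis distances are generally non-Euclidean: negative
        # eigenvalues must be absorbed, not produce NaNs
        rng = np.random.default_rng(83)
        df = pd.DataFrame(rng.uniform(0, 50, (12, 6)),
                          index=[f"s{i}" for i in range(12)])
        dm = bray_curtis(df)
        res = dispersion(dm, ["a"] * 6 + ["b"] * 6, n_perm=99, seed=2)
        assert np.isfinite(res.distances).all()
        assert (res.distances >= 0).all()

    def test_singleton_group_rejected(self):
        dm = _dm(np.random.default_rng(0).normal(size=(3, 2)))
        with pytest.raises(ValueError, match="fewer than two"):
            dispersion(dm, ["a", "a", "b"], n_perm=9, seed=0)


class TestObservedRichness:
    def test_counts_taxa_above_threshold(self):
        df = pd.DataFrame([[0, 5, 0, 2], [0, 0, 0, 0]], index=["s1", "s2"])
        out = observed_richness(df)
        assert out.loc["s1", "richness"] == 2
        assert out.loc["s2", "richness"] == 0

    def test_matches_brute_force_nonzero_count(self):
        rng = np.random.default_rng(89)
        df = pd.DataFrame(rng.integers(0, 3, (10, 25)),
                          index=[f"s{i}" for i in range(10)])
        out = observed_richness(df)
        for s in df.index:
            assert out.loc[s, "richness"] == int((df.loc[s] >= 1).sum())

    def test_group_column_attached(self):
        df = pd.DataFrame([[1, 0], [1, 1]], index=["s1", "s2"])
        groups = pd.Series({"s1": "x", "s2": "y"})
        out = observed_richness(df, groupby=groups)
        assert list(out["group"]) == ["x", "y"]


class TestEnvPrune:
    def test_perfectly_correlated_pair_loses_one(self):
        rng = np.random.default_rng(91)
        a = rng.normal(size=12)
        env = pd.DataFrame({"A": a, "B": 2 * a + 1, "C": rng.normal(size=12)})
        res = env_prune(env)
        assert len(res.removed) == 1
        assert res.removed[0] in {"A", "B"}
        assert "C" in res.retained

    def test_independent_variables_usually_all_survive(self):
        keeps = 0
        for seed in range(40):
            rng = np.random.default_rng(100 + seed)
            env = pd.DataFrame(rng.normal(size=(12, 5)),
                               columns=list("ABCDE"))
            res = env_prune(env)
            keeps += not res.removed
        assert keeps >= 38  # >= 95% of runs

    def test_greedy_rule_trace(self):
        rng = np.random.default_rng(93)
        a = rng.normal(size=12)
        env = pd.DataFrame({"A": a, "B": a.copy(), "C": rng.normal(size=12)})
        res = env_prune(env)
        assert set(res.removed) <= {"A", "B"}
        assert len(res.removed) == 1
        assert "C" in res.retained

    def test_constant_variable_flagged_and_kept(self):
        rng = np.random.default_rng(97)
        env = pd.DataFrame({"A": rng.normal(size=10),
                            "K": np.ones(10)})
        res = env_prune(env)
        assert "K" in res.retained
        assert res.report["constant_pair"].any()

    def test_too_few_observations_rejected(self):
        env = pd.DataFrame({"A": [1, 2], "B": [2, 3]})
        with pytest.raises(ValueError, match="three observations"):
            env_prune(env)
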