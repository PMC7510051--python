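import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import f_oneway, kstest

from fungalscape.community import (
    bray_curtis,
    dbmem,
    envfit_vectors,
    nmds,
    permanova,
    phylo_community_distances,
    temporal_distances,
)
from fungalscape.errors import FormatError, FungalscapeError
from fungalscape.io import read_tree


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        D = bray_curtis(pd.DataFrame([[1, 2, 3], [1, 2, 3]]))
        assert D.iloc[0, 1] == pytest.approx(0.0)

    def test_disjoint_supports_one(self):
        D = bray_curtis(pd.DataFrame([[1, 1, 0, 0], [0, 0, 2, 3]]))
        assert D.iloc[0, 1] == pytest.approx(1.0)

    def test_hand_computed_value(self):
        D = bray_curtis(pd.DataFrame([[1, 1, 0], [0, 1, 1]]))
        assert D.iloc[0, 1] == pytest.approx(0.5)

    def test_zero_row_rejected(self):
        with pytest.raises(FungalscapeError):
            bray_curtis(pd.DataFrame([[0, 0], [1, 1]]))


def oneway_permanova_F(D2, groups):
    """Independent one-factor pseudo-F oracle from squared distances."""
    n = len(groups)
    ss_total = D2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    levels = sorted(set(groups))
    for lev in levels:
        idx = [i for i, g in enumerate(groups) if g == lev]
        sub = D2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    df1, df2 = len(levels) - 1, n - len(levels)
    return (ss_between / df1) / (ss_within / df2)


class TestPermanova:
    def test_perfect_separation(self):
        # duplicated identical compositions: the factor absorbs all variation;
        # permutations that happen to reproduce the partition tie with the
        # observed statistic, so p stays near (ties + 1)/(n_perm + 1)
        X = np.array([[1, 0, 0]] * 4 + [[0, 0, 1]] * 4, dtype=float)
        D = pd.DataFrame(squareform(pdist(X, metric="braycurtis")))
        design = pd.DataFrame({"g": ["a"] * 4 + ["b"] * 4})
        res = permanova(D, design, n_perm=99, seed=0)
        assert res.table.loc["g", "r2_pct"] == pytest.approx(100.0, abs=1e-6)
        assert res.table.loc["g", "p"] < 0.10

    def test_strong_gradient_minimal_p(self):
        # a continuous covariate has no permutation symmetry: with a strong
        # gradient the observed statistic is the unique maximum and p hits
        # its floor 1/(n_perm + 1)
        rng = np.random.default_rng(0)
        x = np.linspace(0, 1, 12)
        X = np.column_stack([x, x**2]) + rng.normal(0, 0.01, (12, 2))
        D = pd.DataFrame(squareform(pdist(X)))
        res = permanova(D, pd.DataFrame({"x": x}), n_perm=99, seed=0)
        assert res.table.loc["x", "p"] == pytest.approx(1 / 100)

    def test_exhaustive_enumeration_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(6, 4))
        D2 = squareform(pdist(X)) ** 2
        groups = ["a", "a", "a", "b", "b", "b"]
        res = permanova(pd.DataFrame(np.sqrt(D2)), pd.DataFrame({"g": groups}),
                        exhaustive=True)
        F_obs = oneway_permanova_F(D2, groups)
        assert res.table.loc["g", "pseudo_F"] == pytest.approx(F_obs, rel=1e-10)
        # oracle p: enumerate all 720 relabelings with the independent formula
        exceed = 0
        total = 0
        for perm in itertools.permutations(range(6)):
            pg = [groups[i] for i in perm]
            exceed += oneway_permanova_F(D2, pg) >= F_obs - 1e-12
            total += 1
        assert res.table.loc["g", "p"] == pytest.approx(exceed / total, abs=1e-12)

    def test_anova_f_equivalence_on_euclidean_univariate(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=14)
        groups = np.repeat(["a", "b"], 7)
        D = pd.DataFrame(squareform(pdist(y[:, None])))
        res = permanova(D, pd.DataFrame({"g": groups}), n_perm=99, seed=0)
        F_classic = f_oneway(y[:7], y[7:]).statistic
        assert res.table.loc["g", "pseudo_F"] == pytest.approx(F_classic, abs=1e-8)

    def test_r2_sums_to_100(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 6))
        D = pd.DataFrame(squareform(pdist(X)))
        design = pd.DataFrame({
            "g": rng.choice(["a", "b"], 20),
            "x": rng.normal(size=20),
        })
        res = permanova(D, design, terms=["g", "x"], n_perm=99, seed=0)
        assert res.table["r2_pct"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_r2_invariant_to_row_order(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 5))
        ids = [f"s{i}" for i in range(12)]
        D = pd.DataFrame(squareform(pdist(X)), index=ids, columns=ids)
        design = pd.DataFrame({"x": rng.normal(size=12)}, index=ids)
        res1 = permanova(D, design, n_perm=99, seed=0)
        order = rng.permutation(12)
        D2 = D.iloc[order, order]
        res2 = permanova(D2, design.loc[D2.index], n_perm=99, seed=0)
        assert res1.table.loc["x", "r2_pct"] == pytest.approx(
            res2.table.loc["x", "r2_pct"], abs=1e-8
        )

    def test_marginal_ss_matches_sequential_for_last_term(self):
        # the last sequential term is conditioned on all others, which is
        # exactly the marginal definition
        rng = np.random.default_rng(6)
        X = rng.normal(size=(20, 5))
        D = pd.DataFrame(squareform(pdist(X)))
        design = pd.DataFrame({"g": rng.choice(["a", "b"], 20),
                               "x": rng.normal(size=20)})
        seq = permanova(D, design, terms=["g", "x"], n_perm=99, seed=0)
        mar = permanova(D, design, terms=["g", "x"], n_perm=99, seed=0,
                        ss_type="marginal")
        assert mar.table.loc["x", "ss"] == pytest.approx(
            seq.table.loc["x", "ss"], rel=1e-10
        )
        assert mar.table.loc["residual", "ss"] == pytest.approx(
            seq.table.loc["residual", "ss"], rel=1e-10
        )

    def test_single_level_term_rejected(self):
        D = pd.DataFrame(squareform(pdist(np.random.default_rng(0).normal(size=(6, 2)))))
        with pytest.raises(FungalscapeError, match="single level"):
            permanova(D, pd.DataFrame({"g": ["a"] * 6}), n_perm=99)

    def test_cross_check_against_skbio_oneway(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(9)
        X = rng.normal(size=(16, 5))
        X[8:] += 0.8
        D = squareform(pdist(X, metric="braycurtis") if False else pdist(X))
        groups = ["a"] * 8 + ["b"] * 8
        res = permanova(pd.DataFrame(D), pd.DataFrame({"g": groups}), n_perm=999, seed=0)
        sk = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(D), grouping=groups, permutations=999
        )
        assert res.table.loc["g", "pseudo_F"] == pytest.approx(
            sk["test statistic"], abs=1e-8
        )


class TestDbmem:
    def test_orthogonal_descending(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(size=(15, 2))
        D = pd.DataFrame(squareform(pdist(pts)))
        basis = dbmem(D)
        V = basis.eigenvectors.to_numpy()
        gram = V.T @ V
        assert np.allclose(gram, np.eye(V.shape[1]), atol=1e-8)
        assert (np.diff(basis.eigenvalues) <= 1e-9).all()
        assert (basis.eigenvalues > 0).all()

    def test_transect_wave_ordering(self):
        x = np.arange(10.0)
        D = pd.DataFrame(np.abs(x[:, None] - x[None, :]))
        basis = dbmem(D)
        for k, expected in enumerate([1, 2, 3]):
            v = basis.eigenvectors.iloc[:, k].to_numpy()
            changes = int(np.sum(np.sign(v[:-1]) * np.sign(v[1:]) < 0))
            assert changes == expected

    def test_two_clusters_first_vector_separates(self):
        pts = np.concatenate([np.random.default_rng(1).normal(0, 0.1, (5, 2)),
                              np.random.default_rng(2).normal(10, 0.1, (5, 2))])
        D = pd.DataFrame(squareform(pdist(pts)))
        basis = dbmem(D)
        v = basis.eigenvectors.iloc[:, 0].to_numpy()
        assert len(set(np.sign(v[:5]))) == 1
        assert len(set(np.sign(v[5:]))) == 1
        assert np.sign(v[0]) != np.sign(v[5])

    def test_identical_points_empty_basis(self):
        D = pd.DataFrame(np.zeros((4, 4)))
        with pytest.warns(UserWarning):
            basis = dbmem(D)
        assert basis.eigenvectors.shape[1] == 0


class TestTemporalDistances:
    def test_winter_pooling(self):
        dates = pd.Series(
            ["2016-02-03", "2016-04-20", "2016-12-05", "2017-01-25", "2016-07-01"],
            index=list("abcde"),
        )
        D = temporal_distances(dates)
        assert D.loc["a", "b"] == 0  # Feb and Apr pool to mid-March
        assert D.loc["c", "d"] == 0  # Dec and next January pool together
        assert D.loc["a", "e"] > 0

    def test_no_pooling_uses_raw_dates(self):
        dates = pd.Series(["2016-02-03", "2016-04-20"], index=["a", "b"])
        D = temporal_distances(dates, pool_winter=False)
        assert D.loc["a", "b"] == 77


class TestPhyloDistances:
    @pytest.fixture
    def tree(self):
        return read_tree("((A:1,B:1):1,C:2);")

    def test_identical_communities_zero(self, tree):
        mem = pd.DataFrame([[1, 1, 0], [1, 1, 0]], index=["s1", "s2"],
                           columns=["A", "B", "C"])
        d = phylo_community_distances(tree, mem)
        assert d["comdistnt"].loc["s1", "s2"] == pytest.approx(0.0)
        assert d["phylosor"].loc["s1", "s2"] == pytest.approx(0.0)

    def test_single_species_patristic(self, tree):
        mem = pd.DataFrame([[1, 0, 0], [0, 1, 0]], index=["s1", "s2"],
                           columns=["A", "B", "C"])
        d = phylo_community_distances(tree, mem)
        assert d["comdist"].loc["s1", "s2"] == pytest.approx(2.0)
        assert d["comdistnt"].loc["s1", "s2"] == pytest.approx(2.0)

    def test_identical_single_species_comdist_zero(self, tree):
        mem = pd.DataFrame([[1, 0, 0], [1, 0, 0]], index=["s1", "s2"],
                           columns=["A", "B", "C"])
        d = phylo_community_distances(tree, mem)
        assert d["comdist"].loc["s1", "s2"] == pytest.approx(0.0)

    def test_unknown_member_named(self, tree):
        mem = pd.DataFrame([[1, 1]], index=["s1"], columns=["A", "Zzz"])
        with pytest.raises(FormatError, match="Zzz"):
            phylo_community_distances(tree, mem)

    def test_phylosor_hand_value(self, tree):
        # {A} vs {A,B}: edges(A) = {A:1, AB:1} (BL 2); edges(AB) adds B:1 (BL 3)
        mem = pd.DataFrame([[1, 0, 0], [1, 1, 0]], index=["s1", "s2"],
                           columns=["A", "B", "C"])
        d = phylo_community_distances(tree, mem)
        assert d["phylosor"].loc["s1", "s2"] == pytest.approx(1 - 2 / 2.5)


class TestNmds:
    def test_planar_distances_embed_with_tiny_stress(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(9, 2))
        D = pd.DataFrame(squareform(pdist(pts)))
        coords, stress, converged = nmds(D, k=2, n_starts=8, seed=0)
        assert stress < 0.01
        assert coords.shape == (9, 2)

    def test_duplicated_points_map_together(self):
        pts = np.array([[0, 0], [0, 0], [3, 0], [0, 4], [2, 2]], dtype=float)
        D = pd.DataFrame(squareform(pdist(pts)))
        coords, stress, _ = nmds(D, k=2, n_starts=8, seed=0)
        gap = np.linalg.norm(coords.iloc[0] - coords.iloc[1])
        scale = np.linalg.norm(coords.iloc[2] - coords.iloc[0])
        assert gap < 1e-2 * max(scale, 1.0)

    def test_seed_determinism(self):
        rng = np.random.default_rng(4)
        D = pd.DataFrame(squareform(pdist(rng.normal(size=(7, 3)))))
        a = nmds(D, seed=3)
        b = nmds(D, seed=3)
        pd.testing.assert_frame_equal(a[0], b[0])
        assert a[1] == b[1]

    def test_too_few_points_rejected(self):
        D = pd.DataFrame(np.zeros((3, 3)))
        with pytest.raises(FungalscapeError):
            nmds(D, k=2)


class TestEnvfit:
    def test_axis_aligned_variable(self):
        rng = np.random.default_rng(0)
        coords = pd.DataFrame(rng.normal(size=(30, 2)), columns=["NMDS1", "NMDS2"])
        env = pd.DataFrame({"v": coords["NMDS1"]})
        res = envfit_vectors(coords, env, n_perm=99, seed=0)
        assert res.loc["v", "r2"] == pytest.approx(1.0, abs=1e-10)
        assert abs(res.loc["v", "dir_NMDS1"]) == pytest.approx(1.0, abs=1e-6)

    def test_constant_variable_skipped(self):
        coords = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 2)))
        with pytest.warns(UserWarning, match="constant"):
            res = envfit_vectors(coords, pd.DataFrame({"c": np.ones(10)}), n_perm=99)
        assert res.empty

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(7)
        coords = pd.DataFrame(rng.normal(size=(25, 2)), columns=["NMDS1", "NMDS2"])
        pvals = []
        for rep in range(500):
            env = pd.DataFrame({"v": rng.normal(size=25)})
            res = envfit_vectors(coords, env, n_perm=199, seed=rep)
            pvals.append(res.loc["v", "p"])
        stat = kstest(pvals, "uniform")
        assert stat.pvalue > 0.01

    def test_determinism(self):
        rng = np.random.default_rng(0)
        coords = pd.DataFrame(rng.normal(size=(12, 2)))
        env = pd.DataFrame({"v": rng.normal(size=12)})
        a = envfit_vectors(coords, env, n_perm=199, seed=5)
        b = envfit_vectors(coords, env, n_perm=199, seed=5)
        pd.testing.assert_frame_equal(a, b)
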