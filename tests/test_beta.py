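"""Beta diversity distances, ordination, group tests and clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

from commsig.beta import (
    bray_curtis,
    consensus_upgma,
    nmds,
    permanova,
    permdisp,
    unifrac_unweighted,
    unifrac_weighted,
    upgma,
)
from commsig.containers import AbundanceTable
from commsig.simulate import SimulationConfig, simulate_community, simulate_tree

from conftest import (
    oracle_bray_curtis,
    oracle_unweighted_unifrac,
    oracle_upgma,
    oracle_weighted_unifrac,
)


def _table(data: dict, taxa: list) -> AbundanceTable:
    return AbundanceTable(pd.DataFrame(data, index=taxa))


class TestBrayCurtis:
    def test_identical_zero_disjoint_one(self):
        t = _table({"x": [1, 1, 0, 0], "y": [1, 1, 0, 0], "z": [0, 0, 2, 3]},
                   list("ABCD"))
        dm = bray_curtis(t)
        assert dm["x", "y"] == pytest.approx(0.0)
        assert dm["x", "z"] == pytest.approx(1.0)

    def test_hand_value(self):
        t = _table({"x": [1, 1, 0], "y": [0, 1, 1]}, list("ABC"))
        assert bray_curtis(t)["x", "y"] == pytest.approx(0.5)


class TestUnifrac:
    def test_unweighted_star_cases(self, rooted_star_tree):
        t = _table(
            {"p": [1, 1, 0, 0], "q": [0, 0, 1, 1], "r": [0, 1, 1, 0]},
            list("ABCD"),
        )
        dm = unifrac_unweighted(t, rooted_star_tree)
        assert dm["p", "q"] == pytest.approx(1.0)
        assert dm["p", "r"] == pytest.approx(2.0 / 3.0)

    def test_weighted_identical_zero(self, balanced_tree):
        t = _table({"p": [3, 1, 2, 0], "q": [6, 2, 4, 0]}, list("ABCD"))
        assert unifrac_weighted(t, balanced_tree)["p", "q"] == pytest.approx(0.0)

    def test_weighted_star_disjoint_is_one(self, rooted_star_tree):
        t = _table({"p": [5, 0, 0, 0], "q": [0, 0, 7, 0]}, list("ABCD"))
        assert unifrac_weighted(t, rooted_star_tree)["p", "q"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_instances_match_branch_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 12))
        tree = simulate_tree(n, seed=seed)
        taxa = [t.name for t in tree.tips()]
        counts = rng.integers(0, 8, size=(n, 3))
        counts[:, counts.sum(axis=0) == 0] += 1
        t = AbundanceTable(pd.DataFrame(counts, index=taxa,
                                        columns=["u", "v", "w"]))
        dw = unifrac_weighted(t, tree)
        du = unifrac_unweighted(t, tree)
        for a, b in itertools.combinations(["u", "v", "w"], 2):
            x = t.data[a].to_numpy()
            y = t.data[b].to_numpy()
            assert dw[a, b] == pytest.approx(
                oracle_weighted_unifrac(x, y, taxa, tree), rel=1e-10, abs=1e-12
            )
            sa = {tx for tx, c in zip(taxa, x) if c > 0}
            sb = {tx for tx, c in zip(taxa, y) if c > 0}
            assert du[a, b] == pytest.approx(
                oracle_unweighted_unifrac(sa, sb, tree), rel=1e-10, abs=1e-12
            )

    def test_bounded_and_symmetric(self, rooted_star_tree):
        t = _table({"p": [5, 1, 0, 0], "q": [0, 7, 2, 0], "r": [1, 1, 1, 1]},
                   list("ABCD"))
        for dm in (unifrac_weighted(t, rooted_star_tree),
                   unifrac_unweighted(t, rooted_star_tree), bray_curtis(t)):
            D = dm.data
            assert np.allclose(D, D.T)
            assert np.allclose(np.diag(D), 0)
            assert (D >= 0).all() and (D <= 1 + 1e-12).all()


class TestNMDS:
    def test_planar_configuration_low_stress(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 2))
        from scipy.spatial.distance import pdist, squareform

        dm = DistanceMatrix(squareform(pdist(X)),
                            ids=[str(i) for i in range(12)])
        res = nmds(dm, k=2, n_starts=4, seed=1)
        assert res.stress < 0.01

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(9, 3))
        from scipy.spatial.distance import pdist, squareform

        dm = DistanceMatrix(squareform(pdist(X)), ids=[str(i) for i in range(9)])
        r1 = nmds(dm, seed=7, n_starts=3)
        r2 = nmds(dm, seed=7, n_starts=3)
        assert r1.stress == r2.stress
        pd.testing.assert_frame_equal(r1.coordinates, r2.coordinates)

    def test_all_zero_distances_rejected(self):
        dm = DistanceMatrix(np.zeros((4, 4)), ids=list("abcd"))
        with pytest.raises(ValueError):
            nmds(dm)


class TestPermanova:
    def test_duplicated_points_r2_one(self):
        # zero within-group distance, positive between
        D = np.zeros((6, 6))
        D[:3, 3:] = 1.0
        D[3:, :3] = 1.0
        dm = DistanceMatrix(D, ids=[str(i) for i in range(6)])
        res = permanova(dm, ["a"] * 3 + ["b"] * 3, n_perm=99, seed=0)
        assert res.r2 == pytest.approx(1.0)

    def test_matches_skbio_statistic(self):
        from skbio.stats.distance import permanova as sk_permanova
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(4)
        X = rng.normal(size=(12, 3))
        X[:6] += 1.0
        dm = DistanceMatrix(squareform(pdist(X)),
                            ids=[str(i) for i in range(12)])
        groups = ["a"] * 6 + ["b"] * 6
        mine = permanova(dm, groups, n_perm=99, seed=0)
        theirs = sk_permanova(dm, grouping=groups, permutations=0)
        assert mine.pseudo_f == pytest.approx(theirs["test statistic"], rel=1e-10)

    def test_p_matches_exhaustive_enumeration(self):
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(5)
        X = rng.normal(size=(6, 2))
        X[:3] += 1.2
        dm = DistanceMatrix(squareform(pdist(X)), ids=[str(i) for i in range(6)])
        labels = np.array([0, 0, 0, 1, 1, 1])
        D2 = dm.data**2
        from commsig.beta import _permanova_ss

        def f_of(lab):
            sst, ssw = _permanova_ss(D2, lab)
            return ((sst - ssw) / 1) / (ssw / 4)

        f_obs = f_of(labels)
        fs = [f_of(np.array(p)) for p in itertools.permutations(labels)]
        p_exact = np.mean([f >= f_obs for f in fs])
        res = permanova(dm, list("aaabbb"), n_perm=1999, seed=1)
        assert res.p_value == pytest.approx(p_exact, abs=0.03)

    def test_single_group_rejected(self):
        dm = DistanceMatrix(np.ones((3, 3)) - np.eye(3), ids=list("abc"))
        with pytest.raises(ValueError):
            permanova(dm, ["g", "g", "g"])


class TestPermdisp:
    def test_mirror_groups_f_near_zero(self):
        # two groups with identical internal geometry
        X = np.array([[0.0, 0], [1, 0], [0, 1], [10, 0], [11, 0], [10, 1]])
        from scipy.spatial.distance import pdist, squareform

        dm = DistanceMatrix(squareform(pdist(X)), ids=[str(i) for i in range(6)])
        f, p = permdisp(dm, ["a"] * 3 + ["b"] * 3)
        assert f == pytest.approx(0.0, abs=1e-10)

    def test_euclidean_matches_direct_geometry(self):
        # distances to the group centroid computed in the original space
        rng = np.random.default_rng(6)
        X = rng.normal(size=(10, 2))
        groups = ["a"] * 5 + ["b"] * 5
        from scipy.spatial.distance import pdist, squareform
        import scipy.stats

        dm = DistanceMatrix(squareform(pdist(X)), ids=[str(i) for i in range(10)])
        f_mine, p_mine = permdisp(dm, groups, center="centroid")
        d = np.zeros(10)
        for g, sl in (("a", slice(0, 5)), ("b", slice(5, 10))):
            c = X[sl].mean(axis=0)
            d[sl] = np.linalg.norm(X[sl] - c, axis=1)
        f_direct, p_direct = scipy.stats.f_oneway(d[:5], d[5:])
        assert f_mine == pytest.approx(f_direct, rel=1e-8)
        assert p_mine == pytest.approx(p_direct, rel=1e-8)

    def test_identical_samples_error(self):
        dm = DistanceMatrix(np.zeros((4, 4)), ids=list("abcd"))
        with pytest.raises(ValueError):
            permdisp(dm, ["a", "a", "b", "b"])


class TestUPGMA:
    def test_hand_example(self):
        D = DistanceMatrix(
            np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float),
            ids=["A", "B", "C"],
        )
        dend = upgma(D)
        assert dend.clades()[0] == frozenset({"A", "B"})
        np.testing.assert_allclose(dend.heights, [1.0, 2.0])

    def test_two_samples(self):
        D = DistanceMatrix(np.array([[0, 3.0], [3.0, 0]]), ids=["x", "y"])
        np.testing.assert_allclose(upgma(D).heights, [1.5])

    def test_ultrametric_reconstruction(self):
        # heights of an ultrametric matrix are recovered exactly
        D = np.array(
            [[0, 2, 8, 8], [2, 0, 8, 8], [8, 8, 0, 4], [8, 8, 4, 0]], dtype=float
        )
        dend = upgma(DistanceMatrix(D, ids=list("abcd")))
        np.testing.assert_allclose(sorted(dend.heights), [1.0, 2.0, 4.0])

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        X = rng.normal(size=(n, 3))
        from scipy.spatial.distance import pdist, squareform

        labels = [f"s{i}" for i in range(n)]
        dm = DistanceMatrix(squareform(pdist(X)), ids=labels)
        dend = upgma(dm)
        mine = sorted(
            (clade, h) for clade, h in zip(dend.clades(), dend.heights)
        )
        theirs = sorted(oracle_upgma(dm.data, labels))
        for (c1, h1), (c2, h2) in zip(mine, theirs):
            assert c1 == c2
            assert h1 == pytest.approx(h2, rel=1e-10)


class TestConsensusUPGMA:
    @pytest.fixture(scope="class")
    def planted(self):
        tree = simulate_tree(120, seed=21)
        cfg = SimulationConfig(n_taxa=120, n_samples_per_group=4, depth=3000,
                               n_signatures_per_group=8, seed=21)
        table, meta, _ = simulate_community(cfg, tree)
        return table, tree, meta

    def test_supports_valid_and_groups_recovered(self, planted):
        table, tree, meta = planted
        ct = consensus_upgma(table, tree, depth=2000, n_iter=40, seed=3)
        assert all(0.5 < s <= 1.0 for s in ct.clades.values())
        # consensus clades are mutually compatible (nested or disjoint)
        clades = list(ct.clades)
        for a, b in itertools.combinations(clades, 2):
            assert not (a & b) or a <= b or b <= a
        groups = meta.groups
        for g in groups.unique():
            members = frozenset(groups.index[groups == g])
            assert ct.clades.get(members, 0.0) >= 0.9

    def test_newick_parses(self, planted):
        table, tree, _ = planted
        ct = consensus_upgma(table, tree, depth=2000, n_iter=10, seed=4)
        import io as _io

        from skbio import TreeNode

        parsed = TreeNode.read(_io.StringIO(ct.newick), convert_underscores=False)
        assert {t.name for t in parsed.tips()} == set(ct.labels)
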