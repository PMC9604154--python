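"""Mass trees, edge PCA, imbalance k-means, edge correlation, factorization."""

import numpy as np
import pandas as pd
import pytest

from glomesieve.analytics import (MassTreeSet, build_mass_trees, edge_correlation,
                                  edge_imbalance, edge_pca, imbalance_kmeans,
                                  mass_trees_from_counts,
                                  placement_factorization)
from glomesieve.phylo import Tree
from glomesieve.placement import Placement, PlacementSet


@pytest.fixture
def chain_tree():
    # ((A,B),C,D) with a trifurcating root; 5 edges
    return Tree.from_newick("((A:0.1,B:0.1):0.2,C:0.3,D:0.3);")


def _pset(entries):
    ps = PlacementSet()
    for name, rows in entries.items():
        ps[name] = [Placement(e, -1.0, w, 0.0, 0.01) for e, w in rows]
    return ps


def _mts(tree, rows, samples=None):
    masses = pd.DataFrame(np.asarray(rows, dtype=float),
                          index=samples or [f"s{i}" for i in range(len(rows))],
                          columns=range(tree.n_edges))
    return MassTreeSet(tree, masses)


class TestBuildMassTrees:
    def test_single_query_full_mass_on_one_edge(self, chain_tree):
        ps = _pset({"q1": [(2, 1.0)]})
        mts = build_mass_trees({"s1": ps}, tree=chain_tree)
        assert mts.masses.loc["s1", 2] == 1.0
        assert mts.masses.loc["s1"].sum() == 1.0

    def test_normalized_sample_sums_to_one(self, chain_tree):
        ps = _pset({"q1": [(0, 0.7), (1, 0.29)], "q2": [(3, 0.99)]})
        mts = build_mass_trees({"s1": ps}, tree=chain_tree, normalize=True)
        assert mts.masses.loc["s1"].sum() == pytest.approx(1.0)

    def test_same_sample_masses_add(self, chain_tree):
        ps = _pset({"q1": [(0, 1.0)]})
        mts = build_mass_trees([("s1", ps), ("s1", ps)], tree=chain_tree)
        assert mts.masses.loc["s1", 0] == 2.0

    def test_tree_mismatch_rejected(self, chain_tree, tmp_path):
        from glomesieve import fixtures as fx
        from glomesieve.placement import write_jplace
        b1 = fx.simulate_reference(5, seed=1)
        b2 = fx.simulate_reference(5, seed=2)
        for i, b in enumerate((b1, b2)):
            name = b.tree.name[b.tree.leaves[0]]
            ps = PlacementSet()
            ps["q"] = [Placement(0, -1.0, 1.0, 0.0, 0.01)]
            write_jplace(ps, b, tmp_path / f"f{i}.jplace")
        with pytest.raises(ValueError):
            build_mass_trees({"a": str(tmp_path / "f0.jplace"),
                              "b": str(tmp_path / "f1.jplace")})

    def test_multiplicity_weighting(self, chain_tree):
        ps = _pset({"u1": [(0, 1.0)], "u2": [(4, 0.5), (3, 0.5)]})
        counts = pd.DataFrame({"u1": [10, 0], "u2": [2, 6]},
                              index=["s1", "s2"])
        mts = mass_trees_from_counts(ps, chain_tree, counts)
        assert mts.masses.loc["s1", 0] == 10.0
        assert mts.masses.loc["s2", 4] == 3.0
        # conservation: per-sample total equals counts x retained LWR
        assert mts.total_mass()["s2"] == pytest.approx(6.0)


class TestEdgeImbalance:
    def test_pendant_edge_definition(self, chain_tree):
        leaf_edge = int(chain_tree.edge_num[
            next(v for v in chain_tree.leaves
                 if chain_tree.name[v] == "C")])
        rows = np.zeros((1, chain_tree.n_edges))
        rows[0, leaf_edge] = 0.3
        other = [e for e in range(chain_tree.n_edges) if e != leaf_edge][0]
        rows[0, other] = 0.7
        imb = edge_imbalance(_mts(chain_tree, rows))
        assert imb.iloc[0][leaf_edge] == pytest.approx(0.3 - 0.7)

    def test_internal_edge_includes_own_mass(self, chain_tree):
        # edge above (A,B): distal side = {A, B, AB-edge}
        ab_edge = 2  # (A{0}, B{1}) then the AB clade edge {2}
        rows = np.zeros((1, chain_tree.n_edges))
        rows[0, 0] = 0.2   # A pendant
        rows[0, 2] = 0.3   # AB edge itself
        rows[0, 4] = 0.5   # D pendant (proximal side)
        imb = edge_imbalance(_mts(chain_tree, rows))
        assert imb.iloc[0][ab_edge] == pytest.approx(0.5 - 0.5)


class TestEdgePCA:
    def test_identical_samples_zero_variance(self, chain_tree):
        rows = np.tile([[0.2, 0.2, 0.1, 0.3, 0.2]], (4, 1))
        res = edge_pca(_mts(chain_tree, rows))
        assert np.allclose(res.coordinates.to_numpy(), 0.0)

    def test_opposite_halves_separate_on_pc1(self, chain_tree):
        # samples alternate between all mass in the (A,B) clade vs on D
        rows = []
        for i in range(6):
            r = np.zeros(chain_tree.n_edges)
            if i % 2 == 0:
                r[0] = r[1] = 0.5
            else:
                r[4] = 1.0
            rows.append(r)
        res = edge_pca(_mts(chain_tree, rows))
        pc1 = res.coordinates["PC1"].to_numpy()
        assert (pc1[::2] * pc1[1::2] < 0).all()
        # the separating (A,B) clade edge carries a maximal |loading|
        load = res.loadings["PC1"].abs()
        assert load[2] == pytest.approx(load.max())

    def test_too_few_samples_rejected(self, chain_tree):
        with pytest.raises(ValueError):
            edge_pca(_mts(chain_tree, np.ones((2, 5))), components=2)

    def test_star_tree_matches_plain_pca_oracle(self):
        """With only pendant edges, edge PCA reduces to ordinary PCA of the
        leaf-mass vectors (up to the fixed 2x scale of imbalances)."""
        star = Tree.from_newick("(A:0.1,B:0.1,C:0.1,D:0.1);")
        rng = np.random.default_rng(3)
        masses = rng.dirichlet(np.ones(4), size=8)
        res = edge_pca(_mts(star, masses))
        from sklearn.decomposition import PCA
        ref = PCA(n_components=2).fit_transform(masses) * 2.0
        got = res.coordinates.to_numpy()
        for k in range(2):
            assert np.allclose(np.abs(got[:, k]), np.abs(ref[:, k]),
                               atol=1e-9)


class TestImbalanceKmeans:
    def test_k_equals_n_zero_inertia(self, chain_tree):
        rng = np.random.default_rng(4)
        rows = rng.dirichlet(np.ones(5), size=5)
        labels, inertia, _ = imbalance_kmeans(_mts(chain_tree, rows), k=5,
                                              seed=1)
        assert inertia == pytest.approx(0.0, abs=1e-12)
        assert labels.nunique() == 5

    def test_k_larger_than_n_rejected(self, chain_tree):
        with pytest.raises(ValueError):
            imbalance_kmeans(_mts(chain_tree, np.ones((3, 5))), k=4)

    def test_duplicated_samples_cocluster(self, chain_tree):
        rng = np.random.default_rng(5)
        x = rng.dirichlet(np.ones(5), size=2)
        rows = np.vstack([x, x, x])
        labels, _, _ = imbalance_kmeans(_mts(chain_tree, rows), k=2, seed=2)
        arr = labels.to_numpy()
        # copies of the same sample always land in the same cluster
        assert len(set(arr[0::2])) == 1
        assert len(set(arr[1::2])) == 1

    def test_planted_clusters_recovered(self, chain_tree):
        from sklearn.metrics import adjusted_rand_score
        rng = np.random.default_rng(6)
        centers = np.eye(3)
        rows, truth = [], []
        for i in range(18):
            c = i % 3
            r = np.zeros(5)
            r[c] = 0.9
            r[(c + 1) % 5] += 0.1
            rows.append(r + rng.uniform(0, 0.02, 5))
            truth.append(c)
        labels, _, contingency = imbalance_kmeans(
            _mts(chain_tree, rows), k=3, seed=3,
            groups=pd.Series(truth, index=[f"s{i}" for i in range(18)]))
        assert adjusted_rand_score(truth, labels.to_numpy()) >= 0.9
        assert contingency.to_numpy().sum() == 18


class TestEdgeCorrelation:
    def test_perfect_monotone_correlation(self, chain_tree):
        n = 8
        phenol = np.linspace(100, 2800, n)
        rows = np.stack([np.array([p, 3000 - p, 0, 0, 0]) / 3000
                         for p in phenol])
        mts = _mts(chain_tree, rows)
        meta = pd.DataFrame({"phenol": phenol}, index=mts.masses.index)
        res = edge_correlation(mts, meta, permutations=200, seed=1)
        assert res["phenol"].loc[0, "rho"] == pytest.approx(1.0)
        assert res["phenol"].loc[1, "rho"] == pytest.approx(-1.0)

    def test_constant_edge_reported_missing(self, chain_tree):
        rng = np.random.default_rng(7)
        rows = rng.dirichlet(np.ones(4), size=6)
        rows = np.hstack([rows, np.full((6, 1), 0.0)])
        rows = rows / rows.sum(axis=1, keepdims=True)
        mts = _mts(chain_tree, rows)
        meta = pd.DataFrame({"pH": rng.normal(7, 1, 6)},
                            index=mts.masses.index)
        res = edge_correlation(mts, meta, permutations=100, seed=2)
        assert np.isnan(res["pH"].loc[4, "rho"])

    def test_constant_variable_reported_missing(self, chain_tree):
        rng = np.random.default_rng(8)
        rows = rng.dirichlet(np.ones(5), size=6)
        mts = _mts(chain_tree, rows)
        meta = pd.DataFrame({"flat": np.ones(6)}, index=mts.masses.index)
        res = edge_correlation(mts, meta, permutations=100, seed=3)
        assert res["flat"]["rho"].isna().all()

    def test_too_few_samples_rejected(self, chain_tree):
        rows = np.ones((3, 5))
        mts = _mts(chain_tree, rows)
        meta = pd.DataFrame({"x": [1, 2, 3]}, index=mts.masses.index)
        with pytest.raises(ValueError):
            edge_correlation(mts, meta)


class TestPlacementFactorization:
    def _binary_split_mts(self, chain_tree, n=12, noise=0.0, rng=None):
        rows, cov = [], []
        for i in range(n):
            contaminated = i % 2
            r = np.zeros(chain_tree.n_edges)
            if contaminated:
                r[0] = r[1] = 0.45
                r[2] = 0.05
                r[3] = r[4] = 0.025
            else:
                r[3] = r[4] = 0.45
                r[0] = r[1] = 0.05
            if rng is not None and noise:
                r = r + rng.uniform(0, noise, len(r))
            rows.append(r)
            cov.append(contaminated)
        mts = _mts(chain_tree, rows)
        meta = pd.DataFrame({"contamination": cov}, index=mts.masses.index,
                            dtype=float)
        return mts, meta

    def test_planted_edge_wins_first_factor(self, chain_tree):
        rng = np.random.default_rng(9)
        mts, meta = self._binary_split_mts(chain_tree, noise=0.01, rng=rng)
        res = placement_factorization(mts, meta, n_factors=3)
        assert res.factors[0].edge == 2  # the (A,B) clade edge
        assert res.factors[0].deviance_fraction > 0.9
        assert len(set(res.winning_edges)) == 3

    def test_shuffled_covariate_explains_little(self, chain_tree):
        rng = np.random.default_rng(10)
        mts, meta = self._binary_split_mts(chain_tree, noise=0.05, rng=rng)
        obs = placement_factorization(mts, meta, n_factors=1)
        null_objs = []
        for _ in range(30):
            shuffled = meta.copy()
            shuffled["contamination"] = rng.permutation(
                meta["contamination"].to_numpy())
            null = placement_factorization(mts, shuffled, n_factors=1)
            null_objs.append(null.factors[0].deviance_fraction)
        assert obs.factors[0].deviance_fraction > \
            np.quantile(null_objs, 0.95)

    def test_rank_deficient_design_rejected(self, chain_tree):
        rng = np.random.default_rng(11)
        mts, meta = self._binary_split_mts(chain_tree, noise=0.05, rng=rng)
        meta["copy"] = meta["contamination"] * 2.0
        with pytest.raises(ValueError):
            placement_factorization(mts, meta)

    def test_factor_winners_invariant_to_sample_order(self, chain_tree):
        rng = np.random.default_rng(12)
        mts, meta = self._binary_split_mts(chain_tree, noise=0.05, rng=rng)
        res1 = placement_factorization(mts, meta, n_factors=2)
        perm = rng.permutation(len(mts.masses))
        mts2 = MassTreeSet(chain_tree, mts.masses.iloc[perm])
        res2 = placement_factorization(mts2, meta, n_factors=2)
        assert res1.winning_edges == res2.winning_edges

    def test_mass_conservation_through_normalization(self, chain_tree):
        rng = np.random.default_rng(13)
        rows = rng.uniform(0.1, 2.0, size=(5, chain_tree.n_edges))
        mts = _mts(chain_tree, rows)
        before = mts.total_mass().copy()
        mts.normalized()
        pd.testing.assert_series_equal(mts.total_mass(), before)
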