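"""Species-composition beta diversity: distances, ordination, tests, DMM."""

import numpy as np
import pandas as pd
import pytest

from glomesieve.beta import (DMMFit, amova, dirichlet_mle,
                             dirichlet_multinomial_logpmf, dmm_fit, homova,
                             metastats, nmds, yue_clayton)


def _table(rows, index=None):
    rows = np.asarray(rows)
    return pd.DataFrame(rows,
                        index=index or [f"s{i}" for i in range(len(rows))],
                        columns=[f"u{j}" for j in range(rows.shape[1])])


class TestYueClayton:
    def test_identical_compositions_distance_zero(self):
        t = _table([[10, 20, 30], [20, 40, 60]])
        d = yue_clayton(t)
        assert d.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_distance_one(self):
        t = _table([[10, 0, 5, 0], [0, 3, 0, 7]])
        assert yue_clayton(t).iloc[0, 1] == pytest.approx(1.0)

    def test_worked_example(self):
        t = _table([[8, 2], [2, 8]])
        # theta = 0.32 / (0.68 + 0.68 - 0.32); d = 1 - theta
        assert yue_clayton(t).iloc[0, 1] == pytest.approx(
            1 - 0.32 / 1.04, abs=1e-9)
        assert yue_clayton(t).iloc[0, 1] == pytest.approx(0.692307692,
                                                          abs=1e-9)

    def test_symmetric_zero_diagonal_bounded(self):
        rng = np.random.default_rng(1)
        t = _table(rng.integers(0, 50, size=(6, 10)) + 1)
        d = yue_clayton(t).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert (d >= 0).all() and (d <= 1).all()

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError):
            yue_clayton(_table([[0, 0], [1, 2]]))


class TestAmovaHomova:
    def _clustered(self, rng, gap):
        a = rng.dirichlet([8, 2, 1, 1], size=6)
        b = rng.dirichlet([1, 1, 2, 8 * gap if gap else 8], size=6)
        counts = np.rint(np.vstack([a, b] if gap else [a, a]) * 500)
        t = _table(counts)
        groups = pd.Series(["A"] * 6 + ["B"] * 6, index=t.index)
        return yue_clayton(t), groups

    def test_planted_effect_detected(self):
        rng = np.random.default_rng(2)
        d, groups = self._clustered(rng, gap=3)
        f, p = amova(d, groups, permutations=999, seed=1)
        assert p <= 0.002
        assert f > 1

    def test_statistic_matches_skbio_permanova(self):
        from skbio import DistanceMatrix
        from skbio.stats.distance import permanova
        rng = np.random.default_rng(3)
        d, groups = self._clustered(rng, gap=2)
        f, _ = amova(d, groups, permutations=10, seed=1)
        res = permanova(DistanceMatrix(d.to_numpy(), ids=list(d.index)),
                        groups.to_numpy(), permutations=10)
        assert f == pytest.approx(res["test statistic"], rel=1e-9)

    def test_single_sample_group_rejected(self):
        rng = np.random.default_rng(4)
        t = _table(rng.integers(1, 30, size=(5, 4)))
        groups = pd.Series(["A", "A", "A", "A", "B"], index=t.index)
        d = yue_clayton(t)
        for fn in (amova, homova):
            with pytest.raises(ValueError):
                fn(d, groups)

    def test_homova_null_on_equal_dispersion(self):
        rng = np.random.default_rng(5)
        x = rng.dirichlet([5, 5, 5, 5], size=12)
        t = _table(np.rint(x * 400))
        groups = pd.Series(["A"] * 6 + ["B"] * 6, index=t.index)
        b, p = homova(yue_clayton(t), groups, permutations=500, seed=2)
        assert p > 0.05

    def test_homova_detects_dispersion_difference(self):
        rng = np.random.default_rng(6)
        tight = rng.dirichlet([80, 80, 80, 80], size=8)
        loose = rng.dirichlet([1.5, 1.5, 1.5, 1.5], size=8)
        t = _table(np.rint(np.vstack([tight, loose]) * 400) + 1)
        groups = pd.Series(["A"] * 8 + ["B"] * 8, index=t.index)
        b, p = homova(yue_clayton(t), groups, permutations=500, seed=3)
        assert p < 0.01


class TestNMDS:
    def test_recoverable_configuration_low_stress(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(12, 2))
        diff = pts[:, None, :] - pts[None, :, :]
        d = pd.DataFrame(np.sqrt((diff ** 2).sum(axis=2)),
                         index=[f"s{i}" for i in range(12)],
                         columns=[f"s{i}" for i in range(12)])
        res = nmds(d, ndim=2, restarts=8, seed=1)
        assert res.stress < 0.01

    def test_duplicate_samples_coincide(self):
        rng = np.random.default_rng(8)
        x = rng.integers(1, 40, size=(5, 6))
        t = _table(np.vstack([x, x[:1]]))  # s5 duplicates s0
        res = nmds(yue_clayton(t), ndim=2, restarts=8, seed=2)
        a = res.coordinates.loc["s0"].to_numpy()
        b = res.coordinates.loc["s5"].to_numpy()
        span = np.abs(res.coordinates.to_numpy()).max()
        assert np.linalg.norm(a - b) < 0.05 * span

    def test_planted_driver_correlates_with_first_axis(self):
        rng = np.random.default_rng(9)
        n = 16
        driver = np.concatenate([np.zeros(n // 2), np.ones(n // 2)])
        comp = np.stack([10 * (1 - driver) + 1, 10 * driver + 1,
                         np.full(n, 3.0)], axis=1)
        counts = np.vstack([rng.multinomial(300, c / c.sum()) for c in comp])
        t = _table(counts)
        meta = pd.DataFrame({"phenol": driver + rng.normal(0, 0.05, n)},
                            index=t.index)
        res = nmds(yue_clayton(t), ndim=2, restarts=10, seed=3,
                   vector_variables=meta)
        rho = res.vectors.loc["phenol", "rho_NMDS1"]
        assert abs(rho) > 0.8

    def test_nonfinite_distances_rejected(self):
        d = pd.DataFrame([[0, np.nan], [np.nan, 0]], index=["a", "b"],
                         columns=["a", "b"])
        with pytest.raises(ValueError):
            nmds(d, ndim=1)


class TestMetastats:
    def _two_groups(self, rng, fold=1.0, n=12):
        base = np.array([30, 30, 20, 10, 5.0])
        a = np.stack([rng.multinomial(400, base / base.sum())
                      for _ in range(n)])
        shifted = base.copy()
        shifted[0] *= fold
        b = np.stack([rng.multinomial(400, shifted / shifted.sum())
                      for _ in range(n)])
        t = _table(np.vstack([a, b]))
        groups = pd.Series(["A"] * n + ["B"] * n, index=t.index)
        return t, groups

    def test_absent_unit_excluded(self):
        rng = np.random.default_rng(10)
        t, groups = self._two_groups(rng)
        t["empty"] = 0
        res = metastats(t, groups, permutations=100, seed=1)
        assert "empty" not in res.index

    def test_planted_tenfold_enrichment_significant(self):
        rng = np.random.default_rng(11)
        t, groups = self._two_groups(rng, fold=10.0)
        res = metastats(t, groups, permutations=999, seed=2)
        assert res.loc["u0", "q"] < 0.05

    def test_sparse_units_use_fisher(self):
        rng = np.random.default_rng(12)
        t, groups = self._two_groups(rng)
        t["sparse"] = 0
        t.iloc[0, t.columns.get_loc("sparse")] = 3
        res = metastats(t, groups, permutations=100, seed=3)
        assert res.loc["sparse", "method"] == "fisher"

    def test_more_than_two_groups_rejected(self):
        rng = np.random.default_rng(13)
        t, groups = self._two_groups(rng)
        groups.iloc[0] = "C"
        with pytest.raises(ValueError):
            metastats(t, groups)


# ---------------------------------------------------------------------------
# DMM


def oracle_dirichlet_mle(counts):
    """Independent oracle: direct numeric optimisation of the
    Dirichlet-multinomial log-likelihood in log-alpha space."""
    from scipy.optimize import minimize
    from scipy.special import gammaln

    counts = np.asarray(counts, dtype=float)
    n = counts.sum(axis=1)

    def nll(log_a):
        a = np.exp(log_a)
        a0 = a.sum()
        ll = (gammaln(a0) - gammaln(n + a0) +
              (gammaln(counts + a) - gammaln(a)).sum(axis=1)).sum()
        return -ll

    x0 = np.log(counts.mean(axis=0) / counts.sum(axis=1).mean() + 1e-3)
    res = minimize(nll, x0, method="Nelder-Mead",
                   options={"maxiter": 20000, "xatol": 1e-10,
                            "fatol": 1e-12})
    return np.exp(res.x)


def _component_data(rng, alphas, n_per, depth=500):
    counts, labels = [], []
    for c, a in enumerate(alphas):
        for _ in range(n_per):
            counts.append(rng.multinomial(depth, rng.dirichlet(a)))
            labels.append(c)
    return _table(np.asarray(counts)), np.asarray(labels)


class TestDMM:
    def test_k1_matches_independent_dirichlet_mle(self):
        rng = np.random.default_rng(14)
        t, _ = _component_data(rng, [np.array([4.0, 2.0, 1.0, 0.5])], 25)
        fit = dmm_fit(t, k_range=[1], seed=1)
        oracle = oracle_dirichlet_mle(t.to_numpy())
        assert np.allclose(fit.alphas[0], oracle, rtol=1e-4, atol=1e-4)

    def test_single_component_recovery_across_seeds(self):
        alphas = [np.array([20, 20, 5, 5, 2, 2, 1, 1.0])]
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            t, _ = _component_data(rng, alphas, 24)
            fit = dmm_fit(t, k_range=range(1, 7), seed=seed)
            hits += fit.k == 1
        assert hits >= 18  # >= 90% of 20 seeds

    def test_three_component_recovery_and_assignment(self):
        rng = np.random.default_rng(15)
        alphas = np.zeros((3, 12))
        for c in range(3):
            m = np.full(12, 0.02)
            m[c * 4:(c + 1) * 4] = 0.23
            alphas[c] = m / m.sum() * 50
        t, labels = _component_data(rng, alphas, 16)
        fit = dmm_fit(t, k_range=range(1, 7), seed=2)
        assert fit.k == 3
        pred = fit.posterior.to_numpy().argmax(axis=1)
        acc = pd.crosstab(labels, pred).max(axis=1).sum() / len(labels)
        assert acc >= 0.9

    def test_posterior_rows_sum_to_one(self):
        rng = np.random.default_rng(16)
        t, _ = _component_data(rng, [np.array([5, 3, 2, 1.0]),
                                     np.array([1, 2, 3, 5.0])], 10)
        fit = dmm_fit(t, k_range=[2], seed=3)
        assert np.allclose(fit.posterior.sum(axis=1), 1.0)
        assert np.all(fit.alphas > 0)
        assert fit.weights.sum() == pytest.approx(1.0)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            dmm_fit(pd.DataFrame())

    def test_em_log_likelihood_nondecreasing(self):
        """EM monotonicity of the DMM objective for fixed k."""
        from glomesieve.beta import _dmm_em
        rng = np.random.default_rng(17)
        t, _ = _component_data(rng, [np.array([5, 3, 2, 1.0]),
                                     np.array([1, 2, 3, 5.0])], 12)
        counts = t.to_numpy(dtype=float)
        # re-run EM capturing the trajectory via small max_iter increments
        lls = []
        for iters in (1, 3, 6, 12, 25):
            *_, ll = _dmm_em(counts, 2, np.random.default_rng(5),
                             max_iter=iters)
            lls.append(ll)
        assert all(b >= a - 1e-6 for a, b in zip(lls, lls[1:]))
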