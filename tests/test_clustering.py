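import numpy as np
import pytest
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from crossband.clustering import (BenefitMatrix, PairPerformanceMatrix,
                                  bold_correlation_clustering,
                                  cluster_pair_summary, gap_statistic,
                                  kmeans_cluster, pair_benefit, pairwise_eval)
from crossband.data import InvalidDataError


class TestPairBenefit:
    def _pairs(self, values):
        n = len(values)
        return PairPerformanceMatrix([f"r{i}" for i in range(n)],
                                     np.asarray(values, float))

    def test_gain_relative_to_best_component(self):
        pairs = self._pairs([[0.27, 0.30], [0.30, 0.31]])
        ben = pair_benefit(pairs)
        assert np.isclose(ben.values[0, 1], -0.01)
        assert ben.values[0, 0] == 0.0

    def test_zero_when_pair_equals_best_single(self):
        pairs = self._pairs([[0.2, 0.4], [0.4, 0.4]])
        assert pair_benefit(pairs).values[0, 1] == 0.0

    def test_symmetry(self, rng):
        v = rng.uniform(size=(5, 5))
        v = (v + v.T) / 2
        ben = pair_benefit(self._pairs(v))
        np.testing.assert_array_equal(ben.values, ben.values.T)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(InvalidDataError):
            self._pairs([[0.1, 0.2], [0.3, 0.1]])


class TestKmeansCluster:
    def test_planted_blocks_recovered_exactly(self, rng):
        M = np.zeros((12, 12))
        M[:6, 6:] = 0.3
        M[6:, :6] = 0.3
        M += rng.normal(0, 0.01, M.shape)
        M = (M + M.T) / 2
        ben = BenefitMatrix([f"r{i}" for i in range(12)], M)
        sol = kmeans_cluster(ben, 2, rng=rng)
        planted = [0] * 6 + [1] * 6
        assert adjusted_rand_score(planted, sol.assignment(ben.labels)) == 1.0

    def test_k1_dispersion_is_total(self, rng):
        pts = rng.standard_normal((10, 4))
        sol = kmeans_cluster(pts, 1, rng=rng)
        total = np.sum((pts - pts.mean(axis=0)) ** 2)
        assert np.isclose(sol.dispersion, total)

    def test_duplicate_rows_co_clustered(self, rng):
        base = rng.standard_normal((4, 6))
        pts = np.vstack([base, base])
        sol = kmeans_cluster(pts, 4, rng=rng)
        labels = sol.assignment([str(i) for i in range(8)])
        assert (labels[:4] == labels[4:]).all()

    def test_k_out_of_range_rejected(self, rng):
        with pytest.raises(InvalidDataError):
            kmeans_cluster(rng.standard_normal((3, 2)), 4, rng=rng)


class TestGapStatistic:
    def test_matches_brute_force_oracle_on_fixed_instance(self):
        """Re-derive Gap(k)/SE(k) with an independent implementation that
        consumes the same random stream."""
        rng = np.random.default_rng(42)
        pts = np.vstack([np.random.default_rng(1).normal(0, 1, (10, 2)),
                         np.random.default_rng(2).normal(8, 1, (10, 2))])
        res = gap_statistic(pts, k_range=range(1, 5), B=20,
                            rng=np.random.default_rng(7), n_restarts=5)

        # oracle: same formulas written independently
        orng = np.random.default_rng(7)

        def disp(p, k):
            if k == 1:
                return float(np.sum((p - p.mean(0)) ** 2))
            km = KMeans(k, n_init=5,
                        random_state=int(orng.integers(2 ** 31 - 1))).fit(p)
            return float(km.inertia_)

        Xc = pts - pts.mean(0)
        _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
        Xp = Xc @ Vt.T
        lo, hi = Xp.min(0), Xp.max(0)
        ks = [1, 2, 3, 4]
        logw = np.array([np.log(disp(pts, k)) for k in ks])
        ref = np.empty((20, 4))
        for b in range(20):
            Z = orng.uniform(lo, hi, Xp.shape) @ Vt + pts.mean(0)
            for j, k in enumerate(ks):
                ref[b, j] = np.log(disp(Z, k))
        gap = ref.mean(0) - logw
        se = ref.std(0, ddof=1) * np.sqrt(1 + 1 / 20)
        np.testing.assert_allclose(res.gap, gap, atol=1e-10)
        np.testing.assert_allclose(res.se, se, atol=1e-10)

    def test_three_separated_blobs_select_k3(self, rng):
        centers = np.array([[0.0, 0.0], [20.0, 0.0], [0.0, 60.0]])
        pts = np.vstack([rng.normal(c, 1.0, (15, 2)) for c in centers])
        res = gap_statistic(pts, k_range=range(1, 7), B=50, rng=rng)
        assert res.chosen_k == 3

    def test_single_gaussian_selects_k1(self, rng):
        pts = rng.standard_normal((40, 2))
        res = gap_statistic(pts, k_range=range(1, 7), B=50, rng=rng)
        assert res.chosen_k == 1
        assert res.no_clustering

    def test_degenerate_points_give_k1(self):
        res = gap_statistic(np.ones((10, 3)), B=20)
        assert res.chosen_k == 1

    def test_invalid_arguments(self, rng):
        with pytest.raises(InvalidDataError):
            gap_statistic(rng.standard_normal((10, 2)), k_range=range(2, 5))
        with pytest.raises(InvalidDataError):
            gap_statistic(rng.standard_normal((10, 2)), B=5)


class TestClusterPairSummary:
    def _solution(self, labels):
        from crossband.clustering import ClusterSolution
        return ClusterSolution({f"r{i}": c for i, c in enumerate(labels)},
                               len(set(labels)), 0.0)

    def test_constant_benefits_have_zero_width_ci(self):
        n = 6
        ben = BenefitMatrix([f"r{i}" for i in range(n)], np.full((n, n), 0.2))
        out = cluster_pair_summary(ben, self._solution([0, 0, 0, 1, 1, 1]))
        cross = out[(out.cluster_a == 0) & (out.cluster_b == 1)].iloc[0]
        assert np.isclose(cross.mean_benefit, 0.2)
        assert np.isclose(cross.ci_lo, cross.ci_hi)

    def test_singleton_self_pair_missing(self):
        ben = BenefitMatrix(["r0", "r1"], np.zeros((2, 2)))
        out = cluster_pair_summary(ben, self._solution([0, 1]))
        self_pair = out[(out.cluster_a == 0) & (out.cluster_b == 0)].iloc[0]
        assert np.isnan(self_pair.mean_benefit)
        assert self_pair.n_entries == 0

    def test_cross_cluster_entries_counted(self, rng):
        n = 5
        v = rng.uniform(size=(n, n))
        v = (v + v.T) / 2
        ben = BenefitMatrix([f"r{i}" for i in range(n)], v)
        out = cluster_pair_summary(ben, self._solution([0, 0, 1, 1, 1]))
        cross = out[(out.cluster_a == 0) & (out.cluster_b == 1)].iloc[0]
        assert cross.n_entries == 6


class TestPairwiseEvalAndBold:
    def test_pair_matrix_shape_and_symmetry(self, small_prepared):
        from crossband.ridge import LosoEvaluator
        from crossband.windows import assemble_design
        design = assemble_design(small_prepared, None, "alpha")
        ev = LosoEvaluator(design, n_repeats=1, n_candidates=4)
        pairs = pairwise_eval(small_prepared, "alpha", evaluator=ev)
        n = len(small_prepared.atlas.gray_bilateral_groups())
        assert pairs.values.shape == (n, n)
        np.testing.assert_allclose(pairs.values, pairs.values.T)
        assert np.all(np.abs(pairs.values) <= 1.0)

    def test_redundant_pair_has_no_benefit(self, small_prepared):
        # two regions from the same planted network carry the same latent
        from crossband.ridge import LosoEvaluator
        from crossband.windows import assemble_design
        design = assemble_design(small_prepared, None, "alpha")
        ev = LosoEvaluator(design, n_repeats=1, n_candidates=4)
        atlas = small_prepared.atlas
        sub = atlas.regions_of_class("subcortical")  # one arousal pair
        r_single = np.nanmean([f.mean_r for f in ev.loso([sub[0]])])
        r_pair = np.nanmean([f.mean_r for f in ev.loso([sub[0], sub[1]])])
        assert r_pair - r_single < 0.1

    def test_bold_correlation_matrix_properties(self, small_prepared, rng):
        sol, gap, corr, ari = bold_correlation_clustering(small_prepared,
                                                          B=20, rng=rng)
        np.testing.assert_allclose(corr, corr.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(corr), 1.0)
        assert ari is None

    def test_bold_ari_is_one_for_identical_solution(self, small_prepared, rng):
        sol, gap, corr, _ = bold_correlation_clustering(small_prepared,
                                                        B=20, rng=rng)
        sol2, _, _, ari = bold_correlation_clustering(
            small_prepared, benefit_solution=sol, B=20,
            rng=np.random.default_rng(rng.integers(100)))
        if sol2.k == sol.k:  # same machinery, same data -> same partition
            assert ari == 1.0
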