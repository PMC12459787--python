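import numpy as np
import pytest

import crossband as cb
from crossband.data import InvalidDataError
from crossband.ridge import (LosoEvaluator, evaluate_fold, fit_ridge,
                             lambda_grid, loso_evaluate, optimize_lambda,
                             shuffle_control)


def ridge_oracle(X, y, lam):
    """Centered normal equations, the closed-form reference solution."""
    xm, ym = X.mean(axis=0), y.mean()
    Xc, yc = X - xm, y - ym
    beta = np.linalg.solve(Xc.T @ Xc + lam * np.eye(X.shape[1]), Xc.T @ yc)
    return beta, ym - xm @ beta


class TestFitRidge:
    def test_exact_fit_without_penalty(self):
        model = fit_ridge(np.array([[1.0], [2.0], [3.0]]),
                          np.array([1.0, 2.0, 3.0]), 0.0)
        assert np.isclose(model.weights[0], 1.0)
        assert np.isclose(model.intercept, 0.0)

    def test_huge_lambda_shrinks_to_mean(self, rng):
        X = rng.standard_normal((50, 5))
        y = rng.standard_normal(50)
        model = fit_ridge(X, y, 1e8)
        assert np.all(np.abs(model.weights) < 1e-4)
        np.testing.assert_allclose(model.predict(X), y.mean(), atol=1e-3)

    @pytest.mark.parametrize("lam", [0.0, 1.0, 100.0])
    def test_matches_normal_equations(self, rng, lam):
        X = rng.standard_normal((200, 50))
        y = rng.standard_normal(200)
        model = fit_ridge(X, y, lam)
        beta, b0 = ridge_oracle(X, y, max(lam, 1e-12))
        np.testing.assert_allclose(model.weights, beta, rtol=1e-6, atol=1e-10)

    def test_dual_matches_primal(self, rng):
        X = rng.standard_normal((30, 80))  # p > n forces the kernel form
        y = rng.standard_normal(30)
        dual = fit_ridge(X, y, 5.0, solver="dual")
        beta, b0 = ridge_oracle(X, y, 5.0)
        np.testing.assert_allclose(dual.weights, beta, rtol=1e-8, atol=1e-10)

    def test_weight_norm_monotone_in_lambda(self, rng):
        X = rng.standard_normal((100, 20))
        y = rng.standard_normal(100)
        norms = [np.sum(fit_ridge(X, y, lam).weights ** 2)
                 for lam in (0.1, 1.0, 10.0, 100.0, 1000.0)]
        assert all(a >= b for a, b in zip(norms, norms[1:]))

    def test_sgd_solver_approximates_solution(self, rng):
        X = rng.standard_normal((500, 10))
        beta_true = rng.standard_normal(10)
        y = X @ beta_true + 0.1 * rng.standard_normal(500)
        exact = fit_ridge(X, y, 1.0)
        sgd = fit_ridge(X, y, 1.0, solver="sgd")
        assert np.corrcoef(exact.weights, sgd.weights)[0, 1] > 0.99

    def test_nonfinite_inputs_rejected(self):
        with pytest.raises(InvalidDataError):
            fit_ridge(np.array([[np.nan], [1.0]]), np.array([0.0, 1.0]), 1.0)


class TestOptimizeLambda:
    def test_pure_noise_prefers_strong_regularization(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((500, 100))
            y = rng.standard_normal(500)
            lam = optimize_lambda(X, y, rng=np.random.default_rng(seed + 100))
            grid = lambda_grid(500)
            if lam >= 10 * grid[0]:
                wins += 1
        assert wins >= 6

    def test_noiseless_signal_prefers_weak_regularization(self):
        wins = 0
        for seed in range(6):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((300, 5))
            y = X @ rng.standard_normal(5)
            lam = optimize_lambda(X, y, rng=np.random.default_rng(seed + 50))
            if lam <= 1e-2 * lambda_grid(300)[-1]:
                wins += 1
        assert wins >= 4

    def test_deterministic_given_rng(self, rng):
        X = np.random.default_rng(1).standard_normal((100, 10))
        y = np.random.default_rng(2).standard_normal(100)
        l1 = optimize_lambda(X, y, rng=np.random.default_rng(3))
        l2 = optimize_lambda(X, y, rng=np.random.default_rng(3))
        assert l1 == l2

    def test_too_few_rows_rejected(self):
        with pytest.raises(InvalidDataError):
            optimize_lambda(np.ones((3, 2)), np.ones(3), n_folds=5)


class TestLosoEvaluation:
    def test_leakage_construction_gives_near_perfect_r(self, small_design):
        # duplicate one subject's rows into a fake training subject with a
        # noiseless linear target: held-out prediction must be near-perfect
        from crossband.windows import WindowDataset
        d = small_design
        rows = np.flatnonzero(d.groups == d.subjects[0])
        X = np.vstack([d.X, d.X[rows], d.X[rows]])
        w = np.random.default_rng(0).standard_normal(d.X.shape[1]) / d.X.shape[1]
        y = X @ w
        groups = np.concatenate([d.groups, ["dup-1"] * len(rows), ["dup-2"] * len(rows)])
        seg = np.concatenate([d.segment_ids, d.segment_ids[rows] + 100,
                              d.segment_ids[rows] + 200])
        dd = WindowDataset(X=X, y=y, groups=groups, region_subset=d.region_subset,
                           segment_ids=seg, band="alpha")
        res = evaluate_fold(dd, d.subjects[0], n_repeats=1, n_candidates=6)
        assert res.mean_r > 0.99

    def test_one_result_per_subject(self, small_design):
        res = loso_evaluate(small_design, n_repeats=1, n_candidates=4)
        assert [f.held_out for f in res] == small_design.subjects

    def test_repeat_seeds_reproducible(self, small_design):
        a = evaluate_fold(small_design, small_design.subjects[0],
                          n_repeats=2, n_candidates=4, base_seed=5)
        b = evaluate_fold(small_design, small_design.subjects[0],
                          n_repeats=2, n_candidates=4, base_seed=5)
        assert a.r_per_seed == b.r_per_seed
        assert a.lambdas == b.lambdas

    def test_no_leakage_of_held_out_rows(self, small_design):
        ev = LosoEvaluator(small_design, n_repeats=1, n_candidates=4)
        held = small_design.subjects[0]
        train_blocks = [sl for sl, s in zip(ev.slices, ev.block_subject)
                        if s != held]
        held_rows = set(map(tuple, np.round(
            small_design.X[small_design.groups == held][:, :6], 6)))
        for sl in train_blocks:
            for row in np.round(small_design.X[sl][:, :6], 6):
                assert tuple(row) not in held_rows

    def test_subset_evaluation_equals_direct_design(self, small_prepared):
        from crossband.windows import assemble_design
        full = assemble_design(small_prepared, None, "alpha")
        names = small_prepared.region_labels
        sub = names[:2]
        ev = LosoEvaluator(full, n_repeats=1, n_candidates=4, base_seed=1)
        direct_design = assemble_design(small_prepared, sub, "alpha")
        ev2 = LosoEvaluator(direct_design, n_repeats=1, n_candidates=4, base_seed=1)
        a = ev.loso(sub)
        b = ev2.loso(None)
        np.testing.assert_allclose([f.mean_r for f in a], [f.mean_r for f in b],
                                   atol=1e-8)


class TestShuffleControl:
    def test_multiset_preserved_per_run(self, small_prepared, rng):
        shuffled = shuffle_control(small_prepared, rng)
        for orig, new in zip(small_prepared.segments, shuffled.segments):
            assert orig.fmri.shape == new.fmri.shape
        for subj in small_prepared.subjects:
            o = np.vstack([s.fmri for s in small_prepared.segments_for(subj)])
            n = np.vstack([s.fmri for s in shuffled.segments_for(subj)])
            np.testing.assert_allclose(np.sort(o, axis=0), np.sort(n, axis=0))

    def test_targets_untouched(self, small_prepared, rng):
        shuffled = shuffle_control(small_prepared, rng)
        for orig, new in zip(small_prepared.segments, shuffled.segments):
            np.testing.assert_array_equal(orig.targets["alpha"],
                                          new.targets["alpha"])

    def test_same_seed_same_permutation(self, small_prepared):
        a = shuffle_control(small_prepared, np.random.default_rng(4))
        b = shuffle_control(small_prepared, np.random.default_rng(4))
        for sa, sb in zip(a.segments, b.segments):
            np.testing.assert_array_equal(sa.fmri, sb.fmri)

    def test_per_region_mode_breaks_rows(self, small_prepared, rng):
        shuffled = shuffle_control(small_prepared, rng, per_region=True)
        o = np.vstack([s.fmri for s in small_prepared.segments])
        n = np.vstack([s.fmri for s in shuffled.segments])
        # column marginals preserved even though rows are recombined
        np.testing.assert_allclose(np.sort(o, axis=0), np.sort(n, axis=0))
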