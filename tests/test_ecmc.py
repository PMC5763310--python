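import warnings

import numpy as np
import pytest

from ecmc import (
    KernelMatrix,
    ViewSet,
    build_M,
    build_N,
    centering_matrix,
    consensus_score,
    ecmc_fit,
    ecmc_objective,
    grid_search,
    max_trace_psd,
    simulate1,
)
from ecmc.kernels import center


def random_views(rng, v=2, n=20, p=4):
    return ViewSet([rng.standard_normal((p, n)) for _ in range(v)])


class TestBuildMN:
    def test_build_M_zero_hyperparams(self, random_psd):
        W = random_psd(6)
        M = build_M(W, [random_psd(6)], [random_psd(6)] * 2, 0.0, 0.0)
        assert np.allclose(M, center(W), atol=1e-12)

    def test_build_M_cancellation(self, random_psd):
        # 2*alpha*C_2 exactly cancels beta*(D_1 + D_2) when all are I/n
        n = 5
        W = random_psd(n)
        eye_n = np.eye(n) / n
        M = build_M(W, [eye_n], [eye_n, eye_n], alpha=1.0, beta=1.0)
        assert np.allclose(M, center(W), atol=1e-12)

    def test_build_M_identity_input(self):
        M = build_M(np.eye(2), [np.zeros((2, 2))], [np.zeros((2, 2))] * 2,
                    0.0, 0.0)
        assert np.allclose(M, centering_matrix(2), atol=1e-12)

    def test_build_N_zero_beta(self, random_psd):
        W = random_psd(6)
        N = build_N(W, [random_psd(6)] * 2, beta=0.0)
        assert np.allclose(N, center(W), atol=1e-12)

    def test_build_N_substitution(self, random_psd):
        C1 = random_psd(5)
        C1 /= np.trace(C1)
        N = build_N(2.0 * C1, [C1], beta=1.0)
        assert np.allclose(N, center(C1), atol=1e-12)

    def test_build_N_feasible_even_when_negative(self, random_psd):
        # beta large enough that the subproblem matrix is negative on the
        # centered subspace: still solvable, objective may be <= 0
        W = random_psd(6)
        C = random_psd(6)
        C /= np.trace(C)
        N = build_N(W, [C], beta=1e6)
        res = max_trace_psd(N)
        res.certify()

    def test_shape_mismatch(self, random_psd):
        with pytest.raises(ValueError):
            build_M(random_psd(4), [random_psd(5)], [], 1.0, 1.0)


class TestEcmcFit:
    def test_decoupled_solution(self, rng):
        views = random_views(rng)
        res = ecmc_fit(views, alpha=0.0, beta=0.0, max_iter=10)
        for C, D, W in zip(res.C_list, res.D_list, views.kernels()):
            expected = max_trace_psd(center(W.values)).C_star
            assert np.allclose(C.values, expected, atol=1e-8)
            assert np.allclose(D.values, expected, atol=1e-8)

    def test_monotone_ascent_per_block_update(self, rng):
        for trial in range(3):
            views = random_views(np.random.default_rng(trial), n=15)
            res = ecmc_fit(views, alpha=1.0, beta=2.0, max_iter=50,
                           track_blocks=True)
            bt = np.array(res.block_objective_trace)
            assert np.all(
                np.diff(bt) >= -1e-9 * np.maximum(1.0, np.abs(bt[:-1])))

    def test_all_parts_feasible(self, rng):
        views = random_views(rng, v=3, n=12)
        res = ecmc_fit(views, alpha=0.5, beta=0.5, max_iter=50)
        for K in res.C_list + res.D_list:
            K.validate()

    def test_identical_views_symmetric_at_convergence(self, rng):
        X = rng.standard_normal((3, 14))
        res = ecmc_fit(ViewSet([X.copy(), X.copy()]), alpha=1.0, beta=1.0,
                       max_iter=100)
        assert np.allclose(res.C_list[0].values, res.C_list[1].values,
                           atol=1e-6)
        assert np.allclose(res.D_list[0].values, res.D_list[1].values,
                           atol=1e-6)

    def test_view_order_invariant_objective(self, rng):
        views = random_views(rng, n=15)
        swapped = ViewSet([views.views[1].copy(), views.views[0].copy()])
        a = ecmc_fit(views, alpha=1.0, beta=1.0, max_iter=100)
        b = ecmc_fit(swapped, alpha=1.0, beta=1.0, max_iter=100)
        assert a.objective_trace[-1] == pytest.approx(
            b.objective_trace[-1], rel=1e-6, abs=1e-6)

    def test_sample_relabeling_equivariance(self, rng):
        views = random_views(rng, n=12)
        perm = rng.permutation(12)
        pviews = ViewSet([V[:, perm] for V in views.views])
        a = ecmc_fit(views, alpha=1.0, beta=1.0, max_iter=100)
        b = ecmc_fit(pviews, alpha=1.0, beta=1.0, max_iter=100)
        sum_a = sum(C.values for C in a.C_list)
        sum_b = sum(C.values for C in b.C_list)
        assert np.allclose(sum_b, sum_a[np.ix_(perm, perm)], atol=1e-6)

    def test_rejects_bad_args(self, rng):
        with pytest.raises(ValueError):
            ecmc_fit(random_views(rng), alpha=-1.0, beta=0.0)

    def test_objective_function_consistency(self, rng):
        W = [(A + A.T) / 2 for A in
             (rng.standard_normal((5, 5)) for _ in range(2))]
        C = [(A + A.T) / 2 for A in
             (rng.standard_normal((5, 5)) for _ in range(2))]
        D = [(A + A.T) / 2 for A in
             (rng.standard_normal((5, 5)) for _ in range(2))]
        H = centering_matrix(5)
        alpha, beta = 1.3, 0.4
        direct = sum(np.trace(W[i] @ H @ (C[i] + D[i]) @ H) for i in range(2))
        direct += alpha * (np.trace(C[0] @ H @ C[1] @ H)
                           + np.trace(C[1] @ H @ C[0] @ H))
        direct -= beta * sum(np.trace(C[i] @ H @ D[j] @ H)
                             for i in range(2) for j in range(2))
        assert ecmc_objective(W, C, D, alpha, beta) == pytest.approx(
            direct, rel=1e-10)


class TestConsensusScore:
    def test_equal_parts_give_half(self, random_psd):
        C = random_psd(6)
        C /= np.trace(C)
        assert consensus_score(C, C) == pytest.approx(0.5)

    def test_rank_one_parts_always_half(self, rng):
        # extremal solver output: the reconstructed-reference score is 1/2
        u = rng.standard_normal(8)
        u -= u.mean()
        u /= np.linalg.norm(u)
        w = rng.standard_normal(8)
        w -= w.mean()
        w /= np.linalg.norm(w)
        score = consensus_score(np.outer(u, u), np.outer(w, w))
        assert score == pytest.approx(0.5, abs=1e-10)

    def test_input_reference_discriminates(self, rng):
        u = rng.standard_normal(8)
        u -= u.mean()
        u /= np.linalg.norm(u)
        w = rng.standard_normal(8)
        w -= w.mean() + u @ w * 0  # just another direction
        w -= (u @ w) * u
        w /= np.linalg.norm(w)
        C, D = np.outer(u, u), np.outer(w, w)
        W = 5.0 * C + 1.0 * D  # input kernel dominated by the consensus part
        s = consensus_score(C, D, reference="input", W_i=W)
        assert s == pytest.approx(5 / 6, rel=1e-8)

    def test_out_of_range_warns_not_clamps(self, rng):
        u = rng.standard_normal(6)
        u -= u.mean()
        u /= np.linalg.norm(u)
        w = rng.standard_normal(6)
        w -= w.mean()
        w -= (u @ w) * u
        w /= np.linalg.norm(w)
        C, D = np.outer(u, u), np.outer(w, w)
        W = -1.0 * C + 2.0 * D  # negative consensus weight -> score < 0
        with pytest.warns(RuntimeWarning):
            s = consensus_score(C, D, reference="input", W_i=W)
        assert s < 0

    def test_degenerate_denominator_raises(self):
        n = 4
        C = np.ones((n, n)) / n  # constant kernel: centering annihilates it
        with pytest.raises(ValueError):
            consensus_score(C, C.copy())


class TestGridSearch:
    def test_single_point_equals_direct_fit(self, two_block_views):
        views, truth = two_block_views
        gs = grid_search(views, [1.0], [1.0], k=2, metric="nmi", truth=truth,
                         seed=0, n_replicates=10)
        direct = ecmc_fit(views, alpha=1.0, beta=1.0)
        assert gs.best_params == (1.0, 1.0)
        assert gs.best_result.objective_trace[-1] == pytest.approx(
            direct.objective_trace[-1], rel=1e-9)
        assert len(gs.table) == 1

    def test_fixed_alpha_grid_shape(self, two_block_views):
        views, truth = two_block_views
        gs = grid_search(views, [1e2], [1e0, 1e1], k=2, metric="nmi",
                         truth=truth, seed=0, n_replicates=5)
        assert set(gs.table["alpha"]) == {1e2}
        assert len(gs.table) == 2

    def test_requires_truth_for_supervised_metrics(self, two_block_views):
        views, _ = two_block_views
        with pytest.raises(ValueError):
            grid_search(views, [1.0], [1.0], k=2, metric="nmi", truth=None)

    def test_silhouette_metric_needs_no_truth(self, two_block_views):
        views, _ = two_block_views
        gs = grid_search(views, [1.0], [0.1, 1.0], k=2, metric="silhouette",
                         seed=0, n_replicates=5)
        assert np.isfinite(gs.best_score)


class TestEcmcOnSimulatedData:
    def test_strong_disagreement_recoverable(self):
        """At t=2 the raw kernels are dominated by view-specific structure,
        yet the consensus decomposition recovers the planted clusters."""
        from ecmc import combine_consensus, evaluate_replicates, spectral_cluster

        d = simulate1(t=2.0, seed=3)
        res = ecmc_fit(d.views, alpha=1.0, beta=100.0, max_iter=30)
        clust = spectral_cluster(combine_consensus(res.C_list), k=2,
                                 n_replicates=30, seed=3)
        ev = evaluate_replicates(clust.replicate_labels, d.truth)
        assert ev.nmi_mean > 0.9

    def test_settles_even_when_iterates_drift(self):
        """Strong independence pressure (large beta) can leave the rank-one
        iterates rotating along a flat ridge; the objective must still be
        settled to ~7 digits by the iteration cap."""
        d = simulate1(t=2.0, seed=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = ecmc_fit(d.views, alpha=1.0, beta=100.0, max_iter=100)
        ot = np.array(res.objective_trace)
        rel = abs(ot[-1] - ot[-2]) / max(1.0, abs(ot[-1]))
        assert res.converged or rel < 1e-6

    def test_convergence_on_structured_views(self):
        d = simulate1(t=0.5, seed=5, n=30)
        with warnings.catch_warnings():
            warnings.simplefilter("error", RuntimeWarning)
            res = ecmc_fit(d.views, alpha=1.0, beta=1.0, max_iter=100)
        assert res.converged
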