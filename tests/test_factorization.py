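import numpy as np
import pytest

import chlnmf
from chlnmf import (
    FactorizationConfig,
    InvalidInputError,
    InvalidParameterError,
    build_hypergraph,
    cauchy_loss,
    fit,
    hq_weights,
    nmf,
    objective,
    update_U,
    update_V,
)
from conftest import random_instance
from oracles import naive_objective, naive_update_U, naive_update_V, textbook_nmf_step


class TestCauchyLoss:
    @pytest.mark.parametrize(
        "x,c,expected",
        [(0.0, 1.0, 0.0), (0.0, 0.2, 0.0), (0.5, 0.5, np.log(2)),
         (1.0, 0.5, np.log(5)), (2.0, 1.0, np.log(5))],
    )
    def test_closed_form_values(self, x, c, expected):
        assert cauchy_loss(x, c) == pytest.approx(expected, abs=1e-12)

    def test_even_and_monotone(self, rng):
        x = rng.normal(size=50)
        assert np.allclose(cauchy_loss(x, 0.7), cauchy_loss(-x, 0.7))
        grid = np.linspace(0, 10, 100)
        assert np.all(np.diff(cauchy_loss(grid, 0.3)) > 0)

    def test_invalid_scale(self):
        with pytest.raises(InvalidParameterError):
            cauchy_loss(1.0, 0.0)


class TestObjective:
    def test_exact_reconstruction_is_zero(self, rng):
        U = rng.uniform(0.1, 1, (6, 2))
        V = rng.uniform(0.1, 1, (2, 5))
        assert objective(U @ V, U, V, None, 0.0, 0.5) == pytest.approx(0.0, abs=1e-12)

    def test_single_cell_residual_at_scale(self):
        # one cell, residual norm^2 = c^2 -> ln 2
        c = 0.7
        X = np.array([[c], [0.0]])
        U = np.zeros((2, 1))
        V = np.zeros((1, 1))
        assert objective(X, U, V, None, 0.0, c) == pytest.approx(np.log(2))

    def test_matches_naive_loop_oracle(self):
        X, U, V = random_instance(3)
        G = build_hypergraph(X, p=3)
        val = objective(X, U, V, G.laplacian, alpha=2.5, c=0.5)
        ref = naive_objective(X, U, V, G.laplacian, 2.5, 0.5)
        assert val == pytest.approx(ref, rel=1e-12)

    def test_errors(self, rng):
        U = rng.uniform(0.1, 1, (6, 2))
        V = rng.uniform(0.1, 1, (2, 5))
        with pytest.raises(InvalidInputError):
            objective(np.ones((6, 4)), U, V, None, 0.0, 0.5)
        with pytest.raises(InvalidInputError):
            objective(U @ V, -U, V, None, 0.0, 0.5)


class TestHQWeights:
    def test_exact_reconstruction_upper_bound(self, rng):
        U = rng.uniform(0.1, 1, (6, 2))
        V = rng.uniform(0.1, 1, (2, 5))
        w = hq_weights(U @ V, U, V, 0.5)
        assert np.allclose(w, 8.0)  # 2 / c^2

    def test_residual_at_scale(self):
        c = 0.4
        X = np.array([[c]])
        w = hq_weights(X, np.zeros((1, 1)), np.zeros((1, 1)), c)
        assert w[0] == pytest.approx(1 / c**2)

    def test_monotone_decay_with_residual(self):
        # residual norms 1, 10, 100 with c = 1 -> 1, 2/101, 2/10001
        for r, expected in [(1.0, 1.0), (10.0, 2 / 101), (100.0, 2 / 10001)]:
            X = np.array([[r]])
            w = hq_weights(X, np.zeros((1, 1)), np.zeros((1, 1)), 1.0)
            assert w[0] == pytest.approx(expected, rel=1e-12)

    def test_range(self, rng):
        X, U, V = random_instance(11)
        w = hq_weights(X, U, V, 0.5)
        assert np.all(w > 0) and np.all(w <= 2 / 0.25 + 1e-12)


class TestUpdates:
    def test_update_U_fixed_point(self, rng):
        U = rng.uniform(0.1, 1, (5, 2))
        V = rng.uniform(0.1, 1, (2, 6))
        omega = rng.uniform(0.5, 2, 6)
        U2 = update_U(U @ V, U, V, omega)
        assert np.allclose(U2, U, rtol=1e-6)

    def test_update_V_fixed_point(self, rng):
        U = rng.uniform(0.1, 1, (5, 2))
        V = rng.uniform(0.1, 1, (2, 6))
        V2 = update_V(U @ V, U, V, np.ones(6), None, None, alpha=0.0)
        assert np.allclose(V2, V, rtol=1e-6)

    def test_constant_omega_matches_classical_rules(self):
        X, U, V = random_instance(5, m=7, n=6, k=3)
        omega = np.full(6, 1.7)  # any constant cancels
        U_cl = U * (X @ V.T) / (U @ V @ V.T + 1e-10)
        assert np.allclose(update_U(X, U, V, omega), U_cl, rtol=1e-9)
        V_cl = V * (U.T @ X) / (U.T @ U @ V + 1e-10)
        assert np.allclose(
            update_V(X, U, V, np.ones(6), None, None, 0.0), V_cl, rtol=1e-12
        )

    def test_update_U_matches_naive_loops(self):
        X, U, V = random_instance(7, m=3, n=4, k=2)
        omega = np.random.default_rng(7).uniform(0.2, 2, 4)
        assert np.allclose(
            update_U(X, U, V, omega), naive_update_U(X, U, V, omega), rtol=1e-12
        )

    def test_update_V_matches_naive_loops(self):
        X, U, V = random_instance(8, m=3, n=5, k=2)
        omega = np.random.default_rng(8).uniform(0.2, 2, 5)
        G = build_hypergraph(X, p=2)
        got = update_V(X, U, V, omega, G.similarity, G.vertex_degrees, 1.3)
        ref = naive_update_V(X, U, V, omega, G.similarity, G.vertex_degrees, 1.3)
        assert np.allclose(got, ref, rtol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_nonnegativity_preserved(self, seed):
        X, U, V = random_instance(seed, m=12, n=9, k=3)
        omega = np.random.default_rng(seed).uniform(0.1, 3, 9)
        G = build_hypergraph(X, p=3)
        for _ in range(5):
            U = update_U(X, U, V, omega)
            V = update_V(X, U, V, omega, G.similarity, G.vertex_degrees, 2.0)
            assert (U >= 0).all() and (V >= 0).all()


class TestFit:
    def test_start_at_optimum_converges_immediately(self, rng):
        U0 = rng.uniform(0.1, 1, (8, 2))
        V0 = rng.uniform(0.1, 1, (2, 6))
        X = U0 @ V0
        cfg = FactorizationConfig(rank=2, alpha=0.0, seed=0)
        res = fit(X, None, cfg, U0=U0, V0=V0)
        assert res.converged and res.n_iter <= 2
        assert res.objective_trace[-1] == pytest.approx(0.0, abs=1e-8)

    def test_noiseless_low_rank_reconstruction(self):
        r = np.random.default_rng(42)
        X = r.uniform(0.1, 1, (50, 2)) @ r.uniform(0.1, 1, (2, 40))
        cfg = FactorizationConfig(rank=2, alpha=0.0, max_iter=500, tol=1e-9, seed=0)
        res = fit(X, None, cfg)
        rel_err = np.linalg.norm(X - res.U @ res.V) / np.linalg.norm(X)
        assert rel_err < 0.05

    def test_bitwise_deterministic(self, small_dataset):
        X, _, _ = small_dataset
        G = build_hypergraph(X, p=5)
        cfg = FactorizationConfig(rank=3, seed=3)
        a = fit(X, G, cfg)
        b = fit(X, G, cfg)
        assert np.array_equal(a.objective_trace, b.objective_trace)
        assert np.array_equal(a.U, b.U) and np.array_equal(a.V, b.V)

    def test_monotone_objective(self, small_dataset):
        X, _, _ = small_dataset
        G = build_hypergraph(X, p=5)
        for alpha, c in [(0.0, 0.5), (1.0, 0.5), (10.0, 0.1), (10.0, 1.0)]:
            cfg = FactorizationConfig(
                rank=3, alpha=alpha, cauchy_scale=c, seed=5, n_init=1,
                max_iter=60, tol=1e-12,
            )
            tr = fit(X, G, cfg).objective_trace
            assert np.max(np.diff(tr)) <= 1e-8

    def test_restarts_pick_lowest_objective(self, small_dataset):
        X, _, _ = small_dataset
        G = build_hypergraph(X, p=5)
        multi = fit(X, G, FactorizationConfig(rank=3, seed=9, n_init=4))
        seeds = np.random.SeedSequence(9).generate_state(4)
        singles = [
            fit(X, G, FactorizationConfig(rank=3, seed=int(s % 2**31), n_init=1))
            for s in seeds
        ]
        assert multi.objective_trace[-1] == min(
            r.objective_trace[-1] for r in singles
        )

    def test_reduction_to_textbook_nmf(self):
        # omega frozen at ones, alpha = 0: iterates coincide with the
        # classical multiplicative scheme started identically
        X, U, V = random_instance(21, m=15, n=10, k=3)
        Uc, Vc = U.copy(), V.copy()
        ones = np.ones(10)
        for _ in range(25):
            U = update_U(X, U, V, ones)
            V = update_V(X, U, V, ones, None, None, 0.0)
            Uc, Vc = textbook_nmf_step(X, Uc, Vc)
        assert np.allclose(U, Uc, rtol=1e-12, atol=0)
        assert np.allclose(V, Vc, rtol=1e-12, atol=0)

    def test_hq_weights_self_consistent_at_convergence(self, small_dataset):
        X, _, _ = small_dataset
        G = build_hypergraph(X, p=5)
        cfg = FactorizationConfig(rank=3, seed=2, tol=1e-6, max_iter=20000)
        res = fit(X, G, cfg)
        assert res.converged
        recomputed = hq_weights(X, res.U, res.V, cfg.cauchy_scale)
        assert np.abs(recomputed - res.omega).max() < cfg.tol

    def test_invalid_configs(self, rng):
        X = rng.uniform(0, 1, (6, 5))
        with pytest.raises(InvalidParameterError):
            fit(X, None, FactorizationConfig(rank=5, alpha=0.0))
        with pytest.raises(InvalidParameterError):
            fit(X, None, FactorizationConfig(rank=2, alpha=0.0, cauchy_scale=-1))
        with pytest.raises(InvalidInputError):
            fit(X, None, FactorizationConfig(rank=2, alpha=1.0))  # no hypergraph
        with pytest.raises(InvalidInputError):
            fit(-X, None, FactorizationConfig(rank=2, alpha=0.0))


class TestBaselineNMF:
    def test_monotone_and_nonnegative(self, rng):
        X = rng.uniform(0, 2, (20, 15))
        res = nmf(X, 3, max_iter=80, tol=1e-12, seed=0)
        assert (res.U >= 0).all() and (res.V >= 0).all()
        assert np.max(np.diff(res.objective_trace)) <= 1e-8

    def test_robustness_advantage_under_contamination(self):
        # directional claim: with 10% outlier cells the Cauchy model clusters
        # at least as well as the Frobenius baseline (small-n version of the
        # full 20-seed study)
        ch, fr = [], []
        for seed in range(5):
            spec = chlnmf.SyntheticSpec(
                n_genes=100, n_cells=60, n_clusters=3,
                marker_genes_per_cluster=5, outlier_fraction=0.1, seed=seed,
            )
            X, truth, _ = chlnmf.generate(spec)
            G = build_hypergraph(X, p=5)
            res = fit(X, G, FactorizationConfig(rank=3, seed=seed))
            ch.append(chlnmf.ari(truth, chlnmf.kmeans_cluster(res.V, 3, seed=seed)))
            base = nmf(X, 3, seed=seed)
            fr.append(chlnmf.ari(truth, chlnmf.kmeans_cluster(base.V, 3, seed=seed)))
        assert np.mean(ch) >= np.mean(fr)
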