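"""The compressed bilinear solver against brute-force Kronecker oracles."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

import spartan
from spartan import affinity


def random_instance(rng, N=30, M=12, Q=5, S=3):
    Y = rng.standard_normal((N, M))
    D = (rng.random((N, Q)) < 0.3).astype(float)
    D[:, D.sum(axis=0) == 0] = 1.0
    P = rng.standard_normal((M, S))
    return Y, D, P


def kron_ridge(Y, D, P, lam2):
    """Explicit (P (x) Y^T D) ridge solution of the compressed system."""
    G, B = Y.T @ D, Y.T @ Y
    A = np.kron(P, G)
    b = B.reshape(-1, order="F")
    w = np.linalg.solve(A.T @ A + lam2 * np.eye(A.shape[1]), A.T @ b)
    return w.reshape(D.shape[1], P.shape[1], order="F")


class TestReducedSystem:
    def test_orthonormal_protein_columns_full_rank_rotation(self, rng):
        P, _ = np.linalg.qr(rng.standard_normal((20, 4)))
        Y = rng.standard_normal((10, 20))
        D = np.ones((10, 2))
        sys_ = spartan.build_reduced_system(Y, D, P, var_retained=1.0)
        np.testing.assert_allclose(sys_.P_red @ sys_.V_k.T, P, atol=1e-10)

    def test_orthonormal_expression_gives_identity_gram(self, rng):
        Y, _ = np.linalg.qr(rng.standard_normal((30, 8)))
        sys_ = spartan.build_reduced_system(Y, np.ones((30, 2)), rng.standard_normal((8, 3)))
        np.testing.assert_allclose(sys_.B, np.eye(8), atol=1e-10)
        assert np.abs(sys_.B - sys_.B.T).max() < 1e-10

    def test_truncation_error_bounded_by_discarded_variance(self, rng):
        Y, D, P = random_instance(rng, N=50, M=20, Q=4, S=8)
        var = 0.9
        sys_ = spartan.build_reduced_system(Y, D, P, var_retained=var)
        resid = P - sys_.P_red @ sys_.V_k.T
        assert np.linalg.norm(resid) ** 2 / np.linalg.norm(P) ** 2 <= 1 - var + 1e-12

    def test_rank_zero_protein_matrix_raises(self):
        with pytest.raises(ValueError, match="rank 0"):
            spartan.build_reduced_system(
                np.ones((4, 3)), np.ones((4, 2)), np.zeros((3, 2))
            )


class TestRidge:
    @pytest.mark.parametrize("var_retained", [1.0, None])
    def test_matches_kronecker_oracle(self, rng, var_retained):
        for _ in range(5):
            Y, D, P = random_instance(rng)
            lam2 = 10 ** rng.uniform(-5, 0)
            sys_ = spartan.build_reduced_system(Y, D, P, var_retained=var_retained)
            W = spartan.solve_ridge_reduced(sys_, lam2).values
            Wk = kron_ridge(Y, D, P, lam2)
            assert np.linalg.norm(W - Wk) / np.linalg.norm(Wk) < 1e-6

    def test_svd_reduction_is_safe_at_full_rank(self, rng):
        Y, D, P = random_instance(rng)
        full = spartan.solve_ridge_reduced(
            spartan.build_reduced_system(Y, D, P, var_retained=1.0), 0.01
        ).values
        none = spartan.solve_ridge_reduced(
            spartan.build_reduced_system(Y, D, P, var_retained=None), 0.01
        ).values
        np.testing.assert_allclose(full, none, atol=1e-8)

    def test_shrinkage_monotone_in_lambda2(self, rng):
        Y, D, P = random_instance(rng)
        sys_ = spartan.build_reduced_system(Y, D, P)
        norms = [
            np.linalg.norm(spartan.solve_ridge_reduced(sys_, lam).values)
            for lam in (1e-4, 1e-2, 1.0, 100.0, 1e8)
        ]
        assert all(a >= b for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 1e-3 * norms[0]  # penalty dominance drives W -> 0

    def test_singular_system_advises_regularization(self, rng):
        Y = np.zeros((6, 4))
        Y[:, 0] = 1.0  # rank-1 expression -> singular Gram at lambda2 = 0
        D = np.ones((6, 2))
        P = np.abs(np.random.default_rng(0).standard_normal((4, 2)))
        sys_ = spartan.build_reduced_system(Y, D, P)
        with pytest.raises(np.linalg.LinAlgError, match="lambda2"):
            spartan.solve_ridge_reduced(sys_, 0.0)

    def test_noise_free_planted_recovery(self):
        # full-column-rank structure (TFs <= proteins) makes W identifiable
        inst = spartan.generate_instance(
            spartan.SimConfig(seed=1, n_tfs=8, noise_sd=0.0, snr=None)
        )
        sys_ = spartan.build_reduced_system(
            inst.Y_clean, inst.D, inst.P_latent, var_retained=1.0
        )
        What = spartan.solve_ridge_reduced(sys_, 1e-10).to_frame()
        W = inst.W_star
        rel = np.linalg.norm(What.to_numpy() - W.to_numpy()) / np.linalg.norm(W.to_numpy())
        assert rel < 1e-4
        rho = spartan.spearman_per_cell(
            spartan.predict_expression(What, inst.D, inst.P_latent), inst.Y_clean
        )
        assert (rho == 1.0).all()


class TestElasticNet:
    def test_lambda1_max_kills_everything(self, rng):
        Y, D, P = random_instance(rng)
        sys_ = spartan.build_reduced_system(Y, D, P)
        lmax = spartan.lambda1_max(sys_)
        W = spartan.solve_elastic_net(sys_, lmax, 0.1)
        assert np.all(W.values == 0.0)
        W2 = spartan.solve_elastic_net(sys_, 0.9 * lmax, 0.1)
        assert not np.all(W2.values == 0.0)

    def test_lambda1_zero_matches_ridge_closed_form(self, planted_training):
        Y, P, D = planted_training
        for vr in (1.0, 0.95):
            sys_ = spartan.build_reduced_system(Y, D, P, var_retained=vr)
            Wr = spartan.solve_ridge_reduced(sys_, 0.1).values
            We = spartan.solve_elastic_net(sys_, 0.0, 0.1).values
            assert np.linalg.norm(We - Wr) / np.linalg.norm(Wr) < 1e-6

    def test_brute_force_kronecker_oracle_small_instance(self, rng):
        # 6 genes / 4 cells / 3 TFs / 2 proteins, lambda2 = 0.1
        Y = rng.standard_normal((6, 4))
        D = np.array(  # three distinct regulons
            [[1, 0, 0], [1, 1, 0], [0, 1, 0], [0, 1, 1], [0, 0, 1], [1, 0, 1]],
            dtype=float,
        )
        P = rng.standard_normal((4, 2))
        sys_ = spartan.build_reduced_system(Y, D, P, var_retained=None)
        W = spartan.solve_elastic_net(sys_, 0.0, 0.1).values
        np.testing.assert_allclose(W, kron_ridge(Y, D, P, 0.1), atol=1e-8)

    def test_objective_non_increasing_across_sweeps(self, planted_training):
        Y, P, D = planted_training
        sys_ = spartan.build_reduced_system(Y, D, P)
        sol = spartan.solve_elastic_net(sys_, 0.05, 0.05)
        diffs = np.diff(sol.objective_path)
        assert np.all(diffs <= 1e-9 * np.abs(sol.objective_path[0]))

    def test_zero_count_monotone_along_l1_path(self, planted_training):
        Y, P, D = planted_training
        sys_ = spartan.build_reduced_system(Y, D, P)
        lmax = spartan.lambda1_max(sys_)
        zeros, W0 = [], None
        for l1 in np.linspace(lmax / 1000, lmax, 10):
            sol = spartan.solve_elastic_net(sys_, l1, 0.1, W0=W0)
            W0 = sol.values
            zeros.append(int((sol.values == 0).sum()))
        assert all(a <= b for a, b in zip(zeros, zeros[1:]))
        assert zeros[-1] == W0.size

    def test_solution_beats_random_perturbations(self, rng):
        # convex objective: local optimality over perturbations is global
        Y, D, P = random_instance(rng, N=12, M=6, Q=4, S=3)
        sys_ = spartan.build_reduced_system(Y, D, P, var_retained=None)
        sol = spartan.solve_elastic_net(sys_, 0.3, 0.2, tol=1e-12)
        Gg, Pg, C = affinity._gram(sys_)
        bb = float(np.sum(sys_.B * sys_.B))
        f_opt = affinity._objective(sol.values, Gg, Pg, C, bb, 0.3, 0.2)
        for scale in (1e-3, 1e-2, 1e-1):
            perturbed = (
                sol.values[None] + scale * rng.standard_normal((3000,) + sol.values.shape)
            )
            f_pert = [
                affinity._objective(Wp, Gg, Pg, C, bb, 0.3, 0.2) for Wp in perturbed
            ]
            assert f_opt <= min(f_pert) + 1e-12

    def test_negative_penalties_rejected(self, rng):
        Y, D, P = random_instance(rng)
        sys_ = spartan.build_reduced_system(Y, D, P)
        with pytest.raises(ValueError):
            spartan.solve_elastic_net(sys_, -1.0, 0.1)


class TestPredictExpression:
    def test_zero_model_and_linearity(self, rng):
        Y, D, P = random_instance(rng)
        Q, S = D.shape[1], P.shape[1]
        assert np.all(spartan.predict_expression(np.zeros((Q, S)), D, P).to_numpy() == 0)
        W = rng.standard_normal((Q, S))
        e1 = np.zeros((1, S))
        e1[0, 0] = 1.0
        col = spartan.predict_expression(W, D, e1).to_numpy()[:, 0]
        np.testing.assert_allclose(col, D @ W[:, 0], atol=1e-12)

    def test_protein_id_mismatch_lists_offenders(self, planted_training):
        Y, P, D = planted_training
        sys_ = spartan.build_reduced_system(Y, D, P)
        W = spartan.solve_ridge_reduced(sys_, 0.1)
        bad = P.rename(columns={P.columns[0]: "WRONG"})
        with pytest.raises(ValueError, match="WRONG"):
            spartan.predict_expression(W, D, bad)


class TestCrossValidate:
    def test_single_grid_point_is_best(self, rng):
        Y, D, P = random_instance(rng, N=40, M=15, Q=4, S=3)
        res = spartan.cross_validate(Y, D, P, grid=[(0.0, 0.01)], folds=3, seed=0)
        assert res.best == (0.0, 0.01)

    def test_same_seed_reproduces_scores(self, rng):
        Y, D, P = random_instance(rng, N=40, M=20, Q=4, S=3)
        grid = [(0.0, 1e-3), (0.0, 1.0)]
        a = spartan.cross_validate(Y, D, P, grid=grid, folds=4, seed=11)
        b = spartan.cross_validate(Y, D, P, grid=grid, folds=4, seed=11)
        assert np.array_equal(a.fold_scores, b.fold_scores)
        assert a.best == b.best

    def test_empty_grid_rejected(self, rng):
        Y, D, P = random_instance(rng)
        with pytest.raises(ValueError, match="grid"):
            spartan.cross_validate(Y, D, P, grid=[], folds=3, seed=0)

    def test_appropriate_regularization_beats_heavy(self):
        inst = spartan.generate_instance(spartan.SimConfig(seed=7))
        Y, P, D = spartan.latent_training_data(inst)
        grid = [(0.0, 1e-6), (0.0, 1e-2), (0.0, 1.0)]
        res = spartan.cross_validate(Y, D, P, grid=grid, folds=5, seed=7,
                                     var_retained=1.0)
        mean = res.mean_scores
        assert res.best[1] < 1.0
        assert mean.max() > mean[2]  # heavy shrinkage loses


class TestEstimator:
    def test_sklearn_protocol(self, planted_training):
        Y, P, D = planted_training
        est = spartan.AffinityRegression(prior=D, lambda2=1e-3, var_retained=1.0)
        cloned = clone(est)
        assert cloned.get_params()["lambda2"] == 1e-3
        est.fit(P, Y.T)
        assert est.W_.shape == (D.shape[1], P.shape[1])
        assert est.n_features_in_ == P.shape[1]
        pred = est.predict(P)
        assert pred.shape == (P.shape[0], Y.shape[0])
        assert est.score(P, Y.T) > 0.5

    def test_requires_prior_and_matching_cells(self, planted_training):
        Y, P, D = planted_training
        with pytest.raises(ValueError, match="prior"):
            spartan.AffinityRegression().fit(P, Y.T)
        with pytest.raises(ValueError, match="cells"):
            spartan.AffinityRegression(prior=D).fit(P.iloc[:-1], Y.T)

    def test_prior_aligned_by_gene_label(self, planted_training):
        Y, P, D = planted_training
        shuffled = D.sample(frac=1.0, random_state=0)  # row order must not matter
        a = spartan.AffinityRegression(prior=D, lambda2=1e-2).fit(P, Y.T)
        b = spartan.AffinityRegression(prior=shuffled, lambda2=1e-2).fit(P, Y.T)
        pd.testing.assert_frame_equal(a.W_, b.W_)

    def test_unfitted_predict_raises(self, planted_training):
        Y, P, D = planted_training
        with pytest.raises(AttributeError, match="not fitted"):
            spartan.AffinityRegression(prior=D).predict(P)
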