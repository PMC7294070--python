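"""Sparse-representation solvers against independent oracles, prox
kernels, penalty preparation, and structural/path properties."""

import numpy as np
import pytest
from scipy.optimize import minimize
from sklearn.linear_model import Lasso, MultiTaskLasso

from connclass import (
    FixtureSpec,
    gsr_networks,
    make_sparse_representation_dataset,
    normalize_signals,
    slr_network,
    sr_network,
    ssgsr_networks,
    wsgr_network,
    wsr_network,
)
from connclass.sparse import (
    EdgeGrouping,
    SolverConfig,
    _weighted_group_prox,
    estimate_sigma,
    group_edges,
    group_soft_threshold,
    group_weights,
    gsr_lambda_max,
    link_penalty_weights,
    soft_threshold,
    sr_lambda_max,
    ssgsr_weights,
    subject_similarity_laplacians,
    svd_soft_threshold,
)
from connclass.pairwise import pair_index, pearson_network

from oracles import cd_lasso, ista_group_lasso, subgradient_ssgsr


def objective_sr(X, W, lam):
    R = X - X @ W
    return 0.5 * float((R * R).sum()) + lam * float(np.abs(W).sum())


class TestProxKernels:
    def test_scalar_soft_threshold(self):
        assert soft_threshold(3.0, 1.0) == 2.0
        assert soft_threshold(-0.5, 1.0) == 0.0
        np.testing.assert_array_equal(soft_threshold([2.0, -3.0], 0.0), [2.0, -3.0])

    def test_group_prox_zeroes_small_vectors(self, rng):
        v = rng.standard_normal(5)
        t = np.linalg.norm(v) * 1.01
        np.testing.assert_array_equal(group_soft_threshold(v, t), np.zeros(5))
        out = group_soft_threshold(v, 0.1)
        np.testing.assert_allclose(out, v * (1 - 0.1 / np.linalg.norm(v)), atol=1e-14)

    def test_svd_prox_shrinks_singular_values(self, rng):
        A = rng.standard_normal((5, 5))
        s = np.linalg.svd(A, compute_uv=False)
        B = svd_soft_threshold(A, s[1] + 1e-9)
        assert np.linalg.matrix_rank(B, tol=1e-8) == 1

    def test_weighted_group_prox_matches_numeric_minimizer(self, rng):
        z = rng.standard_normal(6)
        b = rng.uniform(0.3, 1.0, 6)
        t = 0.7

        def f(u):
            return 0.5 * np.sum((u - z) ** 2) + t * np.linalg.norm(b * u)

        u_fast = _weighted_group_prox(z, b, t)
        res = minimize(f, z, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000})
        assert f(u_fast) <= f(res.x) + 1e-10
        np.testing.assert_allclose(u_fast, res.x, atol=1e-5)

    def test_weighted_group_prox_zero_condition(self, rng):
        b = rng.uniform(0.5, 1.0, 4)
        z = 0.5 * b * 0.99 / np.linalg.norm(np.ones(4))  # ||z/b|| < t
        np.testing.assert_array_equal(_weighted_group_prox(z, b, 0.5), np.zeros(4))


class TestNormalization:
    def test_zero_mean_unit_norm_idempotent(self, rng):
        X = rng.standard_normal((40, 6)) * 3 + 1
        Z = normalize_signals(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(np.linalg.norm(Z, axis=0), 1, atol=1e-12)
        np.testing.assert_allclose(normalize_signals(Z), Z, atol=1e-12)

    def test_correlations_preserved(self, rng):
        X = rng.standard_normal((50, 5))
        np.testing.assert_allclose(
            np.corrcoef(X, rowvar=False),
            np.corrcoef(normalize_signals(X), rowvar=False),
            atol=1e-12,
        )

    def test_constant_column_rejected(self, rng):
        X = rng.standard_normal((20, 4))
        X[:, 1] = 2.0
        with pytest.raises(ValueError, match="constant"):
            normalize_signals(X)


class TestPenaltyPreparation:
    def test_sigma_is_mean_of_subject_stds(self):
        W1 = np.array([[1, 0.2, -0.4], [0.2, 1, 0.6], [-0.4, 0.6, 1]])
        W2 = np.array([[1, 0.1, 0.3], [0.1, 1, -0.5], [0.3, -0.5, 1]])
        def sd(W):
            off = np.abs([W[0, 1], W[0, 2], W[1, 2], W[1, 0], W[2, 0], W[2, 1]])
            return off.std()
        assert estimate_sigma([W1, W2]) == pytest.approx((sd(W1) + sd(W2)) / 2, abs=1e-14)

    def test_link_weights_formula_and_monotonicity(self):
        W = np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.5], [0.1, 0.5, 1.0]])
        C = link_penalty_weights(W, sigma=0.5)
        np.testing.assert_allclose(C, np.exp(-(W**2) / 0.5), atol=1e-15)
        assert C[0, 1] < C[1, 2] < C[0, 2]  # stronger links penalized less

    def test_quantile_grouping_two_bins(self):
        # strengths 0.1, 0.2, 0.8, 0.9 on the 4 edges of a path-like toy
        N = 4
        iu = np.triu_indices(N, k=1)
        W = np.eye(N)
        strengths = [0.1, 0.2, 0.8, 0.9, 0.0, 0.0]
        # assign: edges (0,1)=0.1 (0,2)=0.2 (0,3)=0.8 (1,2)=0.9; rest 0
        vals = [0.1, 0.2, 0.8, 0.9, 0.4, 0.5]
        W[iu] = vals
        W = W + W.T - np.diag(np.diag(W))
        g = group_edges([W], G=2)
        E_sorted = np.sort(g.E)
        low = [e for e, m in zip(range(6), g.membership) if m == np.argmin(g.E)]
        strengths = np.array(vals)
        assert set(strengths[low]) == {0.1, 0.2, 0.4}
        assert E_sorted[0] == pytest.approx(np.mean([0.1, 0.2, 0.4]))
        assert E_sorted[1] == pytest.approx(np.mean([0.5, 0.8, 0.9]))

    def test_grouping_partitions_edges(self, rng):
        pcs = [pearson_network(rng.standard_normal((60, 8))).values for _ in range(3)]
        g = group_edges(pcs, G=5)
        assert g.membership.shape == (28,)
        assert set(np.unique(g.membership)) <= set(range(g.G))
        counts = np.bincount(g.membership, minlength=g.G)
        assert counts.sum() == 28 and np.all(counts > 0)

    def test_identical_strengths_collapse_with_warning(self):
        W = np.full((4, 4), 0.3)
        np.fill_diagonal(W, 1.0)
        with pytest.warns(UserWarning, match="bins"):
            g = group_edges([W], G=3)
        assert g.G == 1

    def test_laplacians_psd_zero_row_sums(self, rng):
        pcs = [pearson_network(rng.standard_normal((40, 6))).values for _ in range(5)]
        Ls = subject_similarity_laplacians(pcs)
        for L in Ls:
            np.testing.assert_allclose(L, L.T, atol=1e-12)
            np.testing.assert_allclose(L.sum(axis=1), 0, atol=1e-10)
            assert np.linalg.eigvalsh(L).min() > -1e-10

    def test_ssgsr_weights_formula(self, rng):
        pcs = [pearson_network(rng.standard_normal((40, 5))).values for _ in range(2)]
        B = ssgsr_weights(pcs)
        assert B.shape == (5, 4, 2)
        keep = [1, 2, 3, 4]
        np.testing.assert_allclose(B[0, :, 0], np.exp(-pcs[0][0, keep] ** 2), atol=1e-15)


class TestSR:
    def test_lambda_max_gives_exact_zero(self, rng):
        X = rng.standard_normal((30, 6))
        lam = sr_lambda_max(X)
        W = sr_network(X, lam * 1.0001)
        assert np.abs(W.values).max() == 0.0

    def test_objective_matches_coordinate_descent_oracle(self, rng):
        X = normalize_signals(rng.standard_normal((30, 8)))
        lam = 0.1
        W = sr_network(X, lam, normalize=False, symmetrize_out=False)
        f_fast = objective_sr(X, W.values, lam)
        W_cd = np.zeros((8, 8))
        for i in range(8):
            keep = [j for j in range(8) if j != i]
            W_cd[keep, i] = cd_lasso(X[:, keep], X[:, i], lam)
        f_cd = objective_sr(X, W_cd, lam)
        assert abs(f_fast - f_cd) / abs(f_cd) <= 1e-6

    def test_solution_matches_sklearn_lasso(self, rng):
        X = normalize_signals(rng.standard_normal((40, 6)))
        lam = 0.05
        cfg = SolverConfig(kkt_tol=1e-9, max_iter=20000)
        W = sr_network(X, lam, cfg, normalize=False, symmetrize_out=False).values
        T = X.shape[0]
        for i in range(6):
            keep = [j for j in range(6) if j != i]
            ref = Lasso(alpha=lam / T, fit_intercept=False, tol=1e-12, max_iter=100000)
            ref.fit(X[:, keep], X[:, i])
            np.testing.assert_allclose(W[keep, i], ref.coef_, atol=1e-6)

    def test_duplicated_signal_dominates_its_rows(self, rng):
        X = rng.standard_normal((50, 5))
        X[:, 1] = X[:, 0] + 1e-3 * rng.standard_normal(50)
        W = sr_network(X, 0.02, symmetrize_out=False).values
        assert abs(W[0, 1]) == pytest.approx(np.abs(W[:, 1]).max())
        assert abs(W[1, 0]) == pytest.approx(np.abs(W[:, 0]).max())

    def test_kkt_certificates(self, rng):
        W = sr_network(rng.standard_normal((30, 6)), 0.05)
        assert all(c.kkt_residual <= 1e-5 for c in W.extras["certificates"])

    def test_l1_norm_non_increasing_in_lambda(self, rng):
        X = rng.standard_normal((40, 6))
        lams = [0.01, 0.03, 0.1, 0.3, 0.6]
        norms = [
            np.abs(sr_network(X, l, symmetrize_out=False).extras["pre_symmetrization"]).sum()
            for l in lams
        ]
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))


class TestWSR:
    def test_unit_weights_collapse_to_sr(self, rng):
        X = rng.standard_normal((30, 6))
        W1 = sr_network(X, 0.08).values
        W2 = wsr_network(X, 0.08, np.ones((6, 6))).values
        np.testing.assert_allclose(W1, W2, atol=1e-12)

    def test_large_sigma_limit_is_sr(self, rng):
        X = rng.standard_normal((30, 6))
        C = link_penalty_weights(pearson_network(X), sigma=1e12)
        W = wsr_network(X, 0.08, C).values
        np.testing.assert_allclose(W, sr_network(X, 0.08).values, atol=1e-6)

    def test_strong_link_survives_where_weak_is_zeroed(self, rng):
        # planted: ROI1 = strong copy of ROI0, ROI3 = weak copy of ROI2
        T = 80
        X = rng.standard_normal((T, 6))
        X[:, 1] = X[:, 0] + 0.15 * rng.standard_normal(T)
        X[:, 3] = X[:, 2] + 1.0 * rng.standard_normal(T)
        pc = pearson_network(X)
        sigma = estimate_sigma([pc])
        C = link_penalty_weights(pc, sigma)
        for lam1 in [0.1, 0.3, 1.0, 3.0, 10.0, 30.0]:
            W = wsr_network(X, lam1, C, symmetrize_out=False).values
            if W[2, 3] == 0 and W[3, 2] == 0:
                assert abs(W[0, 1]) > 0 and abs(W[1, 0]) > 0
                break
        else:
            pytest.fail("weak link never zeroed along the lambda path")


class TestWSGR:
    def _setup(self, rng, N=6, T=40):
        X = rng.standard_normal((T, N))
        pc = pearson_network(X)
        sigma = estimate_sigma([pc])
        C = link_penalty_weights(pc, sigma)
        g = group_edges([pc], G=3)
        d = group_weights(g.E, sigma)
        return X, C, g, d

    def test_lambda2_zero_collapses_to_wsr(self, rng):
        X, C, g, d = self._setup(rng)
        W1 = wsgr_network(X, 0.05, 0.0, C, g, d).values
        W2 = wsr_network(X, 0.05, C).values
        np.testing.assert_allclose(W1, W2, atol=1e-12)

    def test_pure_group_lasso_matches_ista_oracle(self, rng):
        # lambda1 = 0, one group spanning all edges, unit group weight
        N = 5
        X = normalize_signals(rng.standard_normal((30, N)))
        P = N * (N - 1) // 2
        g = EdgeGrouping(G=1, membership=np.zeros(P, dtype=int),
                         E=np.array([1.0]), pairs=pair_index(N))
        lam2 = 0.3
        W = wsgr_network(
            X, 1e-12, lam2, np.ones((N, N)), g, np.array([1.0]),
            normalize=False, symmetrize_out=False,
        ).values
        for i in range(N):
            keep = [j for j in range(N) if j != i]
            w_ref = ista_group_lasso(X[:, keep], X[:, i], lam2, n_iter=50000)
            f = lambda w: 0.5 * np.sum((X[:, i] - X[:, keep] @ w) ** 2) + lam2 * np.linalg.norm(w)
            assert abs(f(W[keep, i]) - f(w_ref)) <= 1e-6 * max(f(w_ref), 1e-12)

    def test_large_lambda2_zeroes_whole_groups(self, rng):
        X, C, g, d = self._setup(rng, N=6)
        for lam2 in [0.2, 0.5, 1.0, 2.0, 5.0]:
            W = wsgr_network(X, 1e-6, lam2, C, g, d, symmetrize_out=False).values
            pre = W
            zero_group = False
            for gid in range(g.G):
                edges = [p for p, m in zip(g.pairs, g.membership) if m == gid]
                if edges and all(
                    pre[i, j] == 0 and pre[j, i] == 0 for (i, j) in edges
                ):
                    zero_group = True
            nonzero_any = np.abs(pre).sum() > 0
            if zero_group and nonzero_any:
                return
        pytest.fail("no intermediate lambda2 produced whole-group sparsity")


class TestGSR:
    def test_identical_subjects_identical_networks(self, rng):
        X = rng.standard_normal((40, 5))
        nets = gsr_networks([X.copy(), X.copy(), X.copy()], 0.05)
        for net in nets[1:]:
            np.testing.assert_allclose(net.values, nets[0].values, atol=1e-10)

    def test_common_support_across_subjects(self, rng):
        Xs = [rng.standard_normal((40, 6)) for _ in range(4)]
        nets = gsr_networks(Xs, 0.08)
        sups = [np.abs(n.extras["pre_symmetrization"]) > 1e-8 for n in nets]
        for s in sups[1:]:
            np.testing.assert_array_equal(s, sups[0])

    def test_lambda_max_gives_zero(self, rng):
        Xs = [rng.standard_normal((30, 5)) for _ in range(3)]
        lam = gsr_lambda_max(Xs)
        nets = gsr_networks(Xs, lam * 1.0001)
        assert max(np.abs(n.values).max() for n in nets) == 0.0

    def test_shared_design_matches_multitask_lasso(self, rng):
        # all subjects share the same signals: the per-ROI problem is a
        # multi-task lasso with a shared design matrix
        X = normalize_signals(rng.standard_normal((40, 5)))
        M, lam = 3, 0.05
        nets = gsr_networks([X] * M, lam, normalize=False, symmetrize_out=False)
        T = X.shape[0]
        for i in range(5):
            keep = [j for j in range(5) if j != i]
            ref = MultiTaskLasso(alpha=lam / T, fit_intercept=False, tol=1e-14, max_iter=200000)
            ref.fit(X[:, keep], np.column_stack([X[:, i]] * M))
            got = np.column_stack([n.extras["pre_symmetrization"][keep, i] for n in nets])
            np.testing.assert_allclose(got, ref.coef_.T, atol=2e-5)


class TestSSGSR:
    def test_collapses_to_gsr(self, rng):
        Xs = [rng.standard_normal((30, 5)) for _ in range(4)]
        B1 = np.ones((5, 4, 4))
        L0 = np.zeros((5, 4, 4))
        a = ssgsr_networks(Xs, 0.05, 0.0, B=B1, laplacians=L0)
        b = gsr_networks(Xs, 0.05)
        for x, y in zip(a, b):
            np.testing.assert_allclose(x.values, y.values, atol=1e-10)

    def test_objective_matches_subgradient_oracle(self, rng):
        # tiny fixture: 6 ROIs, 6 subjects, full SSGSR objective per ROI
        N, M = 6, 6
        Xs = [normalize_signals(rng.standard_normal((25, N))) for _ in range(M)]
        pcs = [pearson_network(X) for X in Xs]
        B = ssgsr_weights(pcs)
        Ls = subject_similarity_laplacians(pcs)
        lam1, lam2 = 0.05, 0.02
        nets = ssgsr_networks(Xs, lam1, lam2, B=B, laplacians=Ls,
                              normalize=False, symmetrize_out=False)
        i = 0
        keep = [j for j in range(N) if j != i]
        Ds = [X[:, keep] for X in Xs]
        xs = [X[:, i] for X in Xs]
        L_i = Ls[i]

        def obj(V):
            val = sum(0.5 * np.sum((xs[m] - Ds[m] @ V[:, m]) ** 2) for m in range(M))
            val += lam1 * np.linalg.norm(B[i] * V, axis=1).sum()
            val += lam2 * np.trace(V @ L_i @ V.T)
            return val

        V_fast = np.column_stack([n.extras["pre_symmetrization"][keep, i] for n in nets])
        f_oracle, _ = subgradient_ssgsr(Ds, xs, lam1, lam2, B[i], L_i, n_iter=100000)
        assert abs(obj(V_fast) - f_oracle) <= 1e-4 * abs(f_oracle)
        assert obj(V_fast) <= f_oracle + 1e-10  # fast solver at least as good

    def test_large_lambda2_shrinks_subject_differences(self, rng):
        N, M = 6, 6
        Xs = [rng.standard_normal((30, N)) for _ in range(M)]
        spreads = []
        for lam2 in [0.0, 0.05, 0.5, 5.0]:
            nets = ssgsr_networks(Xs, 0.02, lam2)
            Ws = [n.values for n in nets]
            spreads.append(
                max(np.abs(a - b).max() for a in Ws for b in Ws)
            )
        assert spreads[-1] < spreads[0]
        assert all(a >= b - 1e-6 for a, b in zip(spreads, spreads[1:]))


class TestSLR:
    def test_lambda2_zero_matches_sr_with_loss_scaling(self, rng):
        # SLR's loss has no 1/2 factor: SLR(lam1, 0) == SR(lam1 / 2)
        X = rng.standard_normal((30, 6))
        W1 = slr_network(X, 0.16, 0.0).values
        W2 = sr_network(X, 0.08).values
        np.testing.assert_allclose(W1, W2, atol=1e-5)

    def test_rank_non_increasing_in_lambda2(self, rng):
        X = rng.standard_normal((40, 8))
        ranks = []
        cfg = SolverConfig(max_iter=20000)
        for lam2 in [0.0, 0.05, 0.2, 0.5, 1.0, 2.0]:
            W = slr_network(X, 0.05, lam2, cfg).values
            ranks.append(np.linalg.matrix_rank(W, tol=1e-6))
        assert all(a >= b for a, b in zip(ranks, ranks[1:]))

    def test_huge_penalties_give_zero(self, rng):
        X = rng.standard_normal((30, 5))
        W = slr_network(X, 50.0, 50.0).values
        assert np.abs(W).max() == 0.0

    def test_admm_residuals_certified(self, rng):
        W = slr_network(rng.standard_normal((30, 6)), 0.1, 0.1)
        assert W.extras["certificates"][0].kkt_residual <= 1e-5


class TestSolverInvariants:
    @pytest.mark.parametrize("method", ["sr", "wsr", "gsr"])
    def test_never_worse_than_zero_solution(self, rng, method):
        X = normalize_signals(rng.standard_normal((30, 6)))
        lam = 0.05
        if method == "sr":
            W = sr_network(X, lam, normalize=False, symmetrize_out=False)
            f = objective_sr(X, W.values, lam)
            f0 = objective_sr(X, np.zeros((6, 6)), lam)
        elif method == "wsr":
            C = link_penalty_weights(pearson_network(X), 0.5)
            W = wsr_network(X, lam, C, normalize=False, symmetrize_out=False)
            f = 0.5 * np.sum((X - X @ W.values) ** 2) + lam * np.abs(C * W.values).sum()
            f0 = 0.5 * np.sum(X**2)
        else:
            nets = gsr_networks([X, X], lam, normalize=False, symmetrize_out=False)
            V = nets[0].extras["pre_symmetrization"]
            f = sum(
                0.5 * np.sum((X - X @ n.extras["pre_symmetrization"]) ** 2) for n in nets
            ) + lam * np.abs(V).sum() * np.sqrt(2) / np.sqrt(2)
            f0 = 2 * 0.5 * np.sum(X**2)
        assert f <= f0 + 1e-12

    def test_all_outputs_symmetric(self, rng):
        X = rng.standard_normal((30, 6))
        Xs = [rng.standard_normal((30, 6)) for _ in range(3)]
        pc = pearson_network(X)
        sigma = estimate_sigma([pc])
        C = link_penalty_weights(pc, sigma)
        g = group_edges([pc], G=3)
        d = group_weights(g.E, sigma)
        mats = [
            sr_network(X, 0.05).values,
            wsr_network(X, 0.05, C).values,
            wsgr_network(X, 0.05, 0.05, C, g, d).values,
            slr_network(X, 0.1, 0.1).values,
        ]
        mats += [n.values for n in gsr_networks(Xs, 0.05)]
        mats += [n.values for n in ssgsr_networks(Xs, 0.05, 0.02)]
        for W in mats:
            assert np.max(np.abs(W - W.T), initial=0.0) <= 1e-10

    def test_support_recovery_on_pair_fixture(self):
        """SR at oracle lambda recovers the planted pair support."""
        f1s = []
        for seed in range(5):
            spec = FixtureSpec(m_per_group=1, n_rois=10, t_points=60,
                               noise_sd=0.05, seed=seed)
            ds, truth = make_sparse_representation_dataset(spec)
            X = ds.subjects[0].data
            best = 0.0
            for lam in [0.02, 0.05, 0.1, 0.2, 0.4]:
                W = sr_network(X, lam).values
                est = np.abs(W) > 1e-8
                np.fill_diagonal(est, False)
                tp = np.sum(est & truth["support"])
                fp = np.sum(est & ~truth["support"])
                fn = np.sum(~est & truth["support"])
                f1 = 2 * tp / (2 * tp + fp + fn) if tp else 0.0
                best = max(best, f1)
            f1s.append(best)
        assert np.mean(f1s) >= 0.9
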