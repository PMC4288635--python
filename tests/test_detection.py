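import numpy as np
import pytest

from tsocd.detection import (
    TSOCD,
    discretize,
    gradient,
    objective_value,
    update_timepoint,
)

from conftest import random_instances


def objective_oracle(H_list, A_list, S, lam, beta, eps=1e-10):
    """Independent term-by-term summation of the objective (nested loops)."""
    T = len(H_list)
    N = A_list[0].shape[0]
    total = 0.0
    U = [H @ H.T for H in H_list]
    for t in range(T):
        for i in range(N):
            for j in range(N):
                if i == j:
                    continue
                u = max(U[t][i, j], eps)
                total += U[t][i, j] - A_list[t][i, j] * np.log(u)
        total += beta * np.sum(H_list[t] ** 2)
    for t in range(1, T):
        for i in range(N):
            for j in range(N):
                total += lam * S[i, j] * (U[t][i, j] - U[t - 1][i, j]) ** 2
    return total


def numerical_gradient(H_list, A_list, S, t, lam, beta, eps=1e-10, h=1e-5):
    """Central-difference gradient of the objective w.r.t. H[t]."""
    G = np.zeros_like(H_list[t])
    for i in range(G.shape[0]):
        for k in range(G.shape[1]):
            Hp = [H.copy() for H in H_list]
            Hm = [H.copy() for H in H_list]
            Hp[t][i, k] += h
            Hm[t][i, k] -= h
            G[i, k] = (
                objective_value(Hp, A_list, S, lam, beta, eps)
                - objective_value(Hm, A_list, S, lam, beta, eps)
            ) / (2 * h)
    return G


class TestObjective:
    def test_matches_independent_oracle(self):
        (H_list, A_list, S), = random_instances(1, N=8, T=3, r=2, seed=42)
        lam, beta = 0.25, 2.0
        ours = objective_value(H_list, A_list, S, lam, beta)
        ref = objective_oracle(H_list, A_list, S, lam, beta)
        assert ours == pytest.approx(ref, abs=1e-10 * max(1, abs(ref)))

    def test_all_ones_substitution(self):
        # U = all-ones, A = all-ones off-diagonal, lam = beta = 0:
        # every off-diagonal term is 1 - ln(1) = 1.
        N = 6
        H = np.ones((N, 1))
        A = np.ones((N, N)) - np.eye(N)
        assert objective_value([H], [A], np.zeros((N, N)), 0.0, 0.0) == pytest.approx(
            N * (N - 1)
        )

    def test_beta_additivity(self):
        (H_list, A_list, S), = random_instances(1, seed=7)
        base = objective_value(H_list, A_list, S, 0.1, 0.0)
        with_beta = objective_value(H_list, A_list, S, 0.1, 3.0)
        fro = sum(float((H**2).sum()) for H in H_list)
        assert with_beta - base == pytest.approx(3.0 * fro, rel=1e-12)

    def test_negative_entry_rejected(self):
        (H_list, A_list, S), = random_instances(1)
        H_list[0][0, 0] = -0.1
        with pytest.raises(ValueError, match="negative"):
            objective_value(H_list, A_list, S, 0.1, 1.0)


class TestGradient:
    def test_matches_central_differences(self):
        lam, beta = 2.0**-4, 2.0**4
        worst = 0.0
        for H_list, A_list, S in random_instances(5, N=10, T=3, r=3, seed=11):
            for t in range(3):
                G = gradient(H_list, A_list, S, t, lam, beta)
                G_num = numerical_gradient(H_list, A_list, S, t, lam, beta)
                rel = np.abs(G - G_num).max() / max(np.abs(G_num).max(), 1.0)
                worst = max(worst, rel)
        assert worst < 1e-5


class TestUpdate:
    def test_fixed_point_unchanged(self):
        # A equals the off-diagonal of U = H H^T exactly -> zero gradient.
        N = 6
        H = np.ones((N, 2)) / np.sqrt(2)
        A = np.ones((N, N)) - np.eye(N)
        H_new, _ = update_timepoint([H], [A], np.zeros((N, N)), 0, lam=0.0, beta=0.0)
        np.testing.assert_allclose(H_new, H, atol=1e-10)

    def test_objective_never_increases(self):
        lam, beta = 2.0**-4, 2.0**4
        for H_list, A_list, S in random_instances(10, seed=5):
            obj = objective_value(H_list, A_list, S, lam, beta)
            for _ in range(3):
                for t in range(len(H_list)):
                    H_list[t], _ = update_timepoint(H_list, A_list, S, t, lam, beta)
                    new = objective_value(H_list, A_list, S, lam, beta)
                    assert new <= obj + 1e-9 * max(abs(obj), 1.0)
                    obj = new

    def test_stationary_at_convergence(self, two_cliques):
        """Single time point, no smoothing: long run reaches a KKT point."""
        model = TSOCD(
            n_components=2, smooth_weight=0.0, lowrank_weight=1.0,
            tol=0.0, max_iter=3000, random_state=0,
        ).fit([two_cliques])
        H = model.factors_[0]
        G = gradient([H], [two_cliques], np.zeros_like(two_cliques), 0, 0.0, 1.0)
        # complementary slackness: H * grad ~ 0; at the floor grad may be > 0
        assert np.abs(H * G).max() < 1e-6


class TestFit:
    def test_planted_partition_recovery(self, two_cliques):
        model = TSOCD(
            n_components=2, smooth_weight=0.0, lowrank_weight=1.0, random_state=1,
            tol=1e-9, max_iter=2000,
        ).fit([two_cliques] * 3)
        for H in model.factors_:
            labels = np.argmax(H, axis=1)
            assert len(set(labels[:4])) == 1
            assert len(set(labels[4:])) == 1
            assert labels[0] != labels[4]

    def test_smoothness_reduces_drift(self, two_cliques):
        """With per-time random inits and a short run, the smoothness term
        pulls consecutive co-membership matrices together on stable pairs
        relative to the uncoupled fit (same seeds). At full convergence
        both reach the same attractor on this toy, so the early phase is
        where the coupling is visible."""
        S = two_cliques.copy()
        A_list = [two_cliques] * 4

        def drift(lam):
            total = 0.0
            for seed in range(3):
                model = TSOCD(
                    n_components=2, smooth_weight=lam, lowrank_weight=1.0,
                    random_state=seed, tol=0.0, max_iter=5,
                ).fit(A_list, S=S)
                U = [H @ H.T for H in model.factors_]
                total += sum(
                    float((S * (U[t] - U[t - 1]) ** 2).sum()) for t in range(1, 4)
                )
            return total

        assert drift(5.0) < drift(0.0)

    def test_fixed_seed_is_bitwise_deterministic(self, two_cliques):
        a = TSOCD(n_components=3, random_state=7, max_iter=20).fit([two_cliques] * 2)
        b = TSOCD(n_components=3, random_state=7, max_iter=20).fit([two_cliques] * 2)
        for Ha, Hb in zip(a.factors_, b.factors_):
            np.testing.assert_array_equal(Ha, Hb)

    def test_decoupling_at_lambda_zero(self, two_cliques):
        """With no smoothing the T subproblems are independent."""
        rng = np.random.default_rng(0)
        T = 3
        H0 = [rng.uniform(0.1, 1.0, size=(8, 2)) for _ in range(T)]
        A_list = [two_cliques] * T
        S = np.zeros((8, 8))
        joint = TSOCD(
            n_components=2, smooth_weight=0.0, lowrank_weight=1.0,
            tol=0.0, max_iter=50,
        ).fit(A_list, S=S, H_init=H0)
        for t in range(T):
            solo = TSOCD(
                n_components=2, smooth_weight=0.0, lowrank_weight=1.0,
                tol=0.0, max_iter=50,
            ).fit([A_list[t]], H_init=[H0[t]])
            np.testing.assert_allclose(joint.factors_[t], solo.factors_[0], atol=1e-10)

    def test_effective_rank_adapts(self):
        """3 planted complexes, rank 50: the trace-norm penalty prunes columns."""
        rng = np.random.default_rng(2)
        N = 30
        A = np.zeros((N, N))
        for block in (range(0, 10), range(10, 20), range(20, 30)):
            ix = np.ix_(block, block)
            A[ix] = 1
        np.fill_diagonal(A, 0)
        model = TSOCD(
            n_components=50, smooth_weight=0.0, random_state=4, tol=1e-8, max_iter=500
        ).fit([A])
        assert 3 <= len(model.complexes_[0]) <= 10

    def test_invalid_tau_rejected(self, two_cliques):
        with pytest.raises(ValueError, match="tau"):
            TSOCD(tau=1.5).fit([two_cliques])


class TestTraceNormIdentity:
    def test_sum_of_singular_values_equals_frobenius(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            H = rng.uniform(0, 1, size=(12, 4))
            sv = np.linalg.svd(H @ H.T, compute_uv=False)
            assert sv.sum() == pytest.approx(float((H**2).sum()), rel=1e-8)


class TestDiscretize:
    def test_row_rule_strongest_membership(self):
        # every protein: memberships (0.5, 0.1); row-normalized (1.0, 0.2)
        H = np.tile([0.5, 0.1], (4, 1))
        _, cxs = discretize(H, tau=0.3, min_size=3)
        assert cxs == [frozenset({0, 1, 2, 3})]

    def test_raw_mode_all_below_tau_gives_no_membership(self):
        H = np.full((5, 2), 0.2)
        B, cxs = discretize(H, tau=0.3, normalize="raw")
        assert cxs == []

    def test_column_with_two_survivors_dropped(self):
        H = np.zeros((5, 1))
        H[:2, 0] = 1.0
        _, cxs = discretize(H, tau=0.3, min_size=3)
        assert cxs == []

    def test_duplicate_columns_collapse(self):
        H = np.zeros((4, 2))
        H[:, 0] = [1, 1, 1, 0]
        H[:, 1] = [1, 1, 1, 0]
        B, cxs = discretize(H, tau=0.3)
        assert B.shape[1] == 1
        assert cxs == [frozenset({0, 1, 2})]

    def test_subset_columns_pruned(self):
        H = np.zeros((6, 2))
        H[:5, 0] = 1.0
        H[:3, 1] = 1.0
        _, cxs = discretize(H, tau=0.3)
        assert cxs == [frozenset(range(5))]

    def test_split_encoding_is_recovered(self):
        # one clique encoded as two proportional half-scale columns
        v = np.array([0.6, 0.6, 0.6, 0.6, 0.0])
        H = np.column_stack([v / np.sqrt(2), v / np.sqrt(2)])
        _, cxs = discretize(H, tau=0.3)
        assert cxs == [frozenset({0, 1, 2, 3})]

    def test_weak_attachment_excluded_by_comembership_floor(self):
        # protein 4's only membership is tiny in absolute terms: its best
        # co-membership 0.05*0.6 is far below tau^2
        H = np.zeros((5, 1))
        H[:4, 0] = 0.6
        H[4, 0] = 0.05
        _, cxs = discretize(H, tau=0.3)
        assert cxs == [frozenset({0, 1, 2, 3})]

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            discretize(np.array([[-1.0]]))

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="normalize"):
            discretize(np.ones((3, 1)), normalize="bogus")
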