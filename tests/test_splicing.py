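import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from splicega import (
    ConfigError,
    DegenerateFeatureError,
    Individual,
    SplicingConfig,
    SplicingState,
    SyntheticSpec,
    backward_sacrifice,
    del_add,
    fit_active,
    forward_sacrifice,
    generate,
    improved_splice,
    loss,
    splice_sweep,
    subset_loss,
    threshold_tau,
)


class TestFitActive:
    def test_constant_column_exact(self):
        beta = fit_active(np.ones((4, 1)), np.full(4, 2.0))
        np.testing.assert_allclose(beta, [2.0])

    def test_orthonormal_projection(self):
        rng = np.random.default_rng(0)
        Q, _ = np.linalg.qr(rng.standard_normal((20, 3)))
        Y = rng.standard_normal(20)
        np.testing.assert_allclose(fit_active(Q, Y), Q.T @ Y, atol=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((20, 3))
        Y = rng.standard_normal(20)
        oracle = np.linalg.solve(X.T @ X, X.T @ Y)
        np.testing.assert_allclose(fit_active(X, Y), oracle, atol=1e-8)

    def test_underdetermined_uses_ridge(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((3, 5))
        beta = fit_active(X, rng.standard_normal(3), ridge_eps=1e-8)
        assert np.all(np.isfinite(beta)) and beta.size == 5

    def test_empty_active_raises(self):
        with pytest.raises(ConfigError):
            fit_active(np.empty((4, 0)), np.zeros(4))


class TestLoss:
    def test_perfect_fit_zero(self):
        X = np.ones((4, 1))
        assert loss(X, np.array([2.0]), np.full(4, 2.0), 4) == 0.0

    def test_hand_value(self):
        # residual (1, 0), n = 2 -> (1/4) * 1 = 0.25
        X = np.ones((2, 1))
        assert loss(X, np.array([0.0]), np.array([1.0, 0.0]), 2) == pytest.approx(0.25)

    def test_homogeneity(self):
        rng = np.random.default_rng(3)
        X, Y = rng.standard_normal((10, 2)), rng.standard_normal(10)
        beta = np.array([0.3, -0.7])
        assert loss(3 * X, beta, 3 * Y, 10) == pytest.approx(9 * loss(X, beta, Y, 10))

    def test_empty_beta_uses_response_norm(self):
        Y = np.array([1.0, 2.0])
        assert loss(np.empty((2, 0)), np.empty(0), Y, 2) == pytest.approx(5 / 4)


class TestSacrifices:
    def test_backward_zero_coefficient(self):
        assert backward_sacrifice(np.ones(4), 0.0, 4) == 0.0

    def test_backward_hand_values(self):
        assert backward_sacrifice(np.ones(4), 2.0, 4) == pytest.approx(2.0)
        x = np.array([2.0, 2.0])  # x'x = 8
        assert backward_sacrifice(x, 1.0, 4) == pytest.approx(1.0)

    def test_forward_orthogonal_residual(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        d = float(x @ np.ones(4)) / 4
        assert d == 0.0
        assert forward_sacrifice(x, d, 4) == 0.0

    def test_forward_hand_value(self):
        x = np.array([1.0, 1.0, 1.0, 1.0])  # x'x = 4, residual = x -> d = 1
        assert forward_sacrifice(x, 1.0, 4) == pytest.approx(0.5)

    def test_forward_zero_norm_column(self):
        with pytest.raises(DegenerateFeatureError):
            forward_sacrifice(np.zeros(4), 0.1, 4)


class TestThresholdTau:
    def test_empty_active_set(self):
        assert threshold_tau(0, 100, 50) == 0.0

    def test_sheep_study_value(self):
        # 0.01 * 30 * ln(54183) * ln(ln 170) / 170, evaluated independently
        assert threshold_tau(30, 54183, 170) == pytest.approx(0.0314738213, abs=1e-8)

    def test_linear_in_active_size(self):
        t1 = threshold_tau(1, 500, 100)
        for a in (2, 7, 30):
            assert threshold_tau(a, 500, 100) == pytest.approx(a * t1)

    def test_small_n_rejected(self):
        with pytest.raises(ConfigError):
            threshold_tau(3, 10, 2)


class TestDelAdd:
    def test_lowest_score_demoted(self, orthogonal_design):
        X, Y, _ = orthogonal_design
        state = SplicingState.from_support([0, 2, 4, 5], X, Y)
        scores = X.shape[0] / (2 * X.shape[0]) * state.beta**2  # x'x = n
        new = del_add(state, scores, 3, X, Y)
        assert new.active.tolist() == [0, 2, 4]
        assert 5 in new.inactive

    def test_noop_below_cap(self, orthogonal_design):
        X, Y, _ = orthogonal_design
        state = SplicingState.from_support([0, 2], X, Y)
        assert del_add(state, np.array([1.0, 2.0]), 3, X, Y) is state

    def test_matches_sorting_oracle(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((30, 8))
        Y = rng.standard_normal(30)
        support = [1, 2, 4, 5, 7]
        state = SplicingState.from_support(support, X, Y)
        scores = rng.permutation(5).astype(float)
        keep_oracle = sorted(
            support, key=lambda j: scores[support.index(j)], reverse=True
        )[:2]
        new = del_add(state, scores, 2, X, Y)
        assert sorted(new.active.tolist()) == sorted(keep_oracle)


class TestSpliceSweep:
    def test_worked_single_swap(self, orthogonal_design):
        # active {0,2,4}: lowest backward score is 4; inactive {1,3,5,6}:
        # highest forward score is 1 -> the k=1 exchange yields {0,1,2}
        X, Y, _ = orthogonal_design
        state = SplicingState.from_support([0, 2, 4], X, Y)
        new = splice_sweep(state, X, Y, k_range=[1])
        assert new.active.tolist() == [0, 1, 2]
        assert new.loss == pytest.approx(0.625)  # residual X4 + 0.5 X5

    def test_all_swaps_rejected(self, orthogonal_design):
        X, _, _ = orthogonal_design
        Y = X @ np.array([3.0, 2.0, 4.0, 0, 0, 0, 0])
        state = SplicingState.from_support([0, 1, 2], X, Y)
        new = splice_sweep(state, X, Y)
        assert new.active.tolist() == [0, 1, 2]
        assert new.loss == state.loss

    def test_oversized_k_skipped(self, orthogonal_design):
        X, Y, _ = orthogonal_design
        state = SplicingState.from_support([0, 2, 4], X, Y)
        new = splice_sweep(state, X, Y, k_range=[50])
        assert new.active.tolist() == [0, 2, 4]


def _oracle_capped_splice(bits, X, Y, s_max, tau_const=0.01, max_iters=100):
    """Line-by-line transcription of the capped splicing procedure.

    Independent of the implementation: plain python loops, lstsq fits,
    scalar score formulas, explicit rank sets with low-index tie-breaks.
    """
    n, p = X.shape
    A = sorted(i for i in range(p) if bits[i])
    I = sorted(i for i in range(p) if not bits[i])

    def ols(cols):
        return np.linalg.lstsq(X[:, cols], Y, rcond=None)[0]

    def loss_of(cols):
        r = Y - X[:, cols] @ ols(cols) if cols else Y
        return float(r @ r) / (2 * n)

    if len(A) > s_max:
        beta = ols(A)
        xi = {j: (X[:, j] @ X[:, j]) / (2 * n) * beta[i] ** 2 for i, j in enumerate(A)}
        dropped = sorted(A, key=lambda j: (xi[j], j))[: len(A) - s_max]
        A = sorted(set(A) - set(dropped))
        I = sorted(set(I) | set(dropped))
    if not A or not I:
        return A, loss_of(A)
    tau = tau_const * len(A) * math.log(p) * math.log(math.log(n)) / n
    for _ in range(max_iters):
        beta = ols(A)
        resid = Y - X[:, A] @ beta
        L0 = loss_of(A)
        xi = {j: (X[:, j] @ X[:, j]) / (2 * n) * beta[i] ** 2 for i, j in enumerate(A)}
        d = {j: float(X[:, j] @ resid) / n for j in I}
        zeta = {
            j: (X[:, j] @ X[:, j])
            / (2 * n)
            * (d[j] / ((X[:, j] @ X[:, j]) / n)) ** 2
            for j in I
        }
        L, cur = L0, list(A)
        for k in range(1, min(len(A), len(I)) + 1):
            Ak = sorted(A, key=lambda j: (xi[j], j))[:k]
            Ik = sorted(I, key=lambda j: (-zeta[j], j))[:k]
            cand = sorted((set(A) - set(Ak)) | set(Ik))
            Ln = loss_of(cand)
            if Ln < L:
                L, cur = Ln, cand
        A = cur
        I = sorted(set(range(p)) - set(A))
        if L0 - L < tau:
            break
    return A, loss_of(A)


class TestImprovedSplice:
    def test_worked_figure_trajectory(self, orthogonal_design):
        # start [1,0,1,0,1,1,0], cap 3: index 5 demoted by the del step,
        # then the k=1 sweep swaps index 4 out for index 1
        X, Y, _ = orthogonal_design
        ind = Individual(np.array([1, 0, 1, 0, 1, 1, 0]))
        out, info = improved_splice(
            ind, X, Y, SplicingConfig(s_max=3, standardize=False), full_output=True
        )
        assert out.active.tolist() == [0, 1, 2]
        assert out.bits.tolist() == [1, 1, 1, 0, 0, 0, 0]
        assert info.loss == pytest.approx(0.625)

    def test_fixed_point_at_best_subset(self):
        Xm, y, _ = generate(SyntheticSpec(n=40, p=8, s_star=3, snr=10, seed=11))
        X, Y = Xm.values, y.values
        best = min(
            combinations(range(8), 3), key=lambda s: subset_loss(X, Y, s)
        )
        ind = Individual.from_support(best, 8)
        out = improved_splice(ind, X, Y, SplicingConfig(s_max=3, standardize=False))
        assert out.active.tolist() == sorted(best)

    def test_recovers_exhaustive_best_subset(self):
        Xm, y, _ = generate(SyntheticSpec(n=50, p=10, s_star=3, snr=10, seed=5))
        X, Y = Xm.values, y.values
        best = min(
            combinations(range(10), 3), key=lambda s: subset_loss(X, Y, s)
        )
        start = Individual(np.ones(10, dtype=np.int8))
        out = improved_splice(start, X, Y, SplicingConfig(s_max=3, standardize=False))
        assert out.active.tolist() == sorted(best)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_literal_transcription_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((30, 8))
        Y = X[:, :3] @ np.array([2.0, -1.5, 1.0]) + 0.3 * rng.standard_normal(30)
        bits = (rng.random(8) < 0.6).astype(np.int8)
        ind = Individual(bits)
        out, info = improved_splice(
            ind, X, Y, SplicingConfig(s_max=3, standardize=False), full_output=True
        )
        oracle_A, oracle_L = _oracle_capped_splice(bits, X, Y, 3)
        assert out.active.tolist() == oracle_A
        assert info.loss == pytest.approx(oracle_L, abs=1e-10)

    @given(seed=st.integers(0, 10_000))
    def test_partition_cap_and_descent_invariants(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((25, 12))
        Y = X[:, :2] @ np.array([1.5, -2.0]) + 0.5 * rng.standard_normal(25)
        bits = (rng.random(12) < 0.5).astype(np.int8)
        out, info = improved_splice(
            Individual(bits), X, Y, SplicingConfig(s_max=4), full_output=True
        )
        assert out.size <= 4
        assert set(out.active) | set(out.inactive) == set(range(12))
        assert not set(out.active) & set(out.inactive)
        # accepted losses strictly decrease
        assert all(b < a for a, b in zip(info.accepted_losses, info.accepted_losses[1:]))

    def test_idempotent_at_convergence(self):
        Xm, y, _ = generate(SyntheticSpec(n=60, p=15, s_star=3, snr=10, seed=21))
        cfg = SplicingConfig(s_max=4)
        start = Individual((np.random.default_rng(2).random(15) < 0.5).astype(np.int8))
        once = improved_splice(start, Xm.values, y.values, cfg)
        twice = improved_splice(once, Xm.values, y.values, cfg)
        assert once.bits.tolist() == twice.bits.tolist()

    def test_output_loss_never_beats_exhaustive(self):
        for seed in range(5):
            Xm, y, _ = generate(SyntheticSpec(n=50, p=10, s_star=3, snr=10, seed=seed))
            X, Y = Xm.values, y.values
            best_loss = min(
                subset_loss(X, Y, s) for s in combinations(range(10), 3)
            )
            start = Individual(np.ones(10, dtype=np.int8))
            _, info = improved_splice(
                start, X, Y, SplicingConfig(s_max=3, standardize=False), full_output=True
            )
            assert info.loss >= best_loss - 1e-9

    def test_empty_individual_passes_through(self, orthogonal_design):
        X, Y, _ = orthogonal_design
        out = improved_splice(
            Individual(np.zeros(7, dtype=np.int8)), X, Y, SplicingConfig(s_max=3)
        )
        assert out.size == 0
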