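"""Fixed-point embeddings: exactness, contraction, spectral bound."""

import numpy as np
import pytest

from phyloar.fixpoint import (
    CONTRACTION_RATE, SPECTRAL_BOUND, FixpointConfig, dirichlet_energy,
    exact_embedding, fixpoint_embedding, interior_spectral_radius,
    iteration_bound, pad_embeddings,
)
from phyloar.treespace import TaxaOrder, attach_leaf, enumerate_topologies, \
    decompose, init_state

from conftest import random_state


def state_of(topology):
    st = init_state(topology.taxa)
    for d in decompose(topology):
        st = attach_leaf(st, d)
    return st


def caterpillar_state(N):
    """Attach each new leaf to the previous leaf's pendant edge: interior path."""
    st = init_state(TaxaOrder.generic(N))
    for n in range(3, N):
        pendant = st.edges.index((n - 1, next(v for u, v in st.edges if u == n - 1)))
        st = attach_leaf(st, pendant)
    return st


class TestDirichletEnergy:
    def test_three_leaf_uniform_embedding_energy(self):
        st = init_state(TaxaOrder.generic(3))
        F = np.full((1, 3), 1.0 / 3.0)
        assert dirichlet_energy(F, st) == pytest.approx(2.0)

    def test_exact_solution_minimizes_energy(self, rng):
        st = random_state(8, rng)
        F = exact_embedding(st)
        base = dirichlet_energy(F, st)
        for _ in range(20):
            pert = F + rng.normal(0, 0.05, size=F.shape)
            assert dirichlet_energy(pert, st) >= base - 1e-12

    def test_dimension_mismatch_rejected(self):
        st = init_state(TaxaOrder.generic(4))
        with pytest.raises(ValueError):
            dirichlet_energy(np.zeros((2, 3)), st)


class TestExactEmbedding:
    def test_three_leaf_star(self):
        F = exact_embedding(init_state(TaxaOrder.generic(3)))
        assert np.allclose(F, 1.0 / 3.0)

    def test_quartet_hand_solved(self):
        # split {0,3} | {1,2}: interior adjacent to (1,2) then to (0,3)
        st = attach_leaf(init_state(TaxaOrder.generic(4)), 0)
        F = exact_embedding(st)
        expected = {
            frozenset([1, 2]): [1 / 8, 3 / 8, 3 / 8, 1 / 8],
            frozenset([0, 3]): [3 / 8, 1 / 8, 1 / 8, 3 / 8],
        }
        got = {frozenset(np.argsort(row)[-2:].tolist()): row for row in F}
        for key, row in got.items():
            assert np.allclose(row, expected[key])

    def test_rows_sum_to_one_and_residual(self, rng):
        for N in (5, 12, 25):
            st = random_state(N, rng)
            F = exact_embedding(st)
            assert np.allclose(F.sum(axis=1), 1.0)
            assert (F >= -1e-12).all()
            resid = F - st.A @ F / 3.0 - st.C / 3.0
            assert np.abs(resid).max() < 1e-12


class TestFixpointIteration:
    def test_rank_three_converges_in_one_step(self):
        st = init_state(TaxaOrder.generic(3))
        F, _ = fixpoint_embedding(st, n_iters=1)
        assert np.allclose(F, exact_embedding(st))

    @pytest.mark.parametrize("mode", ["plain", "power"])
    def test_matches_exact_solve_within_tolerance(self, mode, rng):
        cfg = FixpointConfig(epsilon=1e-5, mode=mode)
        for N in (4, 9, 20, 50):
            st = random_state(N, rng)
            F, _ = fixpoint_embedding(st, cfg)
            err = np.linalg.norm(F - exact_embedding(st))
            assert err < cfg.epsilon * N

    def test_plain_and_power_agree_at_matched_counts(self, rng):
        st = random_state(12, rng)
        for k in (1, 3, 5):
            Fp, _ = fixpoint_embedding(st, FixpointConfig(mode="plain"),
                                       n_iters=2 ** k)
            Fq, _ = fixpoint_embedding(st, FixpointConfig(mode="power"),
                                       n_iters=2 ** k)
            assert np.abs(Fp - Fq).max() < 1e-10

    def test_batched_solve_equals_per_tree(self, rng):
        states = [random_state(10, rng) for _ in range(6)]
        Fb, _ = fixpoint_embedding(states)
        for i, st in enumerate(states):
            Fi, _ = fixpoint_embedding(st)
            assert np.allclose(Fb[i], Fi)

    def test_mixed_rank_batch_rejected(self, rng):
        with pytest.raises(ValueError):
            fixpoint_embedding([random_state(5, rng), random_state(6, rng)])

    def test_contraction_rate_bound(self, rng):
        """Error ratio per step never exceeds 2*sqrt(2)/3 (plus roundoff)."""
        for _ in range(10):
            st = random_state(int(rng.integers(5, 30)), rng)
            Fstar = exact_embedding(st)
            A, C = st.A.astype(float), st.C.astype(float)
            F = np.full_like(Fstar, 1.0 / st.n)
            prev = np.linalg.norm(F - Fstar)
            for _ in range(60):
                F = A @ F / 3.0 + C / 3.0
                cur = np.linalg.norm(F - Fstar)
                if cur < 1e-13:
                    break
                assert cur <= prev * (CONTRACTION_RATE + 1e-9)
                prev = cur

    def test_padding_layout(self, rng):
        st = random_state(6, rng)
        F = exact_embedding(st)
        P = pad_embeddings(F, st.n, 10)
        assert P.shape == (10, 10)
        assert np.allclose(P[:6, :6], np.eye(6))
        assert np.allclose(P[:, 6:], 0.0)
        assert np.allclose(P[6:, :6], F)


class TestIterationBound:
    def test_monotone_in_epsilon(self):
        bounds = [iteration_bound(e, 10) for e in (1e-2, 1e-4, 1e-6, 1e-8)]
        assert bounds == sorted(bounds)

    def test_bound_is_sufficient_for_oracle_error(self, rng):
        eps = 1e-5
        for N in (5, 15, 40):
            st = random_state(N, rng)
            m = iteration_bound(eps, N)
            F, _ = fixpoint_embedding(st, n_iters=m)
            assert np.linalg.norm(F - exact_embedding(st)) < eps * N

    def test_power_mode_squaring_count(self, rng):
        st = random_state(8, rng)
        m = iteration_bound(1e-5, 8)
        _, iters = fixpoint_embedding(st, FixpointConfig(mode="power"))
        assert iters == 2 ** int(np.ceil(np.log2(m)))


class TestSpectralRadius:
    def test_quartet_interior_edge(self, rng):
        st = random_state(4, rng)
        assert interior_spectral_radius(st) == pytest.approx(1.0)

    def test_rank_three_is_zero(self):
        assert interior_spectral_radius(init_state(TaxaOrder.generic(3))) == 0.0

    @pytest.mark.parametrize("N", [5, 7, 10, 15])
    def test_caterpillar_matches_path_graph_spectrum(self, N):
        st = caterpillar_state(N)
        m = N - 2
        # confirm the interior graph is a path, then use its closed form
        deg = st.A.sum(axis=1)
        assert sorted(deg) == [1, 1] + [2] * (m - 2)
        assert interior_spectral_radius(st) == pytest.approx(
            2 * np.cos(np.pi / (m + 1)))

    @pytest.mark.parametrize("N", [4, 5, 6])
    def test_bound_exhaustive_small(self, N):
        for t in enumerate_topologies(N):
            assert interior_spectral_radius(state_of(t)) <= SPECTRAL_BOUND
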