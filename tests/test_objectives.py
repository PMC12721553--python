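"""Objectives: Fitch, JC pruning, priors, annealing, VIMCO, branch model."""

import numpy as np
import pytest
from scipy import stats

from phyloar import autodiff as ad
from phyloar.alignment import Alignment
from phyloar.exhaustive import brute_fitch, brute_pruning_loglik
from phyloar.model import ModelConfig, init_params, log_prob
from phyloar.objectives import (
    AnnealSchedule, anneal_beta, branch_edge_features, branch_loc_scale,
    branch_sample_logpdf, fitch_score, init_branch_params, jc_transition,
    kl_to_target, log_double_factorial, log_prior, parsimony_elbo,
    pruning_loglik, pruning_loglik_batch, pruning_loglik_t, tde_loss,
    vimco_signals,
)
from phyloar.synthdata import (random_branch_lengths, random_topology,
                               simulate_jc_alignment)
from phyloar.treespace import TaxaOrder, enumerate_topologies, init_state


def quartet_with_split(pair):
    ts = enumerate_topologies(4)
    return next(t for t in ts if frozenset(pair) in t.splits())


class TestFitch:
    def test_hand_checked_quartet_sites(self):
        t = quartet_with_split({2, 3})  # split {0,1} | {2,3}
        taxa = t.taxa
        a = Alignment(taxa, np.array([["A"], ["A"], ["C"], ["C"]]))
        b = Alignment(taxa, np.array([["A"], ["C"], ["A"], ["C"]]))
        assert fitch_score(t, a) == 1
        assert fitch_score(t, b) == 2

    def test_constant_sites_cost_nothing(self, rng):
        taxa = TaxaOrder.generic(5)
        aln = Alignment(taxa, np.full((5, 6), "G"))
        for t in enumerate_topologies(5, taxa):
            assert fitch_score(t, aln) == 0

    @pytest.mark.parametrize("N", [4, 5])
    def test_matches_bruteforce_minimum_over_assignments(self, N, rng):
        for _ in range(4):
            t = random_topology(N, rng)
            aln = simulate_jc_alignment(
                t, random_branch_lengths(t, rng, rate=3.0), 5, rng)
            assert fitch_score(t, aln) == brute_fitch(t, aln)

    def test_ambiguity_codes_act_as_state_sets(self):
        t = quartet_with_split({2, 3})
        # N is compatible with anything: (A, N, C, C) needs only one change
        aln = Alignment(t.taxa, np.array([["A"], ["N"], ["C"], ["C"]]))
        assert fitch_score(t, aln) == brute_fitch(t, aln) == 1

    def test_taxa_mismatch_rejected(self, rng):
        t = random_topology(4, rng)
        aln = Alignment(TaxaOrder.generic(5), np.full((5, 3), "A"))
        with pytest.raises(ValueError):
            fitch_score(t, aln)


class TestJukesCantor:
    def test_zero_branch_is_identity(self):
        assert np.allclose(jc_transition(0.0), np.eye(4))

    def test_long_branch_reaches_stationarity(self):
        assert np.allclose(jc_transition(50.0), 0.25, atol=1e-12)

    def test_rows_stochastic_and_symmetric(self, rng):
        for q in rng.exponential(0.3, size=5):
            P = jc_transition(q)
            assert np.allclose(P.sum(axis=1), 1.0)
            assert np.allclose(P, P.T)

    def test_negative_branch_rejected(self):
        with pytest.raises(ValueError):
            jc_transition(-0.1)


class TestPruning:
    def test_three_leaf_star_short_branches_limit(self):
        taxa = TaxaOrder.generic(3)
        t = init_state(taxa).to_topology()
        aln = Alignment(taxa, np.full((3, 4), "A"))
        ll = pruning_loglik(t, np.full(3, 1e-9), aln)
        assert ll == pytest.approx(4 * np.log(0.25), abs=1e-6)

    @pytest.mark.parametrize("N", [4, 5])
    def test_matches_bruteforce_sum_over_assignments(self, N, rng):
        for _ in range(3):
            t = random_topology(N, rng)
            bl = random_branch_lengths(t, rng)
            aln = simulate_jc_alignment(t, bl, 6, rng)
            assert pruning_loglik(t, bl, aln) == pytest.approx(
                brute_pruning_loglik(t, bl, aln), abs=1e-8)

    def test_batched_evaluation_matches_scalar(self, rng):
        t = random_topology(5, rng)
        aln = simulate_jc_alignment(t, random_branch_lengths(t, rng), 10, rng)
        Q = rng.exponential(0.1, size=(7, len(t.edges)))
        batch = pruning_loglik_batch(t, Q, aln)
        for i in range(7):
            assert batch[i] == pytest.approx(pruning_loglik(t, Q[i], aln))

    def test_differentiable_version_value_and_gradient(self, rng):
        t = random_topology(4, rng)
        bl = random_branch_lengths(t, rng)
        aln = simulate_jc_alignment(t, bl, 8, rng)
        q = ad.parameter(bl)
        ll = pruning_loglik_t(t, q, aln)
        assert ll.item() == pytest.approx(pruning_loglik(t, bl, aln))
        ll.backward()
        for i in range(len(bl)):
            h = 1e-6
            bl2 = bl.copy()
            bl2[i] += h
            fp = pruning_loglik(t, bl2, aln)
            bl2[i] -= 2 * h
            fm = pruning_loglik(t, bl2, aln)
            assert (fp - fm) / (2 * h) == pytest.approx(q.grad[i], abs=1e-4)

    def test_ambiguous_leaf_marginalizes(self, rng):
        taxa = TaxaOrder.generic(4)
        t = enumerate_topologies(4, taxa)[0]
        bl = np.full(5, 0.1)
        full = Alignment(taxa, np.array([["N"], ["C"], ["A"], ["C"]]))
        parts = [Alignment(taxa, np.array([[c], ["C"], ["A"], ["C"]]))
                 for c in "ACGT"]
        mix = np.log(sum(np.exp(pruning_loglik(t, bl, a)) for a in parts))
        assert pruning_loglik(t, bl, full) == pytest.approx(mix)


class TestPriors:
    def test_uniform_topology_plus_exponential_branches(self):
        taxa = TaxaOrder.generic(5)
        t = enumerate_topologies(5, taxa)[0]
        q = np.zeros(7)
        assert log_prior(t, q) == pytest.approx(-np.log(15.0) + 7 * np.log(10.0))

    def test_linear_decay_in_total_length(self, rng):
        t = random_topology(6, rng)
        q = random_branch_lengths(t, rng)
        base = log_prior(t, q)
        assert log_prior(t, q + 0.01) == pytest.approx(base - 10.0 * 0.09)

    def test_double_factorial_values(self):
        assert np.exp(log_double_factorial(5)) == pytest.approx(15.0)
        assert np.exp(log_double_factorial(7)) == pytest.approx(105.0)

    def test_negative_lengths_rejected(self, rng):
        t = random_topology(4, rng)
        with pytest.raises(ValueError):
            log_prior(t, -np.ones(5))


class TestAnnealing:
    def test_schedule_floor_cap_and_monotonicity(self):
        s = AnnealSchedule(period=1000)
        assert anneal_beta(0, s) == pytest.approx(0.001)
        assert anneal_beta(999, s) == pytest.approx(1.0)
        betas = [anneal_beta(t, s) for t in range(0, 1200, 50)]
        assert betas == sorted(betas)
        assert betas[-1] == 1.0


class TestVimco:
    def test_equal_weights_give_zero_signals(self):
        assert np.allclose(vimco_signals(np.full(6, -3.7)), 0.0)

    def test_signals_shift_invariant(self, rng):
        l = rng.normal(size=8)
        assert np.allclose(vimco_signals(l), vimco_signals(l + 123.4))

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            vimco_signals(np.array([0.0]))

    def test_leave_one_out_formula_on_small_case(self):
        l = np.array([0.0, np.log(3.0)])
        full = np.log((1 + 3) / 2)
        repl0 = np.log((3 + np.exp(np.log(3))) / 2)  # l0 -> mean of others
        repl1 = np.log((1 + np.exp(0.0)) / 2)
        expected = np.array([full - repl0, full - repl1])
        assert np.allclose(vimco_signals(l), expected)


@pytest.fixture(scope="module")
def parsimony_setup():
    rng = np.random.default_rng(21)
    truth = random_topology(5, rng)
    aln = simulate_jc_alignment(
        truth, random_branch_lengths(truth, rng, rate=4.0), 40, rng)
    cfg = ModelConfig(N=5, d=8, h=2)
    params = init_params(cfg, seed=2)
    return cfg, params, aln


class TestParsimonyBound:

    def test_bound_value_recomputed_from_log_weights(self, parsimony_setup):
        cfg, params, aln = parsimony_setup
        out = parsimony_elbo(params, cfg, aln, K=6, beta=0.5,
                             rng=np.random.default_rng(0))
        l = out["log_weights"]
        assert out["bound"] == pytest.approx(
            np.log(np.exp(l).mean()), abs=1e-9)
        # permutation invariance of the bound
        assert np.log(np.exp(l[::-1]).mean()) == pytest.approx(out["bound"])

    def test_single_sample_degenerates_to_elbo(self, parsimony_setup):
        cfg, params, aln = parsimony_setup
        out = parsimony_elbo(params, cfg, aln, K=1, beta=1.0,
                             rng=np.random.default_rng(1))
        assert out["bound"] == pytest.approx(out["log_weights"][0])

    def test_exp_bound_below_partition_function(self, parsimony_setup):
        """E[exp(bound)] <= Z_beta, by Jensen; checked by Monte Carlo."""
        cfg, params, aln = parsimony_setup
        beta = 0.25
        ts = enumerate_topologies(5, aln.taxa)
        Z = sum(np.exp(-beta * fitch_score(t, aln)) for t in ts)
        rng = np.random.default_rng(5)
        vals = [np.exp(parsimony_elbo(params, cfg, aln, 4, beta, rng)["bound"])
                for _ in range(120)]
        mean = np.mean(vals)
        sem = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert mean <= Z + 3 * sem


@pytest.fixture(scope="module")
def model5():
    cfg = ModelConfig(N=5, d=8, h=2)
    return cfg, init_params(cfg, seed=4)


class TestDensityEstimation:

    def test_single_tree_loss_is_negative_log_prob(self, model5, rng):
        cfg, params = model5
        t = random_topology(5, rng)
        loss = tde_loss(params, cfg, [t], [1.0], None, rng)
        assert loss.item() == pytest.approx(-log_prob(params, cfg, [t]).data[0])

    def test_full_batch_loss_is_cross_entropy_above_entropy(self, model5, rng):
        cfg, params = model5
        ts = enumerate_topologies(5)
        w = rng.dirichlet(np.ones(15))
        loss = tde_loss(params, cfg, ts, w, None, rng).item()
        entropy = -(w * np.log(w)).sum()
        assert loss >= entropy - 1e-9

    def test_empty_training_set_rejected(self, model5, rng):
        cfg, params = model5
        with pytest.raises(ValueError):
            tde_loss(params, cfg, [], [], None, rng)

    def test_kl_to_own_distribution_is_zero(self, model5):
        cfg, params = model5
        ts = enumerate_topologies(5)
        probs = np.exp(log_prob(params, cfg, ts).data)
        probs /= probs.sum()
        assert kl_to_target(params, cfg, ts, probs) == pytest.approx(0.0, abs=1e-6)

    def test_kl_to_uniform_matches_direct_formula(self, model5):
        cfg, params = model5
        ts = enumerate_topologies(5)
        w = np.full(15, 1 / 15)
        lp = log_prob(params, cfg, ts).data
        direct = -np.log(15.0) - lp.mean()
        kl = kl_to_target(params, cfg, ts, w)
        assert kl == pytest.approx(direct)
        assert kl >= 0.0

    def test_unnormalized_target_rejected(self, model5):
        cfg, params = model5
        ts = enumerate_topologies(5)[:3]
        with pytest.raises(ValueError):
            kl_to_target(params, cfg, ts, np.ones(3))


@pytest.fixture(scope="module")
def branch_setup():
    cfg = ModelConfig(N=5, d=8, h=2)
    bparams = init_branch_params(cfg, seed=9)
    t = random_topology(5, np.random.default_rng(2))
    _, feats = branch_edge_features(t)
    return cfg, bparams, feats


class TestBranchModel:

    def test_zero_noise_draw_is_exp_location(self, branch_setup):
        cfg, bparams, feats = branch_setup
        mu, _ = branch_loc_scale(bparams, feats)
        q, _ = branch_sample_logpdf(bparams, feats, None, z=np.zeros(7))
        assert np.allclose(q.data, np.exp(mu.data))

    def test_log_density_matches_scipy_lognorm(self, branch_setup):
        cfg, bparams, feats = branch_setup
        rng = np.random.default_rng(0)
        q, logpdf = branch_sample_logpdf(bparams, feats, rng)
        mu, sigma = branch_loc_scale(bparams, feats)
        ref = sum(
            stats.lognorm.logpdf(q.data[i], s=sigma.data[i],
                                 scale=np.exp(mu.data[i]))
            for i in range(len(q.data)))
        assert logpdf.item() == pytest.approx(ref, abs=1e-9)

    def test_sample_median_near_exp_location(self, branch_setup):
        cfg, bparams, feats = branch_setup
        rng = np.random.default_rng(3)
        draws = np.stack([
            branch_sample_logpdf(bparams, feats, rng)[0].data
            for _ in range(801)])
        mu, _ = branch_loc_scale(bparams, feats)
        med = np.median(draws, axis=0)
        assert np.abs(np.log(med) - mu.data).max() < 0.15
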