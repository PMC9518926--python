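from fractions import Fraction
from math import comb

import numpy as np
import pytest

from oracles import simulate_mutation_process, simulate_two_locus
from popsizehmm.demography import (DemographicModel, Discretization,
                                   tmrca_discretization)
from popsizehmm.tmrca_probs import (build_emission_tmrca,
                                    build_transition_tmrca,
                                    derived_allele_prob,
                                    enumerate_rho_states,
                                    enumerate_theta_states, joint_tmrca_cdf,
                                    rho_rate_matrix, solve_rho_ode,
                                    solve_theta_ode, theta_rate_matrix)


def brute_force_rho_states(n):
    """Exhaustive filter over the full tuple lattice (independent of the
    breadth-first search used by the implementation)."""
    reachable = {(n, 0, 0, 0)}
    changed = True
    while changed:
        changed = False
        for (kab, ka, kb, kp) in list(reachable):
            if (kab, ka, kb) == (1, 0, 0):
                continue
            nxt = []
            if kab >= 2:
                nxt.append((kab - 1, ka, kb, kp))
            if ka >= 1:
                nxt.append((kab, ka - 1, kb, kp))
            if kb >= 1:
                nxt.append((kab, ka, kb - 1, kp))
            if kp == 0 and kab >= 2:
                nxt.append((kab - 1, ka + 1, kb + 1, 1))
            for s in nxt:
                if s not in reachable:
                    reachable.add(s)
                    changed = True
    return reachable


class TestStateSpaces:
    def test_n2_rho_states(self):
        spec = enumerate_rho_states(2)
        assert set(spec.states) == {(2, 0, 0, 0), (1, 0, 0, 0), (1, 1, 1, 1),
                                    (1, 0, 1, 1), (1, 1, 0, 1), (1, 0, 0, 1)}

    @pytest.mark.parametrize("n", [3, 4, 6])
    def test_rho_states_match_brute_force(self, n):
        assert set(enumerate_rho_states(n).states) == brute_force_rho_states(n)

    def test_every_transient_state_can_leave(self, constant_model):
        spec = enumerate_rho_states(5, rho=0.1)
        Q = spec.rate_matrix(constant_model, 0.3)
        for s in spec.states:
            i = spec.index[s]
            if s in spec.absorbing:
                assert np.all(Q[i] == 0.0)
            else:
                assert Q[i].sum() == pytest.approx(0.0, abs=1e-14)
                assert np.any(Q[i] > 0)

    def test_theta_states_n3(self):
        spec = enumerate_theta_states(3)
        assert set(spec.states) == {(3, -1), (2, -1), (1, -1), (3, 3),
                                    (2, 3), (1, 3), (2, 2), (1, 2)}

    def test_theta_states_n2(self):
        assert set(enumerate_theta_states(2).states) == \
            {(2, -1), (1, -1), (2, 2), (1, 2)}

    def test_no_single_lineage_mutation_state(self):
        for n in (2, 5, 9):
            assert (1, 1) not in enumerate_theta_states(n).states

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            enumerate_rho_states(1)
        with pytest.raises(ValueError):
            enumerate_theta_states(1)


class TestRateMatrices:
    def test_rho_rates_n2(self, constant_model):
        spec = enumerate_rho_states(2, rho=0.1)
        Q = rho_rate_matrix(spec, constant_model, 0.0)
        i = spec.index[(2, 0, 0, 0)]
        assert Q[i, spec.index[(1, 0, 0, 0)]] == pytest.approx(1.0)
        assert Q[i, spec.index[(1, 1, 1, 1)]] == pytest.approx(0.1)

    def test_no_second_recombination(self, constant_model):
        spec = enumerate_rho_states(4, rho=0.2)
        Q = rho_rate_matrix(spec, constant_model, 0.0)
        for s in spec.states:
            if s[3] == 1:
                for t in spec.states:
                    if t[3] == 2:
                        assert t not in spec.index
                # recombination would raise kappa; no such target exists
                row = Q[spec.index[s]]
                for t, rate in zip(spec.states, row):
                    if rate > 0 and t != s:
                        assert t[3] == s[3]

    def test_rho_rates_scale_with_lambda(self):
        m = DemographicModel([1.0], np.log([1.0, 2.0]), 1e4)
        spec = enumerate_rho_states(3, rho=0.05)
        Q0 = rho_rate_matrix(spec, m, 0.5)
        Q1 = rho_rate_matrix(spec, m, 1.5)
        assert np.allclose(Q1 - spec.rho * spec.Q_recomb,
                           2 * (Q0 - spec.rho * spec.Q_recomb))

    def test_theta_rates_n3(self, constant_model):
        spec = enumerate_theta_states(3, theta=0.002)
        Q = theta_rate_matrix(spec, constant_model, 0.0)
        i = spec.index[(3, -1)]
        assert Q[i, spec.index[(2, -1)]] == pytest.approx(3.0)
        assert Q[i, spec.index[(3, 3)]] == pytest.approx(0.003)
        assert np.all(Q[spec.index[(1, -1)]] == 0.0)

    def test_one_mutation_only(self, constant_model):
        spec = enumerate_theta_states(4, theta=0.01)
        Q = theta_rate_matrix(spec, constant_model, 0.0)
        for s in spec.states:
            if s[1] != -1:  # already mutated: only coalescence moves left
                for t, rate in zip(spec.states, Q[spec.index[s]]):
                    if rate > 0 and t != s:
                        assert t == (s[0] - 1, s[1])


class TestOdeSolutions:
    def test_pure_pairwise_coalescence(self, constant_model):
        spec = enumerate_rho_states(2, rho=0.0)
        ts = np.array([0.2, 0.9, 2.1])
        g = solve_rho_ode(spec, constant_model, ts)
        expected = 1.0 - np.exp(-ts)
        assert g[:, spec.index[(1, 0, 0, 0)]] == pytest.approx(expected,
                                                               abs=1e-7)

    def test_mass_conserved(self, sawtooth_model):
        spec = enumerate_rho_states(4, rho=0.05)
        g = solve_rho_ode(spec, sawtooth_model, np.linspace(0.05, 6, 25))
        assert g.sum(axis=1) == pytest.approx(np.ones(25), abs=1e-7)
        tspec = enumerate_theta_states(4, theta=0.01)
        gt = solve_theta_ode(tspec, sawtooth_model, np.linspace(0.05, 6, 25))
        assert gt.sum(axis=1) == pytest.approx(np.ones(25), abs=1e-7)

    def test_against_jump_chain_simulation(self, constant_model):
        spec = enumerate_rho_states(3, rho=0.01)
        sim = simulate_two_locus(3, rho=0.01, reps=50_000, seed=4)
        # state occupancy at t = 1 is summarized by the per-locus
        # coalescence indicators it implies
        g = solve_rho_ode(spec, constant_model, [1.0])[0]
        for label, sel in {
            "a done": lambda s: s[0] + s[1] == 1,
            "b done": lambda s: s[0] + s[2] == 1,
            "both done": lambda s: (s[0], s[1], s[2]) == (1, 0, 0),
        }.items():
            model_p = sum(g[spec.index[s]] for s in spec.states if sel(s))
            if label == "a done":
                emp = np.mean(sim["Ta"] <= 1.0)
            elif label == "b done":
                emp = np.mean(sim["Tb"] <= 1.0)
            else:
                emp = np.mean((sim["Ta"] <= 1.0) & (sim["Tb"] <= 1.0))
            se = np.sqrt(emp * (1 - emp) / 50_000)
            assert abs(model_p - emp) < 3 * se + 1e-9, label


class TestJointCdf:
    def test_no_recombination_reduces_to_single_locus(self, constant_model):
        spec = enumerate_rho_states(2, rho=0.0)
        tau = np.log(2)
        assert joint_tmrca_cdf(spec, constant_model, tau, tau) == \
            pytest.approx(0.5, abs=1e-7)

    def test_symmetry(self, constant_model):
        spec = enumerate_rho_states(3, rho=0.08)
        assert joint_tmrca_cdf(spec, constant_model, 0.5, 1.5) == \
            pytest.approx(joint_tmrca_cdf(spec, constant_model, 1.5, 0.5),
                          abs=1e-12)

    def test_monotone_in_each_argument(self, sawtooth_model):
        spec = enumerate_rho_states(3, rho=0.05)
        taus = [0.3, 0.8, 1.5, 3.0, np.inf]
        vals = np.array([[joint_tmrca_cdf(spec, sawtooth_model, a, b)
                          for b in taus] for a in taus])
        assert np.all(np.diff(vals, axis=0) >= -1e-9)
        assert np.all(np.diff(vals, axis=1) >= -1e-9)
        assert vals[-1, -1] == pytest.approx(1.0, abs=1e-6)


class TestTransitionMatrix:
    def test_zero_recombination_gives_identity(self, constant_model):
        disc = tmrca_discretization(8, 3, constant_model)
        ts = build_transition_tmrca(constant_model, 3, disc, rho=0.0)
        assert np.abs(ts.A - np.eye(8)).max() < 1e-5

    def test_pairwise_median_marginal(self, constant_model):
        disc = Discretization([0.0, np.log(2), np.inf])
        ts = build_transition_tmrca(constant_model, 2, disc, rho=0.0)
        assert ts.Pi == pytest.approx([0.5, 0.5], abs=1e-6)

    @pytest.mark.parametrize("n", [2, 3, 5, 10])
    def test_rows_stochastic(self, sawtooth_model, n):
        disc = tmrca_discretization(10, n, sawtooth_model)
        ts = build_transition_tmrca(sawtooth_model, n, disc)
        es = build_emission_tmrca(sawtooth_model, n, disc)
        assert ts.A.sum(axis=1) == pytest.approx(np.ones(10), abs=1e-8)
        assert es.B.sum(axis=1) == pytest.approx(np.ones(10), abs=1e-8)
        assert ts.Pi.sum() == pytest.approx(1.0, abs=1e-8)
        assert np.abs(ts.A_PMF - ts.A_PMF.T).max() < 1e-6

    def test_joint_pmf_matches_simulation(self, constant_model):
        disc = tmrca_discretization(8, 2, constant_model)
        ts = build_transition_tmrca(constant_model, 2, disc, rho=0.05)
        sim = simulate_two_locus(2, rho=0.05, reps=100_000, seed=7)
        b = disc.boundaries
        for i in [1, 3, 5]:
            for j in [2, 4, 6]:
                emp = np.mean((sim["Ta"] > b[i - 1]) & (sim["Ta"] <= b[i])
                              & (sim["Tb"] > b[j - 1]) & (sim["Tb"] <= b[j]))
                p = max(emp, ts.A_PMF[i - 1, j - 1])
                se = np.sqrt(max(p * (1 - p), 1e-10) / 100_000)
                assert abs(ts.A_PMF[i - 1, j - 1] - emp) < 3 * se + 1e-6

    def test_marginal_matches_single_locus_intervals(self, sawtooth_model):
        # Pi from the two-locus machinery must agree with the plain
        # single-locus coalescent interval probabilities
        n = 4
        disc = tmrca_discretization(9, n, sawtooth_model)
        ts = build_transition_tmrca(sawtooth_model, n, disc)
        spec = enumerate_theta_states(n, theta=0.0)
        g = solve_theta_ode(spec, sawtooth_model, disc.finite_boundaries)
        cdf = np.concatenate([[0.0], g[:, spec.index[(1, -1)]], [1.0]])
        assert ts.Pi == pytest.approx(np.diff(cdf), abs=1e-5)


class TestDerivedAlleleProb:
    def test_pairwise_mutation_uniform(self):
        assert [derived_allele_prob(4, 2, d) for d in (1, 2, 3)] == \
            pytest.approx([1 / 3] * 3)

    def test_leaf_branch_mutation(self):
        assert derived_allele_prob(4, 4, 1) == pytest.approx(1.0)
        assert derived_allele_prob(4, 4, 2) == 0.0

    def test_sums_to_one_exact_rationals(self):
        for n in range(2, 13):
            for k_star in range(2, n + 1):
                total = sum(
                    Fraction(comb(n - d - 1, k_star - 2),
                             comb(n - 1, k_star - 1))
                    for d in range(1, n) if n - d - 1 >= k_star - 2)
                assert total == 1

    def test_invalid_d_rejected(self):
        with pytest.raises(ValueError):
            derived_allele_prob(4, 2, 0)


class TestEmissionMatrix:
    def test_zero_mutation_rate_emits_nothing(self, sawtooth_model):
        disc = tmrca_discretization(8, 4, sawtooth_model)
        es = build_emission_tmrca(sawtooth_model, 4, disc, theta=0.0)
        assert np.all(es.B[:, 0] > 1 - 1e-7)

    def test_total_probability_at_infinity(self, constant_model):
        disc = tmrca_discretization(8, 2, constant_model)
        es = build_emission_tmrca(constant_model, 2, disc)
        assert es.B_CDF[-1].sum() == pytest.approx(1.0, abs=1e-6)

    def test_cdf_nondecreasing_in_time(self, constant_model):
        disc = tmrca_discretization(8, 5, constant_model)
        es = build_emission_tmrca(constant_model, 5, disc)
        assert np.all(np.diff(es.B_CDF, axis=0) >= -1e-9)

    def test_small_theta_snp_probability(self, constant_model):
        # P[segregating] ~ theta * E[L] / 2 to first order; E[L] = 2 for
        # a pair
        theta = 0.001
        disc = tmrca_discretization(12, 2, constant_model)
        ts = build_transition_tmrca(constant_model, 2, disc, rho=0.0)
        es = build_emission_tmrca(constant_model, 2, disc, theta=theta)
        p_snp = float(ts.Pi @ es.B[:, 1])
        assert p_snp == pytest.approx(theta, rel=0.05)

    def test_marginal_sfs_matches_jump_chain(self, constant_model):
        n, theta = 4, 0.01
        disc = tmrca_discretization(10, n, constant_model)
        ts = build_transition_tmrca(constant_model, n, disc, rho=0.0)
        es = build_emission_tmrca(constant_model, n, disc, theta=theta)
        model_sfs = ts.Pi @ es.B
        sim = simulate_mutation_process(n, theta, reps=200_000, seed=3)
        rng = np.random.default_rng(9)
        d_sim = np.zeros(len(sim["k_star"]), dtype=int)
        mutated = sim["k_star"] > 0
        # second stage: mutation on one of k* lineages subtends d leaves
        for k_star in range(2, n + 1):
            mask = sim["k_star"] == k_star
            probs = [comb(n - d - 1, k_star - 2) / comb(n - 1, k_star - 1)
                     if n - d - 1 >= k_star - 2 else 0.0
                     for d in range(1, n)]
            d_sim[mask] = rng.choice(np.arange(1, n), size=mask.sum(),
                                     p=probs)
        for d in range(n):
            emp = np.mean(d_sim == d)
            se = np.sqrt(max(emp * (1 - emp), 1e-10) / len(d_sim))
            assert abs(model_sfs[d] - emp) < 3 * se + 1e-9
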