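import numpy as np
import pytest
from scipy.stats import hypergeom

from popsizehmm.demography import DemographicModel, tmrca_discretization
from popsizehmm.em_engine import (EMConfig, SubsetScheme, _initial_simplex,
                                  build_matrices, build_subsets, m_step,
                                  pseudo_haploid_emission, q_function,
                                  run_em)
from popsizehmm.hmm_core import SufficientStats, forward_backward_skipping
from popsizehmm.simdata import sample_from_chmm
from popsizehmm.tmrca_probs import build_emission_tmrca, \
    build_transition_tmrca


class TestSubsets:
    def test_all_overlapping_pairs(self):
        assert len(SubsetScheme.all_pairs(10).subsets) == 45

    def test_nonoverlapping_partition_counts(self):
        scheme = build_subsets(200, sizes=[2, 5, 10], seed=1)
        assert len(scheme.subsets) == 100 + 40 + 20
        for size in (2, 5, 10):
            cls = scheme.of_size(size)
            flat = [i for s in cls for i in s]
            assert len(flat) == len(set(flat))  # disjoint within a size

    def test_full_sample_subset(self):
        scheme = build_subsets(10, sizes=[10], seed=0)
        assert scheme.subsets == [tuple(range(10))]

    def test_remainder_discarded(self):
        scheme = build_subsets(10, sizes=[3], seed=0)
        assert len(scheme.subsets) == 3

    def test_seeded_determinism(self):
        a = build_subsets(30, sizes=[2, 5], seed=7)
        b = build_subsets(30, sizes=[2, 5], seed=7)
        c = build_subsets(30, sizes=[2, 5], seed=8)
        assert a.subsets == b.subsets
        assert a.subsets != c.subsets

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            build_subsets(4, sizes=[5])
        with pytest.raises(ValueError):
            build_subsets(4, sizes=[1])

    def test_explicit_file_round_trip(self, tmp_path):
        path = tmp_path / "subsets.txt"
        path.write_text("0 1 2\n3 4\n# comment\n0 3\n")
        scheme = SubsetScheme.from_file(path)
        assert scheme.subsets == [(0, 1, 2), (3, 4), (0, 3)]


class TestQFunction:
    @pytest.fixture
    def setup(self, constant_model):
        disc = tmrca_discretization(6, 2, constant_model)
        return constant_model, {2: disc}

    def test_single_transition_cell(self, setup):
        model, discs = setup
        A, B, Pi = build_matrices(model, 2, discs[2])
        stats = SufficientStats.zeros(6, 2)
        stats.expected_transitions[1, 3] = 7.0
        val = q_function(model.log_rates, {2: stats}, model, discs)
        assert val == pytest.approx(7.0 * np.log(A[1, 3]))

    def test_regularization_off_matches_unpenalized(self, sawtooth_model):
        disc = tmrca_discretization(6, 2, sawtooth_model)
        stats = SufficientStats.zeros(6, 2)
        stats.expected_initial[:] = 0.2
        a = q_function(sawtooth_model.log_rates, {2: stats}, sawtooth_model,
                       {2: disc}, c12=0.0)
        b = q_function(sawtooth_model.log_rates, {2: stats}, sawtooth_model,
                       {2: disc})
        assert a == b

    def test_regularization_penalizes_roughness(self, sawtooth_model):
        disc = tmrca_discretization(6, 2, sawtooth_model)
        stats = SufficientStats.zeros(6, 2)
        stats.expected_initial[:] = 0.2
        smooth = q_function(sawtooth_model.log_rates, {2: stats},
                            sawtooth_model, {2: disc}, c12=0.0)
        rough = q_function(sawtooth_model.log_rates, {2: stats},
                           sawtooth_model, {2: disc}, c12=1.0)
        penalty = np.sum(np.diff(sawtooth_model.log_rates) ** 2)
        assert smooth - rough == pytest.approx(penalty)

    def test_true_parameters_maximize_on_exact_stats(self, constant_model,
                                                     rng):
        # EM monotonicity surrogate: Q at the generating parameters beats
        # random perturbations when the stats are the exact expectations
        disc = tmrca_discretization(8, 2, constant_model)
        A, B, Pi = build_matrices(constant_model, 2, disc)
        L = 50_000
        stats = SufficientStats(
            expected_transitions=(L - 1) * Pi[:, None] * A,
            expected_emissions=L * Pi[:, None] * B,
            expected_initial=Pi.copy(),
            log_likelihood=0.0, n_s=2)
        q_true = q_function(constant_model.log_rates, {2: stats},
                            constant_model, {2: disc})
        for _ in range(20):
            pert = constant_model.log_rates + rng.normal(0, 0.4, 1)
            assert q_function(pert, {2: stats}, constant_model,
                              {2: disc}) <= q_true + 1e-6


class TestMStep:
    def test_starting_at_optimum_stays(self, constant_model):
        disc = tmrca_discretization(8, 2, constant_model)
        A, B, Pi = build_matrices(constant_model, 2, disc)
        L = 10_000
        stats = SufficientStats((L - 1) * Pi[:, None] * A,
                                L * Pi[:, None] * B, Pi.copy(), 0.0, 2)
        cfg = EMConfig()
        out = m_step({2: stats}, constant_model.log_rates, cfg,
                     constant_model, {2: disc})
        assert np.abs(out - constant_model.log_rates).max() < 0.05

    def test_simplex_rules(self):
        cfg = EMConfig()
        x3 = np.array([0.1, -0.2, 0.4])
        s3 = _initial_simplex(x3, cfg)
        assert s3.shape == (4, 3)
        deltas = s3[1:] - x3
        assert sorted(np.abs(deltas).max(axis=1)) == \
            pytest.approx([0.3, 0.3, 0.3])
        x6 = np.linspace(0.5, 3.0, 6)
        s6 = _initial_simplex(x6, cfg)
        deltas = (s6[1:] - x6)
        for i in range(6):
            assert deltas[i, i] == pytest.approx(0.05 * x6[i])

    def test_one_parameter_recovery(self, constant_model):
        # stats computed from data sampled at lambda = 1 pull the rate back
        disc = tmrca_discretization(10, 2, constant_model)
        A, B, Pi = build_matrices(constant_model, 2, disc)
        obs = sample_from_chmm(A, B, Pi, 300_000, seed=5)
        stats = forward_backward_skipping(obs, A, B, Pi)
        out = m_step({2: stats}, np.array([0.0]), EMConfig(),
                     constant_model, {2: disc})
        assert abs(out[0]) < 0.05


class TestPseudoHaploidEmission:
    def test_hypergeometric_cell_values(self):
        assert hypergeom.pmf(1, 4, 2, 2) == pytest.approx(2 / 3)
        assert hypergeom.pmf(0, 4, 2, 2) == pytest.approx(1 / 6)

    def test_downsampling_rows(self, constant_model):
        disc = tmrca_discretization(8, 4, constant_model)
        es4 = build_emission_tmrca(constant_model, 4, disc)
        es2 = pseudo_haploid_emission(es4, 2)
        assert es2.B.shape == (8, 2)
        assert es2.B.sum(axis=1) == pytest.approx(np.ones(8), abs=1e-10)

    def test_no_derived_stays_no_derived(self, constant_model):
        disc = tmrca_discretization(6, 4, constant_model)
        es4 = build_emission_tmrca(constant_model, 4, disc, theta=0.0)
        es2 = pseudo_haploid_emission(es4, 2)
        assert np.all(es2.B[:, 0] > 1 - 1e-9)

    def test_wrong_size_rejected(self, constant_model):
        disc = tmrca_discretization(6, 3, constant_model)
        es3 = build_emission_tmrca(constant_model, 3, disc)
        with pytest.raises(ValueError):
            pseudo_haploid_emission(es3, 2)


class _Wrap:
    def __init__(self, obs):
        self.obs = obs

    def observations(self, subset):
        return self.obs


class TestRunEm:
    def test_loglik_nondecreasing_and_recovery(self, rng):
        model = DemographicModel.constant(1e5)  # theta = rho = 5e-3
        disc = tmrca_discretization(12, 2, model)
        ts = build_transition_tmrca(model, 2, disc)
        es = build_emission_tmrca(model, 2, disc)
        obs = sample_from_chmm(ts.A, es.B, ts.Pi, 200_000, seed=2)
        m0 = model.with_log_rates([np.log(0.6)])
        cfg = EMConfig(discretization_size=12, max_iters=10)
        fit, history = run_em([_Wrap(obs)], build_subsets(2, sizes=[2]),
                              m0, config=cfg)
        lls = [h["composite_log_likelihood"] for h in history]
        assert np.all(np.diff(lls) >= -1e-4)
        assert abs(np.exp(fit.log_rates[0]) - 1.0) < 0.1

    def test_model_selection_sanity(self, rng):
        # likelihood at the generating size beats a 2x misspecification
        model = DemographicModel.constant(1e5)
        disc = tmrca_discretization(10, 2, model)
        ts = build_transition_tmrca(model, 2, disc)
        es = build_emission_tmrca(model, 2, disc)
        obs = sample_from_chmm(ts.A, es.B, ts.Pi, 100_000, seed=3)
        ll_true = forward_backward_skipping(obs, ts.A, es.B,
                                            ts.Pi).log_likelihood
        wrong = model.with_log_rates([np.log(0.5)])
        ts2 = build_transition_tmrca(wrong, 2, disc)
        es2 = build_emission_tmrca(wrong, 2, disc)
        ll_wrong = forward_backward_skipping(obs, ts2.A, es2.B,
                                             ts2.Pi).log_likelihood
        assert ll_true > ll_wrong
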