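"""Likelihoods and integrated likelihoods: exactness, quadrature, sampling."""

import itertools

import numpy as np
import pytest
from scipy.special import betaln

from markorder.evidence import (
    EvidenceResult,
    IntegrationSettings,
    NodeBudgetError,
    analytic_log_evidence_uniform_init,
    integrated_log_evidence,
    log_likelihood,
)
from markorder.models import MarkovModel
from markorder.simulate import simulate_sequence
from markorder.stats import SufficientStats, SymbolSequence, count_transitions


def all_sequences(length):
    for bits in itertools.product("LR", repeat=length):
        yield "".join(bits)


def swap_lr(text):
    return text.translate(str.maketrans("LR", "RL"))


class TestLogLikelihood:
    def test_order0_half(self):
        model = MarkovModel(0, [0.5])
        stats = count_transitions("LRRL", 0)
        assert log_likelihood(stats, model) == pytest.approx(np.log(0.0625))

    def test_order1_symmetric_chain(self):
        model = MarkovModel(1, np.array([0.5, 0.5]))
        stats = count_transitions("LRRL", 1)
        lp = log_likelihood(stats, model, "stationary")
        assert lp == pytest.approx(np.log(0.5 * 0.5**3))

    @pytest.mark.parametrize("order", [0, 1, 2])
    def test_normalization_over_all_length8_sequences(self, order, rng):
        """Probabilities of all 2^8 sequences sum to 1 for fixed params."""
        model = MarkovModel(order, rng.uniform(0.1, 0.9, 1 << order))
        total = sum(
            np.exp(log_likelihood(count_transitions(s, order), model))
            for s in all_sequences(8)
        )
        assert abs(total - 1.0) < 1e-10

    def test_boundary_params_return_neg_inf(self):
        stats = count_transitions("LRRL", 1)  # one switch from L observed
        model = MarkovModel(1, np.array([0.0, 0.5]))
        assert log_likelihood(stats, model, "uniform") == -np.inf

    def test_order_mismatch(self):
        with pytest.raises(ValueError):
            log_likelihood(count_transitions("LRRL", 1), MarkovModel(0, [0.5]))


class TestAnalyticEvidence:
    def test_order0_all_l(self):
        res = analytic_log_evidence_uniform_init(count_transitions("LLLL", 0))
        assert res.log_evidence == pytest.approx(np.log(1 / 5))

    def test_order0_balanced(self):
        stats = SufficientStats(0, [1], [1], ((),))
        res = analytic_log_evidence_uniform_init(stats)
        assert res.log_evidence == pytest.approx(np.log(1 / 6))

    def test_order1_beta_product(self):
        stats = count_transitions("LRRL", 1)
        res = analytic_log_evidence_uniform_init(stats)
        expected = -np.log(2) + betaln(2, 1) + betaln(2, 2)
        assert res.log_evidence == pytest.approx(expected, abs=1e-12)


class TestGridEvidence:
    def test_matches_analytic_in_uniform_mode(self):
        stats = count_transitions("LRRL", 1)
        grid = integrated_log_evidence(
            stats, 1, IntegrationSettings(method="grid", prefactor_mode="uniform")
        )
        exact = analytic_log_evidence_uniform_init(stats)
        rel = abs(np.expm1(grid.log_evidence - exact.log_evidence))
        assert rel < 1e-3

    def test_order0_dispatches_to_analytic(self):
        stats = count_transitions("LRRLLRL", 0)
        grid = integrated_log_evidence(stats, 0, IntegrationSettings(method="grid"))
        exact = analytic_log_evidence_uniform_init(stats)
        assert grid.log_evidence == exact.log_evidence

    def test_convergence_in_grid_resolution(self, pooled_order1_fixture):
        trials, stats1 = pooled_order1_fixture
        e100 = integrated_log_evidence(
            stats1, 1, IntegrationSettings(method="grid", grid_points_per_dim=100)
        )
        e200 = integrated_log_evidence(
            stats1, 1, IntegrationSettings(method="grid", grid_points_per_dim=200)
        )
        assert abs(e100.log_evidence - e200.log_evidence) < 1e-3
        from markorder.stats import pool_stats

        stats2 = pool_stats([count_transitions(s, 2) for s in trials])
        e20 = integrated_log_evidence(
            stats2, 2, IntegrationSettings(method="grid", grid_points_per_dim=20)
        )
        e40 = integrated_log_evidence(
            stats2, 2, IntegrationSettings(method="grid", grid_points_per_dim=40)
        )
        assert abs(e20.log_evidence - e40.log_evidence) < 1e-3

    def test_node_budget_refused_for_order3(self):
        stats = SufficientStats(3, np.zeros(8, int), np.zeros(8, int), ())
        with pytest.raises(NodeBudgetError, match="Monte Carlo"):
            integrated_log_evidence(stats, 3, IntegrationSettings(method="grid"))


class TestMonteCarloEvidence:
    def test_within_three_standard_errors_of_grid(self, pooled_order1_fixture):
        _, stats = pooled_order1_fixture
        grid = integrated_log_evidence(stats, 1, IntegrationSettings(method="grid"))
        mc = integrated_log_evidence(
            stats, 1, IntegrationSettings(method="monte_carlo", seed=1)
        )
        assert mc.mc_standard_error is not None
        assert abs(mc.log_evidence - grid.log_evidence) < 3 * mc.mc_standard_error

    def test_seed_reproducibility(self, pooled_order1_fixture):
        _, stats = pooled_order1_fixture
        settings = IntegrationSettings(method="monte_carlo", seed=11)
        a = integrated_log_evidence(stats, 1, settings)
        b = integrated_log_evidence(stats, 1, settings)
        assert a.log_evidence == b.log_evidence


class TestEvidenceProperties:
    @pytest.mark.parametrize(
        "settings",
        [
            IntegrationSettings(method="grid", grid_points_per_dim=25),
            IntegrationSettings(method="monte_carlo", mc_samples=2000, seed=0),
            IntegrationSettings(method="uniform_init_analytic"),
        ],
        ids=["grid", "monte_carlo", "analytic"],
    )
    @pytest.mark.parametrize("order", [0, 1, 2])
    def test_prior_mass_is_one_with_no_data(self, order, settings):
        """With empty counts the evidence is the prior's total mass, 1."""
        d = 1 << order
        stats = SufficientStats(order, np.zeros(d, int), np.zeros(d, int), ())
        res = integrated_log_evidence(stats, order, settings)
        assert res.log_evidence == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("order", [0, 1, 2])
    def test_log_evidence_is_nonpositive(self, order, pooled_order1_fixture):
        trials, _ = pooled_order1_fixture
        from markorder.stats import pool_stats

        stats = pool_stats([count_transitions(s, order) for s in trials])
        grid_pts = {0: 100, 1: 100, 2: 25}[order]
        res = integrated_log_evidence(
            stats, order, IntegrationSettings(method="grid", grid_points_per_dim=grid_pts)
        )
        assert res.log_evidence <= 0.0

    @pytest.mark.parametrize("order", [1, 2])
    @pytest.mark.parametrize("mode", ["stationary", "uniform"])
    def test_relabeling_invariance(self, order, mode, pooled_order1_fixture):
        """Swapping L and R in the data leaves every evidence unchanged."""
        trials, _ = pooled_order1_fixture
        from markorder.stats import pool_stats

        def evidence(seqs):
            stats = pool_stats([count_transitions(s, order) for s in seqs])
            settings = IntegrationSettings(
                method="grid",
                grid_points_per_dim=100 if order == 1 else 20,
                prefactor_mode=mode,
            )
            return integrated_log_evidence(stats, order, settings).log_evidence

        swapped = [
            SymbolSequence(s.subject_id, s.trial_id, swap_lr(s.symbols))
            for s in trials
        ]
        assert evidence(trials) == pytest.approx(evidence(swapped), abs=1e-10)

    def test_prefactor_gap_shrinks_relative_to_evidence(self):
        """The initial-word prefactor contributes O(1) to an O(N) log
        evidence: absolute gap between stationary and uniform treatment
        stays bounded, relative gap vanishes for long sequences."""
        model = MarkovModel(1, np.array([0.7, 0.4]))

        def gap_and_size(length):
            seq = simulate_sequence(model, length, burn_in=2000, seed=7)
            stats = count_transitions(seq, 1)
            g = {
                mode: integrated_log_evidence(
                    stats,
                    1,
                    IntegrationSettings(method="grid", prefactor_mode=mode),
                ).log_evidence
                for mode in ("stationary", "uniform")
            }
            return abs(g["stationary"] - g["uniform"]), abs(g["uniform"])

        short_gap, short_size = gap_and_size(20)
        long_gap, long_size = gap_and_size(10_000)
        assert short_gap > 0.01  # noticeable on a 20-symbol trial
        assert long_gap < 1.0  # bounded by log(2 pi_max / pi_min)-ish
        assert long_gap / long_size < 0.1 * short_gap / short_size

    def test_result_metadata(self, pooled_order1_fixture):
        _, stats = pooled_order1_fixture
        res = integrated_log_evidence(stats, 1, IntegrationSettings(method="grid"))
        assert isinstance(res, EvidenceResult)
        assert res.method == "grid" and res.n_points == 100**2
        assert res.mc_standard_error is None


class TestSettingsValidation:
    def test_bad_method(self):
        with pytest.raises(ValueError):
            IntegrationSettings(method="simpson")

    def test_small_grid_rejected(self):
        with pytest.raises(ValueError):
            IntegrationSettings(grid_points_per_dim=1)

    def test_small_mc_rejected(self):
        with pytest.raises(ValueError):
            IntegrationSettings(mc_samples=10)
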