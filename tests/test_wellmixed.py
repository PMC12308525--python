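"""Fixation probabilities, small-mutation Markov chain, risk dominance."""

import numpy as np
import pytest

from guilt_egt import (
    C,
    D,
    DGCN,
    DGCS,
    DGDN,
    DGDS,
    STRATEGIES,
    GameParams,
    StrategyMatrix,
    analytic_thresholds,
    closed_form_payoffs,
    fermi_probability,
    fixation_probability,
    markov_chain,
    monte_carlo_fixation,
    replicator_trajectory,
    risk_dominant,
)
from guilt_egt.wellmixed import (
    PopulationSpec,
    average_payoffs,
    risk_dominance_margin,
    step_probabilities,
    transition_directions,
)


class TestFermi:
    def test_symmetry_and_neutral_limit(self):
        assert fermi_probability(3.0, 3.0, 2.0) == pytest.approx(0.5)
        assert fermi_probability(-1.0, 7.0, 0.0) == pytest.approx(0.5)

    def test_closed_form_value(self):
        assert fermi_probability(0.0, 1.0, 1.0) == pytest.approx(1 / (1 + np.exp(-1)))

    def test_negative_beta_rejected(self):
        with pytest.raises(ValueError):
            fermi_probability(0.0, 1.0, -0.5)

    def test_numerically_stable_for_extreme_differences(self):
        assert fermi_probability(0.0, 1e4, 1.0) == pytest.approx(1.0)
        assert fermi_probability(1e4, 0.0, 1.0) == pytest.approx(0.0)


class TestAveragePayoffs:
    def test_monomorphic_limits(self):
        pa, _ = average_payoffs(100, 100, 1.5, -1.0, 0.0, 0.5)
        assert pa == pytest.approx(1.5)
        pa, _ = average_payoffs(1, 100, 1.5, -1.0, 0.0, 0.5)
        assert pa == pytest.approx(-1.0)

    def test_mixed_population_value(self):
        pa, _ = average_payoffs(50, 100, 1.0, -1.0, 0.0, 0.0)
        assert pa == pytest.approx(-1 / 99)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            average_payoffs(101, 100, 1, 1, 1, 1)


class TestStepProbabilities:
    SPEC = PopulationSpec(20, 0.7)

    def test_absorbing_states(self):
        assert step_probabilities(0, self.SPEC, 1, 2, 3, 4) == (0.0, 0.0)
        assert step_probabilities(20, self.SPEC, 1, 2, 3, 4) == (0.0, 0.0)

    def test_neutral_drift_rates(self):
        spec = PopulationSpec(20, 0.0)
        for k in (1, 7, 19):
            tp, tm = step_probabilities(k, spec, 1, -1, 2, 0)
            expected = (20 - k) * k / (2 * 20**2)
            assert tp == pytest.approx(expected) and tm == pytest.approx(expected)

    def test_ratio_identity(self):
        # T-/T+ = exp(-beta (Pi_A - Pi_B)) underlies the fixation closed form
        for k in range(1, 20):
            tp, tm = step_probabilities(k, self.SPEC, 1.3, -0.2, 0.4, 0.9)
            pa, pb = average_payoffs(k, 20, 1.3, -0.2, 0.4, 0.9)
            assert tm / tp == pytest.approx(np.exp(-self.SPEC.beta * (pa - pb)))


class TestFixation:
    def test_neutral_drift_is_one_over_n(self, canonical_matrix):
        spec = PopulationSpec(100, 0.0)
        for a in STRATEGIES:
            for b in STRATEGIES:
                if a != b:
                    rho = fixation_probability(a, b, spec, canonical_matrix)
                    assert rho == pytest.approx(1 / 100, abs=1e-14)

    def test_payoff_identical_strategies_are_neutral(self):
        # with zero social cost DGCS and DGCN earn identical payoffs off-D
        p = GameParams(T=2, R=1, P=0, S=-1, omega=10, gamma=1.0, gamma_s=0.0)
        m = closed_form_payoffs(p)
        spec = PopulationSpec(100, 1.0)
        rho = fixation_probability(DGCS, DGCN, spec, m)
        assert rho == pytest.approx(1 / 100, abs=1e-12)

    def test_same_strategy_rejected(self, canonical_matrix):
        with pytest.raises(ValueError):
            fixation_probability(C, C, PopulationSpec(10, 1.0), canonical_matrix)

    def test_monte_carlo_agrees_with_formula(self, canonical_matrix):
        spec = PopulationSpec(10, 1.0)
        rho = fixation_probability(D, C, spec, canonical_matrix)
        est, se = monte_carlo_fixation(D, C, spec, canonical_matrix, trials=40_000, seed=3)
        assert abs(est - rho) < 3 * max(se, np.sqrt(rho * (1 - rho) / 40_000))

    def test_monte_carlo_neutral_expectation(self, canonical_matrix):
        spec = PopulationSpec(10, 0.0)
        est, se = monte_carlo_fixation(C, D, spec, canonical_matrix, trials=40_000, seed=9)
        assert abs(est - 0.1) < 3 * np.sqrt(0.1 * 0.9 / 40_000)


class TestMarkovChain:
    def test_rows_and_stationary_normalized(self, canonical_matrix):
        mc = markov_chain(PopulationSpec(50, 1.0), canonical_matrix)
        assert np.allclose(mc.M.sum(axis=1), 1.0, atol=1e-10)
        assert mc.stationary.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(mc.stationary >= 0)
        assert np.allclose(mc.stationary @ mc.M, mc.stationary, atol=1e-10)

    def test_two_identical_strategies_split_evenly(self):
        vals = np.full((6, 6), 1.0)
        matrix = StrategyMatrix(vals)
        mc = markov_chain(PopulationSpec(30, 1.0), matrix, strategies=(C, D))
        assert np.allclose(mc.stationary, [0.5, 0.5], atol=1e-10)

    def test_off_diagonal_transitions_are_scaled_fixations(self, canonical_matrix):
        spec = PopulationSpec(40, 1.0)
        mc = markov_chain(spec, canonical_matrix)
        i, j = 1, 5  # D resident, DGCS mutant
        rho = fixation_probability(STRATEGIES[j], STRATEGIES[i], spec, canonical_matrix)
        assert mc.M[i, j] == pytest.approx(rho / 5)

    def test_stationary_permutation_equivariance(self, canonical_matrix):
        spec = PopulationSpec(40, 1.0)
        base = markov_chain(spec, canonical_matrix)
        perm = (DGCS, C, DGDS, D, DGCN, DGDN)
        permuted = markov_chain(spec, canonical_matrix, strategies=perm)
        for s, p in zip(perm, permuted.stationary):
            assert p == pytest.approx(base.stationary_by_label()[s.label], abs=1e-10)

    def test_transition_directions_match_risk_dominance(self, canonical_matrix):
        # risk dominance is the large-N criterion; at N=100 it predicts the
        # stronger arrow for every non-neutral pair (zero-margin pairs can
        # still show a finite-size bias, e.g. DGDN vs C at gamma exactly c)
        mc = markov_chain(PopulationSpec(100, 1.0), canonical_matrix)
        for (la, lb), winner in transition_directions(mc).items():
            a = next(s for s in STRATEGIES if s.label == la)
            b = next(s for s in STRATEGIES if s.label == lb)
            rd = risk_dominant(a, b, canonical_matrix)
            if rd is not None:
                assert winner == rd.label


class TestRiskDominance:
    def test_dgcs_beats_dgds_when_costs_exceed_c(self):
        p = GameParams.donation(2, 1, omega=10, gamma=1.0, gamma_s=0.1)
        m = closed_form_payoffs(p)
        assert risk_dominant(DGCS, DGDS, m) == DGCS  # gamma + gamma_s = 1.1 > c

    def test_d_always_dominates_dgcn(self):
        rng = np.random.default_rng(13)
        from .conftest import random_valid_params

        for _ in range(25):
            p = random_valid_params(rng)
            assert risk_dominant(D, DGCN, closed_form_payoffs(p)) == D

    def test_dgcs_dgcn_neutral_without_social_cost(self):
        p = GameParams.donation(2, 1, omega=10, gamma=2.0, gamma_s=0.0)
        assert risk_dominant(DGCS, DGCN, closed_form_payoffs(p)) is None


class TestAnalyticThresholds:
    def test_reference_point(self):
        p = GameParams.donation(2, 1, omega=10, gamma=1.5, gamma_s=0.1)
        rep = analytic_thresholds(p)
        assert rep.dgcs_beats_dgds  # 1.6 > 1
        assert rep.dgcs_beats_dgdn  # 13.5 - 0.1 > 9
        assert rep.dgcs_beats_d  # 1.5 + 1.1 < 9
        assert not rep.dgcs_beats_c
        assert rep.cycle_present

    def test_gamma_below_c_blocks_dgdn_condition(self):
        p = GameParams.donation(2, 1, omega=10, gamma=0.5, gamma_s=0.0)
        assert not analytic_thresholds(p).dgcs_beats_dgdn

    def test_margins_match_matrix_risk_dominance(self):
        rng = np.random.default_rng(21)
        for _ in range(40):
            b = rng.uniform(1.5, 5)
            p = GameParams.donation(
                b, 1.0, omega=int(rng.integers(2, 15)),
                gamma=rng.uniform(0, 8), gamma_s=rng.uniform(0, 2),
            )
            m = closed_form_payoffs(p)
            rep = analytic_thresholds(p)
            pairs = [
                (rep.margin_dgds, risk_dominance_margin(DGCS, DGDS, m)),
                (rep.margin_dgdn, risk_dominance_margin(DGCS, DGDN, m)),
                (rep.margin_d, risk_dominance_margin(DGCS, D, m)),
                (rep.margin_c, risk_dominance_margin(DGCS, C, m)),
            ]
            for closed, numeric in pairs:
                assert np.sign(closed) == np.sign(numeric) or (
                    abs(closed) < 1e-9 and abs(numeric) < 1e-9
                )


class TestReplicator:
    def test_monomorphic_corner_is_fixed_point(self, canonical_matrix):
        x0 = np.zeros(6)
        x0[1] = 1.0
        traj = replicator_trajectory(x0, canonical_matrix, np.linspace(0, 50, 20))
        assert np.allclose(traj, x0, atol=1e-8)

    def test_simplex_conservation(self, canonical_matrix):
        x0 = np.full(6, 1 / 6)
        traj = replicator_trajectory(x0, canonical_matrix, np.linspace(0, 100, 50))
        assert np.allclose(traj.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(traj >= 0)

    def test_off_simplex_start_rejected(self, canonical_matrix):
        with pytest.raises(ValueError):
            replicator_trajectory(np.full(6, 0.2), canonical_matrix, np.linspace(0, 1, 5))
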