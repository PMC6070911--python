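"""Strain-design operators: mutation codes, bound transforms, the coupling
objective, and the simulated annealer."""

import math

import numpy as np
import pytest

from ansaflux.optram import (
    FOLD_CHANGE,
    ModificationError,
    MutationCode,
    OptRAMConfig,
    apply_modification,
    design_objective,
    exhaustive_single_modifications,
    metropolis_accept,
    objective_score,
    optimize,
    reference_fluxes,
)


class TestMutationCodes:
    def test_table_of_fold_changes(self):
        assert [FOLD_CHANGE[c] for c in range(1, 6)] == [2, 4, 8, 16, 32]
        assert [FOLD_CHANGE[-c] for c in range(1, 6)] == [
            1 / 2, 1 / 4, 1 / 8, 1 / 16, 1 / 32,
        ]
        assert FOLD_CHANGE[0] == 0.001
        assert MutationCode(3).fold_change == 8
        assert MutationCode(0).is_knockout

    def test_unknown_code_rejected(self):
        with pytest.raises(ModificationError):
            MutationCode(6)


class TestApplyModification:
    def test_reference_fluxes_are_steady_state_and_deterministic(self, toy_model):
        ref = reference_fluxes(toy_model)
        again = reference_fluxes(toy_model)
        assert (ref - again).abs().max() == 0.0
        S, _, rxn_ids = toy_model.stoichiometric_matrix()
        assert np.abs(S @ ref[rxn_ids].to_numpy()).max() < 1e-6

    def test_downcode_caps_at_half_reference(self, toy_model):
        ref = reference_fluxes(toy_model)
        gene = sorted(toy_model.reaction("CS").genes)[0]
        v_ref = ref["CS"]
        assert v_ref > 0
        modified = apply_modification(toy_model, gene, -1, ref)
        assert modified.reaction("CS").upper_bound == pytest.approx(0.5 * v_ref)
        # the original model is untouched
        assert toy_model.reaction("CS").upper_bound == 1000.0

    def test_knockout_zeroes_required_reactions(self, toy_model):
        ref = reference_fluxes(toy_model)
        modified = apply_modification(toy_model, "asm10", 0, ref)
        r = modified.reaction("MT3")
        assert (r.lower_bound, r.upper_bound) == (0.0, 0.0)
        sol = design_objective(modified)
        assert sol.product_target == pytest.approx(0.0, abs=1e-7)
        assert sol.objective_score == 0.0

    def test_isozyme_downcode_is_rescued(self, toy_model):
        ref = reference_fluxes(toy_model)
        gene = sorted(toy_model.reaction("GLCt").genes)[0]
        modified = apply_modification(toy_model, gene, -5, ref)
        r = modified.reaction("GLCt")
        assert r.upper_bound == 1000.0  # the other isozyme keeps it open

    def test_upcode_on_zero_reference_is_noop(self, toy_model):
        ref = reference_fluxes(toy_model)
        assert abs(ref["MT3"]) < 1e-9  # product path idle in the WT reference
        modified = apply_modification(toy_model, "asm10", 3, ref)
        r = modified.reaction("MT3")
        assert (r.lower_bound, r.upper_bound) == (0.0, 1000.0)


class TestObjectiveScore:
    def test_range_equal_target_gives_unit_factor(self):
        # Vmin=0: Range == Target, log term vanishes
        score = objective_score(growth=0.5, v_min=0.0, v_max=2.0, substrate=4.0)
        assert score == pytest.approx(1.0 * 0.5 / 4.0)

    def test_worked_arithmetic_case(self):
        score = objective_score(growth=0.1, v_min=0.2, v_max=0.4, substrate=1.0)
        assert score == pytest.approx(0.04431, abs=1e-5)

    def test_fully_coupled_engages_epsilon_floor(self):
        # Vmax == Vmin: Range floored at eps*Target, factor = 1 - log10(1e-6) = 7
        score = objective_score(growth=1.0, v_min=2.0, v_max=2.0, substrate=2.0)
        assert score == pytest.approx(2.0 * 1.0 / 2.0 * 7.0)

    def test_dead_designs_score_zero(self):
        assert objective_score(0.0, 0.0, 1.0, 1.0) == 0.0
        assert objective_score(1.0, 0.0, 0.0, 1.0) == 0.0


class TestMetropolis:
    def test_improvements_always_accepted(self):
        rng = np.random.default_rng(0)
        assert all(metropolis_accept(1e-12, 1e-6, rng) for _ in range(100))

    def test_zero_delta_accepted(self):
        rng = np.random.default_rng(0)
        assert all(metropolis_accept(0.0, 1.0, rng) for _ in range(100))

    def test_non_positive_temperature_rejected(self):
        with pytest.raises(ValueError):
            metropolis_accept(-1.0, 0.0, np.random.default_rng(0))

    def test_acceptance_rate_at_minus_T(self):
        rng = np.random.default_rng(123)
        trials = 10_000
        accepted = sum(metropolis_accept(-2.0, 2.0, rng) for _ in range(trials))
        assert accepted / trials == pytest.approx(math.exp(-1), abs=0.015)


class TestOptimize:
    def test_seeded_runs_are_identical(self, toy_model):
        cfg = OptRAMConfig(iterations=60, restarts=2, seed=5)
        a = optimize(toy_model, cfg)
        b = optimize(toy_model, cfg)
        assert [(s.modifications, s.objective_score) for s in a] == [
            (s.modifications, s.objective_score) for s in b
        ]

    def test_temperature_schedule_is_geometric(self):
        cfg = OptRAMConfig(T0=2.0, alpha=0.9)
        temps = [cfg.T0 * cfg.alpha**k for k in range(5)]
        for a, b in zip(temps, temps[1:]):
            assert b == pytest.approx(a * cfg.alpha)

    def test_near_zero_temperature_reduces_to_hill_climbing(self, toy_model):
        # with T0 ~ 0 only improvements are ever accepted, so every solution
        # the walk settles on scores at least the wild type
        cfg = OptRAMConfig(T0=1e-12, iterations=80, restarts=2, seed=3)
        sols = optimize(toy_model, cfg)
        wt = design_objective(toy_model)
        assert all(s.objective_score >= wt.objective_score for s in sols)

    def test_finds_an_improving_design(self, toy_model):
        cfg = OptRAMConfig(iterations=300, restarts=2, seed=0)
        best = optimize(toy_model, cfg)[0]
        wt = design_objective(toy_model)
        assert best.objective_score > wt.objective_score
        assert best.n_modifications >= 1

    def test_ranking_is_lexicographic(self, toy_model):
        sols = optimize(toy_model, OptRAMConfig(iterations=120, restarts=3, seed=9))
        keys = [(-s.objective_score, s.n_modifications, -s.growth) for s in sols]
        assert keys == sorted(keys)
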