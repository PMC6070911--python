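"""E-FLUX integration, condition-specific models, and shift reporting."""

import math

import numpy as np
import pandas as pd
import pytest

from ansaflux.expression import (
    ActiveReactionCall,
    ConditionSpec,
    ExpressionProfile,
    build_condition_model,
    call_active_reactions,
    eflux_bounds,
    flux_shift_report,
    glucose_uptake_rate,
    normalized_flux_table,
)
from ansaflux.fba import FluxSolution
from ansaflux.synthetic import KNOCKOUT_ALIASES


class TestUptakeRate:
    def test_worked_arithmetic(self):
        # 1.8 g / (1 gDW * 180.16 g/mol * 24 h) * 1000 = 0.4163 mmol/gDW/h
        rate = glucose_uptake_rate(1.8, 1.0, 24.0)
        assert rate == pytest.approx(0.4163, abs=5e-5)

    def test_zero_consumption_gives_zero(self):
        assert glucose_uptake_rate(0.0, 1.0, 24.0) == 0.0

    def test_halving_dcw_doubles_rate(self):
        assert glucose_uptake_rate(2.0, 0.5, 24.0) == pytest.approx(
            2 * glucose_uptake_rate(2.0, 1.0, 24.0)
        )

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(ValueError):
            glucose_uptake_rate(1.0, 0.0, 24.0)
        with pytest.raises(ValueError):
            glucose_uptake_rate(-1.0, 1.0, 24.0)


def profile_from(dict_of_rows, log_base=10.0):
    return ExpressionProfile(pd.DataFrame(dict_of_rows).T, log_base=log_base)


class TestEfluxBounds:
    def test_silent_genes_block_their_reaction(self, toy_model):
        fpkm = {g: {"d": 0.0} for g in toy_model.genes}
        bounds = eflux_bounds(toy_model, profile_from(fpkm), "d")
        assert bounds["MT3"] == 0.0  # log(0 + 1) = 0

    def test_sum_over_reaction_genes(self, toy_model):
        # expression levels 1.0 and 2.0 -> bound 3.0 on a two-gene reaction
        glct_genes = sorted(toy_model.reaction("GLCt").genes)
        fpkm = {g: {"d": 0.0} for g in toy_model.genes}
        fpkm[glct_genes[0]] = {"d": 9.0}  # log10(10) = 1
        fpkm[glct_genes[1]] = {"d": 99.0}  # log10(100) = 2
        bounds = eflux_bounds(toy_model, profile_from(fpkm), "d")
        assert bounds["GLCt"] == pytest.approx(3.0)

    def test_single_gene_base10(self, toy_model):
        fpkm = {g: {"d": 9.0} for g in toy_model.genes}
        bounds = eflux_bounds(toy_model, profile_from(fpkm), "d")
        assert bounds["MT3"] == pytest.approx(1.0)  # log10(9 + 1)

    def test_exchanges_keep_default_bounds(self, toy_model):
        fpkm = {g: {"d": 5.0} for g in toy_model.genes}
        bounds = eflux_bounds(toy_model, profile_from(fpkm), "d")
        assert "EX_glc" not in bounds and "BIOMASS" not in bounds

    def test_raising_fpkm_never_lowers_bounds(self, toy_model, toy_profile):
        base = eflux_bounds(toy_model, toy_profile, "day1")
        boosted_values = toy_profile.values.copy()
        gene = sorted(toy_model.reaction("SAMS").genes)[0]
        boosted_values.loc[gene, "day1"] *= 7.0
        boosted = eflux_bounds(
            toy_model, ExpressionProfile(boosted_values), "day1"
        )
        for rid in base:
            assert boosted[rid] >= base[rid] - 1e-12

    def test_negative_fpkm_rejected(self):
        with pytest.raises(ValueError, match="negative FPKM"):
            profile_from({"g": {"d": -1.0}})


class TestConditionModels:
    def test_day1_objective_is_pure_biomass(self, toy_model, toy_profile, condition_specs):
        cm = build_condition_model(
            toy_model, toy_profile, condition_specs[0], aliases=KNOCKOUT_ALIASES
        )
        assert cm.spec.c_product == 0.0
        # with no product reward, parsimonious FBA leaves the pathway idle
        assert cm.solution.flux("EX_ap3") == pytest.approx(0.0, abs=1e-7)
        assert cm.solution.flux("BIOMASS") > 0.1

    def test_glucose_exchange_is_fixed_to_measured_uptake(
        self, toy_model, toy_profile, condition_specs
    ):
        spec = condition_specs[1]
        cm = build_condition_model(toy_model, toy_profile, spec, aliases=KNOCKOUT_ALIASES)
        ex = cm.model.reaction("EX_glc")
        assert ex.lower_bound == ex.upper_bound == pytest.approx(-spec.uptake())
        assert cm.solution.flux("EX_glc") == pytest.approx(-spec.uptake(), rel=1e-6)

    def test_knockout_alias_zeroes_the_shunt(self, toy_model, toy_profile, condition_specs):
        cm = build_condition_model(
            toy_model, toy_profile, condition_specs[3], aliases=KNOCKOUT_ALIASES
        )
        shunt = cm.model.reaction("ASM30")  # spec says ansa30; model gene is asm30
        assert shunt.lower_bound == shunt.upper_bound == 0.0

    def test_silent_product_path_blocks_product_despite_reward(
        self, toy_model, toy_profile, condition_specs
    ):
        values = toy_profile.values.copy()
        product_genes = {
            g
            for r in toy_model.reactions
            if r.subsystem == "Product biosynthesis"
            for g in r.genes
        }
        values.loc[sorted(product_genes)] = 0.0
        silenced = ExpressionProfile(values)
        cm = build_condition_model(
            toy_model, silenced, condition_specs[3], aliases=KNOCKOUT_ALIASES
        )
        assert cm.solution.flux("EX_ap3") == pytest.approx(0.0, abs=1e-7)

    def test_product_rises_from_day1_to_day5(self, toy_model, toy_profile, condition_specs):
        day1 = build_condition_model(
            toy_model, toy_profile, condition_specs[0], aliases=KNOCKOUT_ALIASES
        )
        day5 = build_condition_model(
            toy_model, toy_profile, condition_specs[3], aliases=KNOCKOUT_ALIASES
        )
        assert day5.solution.flux("EX_ap3") > day1.solution.flux("EX_ap3")

    def test_fluxes_respect_eflux_bounds(self, toy_model, toy_profile, condition_specs):
        cm = build_condition_model(
            toy_model, toy_profile, condition_specs[2], aliases=KNOCKOUT_ALIASES
        )
        for rid, b in cm.bounds.items():
            assert abs(cm.solution.flux(rid)) <= b + 1e-6


def _fake_condition_models(flux_rows, labels=("day1", "day2", "day3", "day5")):
    """Minimal stand-ins exposing .label, .solution.fluxes and .model."""

    rxn_ids = [f"r{i}" for i in range(len(flux_rows))]

    class FakeModel:
        def has_reaction(self, rid):
            return rid in rxn_ids

    class FakeCM:
        def __init__(self, label, fluxes):
            self.label = label
            self.solution = FluxSolution(0.0, fluxes, "optimal")
            self.model = FakeModel()

    table = pd.DataFrame(flux_rows, index=rxn_ids, columns=labels)
    return [FakeCM(lab, table[lab]) for lab in labels]


class TestActiveReactions:
    def test_clear_single_day_peak(self):
        cms = _fake_condition_models([[10.0, 0.0, 0.0, 0.0]])
        calls = call_active_reactions(cms)
        assert len(calls) == 1
        assert calls[0].condition == "day1"
        assert calls[0].normalized_flux["day1"] == pytest.approx(1.0)

    def test_two_competing_days_is_not_specific(self):
        cms = _fake_condition_models([[10.0, 9.0, 0.0, 0.0]])
        assert call_active_reactions(cms) == []

    def test_exact_half_boundary_does_not_disqualify(self):
        # (0, 0, 4, 8) normalizes to (0, 0, 0.5, 1): specific to the last day
        cms = _fake_condition_models([[0.0, 0.0, 4.0, 8.0]])
        calls = call_active_reactions(cms)
        assert [c.condition for c in calls] == ["day5"]

    def test_sign_convention_invariance_and_zero_rows(self):
        cms = _fake_condition_models([[-8.0, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0]])
        norm = normalized_flux_table(cms)
        assert norm.iloc[1].abs().max() == 0.0
        calls = call_active_reactions(cms)
        assert [c.condition for c in calls] == ["day1"]


class TestFluxShift:
    def test_ratios_to_first_condition(self):
        cms = _fake_condition_models([[8.0, 4.0, 2.0, 2.0]])
        report = flux_shift_report(cms, ["r0"])
        row = report.loc["r0"]
        assert list(row[[f"ratio_{d}" for d in ("day1", "day2", "day3", "day5")]]) == [
            pytest.approx(1.0),
            pytest.approx(0.5),
            pytest.approx(0.25),
            pytest.approx(0.25),
        ]

    def test_zero_baseline_marked_as_new(self):
        cms = _fake_condition_models([[0.0, 0.0, 1.0, 3.0]])
        report = flux_shift_report(cms, ["r0"])
        assert math.isinf(report.loc["r0", "ratio_day5"])

    def test_sam_synthesis_rises_while_citrate_falls(
        self, toy_model, toy_profile, condition_specs
    ):
        cms = [
            build_condition_model(toy_model, toy_profile, s, aliases=KNOCKOUT_ALIASES)
            for s in condition_specs
        ]
        report = flux_shift_report(cms, ["CS", "SAMS"])
        assert report.loc["SAMS", "ratio_day5"] > 1.0
        assert report.loc["CS", "ratio_day5"] < 1.0
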