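"""LP core: FBA, pFBA, FVA, deletion and robustness scans."""

import numpy as np
import pytest

from ansaflux.fba import (
    FbaError,
    flux_variability,
    robustness_scan,
    single_gene_deletion_scan,
    solve_fba,
    solve_pfba,
)
from ansaflux.gpr import Gpr
from ansaflux.model import MetabolicModel, Metabolite, Reaction


def build(reactions, biomass="", product="", substrate=""):
    mets = sorted({m for r in reactions for m in r.stoichiometry})
    model = MetabolicModel(
        metabolites=[Metabolite(m) for m in mets],
        reactions=reactions,
        biomass_reaction_id=biomass,
        product_reaction_id=product,
        substrate_exchange_id=substrate,
    )
    model.validate()
    return model


def R(rid, stoich, lb=0.0, ub=1000.0, gpr=""):
    return Reaction(id=rid, stoichiometry=stoich, lower_bound=lb, upper_bound=ub, gpr=Gpr.parse(gpr))


@pytest.fixture()
def chain():
    """EX_glc(ub 10) -> A -> biomass: a single capacity-limited path."""
    return build(
        [
            R("EX_glc", {"glc": 1}, lb=0, ub=10),
            R("CONV", {"glc": -1, "A": 1}),
            R("BIO", {"A": -1}),
        ],
        biomass="BIO",
    )


def assert_steady_state(model, solution, tol=1e-9):
    S, _, rxn_ids = model.stoichiometric_matrix()
    v = solution.fluxes[rxn_ids].to_numpy()
    norm = max(1.0, float(np.abs(S).sum()))
    assert np.abs(S @ v).max() <= tol * norm
    for r in model.reactions:
        assert r.lower_bound - 1e-9 <= solution.flux(r.id) <= r.upper_bound + 1e-9


class TestSolveFba:
    def test_single_path_capacity_limited(self, chain):
        sol = solve_fba(chain)
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(10.0, abs=1e-9)
        assert_steady_state(chain, sol)

    def test_two_paths_picks_higher_yield(self):
        # P1 converts substrate to biomass 1:1, P2 only 2:1 (yield 0.5);
        # the optimum (hand enumeration of the two extreme solutions) is 10
        # with all flux on P1.
        model = build(
            [
                R("EX_s", {"s": 1}, ub=10),
                R("P1", {"s": -1, "x": 1}),
                R("P2", {"s": -2, "x": 1}),
                R("BIO", {"x": -1}),
            ],
            biomass="BIO",
        )
        sol = solve_fba(model)
        assert sol.objective_value == pytest.approx(10.0, abs=1e-9)
        assert sol.flux("P1") == pytest.approx(10.0, abs=1e-7)
        assert sol.flux("P2") == pytest.approx(0.0, abs=1e-7)

    def test_infeasible_and_unbounded_status(self):
        infeasible = build(
            [R("IN", {"x": 1}, lb=5, ub=10), R("OUT", {"x": -1}, lb=0, ub=1)]
        )
        assert solve_fba(infeasible, {"OUT": 1.0}).status == "infeasible"
        unbounded = build(
            [R("IN", {"x": 1}, lb=0, ub=np.inf), R("OUT", {"x": -1}, lb=0, ub=np.inf)]
        )
        assert solve_fba(unbounded, {"OUT": 1.0}).status == "unbounded"

    def test_relaxing_an_upper_bound_never_decreases_optimum(self, toy_model):
        rng = np.random.default_rng(7)
        base = solve_fba(toy_model).objective_value
        for _ in range(10):
            model = toy_model.copy()
            r = model.reactions[rng.integers(len(model.reactions))]
            r.upper_bound += float(rng.uniform(0, 50))
            relaxed = solve_fba(model).objective_value
            assert relaxed >= base - 1e-7

    def test_agrees_with_cobrapy_on_toy_model(self, toy_model):
        """Independent cross-check of the whole LP route against cobrapy."""
        cobra = pytest.importorskip("cobra")
        from ansaflux.io import to_cobra

        cm = to_cobra(toy_model)
        expected = cm.slim_optimize()
        ours = solve_fba(toy_model).objective_value
        assert ours == pytest.approx(expected, rel=1e-6)


class TestPfba:
    def test_futile_cycle_carries_no_flux(self):
        model = build(
            [
                R("EX_s", {"s": 1}, ub=10),
                R("STEP", {"s": -1, "x": 1}),
                R("CYC_F", {"x": -1, "y": 1}),
                R("CYC_B", {"y": -1, "x": 1}),
                R("BIO", {"x": -1}),
            ],
            biomass="BIO",
        )
        sol = solve_pfba(model)
        assert sol.objective_value == pytest.approx(10.0, rel=1e-6)
        assert sol.flux("CYC_F") == pytest.approx(0.0, abs=1e-7)
        assert sol.flux("CYC_B") == pytest.approx(0.0, abs=1e-7)

    def test_matches_fba_objective_and_smaller_total_flux(self, toy_model):
        fba_sol = solve_fba(toy_model)
        pfba_sol = solve_pfba(toy_model)
        assert pfba_sol.objective_value == pytest.approx(
            fba_sol.objective_value, rel=1e-6
        )
        assert pfba_sol.fluxes.abs().sum() <= fba_sol.fluxes.abs().sum() + 1e-6
        assert_steady_state(toy_model, pfba_sol, tol=1e-7)

    def test_prefers_shorter_of_two_equivalent_paths(self):
        # two unit-yield routes of length 2 and 3; total |v| comparison of the
        # two extreme solutions puts all flux on the short one
        model = build(
            [
                R("EX_s", {"s": 1}, ub=10),
                R("S1", {"s": -1, "a": 1}),
                R("S2", {"a": -1, "x": 1}),
                R("L1", {"s": -1, "b": 1}),
                R("L2", {"b": -1, "c": 1}),
                R("L3", {"c": -1, "x": 1}),
                R("BIO", {"x": -1}),
            ],
            biomass="BIO",
        )
        sol = solve_pfba(model)
        assert sol.flux("S1") == pytest.approx(10.0, rel=1e-6)
        assert sol.flux("L1") == pytest.approx(0.0, abs=1e-7)


class TestFva:
    def test_unique_optimal_path_has_zero_range(self, chain):
        fba_flux = solve_fba(chain).flux("CONV")
        v_min, v_max = flux_variability(chain, "CONV", fix_objective_at=1.0)
        # the objective is held within 1e-6 relative slack, so the range
        # collapses only to that resolution
        assert v_min == pytest.approx(fba_flux, rel=2e-6)
        assert v_max == pytest.approx(fba_flux, rel=2e-6)

    def test_interchangeable_parallel_paths_span_full_range(self):
        model = build(
            [
                R("EX_s", {"s": 1}, ub=10),
                R("P1", {"s": -1, "x": 1}),
                R("P2", {"s": -1, "x": 1}),
                R("BIO", {"x": -1}),
            ],
            biomass="BIO",
        )
        for rid in ("P1", "P2"):
            v_min, v_max = flux_variability(model, rid, fix_objective_at=1.0)
            assert v_min == pytest.approx(0.0, abs=1e-6)
            assert v_max == pytest.approx(10.0, abs=1e-6)

    def test_blocked_reaction_is_zero_at_fraction_zero(self):
        model = build(
            [
                R("EX_s", {"s": 1}, ub=10),
                R("BIO", {"s": -1}),
                R("ORPHAN", {"o1": -1, "o2": 1}),
            ],
            biomass="BIO",
        )
        assert flux_variability(model, "ORPHAN", fix_objective_at=0.0) == (
            pytest.approx(0.0, abs=1e-9),
            pytest.approx(0.0, abs=1e-9),
        )


class TestDeletionScan:
    def test_sole_methyltransferase_is_essential(self, toy_model_copy):
        records = {r.gene: r for r in single_gene_deletion_scan(toy_model_copy)}
        asm10 = records["asm10"]
        assert asm10.product_flux == pytest.approx(0.0, abs=1e-7)
        assert asm10.relative_decrease > 0.9
        assert asm10.essential and asm10.influential
        assert asm10.klass == "essential"

    def test_unused_parallel_path_gene_is_neutral(self, toy_model_copy):
        records = {r.gene: r for r in single_gene_deletion_scan(toy_model_copy)}
        # the shunt consuming the first product intermediate never carries
        # flux under the product objective, so its gene is neutral
        assert records["asm30"].klass == "neutral"
        assert abs(records["asm30"].relative_decrease) < 1e-6

    def test_isozyme_genes_are_neutral(self, toy_model_copy):
        glct = toy_model_copy.reaction("GLCt")
        records = {r.gene: r for r in single_gene_deletion_scan(toy_model_copy)}
        for gene in glct.genes:
            assert records[gene].klass == "neutral"

    def test_scan_restores_bounds_and_is_order_independent(self, toy_model):
        model = toy_model.copy()
        before = {r.id: (r.lower_bound, r.upper_bound) for r in model.reactions}
        first = single_gene_deletion_scan(model)
        after = {r.id: (r.lower_bound, r.upper_bound) for r in model.reactions}
        assert before == after
        second = single_gene_deletion_scan(model)
        assert [(r.gene, r.klass) for r in first] == [(r.gene, r.klass) for r in second]

    def test_error_when_wild_type_cannot_form_product(self):
        model = build(
            [R("EX_s", {"s": 1}, ub=10), R("SINK", {"s": -1}), R("DEAD", {"p": 1}, ub=0, gpr="g1")],
            product="DEAD",
        )
        with pytest.raises(FbaError, match="wild-type"):
            single_gene_deletion_scan(model)

    def test_agrees_with_cobrapy_single_gene_deletion(self, toy_model):
        """Independent oracle: cobrapy's deletion machinery on the same model."""
        cobra = pytest.importorskip("cobra")
        from cobra.flux_analysis import single_gene_deletion
        from ansaflux.io import to_cobra

        cm = to_cobra(toy_model)
        cm.objective = toy_model.product_reaction_id
        table = single_gene_deletion(cm, processes=1)
        theirs = {
            next(iter(ids)): (0.0 if g != g or abs(g) < 1e-9 else g)
            for ids, g in zip(table["ids"], table["growth"])
        }
        ours = {r.gene: r.product_flux for r in single_gene_deletion_scan(toy_model)}
        assert set(ours) == set(theirs)
        for gene in ours:
            assert ours[gene] == pytest.approx(theirs[gene], rel=1e-5, abs=1e-6)


class TestRobustness:
    def test_capping_the_product_sink_tracks_the_cap_then_plateaus(self, toy_model_copy):
        curve = robustness_scan(toy_model_copy, "EX_ap3", grid_points=6)
        capacity = solve_fba(toy_model_copy, "EX_ap3").objective_value
        for cap, prod in zip(curve.bound_grid, curve.product_optimum):
            assert prod == pytest.approx(min(cap, capacity), rel=1e-6, abs=1e-7)
        assert curve.positively_correlated

    def test_methyltransferase_capped_at_zero_kills_product(self, toy_model_copy):
        curve = robustness_scan(toy_model_copy, "MT3", grid_points=5)
        assert curve.product_optimum[0] == pytest.approx(0.0, abs=1e-7)
        assert curve.positively_correlated

    def test_unknown_reaction_id_raises(self, toy_model_copy):
        with pytest.raises(Exception, match="unknown reaction"):
            robustness_scan(toy_model_copy, "NOPE", grid_points=4)
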