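"""Linear-programming core: FBA, pFBA, FVA, deletion and robustness scans.

Flux balance analysis solves

    max  c . v
    s.t. S v = 0,  lb <= v <= ub

over the steady-state flux cone of a :class:`~ansaflux.model.MetabolicModel`.
Parsimonious FBA (pFBA) re-solves at the fixed optimum minimizing total
absolute flux ``sum |v_j|`` (reversible reactions split into two non-negative
half-reactions), which removes futile cycles and makes reported per-reaction
fluxes reproducible across solvers.  All LPs are solved with HiGHS through
:func:`scipy.optimize.linprog`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .model import MetabolicModel

__all__ = [
    "FluxSolution",
    "DeletionRecord",
    "RobustnessCurve",
    "FbaError",
    "solve_fba",
    "solve_pfba",
    "flux_variability",
    "single_gene_deletion_scan",
    "robustness_scan",
]

#: LP feasibility/optimality tolerance used for assertions and comparisons
LP_TOL = 1e-9
#: relative tolerance when fixing an objective at its optimum (pFBA / FVA)
REL_TOL = 1e-6


class FbaError(RuntimeError):
    pass


@dataclass
class FluxSolution:
    """Outcome of one LP solve.

    ``objective_value`` is in the unit of the objective reaction (1/h for
    biomass, mmol/gDW/h otherwise); ``fluxes`` maps reaction id to flux, and
    is ``None`` unless ``status == "optimal"``.
    """

    objective_value: float
    fluxes: Optional[pd.Series]
    status: str  # optimal | infeasible | unbounded

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def flux(self, rxn_id: str) -> float:
        if self.fluxes is None:
            raise FbaError(f"no flux vector available (status={self.status})")
        return float(self.fluxes[rxn_id])


_STATUS = {0: "optimal", 1: "iteration limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def _objective_vector(model: MetabolicModel, objective: Dict[str, float], rxn_ids: List[str]) -> np.ndarray:
    c = np.zeros(len(rxn_ids))
    pos = {r: i for i, r in enumerate(rxn_ids)}
    for rid, coef in objective.items():
        if rid not in pos:
            raise FbaError(f"objective reaction {rid!r} not in model")
        c[pos[rid]] = coef
    return c


def _default_objective(model: MetabolicModel, objective) -> Dict[str, float]:
    if objective is None:
        if not model.biomass_reaction_id:
            raise FbaError("model has no designated biomass reaction and no objective given")
        return {model.biomass_reaction_id: 1.0}
    if isinstance(objective, str):
        return {objective: 1.0}
    return dict(objective)


def solve_fba(
    model: MetabolicModel,
    objective: Optional[Dict[str, float] | str] = None,
    sense: str = "max",
) -> FluxSolution:
    """LP optimum of ``c . v`` subject to ``S v = 0`` and the flux bounds.

    ``objective`` defaults to the model's biomass reaction; it may be a
    reaction id or a ``{reaction-id: coefficient}`` map (e.g. the coupled
    biomass + c * product objective of the condition-specific models).
    """
    if sense not in ("max", "min"):
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
    obj = _default_objective(model, objective)
    S, _, rxn_ids = model.stoichiometric_matrix()
    c = _objective_vector(model, obj, rxn_ids)
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    sign = -1.0 if sense == "max" else 1.0
    res = linprog(sign * c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs")
    status = _STATUS.get(res.status, "numerical")
    if status != "optimal":
        return FluxSolution(objective_value=np.nan, fluxes=None, status=status)
    fluxes = pd.Series(res.x, index=rxn_ids)
    return FluxSolution(objective_value=float(c @ res.x), fluxes=fluxes, status="optimal")


def solve_pfba(
    model: MetabolicModel,
    objective: Optional[Dict[str, float] | str] = None,
) -> FluxSolution:
    """Parsimonious FBA: among flux vectors attaining the FBA optimum (within
    relative tolerance 1e-6) return one minimizing total absolute flux."""
    obj = _default_objective(model, objective)
    fba = solve_fba(model, obj)
    if not fba.optimal:
        return fba
    opt = fba.objective_value

    S, _, rxn_ids = model.stoichiometric_matrix()
    n = len(rxn_ids)
    c = _objective_vector(model, obj, rxn_ids)
    # split v = v_plus - v_minus with both halves non-negative
    A_eq = np.hstack([S, -S])
    bounds = []
    for r in model.reactions:
        bounds.append((max(r.lower_bound, 0.0), max(r.upper_bound, 0.0)))
    for r in model.reactions:
        bounds.append((max(-r.upper_bound, 0.0), max(-r.lower_bound, 0.0)))
    # hold the primary objective at its optimum:  c.v >= opt - tol
    tol = REL_TOL * max(1.0, abs(opt))
    A_ub = -np.concatenate([c, -c])[None, :]
    b_ub = np.array([-(opt - tol)])
    cost = np.ones(2 * n)
    res = linprog(
        cost,
        A_eq=A_eq,
        b_eq=np.zeros(S.shape[0]),
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=bounds,
        method="highs",
    )
    if res.status != 0:
        raise FbaError(f"pFBA LP failed with status {_STATUS.get(res.status)}")
    v = res.x[:n] - res.x[n:]
    fluxes = pd.Series(v, index=rxn_ids)
    return FluxSolution(objective_value=float(c @ v), fluxes=fluxes, status="optimal")


def flux_variability(
    model: MetabolicModel,
    reaction_id: str,
    fix_objective_at: float = 1.0,
    objective: Optional[Dict[str, float] | str] = None,
) -> Tuple[float, float]:
    """(v_min, v_max) of one reaction with the primary objective constrained
    to at least ``fix_objective_at`` times its optimum."""
    if not 0.0 <= fix_objective_at <= 1.0:
        raise ValueError("fix_objective_at must be in [0, 1]")
    model.reaction(reaction_id)  # raises for unknown ids
    obj = _default_objective(model, objective)
    fba = solve_fba(model, obj)
    if not fba.optimal:
        raise FbaError(f"FVA: model is {fba.status} under the primary objective")
    opt = fba.objective_value

    S, _, rxn_ids = model.stoichiometric_matrix()
    c = _objective_vector(model, obj, rxn_ids)
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    target = np.zeros(len(rxn_ids))
    target[rxn_ids.index(reaction_id)] = 1.0
    floor = fix_objective_at * opt - REL_TOL * max(1.0, abs(opt))
    A_ub, b_ub = -c[None, :], np.array([-floor])
    out = []
    for sign in (1.0, -1.0):
        res = linprog(
            sign * target,
            A_eq=S,
            b_eq=np.zeros(S.shape[0]),
            A_ub=A_ub,
            b_ub=b_ub,
            bounds=bounds,
            method="highs",
        )
        if res.status != 0:
            raise FbaError(
                f"FVA for {reaction_id} infeasible after constraining the objective"
            )
        out.append(sign * res.fun)
    # first solve minimized the target flux, second maximized it
    return (out[0], out[1])


@dataclass
class DeletionRecord:
    """Effect of a single-gene knockout on the product optimum."""

    gene: str
    product_flux: float
    relative_decrease: float
    essential: bool  # decrease > 0.9
    influential: bool  # decrease > influence threshold (essential implies influential)

    @property
    def klass(self) -> str:
        if self.essential:
            return "essential"
        if self.influential:
            return "influential"
        return "neutral"


def _knockout_bounds(model: MetabolicModel, genes: set[str]) -> List[Tuple[str, float, float]]:
    """Bounds to zero out: reactions whose GPR evaluates false without ``genes``."""
    out = []
    for r in model.reactions:
        if not r.gpr.is_empty and not r.gpr.evaluate(genes):
            out.append((r.id, r.lower_bound, r.upper_bound))
    return out


def single_gene_deletion_scan(
    model: MetabolicModel,
    objective: Optional[Dict[str, float] | str] = None,
    influence_threshold: float = 0.01,
) -> List[DeletionRecord]:
    """Knock out each gene in turn and re-maximize the product flux.

    The objective defaults to the model's product sink.  A gene is classed
    *essential* when the deletion removes more than 90% of the wild-type
    product optimum, and *influential* above ``influence_threshold``
    (default 1%, separating real decreases from solver noise).  The model is
    restored to its pre-scan bounds afterwards.
    """
    if objective is None:
        if not model.product_reaction_id:
            raise FbaError("model has no designated product reaction")
        objective = {model.product_reaction_id: 1.0}
    wt = solve_fba(model, objective)
    if not wt.optimal or wt.objective_value <= LP_TOL:
        raise FbaError("product cannot be formed in wild-type")
    wt_flux = wt.objective_value

    records = []
    for gene in sorted(model.genes):
        touched = _knockout_bounds(model, {gene})
        try:
            for rid, _, _ in touched:
                r = model.reaction(rid)
                r.lower_bound, r.upper_bound = 0.0, 0.0
            sol = solve_fba(model, objective)
            mutant = sol.objective_value if sol.optimal else 0.0
        finally:
            for rid, lb, ub in touched:
                r = model.reaction(rid)
                r.lower_bound, r.upper_bound = lb, ub
        decrease = (wt_flux - mutant) / wt_flux
        records.append(
            DeletionRecord(
                gene=gene,
                product_flux=mutant,
                relative_decrease=decrease,
                essential=decrease > 0.9,
                influential=decrease > influence_threshold,
            )
        )
    return records


@dataclass
class RobustnessCurve:
    """Product optimum as a function of a cap on one reaction's flux."""

    reaction: str
    bound_grid: List[float]
    product_optimum: List[float]
    positively_correlated: bool


def robustness_scan(
    model: MetabolicModel,
    reaction_id: str,
    grid_points: int = 10,
    objective: Optional[Dict[str, float] | str] = None,
) -> RobustnessCurve:
    """Cap ``reaction_id`` at each point of a uniform grid from 0 to its FVA
    maximum and record the product optimum; flags monotone curves."""
    if grid_points < 3:
        raise ValueError("grid_points must be >= 3")
    rxn = model.reaction(reaction_id)
    if objective is None:
        objective = {model.product_reaction_id: 1.0}
    _, vmax = flux_variability(model, reaction_id, fix_objective_at=0.0, objective=objective)
    grid = list(np.linspace(0.0, max(vmax, 0.0), grid_points))
    lb0, ub0 = rxn.lower_bound, rxn.upper_bound
    product = []
    try:
        for cap in grid:
            rxn.upper_bound = min(ub0, cap)
            rxn.lower_bound = min(lb0, rxn.upper_bound)
            sol = solve_fba(model, objective)
            product.append(sol.objective_value if sol.optimal else 0.0)
    finally:
        rxn.lower_bound, rxn.upper_bound = lb0, ub0
    diffs = np.diff(product)
    monotone = bool(np.all(diffs >= -1e-6 * max(1.0, float(np.max(np.abs(product))))))
    return RobustnessCurve(
        reaction=reaction_id,
        bound_grid=grid,
        product_optimum=product,
        positively_correlated=monotone,
    )
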