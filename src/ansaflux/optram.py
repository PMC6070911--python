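"""Simulated-annealing strain design (OptRAM).

The optimizer searches over per-gene perturbations encoded as integer codes:
positive codes force up-regulation by a fold change (2, 4, 8, 16, 32 for
codes 1..5), negative codes cap flux down (1/2 .. 1/32), and code 0 is a
knockout.  A perturbation is translated into flux bounds relative to the
wild-type pFBA reference flux of each affected reaction.

Candidates are scored by a biomass-product coupling objective

    Obj = (Target * Growth / Substrate) * (1 - log10(Range / Target))

where ``Target = (Vmax + Vmin)/2`` and ``Range = (Vmax - Vmin)/2`` come from
flux variability of the product sink at 100% of the candidate's growth
optimum, Growth is the FBA optimum and Substrate the |pFBA substrate uptake|.
The coupling factor rewards designs whose product flux is forced (small
Range) rather than merely possible; Range is floored at ``eps * Target`` so a
perfectly coupled design earns the finite factor ``1 - log10(eps)``.

The search is a Metropolis annealer: random (gene, code) proposals, worse
moves accepted with probability ``exp(delta_f / T)``, temperature decaying
geometrically ``T(k) = T0 * alpha^k``, with independent seeded restarts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .fba import FbaError, flux_variability, solve_fba, solve_pfba
from .model import MetabolicModel

__all__ = [
    "FOLD_CHANGE",
    "MutationCode",
    "DesignSolution",
    "OptRAMConfig",
    "ModificationError",
    "reference_fluxes",
    "apply_modification",
    "objective_score",
    "design_objective",
    "metropolis_accept",
    "optimize",
    "exhaustive_single_modifications",
]

#: perturbation code -> fold change of the mutated gene's expression
FOLD_CHANGE: Dict[int, float] = {
    1: 2.0, 2: 4.0, 3: 8.0, 4: 16.0, 5: 32.0,
    -1: 1 / 2, -2: 1 / 4, -3: 1 / 8, -4: 1 / 16, -5: 1 / 32,
    0: 0.001,  # knockout: bounds are forced to zero outright
}

_ZERO = 1e-9


class ModificationError(ValueError):
    pass


@dataclass(frozen=True)
class MutationCode:
    code: int
    fold_change: float = field(init=False)

    def __post_init__(self) -> None:
        if self.code not in FOLD_CHANGE:
            raise ModificationError(f"unknown mutation code {self.code}")
        object.__setattr__(self, "fold_change", FOLD_CHANGE[self.code])

    @property
    def is_knockout(self) -> bool:
        return self.code == 0


@dataclass
class DesignSolution:
    modifications: Dict[str, int]
    objective_score: float
    growth: float
    product_target: float
    product_range: float
    substrate_uptake: float
    feasible: bool = True

    @property
    def n_modifications(self) -> int:
        return len(self.modifications)


def reference_fluxes(model: MetabolicModel) -> pd.Series:
    """Wild-type pFBA flux vector (biomass objective), the baseline the
    bound transformations are scaled against."""
    sol = solve_pfba(model)
    if not sol.optimal:
        raise FbaError("reference pFBA failed: model infeasible under biomass objective")
    return sol.fluxes


def _transform_bounds(
    lb: float, ub: float, code: int, required: bool, v_ref: float
) -> Tuple[float, float]:
    """Bound transform of one perturbed reaction; may return lb > ub, which
    the caller treats as an inconsistent (infeasible) candidate.

    Knockout zeroes the bounds where the gene is required.  Up-codes force
    flux magnitude to at least ``FC * v_ref`` (no-op on a zero reference).
    Down-codes cap the magnitude at ``FC * v_ref``, but only where the gene
    is required (isozymes rescue OR-rules).
    """
    if code == 0:
        return (0.0, 0.0) if required else (lb, ub)
    if abs(v_ref) <= _ZERO:
        return lb, ub  # nothing to scale against
    fc = FOLD_CHANGE[code]
    if fc > 1.0:  # force magnitude >= fc * |v_ref|
        if v_ref > 0:
            lb = fc * v_ref
        else:
            ub = fc * v_ref
    elif required:  # cap magnitude where the gene is the sole catalyst
        if v_ref > 0:
            ub = min(ub, fc * v_ref)
            lb = min(lb, ub)
        else:
            lb = max(lb, fc * v_ref)
            ub = max(ub, lb)
    return lb, ub


def apply_modification(
    model: MetabolicModel,
    gene: str,
    code: int,
    reference: pd.Series,
) -> MetabolicModel:
    """Return a copy of ``model`` with the gene perturbation translated into
    flux bounds (see :func:`_transform_bounds` for the rules)."""
    MutationCode(code)  # validates
    if gene not in model.genes:
        raise ModificationError(f"gene {gene!r} not in model")
    out = model.copy()
    for r in out.reactions:
        if gene not in r.genes:
            continue
        required = not r.gpr.evaluate({gene})
        v_ref = float(reference.get(r.id, 0.0))
        r.lower_bound, r.upper_bound = _transform_bounds(
            r.lower_bound, r.upper_bound, code, required, v_ref
        )
        if r.lower_bound > r.upper_bound:
            raise ModificationError(
                f"modification {gene}:{code} makes bounds of {r.id} inconsistent"
            )
    return out


def apply_modifications(
    model: MetabolicModel,
    modifications: Dict[str, int],
    reference: pd.Series,
) -> MetabolicModel:
    out = model
    for gene in sorted(modifications):
        out = apply_modification(out, gene, modifications[gene], reference)
    return out


def objective_score(
    growth: float,
    v_min: float,
    v_max: float,
    substrate: float,
    eps: float = 1e-6,
    log_base: float = 10.0,
) -> float:
    """Coupling objective from growth, the product flux interval, and the
    substrate uptake magnitude; 0 for dead or product-free designs."""
    target = (v_max + v_min) / 2.0
    range_ = (v_max - v_min) / 2.0
    if growth <= _ZERO or target <= _ZERO or substrate <= _ZERO:
        return 0.0
    ratio = max(range_, eps * target) / target
    factor = 1.0 - math.log(ratio) / math.log(log_base)
    return target * growth / substrate * factor


class _GlpkLP:
    """Persistent GLPK problem: fixed constraint matrix, mutable column
    bounds, row bounds and objective; warm-started simplex re-solves."""

    def __init__(self, A_rows):
        import swiglpk as glp

        self.glp = glp
        n = len(A_rows[0])
        m = len(A_rows)
        self.n, self.m = n, m
        lp = glp.glp_create_prob()
        glp.glp_add_rows(lp, m)
        glp.glp_add_cols(lp, n)
        entries = [
            (i + 1, j + 1, float(v))
            for i, row in enumerate(A_rows)
            for j, v in enumerate(row)
            if v
        ]
        ia = glp.intArray(len(entries) + 1)
        ja = glp.intArray(len(entries) + 1)
        ar = glp.doubleArray(len(entries) + 1)
        for k, (i, j, v) in enumerate(entries, start=1):
            ia[k], ja[k], ar[k] = i, j, v
        glp.glp_load_matrix(lp, len(entries), ia, ja, ar)
        for i in range(m):
            glp.glp_set_row_bnds(lp, i + 1, glp.GLP_FX, 0.0, 0.0)
        self.parm = glp.glp_smcp()
        glp.glp_init_smcp(self.parm)
        self.parm.msg_lev = glp.GLP_MSG_OFF
        self.lp = lp

    def set_col_bounds(self, lb, ub):
        glp, lp = self.glp, self.lp
        for j in range(self.n):
            l, u = float(lb[j]), float(ub[j])
            glp.glp_set_col_bnds(lp, j + 1, glp.GLP_FX if l == u else glp.GLP_DB, l, u)

    def set_row_lower(self, i, lower):
        glp = self.glp
        if lower is None:
            glp.glp_set_row_bnds(self.lp, i + 1, glp.GLP_FR, 0.0, 0.0)
        else:
            glp.glp_set_row_bnds(self.lp, i + 1, glp.GLP_LO, float(lower), 0.0)

    def solve(self, obj, maximize):
        """Returns the objective value, or None when not optimal."""
        glp, lp = self.glp, self.lp
        for j in range(self.n):
            glp.glp_set_obj_coef(lp, j + 1, float(obj[j]))
        glp.glp_set_obj_dir(lp, glp.GLP_MAX if maximize else glp.GLP_MIN)
        if glp.glp_simplex(lp, self.parm) != 0:
            return None
        if glp.glp_get_status(lp) != glp.GLP_OPT:
            return None
        return glp.glp_get_obj_val(lp)

    def column_value(self, j):
        return self.glp.glp_get_col_prim(self.lp, j + 1)


class _Evaluator:
    """Array-level candidate scoring: the stoichiometric matrix, objective
    vector and wild-type bounds are built once; a candidate only changes the
    bound vectors, and costs exactly four LP solves (growth FBA, product
    FVA min/max at 100% of the optimum, and pFBA for the substrate flux).
    Solves go through a persistent warm-started GLPK problem when swiglpk is
    importable, falling back to scipy's HiGHS interface otherwise."""

    def __init__(self, model: MetabolicModel, reference: Optional[pd.Series],
                 objective=None, eps: float = 1e-6, log_base: float = 10.0):
        from scipy.optimize import linprog  # local alias for hot path

        self._linprog = linprog
        self.eps, self.log_base = eps, log_base
        S, _, rxn_ids = model.stoichiometric_matrix()
        self.S = S
        self.b_eq = np.zeros(S.shape[0])
        self.n = len(rxn_ids)
        idx = {r: i for i, r in enumerate(rxn_ids)}
        self.lb0 = np.array([r.lower_bound for r in model.reactions])
        self.ub0 = np.array([r.upper_bound for r in model.reactions])
        if objective is None:
            objective = {model.biomass_reaction_id: 1.0}
        elif isinstance(objective, str):
            objective = {objective: 1.0}
        self.c = np.zeros(self.n)
        for rid, coef in objective.items():
            self.c[idx[rid]] = coef
        self.prod_i = idx[model.product_reaction_id]
        self.sub_i = idx[model.substrate_exchange_id]
        # per-gene perturbation targets: (reaction index, required, v_ref)
        self.targets: Dict[str, list] = {}
        for r in model.reactions:
            for gene in r.genes:
                required = not r.gpr.evaluate({gene})
                v_ref = float(reference.get(r.id, 0.0)) if reference is not None else 0.0
                self.targets.setdefault(gene, []).append((idx[r.id], required, v_ref))
        # pFBA arrays (reversible splitting)
        self.A_eq2 = np.hstack([S, -S])
        self.cost2 = np.ones(2 * self.n)
        self.c2 = np.concatenate([self.c, -self.c])
        try:
            # persistent problems: [S; c] for FBA/FVA, [S,-S; c,-c] for pFBA
            self.lp_main = _GlpkLP(np.vstack([S, self.c]))
            self.lp_pfba = _GlpkLP(np.vstack([self.A_eq2, self.c2]))
            self.e_prod = np.zeros(self.n)
            self.e_prod[self.prod_i] = 1.0
        except ImportError:  # pragma: no cover - swiglpk ships with cobra
            self.lp_main = None

    def _zero(self, mods) -> DesignSolution:
        return DesignSolution(dict(mods), 0.0, 0.0, 0.0, 0.0, 0.0, feasible=False)

    def evaluate(self, mods: Dict[str, int]) -> DesignSolution:
        lb, ub = self.lb0.copy(), self.ub0.copy()
        for gene in sorted(mods):
            for j, required, v_ref in self.targets.get(gene, ()):
                lb[j], ub[j] = _transform_bounds(lb[j], ub[j], mods[gene], required, v_ref)
                if lb[j] > ub[j]:
                    return self._zero(mods)
        if self.lp_main is not None:
            return self._evaluate_glpk(mods, lb, ub)
        bounds = np.column_stack([lb, ub])
        res = self._linprog(-self.c, A_eq=self.S, b_eq=self.b_eq,
                            bounds=bounds, method="highs")
        if res.status != 0:
            return self._zero(mods)
        growth = float(self.c @ res.x)
        if growth <= _ZERO:
            return self._zero(mods)
        floor = growth - 1e-6 * max(1.0, abs(growth))
        A_ub, b_ub = -self.c[None, :], np.array([-floor])
        t = np.zeros(self.n)
        t[self.prod_i] = 1.0
        interval = []
        for sign in (1.0, -1.0):
            r = self._linprog(sign * t, A_eq=self.S, b_eq=self.b_eq,
                              A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
            if r.status != 0:
                return self._zero(mods)
            interval.append(sign * r.fun)
        v_min, v_max = interval
        # pFBA for the substrate flux at the held optimum
        bounds2 = np.concatenate([
            np.column_stack([np.maximum(lb, 0.0), np.maximum(ub, 0.0)]),
            np.column_stack([np.maximum(-ub, 0.0), np.maximum(-lb, 0.0)]),
        ])
        r = self._linprog(self.cost2, A_eq=self.A_eq2, b_eq=self.b_eq,
                          A_ub=-self.c2[None, :], b_ub=np.array([-floor]),
                          bounds=bounds2, method="highs")
        if r.status != 0:
            return self._zero(mods)
        v = r.x[: self.n] - r.x[self.n:]
        substrate = abs(float(v[self.sub_i]))
        score = objective_score(growth, v_min, v_max, substrate,
                                eps=self.eps, log_base=self.log_base)
        return DesignSolution(
            modifications=dict(mods),
            objective_score=score,
            growth=growth,
            product_target=(v_max + v_min) / 2.0,
            product_range=(v_max - v_min) / 2.0,
            substrate_uptake=substrate,
        )

    def _evaluate_glpk(self, mods, lb, ub) -> DesignSolution:
        main = self.lp_main
        main.set_col_bounds(lb, ub)
        main.set_row_lower(self.S.shape[0], None)  # objective row free
        growth = main.solve(self.c, maximize=True)
        if growth is None or growth <= _ZERO:
            return self._zero(mods)
        floor = growth - 1e-6 * max(1.0, abs(growth))
        main.set_row_lower(self.S.shape[0], floor)
        v_min = main.solve(self.e_prod, maximize=False)
        v_max = main.solve(self.e_prod, maximize=True)
        if v_min is None or v_max is None:
            return self._zero(mods)
        pfba = self.lp_pfba
        lb2 = np.concatenate([np.maximum(lb, 0.0), np.maximum(-ub, 0.0)])
        ub2 = np.concatenate([np.maximum(ub, 0.0), np.maximum(-lb, 0.0)])
        pfba.set_col_bounds(lb2, ub2)
        pfba.set_row_lower(self.S.shape[0], floor)
        total = pfba.solve(self.cost2, maximize=False)
        if total is None:
            return self._zero(mods)
        substrate = abs(
            pfba.column_value(self.sub_i) - pfba.column_value(self.n + self.sub_i)
        )
        score = objective_score(growth, v_min, v_max, substrate,
                                eps=self.eps, log_base=self.log_base)
        return DesignSolution(
            modifications=dict(mods),
            objective_score=score,
            growth=growth,
            product_target=(v_max + v_min) / 2.0,
            product_range=(v_max - v_min) / 2.0,
            substrate_uptake=substrate,
        )


def design_objective(
    model: MetabolicModel,
    objective=None,
    eps: float = 1e-6,
    log_base: float = 10.0,
    modifications: Optional[Dict[str, int]] = None,
) -> DesignSolution:
    """Score a (possibly already modified) model.  Growth 0 or Target 0
    yields score 0 rather than an error — a valid bad candidate."""
    evaluator = _Evaluator(model, reference=None, objective=objective,
                           eps=eps, log_base=log_base)
    solution = evaluator.evaluate({})
    solution.modifications = dict(modifications or {})
    return solution


def metropolis_accept(delta_f: float, T: float, rng: np.random.Generator) -> bool:
    """Accept improvements outright; accept a worse move with probability
    ``exp(delta_f / T)`` (Metropolis criterion)."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    if delta_f > 0:
        return True
    return math.exp(delta_f / T) > rng.random()


@dataclass
class OptRAMConfig:
    """Annealer settings.  The default schedule cools slowly (alpha close
    to 1) because the design landscape has a deep "starve growth for
    coupling" local basin: the walk needs an extended mid-temperature phase
    to leave it before the greedy endgame."""

    T0: float = 2.0
    alpha: float = 0.999
    iterations: int = 3000
    max_modifications: int = 6
    restarts: int = 25
    seed: int = 0
    eps: float = 1e-6
    log_base: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


def _rank_key(sol: DesignSolution) -> Tuple[float, int, float]:
    # best objective first; implementation cost (fewer edits) breaks ties,
    # then higher growth
    return (-sol.objective_score, sol.n_modifications, -sol.growth)


def _evaluate(
    evaluator: _Evaluator,
    mods: Dict[str, int],
    cache: Dict[frozenset, DesignSolution],
) -> DesignSolution:
    key = frozenset(mods.items())
    if key not in cache:
        cache[key] = evaluator.evaluate(mods)
    return cache[key]


def _prune(
    evaluator: _Evaluator,
    best: DesignSolution,
    cache: Dict[frozenset, DesignSolution],
) -> DesignSolution:
    """Implementation-cost polish: greedily drop modifications that do not
    pay for themselves (score preserved within 1e-9)."""
    improved = True
    while improved and best.modifications:
        improved = False
        for gene in sorted(best.modifications):
            trial = {g: c for g, c in best.modifications.items() if g != gene}
            sol = _evaluate(evaluator, trial, cache)
            if sol.objective_score >= best.objective_score - 1e-9:
                best = sol
                improved = True
                break
    return best


def optimize(
    model: MetabolicModel,
    config: Optional[OptRAMConfig] = None,
    objective=None,
) -> List[DesignSolution]:
    """Run the annealer; returns one best solution per restart, ranked by
    (objective score desc, fewer modifications, growth desc).  Fully
    reproducible for a fixed seed."""
    cfg = config or OptRAMConfig()
    reference = reference_fluxes(model)
    evaluator = _Evaluator(model, reference, objective=objective,
                           eps=cfg.eps, log_base=cfg.log_base)
    active = {
        g
        for g in model.genes
        if any(abs(reference.get(r.id, 0.0)) > _ZERO for r in model.reactions_for_gene(g))
    }
    genes = sorted(active) if active else sorted(model.genes)
    codes = sorted(FOLD_CHANGE)
    cache: Dict[frozenset, DesignSolution] = {}
    wild_type = _evaluate(evaluator, {}, cache)

    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.restarts)
    results: List[DesignSolution] = []
    for seed_seq in seeds:
        rng = np.random.default_rng(seed_seq)
        current = wild_type
        best = wild_type
        mods: Dict[str, int] = {}
        for k in range(cfg.iterations):
            T = max(cfg.T0 * cfg.alpha**k, 1e-300)
            gene = genes[rng.integers(len(genes))]
            code = codes[rng.integers(len(codes))]
            proposal = dict(mods)
            proposal[gene] = code
            if len(proposal) > cfg.max_modifications:
                droppable = sorted(g for g in proposal if g != gene)
                proposal.pop(droppable[rng.integers(len(droppable))])
            candidate = _evaluate(evaluator, proposal, cache)
            delta_f = candidate.objective_score - current.objective_score
            if metropolis_accept(delta_f, T, rng):
                current, mods = candidate, proposal
                if (current.objective_score, -current.n_modifications) > (
                    best.objective_score,
                    -best.n_modifications,
                ):
                    best = current
        results.append(_prune(evaluator, best, cache))
    results.sort(key=_rank_key)
    return results


def exhaustive_single_modifications(
    model: MetabolicModel,
    objective=None,
    eps: float = 1e-6,
    log_base: float = 10.0,
) -> List[DesignSolution]:
    """Brute-force oracle: score every (gene, code) single modification;
    returns all solutions ranked best-first."""
    reference = reference_fluxes(model)
    evaluator = _Evaluator(model, reference, objective=objective,
                           eps=eps, log_base=log_base)
    cache: Dict[frozenset, DesignSolution] = {}
    out = []
    for gene in sorted(model.genes):
        for code in sorted(FOLD_CHANGE):
            out.append(_evaluate(evaluator, {gene: code}, cache))
    out.sort(key=_rank_key)
    return out
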