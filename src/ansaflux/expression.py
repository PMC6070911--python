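"""E-FLUX integration of expression data into condition-specific models.

The transcriptome enters as a gene x condition FPKM matrix.  Each gene's
expression level is ``exp_i = log(FPKM_i + 1)`` (base 10 by default; the base
only rescales all bounds uniformly).  A reaction's E-FLUX bound is the sum of
the expression levels of its GPR genes,

    b_j = sum_{i in rxn_j} exp_i,

applied as the upper bound (and ``-b_j`` as the lower bound of reversible
reactions).  Reactions without gene association keep their default bounds.
The bounds are in expression units, not mmol/gDW/h, and are applied as-is.

A condition-specific model additionally fixes the measured glucose uptake
(``lb = ub = -R_glucose``; negative exchange flux is consumption), applies
strain knockouts, and replaces the objective with ``biomass + c * product``
where ``c`` is the measured product:biomass ratio of that day.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .fba import FbaError, FluxSolution, solve_fba, solve_pfba
from .model import MetabolicModel

__all__ = [
    "ExpressionProfile",
    "ConditionSpec",
    "ConditionModel",
    "ActiveReactionCall",
    "InfeasibleConditionError",
    "glucose_uptake_rate",
    "eflux_bounds",
    "build_condition_model",
    "normalized_flux_table",
    "call_active_reactions",
    "flux_shift_report",
    "GLUCOSE_MW",
]

logger = logging.getLogger(__name__)

#: molar mass of D-glucose, g/mol
GLUCOSE_MW = 180.16

#: sentinel ratio for fluxes that appear on a zero baseline
NEW_FLUX = math.inf


class InfeasibleConditionError(FbaError):
    pass


@dataclass
class ExpressionProfile:
    """Gene x condition FPKM matrix with the log base used for E-FLUX."""

    values: pd.DataFrame  # rows: gene ids, columns: condition labels, FPKM
    log_base: float = 10.0

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            bad = self.values.index[(self.values < 0).any(axis=1)][:5].tolist()
            raise ValueError(f"negative FPKM values (e.g. genes {bad})")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate condition labels")

    @property
    def conditions(self) -> List[str]:
        return list(self.values.columns)

    @property
    def genes(self) -> List[str]:
        return list(self.values.index)

    def expression(self, condition: str) -> pd.Series:
        """Per-gene expression level ``log(FPKM + 1)`` in the profile's base."""
        fpkm = self.values[condition]
        return np.log1p(fpkm) / math.log(self.log_base)

    @classmethod
    def from_tsv(cls, path, log_base: float = 10.0) -> "ExpressionProfile":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        return cls(values=df.astype(float), log_base=log_base)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene")


def glucose_uptake_rate(
    consumption_g: float,
    dcw_g: float,
    hours: float,
    molecular_weight: float = GLUCOSE_MW,
) -> float:
    """Specific glucose uptake rate in mmol/gDW/h.

    ``consumption / (DCW * MW * time)`` converted from mol to mmol.  A zero
    consumption gives rate zero; other non-positive inputs are rejected.
    """
    if dcw_g <= 0 or hours <= 0 or molecular_weight <= 0:
        raise ValueError("DCW, time and molecular weight must be positive")
    if consumption_g < 0:
        raise ValueError("glucose consumption cannot be negative")
    return consumption_g / (dcw_g * molecular_weight * hours) * 1000.0


@dataclass
class ConditionSpec:
    """Everything needed to specialize the base model to one sampling day."""

    label: str
    c_product: float = 0.0
    knockouts: FrozenSet[str] = frozenset()
    #: consumption_g, dcw_g, hours (+ optional molecular_weight)
    measurements: Optional[Dict[str, float]] = None
    glucose_uptake: Optional[float] = None  # mmol/gDW/h; overrides measurements

    def __post_init__(self) -> None:
        self.knockouts = frozenset(self.knockouts)
        if self.c_product < 0:
            raise ValueError("c_product must be >= 0")

    def uptake(self) -> float:
        if self.glucose_uptake is not None:
            if self.glucose_uptake < 0:
                raise ValueError("glucose_uptake must be >= 0")
            return self.glucose_uptake
        if self.measurements is None:
            raise ValueError(f"condition {self.label}: no uptake rate or measurements")
        m = self.measurements
        return glucose_uptake_rate(
            m["consumption_g"],
            m["dcw_g"],
            m["hours"],
            m.get("molecular_weight", GLUCOSE_MW),
        )


def eflux_bounds(
    model: MetabolicModel,
    profile: ExpressionProfile,
    condition: str,
    mode: str = "sum",
    impute: str = "median",
) -> Dict[str, float]:
    """Per-reaction E-FLUX bound ``b_j`` for one condition.

    ``mode="sum"`` adds the expression of every GPR gene (the plain
    sum-over-genes rule); ``mode="gpr"`` instead takes min over AND branches
    and sum over OR branches, the convention of the original E-FLUX method.
    Genes missing from the profile are imputed with the condition median
    (absence of a measurement should not block a reaction) and logged.
    """
    if condition not in profile.values.columns:
        raise KeyError(f"condition {condition!r} not in expression profile")
    expr = profile.expression(condition)
    fill = float(expr.median()) if impute == "median" else 0.0

    def gene_expr(g: str) -> float:
        if g in expr.index:
            return float(expr[g])
        logger.info("gene %s missing from expression profile; imputing %.4g", g, fill)
        return fill

    def eval_node(node) -> float:
        kind, payload = node
        if kind == "gene":
            return gene_expr(payload)
        values = [eval_node(c) for c in payload]
        return min(values) if kind == "and" else sum(values)

    bounds: Dict[str, float] = {}
    for r in model.reactions:
        if r.gpr.is_empty:
            continue
        if mode == "sum":
            bounds[r.id] = sum(gene_expr(g) for g in sorted(r.gpr.genes))
        elif mode == "gpr":
            bounds[r.id] = eval_node(r.gpr.node)
        else:
            raise ValueError(f"unknown E-FLUX mode {mode!r}")
    return bounds


@dataclass
class ConditionModel:
    """Base model specialized to one condition, with its pFBA solution."""

    model: MetabolicModel
    spec: ConditionSpec
    bounds: Dict[str, float]
    solution: FluxSolution

    @property
    def label(self) -> str:
        return self.spec.label


def build_condition_model(
    base: MetabolicModel,
    profile: ExpressionProfile,
    spec: ConditionSpec,
    aliases: Optional[Dict[str, str]] = None,
    mode: str = "sum",
) -> ConditionModel:
    """Apply knockouts, the fixed glucose uptake, and E-FLUX bounds; store the
    pFBA solution under the ``biomass + c * product`` objective."""
    model = base.copy()
    aliases = aliases or {}
    knockouts = {aliases.get(g, g) for g in spec.knockouts}
    unknown = sorted(knockouts - set(model.genes))
    if unknown:
        logger.warning("knockout genes not in model (ignored): %s", unknown)
        knockouts &= set(model.genes)

    bounds = eflux_bounds(model, profile, spec.label, mode=mode)
    for r in model.reactions:
        if r.id in bounds:
            b = bounds[r.id]
            r.upper_bound = b
            r.lower_bound = -b if r.lower_bound < 0 else 0.0
    for r in model.reactions:
        if not r.gpr.is_empty and not r.gpr.evaluate(knockouts):
            r.lower_bound, r.upper_bound = 0.0, 0.0

    uptake = spec.uptake()
    substrate = model.reaction(model.substrate_exchange_id)
    substrate.lower_bound = substrate.upper_bound = -uptake

    objective = {model.biomass_reaction_id: 1.0}
    if spec.c_product:
        objective[model.product_reaction_id] = spec.c_product
    solution = solve_fba(model, objective)
    if not solution.optimal:
        # identify the binding constraint class for the error message
        relaxed = model.copy()
        for r in relaxed.reactions:
            if r.id in bounds:
                r.upper_bound = 1000.0
                r.lower_bound = -1000.0 if base.reaction(r.id).lower_bound < 0 else 0.0
        probe = solve_fba(relaxed, objective)
        cause = (
            "expression-derived bounds" if probe.optimal else "uptake or base bounds"
        )
        raise InfeasibleConditionError(
            f"condition {spec.label!r} is {solution.status}; binding constraint "
            f"class: {cause}"
        )
    pfba = solve_pfba(model, objective)
    return ConditionModel(model=model, spec=spec, bounds=bounds, solution=pfba)


@dataclass
class ActiveReactionCall:
    """A reaction whose flux is specific to one condition.

    ``normalized_flux`` is the per-condition flux divided by the reaction's
    maximum absolute flux across conditions (all-zero rows normalize to 0).
    A reaction is specific to a condition when the 0.5 cut is exceeded there
    (the peak condition always normalizes to 1) and in no other condition.
    """

    reaction: str
    condition: str
    normalized_flux: Dict[str, float]
    specific: bool = True


def normalized_flux_table(condition_models: Sequence[ConditionModel]) -> pd.DataFrame:
    if len(condition_models) < 2:
        raise ValueError("need at least two conditions")
    labels = [cm.label for cm in condition_models]
    fluxes = pd.DataFrame(
        {cm.label: cm.solution.fluxes for cm in condition_models}
    )[labels]
    denom = fluxes.abs().max(axis=1)
    denom = denom.where(denom > 1e-9, 1.0)  # all-zero rows -> stay 0
    normalized = fluxes.div(denom, axis=0)
    normalized[fluxes.abs().max(axis=1) <= 1e-9] = 0.0
    return normalized


def call_active_reactions(
    condition_models: Sequence[ConditionModel],
) -> List[ActiveReactionCall]:
    """Condition-specific active reactions across a set of condition models."""
    normalized = normalized_flux_table(condition_models)
    calls: List[ActiveReactionCall] = []
    # |.| makes the call invariant to the sign convention of reversible fluxes.
    # The condition carrying the maximum always normalizes to 1; a reaction is
    # specific when no other condition exceeds the 0.5 cut (a competing day at
    # exactly 0.5 does not disqualify).
    high = normalized.abs() > 0.5
    for rid, row in high.iterrows():
        if row.sum() == 1:
            label = row.index[row.argmax()]
            calls.append(
                ActiveReactionCall(
                    reaction=rid,
                    condition=label,
                    normalized_flux=normalized.loc[rid].to_dict(),
                )
            )
    return calls


def flux_shift_report(
    condition_models: Sequence[ConditionModel],
    reaction_ids: Iterable[str],
) -> pd.DataFrame:
    """Per-condition pFBA fluxes for a reaction set, with each condition's
    ratio to the first condition (``inf`` marks flux on a zero baseline)."""
    labels = [cm.label for cm in condition_models]
    rows = []
    for rid in reaction_ids:
        if not condition_models[0].model.has_reaction(rid):
            continue
        fluxes = [cm.solution.flux(rid) for cm in condition_models]
        base = fluxes[0]
        ratios = []
        for f in fluxes:
            if abs(base) > 1e-9:
                ratios.append(f / base)
            elif abs(f) > 1e-9:
                ratios.append(NEW_FLUX)
            else:
                ratios.append(np.nan)
        row = {"reaction": rid}
        row.update({f"flux_{lab}": f for lab, f in zip(labels, fluxes)})
        row.update({f"ratio_{lab}": r for lab, r in zip(labels, ratios)})
        rows.append(row)
    return pd.DataFrame(rows).set_index("reaction") if rows else pd.DataFrame()
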