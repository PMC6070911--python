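"""Core domain types for constraint-based metabolic models.

A :class:`MetabolicModel` is a stoichiometric reconstruction: metabolites,
reactions with flux bounds (mmol/gDW/h) and GPR rules, subsystem (pathway)
labels, and three designated reactions — the biomass equation, the product
sink (here the ansamitocin P-3 exporter), and the substrate (glucose)
exchange.  The steady-state flux cone is ``{v : S v = 0, lb <= v <= ub}``
where ``S`` has one row per metabolite and one column per reaction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

from .gpr import Gpr

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ModelStats",
    "ModelError",
    "model_stats",
    "orf_coverage",
    "REACTION_KINDS",
    "DEFAULT_BOUND",
]

REACTION_KINDS = ("internal", "exchange", "transport", "biomass")

#: conventional cap used for bounds declared only as (ir)reversible
DEFAULT_BOUND = 1000.0


class ModelError(ValueError):
    """Raised for structurally invalid models."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"


@dataclass
class Reaction:
    """One column of S: signed stoichiometry plus flux bounds and a GPR."""

    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    gpr: Gpr = field(default_factory=Gpr)
    subsystem: str = ""
    kind: str = "internal"

    def __post_init__(self) -> None:
        if isinstance(self.gpr, str):
            self.gpr = Gpr.parse(self.gpr)
        if self.kind not in REACTION_KINDS:
            raise ModelError(f"reaction {self.id}: unknown kind {self.kind!r}")
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def genes(self) -> frozenset[str]:
        return self.gpr.genes

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


@dataclass
class MetabolicModel:
    metabolites: List[Metabolite]
    reactions: List[Reaction]
    biomass_reaction_id: str = ""
    product_reaction_id: str = ""
    substrate_exchange_id: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        self._index()

    def _index(self) -> None:
        self._met_index = {m.id: m for m in self.metabolites}
        self._rxn_index = {r.id: r for r in self.reactions}

    # -- lookups ---------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return self._met_index[met_id]
        except KeyError:
            raise ModelError(f"unknown metabolite id {met_id!r}") from None

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self._rxn_index[rxn_id]
        except KeyError:
            raise ModelError(f"unknown reaction id {rxn_id!r}") from None

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    @property
    def genes(self) -> frozenset[str]:
        """Union of all GPR leaves."""
        out: set[str] = set()
        for r in self.reactions:
            out |= r.genes
        return frozenset(out)

    @property
    def compartments(self) -> frozenset[str]:
        return frozenset(m.compartment for m in self.metabolites)

    @property
    def subsystems(self) -> Tuple[str, ...]:
        seen: dict[str, None] = {}
        for r in self.reactions:
            if r.subsystem:
                seen.setdefault(r.subsystem, None)
        return tuple(seen)

    def reactions_for_gene(self, gene: str) -> List[Reaction]:
        return [r for r in self.reactions if gene in r.genes]

    # -- linear algebra view --------------------------------------------
    def stoichiometric_matrix(self) -> Tuple[np.ndarray, List[str], List[str]]:
        """Dense S with one row per metabolite, one column per reaction."""
        met_ids = [m.id for m in self.metabolites]
        rxn_ids = [r.id for r in self.reactions]
        pos = {m: i for i, m in enumerate(met_ids)}
        S = np.zeros((len(met_ids), len(rxn_ids)))
        for j, r in enumerate(self.reactions):
            for met, coef in r.stoichiometry.items():
                try:
                    S[pos[met], j] = coef
                except KeyError:
                    raise ModelError(
                        f"reaction {r.id} references undeclared metabolite {met!r}"
                    ) from None
        return S, met_ids, rxn_ids

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            raise ModelError("duplicate metabolite ids")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            raise ModelError("duplicate reaction ids")
        for r in self.reactions:
            if r.kind == "internal" and not r.stoichiometry:
                raise ModelError(f"internal reaction {r.id} has empty stoichiometry")
            for met in r.stoichiometry:
                if met not in self._met_index:
                    raise ModelError(
                        f"reaction {r.id} references undeclared metabolite {met!r}"
                    )
        for label, rid in (
            ("biomass", self.biomass_reaction_id),
            ("product", self.product_reaction_id),
            ("substrate", self.substrate_exchange_id),
        ):
            if rid and rid not in self._rxn_index:
                raise ModelError(f"{label} reaction id {rid!r} not in model")

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=[replace(m) for m in self.metabolites],
            reactions=[r.copy() for r in self.reactions],
            biomass_reaction_id=self.biomass_reaction_id,
            product_reaction_id=self.product_reaction_id,
            substrate_exchange_id=self.substrate_exchange_id,
            name=self.name,
        )


@dataclass
class ModelStats:
    """Composition accounting of a reconstruction."""

    n_genes: int
    n_reactions: int
    n_metabolites: int
    n_exchange: int
    n_transport: int
    n_subsystems: int
    pct_orfs_in_model: float


def orf_coverage(n_genes: int, total_orfs: int) -> float:
    """Percent of the genome's ORFs captured by the model, to 2 decimals."""
    if total_orfs <= 0:
        raise ValueError("total_orfs must be positive")
    if total_orfs < n_genes:
        warnings.warn(
            f"total_orfs ({total_orfs}) is smaller than the model's gene count "
            f"({n_genes}); coverage will exceed 100%",
            stacklevel=2,
        )
    return round(100.0 * n_genes / total_orfs, 2)


def model_stats(model: MetabolicModel, total_orfs: int) -> ModelStats:
    n_genes = len(model.genes)
    return ModelStats(
        n_genes=n_genes,
        n_reactions=len(model.reactions),
        n_metabolites=len(model.metabolites),
        n_exchange=sum(1 for r in model.reactions if r.kind == "exchange"),
        n_transport=sum(1 for r in model.reactions if r.kind == "transport"),
        n_subsystems=len(model.subsystems),
        pct_orfs_in_model=orf_coverage(n_genes, total_orfs),
    )
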