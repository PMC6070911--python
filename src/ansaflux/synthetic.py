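"""Desk-scale synthetic fixtures: a toy actinomycete GSMM and FPKM time courses.

The toy model mirrors the architecture of an ansamitocin-producing
actinomycete: glucose uptake feeds glycolysis, the pentose phosphate pathway
and an open TCA branch; oxaloacetate and aspartate start a
methionine -> S-adenosyl-methionine (SAM) branch; a polyketide product
pathway assembles an AHBA starter with malonyl units and UDP-glucose and
finishes with three SAM-dependent methylations, the last catalyzed by a
dedicated *asm10*-like methyltransferase gene.  Pyruvate overflow and CO2
export act as carbon escape valves so a fixed measured glucose uptake is
always balanceable.  Every reaction carries a subsystem label and a GPR with
one or two genes.

The expression generator encodes the fermentation-time shift the pipeline is
meant to recover: growth-program genes (TCA, PPP, nucleotide synthesis)
decay sharply over the four sampling days, secondary-metabolism genes
(methionine/SAM, product biosynthesis and the product/by-product exporters)
rise sharply, and the constitutive carbon backbone (glycolysis, uptake
transporters, anaplerosis) stays near-flat at high expression so the fixed
glucose uptake remains feasible under E-FLUX caps.  Noise is multiplicative
lognormal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .expression import ConditionSpec, ExpressionProfile, GLUCOSE_MW
from .fba import solve_fba
from .gpr import Gpr
from .io import write_model
from .model import MetabolicModel, Metabolite, Reaction

__all__ = [
    "ToyModelSpec",
    "ExpressionSim",
    "make_toy_model",
    "make_expression",
    "default_condition_specs",
    "gene_regulon",
    "emit_fixtures",
    "KNOCKOUT_ALIASES",
    "GROWTH_SUBSYSTEMS",
    "SECONDARY_SUBSYSTEMS",
]

#: spelling variants of the shunt-gene locus name, as they appear in strain
#: descriptions of the high-yield mutant
KNOCKOUT_ALIASES = {"ansa30": "asm30"}

GROWTH_SUBSYSTEMS = ("TCA", "PPP", "Nucleotide", "Glycolysis/EMP")
SECONDARY_SUBSYSTEMS = ("Methionine/SAM", "Product biosynthesis")

#: reactions whose genes follow the secondary (rising) program although their
#: subsystem is not a secondary one: by-product/product export is recruited
#: together with the product pathway
_SECONDARY_REACTION_IDS = {"SAHt", "AP3t"}
#: constitutive even though their subsystem is a growth one: anaplerosis
#: supplies oxaloacetate to citrate (early) and to aspartate/methionine
#: (late), so it must stay open throughout the fermentation
_HOUSEKEEPING_REACTION_IDS = {"ANA"}


@dataclass
class ToyModelSpec:
    n_parallel_paths: int = 1
    include_methionine_branch: bool = True
    include_pentose_path: bool = True
    n_product_steps: int = 4  # >= 3; the first three steps are SAM methylations
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_product_steps < 3:
            raise ValueError("n_product_steps must be >= 3")
        if self.n_parallel_paths < 1:
            raise ValueError("n_parallel_paths must be >= 1")


class _Builder:
    def __init__(self, seed: int):
        rng = np.random.default_rng(seed)
        numbers = rng.permutation(np.arange(1001, 1201)).tolist()
        self._numbers = iter(numbers)
        self.reactions: List[Reaction] = []
        self.mets: Dict[str, Metabolite] = {}

    def gene(self) -> str:
        return f"peg.{next(self._numbers)}"

    def met(self, token: str) -> str:
        if token not in self.mets:
            name, comp = token[:-3], token[-2]
            self.mets[token] = Metabolite(id=token, name=name, compartment=comp)
        return token

    def rxn(
        self,
        rid: str,
        stoich: Dict[str, float],
        lb: float = 0.0,
        ub: float = 1000.0,
        genes: int | str = 1,
        subsystem: str = "",
        kind: str = "internal",
    ) -> None:
        for tok in stoich:
            self.met(tok)
        if isinstance(genes, str):
            gpr = genes
        elif genes == 0:
            gpr = ""
        elif genes == 1:
            gpr = self.gene()
        else:
            gpr = " or ".join(self.gene() for _ in range(genes))
        self.reactions.append(
            Reaction(
                id=rid,
                stoichiometry=dict(stoich),
                lower_bound=lb,
                upper_bound=ub,
                gpr=Gpr.parse(gpr),
                subsystem=subsystem,
                kind=kind,
            )
        )


def make_toy_model(spec: Optional[ToyModelSpec] = None) -> MetabolicModel:
    """Deterministic toy GSMM (~40 reactions) with positive biomass and
    product optima; the sole terminal methyltransferase gene is ``asm10``."""
    spec = spec or ToyModelSpec()
    b = _Builder(spec.seed)
    TE = "Transport/Exchange"

    # exchanges (no gene association)
    b.rxn("EX_glc", {"glc[e]": -1}, lb=-10, genes=0, subsystem=TE, kind="exchange")
    b.rxn("EX_nh4", {"nh4[e]": -1}, lb=-1000, genes=0, subsystem=TE, kind="exchange")
    b.rxn("EX_pyr", {"pyr[e]": -1}, genes=0, subsystem=TE, kind="exchange")
    b.rxn("EX_co2", {"co2[e]": -1}, genes=0, subsystem=TE, kind="exchange")
    b.rxn("EX_ap3", {"ap3[e]": -1}, genes=0, subsystem=TE, kind="exchange")

    # transporters
    b.rxn("GLCt", {"glc[e]": -1, "glc[c]": 1}, genes=2, subsystem=TE, kind="transport")
    b.rxn("NH4t", {"nh4[e]": -1, "nh4[c]": 1}, genes=2, subsystem=TE, kind="transport")
    b.rxn("PYRt", {"pyr[c]": -1, "pyr[e]": 1}, genes=2, subsystem=TE, kind="transport")
    b.rxn("CO2t", {"co2[c]": -1, "co2[e]": 1}, genes=2, subsystem=TE, kind="transport")
    b.rxn("AP3t", {"ap3[c]": -1, "ap3[e]": 1}, subsystem=TE, kind="transport")

    # glycolysis (EMP): constitutive carbon backbone, isozyme pairs
    glyc = "Glycolysis/EMP"
    b.rxn("HEX", {"glc[c]": -1, "g6p[c]": 1}, genes=2, subsystem=glyc)
    b.rxn("PGI", {"g6p[c]": -1, "f6p[c]": 1}, lb=-1000, genes=2, subsystem=glyc)
    b.rxn("FBA", {"f6p[c]": -1, "g3p[c]": 2}, genes=2, subsystem=glyc)
    for i in range(2, spec.n_parallel_paths + 1):
        b.rxn(f"FBA_alt{i}", {"f6p[c]": -1, "g3p[c]": 2}, genes=1, subsystem=glyc)
    # storage-carbohydrate overflow: excess imported glucose that neither
    # biomass nor product consumes leaves here (before the triose split)
    b.rxn("STO", {"g6p[c]": -1, "sto[c]": 1}, genes=2, subsystem=glyc)
    b.rxn("DM_sto", {"sto[c]": -1}, genes=0, subsystem="Transport/Exchange", kind="exchange")
    b.rxn("GAPDH", {"g3p[c]": -1, "pep[c]": 1}, genes=2, subsystem=glyc)
    b.rxn("PYK", {"pep[c]": -1, "pyr[c]": 1}, genes=2, subsystem=glyc)
    b.rxn("PDH", {"pyr[c]": -1, "accoa[c]": 1, "co2[c]": 1}, genes=2, subsystem=glyc)

    # pentose phosphate pathway
    if spec.include_pentose_path:
        b.rxn("G6PDH", {"g6p[c]": -1, "6pg[c]": 1}, subsystem="PPP")
        b.rxn("GND", {"6pg[c]": -1, "ru5p[c]": 1, "co2[c]": 1}, subsystem="PPP")
        b.rxn("RPI", {"ru5p[c]": -1, "r5p[c]": 1}, lb=-1000, subsystem="PPP")
        b.rxn("TKT", {"r5p[c]": -2, "f6p[c]": 1, "g3p[c]": 1}, subsystem="PPP")
        b.rxn("PRPPS", {"r5p[c]": -1, "prpp[c]": 1}, subsystem="Nucleotide")
    else:
        b.rxn("PRPPS", {"g6p[c]": -1, "prpp[c]": 1}, subsystem="Nucleotide")

    # open TCA branch: citrate -> isocitrate -> 2-oxoglutarate -> glutamate
    b.rxn("CS", {"accoa[c]": -1, "oaa[c]": -1, "cit[c]": 1}, subsystem="TCA")
    b.rxn("ACN", {"cit[c]": -1, "icit[c]": 1}, subsystem="TCA")
    cplx = f"{b.gene()} and {b.gene()}"
    b.rxn("ICDH", {"icit[c]": -1, "akg[c]": 1, "co2[c]": 1}, genes=cplx, subsystem="TCA")
    b.rxn("GLUDH", {"akg[c]": -1, "nh4[c]": -1, "glu[c]": 1}, subsystem="TCA")
    b.rxn("ANA", {"pep[c]": -1, "oaa[c]": 1}, subsystem="TCA")

    # nucleotide synthesis
    b.rxn("PURS", {"prpp[c]": -1, "imp[c]": 1}, subsystem="Nucleotide")
    b.rxn("NUCS", {"imp[c]": -1, "nuc[c]": 1}, subsystem="Nucleotide")

    # aspartate -> homoserine -> homocysteine -> methionine -> SAM
    met_sub = "Methionine/SAM"
    b.rxn("ASPTA", {"oaa[c]": -1, "nh4[c]": -1, "asp[c]": 1}, subsystem=met_sub)
    if spec.include_methionine_branch:
        b.rxn("HSD", {"asp[c]": -1, "hse[c]": 1}, subsystem=met_sub)
        b.rxn("HSK", {"hse[c]": -1, "hcy[c]": 1}, subsystem=met_sub)
        b.rxn("METS", {"hcy[c]": -1, "met[c]": 1}, subsystem=met_sub)
        b.rxn("SAMS", {"met[c]": -1, "sam[c]": 1}, subsystem=met_sub)
        b.rxn("SAHt", {"sah[c]": -1, "sah[e]": 1}, subsystem=TE, kind="transport")
        b.rxn("EX_sah", {"sah[e]": -1}, genes=0, subsystem=TE, kind="exchange")

    # product pathway: AHBA starter + malonyl units + UDP-glucose, then
    # n_product_steps tailoring steps (first three are SAM methylations)
    prod = "Product biosynthesis"
    b.rxn("UDPG", {"g6p[c]": -1, "udpg[c]": 1}, subsystem=prod)
    b.rxn("AHBAS", {"g3p[c]": -1, "pep[c]": -1, "ahba[c]": 1}, subsystem=prod)
    b.rxn(
        "PKS",
        {"ahba[c]": -0.5, "accoa[c]": -0.5, "udpg[c]": -0.2, "pre0[c]": 1},
        subsystem=prod,
    )
    for step in range(1, spec.n_product_steps + 1):
        src = f"pre{step - 1}[c]"
        dst = "ap3[c]" if step == spec.n_product_steps else f"pre{step}[c]"
        stoich = {src: -1, dst: 1}
        methylation = spec.include_methionine_branch and step <= 3
        if methylation:
            stoich.update({"sam[c]": -1 / 3, "sah[c]": 1 / 3})
        gene = "asm10" if step == 3 else 1
        b.rxn(f"MT{step}" if step <= 3 else f"TAIL{step}", stoich, genes=gene, subsystem=prod)
    # shunt consuming the first intermediate; knocked out in the high-yield strain
    b.rxn("ASM30", {"pre0[c]": -1, "apx[c]": 1}, genes="asm30", subsystem=prod)
    b.rxn("DM_apx", {"apx[c]": -1}, genes=0, subsystem=TE, kind="exchange")

    # biomass: glutamate (amino-acid pool) + nucleotides + storage
    # carbohydrate, plus small methionine/SAM maintenance demands
    biomass = {"glu[c]": -0.3, "nuc[c]": -0.3, "g6p[c]": -0.1}
    if spec.include_methionine_branch:
        biomass.update({"met[c]": -0.005, "sam[c]": -0.005})
    b.rxn("BIOMASS", biomass, genes=0, subsystem="Biomass", kind="biomass")

    model = MetabolicModel(
        metabolites=sorted(b.mets.values(), key=lambda m: m.id),
        reactions=b.reactions,
        biomass_reaction_id="BIOMASS",
        product_reaction_id="EX_ap3",
        substrate_exchange_id="EX_glc",
        name=f"toy_aspm_seed{spec.seed}",
    )
    model.validate()
    growth = solve_fba(model)
    product = solve_fba(model, {"EX_ap3": 1.0})
    if not (growth.optimal and growth.objective_value > 1e-6):
        raise RuntimeError("generator bug: toy model has no positive biomass optimum")
    if not (product.optimal and product.objective_value > 1e-6):
        raise RuntimeError("generator bug: toy model has no positive product optimum")
    return model


# --------------------------------------------------------------------------
# expression time courses
# --------------------------------------------------------------------------


@dataclass
class ExpressionSim:
    """Four-day FPKM simulation encoding the growth -> secondary shift."""

    conditions: Tuple[str, ...] = ("day1", "day2", "day3", "day5")
    growth_gene_trend: Tuple[float, ...] = (1.0, 0.15, 0.04, 0.01)
    secondary_gene_trend: Tuple[float, ...] = (0.05, 0.4, 1.5, 60.0)
    housekeeping_gene_trend: Tuple[float, ...] = (1.0, 0.95, 0.9, 0.85)
    noise_sigma: float = 0.3
    base_fpkm_range: Tuple[float, float] = (1.0, 1000.0)
    housekeeping_base_range: Tuple[float, float] = (500.0, 1000.0)
    #: the terminal methyltransferase is the pathway bottleneck: weakly
    #: expressed, so it is the reaction the E-FLUX cap actually pins
    bottleneck_gene: str = "asm10"
    bottleneck_base_range: Tuple[float, float] = (1.0, 3.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name, trend in (
            ("growth_gene_trend", self.growth_gene_trend),
            ("housekeeping_gene_trend", self.housekeeping_gene_trend),
        ):
            if list(trend) != sorted(trend, reverse=True):
                raise ValueError(f"{name} must be decreasing")
        if list(self.secondary_gene_trend) != sorted(self.secondary_gene_trend):
            raise ValueError("secondary_gene_trend must be increasing")
        n = len(self.conditions)
        for trend in (
            self.growth_gene_trend,
            self.secondary_gene_trend,
            self.housekeeping_gene_trend,
        ):
            if len(trend) != n:
                raise ValueError("trend length must match the number of conditions")


def gene_regulon(model: MetabolicModel, gene: str) -> str:
    """Which expression program a gene follows: ``secondary`` (rising),
    ``growth`` (decaying) or ``housekeeping`` (near-flat, highly expressed)."""
    secondary, growth = False, False
    for r in model.reactions_for_gene(gene):
        if r.id in _HOUSEKEEPING_REACTION_IDS:
            continue
        if r.subsystem in SECONDARY_SUBSYSTEMS or r.id in _SECONDARY_REACTION_IDS:
            secondary = True
        elif r.subsystem in ("TCA", "PPP", "Nucleotide"):
            growth = True
    if secondary:
        return "secondary"
    if growth:
        return "growth"
    return "housekeeping"


def make_expression(model: MetabolicModel, sim: Optional[ExpressionSim] = None) -> ExpressionProfile:
    """Seeded FPKM table: ``FPKM_i(day) = base_i * trend(regulon, day) *
    lognormal(0, noise_sigma)`` with log-uniform per-gene baselines."""
    sim = sim or ExpressionSim()
    rng = np.random.default_rng(sim.seed)
    trends = {
        "growth": sim.growth_gene_trend,
        "secondary": sim.secondary_gene_trend,
        "housekeeping": sim.housekeeping_gene_trend,
    }
    genes = sorted(model.genes)
    rows = []
    for gene in genes:
        regulon = gene_regulon(model, gene)
        if gene == sim.bottleneck_gene:
            lo, hi = sim.bottleneck_base_range
        elif regulon == "housekeeping":
            lo, hi = sim.housekeeping_base_range
        else:
            lo, hi = sim.base_fpkm_range

        base = math.exp(rng.uniform(math.log(lo), math.log(hi)))
        noise = (
            np.exp(rng.normal(0.0, sim.noise_sigma, size=len(sim.conditions)))
            if sim.noise_sigma > 0
            else np.ones(len(sim.conditions))
        )
        rows.append(base * np.asarray(trends[regulon]) * noise)
    values = pd.DataFrame(rows, index=genes, columns=list(sim.conditions))
    return ExpressionProfile(values=values)


def default_condition_specs() -> List[ConditionSpec]:
    """The four sampling days of the high-yield mutant fermentation.

    Glucose uptake comes from authored (consumption, DCW, interval)
    measurements; the product objective coefficients are the measured
    product:biomass ratios 0, 0.0013, 0.0068, 0.0084 of days 1/2/3/5.  The
    strain carries the shunt knockout (spelled ``ansa30`` to exercise the
    alias map).
    """
    measured = [
        ("day1", 0.0, {"consumption_g": 13.836, "dcw_g": 0.8, "hours": 24.0}),
        ("day2", 0.0013, {"consumption_g": 17.598, "dcw_g": 1.1, "hours": 24.0}),
        ("day3", 0.0068, {"consumption_g": 19.111, "dcw_g": 1.3, "hours": 24.0}),
        ("day5", 0.0084, {"consumption_g": 31.132, "dcw_g": 1.2, "hours": 48.0}),
    ]
    return [
        ConditionSpec(
            label=label,
            c_product=c,
            knockouts=frozenset({"ansa30"}),
            measurements=dict(m, molecular_weight=GLUCOSE_MW),
        )
        for label, c, m in measured
    ]


def emit_fixtures(
    out_dir,
    model: Optional[MetabolicModel] = None,
    profile: Optional[ExpressionProfile] = None,
    specs: Optional[Sequence[ConditionSpec]] = None,
    seed: int = 0,
) -> Dict[str, Path]:
    """Write the SBML + TSV model, expression TSV and condition YAML that the
    pipeline consumes; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model = model or make_toy_model(ToyModelSpec(seed=seed))
    profile = profile or make_expression(model, ExpressionSim(seed=seed))
    specs = list(specs) if specs is not None else default_condition_specs()

    paths = {
        "sbml": out_dir / "toy_model.xml",
        "tsv": out_dir / "toy_model.tsv",
        "expression": out_dir / "expression.tsv",
        "conditions": out_dir / "conditions.yaml",
    }
    write_model(model, paths["sbml"])
    write_model(model, paths["tsv"])
    profile.to_tsv(paths["expression"])
    payload = [
        {
            "label": s.label,
            "c_product": s.c_product,
            "knockouts": sorted(s.knockouts),
            "measurements": s.measurements,
        }
        for s in specs
    ]
    paths["conditions"].write_text(yaml.safe_dump(payload, sort_keys=False))
    return paths
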