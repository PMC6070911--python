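"""End-to-end pipeline: model stats, growth FBA, essentiality + enrichment,
condition-specific models, metabolic-shift reporting, and strain design.

Each stage writes TSV/JSON artifacts into the output directory and
contributes headline numbers to a machine-readable ``summary.json``.  The
whole run is deterministic for a fixed seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd
import yaml

from . import fba, optram
from .enrichment import enrich
from .expression import (
    ConditionSpec,
    ExpressionProfile,
    build_condition_model,
    call_active_reactions,
    flux_shift_report,
)
from .io import read_model
from .model import MetabolicModel, model_stats
from .synthetic import KNOCKOUT_ALIASES

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_condition_specs"]

#: reactions reported in the metabolic-shift table of the bundled toy system
DEFAULT_SHIFT_REACTIONS = ("CS", "ACN", "ICDH", "ASPTA", "METS", "SAMS", "MT3")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    model_path: Path
    expression_path: Path
    conditions_path: Path
    out_dir: Path
    seed: int = 0
    total_orfs: int = 7279  # genome ORF count for the coverage statistic
    influence_threshold: float = 0.01
    aliases: Dict[str, str] = field(default_factory=lambda: dict(KNOCKOUT_ALIASES))
    shift_reactions: Sequence[str] = DEFAULT_SHIFT_REACTIONS
    optram_iterations: int = 3000
    optram_restarts: int = 25

    def __post_init__(self) -> None:
        for name in ("model_path", "expression_path", "conditions_path", "out_dir"):
            setattr(self, name, Path(getattr(self, name)))


def load_condition_specs(path) -> List[ConditionSpec]:
    payload = yaml.safe_load(Path(path).read_text())
    specs = []
    for entry in payload:
        specs.append(
            ConditionSpec(
                label=entry["label"],
                c_product=float(entry.get("c_product", 0.0)),
                knockouts=frozenset(entry.get("knockouts", ())),
                measurements=entry.get("measurements"),
                glucose_uptake=entry.get("glucose_uptake"),
            )
        )
    return specs


def _write_enrichment(results, path: Path) -> None:
    pd.DataFrame(
        [
            {
                "subsystem": r.subsystem,
                "N": r.N,
                "M": r.M,
                "n": r.n,
                "m": r.m,
                "p_value": r.p_value,
                "bh_p": r.adjusted_p,
            }
            for r in results
        ]
    ).to_csv(path, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> Dict:
    """Run every stage on the configured inputs; returns the summary dict."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    summary: Dict = {"seed": config.seed}

    def stage(name):
        logger.info("stage %s", name)
        return time.time()

    # -- model + composition ------------------------------------------------
    t = stage("load")
    for path in (config.model_path, config.expression_path, config.conditions_path):
        if not path.exists():
            raise FileNotFoundError(path)
    model = read_model(config.model_path)
    profile = ExpressionProfile.from_tsv(config.expression_path)
    specs = load_condition_specs(config.conditions_path)

    stats = model_stats(model, total_orfs=config.total_orfs)
    summary["model"] = {
        "n_genes": stats.n_genes,
        "n_reactions": stats.n_reactions,
        "n_metabolites": stats.n_metabolites,
        "n_exchange": stats.n_exchange,
        "n_transport": stats.n_transport,
        "n_subsystems": stats.n_subsystems,
        "pct_orfs_in_model": stats.pct_orfs_in_model,
    }

    # -- growth and product capacity ---------------------------------------
    stage("fba")
    growth = fba.solve_pfba(model)
    product = fba.solve_fba(model, model.product_reaction_id)
    growth.fluxes.rename("flux").to_csv(out / "growth_fluxes.tsv", sep="\t")
    summary["fba"] = {
        "biomass_optimum": growth.objective_value,
        "product_optimum": product.objective_value,
    }

    # -- essentiality + enrichment ------------------------------------------
    stage("deletions")
    records = fba.single_gene_deletion_scan(
        model, influence_threshold=config.influence_threshold
    )
    pd.DataFrame(
        [
            {
                "gene": r.gene,
                "product_flux": r.product_flux,
                "relative_decrease": r.relative_decrease,
                "class": r.klass,
            }
            for r in records
        ]
    ).to_csv(out / "deletions.tsv", sep="\t", index=False)
    essential = sorted(r.gene for r in records if r.essential)
    influential = sorted(r.gene for r in records if r.influential)
    gene_subsystems = {
        g: sorted({r.subsystem for r in model.reactions_for_gene(g) if r.subsystem})
        for g in model.genes
    }
    gene_enrichment = enrich(model.genes, gene_subsystems, essential)
    _write_enrichment(gene_enrichment, out / "essential_gene_enrichment.tsv")
    summary["deletions"] = {
        "n_essential": len(essential),
        "n_influential": len(influential),
        "top_essential_subsystem": gene_enrichment[0].subsystem if gene_enrichment else None,
    }

    # -- condition-specific models -------------------------------------------
    stage("conditions")
    condition_models = [
        build_condition_model(model, profile, spec, aliases=config.aliases)
        for spec in specs
    ]
    flux_table = pd.DataFrame(
        {cm.label: cm.solution.fluxes for cm in condition_models}
    )
    flux_table.to_csv(out / "condition_fluxes.tsv", sep="\t", index_label="reaction")
    calls = call_active_reactions(condition_models)
    pd.DataFrame(
        [
            dict({"reaction": c.reaction, "condition": c.condition}, **c.normalized_flux)
            for c in calls
        ]
    ).to_csv(out / "active_reactions.tsv", sep="\t", index=False)

    subsystem_map = {r.id: r.subsystem for r in model.reactions}
    universe = [r.id for r in model.reactions if r.subsystem]
    per_day = {}
    for cm in condition_models:
        query = [c.reaction for c in calls if c.condition == cm.label]
        results = enrich(universe, subsystem_map, query) if query else []
        _write_enrichment(results, out / f"active_enrichment_{cm.label}.tsv")
        per_day[cm.label] = {
            "n_specific": len(query),
            "enriched": [r.subsystem for r in results if r.p_value < 0.05],
        }
    summary["conditions"] = {
        "labels": [cm.label for cm in condition_models],
        "biomass_flux": {
            cm.label: cm.solution.flux(model.biomass_reaction_id)
            for cm in condition_models
        },
        "product_flux": {
            cm.label: cm.solution.flux(model.product_reaction_id)
            for cm in condition_models
        },
        "per_day": per_day,
    }

    # -- methionine/TCA flux shift ------------------------------------------
    stage("shift")
    shift = flux_shift_report(
        condition_models, [r for r in config.shift_reactions if model.has_reaction(r)]
    )
    shift.to_csv(out / "flux_shift.tsv", sep="\t")

    # -- strain design --------------------------------------------------------
    stage("optram")
    cfg = optram.OptRAMConfig(
        iterations=config.optram_iterations,
        restarts=config.optram_restarts,
        seed=config.seed,
    )
    designs = optram.optimize(model, cfg)
    pd.DataFrame(
        [
            {
                "rank": i + 1,
                "objective_score": d.objective_score,
                "growth": d.growth,
                "product_target": d.product_target,
                "product_range": d.product_range,
                "n_modifications": d.n_modifications,
                "modifications": ";".join(
                    f"{g}:{c:+d}" for g, c in sorted(d.modifications.items())
                ),
            }
            for i, d in enumerate(designs)
        ]
    ).to_csv(out / "optram_solutions.tsv", sep="\t", index=False)
    best = designs[0]
    summary["optram"] = {
        "best_objective": best.objective_score,
        "best_product_target": best.product_target,
        "best_growth": best.growth,
        "best_modifications": {g: c for g, c in sorted(best.modifications.items())},
        "mean_objective": sum(d.objective_score for d in designs) / len(designs),
        "mean_product_target": sum(d.product_target for d in designs) / len(designs),
    }

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    logger.info("pipeline complete: %s", out / "summary.json")
    return summary
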