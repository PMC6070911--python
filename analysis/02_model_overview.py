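#!/usr/bin/env python
"""Model composition and metabolic capacity.

Loads the toy model, reports its composition (genes/reactions/metabolites,
exchanges, transports, subsystems, ORF coverage) and the FBA growth and
product optima, and writes results/model_overview.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from ansaflux.fba import solve_fba, solve_pfba
from ansaflux.io import read_model
from ansaflux.model import model_stats

ROOT = Path(__file__).resolve().parents[1]


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--model", type=Path, default=ROOT / "data" / "toy" / "toy_model.xml")
    parser.add_argument("--total-orfs", type=int, default=200,
                        help="assumed genome ORF count for the toy organism")
    parser.add_argument("--out", type=Path, default=ROOT / "results")
    args = parser.parse_args()

    model = read_model(args.model)
    stats = model_stats(model, total_orfs=args.total_orfs)
    growth = solve_pfba(model)
    product = solve_fba(model, model.product_reaction_id)

    rows = {
        "n_genes": stats.n_genes,
        "n_reactions": stats.n_reactions,
        "n_metabolites": stats.n_metabolites,
        "n_exchange": stats.n_exchange,
        "n_transport": stats.n_transport,
        "n_subsystems": stats.n_subsystems,
        "pct_orfs_in_model": stats.pct_orfs_in_model,
        "biomass_optimum_per_h": growth.objective_value,
        "product_optimum_mmol_gdw_h": product.objective_value,
    }
    args.out.mkdir(parents=True, exist_ok=True)
    pd.Series(rows, name="value").to_csv(args.out / "model_overview.tsv", sep="\t")

    print(f"model {model.name}: {stats.n_genes} genes, {stats.n_reactions} reactions, "
          f"{stats.n_metabolites} metabolites in {stats.n_subsystems} subsystems")
    print(f"  gene coverage: {stats.pct_orfs_in_model}% of {args.total_orfs} assumed ORFs")
    print(f"  max growth {growth.objective_value:.4f}/h; "
          f"max product {product.objective_value:.4f} mmol/gDW/h (glucose-limited)")


if __name__ == "__main__":
    main()
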