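# Methods

`ansaflux` reimplements a complete constraint-based analysis of ansamitocin
P-3 (AP-3) production in an actinomycete: flux balance analysis on a
genome-scale metabolic model (GSMM), validation by gene essentiality and
robustness scans, E-FLUX integration of fermentation-time transcriptomes
into condition-specific models, hypergeometric pathway enrichment, and
simulated-annealing strain design.  Because the organism's published GSMM
and transcriptome are not redistributable, the package ships a synthetic
generator that reproduces the *structure* of that study system at desk
scale; every analysis, test and acceptance number runs on it end to end.

## Constraint-based core

A model is the triple (S, bounds, GPRs): stoichiometric matrix `S`
(metabolites × reactions), flux bounds `lb ≤ v ≤ ub` in mmol/gDW/h
(±1000 for bounds given only as (ir)reversibility — the usual COBRA
convention), and boolean gene–protein–reaction rules.  FBA solves

    max c·v   s.t.  S·v = 0,  lb ≤ v ≤ ub

with HiGHS (`scipy.optimize.linprog`); feasibility/optimality tolerances
are 1e-9, relative comparisons 1e-6.  All *reported* flux vectors come from
parsimonious FBA — total absolute flux is minimized at the fixed optimum
(`c·v ≥ opt − 1e-6·max(1, |opt|)`) after splitting reversible reactions
into non-negative halves — so futile cycles carry no flux and results do
not depend on the solver's choice among alternate optima.  Flux variability
of a reaction is its LP min/max with the primary objective constrained to a
fraction of its optimum.

Single-gene deletions zero the bounds of every reaction whose GPR evaluates
false without the gene (AND = complex, OR = isozymes, empty rule =
spontaneous) and re-maximize the product flux.  A gene is *essential* when
the deletion removes more than 90% of the wild-type product optimum and
*influential* above a 1% threshold; the 90% cut is the established
convention for this system, while the 1% default is this package's choice
(it separates real decreases from solver noise) and is exposed as a
parameter.  Robustness
scans cap one reaction's upper bound on a uniform grid from 0 to its FVA
maximum and record the product optimum, flagging monotone curves.

## E-FLUX condition-specific models

Expression enters as a gene × condition FPKM matrix.  Each gene's level is
`exp_i = log(FPKM_i + 1)`; the log base defaults to 10 and only rescales
all bounds by a common factor.  A reaction's bound is the plain sum of its
genes' levels, `b_j = Σ_{i∈rxn_j} exp_i`, applied as the upper bound (and
`−b_j` as the lower bound when reversible); the min-over-AND / sum-over-OR
convention of the original E-FLUX formulation is available as
`mode="gpr"` but is off by default.  E-FLUX bounds are in expression units
and are applied as-is; they are caps relative to each other, not calibrated
rates.  Reactions without gene association (exchanges, biomass) keep their
default bounds.  Genes missing from the table are imputed with the
condition median so an absent measurement never blocks a reaction; the
imputation is logged.

A day-specific model additionally (i) applies strain knockouts through the
GPRs, with a user alias map for locus-name variants (`ansa30` ≡ `asm30`);
(ii) fixes the measured glucose uptake, `lb = ub = −R_glucose` with

    R_glucose = consumption / (DCW · MW_glucose · Δt) · 1000   [mmol/gDW/h]

and (iii) replaces the objective by `biomass + c · product`, where `c` is
the measured product:biomass ratio of that day.  The coupled objective is a
linear objective vector, not an edit of the biomass equation — equivalent
for the LP and reversible without touching the model.

Day-specific *active reactions*: per reaction, the across-day flux vector
is normalized by its maximum absolute value (all-zero rows stay 0; using
|flux| makes the call independent of the sign convention of reversible
reactions).  A reaction is specific to the day where |normalized flux|
exceeds 0.5 when no other day exceeds it — the peak day always normalizes
to 1, and a competing day at exactly 0.5 does not disqualify (the
boundary convention that keeps a (0, 0, 4, 8) profile specific to the last
day).  Flux-shift tables report per-day pFBA fluxes and each day's ratio to
day 1; flux appearing on a zero baseline is marked `inf` ("new").

## Enrichment

For a universe of N annotated ids with M_j in subsystem j, and a query of n
ids overlapping m, the p-value is the hypergeometric upper tail
P(X ≥ m) via `scipy.stats.hypergeom.sf`.  Only subsystems with m ≥ 1 are
tested; Benjamini–Hochberg adjusted p-values are reported alongside, but
ranking uses the raw p.  Gene queries use all model genes as the universe;
reaction queries use the subsystem-annotated reactions (unannotated
reactions are excluded because membership is the tested property).  Ids
annotated to several pathways count once per pathway.

## Strain design (simulated annealing)

Perturbations are integer codes with fold changes 2/4/8/16/32 (codes 1–5),
1/2 … 1/32 (−1 … −5) and knockout (0).  They act on bounds relative to the
wild-type pFBA reference flux `v_ref` of each affected reaction: up-codes
force `|v| ≥ FC·v_ref` (a no-op where the reference is zero), down-codes cap
`|v| ≤ FC·v_ref` but only where the gene is required by the GPR (isozymes
rescue OR-rules), knockouts zero required reactions outright.  Inconsistent
bounds make the candidate score 0.

Candidates are scored by

    Obj = (Target · Growth / Substrate) · (1 − log10(Range / Target)),
    Target = (Vmax + Vmin)/2,   Range = (Vmax − Vmin)/2,

with (Vmin, Vmax) the product's flux variability at 100% of the candidate's
growth optimum, Growth its FBA optimum, and Substrate the |pFBA substrate
uptake|.  The grouping rewards *coupling*: a product forced at the growth
optimum (small Range) multiplies the biomass–product yield by up to
`1 − log10(ε) = 7`, Range being floored at `ε·Target` with ε = 1e-6.  The
log base, ε, and the FVA growth fraction (100%) are configurable; dead or
product-free candidates score 0 rather than erroring.

The search is a Metropolis annealer: propose a uniform (gene, code) pair
over genes whose reactions carry nonzero reference flux (re-proposing a
modified gene overwrites its code; beyond `max_modifications` = 6 a random
existing edit is dropped first), accept when Δf > 0 and otherwise with
probability `exp(Δf/T)`, and cool geometrically `T(k) = T0·α^k`.  Defaults
are T0 = 2.0, α = 0.999, 3000 iterations, 25 independent seeded restarts.
The slow schedule matters: the landscape contains a deep local basin in
which growth is throttled by stacked down-codes to buy coupling, and a fast
quench strands 20–40% of restarts there, while the slow schedule reaches
the exhaustive single-modification optimum in 25/25 restarts over four
independent seed sets.  Each restart's best solution is finally pruned by
greedily dropping modifications that do not change its score — the
implementation-cost part of the ranking (objective desc, fewer edits,
growth desc).  Candidate evaluation runs on a persistent, warm-started GLPK
problem (swiglpk) holding the stoichiometry fixed and mutating only bounds
(exactly four LP solves per candidate), with a scipy/HiGHS fallback;
the two paths were verified score-identical on random modification sets.

## The synthetic study system

`make_toy_model` builds a ~47-reaction GSMM with the architecture of an
AP-3 producer: glucose uptake and glycolysis (constitutive isozyme pairs),
pentose phosphate pathway feeding nucleotide synthesis, an open TCA branch
(citrate → isocitrate → 2-oxoglutarate → glutamate) with anaplerotic
PEP → oxaloacetate, an aspartate → homoserine → homocysteine → methionine →
SAM branch, and a product pathway (AHBA starter + malonyl units +
UDP-glucose, then three SAM-dependent methylations, the last owned by a
dedicated `asm10` gene, plus an optional tailoring step).  A shunt gene
(`asm30`) drains the first intermediate and is knocked out in the
high-yield strain.  Biomass consumes glutamate, nucleotides, storage
carbohydrate and small methionine/SAM maintenance amounts.  Pyruvate
overflow, CO2 export and a storage-carbohydrate drain before the triose
split guarantee that a fixed measured uptake is always routable.  Deleting
`asm10` (or any single-copy methionine-branch gene) zeroes the product;
glycolytic entry genes are isozyme pairs and individually neutral.

`make_expression` draws per-gene baseline FPKM log-uniformly in [1, 1000]
and applies per-day multipliers with multiplicative lognormal noise
(σ = 0.3): growth program (TCA, PPP, nucleotide) 1 / 0.15 / 0.04 / 0.01
across days 1/2/3/5; secondary program (methionine/SAM, product pathway,
product and by-product exporters) 0.05 / 0.4 / 1.5 / 60; constitutive
carbon backbone (glycolysis, transporters, anaplerosis) 1 / 0.95 / 0.9 /
0.85 with baselines in [500, 1000] so the fixed uptake stays feasible under
the E-FLUX caps.  The `asm10` methyltransferase gets a low baseline in
[1, 3]: it plays the pathway bottleneck, the role its real counterpart is
known for, which pins the product flux to a single interpretable
constraint and keeps the day-3:day-5 flux ratio well below the 0.5
specificity cut.  Condition specs carry authored measurements giving uptake
rates 4.0 / 3.7 / 3.4 / 3.0 mmol/gDW/h, product objective coefficients
c = 0 / 0.0013 / 0.0068 / 0.0084, and the `ansa30` knockout spelling to
exercise the alias map.

What the generator does *not* emulate: mass/charge balance and cofactor
(ATP/NAD) accounting, realistic FPKM dispersion models, growth-rate
dependence of biomass composition, and absolute flux scales.  Passing
tests therefore demonstrate that the pipeline's logic recovers a planted
growth → secondary-metabolism shift and finds planted design optima — not
that it would quantitatively reproduce a particular organism's fluxes.

## Problem sizes and determinism

Tests and the acceptance script use desk-scale problems chosen for the
package's own test economy: 200 random ≤6-reaction models for the LP
oracle, exhaustive hypergeometric enumeration to N = 12, 10,000 Metropolis
trials, 25–50 seeded replicates for the shift recovery, and 25 annealing
restarts.  Every stochastic component consumes a `numpy` SeedSequence
derived from a single seed; identical seeds give byte-identical pipeline
summaries.  GLPK and HiGHS may pick different vertices among alternate
optima; all asserted quantities are optima, pFBA-unique fluxes, or
tolerance-bounded, so results agree across the two backends.

## Known limitations

- The influential-gene threshold (1%) is a documented guess; the source
  study's influential/essential split cannot be reproduced without it.
- E-FLUX bounds mix expression units with mmol/gDW/h uptake constraints;
  only relative per-day comparisons are meaningful.  An optional
  normalize-to-default-cap rescaling is provided for unit sanity.
- On the toy system the generic model outperforms the decline-phase model
  in absolute designed product flux, because the generic model's substrate
  bound (10 mmol/gDW/h) exceeds the fixed day-5 uptake (3.0); the
  decline-phase comparison is therefore a demonstration of mechanics, not
  a reproduction of the corresponding full-scale result.
- SBML round-trips carry subsystem labels and reaction kinds in notes
  (cobra 0.32 does not serialize subsystems as groups); third-party SBML
  without such notes loses no data but gets inferred kinds and empty
  subsystems, and reactions without subsystems are excluded from
  enrichment universes.
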