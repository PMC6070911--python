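"""Readers and writers for metabolic models.

Two on-disk dialects are supported:

* **SBML Level 3 + fbc** via cobrapy/libsbml: flux bounds as fbc parameters,
  ``geneProductAssociation`` for GPRs, ``fbc:objective`` for the biomass
  reaction.  Subsystem labels and reaction kinds travel in SBML reaction
  notes, and the biomass/product/substrate designators in model notes (cobra
  does not serialize ``Reaction.subsystem`` itself).
* **A tabular TSV dialect** with one reaction per row (columns ``id``,
  ``equation``, ``lb``, ``ub``, ``gpr``, ``subsystem``, ``kind``) and ``#!``
  directives naming the biomass/product/substrate reactions.  Metabolites use
  ``name[compartment]`` tokens, e.g. ``1 glc[e] + 2 atp[c] -> ...``.

Both round-trip stoichiometry, bounds, GPR trees and subsystem labels
exactly.
"""

from __future__ import annotations

import math
import re
from pathlib import Path
from typing import Dict, Optional

import libsbml

from .gpr import Gpr
from .model import DEFAULT_BOUND, MetabolicModel, Metabolite, ModelError, Reaction

__all__ = ["read_model", "write_model", "FormatError", "to_cobra", "from_cobra"]


class FormatError(ValueError):
    """Raised when a model file cannot be parsed in the declared format."""


# --------------------------------------------------------------------------
# TSV dialect
# --------------------------------------------------------------------------

_TSV_COLUMNS = ("id", "equation", "lb", "ub", "gpr", "subsystem", "kind")
_ARROWS = ("<->", "<=>", "->", "=>")
_MET_TOKEN = re.compile(r"^(?P<name>.+)\[(?P<comp>[^\[\]]+)\]$")


def _met_id(name: str, comp: str) -> str:
    return f"{name}[{comp}]"


def _parse_side(text: str, sign: int, stoich: Dict[str, float], rxn_id: str) -> None:
    text = text.strip()
    if not text:
        return
    for term in text.split("+"):
        term = term.strip()
        if not term:
            raise FormatError(f"reaction {rxn_id}: empty term in equation")
        parts = term.split()
        if len(parts) == 1:
            coef, token = 1.0, parts[0]
        elif len(parts) == 2:
            try:
                coef = float(parts[0])
            except ValueError:
                raise FormatError(
                    f"reaction {rxn_id}: bad coefficient {parts[0]!r}"
                ) from None
            token = parts[1]
        else:
            raise FormatError(f"reaction {rxn_id}: cannot parse term {term!r}")
        m = _MET_TOKEN.match(token)
        if not m:
            raise FormatError(
                f"reaction {rxn_id}: metabolite token {token!r} is not 'name[compartment]'"
            )
        mid = _met_id(m.group("name"), m.group("comp"))
        stoich[mid] = stoich.get(mid, 0.0) + sign * coef


def _parse_equation(eq: str, rxn_id: str) -> Dict[str, float]:
    for arrow in _ARROWS:
        if arrow in eq:
            left, right = eq.split(arrow, 1)
            break
    else:
        raise FormatError(f"reaction {rxn_id}: no reaction arrow in equation {eq!r}")
    stoich: Dict[str, float] = {}
    _parse_side(left, -1, stoich, rxn_id)
    _parse_side(right, +1, stoich, rxn_id)
    return {k: v for k, v in stoich.items() if v != 0.0}


def _format_equation(rxn: Reaction) -> str:
    def fmt(items) -> str:
        terms = []
        for mid, coef in items:
            coef_s = f"{abs(coef):g}"
            terms.append(f"{coef_s} {mid}")
        return " + ".join(terms)

    subs = sorted((m, c) for m, c in rxn.stoichiometry.items() if c < 0)
    prods = sorted((m, c) for m, c in rxn.stoichiometry.items() if c > 0)
    arrow = "<->" if rxn.reversible else "->"
    return f"{fmt(subs)} {arrow} {fmt(prods)}".strip()


def _read_tsv(path: Path) -> MetabolicModel:
    directives: Dict[str, str] = {}
    header: Optional[list[str]] = None
    reactions: list[Reaction] = []
    mets: Dict[str, Metabolite] = {}
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#!"):
            key, _, value = line[2:].partition("=")
            directives[key.strip()] = value.strip()
            continue
        if line.startswith("#"):
            continue
        cells = line.split("\t")
        if header is None:
            header = [c.strip() for c in cells]
            missing = set(_TSV_COLUMNS) - set(header)
            if missing:
                raise FormatError(f"{path}: missing TSV columns {sorted(missing)}")
            continue
        row = dict(zip(header, cells))
        rid = row.get("id", "").strip()
        if not rid:
            raise FormatError(f"{path}:{lineno}: missing reaction id")
        for bound_col in ("lb", "ub"):
            if not row.get(bound_col, "").strip():
                raise FormatError(f"{path}:{lineno}: reaction {rid} missing {bound_col}")
        try:
            lb, ub = float(row["lb"]), float(row["ub"])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: reaction {rid} has non-numeric bounds") from None
        stoich = _parse_equation(row["equation"], rid)
        for mid in stoich:
            if mid not in mets:
                m = _MET_TOKEN.match(mid)
                assert m is not None
                mets[mid] = Metabolite(id=mid, name=m.group("name"), compartment=m.group("comp"))
        reactions.append(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=Gpr.parse(row.get("gpr", "")),
                subsystem=row.get("subsystem", "").strip(),
                kind=row.get("kind", "internal").strip() or "internal",
            )
        )
    model = MetabolicModel(
        metabolites=sorted(mets.values(), key=lambda m: m.id),
        reactions=reactions,
        biomass_reaction_id=directives.get("biomass", ""),
        product_reaction_id=directives.get("product", ""),
        substrate_exchange_id=directives.get("substrate", ""),
        name=directives.get("name", path.stem),
    )
    model.validate()
    return model


def _write_tsv(model: MetabolicModel, path: Path) -> None:
    lines = [
        f"#! name={model.name}",
        f"#! biomass={model.biomass_reaction_id}",
        f"#! product={model.product_reaction_id}",
        f"#! substrate={model.substrate_exchange_id}",
        "\t".join(_TSV_COLUMNS),
    ]
    for r in model.reactions:
        lines.append(
            "\t".join(
                [
                    r.id,
                    _format_equation(r),
                    f"{r.lower_bound:g}",
                    f"{r.upper_bound:g}",
                    r.gpr.to_string(),
                    r.subsystem,
                    r.kind,
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# --------------------------------------------------------------------------
# SBML via cobrapy
# --------------------------------------------------------------------------


def to_cobra(model: MetabolicModel):
    """Convert to a cobrapy model (used for SBML serialization and as the
    bridge for independent cross-checks)."""
    import cobra

    cm = cobra.Model(model.name or "model")
    cmets = {}
    for m in model.metabolites:
        cmets[m.id] = cobra.Metabolite(m.id, name=m.name, compartment=m.compartment)
    for r in model.reactions:
        cr = cobra.Reaction(r.id)
        cm.add_reactions([cr])
        cr.add_metabolites({cmets[mid]: coef for mid, coef in r.stoichiometry.items()})
        cr.bounds = (r.lower_bound, r.upper_bound)
        cr.gene_reaction_rule = r.gpr.to_string()
        cr.subsystem = r.subsystem
        cr.notes["subsystem"] = r.subsystem
        cr.notes["kind"] = r.kind
    if model.biomass_reaction_id:
        cm.objective = model.biomass_reaction_id
    cm.notes["biomass"] = model.biomass_reaction_id
    cm.notes["product"] = model.product_reaction_id
    cm.notes["substrate"] = model.substrate_exchange_id
    return cm


def _infer_kind(cr) -> str:
    if len(cr.metabolites) <= 1:
        return "exchange"
    comps = {m.compartment for m in cr.metabolites}
    if len(comps) > 1:
        return "transport"
    return "internal"


def from_cobra(
    cm,
    biomass_reaction_id: str = "",
    product_reaction_id: str = "",
    substrate_exchange_id: str = "",
) -> MetabolicModel:
    notes = dict(cm.notes or {})
    biomass = biomass_reaction_id or notes.get("biomass", "")
    if not biomass:
        # fall back to the fbc objective
        for r in cm.reactions:
            if r.objective_coefficient:
                biomass = r.id
                break
    mets = [
        Metabolite(id=m.id, name=m.name or m.id, compartment=m.compartment or "c")
        for m in cm.metabolites
    ]
    reactions = []
    for cr in cm.reactions:
        rnotes = dict(cr.notes or {})
        kind = rnotes.get("kind", "")
        if kind not in ("internal", "exchange", "transport", "biomass"):
            kind = "biomass" if cr.id == biomass else _infer_kind(cr)
        lb = max(cr.lower_bound, -DEFAULT_BOUND) if math.isfinite(cr.lower_bound) else -DEFAULT_BOUND
        ub = min(cr.upper_bound, DEFAULT_BOUND) if math.isfinite(cr.upper_bound) else DEFAULT_BOUND
        reactions.append(
            Reaction(
                id=cr.id,
                stoichiometry={m.id: coef for m, coef in cr.metabolites.items()},
                lower_bound=lb,
                upper_bound=ub,
                gpr=Gpr.parse(cr.gene_reaction_rule),
                subsystem=rnotes.get("subsystem", cr.subsystem or ""),
                kind=kind,
            )
        )
    model = MetabolicModel(
        metabolites=mets,
        reactions=reactions,
        biomass_reaction_id=biomass,
        product_reaction_id=product_reaction_id or notes.get("product", ""),
        substrate_exchange_id=substrate_exchange_id or notes.get("substrate", ""),
        name=cm.id or "",
    )
    model.validate()
    return model


def _validate_sbml_bounds(path: Path) -> None:
    """Reject SBML files without explicit fbc flux bounds (no silent defaults)."""
    doc = libsbml.readSBMLFromString(path.read_text(encoding="utf-8"))
    if doc.getNumErrors() > 0:
        for i in range(doc.getNumErrors()):
            err = doc.getError(i)
            if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
                raise FormatError(f"{path}: SBML parse error: {err.getMessage().strip()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise FormatError(f"{path}: file contains no SBML model")
    for i in range(sbml_model.getNumReactions()):
        rxn = sbml_model.getReaction(i)
        fbc = rxn.getPlugin("fbc")
        if fbc is None or not fbc.isSetLowerFluxBound() or not fbc.isSetUpperFluxBound():
            raise FormatError(
                f"{path}: reaction {rxn.getId()!r} lacks explicit fbc flux bounds"
            )


def _read_sbml(path: Path, **designators: str) -> MetabolicModel:
    import cobra

    _validate_sbml_bounds(path)
    try:
        cm = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # cobra raises a mix of exception types
        raise FormatError(f"{path}: cannot parse SBML: {exc}") from exc
    return from_cobra(cm, **designators)


def _write_sbml(model: MetabolicModel, path: Path) -> None:
    import cobra

    cobra.io.write_sbml_model(to_cobra(model), str(path))


# --------------------------------------------------------------------------
# dispatch
# --------------------------------------------------------------------------


def _infer_format(path: Path) -> str:
    if path.suffix.lower() in (".xml", ".sbml"):
        return "sbml"
    if path.suffix.lower() in (".tsv", ".txt"):
        return "tsv"
    raise FormatError(f"cannot infer model format from extension {path.suffix!r}")


def read_model(path, format: Optional[str] = None, **designators: str) -> MetabolicModel:
    """Read a model from SBML-fbc or the TSV dialect.

    ``designators`` may override ``biomass_reaction_id`` /
    ``product_reaction_id`` / ``substrate_exchange_id`` when the file does not
    carry them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "sbml":
        return _read_sbml(path, **designators)
    if fmt == "tsv":
        model = _read_tsv(path)
        for attr, value in designators.items():
            if value:
                setattr(model, attr, value)
        model.validate()
        return model
    raise FormatError(f"unknown model format {fmt!r}")


def write_model(model: MetabolicModel, path, format: Optional[str] = None) -> None:
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "sbml":
        _write_sbml(model, path)
    elif fmt == "tsv":
        _write_tsv(model, path)
    else:
        raise FormatError(f"unknown model format {fmt!r}")
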