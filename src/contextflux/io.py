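"""Network I/O.

The native on-disk form is a small JSON dialect (schema below); SBML Level 3
with the FBC package is supported as a compatibility path for models coming
from standard reconstruction tools.

JSON dialect::

    {
      "name": "...",                      # optional
      "objective": "<biomass reaction id>",
      "genes": ["g1", ...],
      "metabolites": [
        {"id": "A_c", "name": "...", "compartment": "c"}, ...
      ],
      "reactions": [
        {"id": "R1",
         "stoichiometry": {"A_c": -1.0, "B_c": 1.0},
         "lower_bound": 0.0, "upper_bound": 1000.0,
         "gpr": "g1 and (g2 or g3)",      # "" for the empty rule
         "subsystem": "",
         "is_exchange": false}, ...
      ]
    }

Writing is canonical (2-space indent, fixed key order, trailing newline) and
preserves metabolite/reaction order, so write->read is the identity on every
field and read->write is byte-identity for canonical files.

The SBML path preserves stoichiometry, bounds, compartments, GPRs, the gene
list and the FBC objective; the ``is_exchange`` flag maps to/from the
conventional ``EX_`` id prefix and ``subsystem`` is not carried.
"""

from __future__ import annotations

import json
from pathlib import Path

import libsbml

from .errors import NetworkParseError
from .gpr import Gpr, GprAnd, GprLeaf, GprNode, GprOr, parse_gpr
from .network import COMPARTMENTS, MetabolicNetwork, Metabolite, Reaction

__all__ = [
    "read_network",
    "write_network",
    "read_json",
    "write_json",
    "read_sbml",
    "write_sbml",
    "network_to_json_dict",
    "export_reaction_table",
    "export_metabolite_table",
]


def read_network(path: str | Path, format: str = "json") -> MetabolicNetwork:
    """Read a network from ``path`` in the declared format ("json"/"sbml")."""
    if format == "json":
        return read_json(path)
    if format == "sbml":
        return read_sbml(path)
    raise ValueError(f"unknown network format {format!r}")


def write_network(network: MetabolicNetwork, path: str | Path, format: str = "json") -> None:
    if format == "json":
        write_json(network, path)
    elif format == "sbml":
        write_sbml(network, path)
    else:
        raise ValueError(f"unknown network format {format!r}")


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def network_to_json_dict(network: MetabolicNetwork) -> dict:
    return {
        "name": network.name,
        "objective": network.objective_id,
        "genes": sorted(network.genes),
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in network.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": {k: float(v) for k, v in r.stoichiometry.items()},
                "lower_bound": float(r.lower_bound),
                "upper_bound": float(r.upper_bound),
                "gpr": r.gpr.to_string(),
                "subsystem": r.subsystem,
                "is_exchange": bool(r.is_exchange),
            }
            for r in network.reactions
        ],
    }


def _network_from_json_dict(doc: dict) -> MetabolicNetwork:
    try:
        metabolites = [
            Metabolite(id=m["id"], compartment=m["compartment"], name=m.get("name", ""))
            for m in doc["metabolites"]
        ]
        reactions = [
            Reaction(
                id=r["id"],
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                lower_bound=float(r["lower_bound"]),
                upper_bound=float(r["upper_bound"]),
                gpr=parse_gpr(r.get("gpr", "")),
                subsystem=r.get("subsystem", ""),
                is_exchange=bool(r.get("is_exchange", False)),
            )
            for r in doc["reactions"]
        ]
        genes = frozenset(doc.get("genes", []))
        objective = doc["objective"]
        name = doc.get("name", "")
    except (KeyError, TypeError, ValueError) as exc:
        raise NetworkParseError(f"malformed network JSON: {exc}") from exc
    return MetabolicNetwork(metabolites, reactions, genes, objective, name)


def read_json(path: str | Path) -> MetabolicNetwork:
    try:
        doc = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise NetworkParseError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise NetworkParseError(f"{path}: top level must be a JSON object")
    return _network_from_json_dict(doc)


def write_json(network: MetabolicNetwork, path: str | Path) -> None:
    text = json.dumps(network_to_json_dict(network), indent=2, sort_keys=False)
    Path(path).write_text(text + "\n")


# ---------------------------------------------------------------------------
# SBML Level 3 + FBC
# ---------------------------------------------------------------------------

def _check(value: int, what: str) -> None:
    if value != libsbml.LIBSBML_OPERATION_SUCCESS:
        raise NetworkParseError(f"libsbml error while {what} (code {value})")


def _gpr_to_fbc(node: GprNode, fbc_assoc_parent, gene_sids: dict[str, str]):
    if isinstance(node, GprLeaf):
        ref = fbc_assoc_parent.createGeneProductRef()
        ref.setGeneProduct(gene_sids[node.gene])
    elif isinstance(node, GprAnd):
        assoc = fbc_assoc_parent.createAnd()
        for child in node.children:
            _gpr_to_fbc(child, assoc, gene_sids)
    elif isinstance(node, GprOr):
        assoc = fbc_assoc_parent.createOr()
        for child in node.children:
            _gpr_to_fbc(child, assoc, gene_sids)


def _fbc_to_gpr(assoc, sid_to_gene: dict[str, str]) -> GprNode:
    if assoc.isGeneProductRef():
        return GprLeaf(sid_to_gene[assoc.getGeneProduct()])
    children = tuple(
        _fbc_to_gpr(assoc.getAssociation(i), sid_to_gene)
        for i in range(assoc.getNumAssociations())
    )
    if assoc.isFbcAnd():
        return GprAnd(children)
    if assoc.isFbcOr():
        return GprOr(children)
    raise NetworkParseError("unsupported FBC association node")


def _sid(raw: str) -> str:
    """Map an id to a valid SBML SId (prefix, non-word chars -> underscore)."""
    cleaned = "".join(ch if (ch.isalnum() or ch == "_") else "_" for ch in raw)
    return "x_" + cleaned


def write_sbml(network: MetabolicNetwork, path: str | Path) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    model = doc.createModel()
    model.setId(_sid(network.name or "model"))
    mplug = model.getPlugin("fbc")
    mplug.setStrict(True)

    for code in sorted({m.compartment for m in network.metabolites}):
        comp = model.createCompartment()
        comp.setId(code)
        comp.setName(COMPARTMENTS[code])
        comp.setConstant(True)

    for m in network.metabolites:
        sp = model.createSpecies()
        sp.setId(_sid(m.id))
        sp.setName(m.name or m.id)
        sp.setCompartment(m.compartment)
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)

    gene_sids = {g: _sid(g) for g in sorted(network.genes)}
    for gene, sid in gene_sids.items():
        gp = mplug.createGeneProduct()
        gp.setId(sid)
        gp.setLabel(gene)

    # flux bounds live in global parameters per FBC
    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            par = model.createParameter()
            par.setId(pid)
            par.setValue(float(value))
            par.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for r in network.reactions:
        rx = model.createReaction()
        rx.setId(_sid(r.id))
        rx.setName(r.id)
        rx.setFast(False)
        rx.setReversible(r.lower_bound < 0)
        for met_id, coeff in r.stoichiometry.items():
            if coeff < 0:
                ref = rx.createReactant()
                ref.setStoichiometry(-float(coeff))
            else:
                ref = rx.createProduct()
                ref.setStoichiometry(float(coeff))
            ref.setSpecies(_sid(met_id))
            ref.setConstant(True)
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(r.lower_bound))
        rplug.setUpperFluxBound(bound_param(r.upper_bound))
        if not r.gpr.is_empty:
            gpa = rplug.createGeneProductAssociation()
            _gpr_to_fbc(r.gpr.root, gpa, gene_sids)

    objective = mplug.createObjective()
    objective.setId("obj")
    objective.setType("maximize")
    fo = objective.createFluxObjective()
    fo.setReaction(_sid(network.objective_id))
    fo.setCoefficient(1.0)
    mplug.setActiveObjectiveId("obj")

    if not libsbml.writeSBMLToFile(doc, str(path)):
        raise NetworkParseError(f"could not write SBML to {path}")


def read_sbml(path: str | Path) -> MetabolicNetwork:
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise NetworkParseError(
            f"{path}: {doc.getError(0).getMessage().strip()}"
        )
    model = doc.getModel()
    if model is None:
        raise NetworkParseError(f"{path}: no model element")
    mplug = model.getPlugin("fbc")
    if mplug is None:
        raise NetworkParseError(f"{path}: FBC package data missing")

    def unsid(sid: str) -> str:
        return sid[2:] if sid.startswith("x_") else sid

    metabolites = []
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        metabolites.append(
            Metabolite(
                id=unsid(sp.getId()),
                compartment=sp.getCompartment(),
                name=sp.getName() if sp.getName() != unsid(sp.getId()) else "",
            )
        )

    sid_to_gene = {}
    for i in range(mplug.getNumGeneProducts()):
        gp = mplug.getGeneProduct(i)
        sid_to_gene[gp.getId()] = gp.getLabel() or unsid(gp.getId())

    params = {
        model.getParameter(i).getId(): model.getParameter(i).getValue()
        for i in range(model.getNumParameters())
    }

    reactions = []
    for i in range(model.getNumReactions()):
        rx = model.getReaction(i)
        rid = unsid(rx.getId())
        stoich: dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            met = unsid(ref.getSpecies())
            stoich[met] = stoich.get(met, 0.0) - ref.getStoichiometry()
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            met = unsid(ref.getSpecies())
            stoich[met] = stoich.get(met, 0.0) + ref.getStoichiometry()
        rplug = rx.getPlugin("fbc")
        try:
            lb = params[rplug.getLowerFluxBound()]
            ub = params[rplug.getUpperFluxBound()]
        except KeyError as exc:
            raise NetworkParseError(f"{path}: unresolved flux bound on {rid}") from exc
        gpa = rplug.getGeneProductAssociation()
        gpr = (
            Gpr(_fbc_to_gpr(gpa.getAssociation(), sid_to_gene))
            if gpa is not None
            else Gpr(None)
        )
        reactions.append(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=gpr,
                is_exchange=rid.startswith("EX_"),
            )
        )

    objective = mplug.getActiveObjective()
    if objective is None or objective.getNumFluxObjectives() == 0:
        raise NetworkParseError(f"{path}: no active FBC objective")
    objective_id = unsid(objective.getFluxObjective(0).getReaction())

    genes = frozenset(sid_to_gene.values())
    return MetabolicNetwork(
        metabolites, reactions, genes, objective_id, unsid(model.getId())
    )


# ---------------------------------------------------------------------------
# TSV exports
# ---------------------------------------------------------------------------

def _equation(rxn: Reaction) -> str:
    lhs = " + ".join(
        f"{-c:g} {m}" for m, c in sorted(rxn.stoichiometry.items()) if c < 0
    )
    rhs = " + ".join(
        f"{c:g} {m}" for m, c in sorted(rxn.stoichiometry.items()) if c > 0
    )
    arrow = "<=>" if rxn.reversible else "-->"
    return f"{lhs} {arrow} {rhs}".strip()


def export_reaction_table(network: MetabolicNetwork, path: str | Path) -> None:
    lines = ["id\tlower_bound\tupper_bound\tgpr\tsubsystem\tis_exchange\tequation"]
    for r in network.reactions:
        lines.append(
            f"{r.id}\t{r.lower_bound:g}\t{r.upper_bound:g}\t{r.gpr.to_string()}"
            f"\t{r.subsystem}\t{int(r.is_exchange)}\t{_equation(r)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def export_metabolite_table(network: MetabolicNetwork, path: str | Path) -> None:
    lines = ["id\tname\tcompartment"]
    for m in network.metabolites:
        lines.append(f"{m.id}\t{m.name}\t{m.compartment}")
    Path(path).write_text("\n".join(lines) + "\n")
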