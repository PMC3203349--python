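"""SBML Level 3 import/export via libsbml.

Reversibility uses the SBML ``reversible`` attribute; organism tags,
pathway labels, reaction flags and elemental formulas — which have no
core-SBML representation — travel in structured notes.  Unknown SBML
constructs are ignored with a logged warning.
"""

from __future__ import annotations

import logging
from fractions import Fraction

import libsbml

from pnsbflux.core import (
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
    SPECIES_TAGS,
    format_formula,
    parse_formula,
)

__all__ = ["read_sbml", "write_sbml", "SbmlError"]

log = logging.getLogger(__name__)


class SbmlError(ValueError):
    pass


def _notes_xml(fields: dict[str, str]) -> str:
    body = "".join(
        f"<p>{k}: {v}</p>" for k, v in fields.items() if v
    )
    return (
        '<notes><body xmlns="http://www.w3.org/1999/xhtml">'
        f"{body}</body></notes>"
    )


def _parse_notes(node) -> dict[str, str]:
    fields: dict[str, str] = {}
    if node is None or not node.isSetNotes():
        return fields
    text = node.getNotesString()
    for line in text.replace("</p>", "\n").splitlines():
        line = line.split(">")[-1].strip()
        if ":" in line:
            k, v = line.split(":", 1)
            fields[k.strip()] = v.strip()
    return fields


def write_sbml(model: MetabolicModel, path) -> None:
    doc = libsbml.SBMLDocument(3, 1)
    sm = doc.createModel()
    sm.setId(model.name or "model")
    comp = sm.createCompartment()
    comp.setId("cell")
    comp.setConstant(True)

    for met in model.metabolites:
        sp = sm.createSpecies()
        sp.setId(met.id)
        sp.setName(met.name or met.id)
        sp.setCompartment("cell")
        sp.setBoundaryCondition(met.external)
        sp.setHasOnlySubstanceUnits(True)
        sp.setConstant(False)
        notes = {}
        if met.formula:
            notes["formula"] = format_formula(met.formula)
        if notes:
            sp.setNotes(_notes_xml(notes))

    for rxn in model.reactions:
        sr = sm.createReaction()
        sr.setId(rxn.id)
        sr.setName(rxn.name or rxn.id)
        sr.setReversible(rxn.reversible)
        sr.setFast(False)
        for mid, coeff in sorted(rxn.stoich.items()):
            ref = sr.createReactant() if coeff < 0 else sr.createProduct()
            ref.setSpecies(mid)
            ref.setStoichiometry(float(abs(coeff)))
            ref.setConstant(True)
        flags = ",".join(
            k for k, v in (("exchange", rxn.is_exchange), ("pseudo", rxn.is_pseudo)) if v
        )
        sr.setNotes(
            _notes_xml(
                {
                    "species_tags": ",".join(sorted(rxn.species)),
                    "pathway": rxn.pathway,
                    "flags": flags,
                }
            )
        )
    libsbml.writeSBMLToFile(doc, str(path))


def read_sbml(path, default_bound: float = 100.0) -> MetabolicModel:
    reader = libsbml.SBMLReader()
    doc = reader.readSBML(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise SbmlError(
            f"malformed SBML {path}: {err.getMessage().strip()} "
            f"(line {err.getLine()})"
        )
    sm = doc.getModel()
    if sm is None:
        raise SbmlError(f"{path}: no model element")

    mets = []
    known = set()
    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        notes = _parse_notes(sp)
        formula = None
        if notes.get("formula"):
            formula = parse_formula(notes["formula"])
        mets.append(
            Metabolite(
                id=sp.getId(),
                name=sp.getName(),
                external=sp.getBoundaryCondition(),
                formula=formula,
            )
        )
        known.add(sp.getId())

    rxns = []
    for i in range(sm.getNumReactions()):
        sr = sm.getReaction(i)
        if not sr.isSetReversible():
            log.warning(
                "reaction %s lacks a reversible attribute; defaulting to "
                "reversible per the SBML specification", sr.getId()
            )
            reversible = True
        else:
            reversible = sr.getReversible()
        stoich: dict[str, Fraction] = {}
        for ref, sign in [
            *((sr.getReactant(j), -1) for j in range(sr.getNumReactants())),
            *((sr.getProduct(j), +1) for j in range(sr.getNumProducts())),
        ]:
            mid = ref.getSpecies()
            if mid not in known:
                raise SbmlError(
                    f"reaction {sr.getId()} references undeclared species {mid!r}"
                )
            coeff = Fraction(ref.getStoichiometry()).limit_denominator(10**6)
            stoich[mid] = stoich.get(mid, Fraction(0)) + sign * coeff
        notes = _parse_notes(sr)
        species = frozenset(
            s for s in notes.get("species_tags", "").split(",") if s
        ) or frozenset(SPECIES_TAGS)
        flags = set(notes.get("flags", "").split(","))
        rxns.append(
            Reaction(
                id=sr.getId(),
                stoich=stoich,
                reversible=reversible,
                species=species,
                pathway=notes.get("pathway", ""),
                is_exchange="exchange" in flags,
                is_pseudo="pseudo" in flags,
                name=sr.getName(),
            )
        )
    try:
        return MetabolicModel(mets, rxns, default_bound=default_bound,
                              name=sm.getId())
    except ModelError as exc:
        raise SbmlError(str(exc)) from exc
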