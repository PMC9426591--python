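"""Model readers and writers: SBML (Level 3 + fbc) and a plain JSON dialect.

The JSON dialect mirrors the in-memory containers field for field::

    {
      "species_id": "toy1",
      "degradation_target": "atz_e",
      "metadata": {"biomass_carbon": 20},
      "metabolites": [
        {"id": "glc_e", "name": "glucose", "formula": "C6H12O6",
         "compartment": "extracellular"},
        ...
      ],
      "reactions": [
        {"id": "EX_glc", "stoichiometry": {"glc_e": -1},
         "lower_bound": -1000, "upper_bound": 1000,
         "is_exchange": true, "is_biomass": false},
        ...
      ]
    }

``compartment`` may be omitted, in which case a ``_e`` id suffix means
extracellular and anything else cytosol. Unspecified bounds default to
(-1000, 1000) for reversible and (0, 1000) for irreversible reactions.

SBML support targets Level 3 with fbc flux bounds and objectives (always
written); on input, Level 2 files carrying LOWER_BOUND/UPPER_BOUND kinetic-law
parameters are tolerated, since older deposited models predate fbc.
Identifier schemes (BiGG-style, ModelSEED ``rxn``/``cpd``, arbitrary) are
passed through uninterpreted.
"""

from __future__ import annotations

import json
import math
import re
from pathlib import Path

import libsbml

from .model import (
    CYTOSOL,
    DEFAULT_BOUND,
    EXTRACELLULAR,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
)

__all__ = ["load_model", "write_model"]


def load_model(path: str | Path, dialect: str | None = None) -> MetabolicModel:
    """Load and validate a model from ``path``.

    ``dialect`` is ``"sbml"`` or ``"json"``; when None it is inferred from
    the file extension (``.xml``/``.sbml`` vs ``.json``).
    """
    path = Path(path)
    if dialect is None:
        dialect = "sbml" if path.suffix.lower() in (".xml", ".sbml") else "json"
    if dialect == "json":
        model = _load_json(path)
    elif dialect == "sbml":
        model = _load_sbml(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    model.validate()
    return model


def write_model(model: MetabolicModel, path: str | Path, dialect: str | None = None) -> None:
    """Validate ``model`` and write it; refuses invariant-violating models."""
    path = Path(path)
    if dialect is None:
        dialect = "sbml" if path.suffix.lower() in (".xml", ".sbml") else "json"
    model.validate()
    if dialect == "json":
        _write_json(model, path)
    elif dialect == "sbml":
        _write_sbml(model, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def _infer_compartment(met_id: str) -> str:
    return EXTRACELLULAR if met_id.endswith("_e") else CYTOSOL


def _load_json(path: Path) -> MetabolicModel:
    with open(path) as fh:
        doc = json.load(fh)
    mets = [
        Metabolite(
            id=m["id"],
            name=m.get("name", ""),
            formula=m.get("formula", ""),
            compartment=m.get("compartment", _infer_compartment(m["id"])),
        )
        for m in doc["metabolites"]
    ]
    rxns = []
    for r in doc["reactions"]:
        reversible = r.get("reversible", True)
        lb = r.get("lower_bound", -DEFAULT_BOUND if reversible else 0.0)
        ub = r.get("upper_bound", DEFAULT_BOUND)
        rxns.append(
            Reaction(
                id=r["id"],
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                lower_bound=float(lb),
                upper_bound=float(ub),
                is_exchange=bool(r.get("is_exchange", False)),
                is_biomass=bool(r.get("is_biomass", False)),
            )
        )
    return MetabolicModel(
        species_id=doc["species_id"],
        metabolites=mets,
        reactions=rxns,
        degradation_target=doc.get("degradation_target"),
        metadata=doc.get("metadata", {}),
    )


def _write_json(model: MetabolicModel, path: Path) -> None:
    doc = {
        "species_id": model.species_id,
        "degradation_target": model.degradation_target,
        "metadata": model.metadata,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "formula": m.formula,
                "compartment": m.compartment,
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "is_exchange": r.is_exchange,
                "is_biomass": r.is_biomass,
            }
            for r in model.reactions
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# SBML
# ---------------------------------------------------------------------------

_FBC_NS = "http://www.sbml.org/sbml/level3/version1/fbc/version2"
_NOTE_KEY = re.compile(r"(\w+)\s*:\s*([^<\s][^<]*)")


def _check(value, message: str):
    if value is None or (isinstance(value, int) and value < 0):
        raise IOError(f"libsbml error: {message} (code {value})")
    return value


def _load_sbml(path: Path) -> MetabolicModel:
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise ModelValidationError(
            f"SBML parse errors in {path}: "
            + doc.getErrorLog().toString().strip()
        )
    sm = doc.getModel()
    if sm is None:
        raise ModelValidationError(f"{path} contains no SBML model")

    extracellular_comps = {
        c.getId()
        for c in (sm.getCompartment(i) for i in range(sm.getNumCompartments()))
        if c.getId() in ("e", "e0", "extracellular")
        or "extracellular" in (c.getName() or "").lower()
    }

    mets = []
    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        if sp.getBoundaryCondition():
            continue  # boundary species are outside the balanced system
        fbc_sp = sp.getPlugin("fbc")
        formula = ""
        if fbc_sp is not None and fbc_sp.isSetChemicalFormula():
            formula = fbc_sp.getChemicalFormula()
        comp = (
            EXTRACELLULAR
            if sp.getCompartment() in extracellular_comps
            or sp.getId().endswith("_e")
            else CYTOSOL
        )
        mets.append(
            Metabolite(
                id=sp.getId(), name=sp.getName() or "", formula=formula,
                compartment=comp,
            )
        )
    met_comp = {m.id: m.compartment for m in mets}
    boundary = {
        sm.getSpecies(i).getId()
        for i in range(sm.getNumSpecies())
        if sm.getSpecies(i).getBoundaryCondition()
    }

    # fbc objective marks the biomass reaction
    fbc_model = sm.getPlugin("fbc")
    biomass_ids: set[str] = set()
    if fbc_model is not None and fbc_model.getNumObjectives() > 0:
        obj = fbc_model.getActiveObjective() or fbc_model.getObjective(0)
        if obj is not None:
            for j in range(obj.getNumFluxObjectives()):
                biomass_ids.add(obj.getFluxObjective(j).getReaction())

    params = {
        sm.getParameter(i).getId(): sm.getParameter(i).getValue()
        for i in range(sm.getNumParameters())
    }

    rxns = []
    for i in range(sm.getNumReactions()):
        sr = sm.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            if ref.getSpecies() in boundary:
                continue
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            if ref.getSpecies() in boundary:
                continue
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()

        lb, ub = _read_bounds(sr, params)
        is_exchange = (
            len(stoich) == 1
            and next(iter(stoich.values())) == -1
            and met_comp.get(next(iter(stoich))) == EXTRACELLULAR
        )
        is_biomass = sr.getId() in biomass_ids or (
            not biomass_ids and "biomass" in sr.getId().lower()
        )
        rxns.append(
            Reaction(
                id=sr.getId(), stoichiometry=stoich,
                lower_bound=lb, upper_bound=ub,
                is_exchange=is_exchange, is_biomass=is_biomass,
            )
        )

    metadata: dict = {}
    target = None
    if sm.isSetNotes():
        notes = sm.getNotesString()
        for key, value in _NOTE_KEY.findall(notes):
            value = value.strip()
            if key == "degradation_target":
                target = value
            elif key == "biomass_carbon":
                metadata["biomass_carbon"] = float(value)

    return MetabolicModel(
        species_id=sm.getId() or path.stem,
        metabolites=mets,
        reactions=rxns,
        degradation_target=target,
        metadata=metadata,
    )


def _read_bounds(sr, params: dict[str, float]) -> tuple[float, float]:
    """fbc bounds first, then Level-2 kinetic-law parameters, then defaults."""
    fbc_r = sr.getPlugin("fbc")
    if fbc_r is not None and (fbc_r.isSetLowerFluxBound() or fbc_r.isSetUpperFluxBound()):
        lb = params.get(fbc_r.getLowerFluxBound(), -DEFAULT_BOUND)
        ub = params.get(fbc_r.getUpperFluxBound(), DEFAULT_BOUND)
        return lb, ub
    kl = sr.getKineticLaw()
    if kl is not None:
        local = {
            kl.getParameter(i).getId(): kl.getParameter(i).getValue()
            for i in range(kl.getNumParameters())
        }
        if "LOWER_BOUND" in local or "UPPER_BOUND" in local:
            default_lb = -DEFAULT_BOUND if sr.getReversible() else 0.0
            return (
                local.get("LOWER_BOUND", default_lb),
                local.get("UPPER_BOUND", DEFAULT_BOUND),
            )
    if sr.getReversible():
        return -DEFAULT_BOUND, DEFAULT_BOUND
    return 0.0, DEFAULT_BOUND


def _write_sbml(model: MetabolicModel, path: Path) -> None:
    ns = libsbml.SBMLNamespaces(3, 1)
    ns.addPackageNamespace("fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(model.species_id)
    fbc_model = sm.getPlugin("fbc")
    fbc_model.setStrict(False)

    notes = []
    if model.degradation_target is not None:
        notes.append(f"degradation_target: {model.degradation_target}")
    if "biomass_carbon" in model.metadata:
        notes.append(f"biomass_carbon: {model.metadata['biomass_carbon']}")
    if notes:
        body = "".join(f"<p>{line}</p>" for line in notes)
        _check(
            sm.setNotes(
                f'<body xmlns="http://www.w3.org/1999/xhtml">{body}</body>'
            ),
            "set model notes",
        )

    for cid, name in (("c", "cytosol"), ("e", "extracellular")):
        comp = sm.createCompartment()
        comp.setId(cid)
        comp.setName(name)
        comp.setConstant(True)

    for m in model.metabolites:
        sp = sm.createSpecies()
        sp.setId(m.id)
        sp.setName(m.name)
        sp.setCompartment("e" if m.compartment == EXTRACELLULAR else "c")
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        if m.formula:
            sp.getPlugin("fbc").setChemicalFormula(m.formula)

    bound_values: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_values:
            pid = f"fb_{len(bound_values)}"
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_values[value] = pid
        return bound_values[value]

    for r in model.reactions:
        sr = sm.createReaction()
        sr.setId(r.id)
        sr.setReversible(r.lower_bound < 0)
        sr.setFast(False)
        for met_id, coeff in r.stoichiometry.items():
            ref = sr.createReactant() if coeff < 0 else sr.createProduct()
            ref.setSpecies(met_id)
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
        fbc_r = sr.getPlugin("fbc")
        fbc_r.setLowerFluxBound(bound_param(r.lower_bound))
        fbc_r.setUpperFluxBound(bound_param(r.upper_bound))

    obj = fbc_model.createObjective()
    obj.setId("obj")
    obj.setType("maximize")
    fo = obj.createFluxObjective()
    fo.setReaction(model.biomass_reaction.id)
    fo.setCoefficient(1.0)
    fbc_model.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"failed to write SBML to {path}")
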