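"""Core data model for genome-scale metabolic networks (GEMs).

A GEM is a set of metabolites distributed over two compartments — cytosol
(``c``) and extracellular space (``e``) — and a set of reactions with signed
stoichiometry, flux bounds in mmol·gDW⁻¹·h⁻¹ and gene/KO annotations.  The
stoichiometric matrix ``S`` (metabolites × reactions) is derived on demand.

Canonical on-disk dialects:

* ``tsv``  — a directory holding ``metabolites.tsv`` and ``reactions.tsv``,
  stoichiometry encoded as ``id:coeff;id:coeff``;
* ``json`` — a single file mirroring the TSV fields;
* ``sbml`` — SBML level 3 with the ``fbc`` package for bounds (best effort).
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy import sparse

UNKNOWN = "UNKNOWN"

COMPARTMENTS = ("c", "e")

REACTION_KINDS = ("metabolic", "transport", "exchange", "demand", "biomass")

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")
_FORMULA_VALID = re.compile(r"^(?:[A-Z][a-z]?\d*)+$")


class ValidationError(ValueError):
    """A model or reaction violates a structural invariant."""


class ParseError(ValueError):
    """A file or equation string could not be parsed."""


def parse_formula(formula: str) -> dict[str, int] | None:
    """Parse an elemental formula like ``C6H12O6`` into element counts.

    Returns ``None`` for the ``UNKNOWN`` token and for formulas that cannot
    be interpreted as a plain element multiset — notably polymeric species
    with indeterminate repeat counts such as ``(C6H10O5)n``.
    """
    if not formula or formula == UNKNOWN:
        return None
    if not _FORMULA_VALID.match(formula):
        return None
    counts: dict[str, int] = {}
    for element, num in _FORMULA_TOKEN.findall(formula):
        counts[element] = counts.get(element, 0) + (int(num) if num else 1)
    return counts


@dataclass
class Metabolite:
    """A chemical species tagged with a compartment.

    ``id`` is unique within a model and conventionally carries the
    compartment as a bracket suffix (``glc[c]``); the ``compartment`` field
    is authoritative.  ``formula`` is an elemental formula string or
    ``UNKNOWN``; ``charge`` is an integer or ``None`` when unknown.
    """

    id: str
    name: str = ""
    formula: str = UNKNOWN
    charge: int | None = None
    compartment: str = "c"

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValidationError(
                f"metabolite {self.id!r}: compartment must be one of "
                f"{COMPARTMENTS}, got {self.compartment!r}"
            )

    @property
    def elements(self) -> dict[str, int] | None:
        return parse_formula(self.formula)


@dataclass
class Reaction:
    """A stoichiometric reaction with flux bounds.

    ``stoichiometry`` maps metabolite id to a signed coefficient (negative =
    consumed).  Bounds are in mmol·gDW⁻¹·h⁻¹; for a biomass reaction the
    flux is read as gDW·h⁻¹.
    """

    id: str
    name: str = ""
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = -1000.0
    upper_bound: float = 1000.0
    genes: list[str] = field(default_factory=list)
    ko_ids: list[str] = field(default_factory=list)
    pathway: str = ""
    subsystem: str = ""
    kind: str = "metabolic"

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ValidationError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} "
                f"exceeds upper bound {self.upper_bound}"
            )
        if self.kind not in REACTION_KINDS:
            raise ValidationError(
                f"reaction {self.id!r}: unknown kind {self.kind!r}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            name=self.name,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            genes=list(self.genes),
            ko_ids=list(self.ko_ids),
            pathway=self.pathway,
            subsystem=self.subsystem,
            kind=self.kind,
        )


@dataclass
class FluxSolution:
    """Outcome of one linear-programming flux computation."""

    status: str  # optimal | infeasible | unbounded
    objective_value: float
    fluxes: dict[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


class GEM:
    """A genome-scale metabolic model: metabolites, reactions, objective."""

    def __init__(
        self,
        metabolites: Iterable[Metabolite] = (),
        reactions: Iterable[Reaction] = (),
        objective_id: str | None = None,
        name: str = "",
    ) -> None:
        self.name = name
        self.metabolites: dict[str, Metabolite] = {}
        self.reactions: dict[str, Reaction] = {}
        self.objective_id = objective_id
        for met in metabolites:
            self.add_metabolite(met)
        for rxn in reactions:
            self.add_reaction(rxn)

    # -- construction -------------------------------------------------

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ValidationError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction, *, allow_new_metabolites: bool = False) -> None:
        if rxn.id in self.reactions:
            raise ValidationError(f"duplicate reaction id {rxn.id!r}")
        for mid in rxn.stoichiometry:
            if mid not in self.metabolites:
                if allow_new_metabolites:
                    self.add_metabolite(_metabolite_from_id(mid))
                else:
                    raise ValidationError(
                        f"reaction {rxn.id!r} references unknown metabolite {mid!r}"
                    )
        self.reactions[rxn.id] = rxn

    def remove_reaction(self, rxn_id: str) -> Reaction:
        rxn = self.reactions.pop(rxn_id)
        if self.objective_id == rxn_id:
            self.objective_id = None
        return rxn

    def copy(self) -> "GEM":
        model = GEM(name=self.name, objective_id=self.objective_id)
        for met in self.metabolites.values():
            model.add_metabolite(
                Metabolite(met.id, met.name, met.formula, met.charge, met.compartment)
            )
        for rxn in self.reactions.values():
            model.add_reaction(rxn.copy())
        return model

    # -- views ---------------------------------------------------------

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.metabolites)

    @property
    def reaction_ids(self) -> list[str]:
        return list(self.reactions)

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.kind == "exchange"]

    def counts_by_kind(self) -> dict[str, int]:
        counts = {kind: 0 for kind in REACTION_KINDS}
        for rxn in self.reactions.values():
            counts[rxn.kind] += 1
        return counts

    def genes(self) -> set[str]:
        out: set[str] = set()
        for rxn in self.reactions.values():
            out.update(rxn.genes)
        return out

    def validate(self) -> None:
        """Check all structural invariants; raise ValidationError on failure."""
        for rxn in self.reactions.values():
            for mid in rxn.stoichiometry:
                if mid not in self.metabolites:
                    raise ValidationError(
                        f"reaction {rxn.id!r} references unknown metabolite {mid!r}"
                    )
            if rxn.kind == "exchange":
                mids = list(rxn.stoichiometry)
                if len(mids) != 1:
                    raise ValidationError(
                        f"exchange reaction {rxn.id!r} must touch exactly one "
                        f"metabolite, touches {len(mids)}"
                    )
                if self.metabolites[mids[0]].compartment != "e":
                    raise ValidationError(
                        f"exchange reaction {rxn.id!r} must act on an "
                        f"extracellular metabolite"
                    )
        if self.objective_id is not None and self.objective_id not in self.reactions:
            raise ValidationError(
                f"objective reaction {self.objective_id!r} not in model"
            )


def _metabolite_from_id(mid: str) -> Metabolite:
    compartment = "e" if mid.endswith("[e]") else "c"
    return Metabolite(id=mid, name=mid, compartment=compartment)


# ---------------------------------------------------------------------------
# Stoichiometric matrix


def stoichiometric_matrix(model: GEM, *, dense: bool = False):
    """Return S with shape (|metabolites|, |reactions|).

    ``S[i, j]`` is the coefficient of metabolite *i* in reaction *j*, zero
    when absent.  Sparse CSC by default; ``dense=True`` gives an ndarray.
    """
    met_index = {mid: i for i, mid in enumerate(model.metabolites)}
    rows: list[int] = []
    cols: list[int] = []
    data: list[float] = []
    for j, rxn in enumerate(model.reactions.values()):
        for mid, coeff in rxn.stoichiometry.items():
            if coeff == 0:
                continue
            rows.append(met_index[mid])
            cols.append(j)
            data.append(float(coeff))
    S = sparse.csc_matrix(
        (data, (rows, cols)),
        shape=(len(model.metabolites), len(model.reactions)),
    )
    return S.toarray() if dense else S


def classify_reaction(rxn: Reaction, model: GEM) -> str:
    """Assign a reaction kind from the compartments it touches.

    All-cytosolic → ``metabolic``; all-extracellular → ``exchange``; mixed
    → ``transport``.  Reactions already flagged ``biomass`` or ``demand``
    keep their flag.
    """
    if rxn.kind in ("biomass", "demand"):
        return rxn.kind
    comps = set()
    for mid in rxn.stoichiometry:
        met = model.metabolites.get(mid)
        if met is None:
            raise ValidationError(
                f"reaction {rxn.id!r} references unknown metabolite {mid!r}"
            )
        comps.add(met.compartment)
    if comps == {"c"} or not comps:
        return "metabolic"
    if comps == {"e"}:
        return "exchange"
    return "transport"


# ---------------------------------------------------------------------------
# Equation strings

_ARROWS = ("<=>", "<->", "=>", "->", "<=")


def parse_equation(equation: str) -> tuple[dict[str, float], bool]:
    """Parse ``"2 A + B <=> C"`` into (stoichiometry, reversible).

    Metabolite tokens may carry a bracket compartment suffix.  ``<=>`` and
    ``<->`` mean reversible; ``=>``/``->`` irreversible forward; ``<=``
    irreversible backward (normalised by sign flip).
    """
    arrow = None
    for candidate in _ARROWS:
        if candidate in equation:
            arrow = candidate
            break
    if arrow is None:
        raise ParseError(f"no reaction arrow found in equation {equation!r}")
    left, right = equation.split(arrow, 1)
    reversible = arrow in ("<=>", "<->")
    flip = arrow == "<="

    stoich: dict[str, float] = {}

    def _accumulate(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split(" + "):
            term = term.strip()
            if not term:
                continue
            parts = term.split(None, 1)
            if len(parts) == 2 and _is_number(parts[0]):
                coeff = float(parts[0])
                mid = parts[1].strip()
            else:
                coeff = 1.0
                mid = term
            if not mid:
                raise ParseError(f"empty metabolite token in {equation!r}")
            stoich[mid] = stoich.get(mid, 0.0) + sign * coeff

    left_sign, right_sign = (1.0, -1.0) if flip else (-1.0, 1.0)
    _accumulate(left, left_sign)
    _accumulate(right, right_sign)
    stoich = {m: c for m, c in stoich.items() if c != 0}
    return stoich, reversible


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def format_equation(rxn: Reaction) -> str:
    """Render a reaction back to an equation string (sorted by id)."""
    lhs = []
    rhs = []
    for mid in sorted(rxn.stoichiometry):
        coeff = rxn.stoichiometry[mid]
        text = mid if abs(coeff) == 1 else f"{_fmt_num(abs(coeff))} {mid}"
        (lhs if coeff < 0 else rhs).append(text)
    arrow = "<=>" if rxn.reversible else "=>"
    return f"{' + '.join(lhs)} {arrow} {' + '.join(rhs)}".strip()


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(x)


# ---------------------------------------------------------------------------
# TSV / JSON / SBML dialects

_MET_COLUMNS = ["id", "name", "formula", "charge", "compartment"]
_RXN_COLUMNS = [
    "id", "name", "stoichiometry", "lower_bound", "upper_bound",
    "genes", "ko_ids", "pathway", "subsystem", "kind",
]


def save_gem(model: GEM, path: str | Path, dialect: str = "tsv") -> None:
    """Serialise a model; the file reloads to an id-identical model."""
    path = Path(path)
    if dialect == "tsv":
        _save_tsv(model, path)
    elif dialect == "json":
        _save_json(model, path)
    elif dialect == "sbml":
        _save_sbml(model, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def load_gem(path: str | Path, dialect: str = "tsv") -> GEM:
    """Load a model from one of the canonical dialects.

    Unparseable formulas are kept verbatim (they behave as ``UNKNOWN`` in
    balance checks); malformed stoichiometry raises :class:`ParseError`
    naming the offending line.
    """
    path = Path(path)
    if dialect == "tsv":
        return _load_tsv(path)
    if dialect == "json":
        return _load_json(path)
    if dialect == "sbml":
        return _load_sbml(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _encode_stoich(stoich: Mapping[str, float]) -> str:
    return ";".join(f"{mid}:{_fmt_num(coeff)}" for mid, coeff in sorted(stoich.items()))


def _decode_stoich(text: str, context: str) -> dict[str, float]:
    stoich: dict[str, float] = {}
    if not text:
        return stoich
    for token in text.split(";"):
        if ":" not in token:
            raise ParseError(f"malformed stoichiometry term {token!r} in {context}")
        mid, _, coeff = token.rpartition(":")
        if not mid:
            raise ParseError(f"malformed stoichiometry term {token!r} in {context}")
        try:
            stoich[mid] = float(coeff)
        except ValueError as exc:
            raise ParseError(
                f"non-numeric coefficient {coeff!r} in {context}"
            ) from exc
    return stoich


def _save_tsv(model: GEM, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "metabolites.tsv", "w") as fh:
        fh.write("\t".join(_MET_COLUMNS) + "\n")
        for met in model.metabolites.values():
            charge = UNKNOWN if met.charge is None else str(met.charge)
            fh.write(
                "\t".join([met.id, met.name, met.formula or UNKNOWN, charge,
                           met.compartment]) + "\n"
            )
    with open(path / "reactions.tsv", "w") as fh:
        fh.write("\t".join(_RXN_COLUMNS + ["objective"]) + "\n")
        for rxn in model.reactions.values():
            fh.write(
                "\t".join([
                    rxn.id,
                    rxn.name,
                    _encode_stoich(rxn.stoichiometry),
                    repr(rxn.lower_bound),
                    repr(rxn.upper_bound),
                    ",".join(rxn.genes),
                    ",".join(rxn.ko_ids),
                    rxn.pathway,
                    rxn.subsystem,
                    rxn.kind,
                    "1" if rxn.id == model.objective_id else "0",
                ]) + "\n"
            )


def _load_tsv(path: Path) -> GEM:
    met_file = path / "metabolites.tsv"
    rxn_file = path / "reactions.tsv"
    if not met_file.exists() or not rxn_file.exists():
        raise FileNotFoundError(
            f"TSV dialect expects {met_file} and {rxn_file}"
        )
    model = GEM(name=path.name)
    with open(met_file) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: header.index(c) for c in _MET_COLUMNS if c in header}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            charge_text = fields[idx["charge"]]
            charge = None if charge_text in ("", UNKNOWN) else int(charge_text)
            model.add_metabolite(Metabolite(
                id=fields[idx["id"]],
                name=fields[idx["name"]],
                formula=fields[idx["formula"]] or UNKNOWN,
                charge=charge,
                compartment=fields[idx["compartment"]],
            ))
    with open(rxn_file) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: header.index(c) for c in header}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            context = f"{rxn_file}:{lineno}"
            rxn = Reaction(
                id=fields[idx["id"]],
                name=fields[idx["name"]],
                stoichiometry=_decode_stoich(fields[idx["stoichiometry"]], context),
                lower_bound=float(fields[idx["lower_bound"]]),
                upper_bound=float(fields[idx["upper_bound"]]),
                genes=_split_list(fields[idx["genes"]]),
                ko_ids=_split_list(fields[idx["ko_ids"]]),
                pathway=fields[idx["pathway"]],
                subsystem=fields[idx["subsystem"]],
                kind=fields[idx["kind"]],
            )
            model.add_reaction(rxn)
            if "objective" in idx and fields[idx["objective"]] == "1":
                model.objective_id = rxn.id
    model.validate()
    return model


def _split_list(text: str) -> list[str]:
    return [t for t in text.split(",") if t]


def _save_json(model: GEM, path: Path) -> None:
    payload = {
        "name": model.name,
        "objective_id": model.objective_id,
        "metabolites": [
            {
                "id": m.id, "name": m.name, "formula": m.formula,
                "charge": m.charge, "compartment": m.compartment,
            }
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id, "name": r.name,
                "stoichiometry": r.stoichiometry,
                "lower_bound": r.lower_bound, "upper_bound": r.upper_bound,
                "genes": r.genes, "ko_ids": r.ko_ids,
                "pathway": r.pathway, "subsystem": r.subsystem,
                "kind": r.kind,
            }
            for r in model.reactions.values()
        ],
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def _load_json(path: Path) -> GEM:
    with open(path) as fh:
        payload = json.load(fh)
    model = GEM(name=payload.get("name", ""))
    for m in payload["metabolites"]:
        model.add_metabolite(Metabolite(
            id=m["id"], name=m.get("name", ""),
            formula=m.get("formula") or UNKNOWN,
            charge=m.get("charge"), compartment=m.get("compartment", "c"),
        ))
    for r in payload["reactions"]:
        model.add_reaction(Reaction(
            id=r["id"], name=r.get("name", ""),
            stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
            lower_bound=float(r["lower_bound"]),
            upper_bound=float(r["upper_bound"]),
            genes=list(r.get("genes", [])), ko_ids=list(r.get("ko_ids", [])),
            pathway=r.get("pathway", ""), subsystem=r.get("subsystem", ""),
            kind=r.get("kind", "metabolic"),
        ))
    model.objective_id = payload.get("objective_id")
    model.validate()
    return model


# SBML ids must be SId-conformant; bracket suffixes are escaped.

def _sbml_id(raw: str) -> str:
    out = re.sub(r"[^A-Za-z0-9_]", "__", raw)
    if not re.match(r"[A-Za-z_]", out):
        out = "_" + out
    return out


def _save_sbml(model: GEM, path: Path) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(_sbml_id(model.name or "model"))
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(True)

    for comp_id in COMPARTMENTS:
        comp = sm.createCompartment()
        comp.setId(comp_id)
        comp.setConstant(True)

    id_map: dict[str, str] = {}
    for met in model.metabolites.values():
        sid = "M_" + _sbml_id(met.id)
        id_map[met.id] = sid
        sp = sm.createSpecies()
        sp.setId(sid)
        sp.setName(met.name or met.id)
        sp.setCompartment(met.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        splug = sp.getPlugin("fbc")
        if met.charge is not None:
            splug.setCharge(met.charge)
        if met.formula != UNKNOWN and parse_formula(met.formula) is not None:
            splug.setChemicalFormula(met.formula)

    bound_ids: dict[float, str] = {}

    def _bound_param(value: float) -> str:
        if value not in bound_ids:
            pid = f"fb_{len(bound_ids)}"
            par = sm.createParameter()
            par.setId(pid)
            par.setValue(value)
            par.setConstant(True)
            bound_ids[value] = pid
        return bound_ids[value]

    for rxn in model.reactions.values():
        rid = "R_" + _sbml_id(rxn.id)
        sr = sm.createReaction()
        sr.setId(rid)
        sr.setName(rxn.name or rxn.id)
        sr.setReversible(rxn.reversible)
        sr.setFast(False)
        for mid, coeff in rxn.stoichiometry.items():
            ref = sr.createReactant() if coeff < 0 else sr.createProduct()
            ref.setSpecies(id_map[mid])
            ref.setStoichiometry(abs(float(coeff)))
            ref.setConstant(True)
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(_bound_param(float(rxn.lower_bound)))
        rplug.setUpperFluxBound(_bound_param(float(rxn.upper_bound)))
        # kind and annotations ride along as notes for lossless reload
        notes = (
            f"<body xmlns='http://www.w3.org/1999/xhtml'>"
            f"<p>kind: {rxn.kind}</p>"
            f"<p>pathway: {rxn.pathway}</p>"
            f"<p>subsystem: {rxn.subsystem}</p>"
            f"<p>genes: {','.join(rxn.genes)}</p>"
            f"<p>ko_ids: {','.join(rxn.ko_ids)}</p>"
            f"<p>original_id: {rxn.id}</p></body>"
        )
        sr.setNotes(notes)

    if model.objective_id is not None:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction("R_" + _sbml_id(model.objective_id))
        fo.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")

    # record original metabolite ids as species names when escaped
    for met in model.metabolites.values():
        sp = sm.getSpecies(id_map[met.id])
        sp.setName(met.id)

    libsbml.writeSBMLToFile(doc, str(path))


_NOTE_FIELD = re.compile(r"<p>\s*([a-z_]+):\s*(.*?)\s*</p>", re.S)


def _load_sbml(path: Path) -> GEM:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise ParseError(
            f"libsbml reported errors reading {path}: "
            f"{doc.getErrorLog().toString()}"
        )
    sm = doc.getModel()
    if sm is None:
        raise ParseError(f"no model element in {path}")
    model = GEM(name=sm.getId())

    sid_to_mid: dict[str, str] = {}
    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        mid = sp.getName() or sp.getId()
        sid_to_mid[sp.getId()] = mid
        splug = sp.getPlugin("fbc")
        formula = UNKNOWN
        charge = None
        if splug is not None:
            if splug.isSetChemicalFormula():
                formula = splug.getChemicalFormula()
            if splug.isSetCharge():
                charge = splug.getCharge()
        model.add_metabolite(Metabolite(
            id=mid, name=mid, formula=formula, charge=charge,
            compartment=sp.getCompartment() or "c",
        ))

    objective_rid = None
    mplug = sm.getPlugin("fbc")
    if mplug is not None and mplug.getNumObjectives() > 0:
        obj = mplug.getActiveObjective() or mplug.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            objective_rid = obj.getFluxObjective(0).getReaction()

    for i in range(sm.getNumReactions()):
        sr = sm.getReaction(i)
        notes = sr.getNotesString() if sr.isSetNotes() else ""
        meta = dict(_NOTE_FIELD.findall(notes))
        rid = meta.get("original_id") or sr.getId()
        stoich: dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            mid = sid_to_mid[ref.getSpecies()]
            stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            mid = sid_to_mid[ref.getSpecies()]
            stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()
        lb, ub = -1000.0, 1000.0
        rplug = sr.getPlugin("fbc")
        if rplug is not None:
            lb_par = sm.getParameter(rplug.getLowerFluxBound() or "")
            ub_par = sm.getParameter(rplug.getUpperFluxBound() or "")
            if lb_par is not None:
                lb = lb_par.getValue()
            if ub_par is not None:
                ub = ub_par.getValue()
        elif not sr.getReversible():
            lb = 0.0
        rxn = Reaction(
            id=rid,
            name=sr.getName() or rid,
            stoichiometry=stoich,
            lower_bound=lb,
            upper_bound=ub,
            genes=_split_list(meta.get("genes", "")),
            ko_ids=_split_list(meta.get("ko_ids", "")),
            pathway=meta.get("pathway", ""),
            subsystem=meta.get("subsystem", ""),
            kind=meta.get("kind", "metabolic"),
        )
        model.add_reaction(rxn)
        if objective_rid is not None and sr.getId() == objective_rid:
            model.objective_id = rid
    model.validate()
    return model
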