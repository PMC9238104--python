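"""Draft network assembly from KO annotations plus refinement steps.

The draft is built by the KO-bridge: a universal reaction pool (KEGG-like
table of reaction equations with KO ids) is intersected with the KO ids
present in a transcriptome annotation table; every pool reaction sharing at
least one KO with the annotated unigene set enters the draft, carrying the
unigenes that map to the shared KOs as its gene list.

Refinement operations cover element/charge balance checking, annotation
completion from the pool, redundancy pruning (duplicates, lumped multi-step
reactions, pool entries flagged general/incomplete), chirality
normalisation by alias map, and the addition of transport + exchange
reaction pairs for nutrients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .model import (
    GEM,
    Metabolite,
    ParseError,
    Reaction,
    ValidationError,
    parse_equation,
    parse_formula,
)


@dataclass(frozen=True)
class KOTable:
    """Unique (unigene, KO) pairs from a transcriptome annotation."""

    rows: tuple[tuple[str, str], ...]

    @classmethod
    def from_pairs(cls, pairs) -> "KOTable":
        seen = dict.fromkeys((str(u), str(k)) for u, k in pairs)
        return cls(rows=tuple(seen))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KOTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        cols = list(df.columns[:2])
        return cls.from_pairs(df[cols].itertuples(index=False, name=None))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.rows, columns=["unigene_id", "ko_id"]).to_csv(
            path, sep="\t", index=False)

    @property
    def ko_ids(self) -> set[str]:
        return {ko for _, ko in self.rows}

    def unigenes_for(self, ko_ids) -> list[str]:
        wanted = set(ko_ids)
        return sorted({u for u, k in self.rows if k in wanted})


@dataclass
class PoolEntry:
    reaction_id: str
    equation: str
    ko_ids: list[str] = field(default_factory=list)
    pathway: str = ""
    subsystem: str = ""
    ec_numbers: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)  # e.g. general, incomplete


class UniversalPool:
    """A universal reaction database in KEGG-like tabular form."""

    COLUMNS = ["reaction_id", "equation", "ko_ids", "pathway", "subsystem",
               "ec_numbers", "flags"]

    def __init__(self, entries=()):
        self.entries: dict[str, PoolEntry] = {}
        for e in entries:
            self.add(e)

    def add(self, entry: PoolEntry) -> None:
        if entry.reaction_id in self.entries:
            raise ValidationError(
                f"duplicate reaction id {entry.reaction_id!r} in pool")
        parse_equation(entry.equation)  # fail fast on malformed equations
        self.entries[entry.reaction_id] = entry

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries.values())

    @classmethod
    def from_tsv(cls, path: str | Path) -> "UniversalPool":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        pool = cls()
        for row in df.itertuples(index=False):
            pool.add(PoolEntry(
                reaction_id=row.reaction_id,
                equation=row.equation,
                ko_ids=_split(getattr(row, "ko_ids", "")),
                pathway=getattr(row, "pathway", ""),
                subsystem=getattr(row, "subsystem", ""),
                ec_numbers=_split(getattr(row, "ec_numbers", "")),
                flags=_split(getattr(row, "flags", "")),
            ))
        return pool

    def to_tsv(self, path: str | Path) -> None:
        rows = [{
            "reaction_id": e.reaction_id,
            "equation": e.equation,
            "ko_ids": ",".join(e.ko_ids),
            "pathway": e.pathway,
            "subsystem": e.subsystem,
            "ec_numbers": ",".join(e.ec_numbers),
            "flags": ",".join(e.flags),
        } for e in self]
        pd.DataFrame(rows, columns=self.COLUMNS).to_csv(path, sep="\t", index=False)

    def to_reaction(self, entry: PoolEntry, *, compartment_suffix: str = "[c]") -> Reaction:
        """Instantiate a pool entry as a cytosolic Reaction."""
        stoich, reversible = parse_equation(entry.equation)
        stoich = {_with_suffix(mid, compartment_suffix): c for mid, c in stoich.items()}
        return Reaction(
            id=entry.reaction_id,
            name=entry.reaction_id,
            stoichiometry=stoich,
            lower_bound=-1000.0 if reversible else 0.0,
            upper_bound=1000.0,
            ko_ids=list(entry.ko_ids),
            pathway=entry.pathway,
            subsystem=entry.subsystem,
        )


def _split(text: str) -> list[str]:
    return [t.strip() for t in str(text).split(",") if t.strip()]


def _with_suffix(mid: str, suffix: str) -> str:
    return mid if mid.endswith(("[c]", "[e]")) else mid + suffix


# ---------------------------------------------------------------------------
# Draft assembly


def build_draft(ko_table: KOTable, pool: UniversalPool) -> GEM:
    """KO-bridge matching: pool reactions sharing a KO with the annotation.

    Every included reaction's gene list is the set of unigenes that map to
    any shared KO.  All metabolites are placed in the cytosol; compartments
    appear later via :func:`add_transfer_reactions`.  An empty intersection
    yields a valid empty model (with a warning attached to ``model.name``
    left to the caller's logging).
    """
    table_kos = ko_table.ko_ids
    model = GEM(name="draft")
    for entry in sorted(pool, key=lambda e: e.reaction_id):
        shared = set(entry.ko_ids) & table_kos
        if not shared:
            continue
        rxn = pool.to_reaction(entry)
        rxn.genes = ko_table.unigenes_for(shared)
        model.add_reaction(rxn, allow_new_metabolites=True)
    return model


# ---------------------------------------------------------------------------
# Balance checking


@dataclass
class BalanceReport:
    """Element/charge conservation check for one reaction."""

    reaction_id: str
    element_deltas: dict[str, float]
    charge_delta: float | None
    verdict: str  # balanced | unbalanced | unknown
    unknown_metabolites: list[str] = field(default_factory=list)


def check_balance(rxn: Reaction, model: GEM, *, tol: float = 1e-9) -> BalanceReport:
    """Net element and charge deltas of a reaction.

    A reaction touching any metabolite with an unparseable formula (the
    ``UNKNOWN`` token or polymeric species with indeterminate repeats) gets
    verdict ``unknown``: it cannot be certified balanced, only flagged.
    """
    deltas: dict[str, float] = {}
    charge_delta: float | None = 0.0
    unknown: list[str] = []
    for mid, coeff in rxn.stoichiometry.items():
        met = model.metabolites[mid]
        counts = parse_formula(met.formula)
        if counts is None:
            unknown.append(mid)
            continue
        for element, n in counts.items():
            deltas[element] = deltas.get(element, 0.0) + coeff * n
        if charge_delta is not None:
            if met.charge is None:
                charge_delta = None
            else:
                charge_delta += coeff * met.charge
    deltas = {e: d for e, d in deltas.items() if abs(d) > tol}
    if unknown:
        verdict = "unknown"
    elif deltas or (charge_delta is not None and abs(charge_delta) > tol):
        verdict = "unbalanced"
    else:
        verdict = "balanced"
    return BalanceReport(
        reaction_id=rxn.id,
        element_deltas=deltas,
        charge_delta=charge_delta,
        verdict=verdict,
        unknown_metabolites=sorted(unknown),
    )


# ---------------------------------------------------------------------------
# Redundancy pruning


def prune_redundant(model: GEM, rules: dict | None = None) -> tuple[GEM, list[tuple[str, str]]]:
    """Remove redundant reactions; return (pruned model, removal log).

    Removes, in order: (i) reactions whose pool metadata flags them
    ``general`` or ``incomplete`` (``rules["pool"]``); (ii) lumped
    multi-step reactions whose net stoichiometry equals the sum of two
    retained elementary steps; (iii) exact duplicate stoichiometries,
    keeping the lexicographically smallest id.  The log lists
    (reaction id, reason).
    """
    rules = rules or {}
    pool: UniversalPool | None = rules.get("pool")
    out = model.copy()
    removed: list[tuple[str, str]] = []

    if pool is not None:
        for rid in sorted(out.reaction_ids):
            entry = pool.entries.get(rid)
            if entry and ({"general", "incomplete"} & set(entry.flags)):
                out.remove_reaction(rid)
                removed.append((rid, "flagged:" + ",".join(sorted(entry.flags))))

    def _canon(stoich: dict[str, float]) -> tuple:
        return tuple(sorted((m, round(c, 9)) for m, c in stoich.items()))

    # (ii) lumped steps: net stoichiometry equals the sum of two others
    rids = sorted(out.reaction_ids)
    protected = {rid for rid in rids
                 if out.reactions[rid].kind in ("biomass", "demand", "exchange")}
    for rid in rids:
        if rid in protected or rid not in out.reactions:
            continue
        target = out.reactions[rid].stoichiometry
        others = [o for o in out.reaction_ids
                  if o != rid and out.reactions[o].kind == "metabolic"]
        found = False
        for i, a in enumerate(others):
            if found:
                break
            sa = out.reactions[a].stoichiometry
            for b in others[i + 1:]:
                summed = dict(sa)
                for m, c in out.reactions[b].stoichiometry.items():
                    summed[m] = summed.get(m, 0.0) + c
                summed = {m: c for m, c in summed.items() if abs(c) > 1e-9}
                if _canon(summed) == _canon(target):
                    out.remove_reaction(rid)
                    removed.append((rid, f"lumped:{a}+{b}"))
                    found = True
                    break

    # (iii) duplicates
    by_stoich: dict[tuple, list[str]] = {}
    for rid in sorted(out.reaction_ids):
        by_stoich.setdefault(_canon(out.reactions[rid].stoichiometry), []).append(rid)
    for group in by_stoich.values():
        for rid in group[1:]:
            out.remove_reaction(rid)
            removed.append((rid, f"duplicate:{group[0]}"))
    return out, removed


def standardize_chirality(model: GEM, aliases: dict[str, str]) -> GEM:
    """Rename metabolites via an alias→canonical id map.

    Intended for metabolites whose chirality annotation is inconsistent
    (e.g. unlabelled vs L-).  Duplicate reactions created by the renaming
    should afterwards be removed with :func:`prune_redundant`.
    """
    out = GEM(name=model.name, objective_id=model.objective_id)
    for met in model.metabolites.values():
        new_id = aliases.get(met.id, met.id)
        if new_id not in out.metabolites:
            out.add_metabolite(Metabolite(
                new_id, met.name, met.formula, met.charge, met.compartment))
    for rxn in model.reactions.values():
        new = rxn.copy()
        stoich: dict[str, float] = {}
        for mid, coeff in rxn.stoichiometry.items():
            nid = aliases.get(mid, mid)
            stoich[nid] = stoich.get(nid, 0.0) + coeff
        new.stoichiometry = {m: c for m, c in stoich.items() if c != 0}
        out.add_reaction(new)
    return out


# ---------------------------------------------------------------------------
# Transfer reactions and annotation completion


def add_transfer_reactions(model: GEM,
                           nutrients: list[tuple[str, bool]]) -> GEM:
    """Add an exchange + transport pair per nutrient; compartmentalise.

    Each nutrient id must name an existing cytosolic metabolite.  An
    extracellular twin is created, a transport reaction and an exchange
    reaction (boundary of the e species).  Both are written in the outward
    direction (c → e → environment), so positive flux is export and uptake
    is negative flux.  Importable nutrients get reversible pairs
    (lb = −1000); non-importable ones get lb = 0 on both, so the species
    can only leave the system — the organism must synthesise it.
    """
    out = model.copy()
    for mid, importable in nutrients:
        met = out.metabolites.get(mid)
        if met is None or met.compartment != "c":
            raise ValidationError(
                f"nutrient {mid!r} is not a cytosolic metabolite of the model")
        base = mid[:-3] if mid.endswith("[c]") else mid
        eid = base + "[e]"
        if eid not in out.metabolites:
            out.add_metabolite(Metabolite(
                id=eid, name=met.name, formula=met.formula,
                charge=met.charge, compartment="e"))
        lb = -1000.0 if importable else 0.0
        t_id = f"T_{base}"
        ex_id = f"EX_{base}"
        if t_id in out.reactions or ex_id in out.reactions:
            raise ValidationError(
                f"transfer reactions for {base!r} already present")
        out.add_reaction(Reaction(
            id=t_id, name=f"{base} transport",
            stoichiometry={mid: -1.0, eid: 1.0},
            lower_bound=lb, upper_bound=1000.0, kind="transport",
        ))
        out.add_reaction(Reaction(
            id=ex_id, name=f"{base} exchange",
            stoichiometry={eid: -1.0},
            lower_bound=lb, upper_bound=1000.0, kind="exchange",
        ))
    return out


def apply_patches(model: GEM, patches: dict[str, str] | str | Path,
                  ) -> tuple[GEM, int]:
    """Replace reaction stoichiometries from a patch mapping or file.

    Patches carry hand-curated rebalanced equations, e.g. after
    :func:`check_balance` reports an imbalance.  A file holds one
    ``reaction_id<TAB>replacement_equation`` per line.  Returns the
    patched model and the number of reactions rewritten; patch entries for
    unknown reactions raise.
    """
    if not isinstance(patches, dict):
        entries: dict[str, str] = {}
        with open(patches) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                rid, _, equation = line.partition("\t")
                entries[rid] = equation
        patches = entries
    out = model.copy()
    for rid, equation in patches.items():
        if rid not in out.reactions:
            raise ValidationError(f"patch names unknown reaction {rid!r}")
        stoich, reversible = parse_equation(equation)
        rxn = out.reactions[rid]
        for mid in stoich:
            if mid not in out.metabolites:
                out.add_metabolite(Metabolite(
                    mid, mid, compartment="e" if mid.endswith("[e]") else "c"))
        rxn.stoichiometry = stoich
        if reversible and rxn.lower_bound >= 0:
            rxn.lower_bound = -1000.0
        elif not reversible and rxn.lower_bound < 0:
            rxn.lower_bound = 0.0
    return out, len(patches)


def annotate_missing(model: GEM, pool: UniversalPool,
                     fallback: str = "metabolic pathway") -> tuple[GEM, int]:
    """Fill blank pathway/subsystem fields from the pool, else a fallback.

    Returns the annotated model and the number of reactions touched.
    """
    out = model.copy()
    n_filled = 0
    for rxn in out.reactions.values():
        if rxn.kind in ("exchange", "transport", "demand", "biomass"):
            continue
        if rxn.pathway and rxn.subsystem:
            continue
        entry = pool.entries.get(rxn.id)
        touched = False
        if not rxn.pathway:
            rxn.pathway = (entry.pathway if entry and entry.pathway else fallback)
            touched = True
        if not rxn.subsystem:
            rxn.subsystem = (entry.subsystem if entry and entry.subsystem else fallback)
            touched = True
        if touched:
            n_filled += 1
    return out, n_filled
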