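"""Network connectivity diagnostics and gap filling.

Connectivity is measured on the bipartite metabolite–reaction graph (an
edge wherever a coefficient is nonzero), reported as weakly connected
components over metabolites.  Producibility of a metabolite is flux-based:
an LP maximising a drain on the metabolite under the medium bounds, so
cofactor coupling is honoured — a pure graph-reachability oracle is used
only as an independent check in the test-suite.

Gap filling restores producibility of target metabolites by greedily adding
the smallest set of reactions (set size 1, then 2) from a universal pool,
either restricted to pathways already represented in the model ("pathway"
scale) or drawn from the whole pool ("global" scale).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx

from .fba import InfeasibleError, fba
from .model import GEM, Reaction
from .reconstruct import UniversalPool

#: minimum drain flux counted as "producible" (mmol·gDW⁻¹·h⁻¹)
PRODUCIBLE_EPS = 1e-6


@dataclass
class ConnectivityReport:
    """Weakly connected components of the metabolite–reaction graph."""

    n_wcc: int
    components: list[list[str]]  # metabolite ids, each sorted; list ordered
    # by smallest member id


def connectivity(model: GEM) -> ConnectivityReport:
    """WCCs of the bipartite graph, reported over metabolites.

    Isolated metabolites form their own components.  Ordering is
    deterministic: components sorted by their smallest metabolite id.
    """
    graph = nx.Graph()
    for mid in model.metabolites:
        graph.add_node(("M", mid))
    for rxn in model.reactions.values():
        graph.add_node(("R", rxn.id))
        for mid, coeff in rxn.stoichiometry.items():
            if coeff != 0:
                graph.add_edge(("R", rxn.id), ("M", mid))
    components = []
    for comp in nx.connected_components(graph):
        mets = sorted(node_id for kind, node_id in comp if kind == "M")
        if mets:
            components.append(mets)
    components.sort(key=lambda mets: mets[0])
    return ConnectivityReport(n_wcc=len(components), components=components)


def is_producible(model: GEM, target: str,
                  medium: dict[str, tuple[float, float]] | None = None,
                  *, eps: float = PRODUCIBLE_EPS) -> tuple[bool, float]:
    """Maximum sustainable drain flux on *target* under the medium bounds.

    A temporary demand reaction is added as the drain, so the measurement
    never competes with an existing exchange that may also be the
    metabolite's supply route.  *medium* maps reaction ids to (lb, ub)
    overrides, e.g. to open specific uptakes.  Returns
    (max_flux > eps, max_flux).
    """
    if target not in model.metabolites:
        raise ValueError(f"target metabolite {target!r} not in model")
    work = model.copy()
    for rid, (lb, ub) in (medium or {}).items():
        rxn = work.reactions[rid]
        rxn.lower_bound, rxn.upper_bound = lb, ub
    drain_id = f"__DM_{target}"
    work.add_reaction(Reaction(
        id=drain_id, name=f"temporary demand for {target}",
        stoichiometry={target: -1.0},
        lower_bound=0.0, upper_bound=1000.0, kind="demand",
    ))
    sol = fba(work, drain_id, "max")
    if sol.status == "infeasible":
        raise InfeasibleError(
            f"model infeasible while testing producibility of {target!r}",
            sol.status)
    if sol.status == "unbounded":
        return True, float("inf")
    flux = sol.objective_value
    return flux > eps, flux


def find_breakpoints(model: GEM, target: str, max_depth: int = 10,
                     medium: dict[str, tuple[float, float]] | None = None,
                     ) -> list[tuple[str, str]]:
    """Backtrack a non-producible target to its upstream blockages.

    Breadth-first traversal from the target over producing reactions.  A
    visited metabolite is reported when it is itself non-producible and
    either has no producing reaction at all (``orphan``) or only producers
    whose substrates are blocked (``blocked``).  Returns [] with a notice
    when the target is already producible.
    """
    ok, _ = is_producible(model, target, medium)
    if ok:
        return []

    producers: dict[str, list[Reaction]] = {mid: [] for mid in model.metabolites}
    for rxn in model.reactions.values():
        if rxn.kind == "exchange":
            continue
        for mid, coeff in rxn.stoichiometry.items():
            can_make = (coeff > 0 and rxn.upper_bound > 0) or \
                       (coeff < 0 and rxn.lower_bound < 0)
            if can_make:
                producers[mid].append(rxn)

    breakpoints: list[tuple[str, str]] = []
    seen = {target}
    frontier = [target]
    depth = 0
    while frontier and depth <= max_depth:
        next_frontier: list[str] = []
        for mid in frontier:
            ok, _ = is_producible(model, mid, medium)
            if not ok:
                if not producers[mid]:
                    breakpoints.append((mid, "orphan"))
                else:
                    breakpoints.append((mid, "blocked"))
            for rxn in producers[mid]:
                for sub_id, coeff in rxn.stoichiometry.items():
                    consumed = (coeff < 0 and rxn.upper_bound > 0) or \
                               (coeff > 0 and rxn.lower_bound < 0)
                    if consumed and sub_id not in seen:
                        seen.add(sub_id)
                        next_frontier.append(sub_id)
        frontier = sorted(next_frontier)
        depth += 1
    # drop the target itself from the report unless it is an orphan
    breakpoints = [
        (m, reason) for m, reason in breakpoints
        if m != target or reason == "orphan"
    ]
    breakpoints.sort()
    return breakpoints


@dataclass
class GapFillResult:
    """Outcome of one gap-filling pass."""

    added_reactions: list[str]
    restored_targets: list[str]
    unrestored_targets: list[str]
    scale: str
    per_target: dict[str, list[str]] = field(default_factory=dict)


def gapfill(model: GEM, pool: UniversalPool, targets: list[str],
            scale: str = "pathway", *, max_set_size: int = 2,
            medium: dict[str, tuple[float, float]] | None = None,
            ) -> tuple[GEM, GapFillResult]:
    """Restore producibility of targets with minimal pool additions.

    Candidates are pool entries not already in the model; at ``pathway``
    scale they must share a pathway with some reaction already present.
    Per target, candidate sets of size 1 then 2 (iterative deepening,
    lexicographic tie-break) are tried until the target becomes producible.
    Reactions are only ever added, so producibility of everything already
    producible is preserved.  Unrestorable targets are reported, not raised.
    """
    if scale not in ("pathway", "global"):
        raise ValueError(f"scale must be 'pathway' or 'global', got {scale!r}")
    for t in targets:
        if t not in model.metabolites:
            raise ValueError(f"gap-filling target {t!r} not in model")

    model_pathways = {r.pathway for r in model.reactions.values() if r.pathway}
    candidates = []
    for entry in sorted(pool, key=lambda e: e.reaction_id):
        if entry.reaction_id in model.reactions:
            continue
        if scale == "pathway" and entry.pathway not in model_pathways:
            continue
        candidates.append(entry)

    work = model.copy()
    added: list[str] = []
    restored: list[str] = []
    unrestored: list[str] = []
    per_target: dict[str, list[str]] = {}

    for target in targets:
        ok, _ = is_producible(work, target, medium)
        if ok:
            restored.append(target)
            per_target[target] = []
            continue
        open_candidates = [c for c in candidates if c.reaction_id not in work.reactions]
        solution = None
        for size in range(1, max_set_size + 1):
            for combo in itertools.combinations(open_candidates, size):
                trial = work.copy()
                for entry in combo:
                    trial.add_reaction(pool.to_reaction(entry),
                                       allow_new_metabolites=True)
                ok, _ = is_producible(trial, target, medium)
                if ok:
                    solution = combo
                    break
            if solution:
                break
        if solution is None:
            unrestored.append(target)
            continue
        ids = [e.reaction_id for e in solution]
        for entry in solution:
            work.add_reaction(pool.to_reaction(entry), allow_new_metabolites=True)
        added.extend(ids)
        restored.append(target)
        per_target[target] = ids

    return work, GapFillResult(
        added_reactions=added,
        restored_targets=restored,
        unrestored_targets=unrestored,
        scale=scale,
        per_target=per_target,
    )
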