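"""Basic-property checks for a GEM, in the style of the COBRA sanity tests.

Ten checks run in a fixed order: (1) leakage of exchanged metabolites from
the fully closed model; (2) leakage through per-metabolite demand
reactions; (3) energy from water; (4) matter from a reversed ATP demand;
(5) flux through the cytosolic proton demand; (6) implausibly high ATP
yield from glucose; (7) duplicated reactions; (8) empty stoichiometry
columns; (9) demand reactions with a negative lower bound; (10) whether a
single-gene-deletion screen runs.

Each check returns a pass/fail verdict with flux witnesses naming the
implicated metabolites or reactions; checks whose prerequisites are absent
(e.g. no ATP demand in the model) are reported as skipped, never silently
passed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .fba import fba, single_gene_deletion
from .model import GEM, Reaction

EPS = 1e-6
DEFAULT_ATP_YIELD_CAP = 40.0  # mol ATP per mol glucose considered plausible


@dataclass
class MetaboliteRoles:
    """Ids of the role metabolites the energy/matter checks refer to."""

    water: str | None = "h2o[c]"
    atp: str | None = "atp[c]"
    proton: str | None = "h[c]"
    glucose: str | None = "glc[c]"


@dataclass
class CheckResult:
    name: str
    passed: bool | None            # None = skipped
    witnesses: list[tuple[str, float]] = field(default_factory=list)
    note: str = ""


@dataclass
class SanityReport:
    checks: list[CheckResult]

    @property
    def all_passed(self) -> bool:
        return all(c.passed is not False for c in self.checks)

    def __getitem__(self, name: str) -> CheckResult:
        for c in self.checks:
            if c.name == name:
                return c
        raise KeyError(name)


def _closed(model: GEM) -> GEM:
    """Copy of the model with every exchange closed to uptake (lb = 0)."""
    out = model.copy()
    for rxn in out.reactions.values():
        if rxn.kind == "exchange" and rxn.lower_bound < 0:
            rxn.lower_bound = 0.0
    return out


def _base(mid: str) -> str:
    return mid[:-3] if mid.endswith(("[c]", "[e]")) else mid


def _find_exchange(model: GEM, cytosolic_id: str | None) -> Reaction | None:
    if cytosolic_id is None:
        return None
    want = _base(cytosolic_id)
    for rxn in model.reactions.values():
        if rxn.kind == "exchange":
            (mid,) = rxn.stoichiometry
            if _base(mid) == want:
                return rxn
    return None


def _find_demand(model: GEM, met_id: str | None) -> Reaction | None:
    if met_id is None:
        return None
    for rxn in model.reactions.values():
        if rxn.kind == "demand" and rxn.stoichiometry.get(met_id, 0) < 0:
            return rxn
    return None


def leak_test_closed(model: GEM, *, eps: float = EPS) -> CheckResult:
    """Check (1): can the closed model export anything from nothing?"""
    closed = _closed(model)
    witnesses = []
    for rxn in closed.exchanges():
        sol = fba(closed, rxn.id, "max")
        flux = sol.objective_value if sol.optimal else (
            float("inf") if sol.status == "unbounded" else 0.0)
        if flux > eps:
            (mid,) = rxn.stoichiometry
            witnesses.append((mid, flux))
    return CheckResult("leak_closed", passed=not witnesses, witnesses=witnesses)


def leak_test_demands(model: GEM, *, eps: float = EPS) -> CheckResult:
    """Check (2): does any per-metabolite demand carry flux when closed?"""
    closed = _closed(model)
    witnesses = []
    for mid in closed.metabolite_ids:
        trial = closed.copy()
        did = f"__DM_{mid}"
        trial.add_reaction(Reaction(
            id=did, stoichiometry={mid: -1.0},
            lower_bound=0.0, upper_bound=1000.0, kind="demand"))
        sol = fba(trial, did, "max")
        flux = sol.objective_value if sol.optimal else (
            float("inf") if sol.status == "unbounded" else 0.0)
        if flux > eps:
            witnesses.append((mid, flux))
    return CheckResult("leak_demands", passed=not witnesses, witnesses=witnesses)


def energy_matter_checks(model: GEM, roles: MetaboliteRoles, *,
                         eps: float = EPS,
                         atp_yield_cap: float = DEFAULT_ATP_YIELD_CAP,
                         ) -> list[CheckResult]:
    """Checks (3)–(6): energy/matter generation pathologies.

    (3) water-only uptake must not drive the ATP demand; (4) a reversed
    ATP demand must not let any exchange export matter; (5) the cytosolic
    proton demand must carry no flux in the closed model; (6) ATP yield
    from 1 mmol glucose must stay below the plausibility cap.
    """
    results: list[CheckResult] = []
    closed = _closed(model)
    atp_demand = _find_demand(model, roles.atp)

    # (3) energy from water
    water_ex = _find_exchange(model, roles.water)
    if atp_demand is None or water_ex is None:
        results.append(CheckResult(
            "energy_from_water", passed=None,
            note="skipped: needs an ATP demand and a water exchange"))
    else:
        trial = _closed(model)
        trial.reactions[water_ex.id].lower_bound = -1000.0
        sol = fba(trial, atp_demand.id, "max")
        flux = sol.objective_value if sol.optimal else (
            float("inf") if sol.status == "unbounded" else 0.0)
        results.append(CheckResult(
            "energy_from_water", passed=flux <= eps,
            witnesses=[(atp_demand.id, flux)] if flux > eps else []))

    # (4) matter from reversed ATP demand
    if atp_demand is None:
        results.append(CheckResult(
            "matter_from_reversed_atp", passed=None,
            note="skipped: no ATP demand in model"))
    else:
        trial = _closed(model)
        trial.reactions[atp_demand.id].lower_bound = -1000.0
        witnesses = []
        for rxn in trial.exchanges():
            sol = fba(trial, rxn.id, "max")
            flux = sol.objective_value if sol.optimal else (
                float("inf") if sol.status == "unbounded" else 0.0)
            if flux > eps:
                (mid,) = rxn.stoichiometry
                witnesses.append((mid, flux))
        results.append(CheckResult(
            "matter_from_reversed_atp", passed=not witnesses, witnesses=witnesses))

    # (5) flux through the proton demand
    if roles.proton is None or roles.proton not in model.metabolites:
        results.append(CheckResult(
            "proton_demand_flux", passed=None,
            note="skipped: proton role not present"))
    else:
        trial = closed.copy()
        demand = _find_demand(trial, roles.proton)
        if demand is None:
            did = "__DM_proton"
            trial.add_reaction(Reaction(
                id=did, stoichiometry={roles.proton: -1.0},
                lower_bound=0.0, upper_bound=1000.0, kind="demand"))
            demand = trial.reactions[did]
        sol = fba(trial, demand.id, "max")
        flux = sol.objective_value if sol.optimal else (
            float("inf") if sol.status == "unbounded" else 0.0)
        results.append(CheckResult(
            "proton_demand_flux", passed=flux <= eps,
            witnesses=[(roles.proton, flux)] if flux > eps else []))

    # (6) ATP yield from glucose
    glc_ex = _find_exchange(model, roles.glucose)
    if atp_demand is None or glc_ex is None:
        results.append(CheckResult(
            "atp_yield_from_glucose", passed=None,
            note="skipped: needs an ATP demand and a glucose exchange"))
    else:
        trial = _closed(model)
        trial.reactions[glc_ex.id].lower_bound = -1.0
        sol = fba(trial, atp_demand.id, "max")
        flux = sol.objective_value if sol.optimal else (
            float("inf") if sol.status == "unbounded" else 0.0)
        results.append(CheckResult(
            "atp_yield_from_glucose", passed=flux <= atp_yield_cap,
            witnesses=[(atp_demand.id, flux)]))
    return results


def structural_checks(model: GEM) -> list[CheckResult]:
    """Checks (7)–(9): duplicates, empty columns, demand lower bounds."""
    canon: dict[tuple, list[str]] = {}
    for rxn in model.reactions.values():
        key = tuple(sorted((m, round(c, 9)) for m, c in rxn.stoichiometry.items()))
        canon.setdefault(key, []).append(rxn.id)
    dupes = [(", ".join(sorted(ids)), float(len(ids)))
             for ids in canon.values() if len(ids) > 1]
    empty = [(rxn.id, 0.0) for rxn in model.reactions.values()
             if not any(rxn.stoichiometry.values())]
    bad_demands = [(rxn.id, rxn.lower_bound)
                   for rxn in model.reactions.values()
                   if rxn.kind == "demand" and rxn.lower_bound < 0]
    return [
        CheckResult("duplicate_reactions", passed=not dupes, witnesses=dupes),
        CheckResult("empty_columns", passed=not empty, witnesses=empty),
        CheckResult("demand_lower_bounds", passed=not bad_demands,
                    witnesses=bad_demands),
    ]


def run_all(model: GEM, roles: MetaboliteRoles | None = None, *,
            eps: float = EPS,
            atp_yield_cap: float = DEFAULT_ATP_YIELD_CAP) -> SanityReport:
    """Run all ten checks; per-check failures never abort the suite."""
    roles = roles or MetaboliteRoles()
    checks: list[CheckResult] = []
    checks.append(leak_test_closed(model, eps=eps))
    checks.append(leak_test_demands(model, eps=eps))
    checks.extend(energy_matter_checks(
        model, roles, eps=eps, atp_yield_cap=atp_yield_cap))
    checks.extend(structural_checks(model))
    if not model.genes():
        checks.append(CheckResult(
            "single_gene_deletion_runs", passed=None,
            note="skipped: model carries no gene associations"))
    else:
        try:
            objective = model.objective_id or model.reaction_ids[0]
            result = single_gene_deletion(model, objective)
            checks.append(CheckResult(
                "single_gene_deletion_runs", passed=True,
                witnesses=[("genes_screened", float(len(result)))]))
        except Exception as exc:  # a crash is the failure being tested for
            checks.append(CheckResult(
                "single_gene_deletion_runs", passed=False, note=str(exc)))
    return SanityReport(checks=checks)
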