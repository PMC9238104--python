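"""Flux balance analysis over a GEM via linear programming.

Solves max/min cᵀv subject to S·v = 0 and lb ≤ v ≤ ub with the HiGHS
solver behind :func:`scipy.optimize.linprog`.  Also provides the bound
policy used throughout the pipeline, single-gene deletion screening and
parsimonious flux comparison between two fixed growth rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .model import GEM, FluxSolution, Reaction, stoichiometric_matrix

#: mass-balance residual tolerance asserted on optimal solutions
STEADY_STATE_TOL = 1e-6

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


class InfeasibleError(RuntimeError):
    """Raised when a computation requires an optimum but the LP has none."""

    def __init__(self, message: str, status: str):
        super().__init__(message)
        self.status = status


def fba(model: GEM, objective: str | None = None, sense: str = "max") -> FluxSolution:
    """Optimise the flux through one reaction at steady state.

    Parameters
    ----------
    model:
        The GEM; ``model.objective_id`` is used when *objective* is None.
    objective:
        Reaction id whose flux is optimised.
    sense:
        ``"max"`` or ``"min"``.

    Returns a :class:`FluxSolution` whose status is reported faithfully —
    an infeasible or unbounded LP never yields silent zero fluxes.
    """
    objective = objective or model.objective_id
    if objective is None:
        raise ValueError("no objective reaction given and model has none set")
    if objective not in model.reactions:
        raise ValueError(f"objective reaction {objective!r} not in model")
    if sense not in ("max", "min"):
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")

    rxn_ids = model.reaction_ids
    n = len(rxn_ids)
    if n == 0:
        return FluxSolution(status="optimal", objective_value=0.0, fluxes={})
    c = np.zeros(n)
    c[rxn_ids.index(objective)] = -1.0 if sense == "max" else 1.0
    S = stoichiometric_matrix(model)
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions.values()]
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": 1e-9,
                 "dual_feasibility_tolerance": 1e-9},
    )
    status = _STATUS.get(res.status, "numerical")
    if status != "optimal":
        return FluxSolution(status=status, objective_value=float("nan"), fluxes={})
    fluxes = dict(zip(rxn_ids, (float(x) for x in res.x)))
    value = fluxes[objective]
    return FluxSolution(status="optimal", objective_value=value, fluxes=fluxes)


def pfba(model: GEM, objective: str | None = None, *,
         fixed_rate: float | None = None) -> FluxSolution:
    """Parsimonious FBA: minimise Σ|v| at a fixed objective flux.

    When *fixed_rate* is None the objective is first maximised and then
    pinned at its optimum.  The total-flux minimisation selects a unique,
    reproducible point from the (generally degenerate) optimal face.
    """
    objective = objective or model.objective_id
    if fixed_rate is None:
        sol = fba(model, objective, "max")
        if not sol.optimal:
            return sol
        fixed_rate = sol.objective_value

    work = model.copy()
    rxn = work.reactions[objective]
    rxn.lower_bound = rxn.upper_bound = float(fixed_rate)

    rxn_ids = work.reaction_ids
    n = len(rxn_ids)
    S = stoichiometric_matrix(work).toarray()
    # split v = p − n only where the sign is genuinely free
    cols: list[np.ndarray] = []
    cost: list[float] = []
    bounds: list[tuple[float, float]] = []
    back: list[tuple[int, float]] = []  # (reaction index, sign)
    for j, r in enumerate(work.reactions.values()):
        if r.lower_bound >= 0:
            cols.append(S[:, j]); cost.append(1.0)
            bounds.append((r.lower_bound, r.upper_bound)); back.append((j, 1.0))
        elif r.upper_bound <= 0:
            cols.append(S[:, j]); cost.append(-1.0)
            bounds.append((r.lower_bound, r.upper_bound)); back.append((j, 1.0))
        else:
            cols.append(S[:, j]); cost.append(1.0)
            bounds.append((0.0, r.upper_bound)); back.append((j, 1.0))
            cols.append(-S[:, j]); cost.append(1.0)
            bounds.append((0.0, -r.lower_bound)); back.append((j, -1.0))
    A = np.column_stack(cols) if cols else np.zeros((S.shape[0], 0))
    res = linprog(
        np.asarray(cost),
        A_eq=A,
        b_eq=np.zeros(A.shape[0]),
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": 1e-9,
                 "dual_feasibility_tolerance": 1e-9},
    )
    status = _STATUS.get(res.status, "numerical")
    if status != "optimal":
        return FluxSolution(status=status, objective_value=float("nan"), fluxes={})
    v = np.zeros(n)
    for x, (j, sign) in zip(res.x, back):
        v[j] += sign * float(x)
    fluxes = dict(zip(rxn_ids, v))
    return FluxSolution(status="optimal", objective_value=fluxes[objective],
                        fluxes=fluxes)


# ---------------------------------------------------------------------------
# Bound policy

#: default bound templates per nutrient class (mmol·gDW⁻¹·h⁻¹)
DEFAULT_CLASS_BOUNDS = {
    "synthesizable": (0.0, 1000.0),
    "feed": (-5.0, 1000.0),
    "trace_element": (-1.0, 1000.0),
    "semi_essential": (-3.0, 1000.0),
}


@dataclass
class BoundsPolicy:
    """The bound conventions used when turning a network into an LP.

    Internal reversible reactions get (−1000, 1000); irreversible ones
    (0, 1000).  Exchange reactions are bounded by nutrient class: nutrients
    the organism synthesises itself are closed to uptake (0, 1000); feed
    nutrients (−5, 1000); trace elements (−1, 1000); semi-essential amino
    acids (−3, 1000).  Per-reaction overrides always win.
    """

    reversible: tuple[float, float] = (-1000.0, 1000.0)
    irreversible: tuple[float, float] = (0.0, 1000.0)
    class_bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_BOUNDS))
    overrides: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (lb, ub) in {**self.class_bounds, **self.overrides,
                               "reversible": self.reversible,
                               "irreversible": self.irreversible}.items():
            if lb > ub:
                raise ValueError(f"policy entry {name!r}: lb {lb} > ub {ub}")


def apply_policy(model: GEM, policy: BoundsPolicy,
                 nutrient_classes: dict[str, str] | None = None) -> GEM:
    """Return a copy of the model with bounds set by class, then overrides.

    *nutrient_classes* maps reaction ids (typically exchange/transport
    reactions) to a class label known to the policy.
    """
    nutrient_classes = nutrient_classes or {}
    for rid, label in nutrient_classes.items():
        if rid not in model.reactions:
            raise ValueError(f"classed reaction {rid!r} not in model")
        if label not in policy.class_bounds:
            raise ValueError(
                f"unknown nutrient class {label!r} for reaction {rid!r}; "
                f"known classes: {sorted(policy.class_bounds)}"
            )
    out = model.copy()
    for rxn in out.reactions.values():
        if rxn.kind == "biomass":
            continue
        base = policy.reversible if rxn.reversible else policy.irreversible
        rxn.lower_bound, rxn.upper_bound = base
    for rid, label in nutrient_classes.items():
        rxn = out.reactions[rid]
        rxn.lower_bound, rxn.upper_bound = policy.class_bounds[label]
    for rid, (lb, ub) in policy.overrides.items():
        if rid in out.reactions:
            rxn = out.reactions[rid]
            rxn.lower_bound, rxn.upper_bound = lb, ub
    return out


# ---------------------------------------------------------------------------
# Gene deletion and flux comparison


def single_gene_deletion(model: GEM, objective: str | None = None) -> dict[str, float]:
    """Optimal objective value after deleting each gene in turn.

    A reaction is disabled only when *all* of its listed genes are deleted,
    so a single deletion silences exactly the reactions supported by that
    one gene alone.  Infeasible knockouts report 0.0.
    """
    objective = objective or model.objective_id
    results: dict[str, float] = {}
    for gene in sorted(model.genes()):
        knocked = model.copy()
        for rxn in knocked.reactions.values():
            if rxn.genes and set(rxn.genes) <= {gene}:
                rxn.lower_bound = rxn.upper_bound = 0.0
        sol = fba(knocked, objective, "max")
        results[gene] = sol.objective_value if sol.optimal else 0.0
    return results


@dataclass
class FluxCompareResult:
    """Reactions whose parsimonious flux shifts between two growth rates."""

    changed: list[tuple[str, float, float, float]]  # (id, v_low, v_high, |Δ|)
    threshold: float
    pathways: dict[str, str] = field(default_factory=dict)
    subsystems: dict[str, str] = field(default_factory=dict)


def flux_compare(model: GEM, objective: str | None = None, *,
                 rate_low: float, rate_high: float,
                 threshold: float = 1e-6) -> FluxCompareResult:
    """Compare parsimonious flux distributions at two fixed biomass rates.

    The biomass flux is pinned (lb = ub = rate) and Σ|v| minimised at each
    rate so the comparison is well defined despite degenerate FBA optima.
    Reactions with |Δflux| > threshold are listed sorted by |Δ| descending
    (ties broken by id).
    """
    objective = objective or model.objective_id
    sols = {}
    for label, rate in (("low", rate_low), ("high", rate_high)):
        sol = pfba(model, objective, fixed_rate=rate)
        if not sol.optimal:
            raise InfeasibleError(
                f"model infeasible with biomass fixed at rate_{label}={rate}",
                sol.status,
            )
        sols[label] = sol
    changed = []
    for rid in model.reaction_ids:
        v_lo = sols["low"].fluxes[rid]
        v_hi = sols["high"].fluxes[rid]
        delta = abs(v_hi - v_lo)
        if delta > threshold:
            changed.append((rid, v_lo, v_hi, delta))
    changed.sort(key=lambda t: (-t[3], t[0]))
    return FluxCompareResult(
        changed=changed,
        threshold=threshold,
        pathways={rid: model.reactions[rid].pathway for rid, *_ in changed},
        subsystems={rid: model.reactions[rid].subsystem for rid, *_ in changed},
    )


def steady_state_residual(model: GEM, solution: FluxSolution) -> float:
    """‖S·v‖∞ for a flux solution, for verifying mass balance."""
    if not solution.fluxes:
        return 0.0
    S = stoichiometric_matrix(model)
    v = np.array([solution.fluxes[rid] for rid in model.reaction_ids])
    return float(np.abs(S @ v).max()) if S.shape[1] else 0.0
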