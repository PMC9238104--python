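"""Nutritional-requirement simulation and growth-rate calculation.

At a biomass rate pinned to 1 gDW·h⁻¹, the flux of each nutrient's
exchange reaction is the optimal absorption needed to accumulate one gram
of dry weight; exchange flux is negative on uptake and requirements are
reported as positive uptake, net exports as negative with an accumulation
flag.  Dividing the simulated uptake by the literature feed demand (after
converting feed contents into mmol·gDW⁻¹·h⁻¹ through the molar mass of
the measured carrier form) gives the deposition rate: the fraction of the
dietary supply that ends up deposited in body mass.

The specific growth rate (SGR) converts a simulated biomass synthesis rate
x (gDW·d⁻¹) into percent body-mass gain per day for an animal of initial
fresh mass m₁ fed a daily ration of f·m₁ grams:

    SGR = [ln(m₁ + f·m₁·x/(1−w)) − ln(m₁)] × 100   (%·d⁻¹)

where w is the body water fraction (dry weight is scaled back to fresh
weight by 1/(1−w)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .fba import InfeasibleError, fba, pfba
from .model import GEM

UNITS = ("percent_of_feed", "g_per_kg", "mg_per_kg")


@dataclass
class LiteratureDemand:
    """A feed-content demand from the literature, in its measured form."""

    nutrient: str                # exchange reaction id or nutrient label
    value: float                 # numeric content in `unit`
    unit: str                    # percent_of_feed | g_per_kg | mg_per_kg
    carrier_molar_mass: float    # g/mol of the measured form

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"{self.nutrient}: negative demand value")
        if self.carrier_molar_mass <= 0:
            raise ValueError(f"{self.nutrient}: molar mass must be positive")
        if self.unit not in UNITS:
            raise ValueError(
                f"{self.nutrient}: unknown unit {self.unit!r}; "
                f"expected one of {UNITS}")


def literature_to_mmol(demand: LiteratureDemand) -> float:
    """Convert a feed content into mmol·gDW⁻¹·h⁻¹ at 1 g feed per day.

    All units reduce to mg nutrient per g feed divided by mg per mmol of
    the carrier: percent → value×10 mg/g; g/kg → value mg/g; mg/kg →
    value/1000 mg/g.
    """
    if demand.unit == "percent_of_feed":
        mg_per_g = demand.value * 10.0
    elif demand.unit == "g_per_kg":
        mg_per_g = demand.value
    else:  # mg_per_kg
        mg_per_g = demand.value / 1000.0
    return mg_per_g / demand.carrier_molar_mass


@dataclass
class RequirementRow:
    """Simulated vs literature demand for one nutrient."""

    nutrient: str
    simulated_mmol: float               # uptake positive, accumulation negative
    literature_mmol: float | None = None
    deposition_rate: float | None = None  # fraction; None when undefined
    accumulated: bool = False


def deposition_rate(simulated: float, literature: float) -> float:
    """Fraction of the dietary requirement deposited into biomass."""
    if literature <= 0:
        raise ValueError("literature demand must be positive")
    return simulated / literature


def simulate_requirements(model: GEM, *, biomass_rate: float = 1.0,
                          objective: str | None = None,
                          parsimonious: bool = False,
                          demands: list[LiteratureDemand] | None = None,
                          ) -> list[RequirementRow]:
    """Optimal nutrient absorption at a fixed biomass synthesis rate.

    The biomass reaction is pinned (lb = ub = biomass_rate) and the flux
    distribution computed by FBA (or pFBA when *parsimonious*).  Each
    exchange reaction's flux gives the nutrient's requirement: uptake
    (negative exchange flux) is reported positive; a net export is
    reported negative and flagged as accumulation.  When literature
    demands are supplied, deposition rates are attached by matching the
    demand's ``nutrient`` field to the exchange reaction id.
    """
    objective = objective or model.objective_id
    if objective is None:
        raise ValueError("model has no biomass objective set")
    work = model.copy()
    rxn = work.reactions[objective]
    rxn.lower_bound = rxn.upper_bound = float(biomass_rate)
    if parsimonious:
        sol = pfba(work, objective, fixed_rate=biomass_rate)
    else:
        sol = fba(work, objective, "max")
    if not sol.optimal:
        raise InfeasibleError(
            f"model infeasible at biomass rate {biomass_rate}; check that "
            f"every biomass precursor is producible", sol.status)
    by_nutrient = {d.nutrient: d for d in (demands or [])}
    rows: list[RequirementRow] = []
    for ex in model.exchanges():
        flux = sol.fluxes[ex.id]
        simulated = -flux  # uptake positive
        row = RequirementRow(
            nutrient=ex.id,
            simulated_mmol=simulated,
            accumulated=simulated < 0,
        )
        demand = by_nutrient.get(ex.id)
        if demand is not None:
            row.literature_mmol = literature_to_mmol(demand)
            if row.literature_mmol > 0 and simulated >= 0:
                row.deposition_rate = deposition_rate(
                    simulated, row.literature_mmol)
        rows.append(row)
    return rows


@dataclass
class SGRParams:
    """Inputs of the specific-growth-rate formulas."""

    m1: float = 8.41                 # initial fresh mass, g
    water_fraction: float = 0.516    # g water / g fresh biomass
    feed_fraction_min: float = 0.03  # daily ration, fraction of body mass
    feed_fraction_max: float = 0.05
    x: float = 0.0                   # simulated biomass synthesis, gDW·d⁻¹

    def __post_init__(self) -> None:
        if not 0 < self.water_fraction < 1:
            raise ValueError("water fraction must lie strictly in (0, 1)")
        if not 0 < self.feed_fraction_min <= self.feed_fraction_max:
            raise ValueError("need 0 < feed_fraction_min ≤ feed_fraction_max")
        if self.m1 <= 0:
            raise ValueError("initial mass must be positive")


def sgr(params: SGRParams) -> tuple[float, float]:
    """Specific growth rate range (%·d⁻¹) for the feed-ration bracket.

    ``SGR = [ln(m₁ + f·m₁·x/(1−w)) − ln(m₁)] × 100`` evaluated at the
    minimum and maximum daily feed fraction f.
    """
    out = []
    for f in (params.feed_fraction_min, params.feed_fraction_max):
        ration = f * params.m1                      # g feed per day
        fresh_gain = ration * params.x / (1.0 - params.water_fraction)
        out.append((math.log(params.m1 + fresh_gain) - math.log(params.m1)) * 100.0)
    return out[0], out[1]


@dataclass
class FeedGrowthResult:
    """Maximum biomass rate under literature feed supply."""

    biomass_rate: float                                  # gDW·h⁻¹
    absorbed: dict[str, float] = field(default_factory=dict)   # uptake used
    offered: dict[str, float] = field(default_factory=dict)    # supply cap
    unabsorbed: dict[str, float] = field(default_factory=dict)  # waste


def growth_under_feed(model: GEM, demands: list[LiteratureDemand], *,
                      objective: str | None = None) -> FeedGrowthResult:
    """Maximise biomass with nutrient uptakes capped at the feed contents.

    Each demand's exchange gets lb = −literature_to_mmol(demand); other
    bounds are left as configured.  Also reports per-nutrient absorbed vs
    offered amounts — the unabsorbed surplus is the fraction of the feed
    excreted to the water.
    """
    objective = objective or model.objective_id
    work = model.copy()
    offered: dict[str, float] = {}
    for demand in demands:
        if demand.nutrient not in work.reactions:
            raise ValueError(
                f"demand {demand.nutrient!r} names no exchange reaction")
        cap = literature_to_mmol(demand)
        offered[demand.nutrient] = cap
        work.reactions[demand.nutrient].lower_bound = -cap
    sol = fba(work, objective, "max")
    if not sol.optimal:
        raise InfeasibleError(
            f"biomass maximisation failed ({sol.status})", sol.status)
    absorbed = {
        rid: max(0.0, -sol.fluxes[rid]) for rid in offered
    }
    unabsorbed = {rid: offered[rid] - absorbed[rid] for rid in offered}
    return FeedGrowthResult(
        biomass_rate=sol.objective_value,
        absorbed=absorbed,
        offered=offered,
        unabsorbed=unabsorbed,
    )
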