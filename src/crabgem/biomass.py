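"""Biomass-equation construction from a measured composition table.

The biomass reaction is a pseudo-reaction consuming each measured
precursor at a coefficient in mmol per gram dry weight and producing one
gram dry weight of a biomass pseudo-metabolite.  Contents are measured on
fresh weight; the dry-weight basis is obtained by dividing out the
non-water fraction:

    coefficient [mmol·gDW⁻¹] = (content/100) / (1 − w) / M × 1000

with content in g per 100 g fresh weight, w the water fraction and M the
molar mass of the measured form in g·mol⁻¹ (equivalently: mg per gDW
divided by mg per mmol).  Growth-associated maintenance is added as ATP
hydrolysis (ATP + H₂O → ADP + Pi), optionally NADPH turnover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .constants import DEFAULT_MAINTENANCE_ATP, DEFAULT_WATER_FRACTION
from .model import GEM, Metabolite, Reaction, ValidationError

COMPONENT_CLASSES = ("amino_acid", "fatty_acid", "mineral", "saccharide", "other")


@dataclass
class CompositionRow:
    component: str          # model metabolite id (cytosolic)
    component_class: str    # one of COMPONENT_CLASSES
    content: float          # g per 100 g fresh weight
    molar_mass: float       # g/mol of the measured form

    def __post_init__(self) -> None:
        if self.content < 0:
            raise ValueError(f"{self.component}: negative content")
        if self.molar_mass <= 0:
            raise ValueError(f"{self.component}: molar mass must be positive")
        if self.component_class not in COMPONENT_CLASSES:
            raise ValueError(
                f"{self.component}: unknown class {self.component_class!r}")


@dataclass
class BiomassComposition:
    """Measured nutritional composition on a fresh-weight basis."""

    rows: list[CompositionRow]
    water_fraction: float = DEFAULT_WATER_FRACTION

    def __post_init__(self) -> None:
        if not 0 < self.water_fraction < 1:
            raise ValueError("water fraction must lie strictly in (0, 1)")

    @classmethod
    def from_tsv(cls, path: str | Path,
                 water_fraction: float = DEFAULT_WATER_FRACTION,
                 ) -> "BiomassComposition":
        df = pd.read_csv(path, sep="\t")
        rows = [
            CompositionRow(
                component=str(r.component),
                component_class=str(getattr(r, "component_class", None)
                                    or getattr(r, "clazz", "other")),
                content=float(r.content_g_per_100g),
                molar_mass=float(r.molar_mass),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(rows=rows, water_fraction=water_fraction)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame([
            {
                "component": r.component,
                "component_class": r.component_class,
                "content_g_per_100g": r.content,
                "molar_mass": r.molar_mass,
            }
            for r in self.rows
        ]).to_csv(path, sep="\t", index=False)


def content_to_coefficient(content: float, molar_mass: float,
                           water_fraction: float = DEFAULT_WATER_FRACTION,
                           ) -> float:
    """Convert g per 100 g fresh weight into mmol per gDW.

    ``(content/100) / (1 − water_fraction) / molar_mass × 1000``.
    """
    if content < 0 or molar_mass <= 0:
        raise ValueError("content must be ≥ 0 and molar mass > 0")
    if not 0 <= water_fraction < 1:
        raise ValueError("water fraction must lie in [0, 1)")
    return (content / 100.0) / (1.0 - water_fraction) / molar_mass * 1000.0


@dataclass
class MaintenanceConfig:
    """Growth-associated maintenance terms of the biomass reaction."""

    atp: float = DEFAULT_MAINTENANCE_ATP       # mmol ATP hydrolysed per gDW
    nadph: float = 0.0                          # mmol NADPH per gDW (off)
    atp_id: str = "atp[c]"
    h2o_id: str = "h2o[c]"
    adp_id: str = "adp[c]"
    pi_id: str = "pi[c]"
    nadph_id: str = "nadph[c]"
    nadp_id: str = "nadp[c]"


@dataclass
class BiomassEquation:
    """Precursor and maintenance coefficients of a biomass reaction."""

    coefficients: dict[str, float]   # metabolite id → mmol·gDW⁻¹ consumed
    maintenance: dict[str, float]    # metabolite id → signed coefficient
    biomass_id: str = "biomass[c]"


def build_biomass(composition: BiomassComposition,
                  maintenance: MaintenanceConfig | None = None,
                  *, biomass_metabolite: str = "biomass[c]",
                  reaction_id: str = "BIOMASS",
                  ) -> tuple[BiomassEquation, Reaction]:
    """Assemble the biomass equation and its Reaction.

    Each composition row contributes a consumed precursor term; maintenance
    ATP enters with hydrolysis stoichiometry (ATP + H₂O → ADP + Pi).  The
    reaction produces exactly 1 unit of the biomass pseudo-metabolite and
    its flux is read in gDW·h⁻¹.
    """
    maintenance = maintenance or MaintenanceConfig()
    coefficients: dict[str, float] = {}
    for row in composition.rows:
        coeff = content_to_coefficient(
            row.content, row.molar_mass, composition.water_fraction)
        coefficients[row.component] = coefficients.get(row.component, 0.0) + coeff

    maint: dict[str, float] = {}
    if maintenance.atp > 0:
        maint[maintenance.atp_id] = -maintenance.atp
        maint[maintenance.h2o_id] = maint.get(maintenance.h2o_id, 0.0) - maintenance.atp
        maint[maintenance.adp_id] = maintenance.atp
        maint[maintenance.pi_id] = maintenance.atp
    if maintenance.nadph > 0:
        maint[maintenance.nadph_id] = -maintenance.nadph
        maint[maintenance.nadp_id] = maintenance.nadph

    stoich: dict[str, float] = {m: -c for m, c in coefficients.items() if c > 0}
    for mid, coeff in maint.items():
        stoich[mid] = stoich.get(mid, 0.0) + coeff
    stoich[biomass_metabolite] = 1.0

    reaction = Reaction(
        id=reaction_id,
        name="biomass synthesis",
        stoichiometry=stoich,
        lower_bound=0.0,
        upper_bound=1000.0,
        kind="biomass",
    )
    equation = BiomassEquation(
        coefficients=coefficients,
        maintenance=maint,
        biomass_id=biomass_metabolite,
    )
    return equation, reaction


def attach_objective(model: GEM, biomass: Reaction) -> GEM:
    """Add the biomass reaction to a model and make it the objective.

    All precursor metabolites must already exist; the biomass
    pseudo-metabolite and a demand draining it are created.  A model that
    already carries a biomass reaction is rejected.
    """
    for rxn in model.reactions.values():
        if rxn.kind == "biomass":
            raise ValidationError(
                f"model already has a biomass reaction ({rxn.id!r})")
    biomass_met = next(
        (mid for mid, c in biomass.stoichiometry.items() if c > 0
         and mid not in model.metabolites),
        None,
    )
    missing = [
        mid for mid in biomass.stoichiometry
        if mid not in model.metabolites and mid != biomass_met
    ]
    if missing:
        raise ValidationError(
            "biomass precursors missing from model: " + ", ".join(sorted(missing)))
    out = model.copy()
    if biomass_met is not None:
        out.add_metabolite(Metabolite(
            id=biomass_met, name="biomass", formula="UNKNOWN", compartment="c"))
    out.add_reaction(biomass.copy())
    if biomass_met is not None:
        out.add_reaction(Reaction(
            id=f"DM_{biomass_met}", name="biomass drain",
            stoichiometry={biomass_met: -1.0},
            lower_bound=0.0, upper_bound=1000.0, kind="demand",
        ))
    out.objective_id = biomass.id
    return out
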