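"""Synthetic toy GEMs with recorded ground truth.

The generator emulates the statistical structure of a whole-body
reconstruction small enough to verify by hand: a bounded substrate uptake
feeding a linear core of cytosolic conversions, biomass precursors split
into *essential* nutrients (import-only routes, as for essential amino
acids and fatty acids) and *synthesizable* ones (internal production from
the core, uptake closed), a biomass pseudo-reaction over all precursors,
optional disconnected island components, an optional polymer-leak reaction
pair with indeterminate-formula species, and optional ATP maintenance.

Because every route is planted, the maximum biomass flux has a closed
form — a Liebig-style minimum ratio over nutrient supplies:

    v* = min( min_i u_i/c_i ,  U / (Σ_j c_j + m) )

over essential nutrients i (uptake bound u_i, biomass coefficient c_i)
and the substrate bound U shared by the synthesizable precursors j and
the maintenance draw m.  Gap planting removes reactions from
biomass-essential paths into a companion pool, so gap-filling recovery can
be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .biomass import BiomassComposition, CompositionRow
from .constants import AMINO_ACID_MW, FATTY_ACID_MW, MINERAL_MW, SACCHARIDE_MW
from .gaps import is_producible
from .model import GEM, Metabolite, Reaction, format_equation
from .reconstruct import KOTable, PoolEntry, UniversalPool, add_transfer_reactions

#: uptake bound (mmol·gDW⁻¹·h⁻¹) for importable nutrients, the feed-class value
DEFAULT_UPTAKE = 5.0


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic model instance."""

    n_core_metabolites: int = 3
    n_essential_nutrients: int = 2
    n_synthesizable_nutrients: int = 2
    n_planted_gaps: int = 0
    n_islands: int = 0
    include_polymer_leak: bool = False
    maintenance_atp: float = 0.0
    uptake_bound: float = DEFAULT_UPTAKE
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_core_metabolites, self.n_essential_nutrients,
                  self.n_synthesizable_nutrients, self.n_planted_gaps,
                  self.n_islands)
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be ≥ 0")
        if self.n_core_metabolites < 1:
            raise ValueError("need at least one core metabolite")
        if self.n_essential_nutrients > 0 and self.uptake_bound <= 0:
            raise ValueError(
                "essential nutrients require a positive uptake bound")


@dataclass
class GroundTruth:
    """Facts recorded at generation time, exact by construction."""

    producible: set[str] = field(default_factory=set)
    planted_gap_ids: list[str] = field(default_factory=list)
    gap_targets: list[str] = field(default_factory=list)
    expected_n_wcc: int = 1
    expected_max_biomass: float = 0.0
    expected_requirements: dict[str, float] = field(default_factory=dict)
    biomass_coefficients: dict[str, float] = field(default_factory=dict)
    essential_ids: list[str] = field(default_factory=list)
    synthesizable_ids: list[str] = field(default_factory=list)
    polymer_reaction_ids: list[str] = field(default_factory=list)
    reaction_kos: dict[str, str] = field(default_factory=dict)
    reaction_genes: dict[str, list[str]] = field(default_factory=dict)


def make_toy_gem(spec: SyntheticSpec) -> tuple[GEM, GroundTruth]:
    """Build a balanced toy model and its analytic ground truth.

    Deterministic for a fixed seed: all randomness flows from one
    ``numpy.random.Generator``.
    """
    rng = np.random.default_rng(spec.seed)
    model = GEM(name=f"toy-seed{spec.seed}")
    truth = GroundTruth()

    # substrate and linear core, all CH2O so 1:1 steps balance exactly
    model.add_metabolite(Metabolite("sub[c]", "substrate", "CH2O"))
    core = ["sub[c]"]
    for i in range(spec.n_core_metabolites):
        mid = f"core{i}[c]"
        model.add_metabolite(Metabolite(mid, f"core intermediate {i}", "CH2O"))
        core.append(mid)
    ko_counter = 0

    def _next_ko_genes(rid: str) -> tuple[str, list[str]]:
        nonlocal ko_counter
        ko_counter += 1
        ko = f"K{ko_counter:05d}"
        genes = [f"UG{ko_counter:04d}.{j}" for j in range(int(rng.integers(1, 3)))]
        truth.reaction_kos[rid] = ko
        truth.reaction_genes[rid] = genes
        return ko, genes

    for i in range(len(core) - 1):
        rid = f"CORE{i}"
        ko, genes = _next_ko_genes(rid)
        model.add_reaction(Reaction(
            id=rid, name=f"core step {i}",
            stoichiometry={core[i]: -1.0, core[i + 1]: 1.0},
            lower_bound=0.0, upper_bound=1000.0,
            ko_ids=[ko], genes=genes,
            pathway="core metabolism", subsystem="central",
        ))
    hub = core[-1]

    # nutrients
    essential = []
    for i in range(spec.n_essential_nutrients):
        mid = f"ess{i}[c]"
        model.add_metabolite(Metabolite(mid, f"essential nutrient {i}", "CH2O"))
        essential.append(mid)
    synthesizable = []
    for i in range(spec.n_synthesizable_nutrients):
        mid = f"syn{i}[c]"
        model.add_metabolite(Metabolite(mid, f"synthesizable nutrient {i}", "CH2O"))
        synthesizable.append(mid)
        rid = f"SYN{i}"
        ko, genes = _next_ko_genes(rid)
        model.add_reaction(Reaction(
            id=rid, name=f"synthesis of syn{i}",
            stoichiometry={hub: -1.0, mid: 1.0},
            lower_bound=0.0, upper_bound=1000.0,
            ko_ids=[ko], genes=genes,
            pathway="biosynthesis", subsystem="anabolism",
        ))

    # maintenance ATP produced from the core hub (competes for substrate)
    maint = float(spec.maintenance_atp)
    if maint > 0:
        model.add_metabolite(Metabolite("atp[c]", "ATP", "CH2O"))
        rid = "ATPS"
        ko, genes = _next_ko_genes(rid)
        model.add_reaction(Reaction(
            id=rid, name="ATP synthesis",
            stoichiometry={hub: -1.0, "atp[c]": 1.0},
            lower_bound=0.0, upper_bound=1000.0,
            ko_ids=[ko], genes=genes,
            pathway="energy metabolism", subsystem="central",
        ))

    # compartmentalise: substrate and essential nutrients importable,
    # synthesizable ones export-only
    nutrients = [("sub[c]", True)]
    nutrients += [(mid, True) for mid in essential]
    nutrients += [(mid, False) for mid in synthesizable]
    model = add_transfer_reactions(model, nutrients)
    u = float(spec.uptake_bound)
    for mid, importable in nutrients:
        base = mid[:-3]
        for rid in (f"EX_{base}", f"T_{base}"):
            model.reactions[rid].pathway = "transport"
            model.reactions[rid].subsystem = "transfer"
        if importable:
            model.reactions[f"EX_{base}"].lower_bound = -u
            model.reactions[f"T_{base}"].lower_bound = -u

    # biomass over all precursors
    coeffs = {}
    for mid in essential + synthesizable:
        coeffs[mid] = float(np.round(rng.uniform(0.05, 0.5), 4))
    stoich = {mid: -c for mid, c in coeffs.items()}
    if maint > 0:
        stoich["atp[c]"] = -maint
    model.add_metabolite(Metabolite("biomass[c]", "biomass", "UNKNOWN"))
    stoich["biomass[c]"] = 1.0
    model.add_reaction(Reaction(
        id="BIOMASS", name="biomass synthesis", stoichiometry=stoich,
        lower_bound=0.0, upper_bound=1000.0, kind="biomass",
        pathway="biosynthesis", subsystem="anabolism",
    ))
    model.add_reaction(Reaction(
        id="DM_biomass", name="biomass drain",
        stoichiometry={"biomass[c]": -1.0},
        lower_bound=0.0, upper_bound=1000.0, kind="demand",
    ))
    model.objective_id = "BIOMASS"

    # islands: disconnected two-metabolite components
    for i in range(spec.n_islands):
        a, b = f"isl{i}a[c]", f"isl{i}b[c]"
        model.add_metabolite(Metabolite(a, formula="CH2O"))
        model.add_metabolite(Metabolite(b, formula="CH2O"))
        model.add_reaction(Reaction(
            id=f"ISL{i}", stoichiometry={a: -1.0, b: 1.0},
            lower_bound=0.0, upper_bound=1000.0,
            pathway="orphan pathway", subsystem="unassigned",
        ))

    # polymer-leak pair: two indeterminate-repeat species whose cycle nets
    # out free substrate, the classic starch/amylose imbalance pattern
    if spec.include_polymer_leak:
        model.add_metabolite(Metabolite(
            "starch[c]", "starch (n repeats)", "UNKNOWN"))
        model.add_metabolite(Metabolite(
            "amylose[c]", "amylose (n repeats)", "UNKNOWN"))
        model.add_reaction(Reaction(
            id="PL_POLY", name="starch <-> amylose",
            stoichiometry={"starch[c]": -1.0, "amylose[c]": 1.0},
            lower_bound=-1000.0, upper_bound=1000.0,
            pathway="starch metabolism", subsystem="saccharides",
        ))
        model.add_reaction(Reaction(
            id="PL_HYDRO", name="amylose <-> starch + substrate",
            stoichiometry={"amylose[c]": -1.0, "starch[c]": 1.0, "sub[c]": 1.0},
            lower_bound=-1000.0, upper_bound=1000.0,
            pathway="starch metabolism", subsystem="saccharides",
        ))
        truth.polymer_reaction_ids = ["PL_POLY", "PL_HYDRO"]

    # --- ground truth -------------------------------------------------
    truth.essential_ids = essential
    truth.synthesizable_ids = synthesizable
    truth.biomass_coefficients = coeffs
    ratios = [u / coeffs[mid] for mid in essential]
    chain_cost = sum(coeffs[mid] for mid in synthesizable) + maint
    if not spec.include_polymer_leak and chain_cost > 0:
        ratios.append(u / chain_cost)
    truth.expected_max_biomass = min(ratios) if ratios else (
        math.inf if spec.include_polymer_leak and chain_cost > 0 else 0.0)
    truth.expected_requirements = {
        f"EX_{mid[:-3]}": coeffs[mid] for mid in essential}
    truth.expected_requirements.update(
        {f"EX_{mid[:-3]}": 0.0 for mid in synthesizable})
    truth.expected_n_wcc = 1 + spec.n_islands
    island_mets = {f"isl{i}{s}[c]" for i in range(spec.n_islands) for s in "ab"}
    truth.producible = {
        mid for mid in model.metabolites if mid not in island_mets}
    return model, truth


# ---------------------------------------------------------------------------
# Gap planting


def _pool_entry_from_reaction(rxn: Reaction) -> PoolEntry:
    return PoolEntry(
        reaction_id=rxn.id,
        equation=format_equation(rxn),
        ko_ids=list(rxn.ko_ids),
        pathway=rxn.pathway,
        subsystem=rxn.subsystem,
    )


def plant_gaps(model: GEM, truth: GroundTruth, n: int, seed: int,
               *, n_decoys: int = 3) -> tuple[GEM, UniversalPool]:
    """Remove *n* biomass-essential reactions into a companion pool.

    Candidates are reactions every biomass route needs: core-chain steps
    (when a synthesizable precursor or maintenance depends on the chain),
    precursor synthesis steps and essential-nutrient transports.  After
    removal the biomass optimum is zero.  The returned pool holds the
    removed reactions plus decoy entries that cannot restore anything.
    """
    rng = np.random.default_rng(seed)
    chain_needed = bool(truth.synthesizable_ids) or any(
        c < 0 for mid, c in model.reactions["BIOMASS"].stoichiometry.items()
        if mid == "atp[c]")
    candidates: list[str] = []
    if chain_needed:
        candidates += [rid for rid in model.reactions if rid.startswith("CORE")]
    candidates += [rid for rid in model.reactions if rid.startswith("SYN")]
    candidates += [f"T_{mid[:-3]}" for mid in truth.essential_ids]
    candidates = sorted(set(candidates))
    if n > len(candidates):
        raise ValueError(
            f"cannot plant {n} gaps: only {len(candidates)} removable "
            f"biomass-essential reactions")
    chosen = sorted(rng.choice(candidates, size=n, replace=False).tolist())

    gapped = model.copy()
    pool = UniversalPool()
    for rid in chosen:
        rxn = gapped.remove_reaction(rid)
        pool.add(_pool_entry_from_reaction(rxn))
    gapped.objective_id = model.objective_id

    for i in range(n_decoys):
        pool.add(PoolEntry(
            reaction_id=f"DECOY{i}",
            equation=f"dec{i}a => dec{i}b",
            pathway="core metabolism",
            subsystem="central",
        ))

    new_truth_targets = []
    if n > 0:
        for mid in truth.essential_ids + truth.synthesizable_ids:
            ok, _ = is_producible(gapped, mid)
            if not ok:
                new_truth_targets.append(mid)
    truth.planted_gap_ids = chosen
    truth.gap_targets = new_truth_targets
    return gapped, pool


# ---------------------------------------------------------------------------
# KO table and composition


def make_pool(model: GEM) -> UniversalPool:
    """Universal pool holding the model's KO-annotated reactions."""
    pool = UniversalPool()
    for rxn in model.reactions.values():
        if rxn.ko_ids:
            pool.add(_pool_entry_from_reaction(rxn))
    return pool


def make_ko_table(model: GEM, dropout: float, seed: int,
                  ) -> tuple[KOTable, set[str]]:
    """Unigene→KO rows covering a (1 − dropout) fraction of reactions.

    Returns the table and the covered reaction-id set; building a draft
    from the table against :func:`make_pool` reproduces exactly the
    covered subset.
    """
    if not 0 <= dropout < 1:
        raise ValueError("dropout must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    annotated = sorted(rid for rid, r in model.reactions.items() if r.ko_ids)
    n_keep = int(round((1 - dropout) * len(annotated)))
    covered = set(rng.choice(annotated, size=n_keep, replace=False).tolist()) \
        if n_keep else set()
    pairs = []
    for rid in sorted(covered):
        rxn = model.reactions[rid]
        for ko in rxn.ko_ids:
            for gene in (rxn.genes or [f"UG_{rid}"]):
                pairs.append((gene, ko))
    return KOTable.from_pairs(pairs), covered


_CLASS_MASSES = {
    "amino_acid": AMINO_ACID_MW,
    "fatty_acid": FATTY_ACID_MW,
    "mineral": MINERAL_MW,
    "saccharide": SACCHARIDE_MW,
}


def make_composition(model: GEM, water_fraction: float = 0.516,
                     seed: int = 0) -> BiomassComposition:
    """Random composition table over the model's biomass precursors.

    Non-water contents are scaled to 90% of the dry fraction, leaving an
    ash/other remainder as real composition tables do.  Classes cycle over
    amino acid / fatty acid / mineral / saccharide; molar masses are drawn
    from the shipped constants table for the assigned class.
    """
    rng = np.random.default_rng(seed)
    biomass = next((r for r in model.reactions.values() if r.kind == "biomass"),
                   None)
    precursors = sorted(
        mid for mid, c in (biomass.stoichiometry.items() if biomass else [])
        if c < 0 and not mid.startswith("atp"))
    if not precursors:
        return BiomassComposition(rows=[], water_fraction=water_fraction)
    raw = rng.uniform(0.5, 2.0, size=len(precursors))
    budget = (1 - water_fraction) * 100.0 * 0.9
    contents = raw / raw.sum() * budget
    classes = list(_CLASS_MASSES)
    rows = []
    for i, mid in enumerate(precursors):
        cls = classes[i % len(classes)]
        mw = float(rng.choice(sorted(_CLASS_MASSES[cls].values())))
        rows.append(CompositionRow(
            component=mid, component_class=cls,
            content=float(np.round(contents[i], 4)), molar_mass=mw))
    return BiomassComposition(rows=rows, water_fraction=water_fraction)
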