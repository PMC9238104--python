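"""Shared fixtures: hand-built toy networks with known LP optima."""

import hypothesis
import pytest

hypothesis.settings.register_profile("det", derandomize=True)
hypothesis.settings.load_profile("det")

from crabgem import (
    GEM,
    Metabolite,
    Reaction,
    SyntheticSpec,
    make_toy_gem,
)


def linear_chain_model(uptake: float = 5.0) -> GEM:
    """glc[e] -(EX, lb=-uptake)-> glc[c] -> biomass; hand-solvable optimum."""
    model = GEM(name="chain")
    model.add_metabolite(Metabolite("glc[e]", compartment="e"))
    model.add_metabolite(Metabolite("glc[c]", compartment="c"))
    model.add_metabolite(Metabolite("biomass[c]", compartment="c"))
    model.add_reaction(Reaction(
        id="EX_glc", stoichiometry={"glc[e]": -1.0},
        lower_bound=-uptake, upper_bound=1000.0, kind="exchange"))
    model.add_reaction(Reaction(
        id="T_glc", stoichiometry={"glc[e]": -1.0, "glc[c]": 1.0},
        lower_bound=-1000.0, upper_bound=1000.0, kind="transport"))
    model.add_reaction(Reaction(
        id="BIOMASS", stoichiometry={"glc[c]": -1.0, "biomass[c]": 1.0},
        lower_bound=0.0, upper_bound=1000.0, kind="biomass"))
    model.add_reaction(Reaction(
        id="DM_biomass", stoichiometry={"biomass[c]": -1.0},
        lower_bound=0.0, upper_bound=1000.0, kind="demand"))
    model.objective_id = "BIOMASS"
    return model


def energy_toy_model() -> GEM:
    """Glucose-fed ATP toy: net 2 ATP per glucose through an ADP cycle."""
    model = GEM(name="energy-toy")
    for mid, comp in [("glc[e]", "e"), ("glc[c]", "c"), ("atp[c]", "c"),
                      ("adp[c]", "c"), ("h2o[e]", "e"), ("h2o[c]", "c"),
                      ("h[c]", "c")]:
        model.add_metabolite(Metabolite(mid, compartment=comp))
    model.add_reaction(Reaction(
        id="EX_glc", stoichiometry={"glc[e]": -1.0},
        lower_bound=0.0, upper_bound=1000.0, kind="exchange"))
    model.add_reaction(Reaction(
        id="T_glc", stoichiometry={"glc[e]": -1.0, "glc[c]": 1.0},
        lower_bound=-1000.0, upper_bound=1000.0, kind="transport"))
    model.add_reaction(Reaction(
        id="EX_h2o", stoichiometry={"h2o[e]": -1.0},
        lower_bound=0.0, upper_bound=1000.0, kind="exchange"))
    model.add_reaction(Reaction(
        id="T_h2o", stoichiometry={"h2o[e]": -1.0, "h2o[c]": 1.0},
        lower_bound=-1000.0, upper_bound=1000.0, kind="transport"))
    model.add_reaction(Reaction(
        id="GLYC", name="substrate-level phosphorylation",
        stoichiometry={"glc[c]": -1.0, "adp[c]": -2.0, "atp[c]": 2.0},
        lower_bound=0.0, upper_bound=1000.0))
    model.add_reaction(Reaction(
        id="DM_atp", stoichiometry={"atp[c]": -1.0, "adp[c]": 1.0},
        lower_bound=0.0, upper_bound=1000.0, kind="demand"))
    return model


def sulfur_fixture() -> GEM:
    """Cysteine toy mirroring a semi-essential amino-acid bound structure.

    Direct uptake capped at 3 (semi-essential exchange bound) plus internal
    synthesis from sulfate + serine, both feed-capped at 5, giving a
    maximum cysteine drain of 8 when the two sulfur-assimilation steps are
    present.
    """
    model = GEM(name="sulfur")
    for mid, comp in [
        ("so4[e]", "e"), ("so4[c]", "c"), ("aps[c]", "c"), ("so3[c]", "c"),
        ("h2s[c]", "c"), ("ser[e]", "e"), ("ser[c]", "c"),
        ("cys[c]", "c"), ("cys[e]", "e"),
    ]:
        model.add_metabolite(Metabolite(mid, compartment=comp))
    for rid, stoich, lb in [
        ("EX_so4", {"so4[e]": -1.0}, -5.0),
        ("T_so4", {"so4[e]": -1.0, "so4[c]": 1.0}, -1000.0),
        ("APS_FORM", {"so4[c]": -1.0, "aps[c]": 1.0}, 0.0),
        ("APS_RED", {"aps[c]": -1.0, "so3[c]": 1.0}, 0.0),
        ("SULFITE_RED", {"so3[c]": -1.0, "h2s[c]": 1.0}, 0.0),
        ("EX_ser", {"ser[e]": -1.0}, -5.0),
        ("T_ser", {"ser[e]": -1.0, "ser[c]": 1.0}, -1000.0),
        ("CYS_SYN", {"ser[c]": -1.0, "h2s[c]": -1.0, "cys[c]": 1.0}, 0.0),
        ("EX_cys", {"cys[e]": -1.0}, -3.0),
        ("T_cys", {"cys[e]": -1.0, "cys[c]": 1.0}, -1000.0),
    ]:
        kind = ("exchange" if rid.startswith("EX_")
                else "transport" if rid.startswith("T_") else "metabolic")
        model.add_reaction(Reaction(
            id=rid, stoichiometry=stoich, lower_bound=lb,
            upper_bound=1000.0, kind=kind))
    return model


@pytest.fixture
def chain_model():
    return linear_chain_model()


@pytest.fixture
def energy_toy():
    return energy_toy_model()


@pytest.fixture
def toy_gem():
    model, truth = make_toy_gem(SyntheticSpec(seed=1))
    return model, truth


@pytest.fixture
def polymer_gem():
    model, truth = make_toy_gem(SyntheticSpec(seed=3, include_polymer_leak=True))
    return model, truth
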