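"""Draft assembly from KO annotations and the refinement operations."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crabgem import (
    GEM,
    KOTable,
    Metabolite,
    PoolEntry,
    Reaction,
    UniversalPool,
    add_transfer_reactions,
    annotate_missing,
    apply_patches,
    build_draft,
    check_balance,
    is_producible,
    prune_redundant,
    standardize_chirality,
)


def _four_reaction_pool() -> UniversalPool:
    return UniversalPool([
        PoolEntry("R0001", "a => b", ko_ids=["K00001"], pathway="p1"),
        PoolEntry("R0002", "b => c", ko_ids=["K00002"], pathway="p1"),
        PoolEntry("R0003", "c => d", ko_ids=["K00003"], pathway="p2"),
        PoolEntry("R0004", "d => e", ko_ids=["K00004"], pathway="p2"),
    ])


class TestBuildDraft:
    def test_intersection_selects_matching_reactions(self):
        table = KOTable.from_pairs([("UG1", "K00001"), ("UG2", "K00003")])
        draft = build_draft(table, _four_reaction_pool())
        assert set(draft.reactions) == {"R0001", "R0003"}
        assert draft.reactions["R0001"].genes == ["UG1"]
        assert draft.reactions["R0003"].genes == ["UG2"]

    def test_absent_ko_yields_empty_draft(self):
        table = KOTable.from_pairs([("UG1", "K99999")])
        draft = build_draft(table, _four_reaction_pool())
        assert len(draft.reactions) == 0

    def test_all_draft_metabolites_cytosolic(self):
        table = KOTable.from_pairs([("UG1", "K00001")])
        draft = build_draft(table, _four_reaction_pool())
        assert all(m.compartment == "c" for m in draft.metabolites.values())

    def test_multiple_unigenes_share_a_ko(self):
        table = KOTable.from_pairs([("UG1", "K00001"), ("UG2", "K00001")])
        draft = build_draft(table, _four_reaction_pool())
        assert draft.reactions["R0001"].genes == ["UG1", "UG2"]

    @settings(max_examples=30, deadline=None)
    @given(st.lists(
        st.tuples(st.sampled_from(["UG1", "UG2", "UG3"]),
                  st.sampled_from(["K00001", "K00002", "K00003", "K00004"])),
        max_size=8))
    def test_monotone_in_annotation_rows(self, pairs):
        """Adding KO rows can only grow the draft, never shrink it."""
        pool = _four_reaction_pool()
        base = build_draft(KOTable.from_pairs(pairs), pool)
        extended = build_draft(
            KOTable.from_pairs(pairs + [("UGX", "K00002")]), pool)
        assert set(base.reactions) <= set(extended.reactions)


class TestBalance:
    def _model(self):
        model = GEM()
        model.add_metabolite(Metabolite("glc[c]", formula="C6H12O6"))
        model.add_metabolite(Metabolite("lac[c]", formula="C3H6O3"))
        model.add_metabolite(Metabolite("poly[c]", formula="(C6H10O5)n"))
        return model

    def test_glycolytic_split_is_balanced(self):
        model = self._model()
        rxn = Reaction(id="R", stoichiometry={"glc[c]": -1.0, "lac[c]": 2.0},
                       lower_bound=0.0)
        model.add_reaction(rxn)
        assert check_balance(rxn, model).verdict == "balanced"

    def test_element_deltas_of_unbalanced_reaction(self):
        model = self._model()
        rxn = Reaction(id="R", stoichiometry={"glc[c]": -1.0, "lac[c]": 1.0},
                       lower_bound=0.0)
        model.add_reaction(rxn)
        report = check_balance(rxn, model)
        assert report.verdict == "unbalanced"
        assert report.element_deltas == {"C": -3.0, "H": -6.0, "O": -3.0}

    def test_polymer_species_gives_unknown_verdict(self):
        model = self._model()
        rxn = Reaction(id="R", stoichiometry={"poly[c]": -1.0, "glc[c]": 1.0},
                       lower_bound=0.0)
        model.add_reaction(rxn)
        report = check_balance(rxn, model)
        assert report.verdict == "unknown"
        assert report.unknown_metabolites == ["poly[c]"]


class TestPruneRedundant:
    def _abc_model(self):
        model = GEM()
        for mid in ("A[c]", "B[c]", "C[c]"):
            model.add_metabolite(Metabolite(mid))
        model.add_reaction(Reaction(
            id="R_AB", stoichiometry={"A[c]": -1.0, "B[c]": 1.0}, lower_bound=0.0))
        model.add_reaction(Reaction(
            id="R_BC", stoichiometry={"B[c]": -1.0, "C[c]": 1.0}, lower_bound=0.0))
        return model

    def test_lumped_reaction_removed(self):
        model = self._abc_model()
        model.add_reaction(Reaction(
            id="R_AC", stoichiometry={"A[c]": -1.0, "C[c]": 1.0}, lower_bound=0.0))
        pruned, removed = prune_redundant(model)
        assert ("R_AC", "lumped:R_AB+R_BC") in removed
        assert "R_AC" not in pruned.reactions

    def test_duplicate_keeps_smallest_id(self):
        model = self._abc_model()
        model.add_reaction(Reaction(
            id="R_AB2", stoichiometry={"A[c]": -1.0, "B[c]": 1.0}, lower_bound=0.0))
        pruned, removed = prune_redundant(model)
        assert "R_AB" in pruned.reactions
        assert ("R_AB2", "duplicate:R_AB") in removed

    def test_clean_model_unchanged(self):
        model = self._abc_model()
        pruned, removed = prune_redundant(model)
        assert removed == []
        assert set(pruned.reactions) == set(model.reactions)

    def test_pruning_preserves_producibility(self):
        """Removing a lumped duplicate never blocks a metabolite that the
        elementary steps could already make."""
        model = self._abc_model()
        model.add_reaction(Reaction(
            id="R_AC", stoichiometry={"A[c]": -1.0, "C[c]": 1.0}, lower_bound=0.0))
        model.add_reaction(Reaction(
            id="SRC_A", stoichiometry={"A[c]": 1.0}, lower_bound=0.0))
        producible_before = [mid for mid in model.metabolite_ids
                             if is_producible(model, mid)[0]]
        assert "C[c]" in producible_before
        pruned, _ = prune_redundant(model)
        for mid in producible_before:
            assert is_producible(pruned, mid)[0], mid

    def test_pool_flags_trigger_removal(self):
        model = self._abc_model()
        pool = UniversalPool([
            PoolEntry("R_AB", "A => B", flags=["general"]),
        ])
        pruned, removed = prune_redundant(model, {"pool": pool})
        assert "R_AB" not in pruned.reactions
        assert removed[0][1].startswith("flagged")


class TestChirality:
    def test_alias_merge_then_prune(self):
        model = GEM()
        for mid in ("ala[c]", "L-ala[c]", "pyr[c]"):
            model.add_metabolite(Metabolite(mid))
        model.add_reaction(Reaction(
            id="R1", stoichiometry={"ala[c]": -1.0, "pyr[c]": 1.0}, lower_bound=0.0))
        model.add_reaction(Reaction(
            id="R2", stoichiometry={"L-ala[c]": -1.0, "pyr[c]": 1.0}, lower_bound=0.0))
        merged = standardize_chirality(model, {"ala[c]": "L-ala[c]"})
        assert "ala[c]" not in merged.metabolites
        pruned, removed = prune_redundant(merged)
        assert len(pruned.reactions) == 1
        assert removed == [("R2", "duplicate:R1")]


class TestTransferReactions:
    def _cytosol_model(self, n):
        model = GEM()
        for i in range(n):
            model.add_metabolite(Metabolite(f"nut{i}[c]", formula="CH2O"))
        return model

    def test_one_nutrient_adds_two_reactions_one_metabolite(self):
        model = self._cytosol_model(1)
        out = add_transfer_reactions(model, [("nut0[c]", True)])
        assert len(out.reactions) == 2
        assert len(out.metabolites) == 2
        assert out.metabolites["nut0[e]"].compartment == "e"

    def test_eighty_nutrients_add_160_transfer_reactions(self):
        model = self._cytosol_model(80)
        out = add_transfer_reactions(
            model, [(f"nut{i}[c]", True) for i in range(80)])
        assert len(out.reactions) - len(model.reactions) == 160
        kinds = out.counts_by_kind()
        assert kinds["exchange"] == 80 and kinds["transport"] == 80

    def test_non_importable_nutrient_outward_only(self):
        model = self._cytosol_model(1)
        out = add_transfer_reactions(model, [("nut0[c]", False)])
        assert out.reactions["EX_nut0"].lower_bound == 0.0
        assert out.reactions["T_nut0"].lower_bound == 0.0

    def test_each_nutrient_gets_exactly_one_pair(self):
        model = self._cytosol_model(3)
        out = add_transfer_reactions(
            model, [(f"nut{i}[c]", bool(i % 2)) for i in range(3)])
        for i in range(3):
            touching = [r.id for r in out.reactions.values()
                        if f"nut{i}[e]" in r.stoichiometry]
            assert sorted(touching) == [f"EX_nut{i}", f"T_nut{i}"]

    def test_missing_nutrient_raises_naming_it(self):
        model = self._cytosol_model(1)
        with pytest.raises(Exception, match="ghost"):
            add_transfer_reactions(model, [("ghost[c]", True)])


class TestApplyPatches:
    def test_patch_file_rewrites_stoichiometry(self, tmp_path):
        model = GEM()
        for mid, formula in [("glc[c]", "C6H12O6"), ("lac[c]", "C3H6O3")]:
            model.add_metabolite(Metabolite(mid, formula=formula))
        model.add_reaction(Reaction(
            id="R_BAD", stoichiometry={"glc[c]": -1.0, "lac[c]": 1.0},
            lower_bound=0.0))
        assert check_balance(model.reactions["R_BAD"], model).verdict == "unbalanced"
        patch = tmp_path / "patch.tsv"
        patch.write_text("R_BAD\tglc[c] => 2 lac[c]\n")
        patched, n = apply_patches(model, patch)
        assert n == 1
        assert check_balance(patched.reactions["R_BAD"], patched).verdict == "balanced"

    def test_unknown_reaction_in_patch_rejected(self, chain_model):
        with pytest.raises(Exception, match="R_GHOST"):
            apply_patches(chain_model, {"R_GHOST": "A => B"})


class TestAnnotateMissing:
    def test_fills_from_pool_else_fallback(self):
        model = GEM()
        model.add_metabolite(Metabolite("a[c]"))
        model.add_metabolite(Metabolite("b[c]"))
        model.add_reaction(Reaction(
            id="R_KNOWN", stoichiometry={"a[c]": -1.0, "b[c]": 1.0},
            lower_bound=0.0))
        model.add_reaction(Reaction(
            id="R_ALIEN", stoichiometry={"b[c]": -1.0, "a[c]": 1.0},
            lower_bound=0.0))
        pool = UniversalPool([
            PoolEntry("R_KNOWN", "a => b", pathway="glycolysis",
                      subsystem="carbohydrate"),
        ])
        out, n_filled = annotate_missing(model, pool)
        assert n_filled == 2
        assert out.reactions["R_KNOWN"].pathway == "glycolysis"
        assert out.reactions["R_ALIEN"].subsystem == "metabolic pathway"

    def test_fully_annotated_model_untouched(self):
        model = GEM()
        model.add_metabolite(Metabolite("a[c]"))
        model.add_reaction(Reaction(
            id="R", stoichiometry={"a[c]": -1.0}, lower_bound=0.0,
            pathway="p", subsystem="s"))
        _, n_filled = annotate_missing(model, UniversalPool())
        assert n_filled == 0
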