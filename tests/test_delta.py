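"""Strain-design deltas: diff, apply, flatten, (de)serialization,
programmatic designs and export."""

import json

import pytest

from gemtest import (
    DeltaError,
    Metabolite,
    Reaction,
    StrainDesign,
    apply_design,
    diff_models,
    export_design_as_model,
    fba,
    flatten_design,
    load_design,
    load_programmatic_design,
    save_design,
)
from gemtest.fixtures import (
    make_design_fixtures,
    make_random_model,
    make_toy_chain,
    mutate_model,
)

TOL = 1e-5


class TestDiff:
    def test_identical_models_give_empty_delta(self, toy_parallel):
        delta = diff_models(toy_parallel, toy_parallel.copy())
        assert delta.is_empty

    def test_mixed_edit_classified_field_by_field(self, toy_chain):
        modified = toy_chain.copy()
        modified.add_metabolite(Metabolite("D"))
        modified.add_reaction(Reaction("R4", {"C": -1.0, "D": 1.0}))
        modified.reactions["EX_A"].lower_bound = -5.0
        delta = diff_models(toy_chain, modified)
        assert [r.id for r in delta.reactions_added] == ["R4"]
        assert [m.id for m in delta.metabolites_added] == ["D"]
        assert [r.id for r in delta.reactions_modified] == ["EX_A"]
        assert delta.reactions_removed == []
        assert delta.metabolites_removed == []

    def test_deletion_recorded_as_removal(self, toy_parallel):
        modified = toy_parallel.copy()
        modified.remove_reaction("R3")
        modified.genes.discard("g3")
        delta = diff_models(toy_parallel, modified)
        assert delta.reactions_removed == ["R3"]
        assert delta.genes_removed == ["g3"]


class TestApply:
    def test_diff_apply_round_trip(self, toy_chain):
        modified = toy_chain.copy()
        modified.add_metabolite(Metabolite("D"))
        modified.add_reaction(Reaction("R4", {"C": -1.0, "D": 1.0}))
        modified.reactions["EX_A"].lower_bound = -5.0
        applied = apply_design(toy_chain, diff_models(toy_chain, modified))
        assert applied.functionally_equal(modified)
        assert fba(applied).objective_value == pytest.approx(
            fba(modified).objective_value, abs=TOL
        )

    def test_hierarchical_application(self, toy_parallel):
        ko, child = make_design_fixtures(toy_parallel)
        resolver = {ko.id: ko, child.id: child}
        applied = apply_design(toy_parallel, child, resolver)
        assert "R1" not in applied.reactions
        assert "R_H" in applied.reactions
        assert "EX_P" in applied.reactions

    def test_empty_delta_is_identity(self, toy_parallel):
        applied = apply_design(toy_parallel, StrainDesign(id="noop"))
        assert applied.functionally_equal(toy_parallel)

    def test_base_model_never_mutated(self, toy_parallel):
        ko, child = make_design_fixtures(toy_parallel)
        apply_design(toy_parallel, child, {ko.id: ko, child.id: child})
        assert "R1" in toy_parallel.reactions
        assert "R_H" not in toy_parallel.reactions

    def test_designs_do_not_interfere(self, toy_parallel):
        """Applying one design never changes the outcome of another
        applied to a fresh base."""
        ko, child = make_design_fixtures(toy_parallel)
        resolver = {ko.id: ko, child.id: child}
        first = apply_design(toy_parallel, child, resolver)
        only_ko = apply_design(toy_parallel, ko, resolver)
        again = apply_design(toy_parallel, child, resolver)
        assert first.functionally_equal(again)
        assert "R_H" not in only_ko.reactions

    def test_base_curation_propagates_to_children(self, toy_parallel):
        """Editing the base changes an untouched child design's result."""
        ko, child = make_design_fixtures(toy_parallel)
        resolver = {ko.id: ko, child.id: child}
        before = apply_design(toy_parallel, child, resolver)
        curated = toy_parallel.copy()
        curated.reactions["EX_A"].lower_bound = -20.0
        after = apply_design(curated, child, resolver)
        assert before.reactions["EX_A"].lower_bound == -10.0
        assert after.reactions["EX_A"].lower_bound == -20.0
        assert fba(after).objective_value == pytest.approx(20.0, abs=TOL)

    def test_missing_removal_target_names_design_and_id(self, toy_parallel):
        design = StrainDesign(id="bad", reactions_removed=["R_NOPE"])
        with pytest.raises(DeltaError, match=r"bad.*R_NOPE"):
            apply_design(toy_parallel, design)

    def test_parent_cycle_detected(self):
        a = StrainDesign(id="a", parent="b")
        b = StrainDesign(id="b", parent="a")
        with pytest.raises(DeltaError, match="cycle"):
            apply_design(make_toy_chain(), a, {"a": a, "b": b})

    def test_removing_referenced_metabolite_is_an_error(self, toy_parallel):
        design = StrainDesign(id="bad", metabolites_removed=["A"])
        with pytest.raises(DeltaError, match="referenced"):
            apply_design(toy_parallel, design)

    def test_collision_within_one_delta_rejected(self):
        design = StrainDesign(
            id="clash",
            reactions_added=[Reaction("R1", {"A": -1.0})],
            reactions_removed=["R1"],
        )
        with pytest.raises(DeltaError, match="added and removed"):
            design.validate()


class TestFlatten:
    def test_parentless_design_flattens_to_itself(self, toy_parallel):
        ko, _ = make_design_fixtures(toy_parallel)
        flat = flatten_design(ko)
        assert flat.reactions_removed == ko.reactions_removed
        assert flat.parent is None

    def test_child_override_wins(self, toy_parallel):
        parent = StrainDesign(
            id="p",
            reactions_modified=[Reaction("EX_A", {"A": -1.0}, -5.0, 1000.0)],
        )
        child = StrainDesign(
            id="c",
            parent="p",
            reactions_modified=[Reaction("EX_A", {"A": -1.0}, -2.0, 1000.0)],
        )
        flat = flatten_design(child, {"p": parent, "c": child})
        assert len(flat.reactions_modified) == 1
        assert flat.reactions_modified[0].lower_bound == -2.0

    def test_flatten_equals_chained_application(self, toy_parallel):
        ko, child = make_design_fixtures(toy_parallel)
        resolver = {ko.id: ko, child.id: child}
        chained = apply_design(toy_parallel, child, resolver)
        flat = flatten_design(child, resolver)
        assert flat.parent is None
        flattened = apply_design(toy_parallel, flat)
        assert flattened.functionally_equal(chained)
        assert fba(flattened).objective_value == pytest.approx(
            fba(chained).objective_value, abs=TOL
        )

    def test_depth_four_chain_flattens_exactly(self, toy_parallel):
        designs = {}
        parent = None
        for depth in range(4):
            design = StrainDesign(
                id=f"d{depth}",
                parent=parent,
                reactions_modified=[
                    Reaction("EX_A", {"A": -1.0}, -10.0 + depth, 1000.0)
                ],
            )
            designs[design.id] = design
            parent = design.id
        leaf = designs["d3"]
        chained = apply_design(toy_parallel, leaf, designs)
        flattened = apply_design(toy_parallel, flatten_design(leaf, designs))
        assert flattened.functionally_equal(chained)

    def test_remove_then_readd_becomes_modification(self, toy_parallel):
        replacement = Reaction("R3", {"A": -1.0, "C": 1.0}, 0.0, 5.0, "g3")
        parent = StrainDesign(id="p", reactions_removed=["R3"])
        child = StrainDesign(id="c", parent="p", reactions_added=[replacement])
        flat = flatten_design(child, {"p": parent, "c": child})
        assert flat.reactions_removed == []
        assert [r.id for r in flat.reactions_modified] == ["R3"]


class TestSerialization:
    def test_save_load_round_trip(self, tmp_path, toy_parallel):
        _, child = make_design_fixtures(toy_parallel)
        path = tmp_path / "child.json"
        save_design(child, path)
        loaded = load_design(path)
        assert loaded.id == child.id
        assert loaded.parent == child.parent
        assert [r.id for r in loaded.reactions_added] == sorted(
            r.id for r in child.reactions_added
        )
        by_id = {r.id: r for r in loaded.reactions_added}
        assert by_id["EX_P"].stoichiometry == {"P": -1.0}
        assert by_id["R_H"].gene_rule.to_string() == "gH"

    def test_saves_are_byte_identical(self, tmp_path, toy_parallel):
        ko, _ = make_design_fixtures(toy_parallel)
        first, second = tmp_path / "a.json", tmp_path / "b.json"
        save_design(ko, first)
        save_design(ko, second)
        assert first.read_bytes() == second.read_bytes()

    def test_missing_schema_version_rejected_with_pointer(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps({"design": {"id": "x"}}))
        with pytest.raises(DeltaError, match="schema"):
            load_design(path)

    def test_schema_violation_reports_location(self, tmp_path):
        payload = {
            "schema_version": "1.0",
            "design": {"id": "x", "reactions_removed": [42]},
        }
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(payload))
        with pytest.raises(DeltaError, match="reactions_removed/0"):
            load_design(path)


class TestProgrammaticDesigns:
    def test_shipped_milp_design_reduces_toy_parallel(self, tmp_path, toy_parallel):
        from gemtest.templates import MILP_DESIGN_SOURCE

        (tmp_path / "minimal_reactions.py").write_text(MILP_DESIGN_SOURCE)
        design = load_programmatic_design(tmp_path, "minimal_reactions")
        assert design.is_programmatic
        reduced = apply_design(toy_parallel, design)
        open_reactions = {
            rid
            for rid, r in reduced.reactions.items()
            if not (r.lower_bound == 0.0 and r.upper_bound == 0.0)
        }
        assert open_reactions == {"EX_A", "R3", "BIOMASS"}
        assert fba(reduced).objective_value == pytest.approx(10.0, abs=TOL)

    def test_identity_hook_is_identity(self, tmp_path, toy_parallel):
        (tmp_path / "noop.py").write_text("def transform(model):\n    return model\n")
        design = load_programmatic_design(tmp_path, "noop")
        applied = apply_design(toy_parallel, design)
        assert applied.functionally_equal(toy_parallel)

    def test_missing_entry_point_rejected(self, tmp_path):
        (tmp_path / "empty.py").write_text("X = 1\n")
        with pytest.raises(DeltaError, match="transform"):
            load_programmatic_design(tmp_path, "empty")

    def test_raising_hook_wrapped_with_design_name(self, tmp_path, toy_parallel):
        (tmp_path / "boom.py").write_text(
            "def transform(model):\n    raise RuntimeError('kaput')\n"
        )
        design = load_programmatic_design(tmp_path, "boom")
        with pytest.raises(DeltaError, match=r"boom.*kaput"):
            apply_design(toy_parallel, design)

    def test_programmatic_design_cannot_be_flattened(self, tmp_path):
        (tmp_path / "noop.py").write_text("def transform(model):\n    return model\n")
        design = load_programmatic_design(tmp_path, "noop")
        with pytest.raises(DeltaError, match="flatten"):
            flatten_design(design)

    def test_stored_lists_must_be_empty_for_programmatic(self):
        design = StrainDesign(
            id="bad", is_programmatic=True, reactions_removed=["R1"]
        )
        with pytest.raises(DeltaError, match="programmatic"):
            design.validate()


class TestExport:
    @pytest.mark.parametrize("format", ["json", "sbml"])
    def test_export_then_reimport_preserves_optimum(
        self, tmp_path, toy_parallel, format
    ):
        from gemtest import io_formats

        ko, child = make_design_fixtures(toy_parallel)
        suffix = "json" if format == "json" else "xml"
        path = tmp_path / f"strain.{suffix}"
        export_design_as_model(
            toy_parallel, child, {ko.id: ko, child.id: child}, format, path
        )
        reimported = io_formats.read_model(path)
        direct = apply_design(toy_parallel, child, {ko.id: ko, child.id: child})
        assert fba(reimported).objective_value == pytest.approx(
            fba(direct).objective_value, abs=TOL
        )
        assert "R_H" in reimported.reactions

    def test_export_empty_delta_round_trips_base(self, tmp_path, toy_parallel):
        from gemtest import io_formats

        path = tmp_path / "base.json"
        export_design_as_model(toy_parallel, StrainDesign(id="noop"), None, "json", path)
        assert io_formats.read_json_model(path).functionally_equal(toy_parallel)

    def test_unsupported_format_rejected(self, tmp_path, toy_parallel):
        with pytest.raises(DeltaError, match="format"):
            export_design_as_model(
                toy_parallel, StrainDesign(id="noop"), None, "matlab", tmp_path / "x"
            )


class TestRoundTripProperty:
    @pytest.mark.parametrize("seed", range(20))
    def test_random_pair_round_trip(self, seed):
        """apply(base, diff(base, modified)) is functionally equal to
        modified for seeded random model pairs."""
        base = make_random_model(seed)
        modified = mutate_model(base, seed + 1000)
        delta = diff_models(base, modified)
        applied = apply_design(base, delta)
        assert applied.functionally_equal(modified)
        assert fba(applied).objective_value == pytest.approx(
            fba(modified).objective_value, abs=TOL, rel=1e-6
        )
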