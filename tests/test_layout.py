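"""Geometry tests: glyph counts, determinism, containment, ordering."""

from __future__ import annotations

import pytest

from bnglcartoon import (
    FixtureParams,
    generate_model,
    layout_molecule_type,
    layout_rule,
    layout_rule_compartments,
    layout_species,
    parse_model,
    parse_pattern,
    parse_rule,
    resolve_pattern,
    serialize_pattern,
)

from conftest import (
    COMPARTMENT_RULE,
    EGF_EGFR_PATTERN,
    EGFR_TYPE,
    PHOS_RULE,
    count_bond_tokens,
)


def species_plan(pattern_text, types=()):
    pat = parse_pattern(pattern_text, require_paired_bonds=False)
    return layout_species(resolve_pattern(pat, list(types)), pat.compartment)


@pytest.fixture
def egfr_types():
    return parse_model(f"begin molecule types\n{EGFR_TYPE}\nend molecule types\n").molecule_types


class TestSpeciesLayout:
    def test_worked_example_glyph_counts(self):
        plan = species_plan(EGF_EGFR_PATTERN)
        assert plan.count("bond_line") == 1
        assert plan.count("bound_any_tick") == 1
        assert plan.count("unknown_mark") == 1
        assert plan.count("state_badge") == 1
        badge = next(s for s in plan.shapes if s.kind == "state_badge")
        assert badge.text == "u"

    def test_bare_molecule(self):
        plan = species_plan("A()")
        assert plan.count("molecule_box") == 1
        for kind in ("bond_line", "bound_any_tick", "unknown_mark", "site_glyph"):
            assert plan.count(kind) == 0

    def test_molecule_boxes_keep_pattern_order_and_do_not_overlap(self):
        plan = species_plan("Alpha(x!1).Beta(y!1).Gamma(z)")
        boxes = [s for s in plan.shapes if s.kind == "molecule_box"]
        assert [b.text for b in boxes] == ["Alpha", "Beta", "Gamma"]
        xs = [b.x for b in boxes]
        assert xs == sorted(xs)
        for a, b in zip(boxes, boxes[1:]):
            assert a.x + a.w <= b.x  # pairwise disjoint along x

    def test_anchor_per_site_on_box_boundary(self):
        plan = species_plan(EGF_EGFR_PATTERN)
        glyphs = [s for s in plan.shapes if s.kind == "site_glyph"]
        assert len(plan.anchors) == len(glyphs)
        boxes = [s for s in plan.shapes if s.kind == "molecule_box"]
        r = glyphs[0].w / 2
        for x, y in plan.anchors.values():
            assert any(
                b.x <= x <= b.x + b.w and abs(y - (b.y + b.h)) <= 2 * r for b in boxes
            )

    def test_all_shapes_inside_plan_bounds(self):
        for text in (EGF_EGFR_PATTERN, "A()", "@EC:egf(r)", "0"):
            plan = species_plan(text)
            for s in plan.shapes:
                assert s.x >= 0 and s.y >= 0
                assert s.x + s.w <= plan.width and s.y + s.h <= plan.height

    def test_grey_propagates_from_non_participating_sites(self, egfr_types):
        plan = species_plan("egfr(tmd!+)", egfr_types)
        grey = {s.text for s in plan.shapes if s.kind == "site_glyph" and s.grey}
        assert grey == {"ecd", "Y1068", "Y1148"}
        # grey sites carry no bond mark and no badge
        assert plan.count("bound_any_tick") == 1
        assert plan.count("unknown_mark") == 0
        assert plan.count("state_badge") == 0

    def test_determinism_bit_identical(self):
        a = species_plan(EGF_EGFR_PATTERN)
        b = species_plan(EGF_EGFR_PATTERN)
        assert a.to_debug() == b.to_debug()
        assert a.anchors == b.anchors

    @pytest.mark.parametrize("seed", range(1, 21))
    def test_bond_glyph_counts_match_token_census(self, seed):
        doc = parse_model(generate_model(FixtureParams(seed=seed)))
        pats = [sp.pattern for sp in doc.species]
        pats += [p for o in doc.observables for p in o.patterns]
        pats += [p for r in doc.rules for p in r.reactants + r.products]
        for pat in pats:
            plan = layout_species(resolve_pattern(pat, doc.molecule_types))
            paired, ticks, marks = count_bond_tokens(serialize_pattern(pat))
            assert plan.count("bond_line") == paired
            assert plan.count("bound_any_tick") == ticks
            assert plan.count("unknown_mark") == marks


class TestRuleLayout:
    def test_phosphorylation_rule_cartoon(self, egfr_types):
        rule = parse_rule(PHOS_RULE)
        plan = layout_rule(rule, egfr_types)
        assert plan.count("molecule_box") == 2
        assert plan.count("site_glyph") == 8  # 4 declared sites per side
        greys = [s for s in plan.shapes if s.kind == "site_glyph" and s.grey]
        assert len(greys) == 4  # ecd and Y1148 on each side
        assert plan.count("arrow") == 1
        badges = [s.text for s in plan.shapes if s.kind == "state_badge"]
        assert badges == ["u", "p"]  # the state flips across the arrow

    def test_trivial_rule(self):
        plan = layout_rule(parse_rule("A() -> B() k"), [])
        assert plan.count("molecule_box") == 2
        assert plan.count("plus_sign") == 0
        (arrow,) = [s for s in plan.shapes if s.kind == "arrow"]
        assert arrow.style_ref == "single"

    def test_reversible_rule_has_one_double_headed_arrow(self):
        plan = layout_rule(parse_rule("A() + B() <-> C() kon, koff"), [])
        arrows = [s for s in plan.shapes if s.kind == "arrow"]
        assert len(arrows) == 1
        assert arrows[0].style_ref == "double"
        assert plan.count("plus_sign") == 1

    def test_rates_never_rendered(self):
        plan = layout_rule(parse_rule("A() -> B() k_forward_rate"), [])
        texts = {s.text for s in plan.shapes if s.text}
        assert "k_forward_rate" not in texts

    def test_label_and_comments_above(self):
        plan = layout_rule(parse_rule("r1: A() -> B() k"), [], comments=("a note",))
        label = next(s for s in plan.shapes if s.style_ref == "rule_label")
        comment = next(s for s in plan.shapes if s.kind == "comment_label")
        assert label.text == "r1" and comment.text == "a note"
        body_top = min(s.y for s in plan.shapes if s.kind == "molecule_box")
        assert label.y < body_top and comment.y < body_top


class TestCompartmentLayout:
    def test_membrane_and_volume_framing(self):
        doc = parse_model(
            "begin compartments\nEC 3 1000\nM 2 1 EC\nend compartments\n"
            f"begin molecule types\negf(r)\n{EGFR_TYPE}\nend molecule types\n"
            f"begin reaction rules\n{COMPARTMENT_RULE}\nend reaction rules\n"
        )
        plan = layout_rule_compartments(doc.rules[0], doc.compartments, doc.molecule_types)
        regions = [s for s in plan.shapes if s.kind == "compartment_region"]
        membranes = [s for s in plan.shapes if s.kind == "membrane_bar"]
        assert [r.text for r in regions] == ["EC"]
        assert [m.text for m in membranes] == ["M", "M"]

    def test_volumetric_region_contains_its_molecules(self):
        doc = parse_model(
            "begin compartments\nEC 3 1000\nend compartments\n"
            "begin reaction rules\n@EC:A(x) -> @EC:A(x!+) k1\nend reaction rules\n"
        )
        plan = layout_rule_compartments(doc.rules[0], doc.compartments, doc.molecule_types)
        regions = [s for s in plan.shapes if s.kind == "compartment_region"]
        boxes = [s for s in plan.shapes if s.kind == "molecule_box"]
        assert len(regions) == 2 and len(boxes) == 2
        for box in boxes:
            assert any(
                r.x <= box.x and box.x + box.w <= r.x + r.w
                and r.y <= box.y and box.y + box.h <= r.y + r.h
                for r in regions
            )

    def test_no_compartments_is_identical_to_plain_rule_layout(self, egfr_types):
        rule = parse_rule(PHOS_RULE)
        framed = layout_rule_compartments(rule, [], egfr_types)
        plain = layout_rule(rule, egfr_types)
        assert framed.to_debug() == plain.to_debug()

    def test_undeclared_compartment_drawn_with_warning(self):
        doc = parse_model(
            "begin compartments\nEC 3 1000\nend compartments\n"
            "begin reaction rules\n@XX:A() -> @XX:B() k1\nend reaction rules\n"
        )
        plan = layout_rule_compartments(doc.rules[0], doc.compartments, doc.molecule_types)
        assert any(s.kind == "compartment_region" and s.text == "XX" for s in plan.shapes)
        assert any(d.code == "undeclared-compartment" for d in plan.diagnostics)


class TestMoleculeTypeLayout:
    def test_receptor_card(self):
        doc = parse_model(f"begin molecule types\n{EGFR_TYPE}\nend molecule types\n")
        plan = layout_molecule_type(doc.molecule_types[0])
        assert plan.count("site_glyph") == 4
        badges = [s.text for s in plan.shapes if s.kind == "state_badge"]
        assert badges == ["u", "p", "u", "p"]

    def test_bare_molecule_card(self):
        doc = parse_model("begin molecule types\nA()\nend molecule types\n")
        plan = layout_molecule_type(doc.molecule_types[0])
        assert plan.count("molecule_box") == 1
        assert plan.count("site_glyph") == 0

    @pytest.mark.parametrize("seed", [1, 4, 13])
    def test_badge_count_equals_declared_state_count(self, seed):
        doc = parse_model(generate_model(FixtureParams(seed=seed)))
        for mt in doc.molecule_types:
            plan = layout_molecule_type(mt)
            assert plan.count("state_badge") == sum(len(s.allowed_states) for s in mt.sites)
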