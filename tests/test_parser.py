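"""Parser unit and property tests: tokens, blocks, comments, round trips."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bnglcartoon import (
    BondSpec,
    BnglParseError,
    FixtureParams,
    MoleculePattern,
    SitePattern,
    SpeciesPattern,
    StateSpec,
    generate_model,
    parse_model,
    parse_pattern,
    parse_rule,
    serialize_model,
    serialize_pattern,
)
from bnglcartoon.parser import UNBOUND, UNSPECIFIED

from conftest import EGF_EGFR_PATTERN, EGFR_TYPE


class TestPatternGrammar:
    def test_worked_example_structure(self):
        pat = parse_pattern(EGF_EGFR_PATTERN)
        assert len(pat.molecules) == 2
        egf, egfr = pat.molecules
        assert egf.name == "egf" and [s.name for s in egf.sites] == ["r"]
        assert egf.sites[0].bond == BondSpec("labeled", 1)
        assert [s.name for s in egfr.sites] == ["ecd", "tmd", "Y1068", "Y11148"]
        by = {s.name: s for s in egfr.sites}
        assert by["ecd"].bond == BondSpec("labeled", 1)
        assert by["tmd"].bond.kind == "bound_any"
        assert by["Y1068"].state == StateSpec("named", "u")
        assert by["Y1068"].bond.kind == "unbound"
        assert by["Y11148"].state.kind == "unspecified"
        assert by["Y11148"].bond.kind == "unknown"

    @pytest.mark.parametrize(
        "text,state,bond",
        [
            ("A(x)", UNSPECIFIED, UNBOUND),
            ("A(x!3)", UNSPECIFIED, BondSpec("labeled", 3)),
            ("A(x!+)", UNSPECIFIED, BondSpec("bound_any")),
            ("A(x!?)", UNSPECIFIED, BondSpec("unknown")),
            ("A(x~p)", StateSpec("named", "p"), UNBOUND),
            ("A(x~p!+)", StateSpec("named", "p"), BondSpec("bound_any")),
        ],
    )
    def test_bond_and_state_tokens_map_one_to_one(self, text, state, bond):
        site = parse_pattern(text, require_paired_bonds=False).molecules[0].sites[0]
        assert site.state == state and site.bond == bond

    def test_minimal_pattern(self):
        pat = parse_pattern("A()")
        assert len(pat.molecules) == 1
        assert pat.molecules[0].sites == ()
        assert pat.compartment is None

    def test_compartment_prefix(self):
        pat = parse_pattern("@EC:egf(r)")
        assert pat.compartment == "EC"
        assert pat.molecules[0].name == "egf"
        assert pat.molecules[0].sites[0].bond.kind == "unbound"

    def test_null_species(self):
        pat = parse_pattern("0")
        assert pat.molecules == ()
        assert serialize_pattern(pat) == "0"

    def test_unpaired_label_names_the_label(self):
        with pytest.raises(BnglParseError, match="9"):
            parse_pattern("A(x!9)")
        with pytest.raises(BnglParseError, match="2"):
            parse_pattern("A(x!2).B(y!2,z!2)")

    def test_malformed_bond_reports_column(self):
        with pytest.raises(BnglParseError) as exc:
            parse_pattern("A(x!)")
        assert exc.value.column is not None

    def test_duplicate_state_or_bond_token_rejected(self):
        with pytest.raises(BnglParseError):
            parse_pattern("A(x~u~p)")  # two states on one pattern site
        with pytest.raises(BnglParseError):
            parse_pattern("A(x!+!?)")

    def test_cbngl_molecule_suffix_rejected_standalone(self):
        with pytest.raises(BnglParseError, match="cBNGL"):
            parse_pattern("egf(r)@EC")


class TestRuleGrammar:
    def test_irreversible_rule(self):
        rule = parse_rule("egfr(tmd!+,Y1068~Y) -> egfr(tmd!+,Y1068~pY) k1")
        assert not rule.reversible
        assert len(rule.reactants) == 1 and len(rule.products) == 1
        assert rule.rates == ("k1",)

    def test_reversible_binding_rule(self):
        rule = parse_rule("A() + B() <-> C() kon, koff")
        assert rule.reversible
        assert len(rule.reactants) == 2 and len(rule.products) == 1
        assert rule.rates == ("kon", "koff")

    def test_rule_label(self):
        rule = parse_rule("bind: A(x) + B(y) -> A(x!1).B(y!1) kon")
        assert rule.label == "bind"

    def test_missing_arrow_is_an_error(self):
        with pytest.raises(BnglParseError, match="arrow"):
            parse_rule("A() B() k1")

    def test_reversible_with_one_rate_is_an_error(self):
        with pytest.raises(BnglParseError, match="2 rate"):
            parse_rule("A() <-> B() k1")

    def test_per_pattern_compartments(self):
        rule = parse_rule("@EC:egf(r) + @M:egfr(ecd) -> @M:egf(r!1).egfr(ecd!1) kon")
        assert rule.reactant_compartments == ("EC", "M")
        assert rule.product_compartments == ("M",)

    def test_per_side_compartment_normalizes_to_patterns(self):
        rule = parse_rule("@EC: A() + B() -> @M: C() k1")
        assert rule.reactant_compartments == ("EC", "EC")
        assert rule.product_compartments == ("M",)


class TestModelBlocks:
    def test_molecule_types_block(self):
        doc = parse_model(f"begin molecule types\n{EGFR_TYPE}\nend molecule types\n")
        assert len(doc.molecule_types) == 1
        mt = doc.molecule_types[0]
        assert mt.name == "egfr" and len(mt.sites) == 4
        assert mt.sites[2].allowed_states == ("u", "p")
        assert mt.sites[3].allowed_states == ("u", "p")

    def test_empty_input(self):
        doc = parse_model("")
        assert doc.molecule_types == [] and doc.rules == []
        assert not any(d.severity == "error" for d in doc.parse_diagnostics)

    def test_model_wrapper_and_case_insensitive_keywords(self):
        doc = parse_model("begin model\nBEGIN Molecule Types\nA(x)\nEND molecule types\nend model\n")
        assert len(doc.molecule_types) == 1

    def test_seed_species_synonym_blocks(self, small_model_doc):
        assert len(small_model_doc.species) == 2
        assert small_model_doc.species[0].initial_amount == "500"

    def test_unbalanced_blocks_report_line(self):
        with pytest.raises(BnglParseError) as exc:
            parse_model("begin molecule types\nA(x)\n")
        assert exc.value.line == 1
        with pytest.raises(BnglParseError):
            parse_model("end species\n")
        with pytest.raises(BnglParseError):
            parse_model("begin species\nend observables\n")

    def test_unrecognized_block_retained_with_warning(self):
        doc = parse_model("begin energy patterns\nfoo bar\nend energy patterns\n")
        assert doc.raw_blocks == [("energy patterns", "foo bar")]
        assert any(d.code == "unrecognized-block" for d in doc.parse_diagnostics)

    def test_parameters_and_actions_retained_non_visual(self, small_model_doc):
        assert [p.name for p in small_model_doc.parameters] == ["k1", "kon"]
        assert small_model_doc.actions == ["generate_network({overwrite=>1})"]

    def test_cbngl_detection_sets_dialect(self):
        doc = parse_model("begin species\negf(r)@EC 10\nend species\n")
        assert doc.dialect == "cbngl_detected"
        assert any(
            d.code == "cbngl-unsupported" and d.severity == "error"
            for d in doc.parse_diagnostics
        )

    def test_vcell_dialect_detected(self, small_model_doc):
        assert small_model_doc.dialect == "vcell_compartmental"

    def test_continuation_lines_joined(self):
        doc = parse_model(
            "begin reaction rules\nA(x) + \\\nB(y) -> A(x!1).B(y!1) kon\nend reaction rules\n"
        )
        assert len(doc.rules) == 1
        assert len(doc.rules[0].reactants) == 2
        assert doc.rules[0].line == 2

    def test_line_numbers_monotonic(self, small_model_doc):
        doc = small_model_doc
        for elems in (doc.molecule_types, doc.species, doc.observables, doc.rules):
            lines = [e.line for e in elems]
            assert lines == sorted(lines)
            assert all(ln >= 1 for ln in lines)


class TestComments:
    def test_inline_comment_attaches_to_same_element(self, small_model_doc):
        assert small_model_doc.comments_for("molecule_types", 1) == ("the receptor",)

    def test_own_line_comment_attaches_to_next_element(self, small_model_doc):
        assert small_model_doc.comments_for("observables", 0) == ("phosphorylated receptor",)

    def test_comment_conservation(self, small_model_text, small_model_doc):
        visual = 0
        block = None
        for line in small_model_text.splitlines():
            s = line.strip()
            if s.startswith("begin "):
                block = s.split(None, 1)[1]
            elif s.startswith("end "):
                block = None
            elif "#" in line and block in (
                "molecule types",
                "seed species",
                "observables",
                "reaction rules",
            ):
                visual += 1
        attached = sum(len(v) for v in small_model_doc.comments.values())
        assert attached == visual


class TestRoundTrip:
    def test_worked_example_round_trip(self):
        text = f"begin species\n{EGF_EGFR_PATTERN} 10\nend species\n"
        doc = parse_model(text)
        assert parse_model(serialize_model(doc)) == doc

    def test_empty_document_serializes_to_empty_skeleton(self):
        assert serialize_model(parse_model("")) == ""

    @pytest.mark.parametrize("seed", range(1, 31))
    def test_fixture_round_trip(self, seed):
        doc = parse_model(generate_model(FixtureParams(seed=seed)))
        again = parse_model(serialize_model(doc))
        assert again == doc
        # serialization is a fixed point after one pass
        assert serialize_model(again) == serialize_model(doc)


# -- property test: structural patterns survive serialize -> parse ----------

_name = st.from_regex(r"[A-Za-z_][A-Za-z0-9_]{0,6}", fullmatch=True)
_state = st.one_of(
    st.just(UNSPECIFIED), st.builds(StateSpec, st.just("named"), _name)
)
_bond = st.sampled_from(
    [UNBOUND, BondSpec("bound_any"), BondSpec("unknown")]
)
_site = st.builds(SitePattern, _name, _state, _bond)
_molecule = st.builds(
    MoleculePattern, _name, st.lists(_site, max_size=4).map(tuple)
)


@st.composite
def _patterns(draw) -> SpeciesPattern:
    mols = draw(st.lists(_molecule, min_size=1, max_size=3))
    if len(mols) >= 2 and draw(st.booleans()):
        # join the first two molecules with one explicit bond label
        a, b = mols[0], mols[1]
        mols[0] = MoleculePattern(
            a.name, a.sites + (SitePattern(draw(_name), UNSPECIFIED, BondSpec("labeled", 1)),)
        )
        mols[1] = MoleculePattern(
            b.name, b.sites + (SitePattern(draw(_name), UNSPECIFIED, BondSpec("labeled", 1)),)
        )
    comp = draw(st.one_of(st.none(), _name))
    return SpeciesPattern(tuple(mols), comp)


@settings(max_examples=100, derandomize=True)
@given(_patterns())
def test_pattern_serialize_parse_identity(pattern):
    assert parse_pattern(serialize_pattern(pattern)) == pattern
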