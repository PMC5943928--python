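"""Expression parsing, validation, wildcard expansion and canonicalisation."""
import pytest

from danai import (
    NotationError,
    canonical_string,
    expand_wildcards,
    parse_macro,
    parse_micro,
)
from danai.notation import MacroInteraction

from .conftest import CYCLIC_DIMER_EXPR, HB, HP, TABLE_HB, TABLE_HP


class TestMacro:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("HB_20_20", ("HB", 20, 20)),
            ("HP_1_1", ("HP", 1, 1)),
            ("PS_6_6", ("PS", 6, 6)),
        ],
    )
    def test_parse(self, text, expected):
        macro = parse_macro(text)
        assert (macro.interaction_type, macro.cgi_1, macro.cgi_2) == expected

    @pytest.mark.parametrize(
        "text", ["XY_1_1", "HB_20", "HB_a_20", "", "HB-20-20", "hb_20_20"]
    )
    def test_rejects_malformed(self, text):
        with pytest.raises(NotationError):
            parse_macro(text)

    def test_round_trip_serialization(self):
        macro = parse_macro("HB_20_20")
        assert str(macro) == "HB_20_20"
        assert parse_macro(str(macro)) == macro

    def test_type_token_validated_on_construction(self):
        with pytest.raises(NotationError):
            MacroInteraction("QQ", 1, 1)


class TestMicroParse:
    def test_linear_two_group_motif(self):
        m = parse_micro("[L2]oL-h:oE-c", HB)
        assert m.structure_class == "L"
        assert m.cg_count == 2
        assert m.n_nodes == 4
        labels = [n.label for n in m.nodes]
        assert labels == ["O20L", "H20O", "O20E", "C20"]
        assert all(not n.strict for n in m.nodes)
        assert len(m.nonbond_edges) == 1
        assert len(m.covalent_edges) == 2
        assert len(set(m.cg_index)) == 2

    def test_ring_unifies_first_and_last_atom(self):
        m = parse_micro("[R3]c1p:c1p:c1p:c1p", HP)
        assert m.n_nodes == 3
        assert len(m.nonbond_edges) == 3
        assert m.ring_closure

    def test_junction_with_covalent_branch(self):
        m = parse_micro("[J3]oL-h:oE(c):h-oL", HB)
        hub = m.junction_node()
        assert m.nodes[hub].label == "O20E"
        assert m.nonbond_degree(hub) == 2
        # the branch carbon is covalently attached to the hub
        assert any(hub in e for e in m.covalent_edges)

    def test_forward_branch_attaches_to_next_atom(self):
        m = parse_micro("[J5]c1p:(c1p:)c1p(:c1p):c1p", HP)
        hub = m.junction_node()
        assert m.nonbond_degree(hub) == 4
        assert m.cg_count == 5

    def test_case_is_semantic(self):
        strict = parse_micro("[L2]OL-H:OE-C", HB)
        relaxed = parse_micro("[L2]oL-h:oE-c", HB)
        assert [n.strict for n in strict.nodes] == [True] * 4
        assert [n.strict for n in relaxed.nodes] == [False] * 4
        assert not strict.is_isomorphic(relaxed)

    def test_abbreviations_and_full_labels_coincide(self):
        assert parse_micro("[L2]h:oE", HB).is_isomorphic(
            parse_micro("[L2]h20o:o20e", HB)
        )

    @pytest.mark.parametrize(
        "text",
        [
            "h:oE",  # no [Sa] prefix
            "[L2]oL-h-oE-c",  # zero non-bonded edges
            "[L3]oL-h:oE-c",  # declared 3 CGs, expression has 2
            "[R2]oL-h:oE-c",  # ring class but endpoints differ
            "[L2]oL-h:oE(c",  # unbalanced brackets
            "[L2]oL-h::oE-c",  # double connector
            "[L2]oL-h:oE-",  # trailing connector
            "[L2]xx:yy",  # unresolvable atom tokens
            "[Q2]oL-h:oE-c",  # unknown structure class
            "[L2]oL-h:oE((c)):h",  # nested branch
            "[R3]c-oL-h:oE#h:oE-c",  # ring endpoints c vs c but CG count wrong
        ],
    )
    def test_rejects_malformed_micro(self, text):
        with pytest.raises(NotationError):
            parse_micro(text, HB)

    def test_class_must_match_topology(self):
        # a junction-shaped motif declared linear is a contradiction
        with pytest.raises(NotationError):
            parse_micro("[L4]c1p:c1p(:c1p):c1p", HP)
        # and a plain chain declared a junction likewise
        with pytest.raises(NotationError):
            parse_micro("[J2]c1p:c1p", HP)

    def test_delocalized_groups_parse_but_flag(self):
        m = parse_micro("[C2]<C6>:<C6>", parse_macro("PS_6_6"))
        assert m.has_deloc
        assert m.n_nodes == 2


class TestWildcards:
    def test_relaxed_expansion_matches_explicit_lowercase(self):
        # oE#h inserts the remaining carboxyl atoms: oE#h == oE-c-o-h
        short = expand_wildcards(parse_micro("[L2]h:oE#h", HB))
        explicit = parse_micro("[L2]h:oE-c-o-h", HB)
        assert short.is_isomorphic(explicit)

    def test_strict_expansion_uses_uppercase(self):
        # oE@h == oE-C-O-h: the inserted atoms become part of the criteria
        short = expand_wildcards(parse_micro("[L2]h:oE@h", HB))
        explicit = parse_micro("[L2]h:oE-C-O-h", HB)
        assert short.is_isomorphic(explicit)
        assert not short.is_isomorphic(parse_micro("[L2]h:oE-c-o-h", HB))

    def test_identity_without_wildcards(self):
        m = parse_micro("[L2]oL-h:oE-c", HB)
        assert expand_wildcards(m) is m

    def test_expansion_leaves_no_wildcards(self):
        for expr in TABLE_HB:
            assert not expand_wildcards(parse_micro(expr, HB)).has_wildcards

    def test_alias_o_is_the_hydroxyl_oxygen(self):
        assert parse_micro("[L2]h:oE-c-o-h", HB).is_isomorphic(
            parse_micro("[L2]h:oE-c-oL-h", HB)
        )


class TestCanonical:
    @pytest.mark.parametrize("expr", TABLE_HB + (CYCLIC_DIMER_EXPR,))
    def test_round_trip_hb(self, expr):
        m = expand_wildcards(parse_micro(expr, HB))
        c = canonical_string(m)
        again = parse_micro(c, HB)
        assert m.is_isomorphic(again)
        assert canonical_string(again) == c

    @pytest.mark.parametrize("expr", TABLE_HP)
    def test_round_trip_hp(self, expr):
        m = expand_wildcards(parse_micro(expr, HP))
        c = canonical_string(m)
        again = parse_micro(c, HP)
        assert m.is_isomorphic(again)
        assert canonical_string(again) == c

    def test_reversed_expression_has_identical_canonical_form(self):
        a = parse_micro("[L2]c-oE:h-oL", HB)
        b = parse_micro("[L2]oL-h:oE-c", HB)
        assert a.is_isomorphic(b)
        assert canonical_string(a) == canonical_string(b)

    def test_case_flags_change_the_canonical_form(self):
        a = parse_micro("[L2]OL-H:OE-C", HB)
        b = parse_micro("[L2]oL-h:oE-c", HB)
        assert canonical_string(a) != canonical_string(b)

    def test_wildcard_motifs_serialise_before_expansion(self):
        m = parse_micro("[L3]oL-h:oE#h:oE-c", HB)
        assert parse_micro(canonical_string(m), HB).is_isomorphic(m)
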