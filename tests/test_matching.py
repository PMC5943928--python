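"""Motif counting semantics, the brute-force oracle and cluster tracing."""
import numpy as np
import pytest

from danai import (
    MatchingError,
    assign_types,
    brute_force_count,
    build_interaction_graph,
    count_motif,
    expand_wildcards,
    make_hb_chain,
    make_methyl_cluster,
    parse_micro,
    random_liquid,
    trace_clusters,
)

from .conftest import (
    CYCLIC_DIMER_EXPR,
    HB,
    HP,
    TABLE_HB,
    TABLE_HP,
    count_on,
    motif_of,
    permute_system,
)
from danai import Frame


def _graphs(topology, frame):
    typed = assign_types(topology)
    return typed, {
        k: build_interaction_graph(frame, typed, topology, k, method="brute")
        for k in ("HB", "HP")
    }


class TestGroundTruthCounts:
    """Hand-enumerated counts on fixtures built to realise known motifs.

    Strictness is per atom: an uppercase atom must carry exactly the
    non-bonded interactions written for it, while its group may interact
    further through atoms that are not written (so in a head-to-tail
    chain every hydrogen-bonded pair matches [L2]OL-H:OE-C — each written
    atom has exactly one bond — even though the middle molecule
    participates twice through different atoms).
    """

    @pytest.mark.parametrize(
        "expr, expected",
        [
            ("[L3]oL-h:oE#h:oE-c", 1),  # the whole chain, once
            ("[L2]oL-h:oE-c", 2),  # each head-to-tail pair
            ("[L2]OL-H:OE-C", 2),  # both pairs are exclusive at the written atoms
            ("[L2]oL-h:oL-h", 0),  # no hydroxyl-hydroxyl bond in this chain
            ("[J3]oL-h:oE(c):h-oL", 0),  # no bifurcation
        ],
    )
    def test_three_chain(self, chain3, expr, expected):
        topology, frame = chain3
        assert count_on(expr, "HB", topology, frame) == expected

    def test_two_chain_head_to_tail(self):
        topology, frame = make_hb_chain(2, "head_to_tail")
        assert count_on("[L2]OL-H:OE-C", "HB", topology, frame) == 1
        assert count_on("[L2]oL-h:oE-c", "HB", topology, frame) == 1

    def test_two_chain_tail_to_tail(self):
        topology, frame = make_hb_chain(2, "tail_to_tail")
        assert count_on("[L2]oL-h:oL-h", "HB", topology, frame) == 1
        assert count_on("[L2]oL-h:oE-c", "HB", topology, frame) == 0

    def test_cyclic_dimer(self, dimer):
        topology, frame = dimer
        # the double hydrogen bond ring counts once (cycle symmetry)
        assert count_on(CYCLIC_DIMER_EXPR, "HB", topology, frame) == 1
        # each of its two bonds is a relaxed head-to-tail pair
        assert count_on("[L2]oL-h:oE-c", "HB", topology, frame) == 2
        # and each written atom has exactly one bond, so the strict
        # variant matches twice as well (atom-level exclusivity)
        assert count_on("[L2]OL-H:OE-C", "HB", topology, frame) == 2

    def test_methyl_star(self, star4):
        topology, frame = star4
        assert count_on("[J4]c1p:c1p(:c1p):c1p", "HP", topology, frame) == 1
        # unordered paths through the hub: C(3, 2)
        assert count_on("[L3]c1p:c1p:c1p", "HP", topology, frame) == 3
        assert count_on("[J5]c1p:(c1p:)c1p(:c1p):c1p", "HP", topology, frame) == 0

    def test_isolated_methyl_pair_is_strict_and_relaxed(self):
        topology, frame = make_methyl_cluster([2])
        assert count_on("[L2]C1p:C1p", "HP", topology, frame) == 1
        assert count_on("[L2]c1p:c1p", "HP", topology, frame) == 1

    def test_isolated_molecule_matches_nothing(self):
        from danai import build_ethanoic_molecule

        topology, xyz = build_ethanoic_molecule()
        frame = Frame(xyz)
        for expr in ("[L2]oL-h:oE-c", "[L2]c1p:c1p"):
            kind = "HB" if "oL" in expr else "HP"
            assert count_on(expr, kind, topology, frame) == 0

    def test_triangle_ring_counts_once(self):
        # three methyls in mutual contact: one R3 ring, modulo symmetry
        from danai.synthetic import _replicate, I_C1P, _rot
        from danai import build_ethanoic_molecule

        _, xyz = build_ethanoic_molecule("anti")
        xyz = xyz - xyz[I_C1P]
        cc = xyz[4] / np.linalg.norm(xyz[4])
        v = np.cross(cc, [0.0, 0.0, 1.0])
        xyz = xyz @ _rot(v, np.arctan2(np.linalg.norm(v), cc[2])).T
        h = 4.0 * np.sqrt(3) / 2
        topology, coords = _replicate(
            [xyz, xyz + np.array([4.0, 0, 0]), xyz + np.array([2.0, h, 0])]
        )
        frame = Frame(coords)
        assert count_on("[R3]c1p:c1p:c1p:c1p", "HP", topology, frame) == 1
        assert count_on("[L3]c1p:c1p:c1p", "HP", topology, frame) == 3


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_random_fixtures_agree(self, seed):
        topology, frame = random_liquid(5, 13.0, min_separation=1.9, seed=seed)
        typed, graphs = _graphs(topology, frame)
        for expr, kind in [(e, "HB") for e in TABLE_HB] + [
            (e, "HP") for e in TABLE_HP
        ]:
            motif = motif_of(expr, kind)
            assert count_motif(motif, graphs[kind], typed, topology) == (
                brute_force_count(motif, graphs[kind], typed, topology)
            ), expr

    def test_empty_interaction_graph(self):
        topology, frame = make_hb_chain(2)
        typed = assign_types(topology)
        graph = build_interaction_graph(frame, typed, topology, "HP", method="brute")
        motif = motif_of("[L2]c1p:c1p", "HP")
        assert brute_force_count(motif, graph, typed, topology) == 0
        assert count_motif(motif, graph, typed, topology) == 0


class TestInvariants:
    @pytest.mark.parametrize(
        "strict_expr, relaxed_expr, kind",
        [
            ("[L2]OL-H:OL-H", "[L2]oL-h:oL-h", "HB"),
            ("[L2]OL-H:OE-C", "[L2]oL-h:oE-c", "HB"),
            ("[L2]C1p:C1p", "[L2]c1p:c1p", "HP"),
        ],
    )
    def test_strict_counts_never_exceed_relaxed(self, strict_expr, relaxed_expr, kind):
        for seed in range(5):
            topology, frame = random_liquid(6, 13.5, min_separation=1.8, seed=seed)
            strict = count_on(strict_expr, kind, topology, frame)
            relaxed = count_on(relaxed_expr, kind, topology, frame)
            assert strict <= relaxed

    def test_wildcard_and_expansion_count_identically(self, chain3):
        topology, frame = chain3
        typed, graphs = _graphs(topology, frame)
        compact = expand_wildcards(parse_micro("[L3]oL-h:oE#h:oE-c", HB))
        explicit = parse_micro("[L3]oL-h:oE-c-o-h:oE-c", HB)
        assert count_motif(compact, graphs["HB"], typed, topology) == count_motif(
            explicit, graphs["HB"], typed, topology
        )

    def test_counts_invariant_under_atom_relabelling(self, chain3):
        topology, frame = chain3
        rng = np.random.default_rng(17)
        reference = {
            expr: count_on(expr, "HB", topology, frame) for expr in TABLE_HB
        }
        for _ in range(3):
            permuted, coords = permute_system(topology, frame.coordinates, rng)
            for expr, expected in reference.items():
                assert count_on(expr, "HB", permuted, Frame(coords)) == expected


class TestErrors:
    def test_unexpanded_wildcard_is_rejected(self, chain3):
        topology, frame = chain3
        typed, graphs = _graphs(topology, frame)
        raw = parse_micro("[L3]oL-h:oE#h:oE-c", HB)
        with pytest.raises(MatchingError, match="wildcard"):
            count_motif(raw, graphs["HB"], typed, topology)

    def test_delocalized_group_is_rejected(self, chain3):
        from danai import parse_macro

        topology, frame = chain3
        typed, graphs = _graphs(topology, frame)
        motif = parse_micro("[C2]<C6>:<C6>", parse_macro("HB_20_20"))
        with pytest.raises(MatchingError, match="delocalized"):
            count_motif(motif, graphs["HB"], typed, topology)

    def test_macro_kind_must_match_graph(self, chain3):
        topology, frame = chain3
        typed, graphs = _graphs(topology, frame)
        with pytest.raises(MatchingError, match="does not match"):
            count_motif(motif_of("[L2]c1p:c1p", "HP"), graphs["HB"], typed, topology)

    def test_brute_force_refuses_large_systems(self):
        topology, frame = random_liquid(15, 16.0, seed=0)
        typed, graphs = _graphs(topology, frame)
        with pytest.raises(MatchingError, match="refused"):
            brute_force_count(
                motif_of("[L2]c1p:c1p", "HP"),
                graphs["HP"],
                typed,
                topology,
                max_atoms=40,
            )


class TestClusters:
    def test_sizes_and_non_participants(self):
        topology, frame = make_methyl_cluster([5, 2, 2, 1])
        typed = assign_types(topology)
        graph = build_interaction_graph(frame, typed, topology, "HP", method="brute")
        components, lone = trace_clusters(graph, typed)
        assert [len(c) for c in components] == [5, 2, 2]
        assert len(lone) == 1

    def test_full_clique(self):
        # star of 4 has 3 contacts; a genuine clique fixture via triangle
        topology, frame = make_methyl_cluster([3], shape="star")
        typed = assign_types(topology)
        graph = build_interaction_graph(frame, typed, topology, "HP", method="brute")
        components, lone = trace_clusters(graph, typed)
        assert [len(c) for c in components] == [3]
        assert lone == set()

    def test_no_edges_means_all_non_participants(self):
        topology, frame = make_methyl_cluster([1, 1])
        typed = assign_types(topology)
        graph = build_interaction_graph(frame, typed, topology, "HP", method="brute")
        components, lone = trace_clusters(graph, typed)
        assert components == []
        assert len(lone) == 2

    def test_partition_bookkeeping(self):
        """Component sizes plus non-participants add up to all methyls."""
        for seed in range(3):
            topology, frame = random_liquid(20, 16.0, min_separation=1.6, seed=seed)
            typed = assign_types(topology)
            graph = build_interaction_graph(frame, typed, topology, "HP")
            components, lone = trace_clusters(graph, typed)
            n_methyl = sum(1 for t in typed if t.dlf_label == "C1p")
            assert sum(len(c) for c in components) + len(lone) == n_methyl
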