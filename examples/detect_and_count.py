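"""Detect hydrogen bonds in constructed fixtures and count motifs.

Builds a three-molecule head-to-tail chain and the cyclic dimer of
ethanoic acid, detects hydrogen bonds under the 2.5 Å / 120° criteria and
counts a few expressions, comparing relaxed (lowercase) against strict
(uppercase) semantics.
"""
from danai import (
    assign_types,
    build_interaction_graph,
    count_motif,
    expand_wildcards,
    make_cyclic_dimer,
    make_hb_chain,
    parse_macro,
    parse_micro,
)

hb = parse_macro("HB_20_20")


def report(name, topology, frame, expressions):
    typed = assign_types(topology)
    graph = build_interaction_graph(frame, typed, topology, "HB")
    print(f"{name}: {graph.n_edges} hydrogen bond(s)")
    for e in graph.edges:
        print(
            f"  H {e.i} -> acceptor {e.j} ({typed[e.j].dlf_label}), "
            f"d = {e.distance:.2f} Å, angle = {e.angle:.0f}°"
        )
    for expr in expressions:
        motif = expand_wildcards(parse_micro(expr, hb))
        print(f"  {expr:22s} counts {count_motif(motif, graph, typed, topology)}")


topology, frame = make_hb_chain(3, "head_to_tail")
report("three-molecule chain", topology, frame,
       ["[L2]oL-h:oE-c", "[L2]OL-H:OE-C", "[L3]oL-h:oE#h:oE-c"])

topology, frame = make_cyclic_dimer()
report("cyclic dimer", topology, frame,
       ["[L2]oL-h:oE-c", "[R2]c-oL-h:oE#h:oE-c"])

# The chain counts the relaxed pair twice (once per bond) and the whole
# chain once; the dimer's double hydrogen bond counts once as a ring.
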