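"""Shared fixtures: parsed expression sets and small known-structure systems."""
from __future__ import annotations

import numpy as np
import pytest

from danai import (
    MolecularTopology,
    assign_types,
    build_interaction_graph,
    count_motif,
    expand_wildcards,
    parse_macro,
    parse_micro,
)

HB = parse_macro("HB_20_20")
HP = parse_macro("HP_1_1")

#: the documented selection of hydrogen-bond expressions
TABLE_HB = (
    "[L2]OL-H:OL-H",
    "[L2]oL-H:OL-h",
    "[L2]oL-h:oL-h",
    "[L2]OL-H:OE-C",
    "[L2]oL-H:OE-c",
    "[L2]oL-h:oE-c",
    "[L3]oL-h:oE#oL(h):h-oL",
    "[L3]oL-h:oE#h:oL-h",
    "[L3]oL-h:oE#h:oE-c",
    "[J3]oL-h:oE(c):h-oL",
)

#: the six hydrophobic expressions
TABLE_HP = (
    "[L2]C1p:C1p",
    "[L2]c1p:c1p",
    "[L3]c1p:c1p:c1p",
    "[R3]c1p:c1p:c1p:c1p",
    "[J4]c1p:c1p(:c1p):c1p",
    "[J5]c1p:(c1p:)c1p(:c1p):c1p",
)

CYCLIC_DIMER_EXPR = "[R2]c-oL-h:oE#h:oE-c"


def macro_for(expression_kind: str):
    return HB if expression_kind == "HB" else HP


def motif_of(expr: str, kind: str = "HB"):
    return expand_wildcards(parse_micro(expr, macro_for(kind)))


def count_on(expr: str, kind: str, topology, frame, method: str = "brute") -> int:
    """Full pipeline count of one expression on one frame."""
    typed = assign_types(topology)
    graph = build_interaction_graph(frame, typed, topology, kind, method=method)
    return count_motif(motif_of(expr, kind), graph, typed, topology)


def permute_system(topology: MolecularTopology, coords: np.ndarray, rng):
    """Relabel atoms by a random permutation (same physical system)."""
    n = topology.n_atoms
    perm = rng.permutation(n)  # perm[new] = old
    inv = np.empty(n, dtype=int)
    inv[perm] = np.arange(n)
    new_top = MolecularTopology(
        elements=tuple(topology.elements[old] for old in perm),
        molecule_ids=tuple(topology.molecule_ids[old] for old in perm),
        bonds=tuple((int(inv[i]), int(inv[j])) for i, j in topology.bonds),
    )
    return new_top, coords[perm]


@pytest.fixture(scope="session")
def chain3():
    from danai import make_hb_chain

    return make_hb_chain(3, "head_to_tail")


@pytest.fixture(scope="session")
def dimer():
    from danai import make_cyclic_dimer

    return make_cyclic_dimer()


@pytest.fixture(scope="session")
def star4():
    from danai import make_methyl_cluster

    return make_methyl_cluster([4], shape="star")


@pytest.fixture(scope="session")
def small_liquid():
    from danai import random_liquid

    return random_liquid(20, 16.0, min_separation=1.6, seed=11)
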