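"""Counting micro-interaction motifs in a per-frame interaction graph.

Semantics
---------
A match maps motif nodes injectively onto atoms such that

* every node maps to an atom carrying the node's DL_F label,
* covalent motif edges map to covalent bonds of the topology,
* non-bonded motif edges map to interaction edges of the frame graph,
* motif nodes of one chemical-group instance map into one group
  occurrence, and distinct instances map to distinct occurrences,
* a STRICT (uppercase) node's atom has a frame interaction degree of the
  motif's macro type exactly equal to the node's non-bonded degree in the
  motif; a RELAXED (lowercase) node tolerates any additional interactions.

The strict test is per atom and per interaction network: hydrogen-bond
degrees never constrain hydrophobic exclusivity and vice versa.

Counting convention
-------------------
* Classes L, R (and C): distinct matches modulo motif automorphism — an
  unordered chain or cycle is counted once, but two chains sharing a
  middle molecule are still two matches.
* Class J: distinct assignments of the junction atom only.  The motif
  ``[J4]c1p:c1p(:c1p):c1p`` therefore counts methyl carbons surrounded by
  at least three (relaxed case) other methyls, not the number of ways of
  choosing the three.

``count_motif`` runs on networkx's VF2 subgraph-monomorphism machinery;
``brute_force_count`` is a deliberately plain recursive enumeration kept
as the independent oracle.
"""
from __future__ import annotations

import itertools

import networkx as nx
from networkx.algorithms import isomorphism as iso

from .atom_typing import MolecularTopology, TypedAtom
from .detection import InteractionGraph
from .errors import MatchingError
from .notation import MicroMotif

__all__ = [
    "host_graph",
    "count_motif",
    "brute_force_count",
    "trace_clusters",
]

_KIND_OF_MACRO = {"HB": "HB", "HP": "HP"}


def _check_motif(motif: MicroMotif, graph: InteractionGraph) -> None:
    if motif.has_wildcards:
        raise MatchingError(
            f"'{motif.source_text}': expand wildcards before matching"
        )
    if motif.has_deloc:
        raise MatchingError(
            f"'{motif.source_text}': unsupported: delocalized groups"
        )
    kind = _KIND_OF_MACRO.get(motif.macro.interaction_type)
    if kind != graph.kind:
        raise MatchingError(
            f"motif macro type {motif.macro.interaction_type} does not match "
            f"interaction graph kind {graph.kind}"
        )


def host_graph(
    graph: InteractionGraph,
    typed_atoms: list[TypedAtom],
    topology: MolecularTopology,
) -> nx.Graph:
    """Combined per-frame graph: covalent bonds + one interaction network.

    Node attributes: ``label`` (DL_F), ``cg`` (group occurrence or None),
    ``nb_degree`` (interaction degree of this frame's macro type).  Edge
    attribute ``etype`` in {cov, nb}.
    """
    g = nx.Graph()
    deg = graph.degrees()
    for ta in typed_atoms:
        g.add_node(
            ta.index, label=ta.dlf_label, cg=ta.cg_instance, nb_degree=int(deg[ta.index])
        )
    for i, j in topology.bonds:
        g.add_edge(i, j, etype="cov")
    for e in graph.edges:
        if g.has_edge(e.i, e.j):
            raise MatchingError(
                f"atoms {e.i}-{e.j} are both bonded and interacting; "
                "cannot build the match graph"
            )
        g.add_edge(e.i, e.j, etype="nb")
    return g


def _node_match(host_attrs: dict, motif_attrs: dict) -> bool:
    if host_attrs["label"] != motif_attrs["label"]:
        return False
    if motif_attrs["strict"]:
        return host_attrs["nb_degree"] == motif_attrs["nb_degree"]
    return host_attrs["nb_degree"] >= motif_attrs["nb_degree"]


def _edge_match(host_attrs: dict, motif_attrs: dict) -> bool:
    return host_attrs["etype"] == motif_attrs["etype"]


def _cg_consistent(
    mapping: dict[int, int], motif: MicroMotif, host: nx.Graph
) -> bool:
    """mapping: motif node -> atom.  Group instances must map bijectively."""
    seen: dict[int, int] = {}
    used: set[int] = set()
    for node, atom in mapping.items():
        comp = motif.cg_index[node]
        inst = host.nodes[atom]["cg"]
        if inst is None:
            return False
        if comp in seen:
            if seen[comp] != inst:
                return False
        else:
            if inst in used:
                return False
            seen[comp] = inst
            used.add(inst)
    return True


def motif_automorphism_count(motif: MicroMotif) -> int:
    """Order of the motif's automorphism group (labels, case and edge
    kinds preserved)."""
    g = motif.to_networkx()
    nm = lambda a, b: (a["label"], a["strict"]) == (b["label"], b["strict"])
    gm = iso.GraphMatcher(g, g, node_match=nm, edge_match=_edge_match)
    return sum(1 for _ in gm.isomorphisms_iter())


def _monomorphisms(
    motif: MicroMotif,
    graph: InteractionGraph,
    typed_atoms: list[TypedAtom],
    topology: MolecularTopology,
):
    host = host_graph(graph, typed_atoms, topology)
    m = motif.to_networkx()
    gm = iso.GraphMatcher(host, m, node_match=_node_match, edge_match=_edge_match)
    for host_to_motif in gm.subgraph_monomorphisms_iter():
        mapping = {v: k for k, v in host_to_motif.items()}
        if _cg_consistent(mapping, motif, host):
            yield mapping


def count_motif(
    motif: MicroMotif,
    graph: InteractionGraph,
    typed_atoms: list[TypedAtom],
    topology: MolecularTopology,
) -> int:
    """Number of occurrences of ``motif`` in one frame's interaction graph."""
    _check_motif(motif, graph)
    if motif.structure_class == "J":
        junction = motif.junction_node()
        return len({m[junction] for m in _monomorphisms(motif, graph, typed_atoms, topology)})
    n = sum(1 for _ in _monomorphisms(motif, graph, typed_atoms, topology))
    aut = motif_automorphism_count(motif)
    if n % aut:
        raise MatchingError(
            f"'{motif.source_text}': {n} embeddings not divisible by "
            f"automorphism order {aut}"
        )
    return n // aut


# ----------------------------------------------------------------------
# brute-force oracle
# ----------------------------------------------------------------------


def _brute_embeddings(
    motif: MicroMotif,
    graph: InteractionGraph,
    typed_atoms: list[TypedAtom],
    topology: MolecularTopology,
):
    """Recursive enumeration of all injective label-compatible assignments.

    Nodes are assigned in index order; an edge between two assigned nodes
    is checked as soon as both ends exist.  No candidate ordering, no
    degree-based pruning, no acceleration structure.
    """
    bonds = {frozenset(b) for b in topology.bonds}
    nb = graph.edge_set()
    deg = graph.degrees()
    n_nodes = motif.n_nodes
    candidates = [
        [ta.index for ta in typed_atoms if ta.dlf_label == motif.nodes[k].label]
        for k in range(n_nodes)
    ]
    edges_with_prev: list[list[tuple[int, str]]] = [[] for _ in range(n_nodes)]
    for e in motif.covalent_edges:
        i, j = sorted(e)
        edges_with_prev[j].append((i, "cov"))
    for e in motif.nonbond_edges:
        i, j = sorted(e)
        edges_with_prev[j].append((i, "nb"))

    assignment: list[int | None] = [None] * n_nodes
    used: set[int] = set()

    def recurse(k: int):
        if k == n_nodes:
            yield dict(enumerate(assignment))
            return
        for atom in candidates[k]:
            if atom in used:
                continue
            ok = True
            for prev, etype in edges_with_prev[k]:
                pair = frozenset((assignment[prev], atom))
                if etype == "cov":
                    if pair not in bonds:
                        ok = False
                        break
                else:
                    if pair not in nb:
                        ok = False
                        break
            if not ok:
                continue
            if motif.nodes[k].strict and deg[atom] != motif.nonbond_degree(k):
                continue
            if not motif.nodes[k].strict and deg[atom] < motif.nonbond_degree(k):
                continue
            assignment[k] = atom
            used.add(atom)
            yield from recurse(k + 1)
            used.discard(atom)
            assignment[k] = None

    host = host_graph(graph, typed_atoms, topology)
    for mapping in recurse(0):
        if _cg_consistent(mapping, motif, host):
            yield mapping


def _brute_automorphisms(motif: MicroMotif) -> int:
    """Automorphism order by filtering all node permutations."""
    n = motif.n_nodes
    specs = motif.nodes
    cov, nb = motif.covalent_edges, motif.nonbond_edges
    count = 0
    for perm in itertools.permutations(range(n)):
        if any(
            (specs[i].label, specs[i].strict) != (specs[perm[i]].label, specs[perm[i]].strict)
            for i in range(n)
        ):
            continue
        mapped_cov = {frozenset(perm[x] for x in e) for e in cov}
        mapped_nb = {frozenset(perm[x] for x in e) for e in nb}
        if mapped_cov == cov and mapped_nb == nb:
            count += 1
    return count


def brute_force_count(
    motif: MicroMotif,
    graph: InteractionGraph,
    typed_atoms: list[TypedAtom],
    topology: MolecularTopology,
    max_atoms: int = 80,
) -> int:
    """Same contract as :func:`count_motif`, by direct enumeration.

    Refuses systems above ``max_atoms`` atoms: the enumeration is meant
    for oracle duty on small fixtures only.
    """
    _check_motif(motif, graph)
    if topology.n_atoms > max_atoms:
        raise MatchingError(
            f"brute-force enumeration refused for {topology.n_atoms} atoms "
            f"(limit {max_atoms})"
        )
    if motif.structure_class == "J":
        junction = motif.junction_node()
        return len(
            {m[junction] for m in _brute_embeddings(motif, graph, typed_atoms, topology)}
        )
    n = sum(1 for _ in _brute_embeddings(motif, graph, typed_atoms, topology))
    aut = _brute_automorphisms(motif)
    if n % aut:
        raise MatchingError(
            f"'{motif.source_text}': {n} embeddings not divisible by "
            f"automorphism order {aut}"
        )
    return n // aut


# ----------------------------------------------------------------------
# cluster tracing
# ----------------------------------------------------------------------


def trace_clusters(
    graph: InteractionGraph,
    typed_atoms: list[TypedAtom],
) -> tuple[list[set[int]], set[int]]:
    """Connected components of the interaction network.

    Returns ``(components, non_participants)``: components sorted by
    size descending (ties by smallest member id), and the set of atoms
    that carry the relevant label but no edge.  For an HP graph the
    relevant atoms are the methyl carbons; for HB, the donor hydrogens
    and acceptor oxygens.
    """
    g = nx.Graph()
    g.add_edges_from((e.i, e.j) for e in graph.edges)
    components = sorted(
        (set(c) for c in nx.connected_components(g)),
        key=lambda c: (-len(c), min(c)),
    )
    participants = set(g.nodes)
    if graph.kind == "HP":
        relevant = {ta.index for ta in typed_atoms if ta.dlf_label == "C1p"}
    else:
        relevant = {
            ta.index
            for ta in typed_atoms
            if ta.dlf_label in ("H20O", "O20E", "O20L")
        }
    return components, relevant - participants
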