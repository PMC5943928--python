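"""Parsing and canonicalisation of DANAI interaction expressions.

A *macro-interaction* names the interaction type and the two Chemical
Groups involved, e.g. ``HB_20_20`` (hydrogen bonding between two
carboxylic-acid groups) or ``HP_1_1`` (hydrophobic contact between alkane
groups).

A *micro-interaction* describes one local interaction mode as a small
labelled graph, written ``[Sa]`` + an atom string, where ``S`` classifies
the topology (J unction, R ing, L inear, C omplex) and ``a`` counts the
chemical-group instances involved.  Atom tokens are DL_F-style labels,
abbreviated against the macro-interaction's groups; the case of the element
letter is semantic (uppercase = strict, lowercase = relaxed, see the
matching module).  Connectors: ``:`` non-bonded interaction, ``-`` covalent
bond, ``#``/``@`` the remainder of the group in relaxed/strict form,
``(X)`` a branch on the neighbouring atom, ``< >`` a delocalised ring
group (parsed, not matched).

Grammar (EBNF, longest-match tokenisation so ``c1p`` is one token)::

    expression  = prefix chain ;
    prefix      = "[" class count "]" ;
    class       = "J" | "R" | "L" | "C" ;
    count       = digit { digit } ;
    chain       = item { [ connector ] item } ;
    item        = atom | branch | deloc ;
    branch      = "(" [ connector ] atom { connector atom } [ connector ] ")" ;
    deloc       = "<" atom ">" ;
    connector   = ":" | "-" | "#" | "@" ;
    atom        = letter [ digits ] [ letters ] ;

A branch with a leading connector hangs off the atom before the bracket
(covalent when the connector is omitted); a branch with a trailing
connector attaches forward to the next main-chain atom, as in
``[J5]c1p:(c1p:)c1p(:c1p):c1p``.  For class R the first and last
main-chain tokens denote one identical atom.
"""
from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field, replace

import networkx as nx

from .atom_typing import CG_REGISTRY, CGTemplate
from .errors import NotationError

__all__ = [
    "MacroInteraction",
    "AtomSpec",
    "MicroMotif",
    "parse_macro",
    "parse_micro",
    "expand_wildcards",
    "canonical_string",
    "MACRO_TYPES",
]

#: the ten macro-interaction type tokens
MACRO_TYPES = ("DD", "HB", "ID", "HP", "EI", "CD", "PS", "PD", "PT", "PI")

_CONN_COV = "-"
_CONN_NB = ":"
_CONN_WILD_RELAXED = "#"
_CONN_WILD_STRICT = "@"
_CONNECTORS = {_CONN_COV, _CONN_NB, _CONN_WILD_RELAXED, _CONN_WILD_STRICT}


@dataclass(frozen=True)
class MacroInteraction:
    """Interaction type between two chemical groups, ``TYPE_CGI1_CGI2``."""

    interaction_type: str
    cgi_1: int
    cgi_2: int

    def __post_init__(self) -> None:
        if self.interaction_type not in MACRO_TYPES:
            raise NotationError(
                f"unknown interaction type '{self.interaction_type}' "
                f"(expected one of {', '.join(MACRO_TYPES)})"
            )
        for cgi in (self.cgi_1, self.cgi_2):
            if not isinstance(cgi, int) or cgi <= 0:
                raise NotationError(f"CGI must be a positive integer, got {cgi!r}")

    def __str__(self) -> str:
        return f"{self.interaction_type}_{self.cgi_1}_{self.cgi_2}"


def parse_macro(text: str) -> MacroInteraction:
    """Parse ``A_CGI1_CGI2``, e.g. ``HB_20_20`` -> (HB, 20, 20)."""
    if not text or not text.strip():
        raise NotationError("empty macro-interaction expression")
    parts = text.strip().split("_")
    if len(parts) != 3:
        raise NotationError(
            f"macro-interaction '{text}' is not of the form TYPE_CGI1_CGI2"
        )
    kind, a, b = parts
    if kind not in MACRO_TYPES:
        raise NotationError(f"unknown interaction type token '{kind}' in '{text}'")
    try:
        cgi_1, cgi_2 = int(a), int(b)
    except ValueError as exc:
        raise NotationError(f"non-numeric CGI in '{text}'") from exc
    return MacroInteraction(kind, cgi_1, cgi_2)


@dataclass(frozen=True)
class AtomSpec:
    """One atom token: full DL_F label, strictness and group index.

    ``strict`` mirrors the case of the element letter in the source text;
    ``short`` is the canonical abbreviated token in display case (the
    element letter is re-cased on rendering).
    """

    label: str
    strict: bool
    cgi: int
    short: str
    deloc: bool = False

    def token(self) -> str:
        if self.deloc:
            return self.short
        s = self.short
        return (s[0].upper() if self.strict else s[0].lower()) + s[1:]


@dataclass
class MicroMotif:
    """A parsed micro-interaction expression as a labelled motif graph.

    Nodes are indices into ``nodes``; ``cg_index`` maps each node to its
    chemical-group instance within the motif (components of the covalent +
    wildcard subgraph).  ``wildcard_edges`` hold unexpanded ``#``/``@``
    connectors as ``(i, j, strict)``.
    """

    structure_class: str
    cg_count: int
    macro: MacroInteraction
    nodes: list[AtomSpec]
    covalent_edges: set[frozenset[int]]
    nonbond_edges: set[frozenset[int]]
    wildcard_edges: list[tuple[int, int, bool]] = field(default_factory=list)
    ring_closure: bool = False
    source_text: str = ""
    cg_index: list[int] = field(default_factory=list)

    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def has_wildcards(self) -> bool:
        return bool(self.wildcard_edges)

    @property
    def has_deloc(self) -> bool:
        return any(n.deloc for n in self.nodes)

    def nonbond_degree(self, i: int) -> int:
        return sum(1 for e in self.nonbond_edges if i in e)

    def junction_node(self) -> int:
        """The unique atom carrying >= 2 non-bonded edges (class J)."""
        hubs = [i for i in range(self.n_nodes) if self.nonbond_degree(i) >= 2]
        if len(hubs) != 1:
            raise NotationError(
                f"'{self.source_text}': expected exactly one junction atom, "
                f"found {len(hubs)}"
            )
        return hubs[0]

    def to_networkx(self) -> nx.Graph:
        """Motif as a graph with node attrs label/strict/nb_degree/cg and
        edge attr ``etype`` in {cov, nb, wild#, wild@}."""
        g = nx.Graph()
        for i, spec in enumerate(self.nodes):
            g.add_node(
                i,
                label=spec.label,
                strict=spec.strict,
                deloc=spec.deloc,
                nb_degree=self.nonbond_degree(i),
                cg=self.cg_index[i],
            )
        for e in self.covalent_edges:
            i, j = tuple(e)
            g.add_edge(i, j, etype="cov")
        for e in self.nonbond_edges:
            i, j = tuple(e)
            g.add_edge(i, j, etype="nb")
        for i, j, strict in self.wildcard_edges:
            g.add_edge(i, j, etype="wild@" if strict else "wild#")
        return g

    def is_isomorphic(self, other: "MicroMotif") -> bool:
        """Graph isomorphism including labels, case flags and edge kinds."""
        if (self.structure_class, self.cg_count) != (
            other.structure_class,
            other.cg_count,
        ):
            return False
        nm = lambda a, b: (a["label"], a["strict"], a["deloc"]) == (
            b["label"],
            b["strict"],
            b["deloc"],
        )
        em = lambda a, b: a["etype"] == b["etype"]
        return nx.is_isomorphic(
            self.to_networkx(), other.to_networkx(), node_match=nm, edge_match=em
        )


# ----------------------------------------------------------------------
# lexing
# ----------------------------------------------------------------------

_PREFIX_RE = re.compile(r"^\[([A-Za-z])(\d+)\]")
_ATOM_RE = re.compile(r"[A-Za-z][A-Za-z0-9]*")
_ATOM_PARTS_RE = re.compile(r"^([A-Za-z])(\d*)([A-Za-z]*)$")


def _lex(body: str, source: str) -> list[tuple[str, str]]:
    tokens: list[tuple[str, str]] = []
    pos = 0
    while pos < len(body):
        ch = body[pos]
        if ch.isspace():
            pos += 1
            continue
        if ch in _CONNECTORS:
            tokens.append(("CONN", ch))
            pos += 1
        elif ch == "(":
            tokens.append(("LPAREN", ch))
            pos += 1
        elif ch == ")":
            tokens.append(("RPAREN", ch))
            pos += 1
        elif ch == "<":
            end = body.find(">", pos)
            if end < 0:
                raise NotationError(f"'{source}': unclosed '<' bracket")
            tokens.append(("DELOC", body[pos : end + 1]))
            pos = end + 1
        else:
            m = _ATOM_RE.match(body, pos)
            if not m:
                raise NotationError(
                    f"'{source}': unexpected character '{ch}' at position {pos}"
                )
            tokens.append(("ATOM", m.group(0)))
            pos = m.end()
    return tokens


def _resolve_atom(
    token: str, macro: MacroInteraction, registry: dict[int, CGTemplate], source: str
) -> AtomSpec:
    m = _ATOM_PARTS_RE.match(token)
    if not m:
        raise NotationError(f"'{source}': malformed atom token '{token}'")
    strict = token[0].isupper()
    display = token[0].upper() + token[1:]
    digits = m.group(2)
    if digits:
        cgi = int(digits)
        template = registry.get(cgi)
        if template is None:
            raise NotationError(f"'{source}': unknown CGI {cgi} in token '{token}'")
        full = template.resolve_short(display)
        if full is None:
            raise NotationError(
                f"'{source}': '{token}' is not a member label of CG "
                f"'{template.name}' (CGI {cgi})"
            )
        return AtomSpec(full, strict, cgi, template.canonical_short(full))
    # abbreviated token: CGI inherited from the macro-interaction
    hits: list[tuple[int, str, str]] = []
    for cgi in dict.fromkeys((macro.cgi_1, macro.cgi_2)):
        template = registry.get(cgi)
        if template is None:
            continue
        full = template.resolve_short(display)
        if full is not None:
            hits.append((cgi, full, template.canonical_short(full)))
    unique = {(c, f) for c, f, _ in hits}
    if not hits:
        raise NotationError(
            f"'{source}': cannot resolve atom token '{token}' against "
            f"macro-interaction {macro}"
        )
    if len(unique) > 1:
        raise NotationError(
            f"'{source}': atom token '{token}' is ambiguous between CGIs of {macro}"
        )
    cgi, full, short = hits[0]
    return AtomSpec(full, strict, cgi, short)


def _resolve_deloc(token: str, source: str) -> AtomSpec:
    inner = token[1:-1]
    m = _ATOM_PARTS_RE.match(inner)
    if not m:
        raise NotationError(f"'{source}': malformed delocalised token '{token}'")
    strict = inner[0].isupper()
    cgi = int(m.group(2)) if m.group(2) else 0
    return AtomSpec(token, strict, cgi, token, deloc=True)


# ----------------------------------------------------------------------
# parsing
# ----------------------------------------------------------------------


def parse_micro(
    text: str,
    macro: MacroInteraction,
    registry: dict[int, CGTemplate] | None = None,
) -> MicroMotif:
    """Parse a ``[Sa]...`` micro-interaction expression into a motif graph.

    Wildcards (``#``/``@``) are kept as unexpanded edges; use
    :func:`expand_wildcards` before matching.
    """
    registry = CG_REGISTRY if registry is None else registry
    source = text.strip()
    m = _PREFIX_RE.match(source)
    if not m:
        raise NotationError(
            f"'{source}': expression must start with a [Sa] class/count prefix"
        )
    structure_class = m.group(1).upper()
    if structure_class not in "JRLC":
        raise NotationError(
            f"'{source}': structure class '{m.group(1)}' not one of J, R, L, C"
        )
    cg_count = int(m.group(2))
    if cg_count < 1:
        raise NotationError(f"'{source}': CG count must be positive")
    tokens = _lex(source[m.end() :], source)
    if not tokens:
        raise NotationError(f"'{source}': empty atomic interaction")

    nodes: list[AtomSpec] = []
    cov: set[frozenset[int]] = set()
    nb: set[frozenset[int]] = set()
    wild: list[tuple[int, int, bool]] = []
    main_chain: list[int] = []

    def add_edge(i: int, j: int, conn: str) -> None:
        if i == j:
            raise NotationError(f"'{source}': self-interaction on one atom")
        if conn == _CONN_COV:
            cov.add(frozenset((i, j)))
        elif conn == _CONN_NB:
            nb.add(frozenset((i, j)))
        else:
            wild.append((i, j, conn == _CONN_WILD_STRICT))

    pending_conn: str | None = None
    forward: list[tuple[int, str]] = []  # pre-branches awaiting the next atom
    idx = 0
    while idx < len(tokens):
        kind, value = tokens[idx]
        if kind == "CONN":
            if pending_conn is not None:
                raise NotationError(f"'{source}': two consecutive connectors")
            pending_conn = value
            idx += 1
        elif kind in ("ATOM", "DELOC"):
            spec = (
                _resolve_deloc(value, source)
                if kind == "DELOC"
                else _resolve_atom(value, macro, registry, source)
            )
            nodes.append(spec)
            node = len(nodes) - 1
            if main_chain:
                if pending_conn is None:
                    raise NotationError(
                        f"'{source}': missing connector before '{value}'"
                    )
                add_edge(main_chain[-1], node, pending_conn)
            elif pending_conn is not None:
                raise NotationError(f"'{source}': expression starts with a connector")
            for b_node, b_conn in forward:
                add_edge(b_node, node, b_conn)
            forward.clear()
            pending_conn = None
            main_chain.append(node)
            idx += 1
        elif kind == "LPAREN":
            if not main_chain:
                raise NotationError(f"'{source}': branch before any atom")
            idx += 1
            lead: str | None = None
            trail: str | None = None
            branch_nodes: list[int] = []
            branch_pending: str | None = None
            while idx < len(tokens) and tokens[idx][0] != "RPAREN":
                bkind, bval = tokens[idx]
                if bkind == "LPAREN":
                    raise NotationError(
                        f"'{source}': nested branches are not supported"
                    )
                if bkind == "CONN":
                    if not branch_nodes and lead is None:
                        if bval in (_CONN_WILD_RELAXED, _CONN_WILD_STRICT):
                            raise NotationError(
                                f"'{source}': wildcard may not open a branch"
                            )
                        lead = bval
                    elif branch_pending is None:
                        branch_pending = bval
                    else:
                        raise NotationError(
                            f"'{source}': two consecutive connectors in branch"
                        )
                else:
                    spec = (
                        _resolve_deloc(bval, source)
                        if bkind == "DELOC"
                        else _resolve_atom(bval, macro, registry, source)
                    )
                    nodes.append(spec)
                    bnode = len(nodes) - 1
                    if branch_nodes:
                        if branch_pending is None:
                            raise NotationError(
                                f"'{source}': missing connector in branch"
                            )
                        add_edge(branch_nodes[-1], bnode, branch_pending)
                        branch_pending = None
                    branch_nodes.append(bnode)
                idx += 1
            if idx >= len(tokens):
                raise NotationError(f"'{source}': unbalanced brackets")
            if branch_pending is not None:
                trail = branch_pending
                if trail in (_CONN_WILD_RELAXED, _CONN_WILD_STRICT):
                    raise NotationError(
                        f"'{source}': wildcard may not close a branch"
                    )
            if not branch_nodes:
                raise NotationError(f"'{source}': empty branch")
            if lead is not None and trail is not None:
                raise NotationError(
                    f"'{source}': branch with both leading and trailing connectors"
                )
            if trail is not None:
                forward.append((branch_nodes[-1], trail))
            else:
                add_edge(main_chain[-1], branch_nodes[0], lead or _CONN_COV)
            idx += 1  # past RPAREN
        else:  # pragma: no cover - RPAREN outside branch
            raise NotationError(f"'{source}': unbalanced brackets")

    if pending_conn is not None:
        raise NotationError(f"'{source}': trailing connector")
    if forward:
        raise NotationError(f"'{source}': forward branch never attached")

    ring_closure = False
    if structure_class == "R":
        if len(main_chain) < 2 or main_chain[0] == main_chain[-1]:
            raise NotationError(f"'{source}': ring expression too short")
        first, last = main_chain[0], main_chain[-1]
        a, b = nodes[first], nodes[last]
        if (a.label, a.strict, a.cgi, a.deloc) != (b.label, b.strict, b.cgi, b.deloc):
            raise NotationError(
                f"'{source}': ring endpoints '{a.token()}' and '{b.token()}' "
                "must denote the identical atom"
            )
        # merge `last` into `first`
        def remap(e: frozenset[int]) -> frozenset[int]:
            return frozenset(first if x == last else x for x in e)

        new_cov = {remap(e) for e in cov}
        new_nb = {remap(e) for e in nb}
        if any(len(e) == 1 for e in itertools.chain(new_cov, new_nb)):
            raise NotationError(f"'{source}': ring closure collapses to a self-edge")
        cov, nb = new_cov, new_nb
        wild = [
            ((first if i == last else i), (first if j == last else j), s)
            for i, j, s in wild
        ]
        keep = [k for k in range(len(nodes)) if k != last]
        renum = {old: new for new, old in enumerate(keep)}
        nodes = [nodes[k] for k in keep]
        cov = {frozenset(renum[x] for x in e) for e in cov}
        nb = {frozenset(renum[x] for x in e) for e in nb}
        wild = [(renum[i], renum[j], s) for i, j, s in wild]
        ring_closure = True

    motif = MicroMotif(
        structure_class=structure_class,
        cg_count=cg_count,
        macro=macro,
        nodes=nodes,
        covalent_edges=cov,
        nonbond_edges=nb,
        wildcard_edges=wild,
        ring_closure=ring_closure,
        source_text=source,
    )
    _finalize(motif)
    return motif


def _finalize(motif: MicroMotif) -> None:
    """Assign CG components and validate the motif's declared structure."""
    src = motif.source_text
    if not motif.nonbond_edges:
        raise NotationError(
            f"'{src}': an atomic interaction must include at least one "
            "non-bonded (:) interaction"
        )
    # CG instances = components of the covalent+wildcard subgraph
    g = nx.Graph()
    g.add_nodes_from(range(motif.n_nodes))
    g.add_edges_from(tuple(e) for e in motif.covalent_edges)
    g.add_edges_from((i, j) for i, j, _ in motif.wildcard_edges)
    comp_index = [0] * motif.n_nodes
    comps = sorted(nx.connected_components(g), key=min)
    for k, comp in enumerate(comps):
        cgis = {motif.nodes[i].cgi for i in comp}
        if len(cgis) > 1:
            raise NotationError(
                f"'{src}': covalently connected atoms with different CGIs {cgis}"
            )
        for i in comp:
            comp_index[i] = k
    motif.cg_index = comp_index
    if len(comps) != motif.cg_count:
        raise NotationError(
            f"'{src}': declared {motif.cg_count} CGs but the expression "
            f"contains {len(comps)} distinct CG instances"
        )

    # CG-level multigraph of non-bonded edges
    cg = nx.MultiGraph()
    cg.add_nodes_from(range(len(comps)))
    for e in motif.nonbond_edges:
        i, j = tuple(e)
        a, b = comp_index[i], comp_index[j]
        if a == b:
            if motif.structure_class != "C":
                raise NotationError(
                    f"'{src}': non-bonded interaction within one CG instance "
                    "is only allowed in class C"
                )
            continue
        cg.add_edge(a, b)
    if motif.has_deloc:
        return  # delocalised groups: structural checks deferred (unsupported)
    if not nx.is_connected(nx.Graph(cg)):
        raise NotationError(f"'{src}': the interaction graph is disconnected")
    n, m = cg.number_of_nodes(), cg.number_of_edges()
    degrees = dict(cg.degree())
    cls = motif.structure_class
    if cls == "R":
        ok = m == n and all(d == 2 for d in degrees.values())
        if not ok:
            raise NotationError(
                f"'{src}': class R requires the CG-level graph to be one cycle"
            )
    elif cls == "L":
        simple_edges = nx.Graph(cg).number_of_edges()
        ok = m == n - 1 and simple_edges == m and all(d <= 2 for d in degrees.values())
        if not ok:
            raise NotationError(
                f"'{src}': class L requires the CG-level graph to be a simple path"
            )
    elif cls == "J":
        hubs = [i for i in range(motif.n_nodes) if motif.nonbond_degree(i) >= 2]
        ok = (
            m == n - 1
            and nx.Graph(cg).number_of_edges() == m
            and len(hubs) == 1
            and degrees[comp_index[hubs[0]]] >= 2
        )
        if not ok:
            raise NotationError(
                f"'{src}': class J requires a CG-level tree branching at "
                "exactly one atom with >= 2 non-bonded interactions"
            )
    # class C: connectivity only


# ----------------------------------------------------------------------
# wildcard expansion
# ----------------------------------------------------------------------


def expand_wildcards(
    motif: MicroMotif, registry: dict[int, CGTemplate] | None = None
) -> MicroMotif:
    """Replace ``#``/``@`` edges by the intervening chemical-group atoms.

    ``#`` inserts the template's covalent path in relaxed (lowercase) form,
    ``@`` the same atoms in strict (uppercase) form.  A motif without
    wildcards is returned unchanged.
    """
    if not motif.wildcard_edges:
        return motif
    registry = CG_REGISTRY if registry is None else registry
    nodes = list(motif.nodes)
    cov = set(motif.covalent_edges)
    nb = set(motif.nonbond_edges)
    for i, j, strict in motif.wildcard_edges:
        a, b = motif.nodes[i], motif.nodes[j]
        if a.cgi != b.cgi or motif.cg_index[i] != motif.cg_index[j]:
            raise NotationError(
                f"'{motif.source_text}': wildcard between atoms of different "
                "CG instances"
            )
        if a.deloc or b.deloc:
            raise NotationError(
                f"'{motif.source_text}': wildcard on a delocalised group"
            )
        template = registry.get(a.cgi)
        if template is None or not template.member_labels:
            raise NotationError(
                f"'{motif.source_text}': no CG template with members for CGI {a.cgi}"
            )
        path = template.covalent_path(a.label, b.label)
        prev = i
        for label in path[1:-1]:
            nodes.append(
                AtomSpec(label, strict, a.cgi, template.canonical_short(label))
            )
            new = len(nodes) - 1
            cov.add(frozenset((prev, new)))
            prev = new
        cov.add(frozenset((prev, j)))
    out = MicroMotif(
        structure_class=motif.structure_class,
        cg_count=motif.cg_count,
        macro=motif.macro,
        nodes=nodes,
        covalent_edges=cov,
        nonbond_edges=nb,
        wildcard_edges=[],
        ring_closure=motif.ring_closure,
        source_text=motif.source_text,
    )
    _finalize(out)
    return out


# ----------------------------------------------------------------------
# canonical serialisation
# ----------------------------------------------------------------------

_ETYPE_TO_CONN = {"cov": "-", "nb": ":", "wild#": "#", "wild@": "@"}


def _render_branch(g: nx.Graph, attach: int, first: int, on_path: set[int]) -> str:
    """Render the pendant chain starting at ``first`` as a branch string."""
    conn = _ETYPE_TO_CONN[g.edges[attach, first]["etype"]]
    parts = [] if conn == "-" else [conn]
    prev, node = attach, first
    while True:
        parts.append(g.nodes[node]["spec"].token())
        nxt = [v for v in g.neighbors(node) if v not in (prev,) and v not in on_path]
        if not nxt:
            break
        if len(nxt) > 1:
            raise NotationError("motif branch is not a simple chain")
        parts.append(_ETYPE_TO_CONN[g.edges[node, nxt[0]]["etype"]])
        prev, node = node, nxt[0]
    return "(" + "".join(parts) + ")"


def _branch_nodes(g: nx.Graph, attach: int, first: int, on_path: set[int]) -> set[int]:
    seen = {first}
    prev, node = attach, first
    while True:
        nxt = [v for v in g.neighbors(node) if v != prev and v not in on_path]
        if not nxt:
            return seen
        if len(nxt) > 1:
            raise NotationError("motif branch is not a simple chain")
        prev, node = node, nxt[0]
        seen.add(node)


def _serialize_walk(g: nx.Graph, walk: list[int], closed: bool) -> str | None:
    """Serialise a main-chain walk, attaching everything else as branches.

    Returns None when this walk cannot represent the whole motif (uncovered
    nodes, chords, or branches that are not simple pendant chains).
    """
    on_path = set(walk)
    parts: list[str] = []
    covered = set(on_path)
    edges_drawn = len(walk) - 1 + (1 if closed else 0)
    for k, node in enumerate(walk):
        parts.append(g.nodes[node]["spec"].token())
        branches = []
        for v in g.neighbors(node):
            in_walk_edge = (k + 1 < len(walk) and v == walk[k + 1]) or (
                k > 0 and v == walk[k - 1]
            )
            if closed and (
                (k == 0 and v == walk[-1]) or (k == len(walk) - 1 and v == walk[0])
            ):
                in_walk_edge = True
            if in_walk_edge:
                continue
            if v in on_path:
                return None  # chord: not drawable on this walk
            try:
                branches.append(_render_branch(g, node, v, on_path))
                chain = _branch_nodes(g, node, v, on_path)
            except NotationError:
                return None
            covered |= chain
            edges_drawn += len(chain)
        parts.extend(sorted(branches))
        if k + 1 < len(walk):
            parts.append(_ETYPE_TO_CONN[g.edges[node, walk[k + 1]]["etype"]])
    if closed:
        parts.append(_ETYPE_TO_CONN[g.edges[walk[-1], walk[0]]["etype"]])
        parts.append(g.nodes[walk[0]]["spec"].token())
    if covered != set(g.nodes) or edges_drawn != g.number_of_edges():
        return None
    return "".join(parts)


def canonical_string(motif: MicroMotif) -> str:
    """Deterministic serialisation: lexicographically smallest expression.

    Isomorphic motifs (same labels, case flags and edge kinds) produce the
    identical string, and the string re-parses to an isomorphic motif.
    Supported shapes are those expressible without nested branches: trees
    whose off-chain parts are simple pendant chains, and single cycles with
    pendant chains (class R).
    """
    g = motif.to_networkx()
    for i, spec in enumerate(motif.nodes):
        g.nodes[i]["spec"] = spec
    prefix = f"[{motif.structure_class}{motif.cg_count}]"
    candidates: list[str] = []
    if motif.ring_closure:
        cycles = nx.cycle_basis(nx.Graph(g))
        if len(cycles) != 1:
            raise NotationError(
                f"'{motif.source_text}': cannot serialise a ring motif whose "
                "graph is not a single cycle"
            )
        cycle = cycles[0]
        n = len(cycle)
        for start in range(n):
            for direction in (1, -1):
                walk = [cycle[(start + direction * k) % n] for k in range(n)]
                s = _serialize_walk(g, walk, closed=True)
                if s is not None:
                    candidates.append(s)
    else:
        nodes = list(g.nodes)
        for u in nodes:
            for v in nodes:
                if u == v:
                    continue
                for path in nx.all_simple_paths(g, u, v):
                    s = _serialize_walk(g, path, closed=False)
                    if s is not None:
                        candidates.append(s)
    if not candidates:
        raise NotationError(
            f"'{motif.source_text}': motif shape not serialisable without "
            "nested branches"
        )
    # prefer the most linear rendering, then break ties lexicographically
    return prefix + min(candidates, key=lambda s: (s.count("("), s))
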