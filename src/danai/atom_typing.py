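"""Chemical-group perception and DL_F-style atom labelling.

Atom labels follow the DL_F convention: element symbol, the Chemical Group
Index (CGI) of the functional group the atom belongs to, and a role letter.
For the carboxylic_acid group (CGI 20) the members are the carbonyl pair
C20/O20E and the hydroxyl pair O20L/H20O; for the alkane group (CGI 1) the
primary (methyl) carbon is C1p.

Only the groups this package can detect interactions for ship with full
templates; the registry is open so users can add further groups.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .errors import TopologyError, TypingError

__all__ = [
    "MolecularTopology",
    "TypedAtom",
    "CGTemplate",
    "CG_REGISTRY",
    "perceive_carboxylic",
    "perceive_alkyl",
    "assign_types",
    "hb_roles",
    "perceive_bonds_from_distance",
]


@dataclass(frozen=True)
class MolecularTopology:
    """Elements, covalent bonds and molecule membership for one system.

    Atom ids are 0-based positions in ``elements``.  Bonds are given
    explicitly (a force-field style sidecar); they must never cross
    molecule boundaries and each molecule must be covalently connected.
    """

    elements: tuple[str, ...]
    molecule_ids: tuple[int, ...]
    bonds: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        n = len(self.elements)
        if len(self.molecule_ids) != n:
            raise TopologyError(
                f"molecule_ids has {len(self.molecule_ids)} entries for {n} atoms"
            )
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise TopologyError(f"bond ({i}, {j}) references invalid atom ids")
            if self.molecule_ids[i] != self.molecule_ids[j]:
                raise TopologyError(
                    f"bond ({i}, {j}) crosses molecule boundary "
                    f"{self.molecule_ids[i]}/{self.molecule_ids[j]}"
                )
        g = self.graph()
        for mol in set(self.molecule_ids):
            members = [a for a in range(n) if self.molecule_ids[a] == mol]
            if len(members) > 1 and not nx.is_connected(g.subgraph(members)):
                raise TopologyError(f"molecule {mol} is not covalently connected")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def graph(self) -> nx.Graph:
        """Covalent-bond graph with atom ids as nodes."""
        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        g.add_edges_from(self.bonds)
        return g

    def neighbors(self, atom: int) -> list[int]:
        return [j if i == atom else i for i, j in self.bonds if atom in (i, j)]

    # ---- sidecar serialization -------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "atoms": [
                {"id": i, "element": e, "molecule": m}
                for i, (e, m) in enumerate(zip(self.elements, self.molecule_ids))
            ],
            "bonds": [list(b) for b in self.bonds],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "MolecularTopology":
        try:
            payload = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise TopologyError(f"topology sidecar is not valid JSON: {exc}") from exc
        for key in ("atoms", "bonds"):
            if key not in payload:
                raise TopologyError(f"topology sidecar missing '{key}' section")
        atoms = sorted(payload["atoms"], key=lambda a: a["id"])
        ids = [a["id"] for a in atoms]
        if ids != list(range(len(atoms))):
            raise TopologyError("atom ids must be 0..n-1 without gaps")
        return cls(
            elements=tuple(str(a["element"]) for a in atoms),
            molecule_ids=tuple(int(a["molecule"]) for a in atoms),
            bonds=tuple((int(i), int(j)) for i, j in payload["bonds"]),
        )


@dataclass(frozen=True)
class TypedAtom:
    """One atom with its DL_F-style label and chemical-group assignment.

    ``cg_instance`` is a system-wide index of the functional-group
    occurrence the atom belongs to; atoms outside any recognised group
    keep their plain element symbol and ``cgi = cg_instance = None``.
    """

    index: int
    element: str
    dlf_label: str
    cgi: int | None = None
    cg_instance: int | None = None


@dataclass(frozen=True)
class CGTemplate:
    """Internal structure and interaction roles of one Chemical Group."""

    name: str
    cgi: int
    member_labels: tuple[str, ...] = ()
    internal_bonds: tuple[tuple[str, str], ...] = ()
    hb_donors: frozenset[str] = frozenset()
    hb_acceptors: frozenset[str] = frozenset()
    # short token in display case (element letter upper) -> full label
    abbreviations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        members = set(self.member_labels)
        for a, b in self.internal_bonds:
            if a not in members or b not in members:
                raise TypingError(f"{self.name}: internal bond {a}-{b} outside members")
        if self.member_labels:
            g = nx.Graph(self.internal_bonds)
            g.add_nodes_from(self.member_labels)
            if not nx.is_connected(g):
                raise TypingError(f"{self.name}: template graph is not connected")
        for role_set in (self.hb_donors, self.hb_acceptors):
            if not role_set <= members:
                raise TypingError(f"{self.name}: HB roles reference non-member labels")

    def graph(self) -> nx.Graph:
        g = nx.Graph(self.internal_bonds)
        g.add_nodes_from(self.member_labels)
        return g

    def covalent_path(self, a: str, b: str) -> list[str]:
        """Shortest covalent path between two member labels (inclusive)."""
        try:
            return nx.shortest_path(self.graph(), a, b)
        except (nx.NodeNotFound, nx.NetworkXNoPath) as exc:
            raise TypingError(
                f"no covalent path between {a} and {b} in CG '{self.name}'"
            ) from exc

    def canonical_short(self, full_label: str) -> str:
        """Preferred abbreviated token (display case) for a member label.

        The role-qualified form wins over bare aliases (OL over O).
        """
        candidates = [s for s, f in self.abbreviations.items() if f == full_label]
        if not candidates:
            return full_label
        candidates.sort(key=lambda s: (-len(s), s))
        return candidates[0]

    def resolve_short(self, token: str) -> str | None:
        """Full label for an abbreviated or full token (case-insensitive)."""
        low = token.lower()
        for short, full in self.abbreviations.items():
            if short.lower() == low:
                return full
        for full in self.member_labels:
            if full.lower() == low:
                return full
        return None


CARBOXYLIC_ACID = CGTemplate(
    name="carboxylic_acid",
    cgi=20,
    member_labels=("C20", "O20E", "O20L", "H20O"),
    internal_bonds=(("C20", "O20E"), ("C20", "O20L"), ("O20L", "H20O")),
    hb_donors=frozenset({"H20O"}),
    hb_acceptors=frozenset({"O20E", "O20L"}),
    abbreviations={"C": "C20", "OE": "O20E", "OL": "O20L", "O": "O20L", "H": "H20O"},
)

ALKANE = CGTemplate(
    name="alkane",
    cgi=1,
    member_labels=("C1p",),
    internal_bonds=(),
    abbreviations={"C1p": "C1p", "Cp": "C1p"},
)

# Groups named in the DL_F scheme but without detectors here: registered so
# their CGI values parse, with no templates or roles.
BENZENE = CGTemplate(name="benzene", cgi=6)
PYRIDINE = CGTemplate(name="pyridine", cgi=501)

CG_REGISTRY: dict[int, CGTemplate] = {
    t.cgi: t for t in (ALKANE, BENZENE, CARBOXYLIC_ACID, PYRIDINE)
}


def perceive_carboxylic(topology: MolecularTopology) -> list[dict[str, int]]:
    """Find carboxylic-acid (COOH) occurrences from connectivity alone.

    A carbon bonded to two oxygens qualifies when exactly one oxygen is
    terminal (carbonyl, O20E) and the other carries exactly one hydrogen
    (hydroxyl, O20L with its H20O).  Ambiguous oxygen roles raise.

    Returns one ``{label: atom_id}`` dict per occurrence, in order of the
    carboxyl carbon's atom id.
    """
    g = topology.graph()
    elem = topology.elements
    out: list[dict[str, int]] = []
    for c in sorted(g.nodes):
        if elem[c].upper() != "C":
            continue
        oxy = [n for n in g.neighbors(c) if elem[n].upper() == "O"]
        if len(oxy) != 2:
            continue
        carbonyl = [o for o in oxy if set(g.neighbors(o)) == {c}]
        hydroxyl = []
        for o in oxy:
            hs = [n for n in g.neighbors(o) if elem[n].upper() == "H"]
            if len(hs) == 1 and set(g.neighbors(o)) == {c, hs[0]}:
                hydroxyl.append((o, hs[0]))
        if not carbonyl and not hydroxyl:
            continue  # e.g. an ester linkage: not a COOH, not an error
        if len(carbonyl) != 1 or len(hydroxyl) != 1:
            raise TypingError(
                f"ambiguous oxygen roles at carboxyl carbon {c}: "
                f"{len(carbonyl)} terminal, {len(hydroxyl)} H-bearing"
            )
        o_e = carbonyl[0]
        o_l, h = hydroxyl[0]
        out.append({"C20": c, "O20E": o_e, "O20L": o_l, "H20O": h})
    return out


def perceive_alkyl(topology: MolecularTopology) -> list[int]:
    """Primary sp3 (methyl) carbons: four neighbours, exactly one heavy.

    Each methyl carbon is one alkane-group occurrence of its own for the
    purpose of hydrophobic contacts.
    """
    g = topology.graph()
    elem = topology.elements
    out = []
    for c in sorted(g.nodes):
        if elem[c].upper() != "C":
            continue
        nbrs = list(g.neighbors(c))
        heavy = [n for n in nbrs if elem[n].upper() != "H"]
        if len(nbrs) == 4 and len(heavy) == 1:
            out.append(c)
    return out


def assign_types(topology: MolecularTopology) -> list[TypedAtom]:
    """Label every atom; recognised groups get DL_F labels and instance ids.

    Instance indices are global and stable under re-runs: carboxylic
    occurrences first (by carboxyl-carbon id), then methyl carbons (by id).
    """
    labels: dict[int, tuple[str, int, int]] = {}
    instance = 0
    for occ in perceive_carboxylic(topology):
        for lab, atom in occ.items():
            labels[atom] = (lab, 20, instance)
        instance += 1
    for c in perceive_alkyl(topology):
        labels[c] = ("C1p", 1, instance)
        instance += 1
    out = []
    for i, e in enumerate(topology.elements):
        if i in labels:
            lab, cgi, inst = labels[i]
            out.append(TypedAtom(i, e, lab, cgi, inst))
        else:
            out.append(TypedAtom(i, e, e))
    return out


def hb_roles(cg: CGTemplate | int) -> tuple[frozenset[str], frozenset[str]]:
    """Donor-hydrogen and acceptor labels of a chemical group.

    Raises :class:`TypingError` for groups with no hydrogen-bond roles
    defined, except the alkane group which legitimately has empty sets.
    """
    template = CG_REGISTRY[cg] if isinstance(cg, int) else cg
    if template.cgi == ALKANE.cgi:
        return frozenset(), frozenset()
    if not template.hb_donors and not template.hb_acceptors:
        raise TypingError(f"no HB roles defined for CG '{template.name}' (CGI {template.cgi})")
    return template.hb_donors, template.hb_acceptors


#: single-bond covalent radii (Å) for the elements this package handles
_COVALENT_RADII = {"H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05}


def perceive_bonds_from_distance(
    elements: list[str],
    coordinates,
    molecule_ids: list[int] | None = None,
    slack: float = 0.4,
) -> MolecularTopology:
    """Distance-based bond guess (covalent radii + ``slack`` Å).

    Fixture convenience only — force-field topologies should be supplied
    explicitly.  Molecule membership defaults to connected components.
    """
    import numpy as np

    xyz = np.asarray(coordinates, dtype=float)
    n = len(elements)
    bonds = []
    for i in range(n):
        for j in range(i + 1, n):
            cut = (
                _COVALENT_RADII.get(elements[i].capitalize(), 0.8)
                + _COVALENT_RADII.get(elements[j].capitalize(), 0.8)
                + slack
            )
            if np.linalg.norm(xyz[i] - xyz[j]) <= cut:
                bonds.append((i, j))
    if molecule_ids is None:
        g = nx.Graph(bonds)
        g.add_nodes_from(range(n))
        mol = [0] * n
        for k, comp in enumerate(nx.connected_components(g)):
            for a in comp:
                mol[a] = k
        molecule_ids = mol
    return MolecularTopology(tuple(elements), tuple(molecule_ids), tuple(bonds))
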