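"""Geometric detection of hydrogen bonds and hydrophobic contacts.

A hydrogen bond is identified between a donor hydrogen and an acceptor
heavy atom when the H···acceptor minimum-image distance is <= ``d`` (2.5 Å
by default) and the donor–H···acceptor angle, with H at the apex, is
>= ``θ`` (120° by default); both comparisons are inclusive.  Donor and
acceptor must belong to different chemical-group instances, which excludes
the intramolecular contact between the two oxygens of one COOH.

A hydrophobic contact joins two primary alkyl (methyl) carbons of
different molecules whose minimum-image distance is <= 4.5 Å — chosen so
only direct nearest-neighbour carbon contacts qualify.

Periodicity is the orthorhombic minimum-image convention; frames without a
box are treated as open clusters.  Pair searches run either over all pairs
(the reference implementation) or through a periodic k-d tree; the two are
asserted equal in the test suite.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .atom_typing import CG_REGISTRY, MolecularTopology, TypedAtom, hb_roles
from .errors import DetectionError
from .trajectory import Frame, Trajectory

#: tolerance making the inclusive <=/>= criteria robust to rounding at
#: exactly-threshold geometries (1 nÅ; far below any physical significance)
_EPS = 1e-9

__all__ = [
    "InteractionCriteria",
    "InteractionEdge",
    "InteractionGraph",
    "minimum_image",
    "detect_hb",
    "detect_hp",
    "build_interaction_graph",
    "rdf",
]


@dataclass(frozen=True)
class InteractionCriteria:
    """Geometric criteria: HB distance/angle and HP cutoff (defaults as above)."""

    hb_distance_max: float = 2.5
    hb_angle_min: float = 120.0
    hp_distance_max: float = 4.5

    def __post_init__(self) -> None:
        if self.hb_distance_max <= 0:
            raise DetectionError("hb_distance_max must be positive")
        if not (0.0 < self.hb_angle_min <= 180.0):
            raise DetectionError("hb_angle_min must be in (0, 180]")
        if self.hp_distance_max <= 0:
            raise DetectionError("hp_distance_max must be positive")


@dataclass(frozen=True)
class InteractionEdge:
    """One non-bonded edge; ``donor`` and ``angle`` are HB-only."""

    i: int  # HB: the hydrogen; HP: lower atom id
    j: int  # HB: the acceptor; HP: higher atom id
    distance: float
    donor: int | None = None
    angle: float | None = None


@dataclass
class InteractionGraph:
    """Per-frame graph of one macro-interaction type over typed atoms."""

    kind: str  # "HB" or "HP"
    n_atoms: int
    edges: list[InteractionEdge] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("HB", "HP"):
            raise DetectionError(f"unsupported macro-interaction kind '{self.kind}'")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_atoms, dtype=int)
        for e in self.edges:
            deg[e.i] += 1
            deg[e.j] += 1
        return deg

    def edge_set(self) -> set[frozenset[int]]:
        return {frozenset((e.i, e.j)) for e in self.edges}


def minimum_image(
    u: np.ndarray, v: np.ndarray, box: np.ndarray | None
) -> tuple[np.ndarray, float]:
    """Shortest periodic displacement v - u and its length.

    Without a box this is the plain Euclidean displacement.  Supports
    broadcasting over leading axes.
    """
    disp = np.asarray(v, dtype=float) - np.asarray(u, dtype=float)
    if box is not None:
        b = np.asarray(box, dtype=float)
        disp = disp - b * np.round(disp / b)
    return disp, float(np.linalg.norm(disp)) if disp.ndim == 1 else np.linalg.norm(
        disp, axis=-1
    )


def _pair_displacements(
    coords_a: np.ndarray, coords_b: np.ndarray, box: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    disp = coords_b[None, :, :] - coords_a[:, None, :]
    if box is not None:
        disp = disp - box * np.round(disp / box)
    return disp, np.linalg.norm(disp, axis=-1)

def _candidate_pairs(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    cutoff: float,
    box: np.ndarray | None,
    method: str,
) -> list[tuple[int, int]]:
    """Index pairs (ia, ib) with minimum-image distance <= cutoff."""
    if method == "brute":
        _, dist = _pair_displacements(coords_a, coords_b, box)
        ia, ib = np.nonzero(dist <= cutoff + _EPS)
        return list(zip(ia.tolist(), ib.tolist()))
    if method != "tree":
        raise DetectionError(f"unknown pair-search method '{method}'")
    if box is not None:
        if cutoff > float(np.min(box)) / 2:
            raise DetectionError(
                f"cutoff {cutoff} exceeds half the smallest box edge"
            )
        wrap_a = np.mod(coords_a, box)
        wrap_b = np.mod(coords_b, box)
        tree_a = cKDTree(wrap_a, boxsize=box)
        tree_b = cKDTree(wrap_b, boxsize=box)
    else:
        tree_a = cKDTree(coords_a)
        tree_b = cKDTree(coords_b)
    out = []
    for ia, hits in enumerate(tree_a.query_ball_tree(tree_b, cutoff + _EPS)):
        out.extend((ia, ib) for ib in hits)
    return out


def _donor_of(h_atom: int, topology: MolecularTopology) -> int:
    heavy = [
        n for n in topology.neighbors(h_atom) if topology.elements[n].upper() != "H"
    ]
    if len(heavy) != 1:
        raise DetectionError(
            f"hydrogen {h_atom} has {len(heavy)} covalent heavy neighbours; "
            "cannot identify its donor"
        )
    return heavy[0]


def detect_hb(
    frame: Frame,
    typed_atoms: list[TypedAtom],
    topology: MolecularTopology,
    criteria: InteractionCriteria | None = None,
    method: str = "tree",
) -> list[InteractionEdge]:
    """All hydrogen bonds of a frame under the distance + angle criteria.

    One hydrogen may carry several bonds (bifurcation is a legitimate
    outcome); exclusivity is a matching-time notion, not a detection-time
    one.
    """
    criteria = criteria or InteractionCriteria()
    donors_h: list[int] = []
    acceptors: list[int] = []
    for ta in typed_atoms:
        if ta.cgi is None:
            continue
        template = CG_REGISTRY.get(ta.cgi)
        if template is None or (not template.hb_donors and not template.hb_acceptors):
            continue
        don, acc = hb_roles(template)
        if ta.dlf_label in don:
            donors_h.append(ta.index)
        if ta.dlf_label in acc:
            acceptors.append(ta.index)
    if not donors_h or not acceptors:
        return []
    coords = frame.coordinates
    box = frame.box
    h_coords = coords[donors_h]
    a_coords = coords[acceptors]
    edges: list[InteractionEdge] = []
    cos_min = np.cos(np.deg2rad(criteria.hb_angle_min))
    for ih, ia in _candidate_pairs(
        h_coords, a_coords, criteria.hb_distance_max, box, method
    ):
        h, a = donors_h[ih], acceptors[ia]
        if typed_atoms[h].cg_instance == typed_atoms[a].cg_instance:
            continue
        d_atom = _donor_of(h, topology)
        v_ha, dist_ha = minimum_image(coords[h], coords[a], box)
        if dist_ha > criteria.hb_distance_max + _EPS:
            continue
        v_hd, dist_hd = minimum_image(coords[h], coords[d_atom], box)
        cos_angle = float(np.dot(v_hd, v_ha) / (dist_hd * dist_ha))
        # angle >= theta  <=>  cos(angle) <= cos(theta)
        if cos_angle <= cos_min + _EPS:
            angle = float(np.degrees(np.arccos(np.clip(cos_angle, -1.0, 1.0))))
            edges.append(InteractionEdge(h, a, dist_ha, donor=d_atom, angle=angle))
    edges.sort(key=lambda e: (e.i, e.j))
    return edges


def detect_hp(
    frame: Frame,
    typed_atoms: list[TypedAtom],
    topology: MolecularTopology,
    criteria: InteractionCriteria | None = None,
    method: str = "tree",
) -> list[InteractionEdge]:
    """All intermolecular methyl-carbon (C1p) contacts within the cutoff."""
    criteria = criteria or InteractionCriteria()
    c1p = [ta.index for ta in typed_atoms if ta.dlf_label == "C1p"]
    if len(c1p) < 2:
        return []
    coords = frame.coordinates[c1p]
    edges: list[InteractionEdge] = []
    for ia, ib in _candidate_pairs(
        coords, coords, criteria.hp_distance_max, frame.box, method
    ):
        if ia >= ib:
            continue
        i, j = c1p[ia], c1p[ib]
        if topology.molecule_ids[i] == topology.molecule_ids[j]:
            continue
        _, dist = minimum_image(frame.coordinates[i], frame.coordinates[j], frame.box)
        edges.append(InteractionEdge(min(i, j), max(i, j), float(dist)))
    edges.sort(key=lambda e: (e.i, e.j))
    return edges


def build_interaction_graph(
    frame: Frame,
    typed_atoms: list[TypedAtom],
    topology: MolecularTopology,
    kind: str,
    criteria: InteractionCriteria | None = None,
    method: str = "tree",
) -> InteractionGraph:
    """Detect edges of one macro-interaction type and wrap them as a graph."""
    if kind == "HB":
        edges = detect_hb(frame, typed_atoms, topology, criteria, method)
    elif kind == "HP":
        edges = detect_hp(frame, typed_atoms, topology, criteria, method)
    else:
        raise DetectionError(
            f"no detector for macro-interaction type '{kind}' "
            "(supported: HB, HP)"
        )
    return InteractionGraph(kind=kind, n_atoms=topology.n_atoms, edges=edges)


def rdf(
    trajectory: Trajectory | Frame,
    typed_atoms: list[TypedAtom],
    label_a: str,
    label_b: str,
    bin_width: float = 0.1,
    r_max: float | None = None,
) -> pd.DataFrame:
    """Radial distribution function g(r) between two atom labels.

    Shell pair counts are normalised by the uniform (ideal-gas)
    expectation in the periodic box.  Returns columns ``r`` (bin centre)
    and ``g``.
    """
    if isinstance(trajectory, Frame):
        trajectory = Trajectory([trajectory])
    sel_a = [ta.index for ta in typed_atoms if ta.dlf_label == label_a]
    sel_b = [ta.index for ta in typed_atoms if ta.dlf_label == label_b]
    if not sel_a:
        raise DetectionError(f"no atoms with label '{label_a}'")
    if not sel_b:
        raise DetectionError(f"no atoms with label '{label_b}'")
    box = trajectory[0].box
    if box is None:
        raise DetectionError("rdf requires a periodic box")
    if r_max is None:
        r_max = float(np.min(box)) / 2
    if r_max > float(np.min(box)) / 2 + 1e-9:
        raise DetectionError(
            f"r_max {r_max} exceeds half the smallest box edge {np.min(box) / 2}"
        )
    n_bins = int(np.ceil(r_max / bin_width))
    hist = np.zeros(n_bins)
    same = label_a == label_b
    for frame in trajectory:
        _, dist = _pair_displacements(
            frame.coordinates[sel_a], frame.coordinates[sel_b], frame.box
        )
        if same:
            iu = np.triu_indices(len(sel_a), k=1)
            d = dist[iu]
        else:
            d = dist.ravel()
        d = d[(d > 0) & (d < r_max)]
        h, _ = np.histogram(d, bins=n_bins, range=(0.0, r_max))
        hist += h
    edges = np.linspace(0.0, r_max, n_bins + 1)
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    volume = float(np.prod(box))
    n_a, n_b = len(sel_a), len(sel_b)
    if same:
        ideal = len(trajectory) * (n_a * (n_a - 1) / 2) * shell_vol / volume
    else:
        ideal = len(trajectory) * n_a * n_b * shell_vol / volume
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(ideal > 0, hist / ideal, 0.0)
    centres = 0.5 * (edges[1:] + edges[:-1])
    return pd.DataFrame({"r": centres, "g": g})
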