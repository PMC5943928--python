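"""Synthetic configurations with known interaction structure.

Everything the detectors and matchers claim is tested against fixtures
built here: an idealised rigid ethanoic-acid (CH3-COOH) molecule placed in
hydrogen-bonded chains, the classic cyclic dimer, methyl clusters with a
prescribed hydrophobic contact pattern, and random pseudo-liquid packings
in a periodic cubic box.

Every builder audits its advertised edge set through the full
typing → detection pipeline after placement and raises
:class:`PlacementError` on any discrepancy — fixtures never rely on
construction shortcuts.

Internal geometry of the molecule (a design choice, not fitted): C–C
1.50 Å, C=O 1.21 Å, C–O 1.34 Å, O–H 0.97 Å, C–H 1.09 Å, trigonal 120°
angles at the carboxyl carbon and tetrahedral 109.47° elsewhere.
"""
from __future__ import annotations

import numpy as np

from .atom_typing import MolecularTopology, TypedAtom, assign_types
from .detection import InteractionCriteria, detect_hb, detect_hp
from .errors import PlacementError
from .trajectory import Frame

__all__ = [
    "build_ethanoic_molecule",
    "molecule_count_from_density",
    "make_hb_chain",
    "make_cyclic_dimer",
    "make_methyl_cluster",
    "random_liquid",
    "AVOGADRO",
    "ETHANOIC_MOLAR_MASS",
]

AVOGADRO = 6.02214076e23
#: CH3COOH, g/mol
ETHANOIC_MOLAR_MASS = 60.052

# bond lengths, Å
_CC = 1.50
_C_DOUBLE_O = 1.21
_C_SINGLE_O = 1.34
_OH = 0.97
_CH = 1.09
_TETRA = np.deg2rad(109.47)

#: atom order of one molecule; indices into the 8-atom template
ATOM_ORDER = ("C1p", "Hm1", "Hm2", "Hm3", "C20", "O20E", "O20L", "H20O")
I_C1P, I_HM1, I_HM2, I_HM3, I_C20, I_O20E, I_O20L, I_H20O = range(8)

_ELEMENTS = ("C", "H", "H", "H", "C", "O", "O", "H")
_BONDS = ((0, 1), (0, 2), (0, 3), (0, 4), (4, 5), (4, 6), (6, 7))


def _rot(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix about ``axis`` by ``angle`` (radians)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    c, s = np.cos(angle), np.sin(angle)
    t = 1 - c
    return np.array(
        [
            [t * x * x + c, t * x * y - s * z, t * x * z + s * y],
            [t * x * y + s * z, t * y * y + c, t * y * z - s * x],
            [t * x * z - s * y, t * y * z + s * x, t * z * z + c],
        ]
    )


def build_ethanoic_molecule(
    conformer: str = "syn",
) -> tuple[MolecularTopology, np.ndarray]:
    """One idealised CH3-COOH molecule: topology plus (8, 3) coordinates.

    ``conformer`` places the hydroxyl hydrogen cis ("syn", the stable form
    and the one adopted in the cyclic dimer) or trans ("anti") to the
    carbonyl oxygen.  The heavy atoms and the acidic hydrogen are coplanar
    (z = 0).
    """
    if conformer not in ("syn", "anti"):
        raise PlacementError(f"unknown conformer '{conformer}'")
    xyz = np.zeros((8, 3))
    # carboxyl carbon at origin; three trigonal directions in the xy plane
    d_c1p = np.array([-1.0, 0.0, 0.0])
    d_oe = np.array([np.cos(np.deg2rad(60)), np.sin(np.deg2rad(60)), 0.0])
    d_ol = np.array([np.cos(np.deg2rad(-60)), np.sin(np.deg2rad(-60)), 0.0])
    xyz[I_C1P] = _CC * d_c1p
    xyz[I_O20E] = _C_DOUBLE_O * d_oe
    xyz[I_O20L] = _C_SINGLE_O * d_ol
    # hydroxyl H: C-O-H angle tetrahedral, in plane; syn points toward O20E
    back = -d_ol  # O20L -> C20 direction
    sign = 1.0 if conformer == "syn" else -1.0
    rot = _rot(np.array([0.0, 0.0, sign]), np.pi - _TETRA)
    xyz[I_H20O] = xyz[I_O20L] + _OH * (rot @ back) * -1.0
    # methyl hydrogens: tetrahedral cage around C1p, one H staggered out of plane
    axis = -d_c1p  # C1p -> C20 direction
    base = _rot(np.array([0.0, 0.0, 1.0]), _TETRA) @ axis
    for k, phase in enumerate((0.0, 2 * np.pi / 3, 4 * np.pi / 3)):
        direction = _rot(axis, phase + np.pi / 6) @ base
        xyz[I_HM1 + k] = xyz[I_C1P] + _CH * direction
    topology = MolecularTopology(_ELEMENTS, (0,) * 8, _BONDS)
    return topology, xyz


def molecule_count_from_density(
    box_edge: float, density: float, molar_mass: float
) -> int:
    """Molecules filling a cubic box of ``box_edge`` Å at ``density`` g/cm³.

    round(ρ · L³ · 10⁻²⁴ · N_A / M): a 40 Å box of ethanoic acid at
    1.05 g/cm³ holds 674 molecules.
    """
    if box_edge <= 0 or molar_mass <= 0 or density < 0:
        raise PlacementError("box edge and molar mass must be positive")
    return int(round(density * box_edge**3 * 1e-24 * AVOGADRO / molar_mass))


def _replicate(
    placements: list[np.ndarray],
) -> tuple[MolecularTopology, np.ndarray]:
    """Concatenate per-molecule coordinate blocks into one system."""
    n = len(placements)
    elements = _ELEMENTS * n
    molecule_ids = tuple(m for m in range(n) for _ in range(8))
    bonds = tuple(
        (i + 8 * m, j + 8 * m) for m in range(n) for i, j in _BONDS
    )
    coords = np.vstack(placements)
    return MolecularTopology(elements, molecule_ids, bonds), coords


def _audit(
    topology: MolecularTopology,
    frame: Frame,
    expected_hb: set[frozenset[int]],
    expected_hp: set[frozenset[int]],
    what: str,
) -> list[TypedAtom]:
    typed = assign_types(topology)
    criteria = InteractionCriteria()
    hb = {frozenset((e.i, e.j)) for e in detect_hb(frame, typed, topology, criteria, method="brute")}
    hp = {frozenset((e.i, e.j)) for e in detect_hp(frame, typed, topology, criteria, method="brute")}
    if hb != expected_hb or hp != expected_hp:
        raise PlacementError(
            f"{what}: placement audit failed "
            f"(HB got {sorted(map(sorted, hb))}, wanted {sorted(map(sorted, expected_hb))}; "
            f"HP got {sorted(map(sorted, hp))}, wanted {sorted(map(sorted, expected_hp))})"
        )
    return typed


def _oriented_template(conformer: str) -> np.ndarray:
    """Template moved so O20L sits at the origin with the O-H bond on +x."""
    _, xyz = build_ethanoic_molecule(conformer)
    xyz = xyz - xyz[I_O20L]
    oh = xyz[I_H20O] / np.linalg.norm(xyz[I_H20O])
    target = np.array([1.0, 0.0, 0.0])
    v = np.cross(oh, target)
    s = np.linalg.norm(v)
    if s < 1e-12:
        return xyz if oh @ target > 0 else xyz @ _rot([0, 0, 1], np.pi).T
    angle = np.arctan2(s, float(oh @ target))
    return xyz @ _rot(v, angle).T


def make_hb_chain(
    n: int, geometry: str = "head_to_tail", twist_deg: float = 120.0
) -> tuple[MolecularTopology, Frame]:
    """``n`` molecules in a single hydrogen-bonded chain along x.

    head_to_tail: molecule i's hydroxyl H donates to molecule i+1's
    carbonyl oxygen (H···O20E 1.8 Å, 180° at H); tail_to_tail: to the
    hydroxyl oxygen O20L instead.  Successive molecules are twisted by
    ``twist_deg`` about the chain axis so nothing else comes within the
    hydrogen-bond or hydrophobic criteria; the final geometry is audited.
    """
    if n < 2:
        raise PlacementError("a chain needs at least two molecules")
    if geometry not in ("head_to_tail", "tail_to_tail"):
        raise PlacementError(f"unknown chain geometry '{geometry}'")
    template = _oriented_template("anti")
    target_idx = I_O20E if geometry == "head_to_tail" else I_O20L
    placements = [template.copy()]
    for i in range(1, n):
        rotated = template @ _rot([1.0, 0.0, 0.0], np.deg2rad(twist_deg) * i).T
        h_prev = placements[-1][I_H20O]
        shift = h_prev + np.array([1.8, 0.0, 0.0]) - rotated[target_idx]
        placements.append(rotated + shift)
    topology, coords = _replicate(placements)
    frame = Frame(coords)
    expected = {
        frozenset((8 * i + I_H20O, 8 * (i + 1) + target_idx)) for i in range(n - 1)
    }
    _audit(topology, frame, expected, set(), f"hb_chain(n={n}, {geometry})")
    return topology, frame


def make_cyclic_dimer() -> tuple[MolecularTopology, Frame]:
    """The classic carboxylic-acid dimer: two molecules, two hydrogen
    bonds (each hydroxyl H to the partner's carbonyl oxygen), no
    hydrophobic contact."""
    a = _oriented_template("syn")
    flip = np.diag([-1.0, -1.0, 1.0])  # 180° about z
    b = a @ flip.T
    shift = a[I_H20O] + np.array([1.8, 0.0, 0.0]) - b[I_O20E]
    b = b + shift
    topology, coords = _replicate([a, b])
    frame = Frame(coords)
    expected = {
        frozenset((I_H20O, 8 + I_O20E)),
        frozenset((8 + I_H20O, I_O20E)),
    }
    _audit(topology, frame, expected, set(), "cyclic_dimer")
    return topology, frame


def make_methyl_cluster(
    sizes: list[int],
    shape: str = "chain",
    contact_distance: float = 4.0,
    cluster_gap: float = 12.0,
) -> tuple[MolecularTopology, Frame]:
    """Disjoint methyl clusters with a prescribed hydrophobic topology.

    Each cluster holds ``size`` parallel molecules whose methyl carbons
    sit ``contact_distance`` apart — consecutively along x for ``shape =
    "chain"``, or one central methyl with the others around it in the xy
    plane for ``shape = "star"`` (star needs size >= 2).  Clusters are
    separated by ``cluster_gap`` along y.  Carboxyl groups all point +z,
    far outside the hydrogen-bond criteria.
    """
    if not sizes or any(s < 1 for s in sizes):
        raise PlacementError("sizes must be a non-empty list of positive counts")
    if shape not in ("chain", "star"):
        raise PlacementError(f"unknown cluster shape '{shape}'")
    # orient template: C1p at origin, C1p->C20 along +z
    _, xyz = build_ethanoic_molecule("anti")
    xyz = xyz - xyz[I_C1P]
    cc = xyz[I_C20] / np.linalg.norm(xyz[I_C20])
    v = np.cross(cc, [0.0, 0.0, 1.0])
    s = np.linalg.norm(v)
    if s > 1e-12:
        xyz = xyz @ _rot(v, np.arctan2(s, cc[2])).T
    placements = []
    expected_hp: set[frozenset[int]] = set()
    mol = 0
    for c, size in enumerate(sizes):
        y0 = c * cluster_gap
        first_mol = mol
        if shape == "chain":
            offsets = [np.array([k * contact_distance, y0, 0.0]) for k in range(size)]
            pairs = [(k, k + 1) for k in range(size - 1)]
        else:
            offsets = [np.array([0.0, y0, 0.0])]
            for k in range(size - 1):
                phi = 2 * np.pi * k / max(size - 1, 1)
                offsets.append(
                    np.array(
                        [contact_distance * np.cos(phi), y0 + contact_distance * np.sin(phi), 0.0]
                    )
                )
            pairs = [(0, k + 1) for k in range(size - 1)]
        for off in offsets:
            placements.append(xyz + off)
            mol += 1
        for a, b in pairs:
            expected_hp.add(
                frozenset(
                    (8 * (first_mol + a) + I_C1P, 8 * (first_mol + b) + I_C1P)
                )
            )
    topology, coords = _replicate(placements)
    frame = Frame(coords)
    _audit(topology, frame, set(), expected_hp, f"methyl_cluster({sizes}, {shape})")
    return topology, frame


def random_liquid(
    n_molecules: int,
    box_edge: float,
    min_separation: float = 1.3,
    seed: int | None = None,
    max_attempts: int = 20000,
) -> tuple[MolecularTopology, Frame]:
    """Rigid random placements in a periodic cubic box.

    Molecules are inserted one by one with uniform random position and
    orientation, rejecting any placement that brings two atoms of
    different molecules within ``min_separation`` (minimum image).  The
    default separation is the largest value at which insertion remains
    feasible at ethanoic acid's liquid density; the packing is a
    pseudo-liquid, not a thermodynamically relaxed structure.
    Deterministic for a fixed ``seed``.
    """
    if n_molecules < 1 or box_edge <= 0:
        raise PlacementError("need at least one molecule and a positive box")
    rng = np.random.default_rng(seed)
    _, template = build_ethanoic_molecule("syn")
    template = template - template.mean(axis=0)
    box = np.full(3, float(box_edge))
    placed: list[np.ndarray] = []
    occupied: np.ndarray | None = None
    for m in range(n_molecules):
        for attempt in range(max_attempts):
            # uniform random rotation from a random axis + angle is biased;
            # use QR on a Gaussian matrix (Haar measure)
            q, r = np.linalg.qr(rng.normal(size=(3, 3)))
            q = q * np.sign(np.diag(r))
            if np.linalg.det(q) < 0:
                q[:, 0] = -q[:, 0]
            pos = rng.uniform(0.0, box_edge, size=3)
            candidate = template @ q.T + pos
            if occupied is None:
                break
            disp = candidate[:, None, :] - occupied[None, :, :]
            disp -= box * np.round(disp / box)
            if np.min(np.linalg.norm(disp, axis=-1)) >= min_separation:
                break
        else:
            raise PlacementError(
                f"could not place molecule {m} after {max_attempts} attempts "
                f"(min_separation={min_separation}, box={box_edge})"
            )
        placed.append(candidate)
        occupied = (
            candidate if occupied is None else np.vstack([occupied, candidate])
        )
    topology, coords = _replicate(placed)
    return topology, Frame(coords, box=box)
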