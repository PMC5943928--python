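"""Geometric interaction detection: criteria, periodicity, RDF."""
import numpy as np
import pytest

from danai import (
    DetectionError,
    Frame,
    InteractionCriteria,
    TypedAtom,
    assign_types,
    build_interaction_graph,
    detect_hb,
    detect_hp,
    minimum_image,
    random_liquid,
    rdf,
)
from danai.synthetic import _oriented_template, _replicate, I_H20O, I_O20E, I_C1P


def _hb_pair(distance: float, angle_deg: float):
    """Two molecules: B's carbonyl oxygen at the given distance from A's
    hydroxyl hydrogen, at the given donor-H···acceptor angle (H apex)."""
    a = _oriented_template("anti")  # O-H along +x, H at (0.97, 0, 0)
    phi = np.pi - np.deg2rad(angle_deg)
    direction = np.array([np.cos(phi), np.sin(phi), 0.0])
    target = a[I_H20O] + distance * direction
    b = _oriented_template("anti") + 12.0  # far away by default
    b = b + (target - b[I_O20E])
    topology, coords = _replicate([a, b])
    return topology, Frame(coords)


def _methyls(offsets):
    """One acid molecule per offset, methyl carbons at the offsets."""
    from danai import build_ethanoic_molecule

    _, xyz = build_ethanoic_molecule("anti")
    xyz = xyz - xyz[I_C1P]
    # point the carboxyl group up so only methyls come close
    cc = xyz[4] / np.linalg.norm(xyz[4])
    from danai.synthetic import _rot

    v = np.cross(cc, [0.0, 0.0, 1.0])
    if np.linalg.norm(v) > 1e-12:
        xyz = xyz @ _rot(v, np.arctan2(np.linalg.norm(v), cc[2])).T
    topology, coords = _replicate([xyz + np.asarray(o, float) for o in offsets])
    return topology, Frame(coords)


class TestMinimumImage:
    def test_wraparound(self):
        _, d = minimum_image(np.array([1.0, 1, 1]), np.array([39.0, 39, 39]), np.array([40.0, 40, 40]))
        assert d == pytest.approx(np.sqrt(12.0))

    def test_identical_points(self):
        _, d = minimum_image(np.zeros(3), np.zeros(3), np.array([40.0, 40, 40]))
        assert d == 0.0

    def test_without_box_is_euclidean(self):
        _, d = minimum_image(np.zeros(3), np.array([0.0, 0, 5]), None)
        assert d == 5.0


class TestHydrogenBonds:
    def _count(self, distance, angle):
        topology, frame = _hb_pair(distance, angle)
        typed = assign_types(topology)
        return len(detect_hb(frame, typed, topology, method="brute"))

    @pytest.mark.parametrize(
        "distance, angle, expected",
        [
            (1.8, 180.0, 1),  # collinear, short: a bond
            (2.6, 180.0, 0),  # beyond the distance criterion
            (2.0, 100.0, 0),  # below the angle criterion
            (2.5, 120.0, 1),  # both thresholds inclusive
        ],
    )
    def test_distance_and_angle_criteria(self, distance, angle, expected):
        assert self._count(distance, angle) == expected

    def test_edges_carry_geometry(self):
        topology, frame = _hb_pair(1.8, 180.0)
        typed = assign_types(topology)
        (edge,) = detect_hb(frame, typed, topology, method="brute")
        assert edge.distance == pytest.approx(1.8)
        assert edge.angle == pytest.approx(180.0)
        assert typed[edge.i].dlf_label == "H20O"
        assert typed[edge.j].dlf_label == "O20E"

    def test_intramolecular_contact_is_excluded(self):
        # a single molecule is its own chemical group: no self hydrogen bond
        topology, frame = _hb_pair(8.0, 180.0)
        typed = assign_types(topology)
        assert detect_hb(frame, typed, topology, method="brute") == []


class TestHydrophobicContacts:
    def _count(self, offsets):
        topology, frame = _methyls(offsets)
        typed = assign_types(topology)
        return len(detect_hp(frame, typed, topology, method="brute"))

    def test_two_methyls_inside_cutoff(self):
        assert self._count([(0, 0, 0), (4.0, 0, 0)]) == 1

    def test_two_methyls_outside_cutoff(self):
        assert self._count([(0, 0, 0), (4.6, 0, 0)]) == 0

    def test_three_mutual_contacts(self):
        h = 4.0 * np.sqrt(3) / 2
        assert self._count([(0, 0, 0), (4.0, 0, 0), (2.0, h, 0)]) == 3


@pytest.fixture(scope="module")
def liquid():
    return random_liquid(30, 16.0, min_separation=1.5, seed=2)


class TestProperties:

    def test_hb_count_monotone_in_criteria(self, liquid):
        topology, frame = liquid
        typed = assign_types(topology)
        by_theta = [
            len(detect_hb(frame, typed, topology, InteractionCriteria(hb_angle_min=t)))
            for t in (110.0, 120.0, 130.0)
        ]
        assert by_theta == sorted(by_theta, reverse=True)
        by_d = [
            len(detect_hb(frame, typed, topology, InteractionCriteria(hb_distance_max=d)))
            for d in (2.3, 2.5, 2.7)
        ]
        assert by_d == sorted(by_d)

    def test_hp_count_monotone_in_cutoff(self, liquid):
        topology, frame = liquid
        typed = assign_types(topology)
        counts = [
            len(detect_hp(frame, typed, topology, InteractionCriteria(hp_distance_max=d)))
            for d in (4.0, 4.5, 5.0)
        ]
        assert counts == sorted(counts)

    def test_translation_with_wrapping_leaves_edges_unchanged(self, liquid):
        topology, frame = liquid
        typed = assign_types(topology)
        shift = np.array([13.1, -4.2, 27.9])
        moved = Frame(np.mod(frame.coordinates + shift, frame.box), box=frame.box)
        for detect in (detect_hb, detect_hp):
            before = {(e.i, e.j) for e in detect(frame, typed, topology)}
            after = {(e.i, e.j) for e in detect(moved, typed, topology)}
            assert before == after

    def test_tree_search_equals_all_pairs(self, liquid):
        topology, frame = liquid
        typed = assign_types(topology)
        for kind in ("HB", "HP"):
            brute = build_interaction_graph(frame, typed, topology, kind, method="brute")
            tree = build_interaction_graph(frame, typed, topology, kind, method="tree")
            assert brute.edge_set() == tree.edge_set()


class TestRDF:
    def test_uniform_gas_is_flat(self):
        rng = np.random.default_rng(0)
        box = np.array([20.0, 20.0, 20.0])
        coords = rng.uniform(0, 20, size=(400, 3))
        typed = [TypedAtom(i, "Ar", "Ar") for i in range(400)]
        frames = [Frame(rng.uniform(0, 20, size=(400, 3)), box=box) for _ in range(10)]
        from danai import Trajectory

        table = rdf(Trajectory(frames), typed, "Ar", "Ar", bin_width=0.5)
        mid = table[(table.r > 3) & (table.r < 9)]
        assert np.abs(mid.g - 1.0).mean() < 0.05

    def test_fixed_pair_occupies_one_bin(self):
        box = np.array([20.0, 20.0, 20.0])
        frame = Frame(np.array([[0.0, 0, 0], [2.0, 0, 0]]), box=box)
        typed = [TypedAtom(0, "O", "O20E"), TypedAtom(1, "H", "H20O")]
        table = rdf(frame, typed, "O20E", "H20O", bin_width=0.1, r_max=5.0)
        nonzero = table[table.g > 0]
        assert len(nonzero) == 1
        assert nonzero.r.iloc[0] == pytest.approx(2.05)

    def test_missing_label_raises(self):
        frame = Frame(np.zeros((1, 3)), box=[10.0, 10, 10])
        with pytest.raises(DetectionError, match="no atoms with label"):
            rdf(frame, [TypedAtom(0, "C", "C1p")], "O20E", "C1p")

    def test_r_max_beyond_half_box_raises(self):
        frame = Frame(np.zeros((2, 3)), box=[10.0, 10, 10])
        typed = [TypedAtom(0, "C", "C1p"), TypedAtom(1, "C", "C1p")]
        with pytest.raises(DetectionError, match="half"):
            rdf(frame, typed, "C1p", "C1p", r_max=8.0)
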