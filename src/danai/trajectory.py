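"""Configuration/trajectory reading and writing (multi-frame XYZ and PDB).

Coordinates are in Å throughout.  Boxes are orthorhombic edge lengths in Å;
a frame without a box is treated as non-periodic.  For PDB files the box
comes from the ``CRYST1`` record; plain XYZ has no standard box record, so
the comment line carries an extended-XYZ style ``Lattice="ax ay az bx by bz
cx cy cz"`` entry (orthorhombic only), with an explicit ``box=`` argument
available as fallback.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .atom_typing import MolecularTopology
from .errors import TrajectoryError

__all__ = ["Frame", "Trajectory", "read_xyz", "write_xyz", "read_pdb", "write_pdb", "frame_schedule"]


@dataclass
class Frame:
    """Coordinates (n, 3) in Å plus an optional orthorhombic box (3,)."""

    coordinates: np.ndarray
    box: np.ndarray | None = None
    time_label: float | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise TrajectoryError(
                f"coordinates must be (n, 3), got {self.coordinates.shape}"
            )
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)
            if not np.all(self.box > 0):
                raise TrajectoryError(f"box edges must be positive, got {self.box}")

    @property
    def n_atoms(self) -> int:
        return len(self.coordinates)


@dataclass
class Trajectory:
    """An ordered sequence of frames sharing one atom count."""

    frames: list[Frame]

    def __post_init__(self) -> None:
        counts = {f.n_atoms for f in self.frames}
        if len(counts) > 1:
            raise TrajectoryError(f"frames disagree on atom count: {sorted(counts)}")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]

    @property
    def n_atoms(self) -> int:
        return self.frames[0].n_atoms if self.frames else 0


def _check_elements(
    file_elements: list[str], topology: MolecularTopology | None, where: str
) -> None:
    if topology is None:
        return
    if len(file_elements) != topology.n_atoms:
        raise TrajectoryError(
            f"{where}: file has {len(file_elements)} atoms, topology has "
            f"{topology.n_atoms}"
        )
    for i, (a, b) in enumerate(zip(file_elements, topology.elements)):
        if a.capitalize() != b.capitalize():
            raise TrajectoryError(
                f"{where}: element mismatch at atom {i}: file '{a}' vs "
                f"topology '{b}'"
            )


_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')
_TIME_RE = re.compile(r"(?:time|Time)\s*=\s*([0-9.eE+-]+)")


def _parse_xyz_comment(comment: str, frame_no: int) -> tuple[np.ndarray | None, float | None]:
    box = None
    m = _LATTICE_RE.search(comment)
    if m:
        vals = [float(x) for x in m.group(1).split()]
        if len(vals) == 3:
            box = np.array(vals)
        elif len(vals) == 9:
            mat = np.array(vals).reshape(3, 3)
            off = mat - np.diag(np.diag(mat))
            if np.any(np.abs(off) > 1e-8):
                raise TrajectoryError(
                    f"frame {frame_no}: non-orthorhombic Lattice is not supported"
                )
            box = np.diag(mat).copy()
        else:
            raise TrajectoryError(
                f"frame {frame_no}: Lattice entry must have 3 or 9 numbers"
            )
    t = _TIME_RE.search(comment)
    return box, float(t.group(1)) if t else None


def read_xyz(
    path: str | Path,
    topology: MolecularTopology | None = None,
    box: np.ndarray | list[float] | None = None,
) -> Trajectory:
    """Read a (multi-frame) XYZ file.

    Elements are cross-checked against ``topology`` when given.  ``box``
    overrides/provides the periodic box for every frame.
    """
    lines = Path(path).read_text().splitlines()
    frames: list[Frame] = []
    pos = 0
    frame_no = 0
    n_expected: int | None = None
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        frame_no += 1
        try:
            n = int(lines[pos].split()[0])
        except ValueError as exc:
            raise TrajectoryError(
                f"frame {frame_no}: expected atom count, got '{lines[pos]}'"
            ) from exc
        if n_expected is None:
            n_expected = n
        elif n != n_expected:
            raise TrajectoryError(
                f"frame {frame_no}: atom count drifted from {n_expected} to {n}"
            )
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        body = lines[pos + 2 : pos + 2 + n]
        if len(body) < n:
            raise TrajectoryError(f"truncated frame {frame_no}")
        elements: list[str] = []
        coords = np.empty((n, 3))
        for i, line in enumerate(body):
            parts = line.split()
            if len(parts) < 4:
                raise TrajectoryError(f"truncated frame {frame_no}")
            elements.append(parts[0])
            coords[i] = [float(x) for x in parts[1:4]]
        _check_elements(elements, topology, f"frame {frame_no}")
        fbox, tlabel = _parse_xyz_comment(comment, frame_no)
        if box is not None:
            fbox = np.asarray(box, dtype=float)
        frames.append(Frame(coords, fbox, tlabel))
        pos += 2 + n
    if not frames:
        raise TrajectoryError(f"{path}: no frames found")
    return Trajectory(frames)


def write_xyz(
    trajectory: Trajectory | Frame,
    path: str | Path,
    elements: list[str] | MolecularTopology,
) -> None:
    """Write frames in XYZ format with a ``Lattice=`` box entry when periodic."""
    if isinstance(trajectory, Frame):
        trajectory = Trajectory([trajectory])
    if isinstance(elements, MolecularTopology):
        elements = list(elements.elements)
    out = []
    for frame in trajectory:
        if len(elements) != frame.n_atoms:
            raise TrajectoryError(
                f"{len(elements)} elements for {frame.n_atoms} coordinates"
            )
        comment = []
        if frame.box is not None:
            a, b, c = frame.box
            comment.append(
                f'Lattice="{a:.6f} 0.0 0.0 0.0 {b:.6f} 0.0 0.0 0.0 {c:.6f}"'
            )
        if frame.time_label is not None:
            comment.append(f"time={frame.time_label:g}")
        out.append(str(frame.n_atoms))
        out.append(" ".join(comment))
        for e, (x, y, z) in zip(elements, frame.coordinates):
            out.append(f"{e:<2s} {x:14.6f} {y:14.6f} {z:14.6f}")
    Path(path).write_text("\n".join(out) + "\n")


def read_pdb(
    path: str | Path, topology: MolecularTopology | None = None
) -> Trajectory:
    """Read a (multi-MODEL) PDB file; CRYST1 provides the box.

    Only orthorhombic cells (90/90/90 angles) are supported.  A file
    without MODEL records is one frame.
    """
    box: np.ndarray | None = None
    frames: list[Frame] = []
    cur_elements: list[str] = []
    cur_coords: list[list[float]] = []
    n_expected: int | None = None
    frame_no = 0
    in_model = False

    def flush() -> None:
        nonlocal n_expected, frame_no
        if not cur_coords:
            return
        frame_no += 1
        if n_expected is None:
            n_expected = len(cur_coords)
        elif len(cur_coords) != n_expected:
            raise TrajectoryError(
                f"frame {frame_no}: atom count drifted from {n_expected} "
                f"to {len(cur_coords)}"
            )
        _check_elements(cur_elements, topology, f"frame {frame_no}")
        frames.append(Frame(np.array(cur_coords), box))
        cur_elements.clear()
        cur_coords.clear()

    for line in Path(path).read_text().splitlines():
        record = line[:6].strip()
        if record == "CRYST1":
            edges = [float(line[6:15]), float(line[15:24]), float(line[24:33])]
            angles = [float(line[33:40]), float(line[40:47]), float(line[47:54])]
            if any(abs(a - 90.0) > 1e-6 for a in angles):
                raise TrajectoryError("non-orthorhombic CRYST1 is not supported")
            box = np.array(edges)
        elif record == "MODEL":
            if in_model:
                raise TrajectoryError("MODEL without matching ENDMDL")
            in_model = True
        elif record == "ENDMDL":
            in_model = False
            flush()
        elif record in ("ATOM", "HETATM"):
            try:
                xyz = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            except ValueError as exc:
                raise TrajectoryError(
                    f"unparsable coordinates in line: '{line.rstrip()}'"
                ) from exc
            element = line[76:78].strip()
            if not element:
                name = line[12:16].strip()
                element = re.sub(r"[^A-Za-z].*", "", name)[:2]
                if len(element) == 2 and element[1].isupper():
                    element = element[0]
            cur_elements.append(element)
            cur_coords.append(xyz)
    if in_model:
        raise TrajectoryError(f"truncated frame {frame_no + 1}")
    flush()
    if not frames:
        raise TrajectoryError(f"{path}: no frames found")
    return Trajectory(frames)


def write_pdb(
    trajectory: Trajectory | Frame,
    path: str | Path,
    elements: list[str] | MolecularTopology,
) -> None:
    if isinstance(trajectory, Frame):
        trajectory = Trajectory([trajectory])
    if isinstance(elements, MolecularTopology):
        elements = list(elements.elements)
    out = []
    for k, frame in enumerate(trajectory, start=1):
        if frame.box is not None:
            a, b, c = frame.box
            out.append(
                f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1"
            )
        out.append(f"MODEL     {k:4d}")
        for i, (e, (x, y, z)) in enumerate(zip(elements, frame.coordinates), 1):
            name = e.capitalize()
            out.append(
                f"ATOM  {i:5d} {name:<4s} MOL A   1    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{e.capitalize():>2s}"
            )
        out.append("ENDMDL")
    out.append("END")
    Path(path).write_text("\n".join(out) + "\n")


def frame_schedule(total_time_ns: float, write_interval_ps: float) -> int:
    """Number of trajectory frames for a run of ``total_time_ns`` sampled
    every ``write_interval_ps`` (must divide the total exactly).

    7 ns written every 4 ps gives 1750 frames.
    """
    if total_time_ns <= 0 or write_interval_ps <= 0:
        raise TrajectoryError("total time and write interval must be positive")
    ratio = total_time_ns * 1000.0 / write_interval_ps
    n = round(ratio)
    if abs(ratio - n) > 1e-9 * max(1.0, abs(ratio)):
        raise TrajectoryError(
            f"write interval {write_interval_ps} ps does not divide "
            f"{total_time_ns} ns"
        )
    return int(n)
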