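"""Coordinate I/O, bead-role mapping and periodic-geometry primitives.

Units are fixed package-wide: lengths in nm, times in ps, energies in
kJ/mol.  Only orthorhombic boxes are supported; triclinic input is a hard
error everywhere.

A :class:`Frame` stores one time point of a coarse-grained system as flat
numpy arrays (one entry per bead) rather than per-bead objects, which keeps
selections and distance computations vectorised.  A trajectory is simply a
list of frames with a constant bead count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

logger = logging.getLogger("cgmem")

#: Semantic bead roles used by every analysis stage.
ROLES = (
    "phosphate",
    "lipid_tail",
    "lipid_other",
    "cation_head",
    "cation_tail",
    "anion",
    "water",
)


class GroParseError(ValueError):
    """Malformed GRO content; message names the offending line number."""


class TrajectoryStructureError(ValueError):
    """Frames of one trajectory disagree structurally (bead count)."""


class UnsupportedBoxError(ValueError):
    """Triclinic (non-orthorhombic) box encountered."""


@dataclass(frozen=True)
class SimulationBox:
    """Orthorhombic periodic box with edge lengths in nm."""

    Lx: float
    Ly: float
    Lz: float

    def __post_init__(self) -> None:
        if not (self.Lx > 0 and self.Ly > 0 and self.Lz > 0):
            raise ValueError(f"box edges must be positive, got {self}")

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.Lx, self.Ly, self.Lz], dtype=float)

    @property
    def volume(self) -> float:
        return self.Lx * self.Ly * self.Lz


@dataclass
class Frame:
    """Typed bead positions for one time point.

    Attributes
    ----------
    time : float
        Frame time in ps.
    box : SimulationBox
    molecule_ids : (N,) int array, 1-based residue/molecule numbers.
    residue_names, bead_names : (N,) string arrays.
    positions : (N, 3) float array, nm.
    """

    time: float
    box: SimulationBox
    molecule_ids: np.ndarray
    residue_names: np.ndarray
    bead_names: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.molecule_ids = np.asarray(self.molecule_ids, dtype=np.int64)
        self.residue_names = np.asarray(self.residue_names, dtype=object)
        self.bead_names = np.asarray(self.bead_names, dtype=object)
        self.positions = np.asarray(self.positions, dtype=float)
        n = len(self.molecule_ids)
        if self.positions.shape != (n, 3):
            raise ValueError(
                f"positions shape {self.positions.shape} != ({n}, 3)"
            )
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite bead position")
        if n and self.molecule_ids.min() < 1:
            raise ValueError("molecule_id must be >= 1")

    @property
    def n_beads(self) -> int:
        return len(self.molecule_ids)

    def wrapped(self) -> "Frame":
        """Return a copy with all positions wrapped into [0, L) per axis."""
        pos = np.mod(self.positions, self.box.lengths)
        return Frame(
            self.time,
            self.box,
            self.molecule_ids.copy(),
            self.residue_names.copy(),
            self.bead_names.copy(),
            pos,
        )


Trajectory = list  # list[Frame]; bead count constant across frames


# ---------------------------------------------------------------------------
# Role maps
# ---------------------------------------------------------------------------

@dataclass
class RoleMap:
    """Mapping (residue_name, bead_name) -> semantic role.

    Built from a YAML config with one section per role, each listing
    ``[residue_name, bead_name]`` pairs::

        phosphate:
          - [DPPC, PO4]
        lipid_tail:
          - [DPPC, C1A]
    """

    rules: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, role in self.rules.items():
            if role not in ROLES:
                raise ValueError(f"unknown role {role!r} for {key}")

    @classmethod
    def from_dict(cls, sections: Mapping[str, Iterable[Sequence[str]]]) -> "RoleMap":
        rules: dict = {}
        for role, pairs in sections.items():
            if role not in ROLES:
                raise ValueError(f"unknown role section {role!r}")
            for res, bead in pairs:
                key = (str(res), str(bead))
                if key in rules and rules[key] != role:
                    raise ValueError(
                        f"bead {key} mapped to both {rules[key]!r} and {role!r}"
                    )
                rules[key] = role
        return cls(rules)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RoleMap":
        with open(path) as fh:
            sections = yaml.safe_load(fh)
        return cls.from_dict(sections or {})

    def role_of(self, residue_name: str, bead_name: str) -> str | None:
        return self.rules.get((residue_name, bead_name))

    def mask(self, frame: Frame, role: str) -> np.ndarray:
        """Boolean mask of beads of `frame` carrying `role`."""
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}")
        out = np.zeros(frame.n_beads, dtype=bool)
        for i in range(frame.n_beads):
            out[i] = (
                self.rules.get((frame.residue_names[i], frame.bead_names[i]))
                == role
            )
        return out


def select(frame: Frame, role_map: RoleMap, role: str) -> dict:
    """Beads of one role grouped by molecule.

    Returns ``{molecule_id: index array}`` with indices into the frame's
    bead arrays.  A role with no matches yields an empty dict (logged, not
    an error).
    """
    mask = role_map.mask(frame, role)
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        logger.info("select: role %r matched no beads", role)
        return {}
    groups: dict = {}
    for i in idx:
        groups.setdefault(int(frame.molecule_ids[i]), []).append(int(i))
    return {m: np.array(v, dtype=np.intp) for m, v in groups.items()}


# ---------------------------------------------------------------------------
# Periodic geometry
# ---------------------------------------------------------------------------

def min_image_disp(a: np.ndarray, b: np.ndarray, box: SimulationBox) -> np.ndarray:
    """Minimum-image displacement b - a, component-wise in [-L/2, L/2).

    Sign convention: the vector points from `a` toward the nearest periodic
    image of `b`; at exactly half the box edge the negative representative
    -L/2 is returned (half-open convention).
    """
    L = box.lengths
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    return d - L * np.floor(d / L + 0.5)


def min_image_dist(a: np.ndarray, b: np.ndarray, box: SimulationBox) -> float:
    return float(np.linalg.norm(min_image_disp(a, b, box)))


def wrap_z(dz: np.ndarray | float, Lz: float) -> np.ndarray | float:
    """Wrap a z-offset into [-Lz/2, Lz/2)."""
    return dz - Lz * np.floor(np.asarray(dz, dtype=float) / Lz + 0.5)


# ---------------------------------------------------------------------------
# GRO reading / writing
# ---------------------------------------------------------------------------

def _parse_box_line(line: str, lineno: int) -> SimulationBox:
    try:
        vals = [float(tok) for tok in line.split()]
    except ValueError as exc:
        raise GroParseError(f"line {lineno}: malformed box line {line!r}") from exc
    if len(vals) == 3:
        return SimulationBox(*vals)
    if len(vals) == 9:
        # GRO triclinic order: xx yy zz xy xz yx yz zx zy
        if any(abs(v) > 1e-12 for v in vals[3:]):
            raise UnsupportedBoxError(
                f"line {lineno}: triclinic box not supported: {line.strip()!r}"
            )
        return SimulationBox(*vals[:3])
    raise GroParseError(f"line {lineno}: box line needs 3 or 9 numbers")


def _parse_atom_line(line: str, lineno: int):
    # Fixed columns: resid %5d, resname %-5s, atomname %5s, atomid %5d,
    # x y z %8.3f each; optional velocities tolerated and discarded.
    if len(line.rstrip("\n")) < 44:
        raise GroParseError(f"line {lineno}: atom line too short: {line!r}")
    try:
        resid = int(line[0:5])
        resname = line[5:10].strip()
        beadname = line[10:15].strip()
        x = float(line[20:28])
        y = float(line[28:36])
        z = float(line[36:44])
    except ValueError as exc:
        raise GroParseError(f"line {lineno}: malformed atom line: {line!r}") from exc
    return resid, resname, beadname, (x, y, z)


def read_gro(path: str | Path) -> list:
    """Read a (possibly multi-frame, concatenated) GRO file.

    Each block is: title line, atom count, fixed-column atom lines, box
    line.  Velocities, if present, are discarded.  Frame times are taken
    from a ``t=`` token on the title line when present, else the block
    index in ps.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.readlines()
    frames: list = []
    i = 0
    n_expected: int | None = None
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        title = lines[i]
        if i + 1 >= len(lines):
            raise GroParseError(f"line {i + 2}: truncated frame header")
        try:
            natoms = int(lines[i + 1])
        except ValueError as exc:
            raise GroParseError(
                f"line {i + 2}: expected atom count, got {lines[i + 1]!r}"
            ) from exc
        if i + 2 + natoms >= len(lines):
            raise GroParseError(f"frame at line {i + 1}: truncated atom block")
        resids, resnames, beadnames, coords = [], [], [], []
        for j in range(natoms):
            lineno = i + 3 + j
            resid, resname, beadname, xyz = _parse_atom_line(lines[i + 2 + j], lineno)
            resids.append(resid)
            resnames.append(resname)
            beadnames.append(beadname)
            coords.append(xyz)
        box = _parse_box_line(lines[i + 2 + natoms], i + 3 + natoms)
        time = float(len(frames))
        if "t=" in title:
            try:
                time = float(title.split("t=")[1].split()[0])
            except (ValueError, IndexError):
                pass
        frame = Frame(
            time,
            box,
            np.array(resids),
            np.array(resnames, dtype=object),
            np.array(beadnames, dtype=object),
            np.array(coords, dtype=float),
        )
        if n_expected is None:
            n_expected = frame.n_beads
        elif frame.n_beads != n_expected:
            raise TrajectoryStructureError(
                f"frame {len(frames)} has {frame.n_beads} beads, "
                f"expected {n_expected}"
            )
        frames.append(frame)
        i += 3 + natoms
    if not frames:
        raise GroParseError("no frames found")
    return frames


def write_gro(trajectory, path: str | Path, title: str = "cgmem") -> None:
    """Write frames as concatenated fixed-column GRO (3-decimal nm).

    Coordinates are rounded half-away-from-zero via printf ``%8.3f``;
    output is byte-stable for identical input.  Orthorhombic boxes only;
    an empty bead list is an error.
    """
    if isinstance(trajectory, Frame):
        trajectory = [trajectory]
    if not trajectory:
        raise ValueError("empty trajectory")
    lines: list[str] = []
    for frame in trajectory:
        if frame.n_beads == 0:
            raise ValueError("cannot write a frame with no beads")
        if not np.all(np.isfinite(frame.positions)):
            raise ValueError("non-finite position")
        lines.append(f"{title} t= {frame.time:.3f}\n")
        lines.append(f"{frame.n_beads:5d}\n")
        for i in range(frame.n_beads):
            resid = int(frame.molecule_ids[i]) % 100000
            atomid = (i + 1) % 100000
            x, y, z = frame.positions[i]
            lines.append(
                f"{resid:5d}{frame.residue_names[i]:<5.5s}"
                f"{frame.bead_names[i]:>5.5s}{atomid:5d}"
                f"{x:8.3f}{y:8.3f}{z:8.3f}\n"
            )
        b = frame.box
        lines.append(f"{b.Lx:10.5f}{b.Ly:10.5f}{b.Lz:10.5f}\n")
    with open(path, "w") as fh:
        fh.writelines(lines)
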