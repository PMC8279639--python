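"""Trajectory containers and plain-text I/O.

The package consumes position + velocity trajectories in extended-XYZ
format: one block per frame, first line the atom count, second line a
comment (an extxyz ``Properties=`` descriptor is honored when present),
then one line per atom with the element symbol, Cartesian positions in
Å and velocities in Å/fs. The timestep is always user-supplied — it is
metadata the file format does not carry reliably.

Masses are filled from the standard-atomic-weight table shipped with
MDAnalysis, keyed on the element symbol, and can be overridden with a
user table (useful for pseudo-atoms or isotopic substitution).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from MDAnalysis.guesser.tables import masses as _MDA_MASSES

__all__ = [
    "Trajectory",
    "AtomSelection",
    "element_masses",
    "read_extxyz",
    "write_extxyz",
    "read_mass_table",
    "write_matrix",
    "read_matrix",
]


@dataclass
class Trajectory:
    """A molecular-dynamics trajectory with velocities.

    Attributes
    ----------
    elements : list of str
        Element symbol per atom (length N).
    masses : ndarray, shape (N,)
        Atomic masses in amu; all strictly positive.
    positions : ndarray, shape (nframes, N, 3)
        Cartesian coordinates in Å.
    velocities : ndarray, shape (nframes, N, 3)
        Cartesian velocities in Å/fs.
    dt : float
        Timestep between consecutive frames, fs.
    """

    elements: list[str]
    masses: np.ndarray
    positions: np.ndarray
    velocities: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (nframes, N, 3)")
        if self.positions.shape != self.velocities.shape:
            raise ValueError(
                f"positions {self.positions.shape} and velocities "
                f"{self.velocities.shape} shapes differ"
            )
        if self.positions.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        n = self.positions.shape[1]
        if len(self.elements) != n:
            raise ValueError(f"{len(self.elements)} element labels for {n} atoms")
        if self.masses.shape != (n,):
            raise ValueError(f"masses shape {self.masses.shape} != ({n},)")
        if not np.all(self.masses > 0):
            raise ValueError("all masses must be positive")
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    @property
    def nframes(self) -> int:
        return self.positions.shape[0]

    @property
    def natoms(self) -> int:
        return self.positions.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Frame times in fs, starting at 0."""
        return np.arange(self.nframes) * self.dt


@dataclass(frozen=True)
class AtomSelection:
    """A named set of atom indices (0-based)."""

    indices: tuple[int, ...]
    label: str = ""

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.indices)
        if len(set(idx)) != len(idx):
            raise ValueError(f"selection {self.label!r}: duplicate indices")
        if idx and min(idx) < 0:
            raise ValueError(f"selection {self.label!r}: negative index")
        object.__setattr__(self, "indices", idx)

    def validate(self, natoms: int) -> None:
        if not self.indices:
            raise ValueError(f"selection {self.label!r} is empty")
        if max(self.indices) >= natoms:
            raise ValueError(
                f"selection {self.label!r}: index {max(self.indices)} out of "
                f"range for {natoms} atoms"
            )

    def __len__(self) -> int:
        return len(self.indices)


def element_masses(
    elements: Sequence[str],
    overrides: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Standard atomic weights (amu) for a list of element symbols.

    ``overrides`` wins over the built-in table; an element found in
    neither is a hard error. The lookup is pure: the same element list
    always yields the same mass vector.
    """
    overrides = dict(overrides or {})
    out = np.empty(len(elements), dtype=float)
    for i, el in enumerate(elements):
        if el in overrides:
            out[i] = float(overrides[el])
        elif el.capitalize() in _MDA_MASSES:
            out[i] = float(_MDA_MASSES[el.capitalize()])
        else:
            raise KeyError(
                f"unknown element {el!r} (atom {i}) and no mass override given"
            )
    return out


def read_mass_table(path: str | Path) -> dict[str, float]:
    """Read a plain-text mass override table: ``element mass`` per line.

    Blank lines and ``#`` comments are ignored.
    """
    table: dict[str, float] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'element mass', got {raw!r}")
        table[parts[0]] = float(parts[1])
    return table


_PROPERTIES_RE = re.compile(r"Properties=(\S+)", re.IGNORECASE)


def _parse_properties(comment: str) -> tuple[int, int, int] | None:
    """Column offsets (species, positions, velocities) from a Properties= string.

    Returns None when the comment carries no Properties descriptor.
    Velocity fields may be named ``vel``, ``velo`` or ``velocities``.
    """
    m = _PROPERTIES_RE.search(comment)
    if m is None:
        return None
    fields = m.group(1).split(":")
    col = 0
    species = pos = vel = None
    for name, _kind, width in zip(fields[0::3], fields[1::3], fields[2::3]):
        w = int(width)
        lname = name.lower()
        if lname == "species":
            species = col
        elif lname == "pos":
            pos = col
        elif lname in ("vel", "velo", "velocities"):
            vel = col
        col += w
    if species is None or pos is None:
        raise ValueError(f"Properties descriptor {m.group(1)!r} lacks species/pos")
    if vel is None:
        return (species, pos, -1)
    return (species, pos, vel)


def read_extxyz(
    path: str | Path,
    dt: float,
    mass_overrides: Mapping[str, float] | None = None,
) -> Trajectory:
    """Read an extended-XYZ trajectory with velocity columns.

    Every frame must have the same atom count and ordering, and every
    atom line must carry velocities (columns 5–7 by position, or per the
    frame's ``Properties=`` descriptor). ``dt`` is the timestep in fs.
    """
    lines = Path(path).read_text().splitlines()
    frames_pos: list[np.ndarray] = []
    frames_vel: list[np.ndarray] = []
    elements: list[str] | None = None
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        frame_no += 1
        try:
            nat = int(lines[i].split()[0])
        except ValueError as exc:
            raise ValueError(
                f"{path}: frame {frame_no}: expected atom count, got {lines[i]!r}"
            ) from exc
        if i + 1 + nat > len(lines):
            raise ValueError(f"{path}: frame {frame_no}: truncated block")
        comment = lines[i + 1]
        layout = _parse_properties(comment)
        if layout is not None and layout[2] == -1:
            raise ValueError(
                f"{path}: frame {frame_no}: Properties descriptor declares no "
                "velocity columns"
            )
        frame_elems: list[str] = []
        pos = np.empty((nat, 3))
        vel = np.empty((nat, 3))
        for a in range(nat):
            tokens = lines[i + 2 + a].split()
            if layout is None:
                if len(tokens) < 7:
                    raise ValueError(
                        f"{path}: frame {frame_no}, atom {a}: velocity columns "
                        f"missing ({len(tokens)} columns, need 7)"
                    )
                sp, pc, vc = 0, 1, 4
            else:
                sp, pc, vc = layout
                if len(tokens) < vc + 3:
                    raise ValueError(
                        f"{path}: frame {frame_no}, atom {a}: too few columns "
                        f"for declared Properties layout"
                    )
            frame_elems.append(tokens[sp])
            pos[a] = [float(x) for x in tokens[pc : pc + 3]]
            vel[a] = [float(x) for x in tokens[vc : vc + 3]]
        if elements is None:
            elements = frame_elems
        elif frame_elems != elements or nat != len(elements):
            raise ValueError(
                f"{path}: frame {frame_no}: atom count/ordering differs from "
                f"frame 1 ({nat} vs {len(elements)} atoms)"
            )
        frames_pos.append(pos)
        frames_vel.append(vel)
        i += 2 + nat
    if elements is None:
        raise ValueError(f"{path}: no frames found")
    masses = element_masses(elements, mass_overrides)
    return Trajectory(
        elements=elements,
        masses=masses,
        positions=np.stack(frames_pos),
        velocities=np.stack(frames_vel),
        dt=dt,
    )


def write_extxyz(traj: Trajectory, path: str | Path) -> None:
    """Write a Trajectory as extended XYZ with a Properties descriptor.

    Values are printed with 17 significant digits so a read/write round
    trip is bit-identical.
    """
    with open(path, "w") as fh:
        for f in range(traj.nframes):
            fh.write(f"{traj.natoms}\n")
            fh.write(
                "Properties=species:S:1:pos:R:3:vel:R:3 "
                f"Time={f * traj.dt:.17g}\n"
            )
            for a in range(traj.natoms):
                x, y, z = traj.positions[f, a]
                vx, vy, vz = traj.velocities[f, a]
                fh.write(
                    f"{traj.elements[a]} {x:.17g} {y:.17g} {z:.17g} "
                    f"{vx:.17g} {vy:.17g} {vz:.17g}\n"
                )


def write_matrix(
    values: np.ndarray,
    row_axis: np.ndarray,
    col_axis: np.ndarray,
    path: str | Path,
    row_label: str = "rows",
    col_label: str = "cols",
) -> None:
    """Export a 2-D grid with its axes as commented plain text.

    Two ``#`` header lines carry the axis values (with their labels and
    units); each subsequent line is one row of the grid. The paired
    :func:`read_matrix` round-trips the file bit-identically.
    """
    values = np.asarray(values, dtype=float)
    row_axis = np.asarray(row_axis, dtype=float)
    col_axis = np.asarray(col_axis, dtype=float)
    if values.ndim != 2:
        raise ValueError("values must be a 2-D grid")
    if values.shape != (row_axis.size, col_axis.size):
        raise ValueError(
            f"grid shape {values.shape} does not match axes "
            f"({row_axis.size}, {col_axis.size})"
        )
    with open(path, "w") as fh:
        fh.write(f"# {row_label}: " + " ".join(f"{v:.17g}" for v in row_axis) + "\n")
        fh.write(f"# {col_label}: " + " ".join(f"{v:.17g}" for v in col_axis) + "\n")
        for row in values:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def read_matrix(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray, str, str]:
    """Read a grid written by :func:`write_matrix`.

    Returns ``(values, row_axis, col_axis, row_label, col_label)``.
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 2 or not lines[0].startswith("#") or not lines[1].startswith("#"):
        raise ValueError(f"{path}: missing axis header lines")

    def _header(line: str) -> tuple[str, np.ndarray]:
        body = line[1:].strip()
        label, _, rest = body.partition(":")
        return label.strip(), np.array([float(x) for x in rest.split()])

    row_label, row_axis = _header(lines[0])
    col_label, col_axis = _header(lines[1])
    values = np.array(
        [[float(x) for x in ln.split()] for ln in lines[2:] if ln.strip()]
    )
    if values.shape != (row_axis.size, col_axis.size):
        raise ValueError(f"{path}: grid shape {values.shape} does not match axes")
    return values, row_axis, col_axis, row_label, col_label
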