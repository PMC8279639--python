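"""Solvation and proton-transfer diagnostics for droplet trajectories.

Structural observables used to characterize a photoacid–water–base
cluster: radial distribution functions g(r) with running coordination
numbers n(r) in a finite (non-periodic) droplet, interatomic distance
and dihedral-angle time series, and distance-based reactive-event
detection — covalent proton assignment, proton-hop events classified as
transient or permanent, and hydronium (three-coordinate oxygen)
lifetimes.

The droplet has no periodic box, so g(r) is normalized against a
user-supplied or automatically estimated reference density rho0; g(r)
decays below 1 near the droplet edge, which is a finite-size feature
and not a structural signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .trajectory_io import AtomSelection, Trajectory

__all__ = [
    "RDFResult",
    "PTEvent",
    "DihedralSeries",
    "HydroniumResult",
    "rdf",
    "coordination_number",
    "distance_series",
    "dihedral_series",
    "assign_protons",
    "detect_pt_events",
    "hydronium_series",
]


@dataclass
class RDFResult:
    """Radial distribution function and running coordination number.

    r holds bin centers (Å); n(r) is the average number of B neighbors
    of an A atom within r, exact (no binning model) because it is the
    cumulative pair count per A atom per frame; it is tabulated at the
    bin right-edges ``r_edges`` (the radius each cumulative count
    actually corresponds to).
    """

    r: np.ndarray
    g: np.ndarray
    n: np.ndarray
    rho0: float
    r_edges: np.ndarray | None = None


@dataclass
class PTEvent:
    """One proton-hop record.

    The hydrogen leaves heavy atom ``from_atom`` for ``to_atom`` at
    ``t_start`` (fs) and resides there until ``t_end`` (next
    reassignment or end of trajectory). ``kind`` is "permanent" when the
    residence lasts at least the permanence threshold, else "transient".
    """

    hydrogen: int
    from_atom: int
    to_atom: int
    t_start: float
    t_end: float
    kind: str

    def __post_init__(self) -> None:
        if self.t_start > self.t_end:
            raise ValueError("t_start must not exceed t_end")
        if self.from_atom == self.to_atom:
            raise ValueError("from_atom and to_atom must differ")


@dataclass
class DihedralSeries:
    """Unwrapped dihedral-angle time series in degrees.

    ``defined`` is False at frames where a collinear atom triple makes
    the angle undefined (value NaN there, never silently dropped).
    Unwrapping continues each angle minimally from the previous frame so
    a series oscillating about planarity reports means near 180° instead
    of jumping between +180° and −180°.
    """

    atoms: tuple[int, int, int, int]
    values: np.ndarray
    defined: np.ndarray


@dataclass
class HydroniumResult:
    """Per-frame hydronium flags and lifetimes.

    ``flags[f, k]`` is True when oxygen ``oxygen_indices[k]`` has exactly
    three covalently assigned hydrogens at frame f. ``lifetimes`` are the
    durations (fs) of maximal consecutive runs, ordered by start time;
    ``runs`` carries (oxygen index, start frame, run length in frames).
    """

    flags: np.ndarray
    oxygen_indices: tuple[int, ...]
    lifetimes: list[float]
    runs: list[tuple[int, int, int]]


def rdf(
    traj: Trajectory,
    selA: AtomSelection,
    selB: AtomSelection,
    r_max: float,
    bin_width: float,
    rho0: float | str = "auto",
) -> RDFResult:
    """A–B radial distribution function in a finite droplet.

    Distances between A and B atoms are histogrammed over all frames and
    normalized, per A atom and frame, by the ideal-gas shell count
    rho0·4πr²·dr. Self-pairs (the same atom index in both selections)
    are excluded. With ``rho0="auto"`` the reference density is the B
    count divided by the volume of the bounding sphere of B's
    time-averaged positions.
    """
    selA.validate(traj.natoms)
    selB.validate(traj.natoms)
    if r_max <= bin_width:
        raise ValueError("r_max must exceed bin_width")
    ia = np.array(selA.indices)
    ib = np.array(selB.indices)
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    edges = edges[edges <= r_max + 1e-12]
    if edges[-1] < r_max:
        edges = np.append(edges, r_max)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = np.zeros(centers.size)
    self_pairs = ia[:, None] == ib[None, :]
    for f in range(traj.nframes):
        d = cdist(traj.positions[f, ia], traj.positions[f, ib])
        d = d[~self_pairs]
        h, _ = np.histogram(d, bins=edges)
        counts += h
    if rho0 == "auto":
        mean_b = traj.positions[:, ib].mean(axis=0)
        radius = _bounding_sphere_radius(mean_b)
        if radius <= 0:
            raise ValueError("cannot auto-estimate rho0 from coincident B atoms")
        rho0_val = ib.size / (4.0 / 3.0 * np.pi * radius**3)
    else:
        rho0_val = float(rho0)
    per_a = counts / (traj.nframes * ia.size)
    shell = rho0_val * 4.0 * np.pi * centers**2 * np.diff(edges)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(shell > 0, per_a / shell, 0.0)
    n = np.cumsum(per_a)
    return RDFResult(r=centers, g=g, n=n, rho0=rho0_val, r_edges=edges[1:])


def _bounding_sphere_radius(points: np.ndarray, n_iter: int = 512) -> float:
    """Radius of the (approximately) minimal enclosing sphere.

    Badoiu–Clarkson iteration: repeatedly step the center toward the
    farthest point with shrinking step 1/(k+2); the radius error decays
    as O(1/k). Using the centroid directly as center would inflate the
    radius by the centroid's own sampling offset for isotropic clouds.
    """
    center = points.mean(axis=0)
    for k in range(n_iter):
        d = np.linalg.norm(points - center, axis=1)
        i = int(np.argmax(d))
        center = center + (points[i] - center) / (k + 2.0)
    return float(np.linalg.norm(points - center, axis=1).max())


def coordination_number(rdfres: RDFResult, r_cut: float) -> float:
    """Average neighbor count within r_cut, interpolated on n(r)."""
    abscissa = rdfres.r_edges if rdfres.r_edges is not None else rdfres.r
    if not 0.0 <= r_cut <= abscissa[-1] + 1e-12:
        raise ValueError(
            f"r_cut = {r_cut:g} Å outside the tabulated range "
            f"[0, {abscissa[-1]:g}] Å"
        )
    return float(np.interp(r_cut, abscissa, rdfres.n, left=0.0))


def distance_series(traj: Trajectory, i: int, j: int) -> np.ndarray:
    """Euclidean i–j distance per frame, Å."""
    if i == j:
        raise ValueError("distance requires two distinct atoms")
    return np.linalg.norm(traj.positions[:, i] - traj.positions[:, j], axis=1)


def dihedral_series(
    traj: Trajectory,
    i: int,
    j: int,
    k: int,
    l: int,
    collinear_tol: float = 1e-8,
) -> DihedralSeries:
    """Signed IUPAC dihedral i–j–k–l per frame, degrees, unwrapped.

    Planar cis is 0°, planar trans ±180°. Frames with a collinear triple
    are flagged undefined (NaN) rather than dropped. Unwrapping applies
    minimal-jump continuation per contiguous defined segment.
    """
    if len({i, j, k, l}) != 4:
        raise ValueError("dihedral requires four distinct atoms")
    p = traj.positions
    a, b, c, d = p[:, i], p[:, j], p[:, k], p[:, l]
    b1, b2, b3 = b - a, c - b, d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    scale = max(float(np.abs(p).max()), 1.0)
    defined = (np.linalg.norm(n1, axis=1) > collinear_tol * scale**2) & (
        np.linalg.norm(n2, axis=1) > collinear_tol * scale**2
    )
    b2n = b2 / np.linalg.norm(b2, axis=1, keepdims=True)
    m1 = np.cross(n1, b2n)
    x = np.einsum("fi,fi->f", n1, n2)
    y = np.einsum("fi,fi->f", m1, n2)
    raw = -np.degrees(np.arctan2(y, x))
    values = np.full(traj.nframes, np.nan)
    # unwrap each contiguous defined segment independently
    f = 0
    while f < traj.nframes:
        if not defined[f]:
            f += 1
            continue
        g = f
        while g < traj.nframes and defined[g]:
            g += 1
        values[f:g] = np.unwrap(raw[f:g], period=360.0)
        f = g
    return DihedralSeries(atoms=(i, j, k, l), values=values, defined=defined)


def assign_protons(
    positions: np.ndarray,
    hydrogens: AtomSelection,
    heavy: AtomSelection,
    r_bond: float = 1.3,
) -> dict[int, tuple[int | None, float]]:
    """Covalent assignment of each hydrogen to its nearest heavy atom.

    ``positions`` is one frame (N, 3). Returns, per hydrogen index, the
    assigned heavy-atom index (or None when the nearest heavy atom is
    farther than ``r_bond``) and the distance. Ties go to the
    lowest-index heavy atom.
    """
    if not hydrogens.indices or not heavy.indices:
        raise ValueError("hydrogen and heavy selections must be non-empty")
    ih = np.array(hydrogens.indices)
    iheavy = np.array(sorted(heavy.indices))  # sorted => argmin ties pick lowest index
    d = cdist(positions[ih], positions[iheavy])
    nearest = np.argmin(d, axis=1)
    out: dict[int, tuple[int | None, float]] = {}
    for row, h in enumerate(ih):
        dist = float(d[row, nearest[row]])
        heavy_idx = int(iheavy[nearest[row]]) if dist <= r_bond else None
        out[int(h)] = (heavy_idx, dist)
    return out


def _assignment_matrix(
    traj: Trajectory,
    hydrogens: AtomSelection,
    heavy: AtomSelection,
    r_bond: float,
) -> np.ndarray:
    """Per-frame covalent assignment, (nframes, nH); −1 means unassigned."""
    hydrogens.validate(traj.natoms)
    heavy.validate(traj.natoms)
    ih = np.array(hydrogens.indices)
    iheavy = np.array(sorted(heavy.indices))
    out = np.empty((traj.nframes, ih.size), dtype=int)
    for f in range(traj.nframes):
        d = cdist(traj.positions[f, ih], traj.positions[f, iheavy])
        nearest = np.argmin(d, axis=1)
        dist = d[np.arange(ih.size), nearest]
        out[f] = np.where(dist <= r_bond, iheavy[nearest], -1)
    return out


def detect_pt_events(
    traj: Trajectory,
    hydrogens: AtomSelection,
    heavy: AtomSelection,
    r_bond: float = 1.3,
    t_permanent: float = 100.0,
) -> list[PTEvent]:
    """Detect proton-hop events from frame-by-frame covalent assignment.

    An event opens when a hydrogen's assigned heavy atom changes (both
    old and new assignments must be actual atoms); it closes at the next
    reassignment or at the end of the trajectory. A return to the donor
    the hydrogen just left closes the open event without opening a new
    one, so a brief round trip is a single transient event. An event is
    permanent when the hydrogen resides on the acceptor for at least
    ``t_permanent`` fs — whether the residence ends with the trajectory
    or with a further onward transfer — and transient otherwise. A loss
    of assignment (hydrogen farther than ``r_bond`` from every heavy
    atom) closes any open event and never opens one. Events are
    returned ordered by start time.
    """
    assign = _assignment_matrix(traj, hydrogens, heavy, r_bond)
    ih = list(hydrogens.indices)
    events: list[PTEvent] = []
    last_frame_t = (traj.nframes - 1) * traj.dt

    def _close(open_ev: dict, t_end: float) -> None:
        duration = t_end - open_ev["t_start"]
        events.append(
            PTEvent(
                hydrogen=open_ev["hydrogen"],
                from_atom=open_ev["from_atom"],
                to_atom=open_ev["to_atom"],
                t_start=open_ev["t_start"],
                t_end=t_end,
                kind="permanent" if duration >= t_permanent else "transient",
            )
        )

    for col, h in enumerate(ih):
        col_assign = assign[:, col]
        change_frames = np.nonzero(col_assign[1:] != col_assign[:-1])[0] + 1
        open_ev: dict | None = None
        for f in change_frames:
            prev, new = int(col_assign[f - 1]), int(col_assign[f])
            t = f * traj.dt
            if open_ev is not None:
                _close(open_ev, t)
                returning = new == open_ev["from_atom"]
                open_ev = None
                if returning:
                    continue
            if prev >= 0 and new >= 0:
                open_ev = {
                    "hydrogen": int(h),
                    "from_atom": prev,
                    "to_atom": new,
                    "t_start": t,
                }
        if open_ev is not None:
            _close(open_ev, last_frame_t)
    events.sort(key=lambda e: (e.t_start, e.hydrogen))
    return events


def hydronium_series(
    traj: Trajectory,
    oxygens: AtomSelection,
    hydrogens: AtomSelection,
    r_bond: float = 1.3,
) -> HydroniumResult:
    """Flag three-coordinate oxygens per frame and measure run lifetimes.

    An oxygen is a hydronium at a frame iff exactly three hydrogens are
    covalently assigned to it. Lifetimes are maximal consecutive runs of
    the flag times the timestep.
    """
    assign = _assignment_matrix(traj, hydrogens, oxygens, r_bond)
    io = tuple(sorted(oxygens.indices))
    flags = np.zeros((traj.nframes, len(io)), dtype=bool)
    for k, o in enumerate(io):
        flags[:, k] = (assign == o).sum(axis=1) == 3
    runs: list[tuple[int, int, int]] = []
    for k, o in enumerate(io):
        col = flags[:, k]
        f = 0
        while f < traj.nframes:
            if not col[f]:
                f += 1
                continue
            g = f
            while g < traj.nframes and col[g]:
                g += 1
            runs.append((o, f, g - f))
            f = g
    runs.sort(key=lambda r: (r[1], r[0]))
    lifetimes = [nrun * traj.dt for (_o, _f, nrun) in runs]
    return HydroniumResult(flags=flags, oxygen_indices=io, lifetimes=lifetimes, runs=runs)
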