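"""Synthetic trajectories with known ground truth.

Three generators cover the analysis surface of the package:

* :func:`make_harmonic` — a molecule whose atoms oscillate as a
  superposition of orthonormal mass-weighted displacement patterns with
  chosen frequencies, amplitudes, phases and (optional) amplitude
  damping. Because the mode vectors, frequencies and damping times are
  inputs, every stage of the mode-extraction and wavelet pipeline can be
  checked against closed-form expectations. Mode vectors are built in
  the orthogonal complement of the translation/rotation subspace at the
  reference geometry, so the synthesized motion carries no net linear or
  angular momentum.
* :func:`make_droplet` — uniform pseudo-atoms in a sphere, the
  ideal-gas null model for g(r).
* :func:`make_pt_script` — scripted proton hops between static heavy
  atoms, the ground truth for event detection.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._units import CM1_PER_CYCLE_FS
from .trajectory_io import AtomSelection, Trajectory

__all__ = [
    "HarmonicSpec",
    "PTScript",
    "internal_mode_basis",
    "make_harmonic",
    "bent_triatomic_spec",
    "linear_triatomic_spec",
    "demo_chromophore_spec",
    "make_droplet",
    "make_pt_script",
]


def _external_space(geometry: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Orthonormal mass-weighted basis of translations + rotations (3N, 5 or 6)."""
    n = geometry.shape[0]
    sqrt_m = np.sqrt(masses)
    com = (masses[:, None] * geometry).sum(0) / masses.sum()
    rc = geometry - com
    vecs = []
    for axis in np.eye(3):  # translations
        v = np.tile(axis, (n, 1)) * sqrt_m[:, None]
        vecs.append(v.ravel())
    for axis in np.eye(3):  # infinitesimal rotations
        v = np.cross(np.broadcast_to(axis, (n, 3)), rc) * sqrt_m[:, None]
        vecs.append(v.ravel())
    M = np.array(vecs).T  # (3N, 6)
    # orthonormalize and drop null directions (rotation about a linear axis)
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    keep = s > 1e-10 * s.max()
    return U[:, keep]


def internal_mode_basis(geometry: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the internal (vibrational) subspace, (3N, k).

    k = 3N − 6 for a nonlinear reference geometry, 3N − 5 for a
    collinear one. Deterministic for a given geometry and mass vector.
    """
    geometry = np.asarray(geometry, dtype=float)
    masses = np.asarray(masses, dtype=float)
    ext = _external_space(geometry, masses)
    dim = geometry.size
    # complement via full SVD of the external projector
    U, s, _ = np.linalg.svd(ext, full_matrices=True)
    rank = int((s > 1e-10).sum())
    basis = U[:, rank:]
    # deterministic sign convention
    for j in range(basis.shape[1]):
        k = int(np.argmax(np.abs(basis[:, j])))
        if basis[k, j] < 0:
            basis[:, j] = -basis[:, j]
    return basis


@dataclass
class HarmonicSpec:
    """Recipe for a synthetic harmonic molecular trajectory.

    mode_vectors are orthonormal mass-weighted displacement patterns
    (3N, k); amplitudes are in mass-weighted Å·√amu; dampings are
    amplitude 1/e times in fs (inf = undamped; band *power* then decays
    twice as fast). phases default to seed-generated uniform values.
    """

    geometry: np.ndarray  # (N, 3), Å
    masses: np.ndarray  # amu
    mode_vectors: np.ndarray  # (3N, k)
    frequencies: np.ndarray  # cm^-1
    amplitudes: np.ndarray
    dampings: np.ndarray | None = None  # fs
    phases: np.ndarray | None = None  # rad
    elements: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.geometry = np.asarray(self.geometry, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        self.mode_vectors = np.asarray(self.mode_vectors, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        n3 = self.geometry.size
        k = self.mode_vectors.shape[1]
        if self.mode_vectors.shape[0] != n3:
            raise ValueError("mode_vectors rows must equal 3N")
        gram = self.mode_vectors.T @ self.mode_vectors
        if np.abs(gram - np.eye(k)).max() > 1e-8:
            raise ValueError("mode_vectors must be orthonormal")
        if np.any(self.frequencies <= 0):
            raise ValueError("frequencies must be positive")
        if self.frequencies.shape != (k,) or self.amplitudes.shape != (k,):
            raise ValueError("frequencies/amplitudes must have one entry per mode")
        kmax = internal_mode_basis(self.geometry, self.masses).shape[1]
        if k > kmax:
            raise ValueError(f"{k} modes exceed the {kmax} internal degrees of freedom")
        if self.dampings is None:
            self.dampings = np.full(k, math.inf)
        else:
            self.dampings = np.asarray(self.dampings, dtype=float)
        if self.phases is None:
            rng = np.random.default_rng(self.seed)
            self.phases = rng.uniform(0.0, 2.0 * math.pi, size=k)
        else:
            self.phases = np.asarray(self.phases, dtype=float)
        if self.elements is None:
            self.elements = ["X"] * self.geometry.shape[0]


def make_harmonic(spec: HarmonicSpec, dt: float, nframes: int) -> Trajectory:
    """Synthesize a trajectory of superposed damped mode oscillations.

    The mass-weighted displacement is
    d(t) = Σ_k A_k L_k cos(2π ν_k t + φ_k) e^(−t/τ_k) and the velocity
    its exact time derivative, so positions and velocities are mutually
    consistent. No global translation or rotation is injected.
    """
    if nframes < 1:
        raise ValueError("nframes must be >= 1")
    nyq = CM1_PER_CYCLE_FS / (2.0 * dt)
    if np.any(spec.frequencies > nyq):
        raise ValueError(
            f"mode frequency {spec.frequencies.max():g} cm^-1 exceeds the "
            f"Nyquist frequency {nyq:g} cm^-1 for dt = {dt:g} fs"
        )
    t = np.arange(nframes) * dt  # (T,)
    omega = 2.0 * math.pi * spec.frequencies / CM1_PER_CYCLE_FS  # rad/fs
    with np.errstate(divide="ignore"):
        gamma = np.where(np.isinf(spec.dampings), 0.0, 1.0 / spec.dampings)
    phase = omega[None, :] * t[:, None] + spec.phases[None, :]  # (T, k)
    env = np.exp(-gamma[None, :] * t[:, None])
    c = spec.amplitudes[None, :] * np.cos(phase) * env  # (T, k)
    cdot = spec.amplitudes[None, :] * env * (
        -omega[None, :] * np.sin(phase) - gamma[None, :] * np.cos(phase)
    )
    d = c @ spec.mode_vectors.T  # mass-weighted displacement, (T, 3N)
    ddot = cdot @ spec.mode_vectors.T
    sqrt_m = np.sqrt(np.repeat(spec.masses, 3))
    positions = spec.geometry.ravel()[None, :] + d / sqrt_m
    velocities = ddot / sqrt_m
    n = spec.geometry.shape[0]
    return Trajectory(
        elements=list(spec.elements),
        masses=spec.masses.copy(),
        positions=positions.reshape(nframes, n, 3),
        velocities=velocities.reshape(nframes, n, 3),
        dt=dt,
    )


def bent_triatomic_spec(
    frequencies: tuple[float, float, float] = (300.0, 800.0, 1600.0),
    amplitude_scale: float = 1e-3,
    dampings: tuple[float, float, float] | None = None,
    seed: int = 0,
) -> HarmonicSpec:
    """Water-like bent triatomic exciting all 3 internal modes.

    Geometry is an O at the origin with two H at ~0.96 Å and a 104.5°
    angle; the three mode patterns are the orthonormal internal basis at
    that geometry with the given frequencies. Amplitudes are distinct
    (1, 0.8, 0.6 × ``amplitude_scale`` Å·√amu) so mode variances are
    non-degenerate.
    """
    theta = math.radians(104.5) / 2.0
    geometry = np.array(
        [
            [0.0, 0.0, 0.0],
            [0.9572 * math.sin(theta), 0.9572 * math.cos(theta), 0.0],
            [-0.9572 * math.sin(theta), 0.9572 * math.cos(theta), 0.0],
        ]
    )
    masses = np.array([15.999, 1.008, 1.008])
    basis = internal_mode_basis(geometry, masses)
    return HarmonicSpec(
        geometry=geometry,
        masses=masses,
        mode_vectors=basis,
        frequencies=np.array(frequencies, dtype=float),
        amplitudes=amplitude_scale * np.array([1.0, 0.8, 0.6]),
        dampings=None if dampings is None else np.array(dampings, dtype=float),
        elements=["O", "H", "H"],
        seed=seed,
    )


def linear_triatomic_spec(
    frequencies: tuple[float, float, float, float] = (480.0, 560.0, 1340.0, 2050.0),
    amplitude_scale: float = 1e-3,
    seed: int = 0,
) -> HarmonicSpec:
    """CO2-like collinear triatomic exciting all 4 internal modes.

    A collinear molecule has 3N − 5 = 4 internal degrees of freedom (two
    bends and two stretches); all four carry energy so that only the 5
    external (translation + 2 rotation) directions stay silent.
    """
    geometry = np.array([[-1.162, 0.0, 0.0], [0.0, 0.0, 0.0], [1.162, 0.0, 0.0]])
    masses = np.array([15.999, 12.011, 15.999])
    basis = internal_mode_basis(geometry, masses)
    return HarmonicSpec(
        geometry=geometry,
        masses=masses,
        mode_vectors=basis,
        frequencies=np.array(frequencies, dtype=float),
        amplitudes=amplitude_scale * np.array([1.0, 0.85, 0.7, 0.55]),
        elements=["O", "C", "O"],
        seed=seed,
    )


def demo_chromophore_spec(seed: int = 0) -> HarmonicSpec:
    """Bent triatomic with two transient low-frequency skeletal modes.

    The demo configuration places damped modes at 110 and 198 cm^-1
    (amplitude 1/e times of 1400 fs, i.e. band power decaying to 1/e in
    about 700 fs) plus an undamped high-frequency mode — a miniature
    stand-in for the wagging/breathing phenomenology the wavelet maps
    are designed to resolve. Documentation fixture; analyses treat these
    numbers as arbitrary inputs.
    """
    return bent_triatomic_spec(
        frequencies=(110.0, 198.0, 1600.0),
        amplitude_scale=1e-3,
        dampings=(1400.0, 1400.0, math.inf),
        seed=seed,
    )


def make_droplet(
    n_points: int,
    radius: float = 19.0,
    seed: int = 0,
) -> Trajectory:
    """Uniform pseudo-atom droplet: the ideal-gas null for g(r).

    Points are drawn uniformly in a sphere of the given radius (Å);
    single frame, unit masses, zero velocities. Deterministic per seed.
    """
    if n_points < 2:
        raise ValueError("need at least 2 points")
    rng = np.random.default_rng(seed)
    directions = rng.normal(size=(n_points, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    radii = radius * rng.uniform(size=n_points) ** (1.0 / 3.0)
    pos = directions * radii[:, None]
    return Trajectory(
        elements=["X"] * n_points,
        masses=np.ones(n_points),
        positions=pos[None],
        velocities=np.zeros((1, n_points, 3)),
        dt=1.0,
    )


@dataclass
class PTScript:
    """A scripted proton-hop trajectory with its selections.

    Heavy atoms come first in the atom order, hydrogens after;
    ``heavy`` and ``hydrogens`` are ready-made selections.
    """

    trajectory: Trajectory
    heavy: AtomSelection
    hydrogens: AtomSelection


def make_pt_script(
    heavy_positions: np.ndarray,
    hydrogen_home: list[int],
    events: list[tuple[int, int, int, float, float | None]],
    dt: float,
    nframes: int,
    bond_length: float = 1.0,
) -> PTScript:
    """Scripted donor→acceptor proton hops between static heavy atoms.

    ``heavy_positions`` is (nheavy, 3) in Å; ``hydrogen_home[h]`` is the
    heavy index each hydrogen starts bonded to. Each event is
    ``(hydrogen, from_heavy, to_heavy, t_hop_fs, return_after_fs)`` with
    ``return_after=None`` for a permanent hop. The hydrogen sits at
    ``bond_length`` from its current heavy atom along the donor–acceptor
    axis and switches sides at the scripted frame, so detection is exact
    to one frame. Overlapping scripts for one hydrogen are an error.
    """
    heavy_positions = np.asarray(heavy_positions, dtype=float)
    nheavy = heavy_positions.shape[0]
    nh = len(hydrogen_home)
    t_end = (nframes - 1) * dt
    by_h: dict[int, list[tuple[int, int, float, float | None]]] = {}
    for (h, frm, to, t_hop, ret) in events:
        if not 0 <= t_hop <= t_end:
            raise ValueError(f"hop time {t_hop} fs outside the trajectory window")
        if frm == to:
            raise ValueError("hop donor and acceptor must differ")
        by_h.setdefault(h, []).append((frm, to, t_hop, ret))
    for h, evs in by_h.items():
        evs.sort(key=lambda e: e[2])
        closing = [-math.inf] + [
            e[2] + (e[3] if e[3] is not None else math.inf) for e in evs
        ]
        for k, e in enumerate(evs):
            if e[2] < closing[k]:
                raise ValueError(f"overlapping scripts for hydrogen {h}")

    positions = np.empty((nframes, nheavy + nh, 3))
    positions[:, :nheavy] = heavy_positions[None]
    times = np.arange(nframes) * dt
    for h in range(nh):
        home = hydrogen_home[h]
        evs = by_h.get(h, [])
        if evs:
            axis_to = evs[0][1]
        else:  # no script: park off the heavy-atom plane
            centroid = heavy_positions.mean(0)
            d = heavy_positions[home] - centroid
            axis_to = None
            u0 = d / np.linalg.norm(d) if np.linalg.norm(d) > 1e-9 else np.array([0.0, 0.0, 1.0])
        current = home
        # per-frame occupancy from the script
        occupancy = np.full(nframes, home, dtype=int)
        for (frm, to, t_hop, ret) in evs:
            f_hop = int(round(t_hop / dt))
            occupancy[f_hop:] = to
            if ret is not None:
                f_back = int(round((t_hop + ret) / dt))
                if f_back < nframes:
                    occupancy[f_back:] = frm
        for f in range(nframes):
            occ = occupancy[f]
            if evs:
                # place along the axis of the nearest scripted partner pair
                partner = None
                for (frm, to, t_hop, ret) in evs:
                    if occ == frm:
                        partner = to
                    elif occ == to:
                        partner = frm
                if partner is None:
                    partner = (occ + 1) % nheavy
                d = heavy_positions[partner] - heavy_positions[occ]
                u = d / np.linalg.norm(d)
                positions[f, nheavy + h] = heavy_positions[occ] + bond_length * u
            else:
                positions[f, nheavy + h] = heavy_positions[occ] + bond_length * u0
    traj = Trajectory(
        elements=["O"] * nheavy + ["H"] * nh,
        masses=np.concatenate([np.full(nheavy, 15.999), np.full(nh, 1.008)]),
        positions=positions,
        velocities=np.zeros_like(positions),
        dt=dt,
    )
    return PTScript(
        trajectory=traj,
        heavy=AtomSelection(tuple(range(nheavy)), "heavy"),
        hydrogens=AtomSelection(tuple(range(nheavy, nheavy + nh)), "H"),
    )
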