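"""Generalized vibrational modes from the mass-weighted velocity covariance.

At any temperature, 3N collective coordinates whose velocities are
mutually uncorrelated can be defined by diagonalizing the time-averaged
covariance matrix of the mass-weighted atomic velocities,

    K_ij = < qdot_i(t) qdot_j(t) >_t ,   qdot_i = sqrt(m_i) v_i .

The eigenvectors (columns of an orthogonal matrix L) are the generalized
modes; unlike Hessian normal modes they require no quadratic potential
and are intrinsically anharmonic. Projecting mass-weighted velocities of
any trajectory — in particular an excited-state trajectory, under the
assumption that the ground-state mode composition still holds near the
Franck–Condon region — onto L gives per-mode velocity signals

    Qdot(t) = L^T qdot(t)

whose Fourier (stationary) or wavelet (time-resolved) spectra carry the
vibrational frequencies.

Six generalized coordinates (five for a linear molecule) correspond to
overall translation and rotation; :func:`remove_global_motion` projects
those out of the velocities frame by frame before K is accumulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import get_window

from ._units import CM1_PER_CYCLE_FS
from .trajectory_io import Trajectory

__all__ = [
    "ModeBasis",
    "ModeVelocitySeries",
    "PowerSpectrum",
    "mass_weight",
    "remove_global_motion",
    "compute_K",
    "diagonalize",
    "project",
    "power_spectrum",
    "save_basis",
    "load_basis",
]


@dataclass
class ModeBasis:
    """Eigen-decomposition of the mass-weighted velocity covariance.

    Attributes
    ----------
    K : ndarray, (3N, 3N)
        Covariance of mass-weighted velocities, amu·Å²/fs².
    L : ndarray, (3N, 3N)
        Orthogonal matrix; column α is generalized mode α.
    eigenvalues : ndarray, (3N,)
        Velocity variances per mode, sorted descending.
    n_zero : int
        Number of near-zero modes (translations/rotations), i.e.
        eigenvalues below ``rel_tol`` times the largest.
    degenerate : ndarray of bool, (3N,)
        Marks members of the near-zero block, whose individual vectors
        are an arbitrary orthonormal spanning set.
    """

    K: np.ndarray
    L: np.ndarray
    eigenvalues: np.ndarray
    n_zero: int
    degenerate: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def size(self) -> int:
        return self.L.shape[0]


@dataclass
class ModeVelocitySeries:
    """Per-mode velocity signals Qdot(t), one column per generalized mode."""

    Qdot: np.ndarray  # (nframes, 3N)
    dt: float
    mode_labels: list[str] | None = None

    @property
    def nframes(self) -> int:
        return self.Qdot.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.nframes) * self.dt


@dataclass
class PowerSpectrum:
    """One-sided power spectrum on a wavenumber grid."""

    frequencies: np.ndarray  # cm^-1, strictly increasing
    power: np.ndarray  # arbitrary units, >= 0

    def peak_frequency(self) -> float:
        """Frequency of the global maximum, cm^-1."""
        return float(self.frequencies[int(np.argmax(self.power))])


def mass_weight(traj: Trajectory) -> np.ndarray:
    """Mass-weighted velocity matrix, one row per frame.

    Row f holds sqrt(m_i)·v_i(f) flattened atom-major (x, y, z per
    atom), so the squared row norm is twice the frame's kinetic energy.
    """
    sqrt_m = np.sqrt(traj.masses)[None, :, None]
    return (traj.velocities * sqrt_m).reshape(traj.nframes, -1)


def _rotation_generators(pos_com: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Mass-weighted infinitesimal-rotation vectors about x, y, z (3, 3N)."""
    n = pos_com.shape[0]
    gens = np.empty((3, n, 3))
    for k, axis in enumerate(np.eye(3)):
        gens[k] = np.cross(np.broadcast_to(axis, (n, 3)), pos_com)
    return (gens * np.sqrt(masses)[None, :, None]).reshape(3, -1)


def remove_global_motion(
    traj: Trajectory,
    inertia_rel_tol: float = 1e-10,
) -> Trajectory:
    """Project overall translation and rigid rotation out of the velocities.

    Per frame, the center-of-mass velocity is subtracted and the rigid
    rotation ω×r is removed, with ω obtained from the instantaneous
    inertia tensor I and angular momentum J as ω = I⁻¹J. The returned
    trajectory has total linear momentum and total angular momentum
    about the center of mass below numerical tolerance in every frame.

    Collinear configurations make I singular along the molecular axis;
    there the pseudo-inverse restricted to the well-defined axes is used
    and the dropped axis count is recorded on the returned trajectory as
    ``traj._dropped_rotation_axes`` (per-frame list).
    """
    if traj.natoms < 2:
        raise ValueError("global-motion removal needs at least 2 atoms")
    m = traj.masses
    mtot = m.sum()
    vel = traj.velocities.copy()
    dropped: list[int] = []
    for f in range(traj.nframes):
        r = traj.positions[f]
        v = vel[f]
        com = (m[:, None] * r).sum(0) / mtot
        vcom = (m[:, None] * v).sum(0) / mtot
        v = v - vcom
        rc = r - com
        # inertia tensor and angular momentum about the COM
        inertia = np.einsum("a,a,ij->ij", m, (rc**2).sum(1), np.eye(3)) - np.einsum(
            "a,ai,aj->ij", m, rc, rc
        )
        J = (m[:, None] * np.cross(rc, v)).sum(0)
        w, U = np.linalg.eigh(inertia)
        good = w > inertia_rel_tol * w.max()
        dropped.append(int((~good).sum()))
        winv = np.where(good, 1.0 / np.where(good, w, 1.0), 0.0)
        omega = U @ (winv * (U.T @ J))
        vel[f] = v - np.cross(omega, rc)
    out = Trajectory(
        elements=list(traj.elements),
        masses=traj.masses.copy(),
        positions=traj.positions.copy(),
        velocities=vel,
        dt=traj.dt,
    )
    out._dropped_rotation_axes = dropped  # type: ignore[attr-defined]
    return out


def compute_K(mwvel: np.ndarray, center: bool = True) -> np.ndarray:
    """Time-averaged covariance of the mass-weighted velocities.

    ``mwvel`` is (nframes, 3N). Velocities are mean-centered per
    coordinate by default (means are ≈0 after global-motion removal;
    centering makes K a true covariance). The result is exactly
    symmetric by construction.
    """
    mwvel = np.asarray(mwvel, dtype=float)
    if mwvel.ndim != 2 or mwvel.shape[0] < 2:
        raise ValueError("need a (nframes, 3N) matrix with nframes >= 2")
    x = mwvel - mwvel.mean(0) if center else mwvel
    K = (x.T @ x) / x.shape[0]
    return 0.5 * (K + K.T)


def diagonalize(
    K: np.ndarray,
    rel_tol: float = 1e-8,
    sym_tol: float = 1e-8,
) -> ModeBasis:
    """Eigen-decompose K into a deterministic generalized-mode basis.

    Eigenvalues are sorted descending. Each eigenvector's sign is fixed
    so its largest-magnitude component is positive (first such component
    on ties), making the output deterministic. ``n_zero`` counts
    eigenvalues below ``rel_tol`` × the largest; vectors in that block
    span the translation/rotation subspace but are individually
    arbitrary, and are flagged ``degenerate``.
    """
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("K must be square")
    scale = max(np.abs(K).max(), 1.0)
    if np.abs(K - K.T).max() > sym_tol * scale:
        raise ValueError("K is not symmetric within tolerance")
    w, V = np.linalg.eigh(0.5 * (K + K.T))
    order = np.argsort(w)[::-1]
    w = w[order]
    V = V[:, order]
    # deterministic sign: largest-|component| of each column positive
    for j in range(V.shape[1]):
        col = V[:, j]
        k = int(np.argmax(np.abs(col)))
        if col[k] < 0:
            V[:, j] = -col
    wmax = w.max() if w.size else 0.0
    near_zero = w < rel_tol * wmax if wmax > 0 else np.ones_like(w, dtype=bool)
    n_zero = int(near_zero.sum())
    return ModeBasis(K=K, L=V, eigenvalues=w, n_zero=n_zero, degenerate=near_zero)


def project(basis: ModeBasis, mwvel: np.ndarray, dt: float = 1.0) -> ModeVelocitySeries:
    """Project mass-weighted velocities onto the generalized modes.

    Computes Qdot(f) = Lᵀ·qdot(f) per frame. The basis may come from a
    ground-state trajectory while ``mwvel`` comes from an excited-state
    one: near the Franck–Condon region the ground-state mode composition
    is assumed to still hold. The transform is orthogonal, so per-frame
    Euclidean norms are preserved.
    """
    mwvel = np.atleast_2d(np.asarray(mwvel, dtype=float))
    if mwvel.shape[1] != basis.size:
        raise ValueError(
            f"velocity dimension {mwvel.shape[1]} does not match basis size "
            f"{basis.size}"
        )
    return ModeVelocitySeries(Qdot=mwvel @ basis.L, dt=dt)


def save_basis(basis: ModeBasis, path) -> None:
    """Export a mode basis as plain text (eigenvalues + L row-major).

    Header lines record the basis size and sort order; values are
    printed with 17 significant digits so :func:`load_basis` round-trips
    bit-identically. K is not stored (it is reconstructible as
    L·diag(λ)·Lᵀ).
    """
    n = basis.size
    with open(path, "w") as fh:
        fh.write(f"# genmodes mode basis  size={n}  sort=descending  n_zero={basis.n_zero}\n")
        fh.write("# eigenvalues (amu*Angstrom^2/fs^2):\n")
        fh.write(" ".join(f"{v:.17g}" for v in basis.eigenvalues) + "\n")
        fh.write("# L row-major (columns are modes):\n")
        for row in basis.L:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def load_basis(path) -> ModeBasis:
    """Read a mode basis written by :func:`save_basis`."""
    with open(path) as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    header = lines[0]
    if "genmodes mode basis" not in header:
        raise ValueError(f"{path}: not a genmodes basis file")
    fields = dict(tok.split("=") for tok in header.split() if "=" in tok)
    n = int(fields["size"])
    n_zero = int(fields.get("n_zero", 0))
    body = [ln for ln in lines[1:] if not ln.startswith("#")]
    eigenvalues = np.array([float(x) for x in body[0].split()])
    L = np.array([[float(x) for x in ln.split()] for ln in body[1 : 1 + n]])
    if L.shape != (n, n) or eigenvalues.size != n:
        raise ValueError(f"{path}: inconsistent basis dimensions")
    K = L @ np.diag(eigenvalues) @ L.T
    wmax = eigenvalues.max() if eigenvalues.size else 0.0
    degenerate = eigenvalues < 1e-8 * wmax if wmax > 0 else np.ones(n, dtype=bool)
    return ModeBasis(K=K, L=L, eigenvalues=eigenvalues, n_zero=n_zero, degenerate=degenerate)


def power_spectrum(
    series: np.ndarray,
    dt: float,
    window: str = "hann",
    zero_pad: int = 4,
) -> PowerSpectrum:
    """Stationary power spectrum of one mode-velocity signal.

    The periodogram of the windowed signal — equivalent, up to the
    window, to Fourier transforming the velocity autocorrelation
    (Wiener–Khinchin). The signal is mean-centered, windowed (Hann by
    default) and zero-padded by ``zero_pad``× before the FFT; the
    frequency axis is returned in cm^-1.
    """
    x = np.asarray(series, dtype=float).ravel()
    n = x.size
    if n < 32:
        raise ValueError(f"signal too short for a spectrum ({n} < 32 frames)")
    if zero_pad < 1:
        raise ValueError("zero_pad must be >= 1")
    win = get_window(window, n)
    if n < win.size:
        raise ValueError("series shorter than window")
    xw = (x - x.mean()) * win
    nfft = int(n * zero_pad)
    spec = np.fft.rfft(xw, n=nfft)
    power = np.abs(spec) ** 2
    freq_cm1 = np.fft.rfftfreq(nfft, d=dt) * CM1_PER_CYCLE_FS
    return PowerSpectrum(frequencies=freq_cm1, power=power)
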