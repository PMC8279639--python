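import numpy as np
import pytest

import genmodes as g


@pytest.fixture(scope="session")
def bent_traj():
    """Bent triatomic, all 3 internal modes excited, 20 ps at 0.5 fs."""
    spec = g.bent_triatomic_spec(seed=11)
    return spec, g.make_harmonic(spec, dt=0.5, nframes=40000)


@pytest.fixture(scope="session")
def bent_basis(bent_traj):
    spec, traj = bent_traj
    clean = g.remove_global_motion(traj)
    mw = g.mass_weight(clean)
    basis = g.diagonalize(g.compute_K(mw))
    return spec, clean, mw, basis


def make_static_trajectory(positions, masses=None, elements=None, dt=1.0, nframes=1):
    """Single geometry repeated over frames, zero velocities."""
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    pos = np.repeat(positions[None], nframes, axis=0)
    return g.Trajectory(
        elements=elements or ["X"] * n,
        masses=np.ones(n) if masses is None else np.asarray(masses, dtype=float),
        positions=pos,
        velocities=np.zeros_like(pos),
        dt=dt,
    )


def dihedral_geometry(phi_deg):
    """Four atoms whose i-j-k-l dihedral equals phi_deg by construction."""
    phi = np.radians(phi_deg)
    return np.stack(
        [
            np.array([-0.5, 1.0, 0.0]),
            np.zeros(3),
            np.array([1.5, 0.0, 0.0]),
            np.array([1.5, 0.0, 0.0]) + np.array([0.5, np.cos(phi), np.sin(phi)]),
        ]
    )
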