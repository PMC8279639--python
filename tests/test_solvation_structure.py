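import numpy as np
import pytest
from MDAnalysis.lib.distances import calc_dihedrals

import genmodes as g
from conftest import dihedral_geometry, make_static_trajectory


def sel(*idx, label=""):
    return g.AtomSelection(tuple(idx), label)


class TestRdf:
    def test_fixed_pair_single_bin(self):
        pos = np.zeros((5, 2, 3))
        pos[:, 1, 0] = 2.65
        traj = g.Trajectory(
            elements=["O", "O"], masses=np.ones(2), positions=pos,
            velocities=np.zeros_like(pos), dt=1.0,
        )
        res = g.rdf(traj, sel(0), sel(1), r_max=4.0, bin_width=0.1, rho0=0.03)
        nonzero = np.nonzero(res.g)[0]
        assert len(nonzero) == 1
        lo, hi = res.r[nonzero[0]] - 0.05, res.r[nonzero[0]] + 0.05
        assert lo <= 2.65 <= hi
        assert g.coordination_number(res, 3.5) == pytest.approx(1.0)

    def test_exact_neighbor_count_no_sampling_error(self):
        # k fixed neighbors inside the cutoff -> n(r) == k exactly
        k = 4
        pos = np.zeros((3, k + 1, 3))
        for j in range(k):
            pos[:, j + 1] = 1.5 + 0.3 * j, 0.0, 0.0
        traj = g.Trajectory(
            elements=["X"] * (k + 1), masses=np.ones(k + 1), positions=pos,
            velocities=np.zeros_like(pos), dt=1.0,
        )
        res = g.rdf(traj, sel(0), sel(*range(1, k + 1)), r_max=5.0, bin_width=0.1, rho0=1.0)
        assert g.coordination_number(res, 4.0) == k

    def test_ideal_gas_null_inner_bins(self):
        # fixed interior probe atoms against many independent droplet frames;
        # rho0 matched to the auto estimate from a single droplet frame
        npts, nframes, radius, nprobe = 4000, 50, 19.0, 20
        probes = g.make_droplet(nprobe, 6.0, seed=5).positions[0]
        frames = [
            np.vstack([probes, g.make_droplet(npts, radius, seed=1000 + f).positions[0]])
            for f in range(nframes)
        ]
        pos = np.stack(frames)
        n = nprobe + npts
        traj = g.Trajectory(
            elements=["X"] * n, masses=np.ones(n), positions=pos,
            velocities=np.zeros_like(pos), dt=1.0,
        )
        selA = sel(*range(nprobe))
        selB = sel(*range(nprobe, n))
        single = g.Trajectory(
            elements=["X"] * n, masses=np.ones(n), positions=pos[:1],
            velocities=np.zeros((1, n, 3)), dt=1.0,
        )
        auto = g.rdf(single, selA, selB, 9.5, 0.25, rho0="auto").rho0
        assert auto == pytest.approx(npts / (4 / 3 * np.pi * radius**3), rel=0.02)
        res = g.rdf(traj, selA, selB, r_max=9.5, bin_width=0.25, rho0=auto)
        inner = (res.r >= 3.5) & (res.r <= 9.25)
        assert (res.r[1:] > res.r[:-1]).all()
        assert np.abs(res.g[inner] - 1.0).max() < 0.05

    def test_poisson_coordination_matches_ideal(self):
        npts, radius, r_cut = 4000, 19.0, 5.0
        counts = []
        for s in range(40):
            d = g.make_droplet(npts, radius, seed=s)
            p = d.positions[0].copy()
            p[0] = 0.0
            t = make_static_trajectory(p)
            res = g.rdf(t, sel(0), sel(*range(1, npts)), r_max=6.0, bin_width=0.2,
                        rho0=1.0)
            counts.append(g.coordination_number(res, r_cut))
        rho = npts / (4.0 / 3.0 * np.pi * radius**3)
        ideal = rho * 4.0 / 3.0 * np.pi * r_cut**3
        assert np.mean(counts) == pytest.approx(ideal, rel=0.05)

    def test_running_integral_monotone(self):
        d = g.make_droplet(500, 10.0, seed=3)
        res = g.rdf(d, sel(0, 1, 2), sel(*range(3, 500)), 8.0, 0.2, "auto")
        assert np.all(np.diff(res.n) >= 0)
        assert np.all(res.g >= 0)

    def test_contracts(self):
        d = g.make_droplet(10, 5.0, seed=0)
        with pytest.raises(ValueError):
            g.rdf(d, g.AtomSelection((), "empty"), sel(1), 3.0, 0.1)
        with pytest.raises(ValueError, match="r_max"):
            g.rdf(d, sel(0), sel(1), 0.05, 0.1)
        res = g.rdf(d, sel(0), sel(*range(1, 10)), 3.0, 0.1, rho0=1.0)
        with pytest.raises(ValueError, match="r_cut"):
            g.coordination_number(res, 9.0)


class TestDistanceSeries:
    def test_static_pair(self):
        pos = np.zeros((4, 2, 3))
        pos[:, 1, 2] = 1.78
        t = g.Trajectory(elements=["O", "O"], masses=np.ones(2), positions=pos,
                         velocities=np.zeros_like(pos), dt=1.0)
        np.testing.assert_allclose(g.distance_series(t, 0, 1), 1.78)

    def test_linear_separation(self):
        pos = np.zeros((5, 2, 3))
        pos[:, 1, 0] = 1.0 + 0.1 * np.arange(5)
        t = g.Trajectory(elements=["O", "O"], masses=np.ones(2), positions=pos,
                         velocities=np.zeros_like(pos), dt=1.0)
        np.testing.assert_allclose(g.distance_series(t, 0, 1), 1.0 + 0.1 * np.arange(5))

    def test_same_atom_rejected(self):
        t = make_static_trajectory(np.zeros((2, 3)))
        with pytest.raises(ValueError):
            g.distance_series(t, 1, 1)


class TestDihedralSeries:
    @pytest.mark.parametrize("phi", [0.0, 60.0, -60.0, 120.0, 180.0])
    def test_constructed_angles_exact(self, phi):
        t = make_static_trajectory(dihedral_geometry(phi))
        val = g.dihedral_series(t, 0, 1, 2, 3).values[0]
        assert abs(abs(val) - abs(phi)) < 1e-6 if abs(phi) == 180 else abs(val - phi) < 1e-6

    def test_agrees_with_mdanalysis(self):
        rng = np.random.default_rng(7)
        pos = rng.normal(size=(100, 4, 3)) * 2.0
        t = g.Trajectory(elements=["C"] * 4, masses=np.ones(4), positions=pos,
                         velocities=np.zeros_like(pos), dt=1.0)
        ours = g.dihedral_series(t, 0, 1, 2, 3).values
        wrapped = (ours + 180.0) % 360.0 - 180.0
        ref = np.degrees(calc_dihedrals(pos[:, 0], pos[:, 1], pos[:, 2], pos[:, 3]))
        dev = np.abs(((wrapped - ref) + 180.0) % 360.0 - 180.0)
        assert dev.max() < 1e-3  # reference computes in float32

    def test_unwrap_across_trans(self):
        pos = np.stack([dihedral_geometry(179.0), dihedral_geometry(-179.0)])
        t = g.Trajectory(elements=["C"] * 4, masses=np.ones(4), positions=pos,
                         velocities=np.zeros_like(pos), dt=1.0)
        np.testing.assert_allclose(g.dihedral_series(t, 0, 1, 2, 3).values, [179.0, 181.0])

    def test_oscillation_about_planarity_reports_mean_near_183(self):
        angles = 183.0 + 6.0 * np.sin(np.linspace(0, 8 * np.pi, 200))
        pos = np.stack([dihedral_geometry(a) for a in angles])
        t = g.Trajectory(elements=["C"] * 4, masses=np.ones(4), positions=pos,
                         velocities=np.zeros_like(pos), dt=1.0)
        series = g.dihedral_series(t, 0, 1, 2, 3)
        assert np.all(np.abs(np.diff(series.values)) < 180.0)
        # continuous series about planarity: mean is 183 degrees mod 360
        assert series.values.mean() % 360.0 == pytest.approx(183.0, abs=0.5)

    def test_mirror_negates(self):
        geo = dihedral_geometry(60.0)
        mirrored = geo * np.array([1.0, 1.0, -1.0])
        t1 = make_static_trajectory(geo)
        t2 = make_static_trajectory(mirrored)
        v1 = g.dihedral_series(t1, 0, 1, 2, 3).values[0]
        v2 = g.dihedral_series(t2, 0, 1, 2, 3).values[0]
        assert v2 == pytest.approx(-v1, abs=1e-10)

    def test_collinear_flagged_not_dropped(self):
        geo = dihedral_geometry(60.0)
        collinear = geo.copy()
        collinear[0] = [-1.0, 0.0, 0.0]  # a on the b-c axis
        pos = np.stack([geo, collinear, geo])
        t = g.Trajectory(elements=["C"] * 4, masses=np.ones(4), positions=pos,
                         velocities=np.zeros_like(pos), dt=1.0)
        series = g.dihedral_series(t, 0, 1, 2, 3)
        assert series.defined.tolist() == [True, False, True]
        assert np.isnan(series.values[1])
        assert np.isfinite(series.values[[0, 2]]).all()

    def test_distinct_atoms_required(self):
        t = make_static_trajectory(dihedral_geometry(60.0))
        with pytest.raises(ValueError):
            g.dihedral_series(t, 0, 1, 2, 2)


class TestAssignProtons:
    def test_nearest_heavy_atom(self):
        pos = np.array([[0.0, 0, 0], [2.6, 0, 0], [1.0, 0, 0]])  # Oa, Ob, H
        out = g.assign_protons(pos, sel(2), sel(0, 1))  # 1.0 A vs 1.6 A
        assert out[2] == (0, pytest.approx(1.0))

    def test_tie_breaks_to_lowest_index(self):
        pos = np.array([[0.0, 0, 0], [2.0, 0, 0], [1.0, 0, 0]])
        out = g.assign_protons(pos, sel(2), sel(1, 0))  # selection order irrelevant
        assert out[2][0] == 0

    def test_beyond_cutoff_unassigned(self):
        pos = np.array([[0.0, 0, 0], [10.0, 0, 0], [2.5, 0, 0]])
        out = g.assign_protons(pos, sel(2), sel(0, 1), r_bond=1.3)
        assert out[2][0] is None


def brute_force_events(traj, hydrogens, heavy, r_bond=1.3, t_permanent=100.0):
    """Frame-by-frame oracle: plain-python nearest-atom bookkeeping."""
    events = []
    for h in hydrogens.indices:
        state = []  # per-frame assignment
        for f in range(traj.nframes):
            best, bd = None, None
            for o in sorted(heavy.indices):
                d = float(np.linalg.norm(traj.positions[f, h] - traj.positions[f, o]))
                if bd is None or d < bd - 1e-15:
                    best, bd = o, d
            state.append(best if bd <= r_bond else None)
        open_ev = None
        for f in range(1, traj.nframes):
            if state[f] == state[f - 1]:
                continue
            t = f * traj.dt
            if open_ev is not None:
                dur = t - open_ev[3]
                events.append((h, open_ev[1], open_ev[2], open_ev[3], t,
                               "permanent" if dur >= t_permanent else "transient"))
                came_from = open_ev[1]
                open_ev = None
                if state[f] == came_from:
                    continue
            if state[f - 1] is not None and state[f] is not None:
                open_ev = (h, state[f - 1], state[f], t)
        if open_ev is not None:
            t_end = (traj.nframes - 1) * traj.dt
            dur = t_end - open_ev[3]
            events.append((h, open_ev[1], open_ev[2], open_ev[3], t_end,
                           "permanent" if dur >= t_permanent else "transient"))
    events.sort(key=lambda e: (e[3], e[0]))
    return events


class TestDetectPtEvents:
    heavy_pos = np.array([[0.0, 0, 0], [2.8, 0, 0], [5.6, 0, 0]])

    def test_permanent_hop_at_800fs(self):
        s = g.make_pt_script(self.heavy_pos, [0], [(0, 0, 1, 800.0, None)],
                             dt=0.2, nframes=5001)
        events = g.detect_pt_events(s.trajectory, s.hydrogens, s.heavy)
        assert len(events) == 1
        e = events[0]
        assert (e.kind, e.from_atom, e.to_atom, e.t_start) == ("permanent", 0, 1, 800.0)

    def test_round_trip_is_one_transient(self):
        s = g.make_pt_script(self.heavy_pos, [0], [(0, 0, 1, 400.0, 20.0)],
                             dt=0.2, nframes=5001)
        events = g.detect_pt_events(s.trajectory, s.hydrogens, s.heavy)
        assert [e.kind for e in events] == ["transient"]
        assert events[0].t_end - events[0].t_start == pytest.approx(20.0)

    def test_three_brief_hops(self):
        script = [(0, 0, 1, 300.0, 12.0), (0, 0, 1, 620.0, 8.0), (0, 0, 1, 850.0, 15.0)]
        s = g.make_pt_script(self.heavy_pos, [0], script, dt=0.2, nframes=5001)
        events = g.detect_pt_events(s.trajectory, s.hydrogens, s.heavy)
        assert [e.kind for e in events] == ["transient"] * 3
        assert [e.t_start for e in events] == [300.0, 620.0, 850.0]

    def test_relay_through_water_to_acceptor(self):
        # hop to the bridge water at 800 fs, onward to the acceptor at 1 ps
        s = g.make_pt_script(self.heavy_pos, [0, 1],
                             [(0, 0, 1, 800.0, None), (1, 1, 2, 1000.0, None)],
                             dt=0.2, nframes=6001)
        events = g.detect_pt_events(s.trajectory, s.hydrogens, s.heavy)
        assert [(e.from_atom, e.to_atom, e.kind) for e in events] == [
            (0, 1, "permanent"), (1, 2, "permanent")]

    def test_no_reassignment_gives_no_events(self):
        s = g.make_pt_script(self.heavy_pos, [0], [], dt=0.2, nframes=100)
        assert g.detect_pt_events(s.trajectory, s.hydrogens, s.heavy) == []

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        nframes = 1500
        script = []
        t_free = 10.0
        for _ in range(4):
            t_hop = t_free + float(rng.uniform(5, 40))
            ret = float(rng.uniform(3, 150)) if rng.uniform() < 0.7 else None
            script.append((0, 0, 1, round(t_hop, 1), None if ret is None else round(ret, 1)))
            t_free = t_hop + (ret or (nframes * 0.2)) + 10.0
            if t_free > nframes * 0.2 - 50:
                break
        s = g.make_pt_script(self.heavy_pos, [0, 1], script, dt=0.2, nframes=nframes)
        got = g.detect_pt_events(s.trajectory, s.hydrogens, s.heavy)
        expected = brute_force_events(s.trajectory, s.hydrogens, s.heavy)
        assert [(e.hydrogen, e.from_atom, e.to_atom, e.t_start, e.t_end, e.kind)
                for e in got] == expected


class TestHydronium:
    def test_three_protons_for_500_frames(self):
        pos = np.zeros((500, 4, 3))
        pos[:, 1] = [1.0, 0, 0]
        pos[:, 2] = [0, 1.0, 0]
        pos[:, 3] = [0, 0, 1.0]
        t = g.Trajectory(elements=["O", "H", "H", "H"], masses=np.array([16.0, 1, 1, 1]),
                         positions=pos, velocities=np.zeros_like(pos), dt=0.2)
        res = g.hydronium_series(t, sel(0), sel(1, 2, 3))
        assert res.lifetimes == [100.0]
        assert res.flags.all()

    def test_water_never_flags(self):
        pos = np.zeros((50, 3, 3))
        pos[:, 1] = [1.0, 0, 0]
        pos[:, 2] = [0, 1.0, 0]
        t = g.Trajectory(elements=["O", "H", "H"], masses=np.array([16.0, 1, 1]),
                         positions=pos, velocities=np.zeros_like(pos), dt=0.2)
        res = g.hydronium_series(t, sel(0), sel(1, 2))
        assert res.lifetimes == [] and not res.flags.any()

    def test_disjoint_runs(self):
        nframes = 100
        pos = np.zeros((nframes, 4, 3))
        pos[:, 1] = [1.0, 0, 0]
        pos[:, 2] = [0, 1.0, 0]
        pos[:, 3] = [5.0, 0, 0]  # third H far away by default
        near = [0, 0, 1.0]
        for f in list(range(10, 20)) + list(range(50, 70)):
            pos[f, 3] = near
        t = g.Trajectory(elements=["O", "H", "H", "H"], masses=np.array([16.0, 1, 1, 1]),
                         positions=pos, velocities=np.zeros_like(pos), dt=0.2)
        res = g.hydronium_series(t, sel(0), sel(1, 2, 3))
        assert res.lifetimes == [pytest.approx(2.0), pytest.approx(4.0)]
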