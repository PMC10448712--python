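import numpy as np
import pytest

from gagcg import constants as c
from gagcg.potentials import TabulatedPotential
from gagcg.simulator import (SimulationConfig, SimulationUnstableError, System,
                             compute_forces, minimize, neighbor_pairs,
                             run_simulation)
from gagcg.topology import build_gag_chain, initial_conformation

KT = c.KB * 300.0


def two_bead_system(k=8038.0, r0=0.56):
    return System(
        masses=np.array([176.1, 203.2]),
        bond_index=np.array([[0, 1]]), bond_r0=np.array([r0]), bond_k=np.array([k]),
        angle_index=np.zeros((0, 3), dtype=int), angle_table=np.zeros(0, dtype=int),
        dihedral_index=np.zeros((0, 4), dtype=int), dihedral_table=np.zeros(0, dtype=int),
        tables=[], nonbonded_on=False)


class TestComputeForces:
    def test_two_bead_equilibrium_zero_force(self):
        sys_ = two_bead_system()
        e, f = compute_forces(sys_, np.array([[0.0, 0, 0], [0.56, 0, 0]]))
        assert e == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(f, 0.0, atol=1e-10)

    def test_finite_difference_oracle_random_16mer(self, ha16, ha16_system):
        pos = initial_conformation(ha16, 3)
        e, f = compute_forces(ha16_system, pos)
        fmax = np.abs(f).max()
        rng = np.random.default_rng(0)
        h = 1e-6
        for _ in range(30):
            i, d = rng.integers(0, ha16.n_beads), rng.integers(0, 3)
            pp, pm = pos.copy(), pos.copy()
            pp[i, d] += h
            pm[i, d] -= h
            fd = -(compute_forces(ha16_system, pp)[0]
                   - compute_forces(ha16_system, pm)[0]) / (2 * h)
            assert abs(fd - f[i, d]) / fmax < 1e-4

    def test_translation_invariance(self, ha16, ha16_system):
        pos = initial_conformation(ha16, 5)
        e1, f1 = compute_forces(ha16_system, pos)
        e2, f2 = compute_forces(ha16_system, pos + np.array([1.0, 2.0, 3.0]))
        assert e1 == pytest.approx(e2, rel=1e-12)
        np.testing.assert_allclose(f1, f2, atol=1e-8)

    def test_net_force_and_torque_vanish(self, ha16, ha16_system):
        pos = initial_conformation(ha16, 9)
        _, f = compute_forces(ha16_system, pos)
        np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(np.cross(pos, f).sum(axis=0), 0.0, atol=1e-8)

    def test_distant_chains_do_not_interact(self, ha16, known_pots):
        # compactly supported nonbonded terms: energy is unchanged when a
        # chain is alone vs. translated far from the origin
        from gagcg.simulator import system_from_topology

        sys_ = system_from_topology(ha16, known_pots, nonbonded_on=True)
        pos = initial_conformation(ha16, 2)
        e1, _ = compute_forces(sys_, pos)
        e2, _ = compute_forces(sys_, pos + 500.0)
        assert e1 == pytest.approx(e2, rel=1e-12)


class TestLangevin:
    def test_harmonic_bond_variance(self):
        sys_ = two_bead_system()
        cfg = SimulationConfig(dt_fs=2.0, n_steps=400_000, record_every=50, seed=42,
                               nonbonded_on=False)
        traj = run_simulation(sys_, cfg, positions=np.array([[0.0, 0, 0], [0.56, 0, 0]]))
        d = np.linalg.norm(np.diff(traj.equilibrated(0.1), axis=1), axis=-1).ravel()
        expect = KT / 8038.0
        blocks = np.array_split(d, 10)
        block_vars = [b.var() for b in blocks]
        se = np.std(block_vars, ddof=1) / np.sqrt(10)
        assert abs(d.var() - expect) < 3 * se + 0.05 * expect

    def test_kinetic_temperature(self):
        sys_ = two_bead_system()
        cfg = SimulationConfig(dt_fs=2.0, n_steps=300_000, record_every=50, seed=9,
                               nonbonded_on=False)
        traj = run_simulation(sys_, cfg, positions=np.array([[0.0, 0, 0], [0.56, 0, 0]]))
        t_kin = 2 * traj.mean_kinetic_energy / (6 * c.KB)
        assert t_kin == pytest.approx(300.0, rel=0.02)

    def test_determinism(self, ha16_system, ha16_minimized):
        cfg = SimulationConfig(dt_fs=5.0, n_steps=5_000, record_every=100, seed=3)
        t1 = run_simulation(ha16_system, cfg, positions=ha16_minimized)
        t2 = run_simulation(ha16_system, cfg, positions=ha16_minimized)
        assert np.array_equal(t1.frames, t2.frames)
        assert np.all(np.isfinite(t1.frames))
        assert t1.n_frames == 5_000 // 100 + 1

    def test_dihedral_dof_samples_boltzmann(self):
        # a single dihedral DOF: its equilibrium marginal is exp(-V/kT)/Z
        # (the torsion carries a flat configurational measure)
        from gagcg.geometry import dihedrals_deg

        nodes = np.arange(-180.0, 180.1, 7.2)
        v = 6.0 * (1 + np.cos(np.radians(nodes - 40.0))) / 2
        v[-1] = v[0]
        dih_table = TabulatedPotential.from_energy(nodes, v, periodic=True)
        ang_nodes = np.arange(0.0, 181.0, 1.0)
        ang_table = TabulatedPotential.from_energy(
            ang_nodes, 0.5 * 0.05 * (ang_nodes - 110.0) ** 2)
        sys_ = System(
            masses=np.full(4, 150.0),
            bond_index=np.array([[0, 1], [1, 2], [2, 3]]),
            bond_r0=np.full(3, 0.5), bond_k=np.full(3, 8038.0),
            angle_index=np.array([[0, 1, 2], [1, 2, 3]]),
            angle_table=np.array([0, 0]),
            dihedral_index=np.array([[0, 1, 2, 3]]), dihedral_table=np.array([1]),
            tables=[ang_table, dih_table], nonbonded_on=False)
        pos0 = np.array([[0.0, 0, 0], [0.5, 0, 0], [0.7, 0.45, 0], [0.7, 0.7, 0.4]])
        cfg = SimulationConfig(dt_fs=2.0, friction=0.5, n_steps=4_000_000,
                               record_every=100, seed=12, nonbonded_on=False)
        traj = run_simulation(sys_, cfg, positions=minimize(sys_, pos0))
        phi = dihedrals_deg(traj.equilibrated(0.1), np.array([[0, 1, 2, 3]])).ravel()
        hist, edges = np.histogram(phi, bins=np.arange(-180, 180.5, 7.2), density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        e, _ = dih_table(centers)
        expect = np.exp(-e / KT)
        expect /= np.sum(expect) * 7.2
        assert np.max(np.abs(hist - expect)) < 0.15 * expect.max()

    def test_instability_reported(self):
        sys_ = two_bead_system(k=8.0e5)
        cfg = SimulationConfig(dt_fs=500.0, n_steps=2_000, record_every=10, seed=1,
                               nonbonded_on=False)
        with pytest.raises(SimulationUnstableError) as exc:
            run_simulation(sys_, cfg, positions=np.array([[0.0, 0, 0], [0.9, 0, 0]]))
        assert exc.value.step > 0


class TestMinimize:
    def test_equilibrium_unchanged(self):
        sys_ = two_bead_system()
        pos = np.array([[0.0, 0, 0], [0.56, 0, 0]])
        out = minimize(sys_, pos)
        np.testing.assert_allclose(out, pos, atol=1e-6)

    def test_stretched_bond_relaxes(self):
        sys_ = two_bead_system()
        out = minimize(sys_, np.array([[0.0, 0, 0], [0.9, 0, 0]]))
        assert np.linalg.norm(out[1] - out[0]) == pytest.approx(0.56, abs=1e-3)

    def test_gradient_norm_at_exit(self, ha16, ha16_system):
        out = minimize(ha16_system, initial_conformation(ha16, 4), f_tol=1.0)
        _, f = compute_forces(ha16_system, out)
        assert np.abs(f).max() < 1.0

    def test_energy_decreases(self, ha16, ha16_system):
        pos = initial_conformation(ha16, 8)
        e0, _ = compute_forces(ha16_system, pos)
        e1, _ = compute_forces(ha16_system, minimize(ha16_system, pos))
        assert e1 <= e0


class TestNeighborPairs:
    def test_empty_beyond_cutoff(self):
        pos = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        assert len(neighbor_pairs(pos, 1.0)) == 0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(17)
        pos = rng.uniform(0, 5, size=(200, 3))
        cutoff = 1.1
        got = {tuple(p) for p in neighbor_pairs(pos, cutoff)}
        want = set()
        for i in range(200):
            for j in range(i + 1, 200):
                if np.linalg.norm(pos[i] - pos[j]) <= cutoff:
                    want.add((i, j))
        assert got == want

    def test_exclusions_removed(self):
        pos = np.array([[0.0, 0, 0], [0.5, 0, 0], [1.0, 0, 0]])
        pairs = neighbor_pairs(pos, 0.7, exclusions={(0, 1), (1, 2)})
        assert len(pairs) == 0

    def test_invalid_cutoff(self):
        with pytest.raises(ValueError):
            neighbor_pairs(np.zeros((2, 3)), 0.0)


class TestFreelyJointedLimit:
    def test_mean_squared_end_to_end(self):
        # bonds only: <Ree^2> = sum of squared bond lengths
        n = 24
        t = build_gag_chain("HA", n)
        sys_ = System(
            masses=t.masses,
            bond_index=t.bond_index,
            bond_r0=np.array([b[2] for b in t.bonds]),
            bond_k=np.array([b[3] for b in t.bonds]),
            angle_index=np.zeros((0, 3), dtype=int), angle_table=np.zeros(0, dtype=int),
            dihedral_index=np.zeros((0, 4), dtype=int),
            dihedral_table=np.zeros(0, dtype=int), tables=[], nonbonded_on=False)
        expect = float(np.sum(np.array([b[2] for b in t.bonds]) ** 2))
        vals = []
        for seed in (1, 2, 3):
            cfg = SimulationConfig(dt_fs=5.0, friction=0.2, n_steps=400_000,
                                   record_every=100, seed=seed, nonbonded_on=False)
            traj = run_simulation(sys_, cfg, positions=initial_conformation(t, seed))
            ree = traj.equilibrated(0.3)[:, -1] - traj.equilibrated(0.3)[:, 0]
            vals.append(np.mean(np.sum(ree ** 2, axis=-1)))
        mean = np.mean(vals)
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(mean - expect) < 3 * se + 0.15 * expect
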