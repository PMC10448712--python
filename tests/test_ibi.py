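import copy

import numpy as np
import pytest

from gagcg import constants as c
from gagcg import ibi
from gagcg.fixtures import make_known_bonded_potentials, make_target_pdfs_from_known_potentials
from gagcg.potentials import ANGLE_GRID, DIHEDRAL_GRID, TabulatedPotential
from gagcg.simulator import SimulationConfig
from gagcg.topology import build_gag_chain

KT = c.KB * 300.0


class TestHistograms:
    def test_identical_frames_single_bin(self, ha16):
        from gagcg.topology import initial_conformation

        frames = np.repeat(initial_conformation(ha16, 0)[None], 5, axis=0)
        centers, dens = ibi.histogram_dof(frames, ha16, "GXGX")
        occupied = dens > 0
        # every instance falls in some bin; total integrates to 1
        assert np.sum(dens) * 7.2 == pytest.approx(1.0, abs=1e-12)
        assert occupied.sum() <= ha16.dihedral_index("GXGX").shape[0]

    def test_dihedral_bin_count(self, ha16, ha16_short_traj):
        centers, dens = ibi.histogram_dof(ha16_short_traj, ha16, "XGXG")
        assert len(centers) == 50  # 360 / 7.2
        assert np.sum(dens) * 7.2 == pytest.approx(1.0, abs=1e-12)

    def test_angle_bins_and_normalization(self, ha16, ha16_short_traj):
        centers, dens = ibi.histogram_dof(ha16_short_traj, ha16, "GXG")
        assert len(centers) == 180
        assert np.sum(dens) * 1.0 == pytest.approx(1.0, abs=1e-12)

    def test_unknown_dof(self, ha16, ha16_short_traj):
        with pytest.raises(KeyError):
            ibi.histogram_dof(ha16_short_traj, ha16, "QQQQ")

    def test_empty_trajectory(self, ha16):
        with pytest.raises(ValueError):
            ibi.histogram_dof(np.zeros((0, 16, 3)), ha16, "GXG")


class TestConvergenceMetric:
    def test_identical_zero(self):
        p = np.random.default_rng(0).random(50)
        assert ibi.convergence_metric(p, p) == 0.0

    def test_offset_boxes(self):
        # single-bin boxes offset by one bin: the pointwise difference is
        # one box height at each of the two bins
        p = np.zeros(50)
        q = np.zeros(50)
        p[10] = q[11] = 1.0 / 7.2
        assert ibi.convergence_metric(p, q) == pytest.approx(1.0 / 7.2)

    def test_symmetry_and_grid_check(self):
        rng = np.random.default_rng(1)
        p, q = rng.random(50), rng.random(50)
        assert ibi.convergence_metric(p, q) == ibi.convergence_metric(q, p)
        with pytest.raises(ValueError):
            ibi.convergence_metric(p, q[:10])


class TestIBIInit:
    def test_gaussian_target_harmonic_v0(self):
        s = 8.0
        dens = np.exp(-((ANGLE_GRID - 100.0) / s) ** 2 / 2)
        dens /= np.trapezoid(dens, ANGLE_GRID)
        state = ibi.ibi_init({"GXG": np.interp(ibi.ANGLE_NODES, ANGLE_GRID, dens)},
                             alpha=1.0, T=300.0)
        v = state.potentials["GXG"]
        core = (v.grid > 75) & (v.grid < 125)
        coef = np.polyfit(v.grid[core], v.energy[core], 2)
        assert coef[0] == pytest.approx(KT / (2 * s * s), rel=1e-2)

    def test_linear_in_alpha(self):
        dens = np.exp(-((ANGLE_GRID - 100.0) / 10.0) ** 2 / 2)
        dens /= np.trapezoid(dens, ANGLE_GRID)
        target = np.interp(ibi.ANGLE_NODES, ANGLE_GRID, dens)
        v1 = ibi.ibi_init({"GXG": target}, alpha=1.0).potentials["GXG"].energy
        v05 = ibi.ibi_init({"GXG": target}, alpha=0.5).potentials["GXG"].energy
        np.testing.assert_allclose(v05, 0.5 * v1, atol=1e-9)

    def test_uniform_target_constant_v0(self):
        target = np.full(len(ibi.DIHEDRAL_NODES), 1.0 / 360.0)
        state = ibi.ibi_init({"GXGX": target}, alpha=0.7)
        np.testing.assert_allclose(state.potentials["GXGX"].energy, 0.0, atol=1e-10)

    def test_alpha_validation(self):
        target = np.full(len(ibi.DIHEDRAL_NODES), 1.0 / 360.0)
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                ibi.ibi_init({"GXGX": target}, alpha=bad)

    def test_unnormalized_target_rejected(self):
        with pytest.raises(ValueError):
            ibi.ibi_init({"GXGX": np.full(len(ibi.DIHEDRAL_NODES), 1.0)}, alpha=0.5)


class TestIBIUpdate:
    @staticmethod
    def _state():
        dens = np.exp(-((ANGLE_GRID - 110.0) / 9.0) ** 2 / 2)
        dens /= np.trapezoid(dens, ANGLE_GRID)
        target = np.interp(ibi.ANGLE_NODES, ANGLE_GRID, dens)
        ddens = np.full(len(ibi.DIHEDRAL_NODES), 1.0 / 360.0)
        return ibi.ibi_init({"GXG": target, "GXGX": ddens}, alpha=0.3)

    def test_fixed_point(self):
        state = self._state()
        before = {k: v.energy.copy() for k, v in state.potentials.items()}
        ibi.ibi_update(state, dict(state.target_fits))
        for name in before:
            np.testing.assert_allclose(state.potentials[name].energy, before[name],
                                       atol=1e-12)
        assert state.iteration == 1

    def test_oversampled_mode_raises_potential(self):
        state = self._state()
        target = np.asarray(state.target_fits["GXG"], dtype=float)
        mode = np.argmax(target)
        sharper = target ** 2
        sharper /= np.trapezoid(sharper, ibi.ANGLE_NODES)
        v_before = state.potentials["GXG"].energy.copy()
        ibi.ibi_update(state, {"GXG": sharper, "GXGX": state.target_fits["GXGX"]})
        v_after = state.potentials["GXG"].energy
        # relative to the (shifted) minimum, the mode is pushed up
        delta = (v_after - v_after.min()) - (v_before - v_before.min())
        assert delta[mode] > 0

    def test_penalty_entry_immutable(self):
        state = self._state()
        pen_before = state.potentials["XGG"]
        ibi.ibi_update(state, dict(state.target_fits))
        assert state.potentials["XGG"] is pen_before
        assert pen_before.energy.tobytes() == state.potentials["XGG"].energy.tobytes()

    def test_missing_measured_pdf(self):
        state = self._state()
        with pytest.raises(KeyError, match="GXGX"):
            ibi.ibi_update(state, {"GXG": state.target_fits["GXG"]})


class TestCouplingCandidates:
    def test_enumeration_includes_gxgg(self):
        t = build_gag_chain("HA", 7)  # a GXGXGXG window
        cands = ibi.enumerate_coupling_candidates(t)
        assert "GXGG" in cands and cands["GXGG"]["kind"] == "dihedral"
        assert (0, 1, 2, 4) in cands["GXGG"]["instances"]
        # both window families are present
        assert "GG" in cands and "XX" in cands

    def test_identical_samples_score_zero(self):
        rng = np.random.default_rng(0)
        samples = {"GXGG": rng.uniform(-180, 180, 1000),
                   "GGXG": rng.uniform(-180, 180, 1000)}
        ranked = ibi.rank_coupling_candidates(samples, copy.deepcopy(samples))
        assert all(score == 0.0 for _, score in ranked)

    def test_single_differing_candidate_ranked_first(self):
        rng = np.random.default_rng(1)
        base = {n: rng.uniform(-180, 180, 20_000) for n in ("GXGG", "GGXG", "XGGX")}
        model = {n: rng.uniform(-180, 180, 20_000) for n in base}
        base["GXGG"] = rng.normal(-60, 15, 20_000)  # only this one differs
        ranked = ibi.rank_coupling_candidates(base, model)
        assert ranked[0][0] == "GXGG"
        assert ranked[0][1] > 5 * ranked[1][1]

    def test_missing_candidate(self):
        with pytest.raises(KeyError):
            ibi.rank_coupling_candidates({"GXGG": np.zeros(10)}, {})


class TestInverseProblem:
    def test_recovers_known_potentials(self):
        """Well-posed inverse problem: consecutive-window DOFs, exact
        analytic chain-marginal targets.  Dihedral potentials (whose spline
        fits carry no family bias) must come back within 0.5 kT wherever
        the target density exceeds 1e-3 deg^-1; angle recovery is limited
        by the log-normal/Gumbel fit family and is gated at 1 kT."""
        t = build_gag_chain("HA", 16)
        pots = {k: v for k, v in make_known_bonded_potentials(0).items()
                if k != "GXGG"}
        targets = make_target_pdfs_from_known_potentials(pots)
        cfg = SimulationConfig(dt_fs=2.0, friction=5.0, n_steps=1_500_000,
                               record_every=125, seed=0, nonbonded_on=False)
        res = ibi.run_ibi(t, dict(targets), alpha=0.2, max_iter=40,
                          preset="fast", sim_config=cfg, seed=7,
                          include_coupling=False)
        assert res.converged
        for name, pot in res.state.potentials.items():
            if name == "XGG":
                continue
            grid = pot.grid
            e_fit, _ = pot(grid)
            e_true, _ = pots[name](grid)
            mask = np.asarray(targets[name](grid)) > 1e-3
            d = (e_fit - e_true)[mask]
            d -= np.median(d)
            gate = 0.5 * KT if len(name) == 4 else 1.0 * KT
            assert np.max(np.abs(d)) < gate, name
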