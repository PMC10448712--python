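"""Synthetic inputs with known ground truth.

Everything the test suite and the worked examples need is generated here:
stand-in fine-model parameters (the real geometry and glycosidic 2D
potentials are external configuration), correlated dihedral samples on the
torus, target PDFs from known potentials, and a grid-resolved
coupled-torus model demonstrating the dihedral-coupling machinery.

The synthetic 2D dihedral wells are sized so that the decoupled 1D
potentials peak near 40 kB T (so the 20 kB T cap genuinely bites) and the
torus mixtures carry substantial psi-phi correlation, mimicking the
numerical pathologies and couplings of real glycosidic linkages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constants as c
from .geometry import wrap_deg
from .mdbathe import DIH_NODES, FineModelParams, solve_cc_length
from .potentials import ANGLE_GRID, DIHEDRAL_GRID, TabulatedPotential
from .simulator import SimulationConfig, minimize, run_simulation, system_from_topology
from .topology import GAGTopology, initial_conformation

ANGLE_NODES = np.arange(0.0, 181.0, 1.0)
DIHEDRAL_NODES = DIH_NODES


# --------------------------------------------------------------------------
# Coupled dihedral samples on the torus
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TorusComponent:
    center: tuple[float, float]  # deg
    width: tuple[float, float]  # deg
    weight: float


@dataclass
class CoupledTorusSpec:
    """Mixture of correlated wrapped Gaussians on the (psi, phi) torus."""

    components: list[TorusComponent] = field(default_factory=lambda: [
        TorusComponent((-70.0, -50.0), (25.0, 25.0), 0.6),
        TorusComponent((50.0, 70.0), (25.0, 25.0), 0.4),
    ])
    rho: float = 0.6  # psi-phi correlation within each component
    n_samples: int = 200_000
    seed: int = 0

    def __post_init__(self):
        w = np.array([comp.weight for comp in self.components])
        if not np.isclose(w.sum(), 1.0):
            raise ValueError("component weights must sum to 1")
        if np.any([min(comp.width) <= 0 for comp in self.components]):
            raise ValueError("component widths must be positive")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [0, 1]")


def sample_coupled_dihedrals(spec: CoupledTorusSpec) -> tuple[np.ndarray, np.ndarray]:
    """Draw (psi, phi) samples from the torus mixture; seeded, wrapped."""
    rng = np.random.default_rng(spec.seed)
    weights = np.array([comp.weight for comp in spec.components])
    comp_idx = rng.choice(len(spec.components), size=spec.n_samples, p=weights)
    u = rng.standard_normal(spec.n_samples)
    v = rng.standard_normal(spec.n_samples)
    psi = np.empty(spec.n_samples)
    phi = np.empty(spec.n_samples)
    for i, comp in enumerate(spec.components):
        sel = comp_idx == i
        psi[sel] = comp.center[0] + comp.width[0] * u[sel]
        phi[sel] = comp.center[1] + comp.width[1] * (
            spec.rho * u[sel] + np.sqrt(max(1.0 - spec.rho ** 2, 0.0)) * v[sel])
    return wrap_deg(psi), wrap_deg(phi)


def torus_joint_density(spec: CoupledTorusSpec,
                        grid: np.ndarray = DIHEDRAL_GRID) -> np.ndarray:
    """Exact mixture density on the grid x grid torus (deg^-2), wrapped."""
    gx, gy = np.meshgrid(grid, grid, indexing="ij")
    dens = np.zeros_like(gx)
    rho = spec.rho
    det = 1.0 - rho * rho if rho < 1.0 else 1e-12
    for comp in spec.components:
        sx, sy = comp.width
        for kx in (-1, 0, 1):
            for ky in (-1, 0, 1):
                dx = (gx + 360.0 * kx - comp.center[0]) / sx
                dy = (gy + 360.0 * ky - comp.center[1]) / sy
                q = (dx * dx - 2 * rho * dx * dy + dy * dy) / det
                dens += comp.weight * np.exp(-0.5 * q) / (
                    2 * np.pi * sx * sy * np.sqrt(det))
    bw = grid[1] - grid[0]
    return dens / (dens.sum() * bw * bw)


# --------------------------------------------------------------------------
# Known bonded potentials and target PDFs
# --------------------------------------------------------------------------

def _well_table_angle(theta0: float, sd_deg: float, nodes=ANGLE_NODES) -> TabulatedPotential:
    k = c.KB * c.DEFAULT_TEMPERATURE / sd_deg ** 2  # kJ/mol per deg^2
    return TabulatedPotential.from_energy(nodes, 0.5 * k * (nodes - theta0) ** 2)


def _well_table_dihedral(centers, sds, weights, nodes=DIHEDRAL_NODES,
                         cap_kt: float = 25.0) -> TabulatedPotential:
    kt = c.KB * c.DEFAULT_TEMPERATURE
    p = np.zeros_like(nodes)
    for c0, s0, w0 in zip(centers, sds, weights):
        for k in (-1, 0, 1):
            p += w0 * np.exp(-0.5 * ((nodes + 360.0 * k - c0) / s0) ** 2) / s0
    v = -kt * np.log(np.maximum(p, p.max() * np.exp(-cap_kt)))
    v -= v.min()
    v[-1] = v[0]
    return TabulatedPotential.from_energy(nodes, v, periodic=True)


def make_known_bonded_potentials(seed: int = 0) -> dict[str, TabulatedPotential]:
    """A realistic 5-DOF bonded potential set with seeded well placement.

    Dihedral wells are capped at 6 kB T so inter-well barriers are crossed
    many times per nanosecond: recovery experiments need ergodic sampling
    of the relative well depths at the run lengths a desk-scale inverse
    problem uses.
    """
    rng = np.random.default_rng(seed)
    j = lambda lo, hi: float(rng.uniform(lo, hi))
    cap = 6.0
    return {
        "GXG": _well_table_angle(j(115.0, 125.0), j(8.0, 10.0)),
        "XGX": _well_table_angle(j(108.0, 118.0), j(7.0, 9.0)),
        "GXGX": _well_table_dihedral([j(-80.0, -50.0), j(150.0, 175.0)],
                                     [20.0, 25.0], [0.7, 0.3], cap_kt=cap),
        "XGXG": _well_table_dihedral([j(40.0, 75.0)], [22.0], [1.0], cap_kt=cap),
        "GXGG": _well_table_dihedral([j(-120.0, -80.0)], [35.0], [1.0], cap_kt=cap),
    }


@dataclass
class TargetPDF:
    """A target density on a standard histogram grid.

    ``exact`` marks analytic Boltzmann densities (numerically normalized)
    as opposed to sampled histograms.
    """

    grid: np.ndarray
    density: np.ndarray
    exact: bool

    def __call__(self, x):
        return np.interp(np.asarray(x, dtype=float), self.grid, self.density,
                         left=self.density[0], right=self.density[-1])


def make_target_pdfs_from_known_potentials(potentials: dict[str, TabulatedPotential],
                                           T: float = c.DEFAULT_TEMPERATURE,
                                           n_samples: int | None = None,
                                           seed: int = 0,
                                           jacobian: str = "chain") -> dict[str, TargetPDF]:
    """Boltzmann target densities of isolated DOFs.

    In a chain the internal-coordinate measure factorizes: a torsion's
    equilibrium marginal is exp(-V/kB T)/Z on a flat measure, while a
    bending angle carries the sin(theta) volume element.  The default
    ``jacobian='chain'`` therefore weights angle densities by sin(theta)
    (use ``'flat'`` for the bare Boltzmann factor).  With ``n_samples``
    set, a multinomial draw from the exact density is histogrammed instead
    (exact=False).
    """
    rng = np.random.default_rng(seed)
    kt = c.KB * T
    out = {}
    for name, pot in potentials.items():
        grid = DIHEDRAL_GRID if pot.periodic else ANGLE_GRID
        e, _ = pot(grid)
        p = np.exp(-(e - e.min()) / kt)
        if jacobian == "chain" and not pot.periodic:
            p *= np.sin(np.radians(grid))
        bw = grid[1] - grid[0]
        p /= p.sum() * bw
        if n_samples is None:
            out[name] = TargetPDF(grid, p, exact=True)
        else:
            counts = rng.multinomial(n_samples, p * bw / np.sum(p * bw))
            out[name] = TargetPDF(grid, counts / (n_samples * bw), exact=False)
    return out


def simulate_target_pdfs(topology: GAGTopology,
                         potentials: dict[str, TabulatedPotential],
                         config: SimulationConfig | None = None,
                         seed: int = 1234) -> dict[str, TargetPDF]:
    """Target PDFs measured from a simulation of a chain with known
    potentials (so chain Jacobian effects match the inverse problem)."""
    from .ibi import histogram_dof

    config = config or SimulationConfig(dt_fs=2.0, n_steps=2_000_000,
                                        record_every=100, seed=seed,
                                        nonbonded_on=False, friction=5.0)
    system = system_from_topology(topology, potentials, nonbonded_on=False)
    pos = minimize(system, initial_conformation(topology, seed))
    traj = run_simulation(system, config, positions=pos)
    frames = traj.equilibrated(0.2)
    out = {}
    for name in potentials:
        centers, dens = histogram_dof(frames, topology, name)
        out[name] = TargetPDF(centers, dens, exact=False)
    return out


def sample_fjc_conformation(bond_lengths: np.ndarray, seed: int) -> np.ndarray:
    """Exact equilibrium draw of a freely-jointed chain (nm): independent
    uniformly oriented steps of the given lengths."""
    rng = np.random.default_rng(seed)
    steps = rng.normal(size=(len(bond_lengths), 3))
    steps *= (np.asarray(bond_lengths, dtype=float)
              / np.linalg.norm(steps, axis=1))[:, None]
    pos = np.zeros((len(bond_lengths) + 1, 3))
    pos[1:] = np.cumsum(steps, axis=0)
    return pos


def sample_wlc_conformation(n_beads: int, l_b: float, kappa_kt: float,
                            seed: int) -> np.ndarray:
    """Exact equilibrium draw of a discrete worm-like chain (nm).

    Bend cosines follow p(u) ~ exp(kappa_kt * u) on [-1, 1] (the equilibrium
    of the bending energy kappa*(1 - cos gamma) with the sin(gamma) volume
    element), azimuths are uniform.  Used to start stiff-chain simulations
    at equilibrium: segment orientations of a stiff chain decorrelate only
    by rotational diffusion, far too slowly to forget a biased start.
    """
    rng = np.random.default_rng(seed)
    u01 = rng.random(n_beads - 2)
    u = 1.0 + np.log(u01 * (1 - np.exp(-2 * kappa_kt)) + np.exp(-2 * kappa_kt)) / kappa_kt
    phi = rng.uniform(0, 2 * np.pi, n_beads - 2)
    dirs = np.zeros((n_beads - 1, 3))
    dirs[0] = [1.0, 0.0, 0.0]
    for i in range(1, n_beads - 1):
        d = dirs[i - 1]
        a = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        e1 = np.cross(d, a)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(d, e1)
        s = np.sqrt(max(1.0 - u[i - 1] ** 2, 0.0))
        dirs[i] = u[i - 1] * d + s * (np.cos(phi[i - 1]) * e1 + np.sin(phi[i - 1]) * e2)
    pos = np.zeros((n_beads, 3))
    pos[1:] = np.cumsum(l_b * dirs, axis=0)
    return pos


# --------------------------------------------------------------------------
# Synthetic fine-model parameters (stand-in for external geometry tables)
# --------------------------------------------------------------------------

def make_coupled_well_grid(seed: int, rho: float = 0.5,
                           depth_kt: float = 40.0,
                           nodes: np.ndarray = DIHEDRAL_NODES) -> np.ndarray:
    """A periodic 2D glycosidic potential with correlated bimodal wells.

    Well depth is sized so the Boltzmann-inverted marginals reach about
    ``depth_kt`` kB T, exercising potential capping downstream.
    """
    rng = np.random.default_rng(seed)
    c1 = (rng.uniform(-120, -40), rng.uniform(-120, -40))
    c2 = (rng.uniform(30, 110), rng.uniform(30, 110))
    spec = CoupledTorusSpec(
        components=[TorusComponent(c1, (18.0, 18.0), 0.65),
                    TorusComponent(c2, (22.0, 22.0), 0.35)],
        rho=rho, n_samples=1, seed=seed)
    dens = torus_joint_density(spec, nodes)
    kt = c.KB * c.DEFAULT_TEMPERATURE
    v = -kt * np.log(np.maximum(dens, dens.max() * np.exp(-depth_kt)))
    v -= v.min()
    v[-1, :] = v[0, :]
    v[:, -1] = v[:, 0]
    return v


def make_synthetic_fine_params(gag_type: str, seed: int = 0,
                               rho: float = 0.5,
                               depth_kt: float = 40.0) -> FineModelParams:
    """Complete, loadable fine-model parameters with no external inputs.

    Geometry is solved so the glycosidic-oxygen spacings reproduce the
    0.56/0.49 nm coarse bonds; the glycosidic 2D wells are seeded and carry
    tunable psi-phi coupling.  Different seeds change the wells, never the
    geometry table.  ``depth_kt`` sizes the wells: the default 40 kB T
    exercises the 20 kB T capping path; ergodicity studies that must cross
    between wells at desk-scale run lengths should request shallower wells.
    """
    b_co = 0.143
    occ, cco, coc = 109.5, 109.5, 116.5
    tau_g, tau_x = 150.0, -150.0
    cc_g = solve_cc_length(c.R0_GX, b_co, occ, cco, tau_g)
    cc_x = solve_cc_length(c.R0_XG, b_co, occ, cco, tau_x)
    return FineModelParams(
        bond_lengths={"CO": b_co, "CC_G": cc_g, "CC_X": cc_x},
        angles_deg={"OCC": occ, "CCO": cco, "COC": coc},
        ring_dihedral_deg={"G": tau_g, "X": tau_x},
        V2d={"beta14": make_coupled_well_grid(seed * 2 + 1, rho, depth_kt),
             "beta13": make_coupled_well_grid(seed * 2 + 2, rho, depth_kt)},
    )


# --------------------------------------------------------------------------
# Grid-resolved coupled-torus model (coupling-efficacy demonstration)
# --------------------------------------------------------------------------

@dataclass
class TorusCouplingResult:
    ranking: list[tuple[str, float]]
    deviation_uncoupled: float  # deg^-2
    deviation_coupled: float  # deg^-2
    joint_reference: np.ndarray
    joint_uncoupled: np.ndarray
    joint_coupled: np.ndarray
    history: list[float]

    @property
    def reduction(self) -> float:
        return 1.0 - self.deviation_coupled / self.deviation_uncoupled


def coupled_torus_demo(spec: CoupledTorusSpec | None = None,
                       T: float = c.DEFAULT_TEMPERATURE,
                       alpha: float = 0.5, n_iter: int = 40,
                       n_rank_samples: int = 200_000,
                       seed: int = 0) -> TorusCouplingResult:
    """Re-introduce dihedral coupling on the torus via an extra IBI'd DOF.

    The reference is the correlated torus mixture.  A model matching only
    the psi and phi marginals (their product) misses the joint structure;
    candidate coupling coordinates (the wrapped sum and difference of psi
    and phi) are ranked by marginal discrepancy against the reference, and
    the top-ranked one receives a potential refined by the IBI update on an
    exactly grid-resolved Boltzmann model.  Returns the sup-norm deviations
    of the uncoupled and coupled joints from the reference.
    """
    from .ibi import rank_candidates

    spec = spec or CoupledTorusSpec(seed=seed)
    grid = DIHEDRAL_GRID
    nb = len(grid)
    bw = grid[1] - grid[0]
    kt = c.KB * T
    p_ref = torus_joint_density(spec, grid)
    ref_psi = p_ref.sum(axis=1) * bw
    ref_phi = p_ref.sum(axis=0) * bw
    q0 = np.outer(ref_psi, ref_phi)  # matches both 1D marginals exactly

    # rank candidate coupling coordinates from samples
    psi_r, phi_r = sample_coupled_dihedrals(
        CoupledTorusSpec(spec.components, spec.rho, n_rank_samples, spec.seed))
    rng = np.random.default_rng(seed + 1)
    psi_m = rng.choice(grid, p=ref_psi * bw / np.sum(ref_psi * bw), size=n_rank_samples) \
        + rng.uniform(-bw / 2, bw / 2, n_rank_samples)
    phi_m = rng.choice(grid, p=ref_phi * bw / np.sum(ref_phi * bw), size=n_rank_samples) \
        + rng.uniform(-bw / 2, bw / 2, n_rank_samples)
    cands_ref = {"diff": wrap_deg(psi_r - phi_r), "sum": wrap_deg(psi_r + phi_r)}
    cands_mod = {"diff": wrap_deg(psi_m - phi_m), "sum": wrap_deg(psi_m + phi_m)}
    ranking = rank_candidates(cands_ref, cands_mod,
                              kinds={"diff": "dihedral", "sum": "dihedral"})
    top = ranking[0][0]

    ii, jj = np.meshgrid(np.arange(nb), np.arange(nb), indexing="ij")
    cls = (ii - jj) % nb if top == "diff" else (ii + jj) % nb

    def class_marginal(joint):
        return np.bincount(cls.ravel(), weights=joint.ravel(), minlength=nb) * bw * bw / bw

    p_ref_c = class_marginal(p_ref)
    v_psi = -kt * np.log(np.maximum(ref_psi, 1e-12))
    v_phi = -kt * np.log(np.maximum(ref_phi, 1e-12))
    v_c = np.zeros(nb)
    history = []
    joint = q0
    for _ in range(n_iter):
        # exact Boltzmann joint of the current three potentials
        logq = -(v_psi[:, None] + v_phi[None, :] + v_c[cls]) / kt
        q = np.exp(logq - logq.max())
        joint = q / (q.sum() * bw * bw)
        m_psi = joint.sum(axis=1) * bw
        m_phi = joint.sum(axis=0) * bw
        m_c = class_marginal(joint)
        history.append(float(np.max(np.abs(m_c - p_ref_c))))
        v_psi = v_psi + alpha * kt * np.log(np.maximum(m_psi, 1e-12) / np.maximum(ref_psi, 1e-12))
        v_phi = v_phi + alpha * kt * np.log(np.maximum(m_phi, 1e-12) / np.maximum(ref_phi, 1e-12))
        v_c = v_c + alpha * kt * np.log(np.maximum(m_c, 1e-12) / np.maximum(p_ref_c, 1e-12))
    dev0 = float(np.max(np.abs(q0 - p_ref)))
    dev1 = float(np.max(np.abs(joint - p_ref)))
    return TorusCouplingResult(ranking, dev0, dev1, p_ref, q0, joint, history)
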