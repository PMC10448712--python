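"""Langevin dynamics of bead chains with midpoint virtual sites.

A :class:`System` is the engine-level description of one chain: masses,
harmonic bonds, tabulated angle/dihedral terms, XGG penalty triplets, and
virtual-site nonbonded parameters.  Both the 1BPS topology and the
fine-scale reference chain compile down to a System, so a single kernel
serves the whole package.  There are no periodic boundaries: a single chain
in open implicit solvent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from . import constants as c
from . import _kernels
from .potentials import ElectrostaticsParams, PenaltyParams, TabulatedPotential, debye_length
from .topology import GAGTopology


class SimulationUnstableError(RuntimeError):
    def __init__(self, step: int, max_disp: float):
        super().__init__(f"simulation unstable at step {step} "
                         f"(max per-step displacement {max_disp:.3g} nm)")
        self.step = step
        self.max_disp = max_disp


@dataclass
class System:
    masses: np.ndarray
    bond_index: np.ndarray  # (nb, 2)
    bond_r0: np.ndarray
    bond_k: np.ndarray
    angle_index: np.ndarray  # (na, 3)
    angle_table: np.ndarray  # (na,) into tables
    dihedral_index: np.ndarray  # (nd, 4)
    dihedral_table: np.ndarray
    tables: list[TabulatedPotential]
    penalty_index: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), dtype=int))
    penalty: PenaltyParams = PenaltyParams()
    site_parents: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), dtype=int))
    site_charge: np.ndarray = field(default_factory=lambda: np.zeros(0))
    site_sigma: np.ndarray = field(default_factory=lambda: np.zeros(0))
    electrostatics: ElectrostaticsParams = ElectrostaticsParams()
    eps_lj: float = c.EPS_LJ
    nonbonded_on: bool = True
    exclude_adjacent_sites: bool = False

    @property
    def n_beads(self) -> int:
        return len(self.masses)

    def packed(self) -> tuple:
        """Flatten tables and index arrays into kernel arguments."""
        nt = len(self.tables)
        tn = np.array([len(t.grid) for t in self.tables], dtype=np.int64)
        toff = np.zeros(nt, dtype=np.int64)
        if nt:
            toff[1:] = np.cumsum(tn)[:-1]
        tx0 = np.array([t.grid[0] for t in self.tables]) if nt else np.zeros(0)
        tdx = np.array([t.dx for t in self.tables]) if nt else np.zeros(0)
        tE = np.concatenate([t.energy for t in self.tables]) if nt else np.zeros(0)
        tS = np.concatenate([-t.force for t in self.tables]) if nt else np.zeros(0)
        tper = np.array([1 if t.periodic else 0 for t in self.tables], dtype=np.uint8)
        es = self.electrostatics
        lam = debye_length(es)
        return (
            np.ascontiguousarray(self.bond_index, dtype=np.int64),
            np.ascontiguousarray(self.bond_r0, dtype=np.float64),
            np.ascontiguousarray(self.bond_k, dtype=np.float64),
            np.ascontiguousarray(self.angle_index, dtype=np.int64).reshape(-1, 3),
            np.ascontiguousarray(self.angle_table, dtype=np.int64),
            np.ascontiguousarray(self.dihedral_index, dtype=np.int64).reshape(-1, 4),
            np.ascontiguousarray(self.dihedral_table, dtype=np.int64),
            np.ascontiguousarray(self.penalty_index, dtype=np.int64).reshape(-1, 3),
            float(self.penalty.a), float(self.penalty.b),
            tx0, tdx, tn, toff, tE, tS, tper,
            np.ascontiguousarray(self.site_parents, dtype=np.int64).reshape(-1, 2),
            np.ascontiguousarray(self.site_charge, dtype=np.float64),
            np.ascontiguousarray(self.site_sigma, dtype=np.float64),
            bool(self.nonbonded_on), bool(self.exclude_adjacent_sites),
            c.F_COULOMB / es.eps_r, 1.0 / lam, es.cutoff_factor * lam,
            float(self.eps_lj),
        )


def system_from_topology(topology: GAGTopology,
                         potentials: dict[str, TabulatedPotential],
                         electrostatics: ElectrostaticsParams | None = None,
                         penalty: PenaltyParams = PenaltyParams(),
                         nonbonded_on: bool = True,
                         include_coupling: bool = True) -> System:
    """Assemble the engine System for a 1BPS topology.

    ``potentials`` maps DOF names (GXG, XGX, GXGX, XGXG, GXGG, ...) to
    tabulated potentials; the XGG penalty is analytic and always present.
    ``include_coupling=False`` drops the GXGG term (the "without-coupling"
    variant of the model).
    """
    tables: list[TabulatedPotential] = []
    tid: dict[str, int] = {}

    def table_id(name: str) -> int:
        if name not in tid:
            if name not in potentials:
                raise KeyError(f"no tabulated potential supplied for DOF {name!r}")
            tid[name] = len(tables)
            tables.append(potentials[name])
        return tid[name]

    ang_rows, ang_t = [], []
    for i, j, k, name in topology.angles:
        ang_rows.append((i, j, k))
        ang_t.append(table_id(name))
    dih_rows, dih_t = [], []
    for i, j, k, l, name in topology.dihedrals:
        if name == "GXGG" and not include_coupling:
            continue
        dih_rows.append((i, j, k, l))
        dih_t.append(table_id(name))
    sites = topology.virtual_sites
    return System(
        masses=topology.masses,
        bond_index=topology.bond_index,
        bond_r0=np.array([b[2] for b in topology.bonds]),
        bond_k=np.array([b[3] for b in topology.bonds]),
        angle_index=np.array(ang_rows, dtype=int).reshape(-1, 3),
        angle_table=np.array(ang_t, dtype=int),
        dihedral_index=np.array(dih_rows, dtype=int).reshape(-1, 4),
        dihedral_table=np.array(dih_t, dtype=int),
        tables=tables,
        penalty_index=np.array(topology.penalty_angles, dtype=int).reshape(-1, 3) if include_coupling
        else np.zeros((0, 3), dtype=int),
        penalty=penalty,
        site_parents=np.array([s.parent_pair for s in sites], dtype=int).reshape(-1, 2),
        site_charge=np.array([s.charge for s in sites]),
        site_sigma=np.array([s.sigma for s in sites]),
        electrostatics=electrostatics or ElectrostaticsParams(),
        nonbonded_on=nonbonded_on,
        exclude_adjacent_sites=topology.exclude_adjacent_sites,
    )


@dataclass
class SimulationConfig:
    """Langevin-dynamics protocol (defaults follow the development protocol:
    300 K, friction 50 ps^-1)."""

    dt_fs: float = 1.0
    friction: float = c.DEFAULT_FRICTION  # ps^-1
    T: float = c.DEFAULT_TEMPERATURE  # K
    n_steps: int = 100_000
    record_every: int = 250  # steps
    seed: int = 0
    nonbonded_on: bool = True
    cutoff_factor: float = c.DEFAULT_CUTOFF_FACTOR
    exclude_adjacent_sites: bool = False

    def __post_init__(self):
        if self.dt_fs <= 0 or self.friction <= 0:
            raise ValueError("dt and friction must be positive")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")


@dataclass
class Trajectory:
    """Recorded bead positions (nm) with timestep metadata."""

    frames: np.ndarray  # (n_frames, n_beads, 3)
    times: np.ndarray  # ps
    seed: int
    config: SimulationConfig | None = None
    mean_kinetic_energy: float = float("nan")  # kJ/mol, over recorded steps

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def equilibrated(self, discard_fraction: float = 0.2) -> np.ndarray:
        """Frames after discarding the initial ``discard_fraction``."""
        start = int(np.floor(self.n_frames * discard_fraction))
        return self.frames[start:]


def compute_forces(system: System, positions: np.ndarray) -> tuple[float, np.ndarray]:
    """Total potential energy (kJ/mol) and per-bead forces (kJ/mol/nm)."""
    pos = np.ascontiguousarray(positions, dtype=np.float64)
    if pos.shape != (system.n_beads, 3):
        raise ValueError(f"positions shape {pos.shape} != ({system.n_beads}, 3)")
    f = np.zeros_like(pos)
    energy = _kernels._forces(pos, f, *system.packed())
    if not np.isfinite(energy) or not np.all(np.isfinite(f)):
        bad = np.flatnonzero(~np.all(np.isfinite(f), axis=1))
        raise FloatingPointError(
            f"non-finite energy/force (beads {bad[:4].tolist()}); overlapping sites?")
    return energy, f


def run_simulation(system: System, config: SimulationConfig,
                   positions: np.ndarray | None = None,
                   topology: GAGTopology | None = None) -> Trajectory:
    """Langevin dynamics; bit-reproducible for a fixed seed.

    If ``positions`` is omitted, a seeded initial conformation is built from
    ``topology`` and energy-minimized first.
    """
    if positions is None:
        if topology is None:
            raise ValueError("provide positions or a topology to start from")
        from .topology import initial_conformation
        positions = minimize(system, initial_conformation(topology, config.seed))
    pos = np.ascontiguousarray(positions, dtype=np.float64)
    system = replace(system, nonbonded_on=config.nonbonded_on and system.nonbonded_on,
                     electrostatics=replace(system.electrostatics,
                                            T=config.T, cutoff_factor=config.cutoff_factor))
    dt_ps = config.dt_fs * 1e-3
    n_frames = config.n_steps // config.record_every + 1
    frames = np.zeros((n_frames, system.n_beads, 3))
    kin_out = np.zeros(1)
    status, max_pen, max_disp, n_rec = _kernels._integrate(
        pos, np.ascontiguousarray(system.masses, dtype=np.float64),
        dt_ps, config.friction, c.KB * config.T,
        config.n_steps, config.record_every, config.seed % (2 ** 31),
        *system.packed(), frames, kin_out)
    if status != -1:
        raise SimulationUnstableError(status, max_disp)
    times = np.arange(n_frames) * config.record_every * dt_ps
    traj = Trajectory(frames[:n_rec], times[:n_rec], config.seed, config,
                      mean_kinetic_energy=float(kin_out[0]))
    traj.max_penalty_angle = float(max_pen)  # rad, over every step
    return traj


def minimize(system: System, positions: np.ndarray,
             f_tol: float = 1.0, max_iter: int = 50_000) -> np.ndarray:
    """Steepest-descent energy minimization with adaptive step size.

    Terminates when the maximum force component drops below ``f_tol``
    (kJ/mol/nm) or after ``max_iter`` iterations; the energy never increases
    between accepted iterations.
    """
    pos = np.array(positions, dtype=np.float64)
    e, f = compute_forces(system, pos)
    if not np.isfinite(e):
        raise FloatingPointError("non-finite initial energy")
    step = 0.01  # nm against the largest force component
    for _ in range(max_iter):
        fmax = np.abs(f).max()
        if fmax < f_tol:
            break
        trial = pos + step * f / fmax
        try:
            e_t, f_t = compute_forces(system, trial)
        except FloatingPointError:
            step *= 0.5
            continue
        if e_t < e:
            pos, e, f = trial, e_t, f_t
            step = min(step * 1.2, 0.05)
        else:
            step *= 0.5
            if step < 1e-10:
                break
    return pos


def neighbor_pairs(positions: np.ndarray, cutoff: float,
                   exclusions: set[tuple[int, int]] | None = None) -> np.ndarray:
    """All (i, j), i < j, within ``cutoff``; identical to a brute-force scan."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    pos = np.asarray(positions, dtype=float)
    pairs = cKDTree(pos).query_pairs(cutoff, output_type="ndarray")
    if len(pairs):
        pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]
    if exclusions:
        excl = {(min(i, j), max(i, j)) for i, j in exclusions}
        keep = [n for n, (i, j) in enumerate(pairs) if (i, j) not in excl]
        pairs = pairs[keep] if keep else np.zeros((0, 2), dtype=int)
    return pairs.reshape(-1, 2)
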