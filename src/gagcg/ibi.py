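"""Iterative Boltzmann inversion of the 1BPS bonded potentials.

The update rule is

    V_{I+1}(phi) = V_I(phi) + alpha kB T ln( P_I(phi) / P_target(phi) )

applied per degree of freedom to analytic fits of the sampled and target
distributions (log-normal/Gumbel mixtures for bending angles, periodic
quadratic splines for dihedrals), starting from
V_0(phi) = -alpha kB T ln P_target(phi).  The XGG penalty term is part of
the model but is never updated: its role is to forbid near-collinear
triplets, not to match a distribution.  Nonbonded interactions are switched
off throughout IBI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import constants as c
from . import geometry
from .potentials import (ANGLE_GRID, DIHEDRAL_GRID, AngleFitParams, FitError,
                         PeriodicSplineDensity, TabulatedPotential,
                         angle_mixture_pdf, boltzmann_invert, fit_angle_pdf,
                         fit_dihedral_spline)
from .simulator import SimulationConfig, System, Trajectory, minimize, run_simulation, system_from_topology
from .topology import GAGTopology, initial_conformation

log = logging.getLogger(__name__)

ANGLE_NODES = np.arange(0.0, 180.0 + 0.5 * c.ANGLE_BIN_DEG, c.ANGLE_BIN_DEG)
DIHEDRAL_NODES = np.arange(-180.0, 180.0 + 0.5 * c.DIHEDRAL_BIN_DEG, c.DIHEDRAL_BIN_DEG)


class IBIDivergenceError(RuntimeError):
    def __init__(self, history):
        super().__init__("IBI metric increased for 5 consecutive iterations")
        self.history = history


def dof_kind(dof_name: str) -> str:
    return "dihedral" if len(dof_name) == 4 else "angle"


def histogram_dof(trajectory, topology: GAGTopology, dof_name: str):
    """Normalized density of one DOF over a trajectory.

    1-degree bins on (0, 180] for angles, 7.2-degree bins on (-180, 180]
    for dihedrals; returns (bin_centers, density in deg^-1).
    """
    frames = trajectory.frames if isinstance(trajectory, Trajectory) else np.asarray(trajectory)
    if len(frames) == 0:
        raise ValueError("empty trajectory")
    samples = dof_samples(frames, topology, dof_name)
    return histogram_series(samples, dof_kind(dof_name) if dof_name != "XGG" else "angle")


def histogram_series(samples: np.ndarray, kind: str):
    samples = np.asarray(samples, dtype=float)
    samples = samples[np.isfinite(samples)]
    if kind == "angle":
        edges = np.arange(0.0, 180.0 + 0.5 * c.ANGLE_BIN_DEG, c.ANGLE_BIN_DEG)
    elif kind == "dihedral":
        edges = np.arange(-180.0, 180.0 + 0.5 * c.DIHEDRAL_BIN_DEG, c.DIHEDRAL_BIN_DEG)
    else:
        raise ValueError(f"unknown DOF kind {kind!r}")
    dens, _ = np.histogram(samples, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, dens


def dof_samples(frames: np.ndarray, topology: GAGTopology, dof_name: str) -> np.ndarray:
    """Flat sample series of a named DOF over all instances and frames."""
    idx = topology.dof_index(dof_name)
    if idx.shape[1] == 3:
        vals = geometry.angles_deg(frames, idx)
    else:
        vals = geometry.dihedrals_deg(frames, idx)
    return vals.ravel()


def all_dof_samples(frames: np.ndarray, topology: GAGTopology) -> dict[str, np.ndarray]:
    out = {}
    for name in topology.angle_dof_names + topology.dihedral_dof_names + ["XGG"]:
        if len(topology.dof_index(name)):
            out[name] = dof_samples(frames, topology, name)
    return out


def convergence_metric(p_i, p_target) -> float:
    """Sup-norm of the density difference (deg^-1); zero iff identical."""
    p_i = np.asarray(p_i, dtype=float)
    p_target = np.asarray(p_target, dtype=float)
    if p_i.shape != p_target.shape:
        raise ValueError("density grids do not match")
    return float(np.max(np.abs(p_i - p_target)))


# --------------------------------------------------------------------------
# IBI state
# --------------------------------------------------------------------------

@dataclass
class IBIState:
    iteration: int
    potentials: dict[str, TabulatedPotential]
    target_fits: dict  # dof name -> callable density (deg^-1)
    current_fits: dict = field(default_factory=dict)
    alpha: float = 0.2
    T: float = c.DEFAULT_TEMPERATURE
    immutable: frozenset = frozenset({"XGG"})
    history: list = field(default_factory=list)  # per-iteration {dof: metric}

    def nodes(self, name: str) -> np.ndarray:
        return self.potentials[name].grid


def _density_on(fit, x: np.ndarray) -> np.ndarray:
    return np.asarray(fit(x), dtype=float) if callable(fit) else np.asarray(fit, dtype=float)


def ibi_init(target_fits: dict, alpha: float, T: float = c.DEFAULT_TEMPERATURE,
             v_wall_kt: float = 50.0) -> IBIState:
    """V_0(phi) = -alpha kB T ln P_target(phi), per non-penalty DOF."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    potentials = {}
    for name, fit in target_fits.items():
        if name in ("XGG",):
            continue
        kind = dof_kind(name)
        nodes = DIHEDRAL_NODES if kind == "dihedral" else ANGLE_NODES
        dens = _density_on(fit, nodes)
        norm = np.trapezoid(dens, nodes)
        if not np.isclose(norm, 1.0, atol=0.05):
            raise ValueError(f"target PDF for {name!r} is not normalized (integral {norm:.3f})")
        base = boltzmann_invert(nodes, dens, T, periodic=(kind == "dihedral"),
                                v_wall_kt=v_wall_kt)
        v0 = alpha * base.energy
        potentials[name] = TabulatedPotential.from_energy(nodes, v0,
                                                          periodic=(kind == "dihedral"))
    # the fixed XGG penalty, tabulated for bookkeeping/serialization only
    from .potentials import PenaltyParams, penalty_energy
    kt = c.KB * T
    pen = np.minimum(penalty_energy(np.radians(np.clip(ANGLE_NODES, 1e-6, None)),
                                    PenaltyParams()), v_wall_kt * kt)
    potentials["XGG"] = TabulatedPotential.from_energy(ANGLE_NODES, pen)
    return IBIState(iteration=0, potentials=potentials, target_fits=dict(target_fits),
                    alpha=alpha, T=T)


def ibi_update(state: IBIState, measured_fits: dict,
               p_floor: float = 1e-8, v_wall_kt: float = 50.0) -> IBIState:
    """Apply the IBI correction to every non-penalty DOF; increment iteration.

    Where either density falls below ``p_floor`` the log-ratio is untrusted
    and the potential is linearly continued from the sampled region instead
    (capped at ``v_wall_kt`` kB T).
    """
    kt = c.KB * state.T
    for name, pot in state.potentials.items():
        if name in state.immutable:
            continue
        if name not in measured_fits:
            raise KeyError(f"no measured PDF supplied for DOF {name!r}")
        nodes = pot.grid
        p_i = np.maximum(_density_on(measured_fits[name], nodes), p_floor)
        p_t = np.maximum(_density_on(state.target_fits[name], nodes), p_floor)
        # floored log-ratio: exactly zero wherever both densities are below
        # the floor (unsampled high-energy regions keep their wall), and
        # exactly zero at the fixed point P_I = P_target
        v = pot.energy + state.alpha * kt * np.log(p_i / p_t)
        v -= v.min()
        v = np.minimum(v, v_wall_kt * kt)
        if pot.periodic:
            v[-1] = v[0]
        state.potentials[name] = TabulatedPotential.from_energy(nodes, v, periodic=pot.periodic)
    state.current_fits = dict(measured_fits)
    state.iteration += 1
    return state


# --------------------------------------------------------------------------
# Full IBI driver
# --------------------------------------------------------------------------

PRESETS = {
    # full protocol: 40 ns, 1 fs, friction 50 ps^-1, recorded every 250 fs
    "paper": dict(dt_fs=1.0, n_steps=40_000_000, record_every=250, friction=50.0),
    # scaled-down per-iteration protocol: 2 ns, 2 fs, recorded every 250 fs.
    # Friction is lowered to 5 ps^-1: equilibrium distributions are
    # friction-independent, and faster decorrelation buys ~3x more effective
    # samples per ns, keeping the fit-noise floor well below the IBI
    # convergence threshold at this run length.
    "fast": dict(dt_fs=2.0, n_steps=1_000_000, record_every=125, friction=5.0),
}


@dataclass
class IBIResult:
    state: IBIState
    converged: bool
    iterations: int
    history: list  # per-iteration {dof: sup-norm metric}
    final_fits: dict
    final_trajectory: Trajectory | None = None


def fit_measured(centers: np.ndarray, density: np.ndarray, kind: str,
                 init: AngleFitParams | None = None,
                 target_init: AngleFitParams | None = None):
    """Fit one measured histogram; angles retry with the target-fit
    initialization and then with tightened bounds on a poor fit."""
    if kind == "dihedral":
        return fit_dihedral_spline(centers, density)
    tries = [init, target_init]
    last_exc = None
    best = None
    for guess in tries:
        try:
            fitted = fit_angle_pdf(centers, density, init=guess)
        except FitError as exc:
            last_exc = exc
            continue
        if best is None or fitted.residual < best.residual:
            best = fitted
        if fitted.residual < 5e-4:
            return fitted
    if best is not None:
        return best
    raise last_exc


def run_ibi(topology: GAGTopology, target_pdfs: dict, alpha: float = 0.2,
            max_iter: int = 30, threshold: float = 0.005, patience: int = 3,
            preset: str = "fast", seed: int = 0,
            T: float = c.DEFAULT_TEMPERATURE,
            sim_config: SimulationConfig | None = None,
            equilibration_fraction: float = 0.2,
            include_coupling: bool = True) -> IBIResult:
    """Derive bonded potentials by IBI against target PDFs.

    ``target_pdfs`` maps DOF names to densities on the standard histogram
    grids (arrays) or callables.  Iterates minimize -> simulate -> histogram
    -> fit -> update with nonbonded interactions off, until the sup-norm
    discrepancy between fitted and target densities stays below
    ``threshold`` (deg^-1) for ``patience`` consecutive iterations.  Raises
    IBIDivergenceError if the metric increases 5 iterations in a row.
    """
    # analytic fits of the targets (also the smoothing reference for P_I fits)
    target_fits = {}
    target_angle_params = {}
    for name, target in target_pdfs.items():
        kind = dof_kind(name)
        grid = DIHEDRAL_GRID if kind == "dihedral" else ANGLE_GRID
        dens = _density_on(target, grid)
        if kind == "dihedral":
            target_fits[name] = fit_dihedral_spline(grid, dens)
        else:
            params = fit_angle_pdf(grid, dens)
            target_angle_params[name] = params
            target_fits[name] = lambda x, p=params: angle_mixture_pdf(x, p)

    state = ibi_init(target_fits, alpha, T)
    base_cfg = sim_config or SimulationConfig(**PRESETS[preset], seed=seed,
                                              nonbonded_on=False, T=T)
    prev_angle_params = dict(target_angle_params)
    positions = None
    converged_streak = 0
    worsening = 0
    prev_worst = np.inf
    traj = None
    for it in range(max_iter):
        system = system_from_topology(topology, state.potentials,
                                      nonbonded_on=False,
                                      include_coupling=include_coupling)
        cfg = SimulationConfig(**{**PRESETS[preset], **({} if sim_config is None else dict(
            dt_fs=sim_config.dt_fs, n_steps=sim_config.n_steps,
            record_every=sim_config.record_every, friction=sim_config.friction))},
            seed=seed + it, nonbonded_on=False, T=T)
        if positions is None:
            positions = minimize(system, initial_conformation(topology, seed))
        traj = run_simulation(system, cfg, positions=positions)
        positions = traj.frames[-1]
        frames = traj.equilibrated(equilibration_fraction)
        fits = {}
        metrics = {}
        for name in state.potentials:
            if name in state.immutable:
                continue
            kind = dof_kind(name)
            centers, dens = histogram_dof(frames, topology, name)
            try:
                fits[name] = fit_measured(centers, dens, kind,
                                          init=prev_angle_params.get(name),
                                          target_init=target_angle_params.get(name))
            except FitError as exc:
                raise FitError(f"DOF {name!r} at iteration {it}: {exc}") from exc
            if kind == "angle" and isinstance(fits[name], AngleFitParams):
                prev_angle_params[name] = fits[name]
                fitted = lambda x, p=fits[name]: angle_mixture_pdf(x, p)
            else:
                fitted = fits[name]
            grid = DIHEDRAL_GRID if kind == "dihedral" else ANGLE_GRID
            metrics[name] = convergence_metric(_density_on(fitted, grid),
                                               _density_on(target_fits[name], grid))
        state.history.append(metrics)
        worst = max(metrics.values())
        log.info("IBI iteration %d: worst sup-norm %.3g deg^-1", it, worst)
        if worst < threshold:
            converged_streak += 1
            if converged_streak >= patience:
                measured_angle_fits = {n: (lambda x, p=f: angle_mixture_pdf(x, p))
                                       if isinstance(f, AngleFitParams) else f
                                       for n, f in fits.items()}
                return IBIResult(state, True, it + 1, state.history,
                                 measured_angle_fits, traj)
        else:
            converged_streak = 0
        worsening = worsening + 1 if worst > prev_worst else 0
        if worsening >= 5:
            raise IBIDivergenceError(state.history)
        prev_worst = worst
        measured_for_update = {n: (lambda x, p=f: angle_mixture_pdf(x, p))
                               if isinstance(f, AngleFitParams) else f
                               for n, f in fits.items()}
        state = ibi_update(state, measured_for_update)
    final = {n: (lambda x, p=f: angle_mixture_pdf(x, p)) if isinstance(f, AngleFitParams) else f
             for n, f in fits.items()}
    return IBIResult(state, False, max_iter, state.history, final, traj)


# --------------------------------------------------------------------------
# Coupling-candidate enumeration and ranking
# --------------------------------------------------------------------------

def enumerate_coupling_candidates(topology: GAGTopology) -> dict[str, dict]:
    """All bonded DOFs able to couple adjacent backbone dihedrals.

    For the dihedral pair sharing window G_k..G_{k+2} (beads 2k..2k+4) the
    coupling term must involve both outer beads 2k and 2k+4; analogously for
    the X_k..X_{k+2} window.  Returns {name: {kind, instances}} with names
    written in generic G/X letters.
    """
    n = topology.n_beads
    labels = ["G" if b.index % 2 == 0 else "X" for b in topology.beads]
    out: dict[str, dict] = {}

    def add(kind: str, idx: tuple[int, ...]):
        name = "".join(labels[i] for i in idx)
        entry = out.setdefault(name, {"kind": kind, "instances": []})
        entry["instances"].append(idx)

    for start in range(0, n - 4):
        a, b = start, start + 4  # outer beads of the window
        add("bond", (a, b))
        for j in range(a + 1, b):
            add("angle", (a, j, b))
        inner = [a + 1, a + 2, a + 3]
        for p in range(3):
            for q in range(p + 1, 3):
                add("dihedral", (a, inner[p], inner[q], b))
    return out


def rank_candidates(reference_samples: dict[str, np.ndarray],
                    model_samples: dict[str, np.ndarray],
                    kinds: dict[str, str] | None = None,
                    distance_bin: float = 0.02) -> list[tuple[str, float]]:
    """Rank candidate DOFs by the discrepancy of their marginal PDFs.

    The score is the sup-norm of the per-bin probability difference
    (density x bin width, dimensionless so bonds, angles and dihedrals are
    comparable), sorted descending.
    """
    scores = []
    for name, ref in reference_samples.items():
        if name not in model_samples:
            raise KeyError(f"missing model samples for candidate {name!r}")
        mod = model_samples[name]
        kind = (kinds or {}).get(name)
        if kind is None:
            kind = {2: "bond", 3: "angle", 4: "dihedral"}.get(len(name), "angle")
        ref = np.asarray(ref, dtype=float)
        mod = np.asarray(mod, dtype=float)
        ref = ref[np.isfinite(ref)]
        mod = mod[np.isfinite(mod)]
        if kind == "bond":
            lo = min(ref.min(), mod.min())
            hi = max(ref.max(), mod.max())
            edges = np.arange(lo, hi + distance_bin, distance_bin)
        elif kind == "angle":
            edges = np.arange(0.0, 180.0 + 0.5, c.ANGLE_BIN_DEG)
        else:
            edges = np.arange(-180.0, 180.0 + 0.5, c.DIHEDRAL_BIN_DEG)
        p_ref, _ = np.histogram(ref, bins=edges, density=True)
        p_mod, _ = np.histogram(mod, bins=edges, density=True)
        width = edges[1] - edges[0]
        scores.append((name, float(np.max(np.abs(p_ref - p_mod)) * width)))
    scores.sort(key=lambda t: -t[1])
    return scores


def rank_coupling_candidates(fine_dof_samples: dict[str, np.ndarray],
                             coarse_dof_samples: dict[str, np.ndarray],
                             kinds: dict[str, str] | None = None) -> list[tuple[str, float]]:
    """Candidate coupling DOFs sorted by fine-vs-coarse PDF discrepancy."""
    return rank_candidates(fine_dof_samples, coarse_dof_samples, kinds=kinds)
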