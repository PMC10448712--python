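"""File formats: potential tables, trajectories, run configuration.

Potential tables use a GROMACS-style whitespace-separated dialect with
three columns x, V(x), -V'(x) (degrees, kJ/mol, kJ/mol/deg) and ``#``
comment/header lines; this is also the ingestion path for externally
supplied table files.  Trajectories persist as NumPy .npz containers with
an optional XYZ text export.  Run configuration is strict YAML: unknown
keys are errors.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .potentials import TabulatedPotential
from .simulator import SimulationConfig, Trajectory

log = logging.getLogger(__name__)


def write_potential_table(pot: TabulatedPotential, path) -> None:
    header = (f"# gagcg potential table v1\n"
              f"# periodic: {str(pot.periodic).lower()}\n"
              f"# columns: x  V(x)[kJ/mol]  -dV/dx\n")
    body = "\n".join(f"{x: .6f} {e: .10e} {f: .10e}"
                     for x, e, f in zip(pot.grid, pot.energy, pot.force))
    Path(path).write_text(header + body + "\n")


def read_potential_table(path, recompute_force: str = "never") -> TabulatedPotential:
    """Parse a potential table; validates force/energy consistency.

    If more than half of the interior rows have a force column inconsistent
    with the centered finite difference of the energy column, a warning is
    logged; ``recompute_force='always'`` (or ``'auto'`` on inconsistency)
    replaces the force column by the finite-difference one.
    """
    periodic = False
    xs, es, fs = [], [], []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#") or line.startswith(";"):
            if "periodic:" in line:
                periodic = line.split("periodic:")[1].strip().lower() == "true"
            continue
        parts = line.split()
        if len(parts) < 3:
            raise ValueError(f"{path}: line {lineno}: expected 3 columns, got {len(parts)}")
        try:
            x, e, f = float(parts[0]), float(parts[1]), float(parts[2])
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: non-numeric value") from exc
        xs.append(x)
        es.append(e)
        fs.append(f)
    grid = np.array(xs)
    energy = np.array(es)
    force = np.array(fs)
    ref = TabulatedPotential.from_energy(grid, energy, periodic=periodic)
    interior = slice(1, -1)
    scale = max(np.abs(ref.force).max(), 1e-12)
    bad = np.abs(force[interior] - ref.force[interior]) > 1e-4 * scale + 1e-10
    inconsistent = bad.mean() > 0.5
    if inconsistent:
        log.warning("%s: force column inconsistent with energy at %d/%d interior "
                    "points", path, int(bad.sum()), bad.size)
    if recompute_force == "always" or (recompute_force == "auto" and inconsistent):
        return ref
    return TabulatedPotential(grid, energy, force, periodic=periodic)


def write_potential_set(potentials: dict[str, TabulatedPotential], out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, pot in potentials.items():
        write_potential_table(pot, out / f"{name}.table")


def read_potential_set(in_dir) -> dict[str, TabulatedPotential]:
    return {p.stem: read_potential_table(p) for p in sorted(Path(in_dir).glob("*.table"))}


# --------------------------------------------------------------------------
# Trajectories
# --------------------------------------------------------------------------

def save_trajectory(traj: Trajectory, path) -> None:
    cfg = asdict(traj.config) if traj.config is not None else {}
    np.savez_compressed(path, frames=traj.frames, times=traj.times,
                        seed=traj.seed, config=json.dumps(cfg),
                        mean_kinetic_energy=traj.mean_kinetic_energy)


def load_trajectory(path) -> Trajectory:
    with np.load(path, allow_pickle=False) as data:
        cfg = json.loads(str(data["config"]))
        config = SimulationConfig(**cfg) if cfg else None
        return Trajectory(data["frames"], data["times"], int(data["seed"]),
                          config, float(data["mean_kinetic_energy"]))


def export_xyz(traj: Trajectory, path, labels=None, stride: int = 1) -> None:
    """Plain XYZ text export (coordinates in Angstrom, one block per frame)."""
    n = traj.frames.shape[1]
    labels = labels or ["C"] * n
    with open(path, "w") as fh:
        for f, t in zip(traj.frames[::stride], traj.times[::stride]):
            fh.write(f"{n}\nt = {t:.4f} ps\n")
            for lab, (x, y, z) in zip(labels, f * 10.0):
                fh.write(f"{lab} {x:.4f} {y:.4f} {z:.4f}\n")


# --------------------------------------------------------------------------
# Run configuration (strict YAML)
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    gag_type: str = "HA"
    n_mono: int = 16
    salt_mol_l: float = 0.150
    temperature: float = 300.0
    cutoff_factor: float = 8.0
    dt_fs: float = 20.0
    n_steps: int = 100_000
    record_every: int = 250
    friction: float = 50.0
    nonbonded_on: bool = True
    exclude_adjacent_sites: bool = False
    potential_dir: str | None = None
    seeds: list[int] = field(default_factory=lambda: [1])
    out_dir: str = "out"

    def validate(self) -> None:
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("replica seeds must be distinct")
        if self.potential_dir is not None and not Path(self.potential_dir).is_dir():
            raise FileNotFoundError(f"potential_dir not found: {self.potential_dir}")

    def simulation_config(self, seed: int) -> SimulationConfig:
        return SimulationConfig(dt_fs=self.dt_fs, friction=self.friction,
                                T=self.temperature, n_steps=self.n_steps,
                                record_every=self.record_every, seed=seed,
                                nonbonded_on=self.nonbonded_on,
                                cutoff_factor=self.cutoff_factor,
                                exclude_adjacent_sites=self.exclude_adjacent_sites)


def load_run_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    cfg.validate()
    log.info("run config: %s", asdict(cfg))
    return cfg
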