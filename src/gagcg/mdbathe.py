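"""Fine-scale reference chain (three sites per saccharide).

The reference model represents each monosaccharide by two carbon sites
flanking the ring plus the glycosidic oxygen that precedes it, with every
internal distance, angle and through-ring torsion held by stiff harmonic
terms and only the glycosidic dihedral pair (psi, phi) of each linkage
free, driven by 2D potentials V(psi, phi) supplied as configuration.  The
MD form of the model requires single-variable dihedral potentials, so
V(psi, phi) is decoupled by marginalizing the Boltzmann joint distribution
and re-inverting each marginal, capped at a maximum (default 20 kB T).

Site order along the chain is O_0, Ca_0, Cb_0, O_1, Ca_1, Cb_1, ...; the
oxygens (every third site) are the 1BPS bead positions, so mapping a fine
trajectory to the coarse model is a strided slice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from . import constants as c
from .ibi import all_dof_samples
from .potentials import TabulatedPotential, boltzmann_invert, cap_potential
from .simulator import System
from .topology import GAGTopology, build_gag_chain

DIH_NODES = np.arange(-180.0, 180.0 + 3.6, 7.2)  # 51 periodic nodes


@dataclass
class FineModelParams:
    """Geometry and glycosidic-potential configuration of the fine model.

    ``bond_lengths``: nm, keys CO (carbon-oxygen) and CC_G / CC_X (the
    through-ring carbon-carbon span of G-type and X-type saccharides).
    ``angles_deg``: equilibrium angles OCC, CCO, COC.  ``ring_dihedral_deg``:
    equilibrium through-ring torsion per saccharide type (keys G, X).
    ``V2d``: per linkage type ("beta14", "beta13") a (51, 51) potential grid
    in kJ/mol on the periodic node grids ``psi_nodes`` x ``phi_nodes``.
    """

    bond_lengths: dict
    angles_deg: dict
    ring_dihedral_deg: dict
    V2d: dict
    psi_nodes: np.ndarray = field(default_factory=lambda: DIH_NODES.copy())
    phi_nodes: np.ndarray = field(default_factory=lambda: DIH_NODES.copy())
    k_bond: float = 1.5e6  # kJ mol^-1 nm^-2
    k_angle: float = 1.0e4  # kJ mol^-1 rad^-2
    k_ring_dihedral: float = 3.0e3  # kJ mol^-1 rad^-2
    vmax_kt: float = 20.0
    virtual_site_variant: str = "midpoint"

    def validate(self) -> None:
        for key in ("CO", "CC_G", "CC_X"):
            if key not in self.bond_lengths:
                raise ValueError(f"missing bond length {key!r}")
        for key in ("OCC", "CCO", "COC"):
            if key not in self.angles_deg:
                raise ValueError(f"missing angle {key!r}")
        for key in ("G", "X"):
            if key not in self.ring_dihedral_deg:
                raise ValueError(f"missing ring dihedral for type {key!r}")
        for link in ("beta14", "beta13"):
            if link not in self.V2d:
                raise ValueError(f"missing 2D dihedral potential for {link!r}")
            grid = np.asarray(self.V2d[link])
            if grid.shape != (len(self.psi_nodes), len(self.phi_nodes)):
                raise ValueError(f"V2d[{link!r}] has shape {grid.shape}, expected "
                                 f"({len(self.psi_nodes)}, {len(self.phi_nodes)})")
            if not (np.allclose(grid[0], grid[-1]) and np.allclose(grid[:, 0], grid[:, -1])):
                raise ValueError(f"V2d[{link!r}] is not periodic in both coordinates")


def save_fine_params(params: FineModelParams, out_dir) -> None:
    """Write FineModelParams as params.yml plus one CSV per 2D grid.

    Schema: ``bond_lengths`` (nm), ``angles_deg``, ``ring_dihedral_deg``,
    spring constants, ``vmax_kt``, ``virtual_site_variant`` and
    ``V2d_files`` mapping linkage type to a CSV of the (psi x phi) grid in
    kJ/mol on the periodic 7.2-degree node grids.
    """
    import yaml
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    doc = {
        "bond_lengths": {k: float(v) for k, v in params.bond_lengths.items()},
        "angles_deg": {k: float(v) for k, v in params.angles_deg.items()},
        "ring_dihedral_deg": {k: float(v) for k, v in params.ring_dihedral_deg.items()},
        "k_bond": float(params.k_bond),
        "k_angle": float(params.k_angle),
        "k_ring_dihedral": float(params.k_ring_dihedral),
        "vmax_kt": float(params.vmax_kt),
        "virtual_site_variant": params.virtual_site_variant,
        "V2d_files": {link: f"V2d_{link}.csv" for link in params.V2d},
    }
    (out / "params.yml").write_text(yaml.safe_dump(doc, sort_keys=True))
    for link, grid in params.V2d.items():
        np.savetxt(out / f"V2d_{link}.csv", np.asarray(grid), delimiter=",")


def load_fine_params(params_yml) -> FineModelParams:
    """Load and validate FineModelParams written by :func:`save_fine_params`."""
    import yaml
    from pathlib import Path

    path = Path(params_yml)
    doc = yaml.safe_load(path.read_text())
    v2d = {link: np.loadtxt(path.parent / fname, delimiter=",")
           for link, fname in doc["V2d_files"].items()}
    params = FineModelParams(
        bond_lengths=doc["bond_lengths"],
        angles_deg=doc["angles_deg"],
        ring_dihedral_deg=doc["ring_dihedral_deg"],
        V2d=v2d,
        k_bond=doc.get("k_bond", 1.5e6),
        k_angle=doc.get("k_angle", 1.0e4),
        k_ring_dihedral=doc.get("k_ring_dihedral", 3.0e3),
        vmax_kt=doc.get("vmax_kt", 20.0),
        virtual_site_variant=doc.get("virtual_site_variant", "midpoint"),
    )
    params.validate()
    return params


def decouple_dihedral(V2d: np.ndarray, T: float, vmax: float | None = None,
                      psi_nodes: np.ndarray = DIH_NODES,
                      phi_nodes: np.ndarray = DIH_NODES
                      ) -> tuple[TabulatedPotential, TabulatedPotential]:
    """Split a 2D glycosidic potential into two 1D tabulated potentials.

    Converts V(psi, phi) to the Boltzmann joint P = exp(-V/kB T),
    marginalizes over the other coordinate, re-inverts each marginal and
    caps at ``vmax`` (kJ/mol; None for no cap).  Offsets set so min(V) = 0.
    """
    V2d = np.asarray(V2d, dtype=float)
    if not (np.allclose(V2d[0], V2d[-1]) and np.allclose(V2d[:, 0], V2d[:, -1])):
        raise ValueError("V2d must be periodic in both coordinates")
    kt = c.KB * T
    p = np.exp(-(V2d - V2d.min()) / kt)
    p_psi = np.trapezoid(p, phi_nodes, axis=1)
    p_phi = np.trapezoid(p, psi_nodes, axis=0)
    p_psi /= np.trapezoid(p_psi, psi_nodes)
    p_phi /= np.trapezoid(p_phi, phi_nodes)
    wall = 200.0  # kT; generous, capping happens below
    v_psi = boltzmann_invert(psi_nodes, p_psi, T, periodic=True, v_wall_kt=wall)
    v_phi = boltzmann_invert(phi_nodes, p_phi, T, periodic=True, v_wall_kt=wall)
    if vmax is not None:
        v_psi = cap_potential(v_psi, vmax)
        v_phi = cap_potential(v_phi, vmax)
    return v_psi, v_phi


def _harmonic_angle_table(theta0_deg: float, k_rad: float) -> TabulatedPotential:
    grid = np.arange(0.0, 181.0, 1.0)
    v = 0.5 * k_rad * np.radians(grid - theta0_deg) ** 2
    return TabulatedPotential.from_energy(grid, v, periodic=False)


def _harmonic_dihedral_table(phi0_deg: float, k_rad: float) -> TabulatedPotential:
    grid = DIH_NODES
    d = (grid - phi0_deg + 180.0) % 360.0 - 180.0
    v = 0.5 * k_rad * np.radians(d) ** 2
    v[-1] = v[0]
    return TabulatedPotential.from_energy(grid, v, periodic=True)


def _oo_distance(d_cc: float, b_co: float, occ_deg: float, cco_deg: float,
                 tau_deg: float) -> float:
    """|O..O'| across one saccharide for given geometry (NeRF placement)."""
    o = np.zeros(3)
    ca = np.array([b_co, 0.0, 0.0])
    th1 = math.radians(180.0 - occ_deg)
    cb = ca + d_cc * np.array([math.cos(th1), math.sin(th1), 0.0])
    # place O' with bond b_co, angle cco at cb, dihedral tau about ca->cb
    b1 = ca - o
    b2 = cb - ca
    b2h = b2 / np.linalg.norm(b2)
    n = np.cross(b1, b2)
    n /= np.linalg.norm(n)
    m = np.cross(n, b2h)
    ang = math.radians(cco_deg)
    tau = math.radians(tau_deg)
    d = np.array([-math.cos(ang), math.sin(ang) * math.cos(tau), math.sin(ang) * math.sin(tau)])
    o2 = cb + b_co * (d[0] * b2h + d[1] * m + d[2] * n)
    return float(np.linalg.norm(o2 - o))


def solve_cc_length(target_oo: float, b_co: float, occ_deg: float, cco_deg: float,
                    tau_deg: float) -> float:
    """Carbon-carbon span giving the required oxygen-oxygen distance."""
    fn = lambda d: _oo_distance(d, b_co, occ_deg, cco_deg, tau_deg) - target_oo
    return float(optimize.brentq(fn, 0.05, 0.55))


@dataclass
class FineChain:
    """Fine-scale system plus the metadata needed for coarse mapping."""

    system: System
    gag_type: str
    n_mono: int
    oxygen_indices: np.ndarray  # coarse bead <- fine site map
    psi_indices: np.ndarray  # (n_linkages, 4)
    phi_indices: np.ndarray
    initial_positions: np.ndarray

    @property
    def coarse_topology(self) -> GAGTopology:
        return build_gag_chain(self.gag_type, self.n_mono)


def build_fine_chain(gag_type: str, n_mono: int, params: FineModelParams,
                     T: float = c.DEFAULT_TEMPERATURE) -> FineChain:
    """Assemble the stiff three-site-per-saccharide chain.

    Every rigid DOF becomes a stiff harmonic term; each linkage's glycosidic
    dihedrals psi (about Cb-O) and phi (about O-Ca) get the decoupled,
    capped 1D potentials of the linkage's 2D table.
    """
    params.validate()
    if n_mono < 2:
        raise ValueError("n_mono must be at least 2")
    n_sites = 3 * n_mono
    labels = ["G" if i % 2 == 0 else "X" for i in range(n_mono)]

    masses = np.empty(n_sites)
    mass_of = {"G": c.MASS_BEAD["G"], "X": c.MASS_BEAD[
        {"HA": "N", "C4S": "A", "C6S": "S"}[gag_type]]}
    for k, lab in enumerate(labels):
        res = mass_of[lab]
        masses[3 * k] = 16.0  # oxygen
        masses[3 * k + 1] = masses[3 * k + 2] = (res - 16.0) / 2.0

    b_co = params.bond_lengths["CO"]
    bonds_idx, bonds_r0 = [], []
    for k in range(n_mono):
        o, ca, cb = 3 * k, 3 * k + 1, 3 * k + 2
        bonds_idx += [(o, ca), (ca, cb)]
        bonds_r0 += [b_co, params.bond_lengths["CC_" + labels[k]]]
        if k < n_mono - 1:
            bonds_idx.append((cb, 3 * (k + 1)))
            bonds_r0.append(b_co)

    tables: list[TabulatedPotential] = []

    def add_table(t: TabulatedPotential) -> int:
        tables.append(t)
        return len(tables) - 1

    t_occ = add_table(_harmonic_angle_table(params.angles_deg["OCC"], params.k_angle))
    t_cco = add_table(_harmonic_angle_table(params.angles_deg["CCO"], params.k_angle))
    t_coc = add_table(_harmonic_angle_table(params.angles_deg["COC"], params.k_angle))
    t_ring = {lab: add_table(_harmonic_dihedral_table(params.ring_dihedral_deg[lab],
                                                      params.k_ring_dihedral))
              for lab in ("G", "X")}
    vmax = params.vmax_kt * c.KB * T
    t_link = {}
    for link in ("beta14", "beta13"):
        v_psi, v_phi = decouple_dihedral(np.asarray(params.V2d[link], dtype=float), T,
                                         vmax=vmax, psi_nodes=params.psi_nodes,
                                         phi_nodes=params.phi_nodes)
        t_link[link] = (add_table(v_psi), add_table(v_phi))

    ang_idx, ang_t = [], []
    dih_idx, dih_t = [], []
    psi_rows, phi_rows = [], []
    for k in range(n_mono):
        o, ca, cb = 3 * k, 3 * k + 1, 3 * k + 2
        ang_idx.append((o, ca, cb))
        ang_t.append(t_occ)
        if k < n_mono - 1:
            o2, ca2, cb2 = 3 * (k + 1), 3 * (k + 1) + 1, 3 * (k + 1) + 2
            ang_idx.append((ca, cb, o2))
            ang_t.append(t_cco)
            ang_idx.append((cb, o2, ca2))
            ang_t.append(t_coc)
            # through-ring torsion of saccharide k (rigid)
            dih_idx.append((o, ca, cb, o2))
            dih_t.append(t_ring[labels[k]])
            # glycosidic pair of linkage k: the linkage oxygen is bead k+1
            link = "beta14" if (k + 1) % 2 == 0 else "beta13"
            psi = (ca, cb, o2, ca2)
            phi = (cb, o2, ca2, cb2)
            dih_idx.append(psi)
            dih_t.append(t_link[link][0])
            dih_idx.append(phi)
            dih_t.append(t_link[link][1])
            psi_rows.append(psi)
            phi_rows.append(phi)

    system = System(
        masses=masses,
        bond_index=np.array(bonds_idx, dtype=int),
        bond_r0=np.array(bonds_r0),
        bond_k=np.full(len(bonds_idx), params.k_bond),
        angle_index=np.array(ang_idx, dtype=int),
        angle_table=np.array(ang_t, dtype=int),
        dihedral_index=np.array(dih_idx, dtype=int),
        dihedral_table=np.array(dih_t, dtype=int),
        tables=tables,
        nonbonded_on=False,
    )
    init = _build_initial_positions(gag_type, n_mono, params, t_link, tables)
    return FineChain(system, gag_type, n_mono, np.arange(0, n_sites, 3),
                     np.array(psi_rows, dtype=int), np.array(phi_rows, dtype=int), init)


def _build_initial_positions(gag_type, n_mono, params: FineModelParams,
                             t_link, tables) -> np.ndarray:
    """NeRF chain growth at equilibrium geometry, glycosidic dihedrals at
    the minima of their decoupled potentials."""
    labels = ["G" if i % 2 == 0 else "X" for i in range(n_mono)]
    b_co = params.bond_lengths["CO"]

    def torsion_minimum(link: str) -> tuple[float, float]:
        vpsi = tables[t_link[link][0]]
        vphi = tables[t_link[link][1]]
        return (float(vpsi.grid[np.argmin(vpsi.energy)]),
                float(vphi.grid[np.argmin(vphi.energy)]))

    n_sites = 3 * n_mono
    # per-site (bond to predecessor, angle, torsion); entries for the first
    # three sites are placed explicitly below
    recs = [None, None, None]
    for i in range(3, n_sites):
        k = i // 3
        if i % 3 == 0:  # O_k after Cb_{k-1}; ring torsion of saccharide k-1
            recs.append((b_co, params.angles_deg["CCO"],
                         params.ring_dihedral_deg[labels[k - 1]]))
        elif i % 3 == 1:  # Ca_k after O_k; psi of the linkage at O_k
            link = "beta14" if k % 2 == 0 else "beta13"
            recs.append((b_co, params.angles_deg["COC"], torsion_minimum(link)[0]))
        else:  # Cb_k after Ca_k; phi of the linkage at O_k
            link = "beta14" if k % 2 == 0 else "beta13"
            recs.append((params.bond_lengths["CC_" + labels[k]],
                         params.angles_deg["OCC"], torsion_minimum(link)[1]))
    pos = np.zeros((n_sites, 3))
    pos[1] = [b_co, 0.0, 0.0]
    th = math.radians(180.0 - params.angles_deg["OCC"])
    cc0 = params.bond_lengths["CC_" + labels[0]]
    pos[2] = pos[1] + cc0 * np.array([math.cos(th), math.sin(th), 0.0])
    for i in range(3, n_sites):
        b, ang, tor = recs[i]
        pos[i] = _nerf(pos[i - 3], pos[i - 2], pos[i - 1], b, ang, tor)
    return pos


def _nerf(a, b, c_, bond, angle_deg, torsion_deg):
    """Place atom d given a-b-c, |c-d|, angle(b,c,d) and torsion(a,b,c,d)."""
    bc = c_ - b
    bch = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        n = np.cross(np.array([0.0, 0.0, 1.0]), bc)
        nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, bch)
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    d = np.array([-math.cos(ang), math.sin(ang) * math.cos(tor),
                  math.sin(ang) * math.sin(tor)])
    return c_ + bond * (d[0] * bch + d[1] * m + d[2] * n)


def map_fine_to_coarse(fine_trajectory, fine_chain: FineChain):
    """Coarse bead positions and coarse DOF sample series of a fine run.

    Oxygen sites become the 1BPS beads; returns (coarse_positions, samples)
    where samples maps every coarse DOF name (bonds excluded) to its series.
    Dihedral samples at collinear triplets are dropped as missing, not NaN.
    """
    frames = fine_trajectory.frames if hasattr(fine_trajectory, "frames") else np.asarray(fine_trajectory)
    coarse = frames[:, fine_chain.oxygen_indices, :]
    topo = fine_chain.coarse_topology
    samples = {name: s[np.isfinite(s)] for name, s in all_dof_samples(coarse, topo).items()}
    return coarse, samples
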