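"""One-bead-per-saccharide (1BPS) chain topologies for GAGs.

Each monosaccharide is represented by a single bead placed on a glycosidic
oxygen.  Beads alternate G, X, G, X, ... along the chain, where G marks the
beta-1,4 oxygen preceding a GlcUA unit and X the beta-1,3 oxygen preceding
the amino sugar of the GAG type (N for hyaluronic acid, A for
chondroitin-4-sulfate, S for chondroitin-6-sulfate).  Chains start with a
G bead; bead indices are 0-based.

Nonbonded interactions act on massless virtual sites at bond midpoints: the
site on bond m carries the charge and steric radius of the monosaccharide
lying between beads m and m+1 (a G-type unit when bead m is a G bead).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constants as c

GAG_X_BEAD = {"HA": "N", "C4S": "A", "C6S": "S"}


@dataclass(frozen=True)
class BeadSpec:
    label: str  # one of G, N, A, S
    mass: float  # Da
    index: int  # 0-based chain position

    def __post_init__(self):
        if self.label not in ("G", "N", "A", "S"):
            raise ValueError(f"unknown bead label {self.label!r}")
        if self.mass <= 0:
            raise ValueError("bead mass must be positive")


@dataclass(frozen=True)
class VirtualSiteSpec:
    parent_pair: tuple[int, int]
    charge: float  # e; 0 for VN, -1 otherwise
    sigma: float  # nm
    label: str  # VG, VN, VA, VS


@dataclass
class GAGTopology:
    gag_type: str
    beads: list[BeadSpec]
    bonds: list[tuple[int, int, float, float]]  # (i, j, r0 nm, k kJ/mol/nm^2)
    angles: list[tuple[int, int, int, str]]  # (i, j, k, dof_name)
    dihedrals: list[tuple[int, int, int, int, str]]  # dof_name in GXGX/XGXG/GXGG
    penalty_angles: list[tuple[int, int, int]]  # XGG triplets
    virtual_sites: list[VirtualSiteSpec]
    exclude_adjacent_sites: bool = False  # adjacent-monosaccharide nonbonded off?
    extra: dict = field(default_factory=dict)

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def masses(self) -> np.ndarray:
        return np.array([b.mass for b in self.beads])

    @property
    def bond_index(self) -> np.ndarray:
        return np.array([(b[0], b[1]) for b in self.bonds], dtype=int).reshape(-1, 2)

    def angle_index(self, dof_name: str | None = None) -> np.ndarray:
        rows = [(a[0], a[1], a[2]) for a in self.angles
                if dof_name is None or a[3] == dof_name]
        return np.array(rows, dtype=int).reshape(-1, 3)

    def dihedral_index(self, dof_name: str | None = None) -> np.ndarray:
        rows = [(d[0], d[1], d[2], d[3]) for d in self.dihedrals
                if dof_name is None or d[4] == dof_name]
        return np.array(rows, dtype=int).reshape(-1, 4)

    @property
    def angle_dof_names(self) -> list[str]:
        return sorted({a[3] for a in self.angles})

    @property
    def dihedral_dof_names(self) -> list[str]:
        return sorted({d[4] for d in self.dihedrals})

    def dof_kind(self, dof_name: str) -> str:
        if dof_name in self.angle_dof_names or dof_name == "XGG":
            return "angle"
        if dof_name in self.dihedral_dof_names:
            return "dihedral"
        raise KeyError(f"unknown DOF {dof_name!r}")

    def dof_index(self, dof_name: str) -> np.ndarray:
        """Bead-index rows of every instance of a named DOF."""
        if dof_name == "XGG":
            return np.array(self.penalty_angles, dtype=int).reshape(-1, 3)
        if dof_name in self.angle_dof_names:
            return self.angle_index(dof_name)
        if dof_name in self.dihedral_dof_names:
            return self.dihedral_index(dof_name)
        raise KeyError(f"unknown DOF {dof_name!r}")


def build_gag_chain(gag_type: str, n_mono: int,
                    masses: dict[str, float] | None = None,
                    exclude_adjacent_sites: bool = False) -> GAGTopology:
    """Build the 1BPS topology of a GAG chain with ``n_mono`` monosaccharides.

    The chain has n bonds = n_mono - 1 with equilibrium lengths alternating
    0.56 nm (GX) and 0.49 nm (XG), one midpoint virtual site per bond,
    n_mono - 2 bending angles (GXG/XGX), n_mono - 3 backbone dihedrals
    (GXGX/XGXG), one GXGG coupling dihedral per G_k-X_k-G_{k+1}-G_{k+2}
    quadruple and one XGG penalty angle per X_k-G_{k+1}-G_{k+2} triple.
    """
    if gag_type not in GAG_X_BEAD:
        raise ValueError(f"unknown gag_type {gag_type!r}; expected one of {sorted(GAG_X_BEAD)}")
    if n_mono < 2:
        raise ValueError("n_mono must be at least 2")
    x = GAG_X_BEAD[gag_type]
    masses = {**c.MASS_BEAD, **(masses or {})}
    labels = [("G" if i % 2 == 0 else x) for i in range(n_mono)]
    beads = [BeadSpec(lab, masses[lab], i) for i, lab in enumerate(labels)]

    bonds = []
    sites = []
    for i in range(n_mono - 1):
        r0 = c.R0_GX if labels[i] == "G" else c.R0_XG
        bonds.append((i, i + 1, r0, c.K_BOND))
        vlab = "V" + labels[i]
        sites.append(VirtualSiteSpec((i, i + 1), c.CHARGE_SITE[vlab], c.SIGMA_SITE[vlab], vlab))

    angles = [(i, i + 1, i + 2, labels[i] + labels[i + 1] + labels[i + 2])
              for i in range(n_mono - 2)]
    dihedrals = [(i, i + 1, i + 2, i + 3,
                  "".join(labels[i:i + 4]).replace(x, "X"))
                 for i in range(n_mono - 3)]
    # generic DOF names use X for the amino sugar
    angles = [(i, j, k, name.replace(x, "X")) for (i, j, k, name) in angles]

    # coupling dihedral G_k-X_k-G_{k+1}-G_{k+2}: beads (2k, 2k+1, 2k+2, 2k+4)
    for m in range(0, n_mono, 2):
        if m + 4 <= n_mono - 1:
            dihedrals.append((m, m + 1, m + 2, m + 4, "GXGG"))
    # penalty angle X_k-G_{k+1}-G_{k+2}: beads (2k+1, 2k+2, 2k+4)
    penalty = [(m + 1, m + 2, m + 4) for m in range(0, n_mono, 2) if m + 4 <= n_mono - 1]

    return GAGTopology(gag_type, beads, bonds, angles, dihedrals, penalty, sites,
                       exclude_adjacent_sites=exclude_adjacent_sites)


def virtual_site_positions(topology: GAGTopology, bead_positions: np.ndarray) -> np.ndarray:
    """Midpoint positions of all virtual sites; accepts (n,3) or (frames,n,3)."""
    pos = np.asarray(bead_positions, dtype=float)
    single = pos.ndim == 2
    if single:
        pos = pos[None]
    if pos.shape[-2] != topology.n_beads:
        raise ValueError(f"positions have {pos.shape[-2]} beads, topology has {topology.n_beads}")
    pairs = np.array([s.parent_pair for s in topology.virtual_sites], dtype=int)
    out = 0.5 * (pos[:, pairs[:, 0]] + pos[:, pairs[:, 1]])
    return out[0] if single else out


def initial_conformation(topology: GAGTopology, seed: int,
                         max_bend_deg: float = 30.0) -> np.ndarray:
    """Seeded self-avoiding random-walk starting structure (nm).

    Bonds are placed at their equilibrium lengths; successive bond directions
    deviate by at most ``max_bend_deg`` so the walk keeps moving forward, and
    any placement closer than the smallest steric radius (0.329 nm) to an
    earlier bead is re-drawn.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    n = topology.n_beads
    r0 = np.array([b[2] for b in topology.bonds])
    min_sep = min(c.SIGMA_SITE.values())
    pos = np.zeros((n, 3))
    direction = np.array([1.0, 0.0, 0.0])
    for i in range(1, n):
        for _ in range(200):
            # perturb the previous direction within the bend cone
            perturb = rng.normal(size=3)
            perturb -= perturb @ direction * direction
            pn = np.linalg.norm(perturb)
            if pn < 1e-12:
                continue
            theta = np.radians(max_bend_deg) * rng.random()
            cand = np.cos(theta) * direction + np.sin(theta) * perturb / pn
            cand /= np.linalg.norm(cand)
            new = pos[i - 1] + r0[i - 1] * cand
            # nonbonded clash check against all beads but the bonded neighbor
            if i >= 2:
                d = np.linalg.norm(pos[: i - 1] - new, axis=1)
                if d.min() < min_sep:
                    continue
            pos[i] = new
            direction = cand
            break
        else:  # pragma: no cover - cone + min bond length make this unreachable
            raise RuntimeError(f"could not place bead {i} without clashes")
    return pos


def to_text(topology: GAGTopology) -> str:
    """Plain-text serialization (sectioned columnar layout)."""
    lines = [f"# gagcg topology v1", f"gag_type {topology.gag_type}",
             f"exclude_adjacent_sites {int(topology.exclude_adjacent_sites)}",
             "[beads]  # index label mass"]
    for b in topology.beads:
        lines.append(f"{b.index} {b.label} {b.mass:.4f}")
    lines.append("[bonds]  # i j r0_nm k_kJ_mol_nm2")
    for i, j, r0, k in topology.bonds:
        lines.append(f"{i} {j} {r0:.6f} {k:.4f}")
    lines.append("[angles]  # i j k dof")
    for i, j, k, name in topology.angles:
        lines.append(f"{i} {j} {k} {name}")
    lines.append("[dihedrals]  # i j k l dof")
    for i, j, k, l, name in topology.dihedrals:
        lines.append(f"{i} {j} {k} {l} {name}")
    lines.append("[penalty_angles]  # i j k")
    for i, j, k in topology.penalty_angles:
        lines.append(f"{i} {j} {k}")
    lines.append("[virtual_sites]  # i j charge sigma label")
    for s in topology.virtual_sites:
        lines.append(f"{s.parent_pair[0]} {s.parent_pair[1]} {s.charge:.1f} {s.sigma:.4f} {s.label}")
    return "\n".join(lines) + "\n"


def from_text(text: str) -> GAGTopology:
    gag_type = "HA"
    excl = False
    section = None
    beads: list[BeadSpec] = []
    bonds, angles, dihedrals, penalty, sites = [], [], [], [], []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            section = line.strip("[]")
            continue
        parts = line.split()
        if section is None:
            if parts[0] == "gag_type":
                gag_type = parts[1]
            elif parts[0] == "exclude_adjacent_sites":
                excl = bool(int(parts[1]))
        elif section == "beads":
            beads.append(BeadSpec(parts[1], float(parts[2]), int(parts[0])))
        elif section == "bonds":
            bonds.append((int(parts[0]), int(parts[1]), float(parts[2]), float(parts[3])))
        elif section == "angles":
            angles.append((int(parts[0]), int(parts[1]), int(parts[2]), parts[3]))
        elif section == "dihedrals":
            dihedrals.append((int(parts[0]), int(parts[1]), int(parts[2]), int(parts[3]), parts[4]))
        elif section == "penalty_angles":
            penalty.append((int(parts[0]), int(parts[1]), int(parts[2])))
        elif section == "virtual_sites":
            sites.append(VirtualSiteSpec((int(parts[0]), int(parts[1])),
                                         float(parts[2]), float(parts[3]), parts[4]))
    return GAGTopology(gag_type, beads, bonds, angles, dihedrals, penalty, sites,
                       exclude_adjacent_sites=excl)


def export_pdb(topology: GAGTopology, positions: np.ndarray, path: str) -> None:
    """Write bead coordinates as a PDB file for visualization (via MDAnalysis)."""
    import MDAnalysis as mda

    n = topology.n_beads
    u = mda.Universe.empty(n, trajectory=True)
    u.add_TopologyAttr("names", [b.label for b in topology.beads])
    u.add_TopologyAttr("resids", [1])
    u.add_TopologyAttr("resnames", [topology.gag_type])
    u.atoms.positions = np.asarray(positions, dtype=float) * 10.0  # nm -> A
    u.atoms.write(path)
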