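"""Physical constants and model defaults (GROMACS-style units).

Units throughout the package: nm (length), ps (time), K (temperature),
kJ/mol (energy), Da (mass), elementary charges.  Angles and dihedrals are
handled in degrees at the user-facing level and converted to radians only
inside force kernels.
"""

# CODATA 2018
KB = 0.008314462618  # Boltzmann constant x Avogadro, kJ mol^-1 K^-1
F_COULOMB = 138.935458  # e^2 / (4 pi eps0), kJ mol^-1 nm e^-2
ELEMENTARY_CHARGE = 1.602176634e-19  # C
EPS0 = 8.8541878128e-12  # F m^-1
KB_SI = 1.380649e-23  # J K^-1
N_AVOGADRO = 6.02214076e23  # mol^-1

DEFAULT_TEMPERATURE = 300.0  # K
DEFAULT_FRICTION = 50.0  # ps^-1
DEFAULT_EPS_R = 80.0  # dielectric constant of water

# 1BPS geometry: distance between adjacent glycosidic oxygens
R0_GX = 0.56  # nm, bond spanning a GlcUA unit
R0_XG = 0.49  # nm, bond spanning a GlcNAc/GalNAc unit
L_BOND = 0.525  # nm, average bond length l_b used in C_N and l_p
K_BOND = 8038.0  # kJ mol^-1 nm^-2, backbone spring constant

# XGG penalty potential parameters
PENALTY_A = 100.0  # kJ/mol
PENALTY_B = 0.026  # rad

# Virtual-site nonbonded parameters
SIGMA_SITE = {"VG": 0.329, "VN": 0.356, "VA": 0.356, "VS": 0.356}  # nm
CHARGE_SITE = {"VG": -1.0, "VN": 0.0, "VA": -1.0, "VS": -1.0}  # e
EPS_LJ = 0.6276  # kJ/mol, WCA well depth

# Monosaccharide residue masses (Da).  Not printed in the source model;
# chosen from standard residue composition: GlcUA (GCU), GlcNAc (NAG),
# GalNAc-4S (ASG), GalNAc-6S (NG6).  Equilibrium observables are
# mass-independent under Langevin dynamics.
MASS_BEAD = {"G": 176.1, "N": 203.2, "A": 282.3, "S": 282.3}

# Histogram conventions
ANGLE_BIN_DEG = 1.0  # deg, angle histograms on (0, 180]
DIHEDRAL_BIN_DEG = 7.2  # deg, dihedral histograms on (-180, 180]

DEFAULT_CUTOFF_FACTOR = 8.0  # electrostatic cutoff in Debye lengths
BATHE_CUTOFF_FACTOR = 3.0  # cutoff used by the three-site reference model
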