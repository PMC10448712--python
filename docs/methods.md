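# Methods

## The model

`gagcg` implements a one-bead-per-saccharide (1BPS) coarse-grained model of
unbranched glycosaminoglycans — hyaluronic acid (HA), chondroitin-4-sulfate
(C4S) and chondroitin-6-sulfate (C6S).  Each monosaccharide is a single bead
placed on a glycosidic oxygen; a chain of N monosaccharides is a GX repeat
(G = the beta-1,4 oxygen preceding GlcUA; X = the beta-1,3 oxygen preceding
GlcNAc, GalNAc-4S or GalNAc-6S).  Chains always start with a G bead and use
0-based indices.

Bonded interactions:

* GX and XG bonds: harmonic, r0 = 0.56 and 0.49 nm,
  k = 8038 kJ mol^-1 nm^-2.
* GXG / XGX bending angles and GXGX / XGXG backbone dihedrals: tabulated
  potentials derived by iterative Boltzmann inversion (IBI).
* A GXGG *coupling dihedral* over the non-consecutive quadruple
  G_k–X_k–G_{k+1}–G_{k+2}.  Coarse-graining to one bead per saccharide loses
  the correlation between adjacent backbone dihedrals; this extra bonded
  term re-introduces it.  It is derived by the same IBI update as the other
  DOFs.
* An XGG *penalty angle* over X_k–G_{k+1}–G_{k+2}.  The dihedral force is
  singular when the three inner beads of a dihedral approach collinearity;
  the penalty forbids that region so the model remains stable at a 20 fs
  timestep:

      V(theta) = a b^2 / ((pi - theta)^2 - b^2),   theta < pi - b,

  with a = 100 kJ/mol and b = 0.026 rad, and V = +inf for theta >= pi - b.
  The displayed equation for this term was not machine-readable in the
  source we worked from; the form above is the package's own choice,
  constrained to reproduce every documented property of the term: it
  diverges at theta = pi - b (so "never samples within b of 180 degrees" is
  a hard guarantee), it is strictly increasing toward 180 degrees, linear
  in a, below 0.1 kT at the XGG distribution peak, and it expresses no
  preference for any particular angle away from the pole.  In the force
  kernel the pole is continued linearly (C1) behind theta = pi - b with the
  pole-side slope, so a pathological starting structure produces a huge
  restoring force rather than a NaN.  This term is never updated by IBI.

Nonbonded interactions act only on massless virtual sites at bond midpoints
(VG/VN/VA/VS, one per bond; the site on bond m carries the identity of the
monosaccharide between beads m and m+1).  Forces on a site are redistributed
half-and-half to its two parent beads (the chain rule of the midpoint
definition).  Two terms:

* Debye–Hueckel screened electrostatics,
  V = f z_i z_j exp(-kappa r) / (eps_r r), f = e^2/(4 pi eps0) =
  138.935 kJ mol^-1 nm, eps_r = 80, charges z = 0 (VN) and -1 (VG, VA, VS).
  kappa^-1 = sqrt(eps0 eps_r kB T / (2 e^2 N_A C_s)); at 150 mM and 300 K
  this is 0.795 nm.  Truncated (unshifted) at `cutoff_factor` Debye lengths,
  default 8 (3 reproduces the older three-site model's convention; the
  persistence length at low salt is underestimated there).
* WCA sterics: Lennard-Jones shifted up by eps_ij = 0.6276 kJ/mol and
  truncated at 2^(1/6) sigma_ij, sigma_ij = (sigma_i + sigma_j)/2 with
  sigma = 0.329 nm (VG) and 0.356 nm (VN/VA/VS).

Adjacent-monosaccharide site pairs interact by default (a flag excludes
them for comparison with the three-site reference model's convention).

Bead masses are not part of the published parameter set; we assign standard
residue masses (GCU 176.1, NAG 203.2, sulfated GalNAc 282.3 Da).  Under
Langevin dynamics every configurational observable is mass-independent, so
this choice affects kinetics and the mass-weighted R_g only (a geometric
weighting is available).

## Dynamics

BAOAB Langevin splitting, 300 K, friction 50 ps^-1 by default, no periodic
boundaries (one chain in open implicit solvent).  What every observable in
this package relies on is equilibrium configurational sampling, for which
BAOAB's timestep bias is small and well characterized; trajectories are
bit-reproducible for a fixed seed.  Virtual sites are never integrated —
their positions are recomputed from the parents at every evaluation.
Tabulated potentials are evaluated by C1 cubic Hermite interpolation of
(energy, nodal slope); nodal slopes are the centered finite differences of
the energy column (periodic-aware), which makes the tabulated force exactly
consistent with the energy column and the interpolated force the exact
derivative of the interpolated energy.  Angle tables span 0–180 degrees at
1 degree, dihedral tables are periodic on (-180, 180] at 7.2 degrees,
matching the histogram bins.

Energy minimization is plain steepest descent with an adaptive step and a
force-tolerance exit, used before every production run.

## Iterative Boltzmann inversion

Targets are per-DOF densities (1-degree angle bins, 7.2-degree dihedral
bins).  Measured histograms are smoothed by analytic fits before entering
the update: angles by a convex mixture beta·f_LN + (1-beta)·f_Gumbel of a
log-normal and a Gumbel density (bounded least-squares; bounds default to
positivity plus beta in [0,1]; on a poor fit the optimizer retries from the
target-fit parameters), dihedrals by periodic quadratic splines through the
bin heights, floored at a small positive value and renormalized.  The
update is

    V_{I+1} = V_I + alpha kT ln(P_I / P_target),    V_0 = -alpha kT ln P_target,

with both densities floored at 1e-8 deg^-1 inside the logarithm (so the
update is exactly zero at the fixed point and in unsampled regions), the
result shifted to min 0 and capped at a 50 kT wall.  alpha defaults to 0.2;
the original work states only that it lies between 0 and 1.  Convergence is
declared when the sup-norm between fitted and target densities stays below
0.005 deg^-1 for 3 consecutive iterations; five consecutive worsening
iterations abort with the history attached.  Nonbonded terms are off during
IBI.  Two presets: `paper` (40 ns per iteration, dt 1 fs, friction
50 ps^-1, recorded every 250 fs) and `fast` (2 ns, dt 2 fs, friction
5 ps^-1, recorded every 250 fs).  The fast preset lowers the friction
because equilibrium distributions are friction-independent while the
decorrelation time is proportional to it: at fixed run length this cuts the
fitted-PDF noise floor about threefold, keeping it safely below the
convergence threshold.

Two accuracy limits of IBI are worth stating plainly, because the test
suite is designed around them.  First, the recovered potentials can never
be more accurate than the analytic fit family: the log-normal/Gumbel
mixture carries an irreducible bias of order 0.5 kT (at densities above
1e-3 deg^-1) against exact chain angle marginals, and IBI converges to the
*fitted* target.  Second, once the GXGG coupling term (or the penalty) is
present, the per-DOF potentials are no longer uniquely determined by the
one-dimensional marginals — these terms are not tree internal coordinates,
so they correlate the other DOFs and open soft modes along which potentials
can drift while every marginal still matches.  The inverse-problem tests
therefore check potential recovery (0.5 kT for the bias-free dihedral
splines, 1 kT for angles, on well-sampled regions) on the well-posed
variant without coupling terms, and check distribution recovery (sup-norm
below 0.005 deg^-1 within 30 iterations) on the full five-DOF problem.

### Coupling-candidate ranking

For the dihedral pair sharing the window G_k..G_{k+2}, any bonded term that
involves both outer beads can couple them: the G–G bond, three angles and
three dihedrals per window (and the same for X_k..X_{k+2}).
`enumerate_coupling_candidates` lists them from the topology;
`rank_coupling_candidates` scores each candidate by the sup-norm of the
per-bin probability difference between the fine-mapped and coarse sample
sets (probability per bin rather than density, so bonds, angles and
dihedrals are comparable) and sorts descending.

## Fine-scale reference model

Three sites per saccharide — O_k (the glycosidic oxygen preceding
saccharide k, which *is* coarse bead k), and two carbons Ca_k, Cb_k — with
all internal DOFs stiffly harmonic except the glycosidic dihedral pair
psi_k (about Cb_k–O_{k+1}) and phi_k (about O_{k+1}–Ca_{k+1}).  The
supplied 2D potential V(psi, phi) of each linkage type is decoupled for MD
by converting to the Boltzmann joint P = exp(-V/kT), marginalizing,
re-inverting each marginal, and capping at 20 kT (a 40 kT uncapped maximum
leaves low-energy states unreachable on accessible timescales; 20 kT
reproduces the reference chain statistics).  Stiff spring constants default
to k_bond = 1.5e6 kJ mol^-1 nm^-2 and k_angle = 1e4 kJ mol^-1 rad^-2,
putting rigid-DOF fluctuations below 1% of the equilibrium value at 300 K;
the stiff bonds cap the usable timestep at 1 fs in this module.  Mapping a
fine trajectory to the coarse model is a strided slice over the oxygens;
dihedral samples at collinear triplets are dropped as missing rather than
propagated as NaN.  Virtual sites, when enabled on mapped coordinates, use
the midpoint-of-oxygens placement (the adopted simplification; the original
center-of-charge/geometry placement differs by about 1% in persistence
length and is not implemented).

The real geometry table and glycosidic 2D potentials are external
configuration.  The package ships a synthetic generator
(`make_synthetic_fine_params`) producing physically sensible stand-ins:
C–O bonds of 0.143 nm, tetrahedral-ish angles, and through-ring spans
solved numerically so the oxygen spacings reproduce the 0.56/0.49 nm coarse
bonds exactly; the 2D wells are seeded bimodal mixtures of correlated
wrapped Gaussians whose inverted marginals reach ~40 kT, so the 20 kT
capping path is genuinely exercised.  Synthetic parameters emulate the
geometry, stiffness separation and dihedral coupling of real GAG linkages;
they do not reproduce any published geometry table, so tests passing on
them validate the machinery, not the published force-field values.

## Synthetic fixtures and what passing tests show

* `CoupledTorusSpec` / `sample_coupled_dihedrals`: mixtures of correlated
  wrapped Gaussians on the (psi, phi) torus with exact grid densities —
  the stand-in for the reference model's joint dihedral statistics.
* `make_known_bonded_potentials`: a five-DOF bonded set with seeded well
  placement.  Dihedral wells are capped at 6 kT so that inter-well plateaus
  are crossed many times per nanosecond: recovery experiments require the
  relative well depths to be identifiable at desk-scale run lengths
  (with 20–25 kT caps the populations stay frozen at their initial values
  for any feasible run).
* `make_target_pdfs_from_known_potentials`: exact chain marginals — flat
  measure for torsions, sin(theta) volume element for bending angles — or
  sampled histograms, flagged by `exact`.
* `coupled_torus_demo`: the coupling-efficacy experiment.  The reference is
  the correlated torus mixture; the model matching only the psi and phi
  marginals is their product; candidates (the wrapped sum and difference)
  are ranked from samples; the top-ranked coordinate receives a potential
  refined by the IBI update on a grid-resolved Boltzmann model (the joint
  is computed exactly on the 7.2-degree grid each iteration).  Exact grid
  numerics make the measured deviation reduction a property of the method
  rather than of simulation noise.  For a positively correlated reference
  the difference coordinate wins and the sup-norm deviation of the joint
  drops by well over the 30% gate (~94% for the default two-component
  mixture with rho = 0.6).

## Analysis conventions

* Characteristic ratio C_N = <Ree^2> / (N l_b^2) with N the number of
  monosaccharides and l_b = 0.525 nm (the literal convention; an (N-1)
  bond-count denominator is available).  A straight N-bead chain at spacing
  l_b therefore gives C_N = (N-1)^2/N.
* Bond autocorrelation C(n) = < b_i.b_{i+n} / (|b_i||b_{i+n}|) >, averaged
  over frames and bond pairs; C(0) = 1 exactly.  Persistence length from a
  single-parameter least-squares fit of exp(-n l_b / l_p), default fit
  range n in [1, 20] (shrunk with a warning if C(n) goes nonpositive).
* R_g is mass-weighted by default (matching light-scattering comparisons);
  geometric weighting available.
* Ramachandran-type densities pair the GXGX dihedral at window k with the
  XGXG dihedral of the adjacent window sharing its last three beads; the
  pairing is a documented interpretation.  Densities are 2D histograms on
  (-180, 180]^2 at 7.2 degrees; `max_abs_deviation` is their sup-norm.
* Statistics discard the first 20% of frames by default; replica errors are
  standard deviations over replica simulations.
* The R_g–mass exponent comes from a log-log linear regression with a
  t-based 95% CI, fit on replica means.

## Problem sizes

The default test and acceptance runs use desk-scale protocols chosen for
statistical power: 1e6-step single-bond and 128-mer runs, five replicas of
1e4 recorded frames for the freely-jointed 64-mer, 2 ns per IBI iteration
on a 16-mer, three replicas for worm-like-chain and R_g-scaling fits.
Full-protocol presets (40 ns per IBI iteration at 1 fs) are provided for
production use.

## Known limitations

* Single chains only: no multi-chain systems, pressure coupling or replica
  exchange; no PME/Ewald electrostatics, explicit ions, hydrogen-bond or
  multivalent-ion terms (beyond the model's resolution).
* The published supplementary geometry tables and glycosidic 2D potentials
  are not redistributed; quantitative agreement with published chain
  statistics requires supplying them as configuration.
* IBI potential accuracy is bounded by the analytic fit family and, with
  coupling terms present, by the non-uniqueness of potentials given 1D
  marginals (see above).
* The GGXG extra coupling term is deliberately not implemented (it
  destabilizes the model for the gain it brings).
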