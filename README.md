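# gagcg

Coarse-grained modeling of glycosaminoglycan (GAG) chains at one bead per
saccharide, for people who need hyaluronic acid and chondroitin sulfate
chains with hundreds to thousands of monosaccharides — scales where
atomistic and even three-site-per-saccharide models are too expensive —
while keeping the chain statistics (characteristic ratio, persistence
length, radius of gyration) of the finer models.

Each monosaccharide is a single bead on a glycosidic oxygen; chains are GX
repeats (G before GlcUA, X before the amino sugar: N for HA, A for C4S, S
for C6S).  Bonds are harmonic (r0 = 0.56/0.49 nm, k = 8038 kJ mol⁻¹ nm⁻²);
angles and dihedrals carry tabulated potentials derived by iterative
Boltzmann inversion (IBI) against a fine-scale three-site reference model,

    V_{I+1}(φ) = V_I(φ) + α k_B T ln[ P_I(φ) / P_target(φ) ],  V_0 = −α k_B T ln P_target,

including an explicit GXGG *coupling dihedral* that restores the
correlation between adjacent backbone dihedrals lost in coarse-graining,
and an XGG *penalty angle* that keeps bead triplets away from 180° (where
the dihedral force is singular), allowing a 20 fs timestep.  Nonbonded
terms act on midpoint virtual sites: Debye–Hückel screened electrostatics
(κ⁻¹ set by the salt concentration) and WCA sterics.  Dynamics are BAOAB
Langevin (300 K, friction 50 ps⁻¹, implicit solvent), analysis covers
C_N = ⟨R_ee²⟩/(N l_b²), bond autocorrelation C(n) with the exp(−n l_b/l_p)
persistence-length fit, R_g and its mass-scaling exponent, and
Ramachandran-type joint dihedral densities.

See `docs/methods.md` for the model, conventions and limitations.

## Worked example

Build an HA chain, derive its bonded potentials by IBI against target
distributions (here generated from a known potential set, so the answer is
checkable), and demonstrate the dihedral-coupling machinery:

```python
from gagcg import build_gag_chain, run_ibi
from gagcg.fixtures import coupled_torus_demo, make_known_bonded_potentials, simulate_target_pdfs
from gagcg.potentials import ElectrostaticsParams, debye_length

print(f"Debye length at 150 mM, 300 K: {debye_length(ElectrostaticsParams(C_s=0.150)):.3f} nm")

chain = build_gag_chain("HA", 16)
print(f"HA 16-mer: {chain.n_beads} beads, {len(chain.bonds)} bonds, "
      f"{len(chain.virtual_sites)} virtual sites, "
      f"{len(chain.dihedrals)} dihedrals (incl. coupling), "
      f"{len(chain.penalty_angles)} penalty angles")

targets = simulate_target_pdfs(chain, make_known_bonded_potentials(0), seed=1234)
result = run_ibi(chain, dict(targets), alpha=0.2, max_iter=30, preset="fast", seed=5)
print(f"IBI converged: {result.converged} after {result.iterations} iterations; "
      f"worst PDF sup-norm {max(result.history[-1].values()):.4f} deg^-1")

demo = coupled_torus_demo(seed=0)
print(f"coupling candidate ranking: {[name for name, _ in demo.ranking]}")
print(f"joint-density deviation: {demo.deviation_uncoupled:.2e} -> "
      f"{demo.deviation_coupled:.2e} deg^-2 ({100 * demo.reduction:.0f}% reduction)")
```

Output (a few minutes; the IBI loop runs 2 ns of Langevin dynamics per
iteration):

```
Debye length at 150 mM, 300 K: 0.795 nm
HA 16-mer: 16 beads, 15 bonds, 15 virtual sites, 19 dihedrals (incl. coupling), 6 penalty angles
IBI converged: True after 12 iterations; worst PDF sup-norm 0.0034 deg^-1
coupling candidate ranking: ['diff', 'sum']
joint-density deviation: 9.87e-05 -> 6.21e-06 deg^-2 (94% reduction)
```

Reading the numbers: the screening length sets the electrostatic cutoff
(8 κ⁻¹ by default); the 16-mer has N−1 bonds/virtual sites, N−3 backbone
dihedrals plus one GXGG coupling dihedral and one XGG penalty angle per
eligible window; IBI drives every degree of freedom's distribution onto its
target within 30 iterations; and on the correlated-torus fixture the
top-ranked coupling coordinate (the wrapped dihedral difference) removes
~94% of the joint-density error that a marginals-only model leaves behind.

A command-line interface wraps the same machinery:

```sh
gagcg build --gag HA --n-mono 128 --out ha128.txt
gagcg fixtures --out-dir fx --seed 0        # synthetic fine-model parameters
gagcg reference --gag HA --n-mono 16 --out-dir targets   # fine-scale target PDFs
gagcg ibi --gag HA --targets-dir targets --out-dir ibi_run
gagcg simulate --config run.yml
gagcg analyze out/traj_seed*.npz --out stats.csv
```

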