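# dropletmd

Molecular dynamics of rigid TIP3P water droplets in uniform external
electrostatic fields, with mean-force and potential-of-mean-force (PMF)
analysis on fixed solutes.

## The problem

An external electrostatic field **E**^ext polarizes water. Polarized water
screens the Coulomb interaction between charged atoms, so a field strong
enough to approach dielectric saturation changes the *effective* interaction
between solutes — polar contacts (ion pairs, hydrogen-bond donor/acceptor
pairs) and hydrophobic contacts alike. This package reproduces that
computational study end to end:

* **Engine** — NVE dynamics of a spherical water droplet (no periodic
  boundaries): rigid three-site TIP3P (SHAKE constraints), leapfrog Verlet at
  2 fs, all-pairs Coulomb + Lennard-Jones (99 Å nominal cutoff, i.e. every
  pair in a ≤25 Å droplet), a half-harmonic boundary restraint at the droplet
  radius, a uniform external field **E**^ext (MV/cm) acting on every charge,
  and fixed solutes. Protocol per run: minimize, equilibrate with velocity
  rescaling to 300 K, then strictly NVE production saving frames every 20 fs.
* **Observables** — the per-water dipole *p* and net field *E*^net at the
  oxygens (uniform-field runs); radial profiles *p*(*r*), *N*(*r*),
  *E*^net(*r*) around a central ion (Δr = 0.1 Å); the solvent molecular
  polarizability ε₀γ_mol = d*p*/d*E*^net fitted in the linear-response window
  |*E*^net| < 25 kcal/(mol·eÅ).
* **Mean forces** — the net mean force on a tagged fixed solute S₂,
  decomposed exactly as F^net = F^E + F^S1 + F^solv, with
  F^E = Q₂E, F^S1 the direct Coulomb + LJ force from the partner solute, and
  F^solv the frame-averaged solvent force.
* **PMF pipeline** — distance scans (one independent droplet run per
  separation *d*), trapezoidal integration of −F from the largest separation
  inward (zero-force tail), the "second peak at zero" shift convention, the
  continuum point-charge superposition estimate
  F^est(d; E) = F(two_atoms; 0)(d) + F^net(one_atom; E), and the
  excluded-solvent residual F(two; E) − F(two; 0) − F^net(one; E).

Units are AKMA-like throughout: Å, kcal/mol, e, amu, ps; the Coulomb constant
is 332.0636 kcal·Å/(mol·e²) and 1 MV/cm = 0.23061 kcal/(mol·e·Å).

## Worked example

Mean-force decomposition on the +1 e member of a contact ion pair
(Q₁ = −1 e at (−1.5, 0, 0), Q₂ = +1 e at (+1.5, 0, 0)) in a 12 Å droplet:

```python
import dropletmd as dm

s1, s2 = dm.solute_pair(-1.0, +1.0, d=3.0)
cluster = dm.build_cluster(12.0, [s1, s2], seed=21)   # 240 waters
traj = dm.run(cluster, dm.FieldSpec.zero(), dm.EngineConfig.desk(), seed=21)
dec = dm.decompose(traj, s2=s2, s1=s1)
print(f"F_X = {dec.f_net[0]:.2f} +- {dec.sem[0]:.2f}")
print(f"F_S1 = {dec.f_s1[0]:.2f}, F_solv = {dec.f_solv[0]:.2f}")
```

prints (about 20 s on one CPU):

```
F_X = -3.76 +- 0.30
F_S1 = -34.15, F_solv = 30.39
```

The direct attraction of −34.15 kcal/(mol·Å) (Coulomb −36.90, LJ +2.75) is
screened by the solvent down to a net −3.8 kcal/(mol·Å) — the contact-well
depth of the ion-pair mean-force curve. The analysis drivers under
`analysis/` (`01_dipole_response.py` … `05_neutral_pair.py`) run the full
studies — dipole response, polarizability, parallel- and perpendicular-field
ion-pair scans, neutral-pair scans — and write their tables under
`results/`. A thin CLI (`dropletmd build|run|scan|analyze|pmf`) exposes the
same steps for shell use; `--profile full` switches any of them from the
desk scale to the full-scale protocol (20–25 Å droplets, 200 ps
equilibration, 1 ns production).

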