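# Methods

## Model

Water is rigid three-site TIP3P: charges −0.834 e (O) and +0.417 e (H), O–H
0.9572 Å, H–O–H 104.52°, LJ parameters ε_O = 0.1521 kcal/mol,
R_min/2(O) = 1.7682 Å, ε_H = 0.046, R_min/2(H) = 0.2245 (well depths stored
as positive magnitudes; the CHARMM convention prints them negative). The
rigid geometry fixes the molecular dipole at 2·q_H·b·cos(θ/2) = 0.4886 eÅ,
which is also the saturation value of the per-water mean dipole under a
strong aligning field.

Solutes are fixed monatomic LJ sites with a point charge; by default they
carry the TIP3P-oxygen vdW parameters. Pair LJ parameters follow the
standard combining rules ε_ij = √(ε_i ε_j), R_min,ij = R_min,i/2 + R_min,j/2.
The LJ convention engine-wide is U = ε[(R_min/R)¹² − 2(R_min/R)⁶] with force
(12ε/R)[(R_min/R)¹² − (R_min/R)⁶] along the separation vector.

Internal units: Å, kcal/mol, e, amu, ps. Coulomb constant
332.0636 kcal·Å/(mol·e²). External field magnitudes are specified in MV/cm
and converted once at the boundary: 1 MV/cm = 0.230605 kcal/(mol·e·Å)
(derived from SI constants; prints as 0.231 at 3 decimals). A uniform field
contributes force qE to every charge and energy −q E·r, so it is part of the
conserved total energy.

## Droplet construction (the synthetic-data generator)

Systems are spherical droplets, never periodic. The water count is
density-implied: N = round((4/3)πR³·0.0334 Å⁻³) minus one water per solute
(substitution). This number density uniquely reproduces the reference
molecule counts — 1119 waters at R = 20 Å, 2185 at R = 25 Å with one solute,
1117 at 20 Å with two — and gives 242 waters at the 12 Å desk scale.
Oxygens are placed by seeded random insertion with rejection (minimum O–O
2.4 Å; minimum O–solute 0.85·R_min,ij), each molecule then gets the rigid
internal geometry at a uniformly random orientation. Random insertion was
chosen over lattice carving to avoid crystalline artifacts surviving short
equilibrations; everything is deterministic given the seed. Two-solute
systems place the solutes at exactly (∓d/2, 0, 0).

What the generator emulates: bulk-density liquid droplets with embedded
fixed ions at controlled separations, the systems this study needs. What it
does not emulate: pre-equilibrated liquid structure (hence the explicit
minimize + equilibrate protocol), surface tension effects beyond the
restraint, dissolved counterions, or any macromolecular context — so passing
tests show the solvent response and mean-force machinery are right, not that
real biomolecular fields behave identically.

Initial velocities are Maxwell–Boltzmann at the target temperature with net
water momentum removed, relative velocities along the constraints projected
out, and an exact rescale to the target kinetic temperature (6 degrees of
freedom per rigid water).

## Dynamics

Leapfrog Verlet, dt = 2 fs, with SHAKE on the three distances of each water
(O–H, O–H, and the angle-implied H–H at 1.5139 Å). The SHAKE solver is the
matrix variant: per molecule, the three Lagrange multipliers are solved
coupled by a 3×3 Newton step each sweep, converging quadratically (3–5
sweeps to the default relative tolerance of 1e-8, versus ~30 for the
decoupled update; both converge to the same positions). Velocities are
recovered as (x(t+dt) − x(t))/dt after the constraint projection.

Nonbonded interactions are all-pairs Coulomb + LJ between atoms of distinct
molecules. The nominal 99 Å cutoff is honored literally: every pair in a
≤25 Å droplet interacts and no switching/shifting function is applied.

"Spherical boundary conditions" are a half-harmonic restraint on water
oxygens only, U = ½k(r − R)² for r > R with k = 2 kcal/(mol·Å²) (exposed in
`EngineConfig.boundary_k`). The restraint family matches droplet restraints
in common force-field codes; the original functional form and constant are
not recoverable, so results in the outermost layer should not be trusted —
the observables exclude it (below).

Protocol per run: steepest-descent minimization with adaptive step
(constraints re-imposed after every move), equilibration with velocity
rescaling to 300 K every 0.1 ps (a strictly NVE equilibration cannot reach a
target temperature), then strictly NVE production, frames saved every 20 fs
and energies logged every 0.2 ps. Solutes are held rigidly fixed — forces on
them are recorded, positions never updated — because the analysis needs the
mean force *at* a prescribed position. A blow-up guard aborts when the
kinetic temperature diverges.

Two schedules are provided. Desk scale (`EngineConfig.desk()`, the default):
12 Å droplets (~240 waters), 200 minimization steps, 10 ps equilibration,
50 ps production. Full scale (`EngineConfig.full()`): 1000 steps, 200 ps,
1 ns, intended for 20–25 Å droplets. All quantitative checks in the test
suite and the acceptance script use the desk scale; it reproduces the
full-scale headline numbers within the ±20% band used throughout.

### Mixed precision

The integrator's pairwise force sweep runs in float32 via a branch-free
full-N² kernel (intramolecular terms removed in a second pass); positions,
velocities, constraints, the boundary/field terms, energies, and every
observable use float64, and a float64 reference kernel backs the public
`compute_forces`. The float32 force error (~1e-7 relative) is far below
thermal noise; measured NVE drift at desk scale is ~3e-3 kcal/mol per DOF
over 10 ps, well under the 0.02 acceptance bound. `EngineConfig(precision=
"double")` selects the reference kernel inside the integrator for exactness
tests (momentum conservation, time reversibility).

## Observables

Uniform-field runs: p is the occupancy-weighted mean molecular dipole over
all saved frames and all waters whose oxygen lies within r_cut of the
origin; E^net is the external field plus the mean Coulomb field at those
oxygens from all atoms of other molecules (solutes included). Both are
reported as the component along the field axis. r_cut is not prescribed by
the protocol; the default is droplet radius − 4 Å, excluding the orientation-
distorted surface layer (exposed as an argument).

Charged-solute runs: radial profiles bin the oxygen distance with
Δr = 0.1 Å. Per bin, p(r) is the mean radial projection of the molecular
dipole and E^net(r) the mean radial field at the oxygen — the solute
point-charge term kq_j/r² plus the field from all atoms of other waters.
Bins never visited are NaN, not zero. The polarizability ε₀γ_mol is the
occupancy-weighted least-squares slope of pooled (E^net, p) bin pairs
(across solute charges, bins within radius − 4 Å) restricted to
|E^net| < 25 kcal/(mol·eÅ); the weighting reflects that each bin is an
average of N(r) observations.

Mean-force decomposition on S₂: F^E = Q₂E exactly; F^S1 closed-form
Coulomb + LJ at the fixed separation; F^solv frame-averaged over all water
atoms. The identity F^net = F^E + F^S1 + F^solv holds to machine precision
by construction. Standard errors come from block averaging of the per-frame
solvent force with 5 ps blocks (the other terms are constant).

## PMF pipeline

Scans run one independent droplet per separation (fresh build, fresh seed
spawned from the scan seed via `SeedSequence`). PMFs integrate −F by the
trapezoid rule from the largest separation inward with a zero-force tail
beyond it (curves have visibly decayed by 8 Å; the scans go no farther).
The zero of energy is placed at the "second peak": scanning from small d on
a lightly smoothed curve (0.4 Å moving average), the first local minimum is
the contact well and the next local maximum is the barrier out of it; that
barrier is set to zero, matching the escape-energy comparison the curves are
used for. Ties break toward smaller d; if no such peak exists the curve is
returned unshifted with a warning. The smoothing affects only peak
*identification*, never the reported curve or extrema values.

Scan extrema are reported as the raw minimum/maximum over the grid (no
smoothing), as the protocols define them.

## Numerical choices and degenerate inputs

* Overlapping atoms (any pair below 0.1 Å) are rejected with an error.
* Zero-water systems are legal (vacuum controls); the scan must then equal
  the closed-form direct force, which the tests assert to 1e-12.
* Empty radial bins are NaN; fits drop non-finite points.
* The slope fit through the origin (dipole response) and the windowed
  weighted fit (polarizability) both require ≥2 usable points and fail
  loudly otherwise.
* Seeds are spawned per run from one base seed and kept below 2³¹.

## Known limitations

* The droplet boundary constant and the equilibration thermostat details are
  this package's own choices (the protocol source states neither); near-edge
  structure and the first ~0.1 ps of equilibration are implementation-
  specific.
* Desk-scale mean-force values carry ~0.3–0.6 kcal/(mol·Å) sampling error at
  50 ps; extrema read off noisy grids are biased outward by selection. The
  ±20%/±0.5 tolerance band absorbs both.
* No electronic polarizability: the water model is fixed-charge, so the
  saturation dipole is geometry-capped at 0.4886 eÅ regardless of field.
* Droplets, not bulk: dielectric response differs from periodic bulk water,
  particularly within ~4 Å of the surface (excluded from averages).
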