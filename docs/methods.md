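# Methods

## The model

`capsidyn` implements a single-basin structure-based ("Gō-like")
potential: every stabilizing interaction is defined from one reference
conformation, which thereby becomes the global potential-energy minimum.
For capsid expansion studies the reference is the *expanded/mature*
shell and the simulation starts from the *compact* state, so expansion
and tail translocation occur spontaneously, rate-limited only by
sterics and configurational entropy — precisely the effects the model is
built to isolate.

Functional forms (reduced units; ε = 1 per contact is the energy unit,
lengths in nm, unit atomic masses):

| term | form | defaults |
|---|---|---|
| bond | ½ k_b (r − r₀)² | k_b = 2000 ε/nm² (atomistic), 200 (toy) |
| angle | ½ k_a (θ − θ₀)² | k_a = 40 ε/rad² (atomistic), 20 (toy) |
| rigid dihedral | k (1 − cos 2φ) | k = 10 ε; minima at 0°, 180° |
| flexible dihedral | k[(1 − cos Δ) + ½(1 − cos 3Δ)], Δ = φ − φ₀ | k set by the energy-ratio rule |
| native contact | ε[(σ/r)¹² − 2(σ/r)⁶] | σ = 0.95 · r_native; Gaussian well optional |
| excluded volume | ε_ev (a/r)¹², shifted to 0 at the cutoff | a = 0.25 nm, cutoff 0.6 nm |

Bond and angle *equilibria* come from a condensed, type-based
transcription of the Amber ff03 parameter set (backbone terms and the
common side-chain classes for all 20 standard residues); any term
without a tabulated value falls back to the reference geometry and the
fallback is logged.  For the coarse one-bead-per-residue toy chains
every bonded equilibrium is reference geometry by construction.  The
softer toy stiffnesses keep the strain energy released during
spontaneous expansion (the compact state is ~12% compressed relative to
the reference) small enough that the transient heating dissipates within
about one friction time.

Flexible-dihedral strength follows the usual structure-based
convention: the summed contact energy is twice the summed
flexible-dihedral energy (configurable ratio), distributed equally.

### Shadow contact map

A pair within the 0.6 nm cutoff is a native contact unless occluded: a
third atom whose centre lies within r_ij of atom i and within the
occluding radius (0.1 nm; shrunk to 0.05 nm for atoms covalently bonded
to either endpoint) of the segment i→j screens the pair.  Intra-chain
pairs closer than 3 residues in sequence, and all 1-2/1-3/1-4 bonded
pairs, are excluded.  The implementation is checked for exact set
equality against an independent brute-force occlusion oracle on seeded
random clouds.  The 0.95 scaling of the contact minima keeps the
radius-of-gyration minimum at the mature reference instead of
overshooting it; scaling composes multiplicatively if applied twice.

### Exclusions and bracing bonds

Excluded-volume exclusions are the 1-2/1-3/1-4 pairs of the covalent
graph, with one refinement: the 1-3/1-4 expansion walks only bonds
joining the same or adjacent residues.  Long-range *bracing* bonds
(used by the toy generator to stiffen rim rings and anchor ridges) are
restraints, not chemistry, and must not vaporize the excluded volume
around the atoms they join.  Atomistic covalent bonds always join
adjacent residues, so the refinement changes nothing for real
structures.  Angles and torsions are likewise enumerated only along
same/adjacent-residue bonds.

## Integration

Langevin dynamics uses the BAOAB splitting of velocity Verlet: half-kick,
half-drift, Ornstein–Uhlenbeck velocity update (exact for the chosen
friction), half-drift, force evaluation, half-kick.  With friction = 0
the O-step is the identity and the scheme reduces to symplectic velocity
Verlet; energy conservation in this limit is asserted at dt = 0.0005 to
1e-4 relative over 10⁴ steps.  Defaults: reduced temperature 0.582
(production), 1.0 (tail generation), dt = 0.002, friction 1.0 (exposed
in the config; the kinetics, not the equilibrium, depend on it).

Excluded volume runs over a Verlet neighbour list (skin 0.25 nm)
rebuilt by the half-skin maximum-displacement criterion, built with a
cell grid.  The kernel energies agree with the list-free reference
evaluation to 1e-10, forces were validated against finite differences
of the reference energy, and all kernels are single-threaded, making
trajectories bit-reproducible for a given seed on one machine.
Non-finite coordinates abort the run with the step number.  The torsion
force is skipped (energy kept) when an internal bond angle is within
sin²θ < 1e-3 of collinear, where it is numerically undefined; this can
only occur for coarse bead chains far from their reference geometry.

Disordered tail ensembles are produced by the restrained protocol: all
non-tail atoms harmonically restrained (default k = 500 ε/nm²), reduced
temperature 1.0, samples taken at a fixed stride after an equilibration
stride; a warning is recorded if the stride is shorter than the measured
tail-R_g autocorrelation time.

## Observables

Q_i is the formed fraction of the mature-specific *intermolecular*
contacts of chain i's terminal tail (formed: r < 1.5 · r_native; the
denominator scope is configurable to include intramolecular tail
contacts).  Translocation is the first passage of Q_i ≥ 0.8, inclusive,
without hysteresis (an optional dwell requirement exists for noisy toy
systems, default off).  Counts per position class are accumulated over
the run ensemble; N_i(t) step curves get ensemble mean and sample SD
(n−1).  Q probability distributions are normalized histograms (50 bins
by default) computed after discarding each run's expansion phase (first
time R_g reaches 95% of its plateau); peaks are local maxima above 2%
of the modal bin, classified endpoint (Q < 0.2 or > 0.8) versus
intermediate.  Because a toy tail has only ~5–15 contacts, Q is
discrete; histograms of toy ensembles should use bins wider than
1/n_contacts (the canned experiment uses 8) or the comb of allowed
values masquerades as peaks.

## The toy shell generator

The generator emulates the statistical and steric structure the
analysis assumes, not capsid geometry: a closed quasi-uniform spherical
bead mesh (Fibonacci spiral, spacing ~0.38 nm, with a deterministic
coverage-repair pass so no wall spot is farther than 0.25 nm from a
bead), partitioned into chains by Voronoi patches around quasi-uniform
chain centres.  Per chain:

- a circular hole punched at the patch centre, rimmed by a closed,
  braced bead ring of radius w — the class-specific **cavity
  half-width**, realized as a steric gap;
- a terminal tail (default 4 beads) attached at the rim through the
  serial backbone, helically draped on the interior in the compact
  state (a deterministic relaxation pass removes inter-tail clashes)
  and threaded/exterior in the expanded reference;
- an **anchor ridge**: an elevated bead row flanking the exterior tail
  path.  The proximal section belongs to the chain itself and forms the
  intramolecular zipper that drives threading; the distal section lies
  past the patch boundary, belongs to the neighbouring chain, and is a
  double-decker row with a tip cap — these are the mature-specific
  intermolecular contacts that define Q and translocation.

Three design constraints matter and are deliberate:

1. **Side safety.** The toy wall is one bead thick, so any anchor that
   a tail could approach from the interior within 1.5 · r_native would
   make Q formable without translocation.  All beads that can carry
   intermolecular contacts therefore sit at height 0.70 nm above the
   wall, beyond formed-range from the interior.
2. **Bare gates.** Native contacts between a tail and its own rim would
   disarm the steric gate exactly where it should bite (the LJ well
   replaces the excluded-volume wall).  The generator therefore strips
   all tail–throat contacts through a contact filter passed to
   `build_topology` — the throat is pure excluded volume.
3. **Independent lanes.** Tail paths are offset 0.31 nm from the
   centre-to-centre geodesic with an antisymmetric sign convention, so
   mutually-targeting tails neither collide nor share native contacts
   (their separation, 0.62 nm, exceeds the contact cutoff), keeping
   per-chain Q independent.

Position-class labels are assigned to sphere sites by a seeded balanced
shuffle, so site-specific geometric quirks average out across replicate
shells instead of confounding class comparisons.

The default width tables sit in the regime where the excluded-volume
cost of a bead passing the rim varies steeply with w (≈3 ε at 0.28 nm
down to ≈0.01 ε at 0.50 nm), so rim sterics are rate-limiting; the
default table mirrors the qualitative ordering observed for the real
capsid (E > D > C ≈ F ≈ G ≈ B > A) as a testable construction, and a
strictly ordered table is provided for rank-correlation experiments.
These widths, like the shell size (7 classes × 3 chains, ~40
residues/chain, ~1030 pseudo-atoms, radii 2.24 → 2.55 nm preserving the
25:28.5 ratio), were calibrated once while designing the generator so
that a 130k-step production window resolves the hierarchy on a single
CPU, and are fixed.

"Kinked" classes realize an occluded exit route as a tight collar ring
(radius 0.26 nm) around the path that replaces one distal anchor
station; the tail must thread it mid-route after forming part of its
intermolecular contacts, producing a long-lived intermediate at partial
Q.  Collar beads are contact-stripped like the throat.

**What passing toy tests does and does not show.**  The toy shell
reproduces the *structure* of the real problem — a closed steric wall,
interior-to-exterior first-passage through class-specific constrictions,
intermolecular native contacts attainable only after passage — so green
tests demonstrate that the force field, integrator and analysis
faithfully implement the model and can resolve steric rate hierarchies
and intermediates.  They do not show that toy kinetics quantitatively
match the real capsid's event counts or timescales, which require the
10⁶-atom system; the toy makes no claim of icosahedral T=7 geometry,
real sequence, or shared two-tail cavities.

## Numerical and design choices

- Coordinates are nm internally; PDB Å are converted on read/write.
  Residue numbering is taken verbatim from the input file.  First
  altloc kept; insertion-coded atoms dropped with a warning.
- PDB output is limited to single-character chain ids (format column
  width); multi-chain assemblies round-trip through the plain
  tab-separated dialect instead.
- The real tail is described as residues 1–23 when generating disorder
  but 2–25 (Ala2–Leu25) in the Q definition; both intervals are
  configurable and the defaults follow that split (tails annotated per
  chain; analysis takes an optional override).
- Angles with near-collinear reference values (outside 10–170°) carry
  no angle term; they arise only in coarse bead chains.
- Seeds: every stream (toy geometry, tail generation, each production
  run) derives from one master seed via named seed-sequence splitting
  (CRC32 stream tags), all below 2³¹.
- The expanded reference is not an exact stationary point when the
  contact minima are scaled by 0.95 (contacts pull slightly inward);
  it is nevertheless a local minimum in the practical sense asserted by
  the tests: random 0.01 nm/atom perturbations strictly raise the
  energy, because the quadratic bonded terms dominate the small linear
  contact term in any random direction.

## Known limitations

- Single-basin only: no multi-basin stabilization of compact and
  expanded states simultaneously, no electrostatics, no solvent or DNA,
  no hydrogen atoms.
- Reduced time units are not mapped to physical time.
- The condensed ff03 table covers backbone and common side-chain bonded
  classes; exotic terms fall back to reference geometry (logged).
- Toy translocation statistics are ensemble-scale observables;
  individual toy event counts carry Poisson noise of a few events per
  class at the default problem size.
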