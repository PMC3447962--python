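# Methods

## The forcefield

`saxsbm` builds an all-atom (heavy-atom) structure-based model whose
global energy minimum is the input structure.  With r, θ, ξ, φ the bond
lengths, bend angles, improper and proper torsions, and r₀, θ₀, ξ₀, φ₀
their values in the native structure:

| term | form | parameter (reduced units) |
|---|---|---|
| bond | ε_r (r − r₀)² | ε_r = 100 / Å² |
| angle | ε_θ (θ − θ₀)² | ε_θ = 20 / rad² |
| improper / rigid torsion | ε_ξ wrap(φ − φ₀)² | ε_ξ = 10 / rad² |
| flexible torsion | w·[(1 − cos Δφ) + ½(1 − cos 3Δφ)] | w from normalization |
| native contact | ε_C [(r₀/r)¹² − 2(r₀/r)⁶] | ε_C from normalization |
| excluded volume | ε_nc (σ_nc/r)¹² | ε_nc = 0.01, σ_nc = 2.5 Å |

Native contacts are selected by the shadow criterion: a pair is a contact
iff (a) its native distance is < 6 Å, (b) the atoms are ≥ 4 residues apart
in sequence (pairs on different chains always qualify), and (c) no third
atom — itself within the cutoff of both partners — passes within 1 Å
(the shadowing radius) of the open line segment between them.  The
screening test operationalizes "no atom between them" as a perpendicular-
distance condition; 1 Å is the conventional shadowing radius for all-atom
maps.  The sequence rule is read as |Δresidue| ≥ 4.

Stabilizing energy is normalized to N_atoms·ε (ε = 1 reduced unit), split
2:1 between contacts and flexible torsions and uniformly within each
class; one torsion per central bond is eligible for weight (the rest are
redundant parameterizations of the same rotation).  If either class is
empty the whole budget goes to the other.

**Domain decoupling.**  Every contact whose atoms carry different domain
labels is removed, linkers counting as their own label, so linker–domain
contacts go too — this maximizes linker freedom, leaving only steric
repulsion between domains.  Flexible torsions with any linker atom carry
zero weight.  Torsions are classified hybridization-rigid when their
central bond lies in a ring or is an inter-residue C–N (peptide ω) bond;
rigid torsions are restrained harmonically everywhere, including linkers.

**Connectivity** is inferred from interatomic distances with per-element
covalent radii (bond iff d < 1.25·(rᵢ+rⱼ); S–S capped at 2.3 Å so
disulfides are found without spurious S···S bonds).  One rule covers real
PDB inputs and the synthetic bead-chain toys alike; an atom with no
bonding partner is reported as uninterpretable chemistry.  Impropers are
placed at every branch center (≥ 3 neighbours), which maintains local
chirality and planarity at the native values.

## Sampling

Langevin dynamics with the BAOAB splitting of velocity Verlet; unit
masses (the SBM convention — reported radii of gyration always use real
atomic masses), dt = 5·10⁻⁴ reduced time, snapshots every 0.5 time units
(the native protocol is 20,000 time units → 40,000 candidates).  The
thermostat temperature and friction are not prescribed by the model;
defaults are T = 1.0 and γ = 1.0 in reduced units — a near-native-basin
sampling temperature — and both are exposed in the configuration.  With
γ = 0 the integrator is plain (symplectic) velocity Verlet; the test
suite checks equipartition of a harmonic dimer to 5% and total-energy
drift < 10⁻³ of the contact-energy depth over 10⁵ NVE steps.  Excluded
volume acts on all atom pairs except bonded 1-2/1-3/1-4 neighbours and
native-contact pairs; the pair list is static (all pairs), which is exact
and cheap at the system sizes this package targets (≲ 10³ atoms).  The
force loop and integrator are numba-compiled; the numpy implementation of
the same potential is the documented API and the reference the kernels are
tested against.  Thermostat noise is pre-drawn from numpy's seeded
generator, so trajectories are bit-reproducible for a given seed.

Scaled-down protocol sizes used by the tests and the acceptance script
(chosen so the whole suite stays interactive): two-domain 70-atom system,
250 time units (500 snapshots) for the sampling-breadth check; the
discrete-state library for ensemble analysis has 300 members.

## Scattering

Theoretical profiles use the exact Debye double sum with 5-Gaussian
(Cromer–Mann) vacuum form factors; an optional excluded-solvent mode
subtracts a Gaussian dummy-atom term ρ·V·exp(−q²V^{2/3}/4π) per atom
(ρ = 0.334 e/Å³, Fraser–MacRae–Suzuki volumes).  No hydration-shell
contrast layer is modelled: at the momentum transfers this workflow uses
(q ≤ 0.18 Å⁻¹, 100-point default grid) the Debye sum is exact for the
atomic model, and the χ² scale fit absorbs the residual overall-intensity
difference a shell model would contribute.  The q = 0 limit is taken
analytically.  The optimized (vectorized, chunked) sum is tested against
a literal double loop to 10⁻¹⁰ relative.

Guinier analysis fits ln I against q² by error-weighted least squares over
a self-consistent low-q window, iterating q·Rg ≤ 1.3 from a seed window of
the lowest 15% of points until stable; a non-negative slope or an
under-populated window is an error, not a number.  The Kratky transform
is I(q)·q² on the unchanged grid.

## Ensemble analysis

χ² is the reduced, error-normalized discrepancy with a closed-form fitted
multiplicative scale (simulated intensities are on an arbitrary scale; an
additive background term is deliberately not fitted).  The candidate
filter keeps the ⌊fraction·N⌋ lowest-χ² conformations (default 5%), ties
broken toward earlier frames.  P(Rg) uses 0.25 Å bins aligned to
multiples of the bin width (so nested subsets land on comparable grids)
and peak detection with a prominence threshold of 5% of the tallest bin.
A peak's membership window is the contiguous run of bins above half its
height.  Representatives are chosen greedily by increasing χ² inside each
of the top-3 peaks' windows, skipping any conformation within 2 Å
superposed RMSD of one already selected anywhere; a peak that cannot fill
its quota yields a smaller group (with a warning), and an empty group is
dropped.  The weight grid is exactly wᵢ = 0.1·n enumerated in integer
arithmetic (the last component is stored as the exact complement so each
vector sums to 1.0 bit-exactly); zero weights are allowed, since a state
may be absent from a condition.  The combination search evaluates every
one-per-peak choice (4×4×4 = 64 with the defaults) times every weight
vector (66 for three members) and returns the global minimum, ties going
to the lexicographically smallest weight vector.

## Synthetic data: what it emulates and what it does not

The toy structures are compact self-avoiding clusters (bonds ≈ 1.5 Å,
non-bonded floor 2.2 Å) joined by extended linkers, one residue per atom.
Defaults — 3 domains × 60 atoms, 16-atom linkers, hinge angles up to
±2.5 rad — were chosen once so that the conformer family's relative Rg
span, (max−min)/mean ≈ 0.57, matches the compact↔extended span a flexible
three-domain kinase shows in solution; with a much smaller span the
members of a mixture would be indistinguishable at q ≤ 0.18 Å⁻¹ and no
selection method could recover weights.  Mock curves are noisy mixtures
with σ(q) = 0.01·I(q)·(1 + 3·q/q_max): 1% multiplicative noise whose
linear q-inflation reproduces the error growth of real detector data at
high angle.  Not emulated: real folds, buffer-subtraction artifacts,
interparticle structure factors, radiation damage, or correlated noise —
so a passing synthetic test demonstrates the correctness of the machinery
and the identifiability of well-posed mixtures, not robustness to every
systematic error of a beamline.

Two conformer generators serve different roles.  `conformer_family`
(hinge mode) rotates everything downstream of each linker rigidly about a
random axis, producing a family ordered by strictly increasing Rg that
brackets the input structure — between-state diversity.
`domain_rotation_jitter` rotates each domain about its own centroid:
because domain centroids are preserved, frames are RMSD-distinct (Å
scale) while their scattering curves barely move — within-state thermal
diversity, which is how one conformational population looks to SAXS.

## Closure: design and identifiability

The end-to-end recovery test plants a three-state mixture
(0.5/0.3/0.2, 1% noise) and requires the whole chain — score, filter,
P(Rg) peaks, representatives, grid search — to return the generating
states and weights in ≥ 95% of noise realizations.  Two facts shape its
design, both reproducible with this package:

* On a *smooth* pool (a continuum of hinge conformers), the lowest-χ²
  survivors of a mixture curve collapse onto intermediate-Rg conformers —
  the single-conformer χ² optimum — so a stringent filter hides the true
  components.  This is a property of the inverse problem, not a bug; it
  is why pool-selection studies inspect P(Rg) populations rather than
  trusting single best fits.
* The weight-grid assignment between two states is well-conditioned only
  when within-state curve variation is small compared with one grid step
  times the between-state curve difference.

The closure test therefore uses a pool that is a *library of discrete
candidate states* (3 anchors × 100 domain-rotation samples) and a filter
fraction of 0.7 — above 2/3, so every state provably survives the rank
filter — and then demands exact per-state weights.  The stringency of the
low-χ² filter itself is validated separately: filtering the same pool at
2.5%, 5% and 7.5% must leave every P(Rg) peak within one bin.

## Known limitations

* The torsion potential's cosine form and the 2:1 contact:torsion energy
  split follow the standard all-atom SBM convention; other splits would
  change sampling temperature scales.
* Connectivity by covalent radii can mis-bond exotic chemistry (metal
  sites, modified residues); a user-supplied contact map and topology
  JSON provide the escape hatch.
* The Debye sum is O(N²·N_q) per conformation — appropriate up to a few
  thousand atoms; no coarse-graining or sampling approximation is
  implemented.
* Weight uncertainty is not estimated; the grid search returns a point
  estimate, and continuous-weight methods (NNLS, Bayesian reweighting)
  are out of scope.
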