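# Methods

This note documents the models implemented in `graphdock`, the defaults
and why they were chosen, what the synthetic test systems do and do not
show, and the package's known limitations.

## Carrier lattice and the 168-atom calibration

Pristine sheets are cut from an ideal honeycomb lattice with aromatic C–C
bond length 1.42 Å, laid in the z = 0 plane.  The lattice convention is:
one hexagon centre at the origin, the central hexagon's vertices at
angles 30° + 60°·k.  A circular cut keeps every carbon whose distance
from the origin is at most the requested radius; carbons left with fewer
than two carbon neighbours are pruned iteratively, and each remaining
two-coordinate edge carbon receives one in-plane hydrogen (C–H 1.08 Å).
Under this convention the 21.760 Å circle contains 138 ring carbons and
30 edge hydrogens — 168 atoms, hydrogens included.  Rectangular cuts use
the same lattice and termination with an axis-aligned window.

All carbons of a pristine sheet are typed aromatic (`C.ar`) and all ring
bonds aromatic.  The sheet is a molecule, not a periodic slab: edge
effects are physical at these sizes and are the reason the screening
filter rejects ligands longer than the carrier diameter.

## Functionalization and aromaticity bookkeeping

GO models are produced by grafting, onto a pristine sheet:

- **hydroxyl** (–OH) on a basal-plane carbon,
- **epoxy** (–O–) bridging two bonded basal-plane carbons,
- **carboxyl** (–COOH) replacing an edge hydrogen,

in the requested counts.  Basal groups go on the upper, lower, or both
surfaces; placements are drawn without replacement from a seeded RNG
(`random` manner) or enumerated lexicographically (`systematic` manner).
Carbons bearing a hydroxyl or epoxy are re-typed sp³ and their ring bonds
demoted to single bonds, removing them from the π system; the edge carbon
bearing a carboxyl stays aromatic.  π bookkeeping is deliberately simple:
one π electron per conjugated aromatic carbon, so a model with c aromatic
carbons has π count c, satisfies the 4n+2 rule iff c ≡ 2 (mod 4), and is
π-connected iff the graph induced by its aromatic bonds has one component.

Every emitted model must keep a connected π system; candidates that
fragment the aromatic network (or repeat an earlier fingerprint) are
rejected and regenerated.  The 4n+2 count is *reported*, not enforced, by
default: grafting N hydroxyls and N epoxies removes exactly 3N π
electrons, so the count's residue mod 4 is fixed by N and cannot be
repaired by re-placement — an ensemble spanning N = 1..5 necessarily
contains non-4n+2 members.  Callers who need strict Hückel compliance set
`FunctionalizationSpec(require_hueckel=True)`.

Duplicate removal follows fingerprint equality only: two models are the
same carrier iff their 2048-bit radius-5 Morgan (ECFP-style) fingerprints
match.  The fingerprint is computed on the molecular graph, so rigid
rotation, translation and atom renumbering cannot distinguish models;
fingerprint collisions between genuinely different graphs are accepted as
duplicates, which at 2048 bits is a negligible risk for this family of
structures.

## Force field

Functional forms follow the Tripos 5.2 force field:

| term | form | notes |
|---|---|---|
| bond | k (r − r₀)² | k in kcal/mol/Å² |
| angle | k (θ − θ₀)² | θ in degrees, keyed by the centre atom's type |
| torsion | V/2 (1 + s cos nφ) | keyed by the central bond's types |
| out-of-plane | k d² | d = distance of an sp² centre from its substituent plane |
| van der Waals | ε[(R/r)¹² − 2(R/r)⁶] | R = Rᵢ + Rⱼ, ε = √(εᵢεⱼ); pairs > 2 bonds apart |
| electrostatic | 332.0637 qᵢqⱼ / (4r·r) | distance-dependent dielectric ε(r) = 4r |

1–4 pairs are scaled by 0.5 (van der Waals and Coulomb); no cutoff is
applied at the system sizes this package targets.  Partial charges are
Gasteiger (iterative electronegativity equalization, via RDKit), summing
to the total formal charge within 10⁻⁶ e; spin multiplicity is reported
as 1 throughout (ground-state models).  The embedded parameter table
(`data/tripos_ff.yaml`) covers the atom types the builder and fixture
catalogue emit; missing bonded parameters fall back to documented
defaults with a logged warning, while a missing van der Waals entry is an
error because the nonbonded terms carry the physics of adsorption.

**Aromatic-carbon radius.**  One parameter deviates from the published
Tripos table.  Summing 6-12 interactions over a lattice plane moves the
energy minimum well below the pairwise optimum R\* (for a continuum plane
the minimum sits at (2/5)^{1/6} R\* ≈ 0.86 R\*), so the textbook 1.70 Å
carbon radius would stack benzene ~3.0 Å above a graphene patch.  The
`C.ar` radius is therefore set to 1.90 Å, which places the plane-summed
stacking optimum at 3.36 Å — the graphitic interlayer spacing — while all
other radii keep their Tripos values.

During pose search the carrier is rigid and the ligand's bond lengths and
angles are fixed by construction (only torsions, rotation and translation
change), so the bonded terms of both fragments are constants; they are
still included in the reported totals, and the binding energy
E_Δ = E_GDDS − E_G − E_lig reduces exactly to the intermolecular
nonbonded sum.  The idealized 1.42 Å sheet therefore carries a constant,
positive internal strain relative to the 1.395 Å aromatic reference bond
length; this offsets E_GDDS but cancels in E_Δ and cannot change which
pose wins.

Minimization is derivative-free Powell over Cartesian coordinates
(SciPy's direction-set implementation) with a golden-section line search,
default energy tolerance 10⁻⁴ kcal/mol; the per-iteration energy trace is
non-increasing and the final energy never exceeds the initial one.

## Pose encoding and the quantum genetic algorithm

A pose is the real vector (τ₁..τ_T, t_x, t_y, t_z, q₁..q₄): one torsion
per freely rotatable bond (single, acyclic, between heavy atoms,
excluding amides and bonds whose rotation only permutes equivalent
terminal atoms such as methyl or hydroxyl), a displacement of the ligand
centroid, and a quaternion applied about the centroid.  Bounds: torsions
[−π, π); translation inside the carrier's bounding box expanded by 10 Å
in x/y and spanning ±8 Å in z; quaternion components raw in [−1, 1],
normalized on decode (the all-zero quaternion decodes to the identity
rotation).  Each variable is linearly quantized to 16 bits by default
(torsion resolution 2π/65536); encoding and decoding agree within half a
quantization step.

Each bit is a qubit θ with (α, β) = (cos θ, sin θ), so α² + β² = 1 holds
identically under every operator.  Fresh qubits start at θ = π/4
(unbiased superposition).  Measurement draws u ∈ [0, 1) per qubit and
collapses to bit 1 iff u < |cos θ|²; the opposite polarity is available
as a configuration switch because conventions differ in the field.

Operators, applied once per generation:

- **Rotation gate (QRGO)**, probability 0.5 per chromosome: each qubit
  rotates by Δθ looked up from (own bit, best-archived bit, own fitness ≥
  best fitness).  The shipped schedule (`data/delta_theta.yaml`) uses 0 on
  agreement, 0.05π toward the best bit when the chromosome is worse, and
  0.01π reinforcing its own bit when it is better; the sign is chosen so
  the measurement probability moves toward the target bit, with a random
  direction at the stationary points so fully collapsed qubits can
  escape.  The schedule is an editable table because published variants
  of this lookup differ.
- **NOT gate (QNGO)**, probability 0.1 per qubit: (α, β) → (β, α), i.e.
  θ → π/2 − θ.  An involution with fixed point π/4.
- **Crossover**, probability 0.7 per adjacent pair: single-point exchange
  of θ segments after a uniformly drawn cut; the θ multiset of the pair
  is conserved.
- **Catastrophe**: when the average fitness changes by less than the
  convergence threshold (default 0.001) for 50 consecutive generations,
  every qubit in every chromosome is reset to π/4.  The best-so-far
  chromosomes live in an external archive (default size 10) and survive
  catastrophes, so the best fitness trace is non-decreasing.

Termination: at the generation cap, or — when the convergence check is
enabled — after the same flat-average condition holds for a longer window
(default 100 generations, configurable separately from the catastrophe
window).  Fitness is −E_GDDS by default or −E_Δ in `binding` mode; with a
rigid carrier the two orderings coincide up to constants.  A fixed seed
makes runs bit-identical; fitness values are memoized per bit string,
which is safe because every engine is deterministic.

## Cascade protocol and seeding

A cascade is an ordered list of (engine, QGA-parameter) layers.  The
default two-layer protocol runs the force-field layer with fine
parameters (5000 generations, population 100, catastrophe on, convergence
check off — it should keep producing diverse optima) and the
high-accuracy layer with coarse parameters (500 generations, population
20, catastrophe off, convergence check on).  The ten best bit strings
migrate forward and are re-scored by the new engine; if the layers'
quantizations differ the strings are decoded, clipped and re-encoded.

A migrated bit string becomes a qubit chromosome through the seeding bias
ε (default 0.05): θ is set so the qubit re-measures its source bit with
probability 1 − ε.  ε = 0 freezes the seed; ε = 0.5 erases it.  The
default keeps the seeds near-deterministic while leaving room for
exploration around them.

External engines are invoked through a command template with `{input}` /
`{output}` placeholders; geometries are written as XYZ with the total
formal charge and multiplicity 1 in the comment line, energies are parsed
by a configurable regex and converted to kcal/mol (hartree, eV and kJ/mol
factors built in).  The binding energy always comes from three runs:
complex, carrier, ligand.  No specific quantum-chemistry package is
wrapped or required; the test suite substitutes mock engines.

## Screening

Library filters mirror standard practice for graphitic carriers: keep
ligands whose computed logP (Crippen atomic contributions) exceeds the
threshold (default 5.0 — strongly hydrophobic molecules are the relevant
cargo) and whose longest intramolecular distance fits within the carrier
diameter.  The size rule compares against the full diameter, which is
geometrically permissive for a molecule lying across the centre; it is
kept as the conventional, simple criterion.  Each surviving ligand is
docked `repeats` times (default 3, seeds S, S+1, S+2) and records are
ranked by the average best-pose binding energy, ties broken by ligand id;
failed ligands are flagged and ranked last, never dropped.

## Synthetic test systems

The fixture catalogue (benzene, n-butane, biphenyl, methanol, methane,
naphthalene, a 7-ring coronene-like patch, a one-hydroxyl GO patch) is
generated deterministically from SMILES templates (seeded ETKDG
embedding) and the lattice builder.  These systems exercise every code
path — typing, charges, rotatable-bond detection, π bookkeeping,
fingerprinting, docking — at sizes where independent oracles (brute-force
enumeration, rigid-body grid scans, analytic minima) are exact.  They do
not emulate real drug-scale ligands: conformational entropy, solvation,
and the flexibility of a large GO sheet are outside the model, so passing
tests demonstrate the correctness of the machinery, not the accuracy of
predicted binding energies for pharmaceutical systems.  Problem sizes in
the test suite (patches of 24–138 carbons, populations of 20–60, hundreds
of generations) were chosen as the smallest systems on which each
property is decidable.

## Numerical choices and degenerate cases

- Lattice vertex merging uses a 10⁻⁶ Å rounding key (distinct sites are
  ≥ 1.42 Å apart).
- The all-zero quaternion decodes to the identity rotation.
- Equal best fitness is tie-broken by earliest generation, then lowest
  chromosome index; the archive keeps the first sighting of a bit string.
- Gasteiger residual charge (numerical, ≲10⁻⁸ e) is spread uniformly so
  sums are exact to 10⁻⁶ e.
- Angle bending uses a clipped arccos; torsions with a degenerate central
  axis contribute zero.
- Powell returns the initial geometry unchanged if no iterate improves
  the energy.

## Limitations

- The internal force field has a minimal parameter table; exotic atom
  types fail fast rather than silently extrapolating.
- The carrier is rigid during pose search and ligand bond lengths/angles
  are frozen; only torsions, orientation and position are searched.
- No periodic boundary conditions, implicit solvent, or analytic
  gradients in the internal engine; solvation enters only through
  external engines.
- GO chemistry is limited to hydroxyl/epoxy/carboxyl; carbonyls, amines,
  lattice vacancies and basal carboxyls are not modelled.
- Quantum-computer execution of the qubit population is out of scope; the
  algorithm is a classical simulation of quantum-inspired operators.
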