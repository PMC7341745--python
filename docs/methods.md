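# Methods

## Scope and intent

pdzdesign implements a complete fixed-backbone sequence-design pipeline at
desk scale.  The claims it supports are structural and algorithmic — exact
pairwise decomposition of the NEA energy, detailed balance of the sampler,
correctness of the filter bookkeeping, parameter recovery of the DSF fits —
not force-field accuracy.  Absolute energies produced by the packaged
parameter set are not comparable to experiment; only differences and
rankings within a run are meaningful.

## Scaffolds and geometry

Synthetic scaffolds are built by internal-coordinate (NeRF) construction
from standard peptide covalent geometry (N–CA 1.458 Å, CA–C 1.525 Å,
C–N 1.329 Å, C=O 1.231 Å, omega = 180°), with phi/psi presets
helix (−57°, −47°) and strand (−139°, +135°); hairpins insert a fixed
two-residue turn at the apex.  Backbones are ideal by construction, so
build-then-measure tests can demand 1e-3-degree agreement.  Real structures
are read from PDB files (first model, first chain, altloc "A"/blank,
insertion codes rejected) through biotite, with explicit validation of the
four backbone atoms per residue and chain connectivity (C–N < 2 Å).

Side chains are united-atom heavy atoms plus polar hydrogens (amide H,
hydroxyl/thiol/amine/guanidinium/imidazole H).  Histidine uses a single
neutral tautomer (proton on NE2).  Each side-chain atom is placed from a
packaged internal-coordinate table (bond, angle, fixed or chi torsion)
derived once from ideal residue templates and frozen as text; chi torsions
measured on built side chains reproduce the request to < 1e-6 degrees.
Proline's ring is built from a single fixed pucker; ring closure is
approximate (the CD–N bond is treated as a constraint of the bond graph
only), which is acceptable because proline never mutates and only native
prolines occur.

The rotamer library is deliberately coarse and backbone-independent:
canonical gauche−/trans/gauche+ wells, 1–9 rotamers per type (chi2/chi3 of
long side chains partially fixed at trans to stay within 9).  This is a
library choice, not a claim about any particular published library;
backbone-dependent rotamers are a known possible refinement.

## Energy function

Nonbonded terms use Lorentz–Berthelot combining, 1–2/1–3 exclusions and
1–4 scaling (LJ × 0.5, Coulomb × 1/1.2), no distance cutoffs (toy scale;
exactness of oracle tests outweighs speed).  Constants: eps_P = 4,
eps_W = 80, probe 1.4 Å, electrostatic constant 332.0636 kcal·Å/mol/e².
The per-class parameter table (LJ sigma/epsilon, intrinsic Born radius,
surface tension, partial charges summing to integer residue charges) is a
reduced set packaged with the artifact.

GB polarization is Still's form, f_GB = sqrt(r² + BiBj exp(−r²/4BiBj)),
self terms included, over HCT pairwise-descreened Born radii with a uniform
neighbour scale factor of 0.8.  The descreening integral is implemented in
closed form and verified against numeric shell integration.  Inverse radii
are floored at 1/1000 Å⁻¹ as a deep-burial guard.

The nonpolar term is sigma_k × A_k with A_k from an analytic pairwise
spherical-cap model: A_k = 4πR² minus the sum over neighbours of the
spherical cap of sphere k buried in each neighbour (per-pair clamped to
[0, full sphere]; R = intrinsic Born radius + probe).  Triple and higher
overlaps are not corrected, so deeply buried atoms can overcount burial;
the model is used identically in both solvation modes, keeping
NEA(native) = FDB(native) exact and the NEA decomposition pairwise.  An
exact Shrake–Rupley surface (deterministic golden-spiral point set,
960 points/atom) is provided separately for geometric queries and is
cross-checked against an independent library implementation in the tests.

### NEA and the energy matrix

In FDB mode every energy evaluation recomputes all Born radii from the
current atoms (many-body).  In NEA mode backbone and frozen-residue atoms
keep the radii computed once from the native structure, and a designed
side-chain atom is descreened against its own residue's current atoms plus
the native atoms of all other residues.  Every term then depends on at most
two positions' states, so the total energy decomposes exactly into a
constant (backbone + frozen side chains), per-position self terms, and
position-pair terms.  `precompute_energy_matrix` materializes this
decomposition (frozen positions are assumed at native type, rotamer 0);
reconstruction is tested against direct evaluation at 1e-6 kcal/mol on
random states.  FDB admits no such decomposition and requesting one raises
an error.

## Unfolded state

E_ext(t) is the minimum over packaged rotamers of the total energy of the
extended (phi/psi = −139°/+135°) Ala-t-Ala tripeptide in FDB mode.  The
flanking-alanine contribution is a constant shift common to all types and
cancels in differences.  Chemical potentials mu_t default to zero with a
config hook; without fitted mu the Monte Carlo composition drifts toward
types whose folded-state solvation is favourable (visibly: charged types),
which is the expected behaviour of this model class and the reason such
pipelines fit mu against reference compositions.  All package tests are
mu-explicit or composition-controlled.

## Monte Carlo

Single-temperature Metropolis at kT = 0.6 kcal/mol by default, with an
optional small replica ladder (state swaps by the standard exchange
criterion every `swap_interval` steps).  Moves pick a non-frozen position
uniformly; with probability 0.3 a mutable position draws a new
(type, rotamer) pair uniformly over its allowed combinations, otherwise the
rotamer is redrawn for the current type.  Both draws exclude the current
choice when an alternative exists; because the number of alternatives is
state-independent within a position, the proposal is symmetric and the
chain satisfies detailed balance (verified by chi-square against exact
partition-function weights on a fully enumerable 2-position system, with
visits thinned every 50 steps and low-expectation states pooled, the
standard validity conditions of the test).  NEA runs use incremental matrix
deltas, cross-checked against a fresh reconstruction every 1000 steps; FDB
runs re-evaluate the full energy per step and warn above 30 design
positions (O(N²) radii per step).  The archive keeps each distinct
sequence's best folding energy, ordered ascending, ties broken by first
observation.

## Filtering cascade

Stage order and thresholds follow the study defaults: (1) top-2000 energy
cut; (2) exclusion of isoelectric points in [6.5, 8.5] (inclusive); (3)
fold-recognition match length strictly above the mean over the stage's
input and log10 E < −31; (4) best-hit substitution-matrix similarity
(BLOSUM40, optional position subset) at or above the stage-input mean; (5)
no buried cavity ≥ 30 Å3 (occupancy grid at 1 Å, probe 1.4 Å, flood fill
from the box boundary); (6) |formal charge| < 6, charge counted as
+1 Arg/Lys, −1 Asp/Glu, His neutral, termini cancelling; (7) ≤ 15 drastic
mutations (BLOSUM62 ≤ −2, inclusive).  Stages 3–4 are order-sensitive
(means over survivors); stages 5–7 are independent predicates.  pI is the
bisection root of the Henderson–Hasselbalch net charge with an
EMBOSS-style pKa set (C 8.5, D 3.9, E 4.1, H 6.5, K 10.8, R 12.5, Y 10.1,
termini 8.6/3.6); monotone-charge sequences get the boundary pH with a
warning.  Note that the strictly-above-mean rule means a lone sequence can
never pass stage 3 against its own mean; survivor examples therefore need
at least one weaker companion.

The planted benchmark (`make_planted_cascade`) constructs 200 sequences
each carrying at most one defect, placed so it passes all earlier stages
(similarity is scored on positions 0–9 only; compositional defects sit at
positions ≥ 10), giving a fully deterministic expected attrition chain
200 → 160 → 140 → 110 → 95 → 85 → 73 → 65.

## Thermal shifts

T1/2 is the midpoint of a four-parameter Boltzmann sigmoid fitted by
least squares, initialized at the steepest grid point; the slope sign is
free, so descending curves fit symmetrically.  delta = holo − apo
(positive = stabilization), significant iff delta > sd_apo + sd_holo with
sample (n−1) standard deviations, 0 for single replicates.  Applied to
printed replicate statistics the rule can flag borderline conditions that a
careful reader would not call binding (e.g. a +0.4 °C shift against two
±0.1 spreads); such cases are reported as the rule states them.

## Synthetic data: what it does and does not emulate

Generators produce ideal-geometry mini-scaffolds (helix/hairpin topologies,
not a real PDZ fold), uniform-substitution alignments without indels,
two-component Gaussian fold-recognition score tables, and noisy sigmoidal
melt curves.  They emulate the *interfaces and statistics* the pipeline
consumes, not real structural or evolutionary detail: passing tests shows
the machinery is correct and calibrated on its stated models, not that the
energy function would fold a real protein.  Problem sizes in the analysis
drivers and the acceptance script (10–83-residue scaffolds, 2-position
enumerable sampler checks, 50k-step design runs, 200-sequence cascade) are
the package's chosen desk-scale study conditions.

## Numerical choices

Fit tolerance: scipy least squares defaults, max 20000 evaluations;
bisection to 1e-4 pH; cavity volumes = voxel count × spacing³; Born-radius
floor 1/1000 Å⁻¹; coincident atoms raise degenerate-geometry errors in
energy paths, while SASA credits the union area of exact duplicates to the
lowest-index copy.  All randomness flows through numpy Generators seeded
from explicit config fields; identical configs give byte-identical outputs.

## Known limitations

No backbone flexibility, loop rebuilding, multi-chain design, or
crystallographic symmetry; no Poisson–Boltzmann reference, salt dependence,
or polarizable terms; no His tautomer/protonation enumeration; no
triple-overlap surface correction; the proline ring closure is approximate;
the reduced parameter set is not a validated force field; mu_t = 0 leaves
sequence composition uncontrolled.
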