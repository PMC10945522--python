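# Methods

`chromion` implements a residue-level coarse-grained model of chromatin with
explicit monovalent and divalent counterions, together with the machinery
needed to compute salt-dependent free-energy landscapes: topology building,
the interaction model, NVT dynamics with rigid bodies and umbrella biases,
chromatin reaction coordinates, trajectory observables, and WHAM
reconstruction.  This note records the model, its assumptions, the numerical
choices, and what the desk-scale validations do and do not demonstrate.

## Representation

**Proteins** are one bead per amino acid, centered on the C-alpha position.
Folded regions carry a structure-based (Go-like) energy: harmonic bonds and
angles, cosine dihedrals about the reference geometry, and attractive 12-10
wells at the native distances of residue pairs with sequence separation at
least 4 that lie within `contact_scale * contact_cutoff` (1.5 x 6.5 A) in
the reference structure.  Disordered regions (histone tails) keep only chain
connectivity.  Non-native residue pairs interact through a Lennard-Jones
term whose depth is a globally rescaled Miyazawa-Jernigan contact energy
(packaged as a 20 x 20 table in RT units; the default scale sets the
strongest pair, Leu-Leu, to about 1 kcal/mol).  Arg/Lys carry +1, Asp/Glu
-1; histidine is treated as neutral at pH 7.

**DNA** uses three sites per nucleotide — phosphate (P), sugar (S), base —
with the 5'-terminal nucleotide of each strand lacking its phosphate, so a
strand of n nucleotides has 3n-1 beads and a duplex carries 2n-2 phosphates.
Every phosphate carries the full -1 charge; with explicit ions there is no
reason to scale it down as implicit-salt models do.  Intra-DNA energetics
are a simplified harmonic model: bonds (S-P, P-S, S-B), backbone angles
(S-P-S, P-S-P), backbone dihedrals, plus soft harmonic "pairing bonds"
between paired base beads that stand in for the base-pairing potential of
full three-site DNA models.  Reference values come from the idealized
straight B-form build (rise 3.4 A, twist 36 deg/bp), so ideal B-DNA is
strain-free by construction.  Sequence-dependent stacking, pairing and
cross-stacking energetics are out of scope.

**Ions** (Na+, Mg2+, Cl-) are single beads.  Interactions between ions and
charged particles (P, charged amino acids, other ions) use the packaged
charged-pair table: a WCA repulsive core from (eps, sigma), a Gaussian well
of depth eps centered at (rm_eps, sigma_eps), and one or two hydration-shell
Gaussians (amplitude H1/H2 at rm_h1/rm_h2 with widths sigma_h1/sigma_h2).
The hydration Gaussians are amplitude-form: at r = rm_h1 the term
contributes exactly H1.  Ion interactions with neutral particles (sugar,
bases, neutral amino acids) are purely repulsive WCA terms from the second
packaged table.  The pair algebra is isolated in
`chromion.potentials.ion_pair_energy_terms` so the functional form can be
swapped without touching callers.

**Electrostatics.**  All charged beads interact through Coulomb's law with
a uniform dielectric of 78 (the only solvent remnant in an explicit-ion
model; salt dependence is carried by the ions themselves).  Periodic boxes
use Ewald summation with tin-foil boundaries; the splitting parameter and
k-space cutoff derive from one accuracy target (default 1e-4, the typical
per-atom force accuracy of mesh solvers).  Open-boundary systems use the
direct pairwise sum.  No pairs are excluded from Coulomb (neighboring
phosphate-phosphate repulsion is physical and retained); short-range
nonbonded terms exclude pairs within three bonds, native-contact pairs, and
pairs frozen inside the same rigid body.

**Excluded volume.**  Protein-DNA and non-phosphate DNA-DNA pairs get a
weak, non-specific Lennard-Jones (eps = 0.1 kcal/mol, sigma = sum of bead
radii), cut and shifted at 2.5 sigma.

## Dynamics

NVT dynamics with a BAOAB Langevin integrator (default: 10 fs timestep,
300 K, 1 ps damping) or a Nose-Hoover thermostat; both reproduce the target
temperature on fixture systems to within a few percent.  The histone core
plus the inner DNA layer (default: the central 73 bp, one superhelical
turn) can be frozen as a rigid body: net force translates the center of
mass, torque rotates the body through an exact Rodrigues rotation, so
intra-body distances are preserved to machine precision.  Rigid-body masses
may be scaled down (`rigid_mass_scale`); equilibrium distributions are
independent of masses, and lighter bodies diffuse and reorient fast enough
to sample at desk scale.  Umbrella biases are stiff harmonic penalties
(`U = k (cv - center)^2`, so a unit displacement feels a 2k restoring
force); the DNA-origami-style "constraints" (arc confinement, plane
orientation, position pinning) are implemented the same way rather than as
holonomic constraints, which keeps WHAM post-processing simple.

Short-range pair terms use displacement-triggered neighbor culling (6 A
skin, rebuild when any bead moves half a skin): culled pairs are exactly
zero beyond their cutoffs, so energies are identical to the brute-force
evaluation.

A short force-capped pre-equilibration (per-bead force norms clipped,
default 50 kcal/mol/A) resolves constructed clashes when umbrella windows
are retargeted; production sampling is never force-capped.

## Reaction coordinates and observables

* DNA end-to-end distance: distance between the terminal base-pair centers.
* Unwrapped base pairs: counted inward from both DNA ends; a base pair is
  detached when its minimum bead distance to the histone core exceeds its
  build-time native distance plus a 10 A margin (threshold configurable).
* Nucleosome center and plane normal: geometric center of the nucleosome
  beads; the normal is the smallest-eigenvalue eigenvector of the
  wrapped-DNA gyration tensor (the superhelical axis).  Its analytic
  gradient follows from first-order eigenvector perturbation theory, so the
  plane angle theta = arccos|w1.w2| (folded into [0, 90] deg, faces being
  unsigned planes) is usable as a biased CV.
* Two-start-helix similarity: a Gaussian overlap of nucleosome-center pair
  distances over (i, i+1) and (i, i+2) pairs, Q in (0, 1], equal to 1 at
  the reference stack.  This functional form is this package's
  concretization of the similarity coordinate.
* Ion condensation: ions within 10 A (default) of the target group,
  minimum-image aware; bound fractions and neutralized charge
  (Na+ + 2 Mg2+) are averaged over frames with frame-to-frame standard
  deviations as error estimates.
* Inter-nucleosome contacts: tail-DNA and core-DNA bead pairs across
  nucleosomes within a 10 A cutoff (the published condensation cutoff; the
  contact-map cutoff is not printed, so it is exposed in config).
* Sedimentation coefficient: Kirkwood rigid-array estimate
  `S = S1 (1 + (R/N) sum_{i!=j} 1/r_ij)` over nucleosome centers with
  S1 = 11.1 S and R = 5.5 nm, standard mononucleosome values in the
  chromatin-modeling literature; both configurable.

## Free-energy reconstruction

WHAM with direct self-consistent iteration, tolerance 1e-7 k_BT on the
window offsets, up to 1e5 iterations; 1D and 2D grids with per-dimension
harmonic biases in the same `k (x - c)^2` convention as the engine.  Bins
never visited stay undefined (NaN), not interpolated.  A window sharing no
occupied bin with any other raises an error naming it; adjacent-window
gaps warn.  Reweighted observable averages use the continuous WHAM weights;
the quoted error derives from the weighted effective sample size.  Error
bars on profiles follow the independent-replica protocol: per-bin standard
deviation across separately normalized estimates (not bootstrap).

Binding free energies are read off a distance profile as (mean plateau at
large separation) minus (global minimum), which is invariant to the
normalization convention.  For a freely moving pair the distance PMF
carries the 3D volume factor; the unrestrained profile is corrected by
+2 k_BT ln r before the depth is read.  The arc-restrained pathway is
one-dimensional and needs no correction.

## Synthetic validation systems

The fixture generator produces deterministic desk-scale systems: pure ion
boxes, short ideal duplexes, a folded mini-protein (alpha-helical trace)
with a disordered tail, and a **toy dinucleosome** — two synthetic
nucleosomes, each a DNA duplex wrapped one superhelical turn (28 bp,
radius 15 A) around two *filled* disks of arginine beads (solid, so no
rim can thread through the particle), with two lysine tails per face.
Each tail leaves the face along its normal through a short rigid stalk
(its first residues are folded into the core body), so the flexible
segment starts proud of the face surface.  The toy reproduces the charge
layout and geometry class of a nucleosome (basic protein disk inside
wrapped polyanionic DNA, positively charged flexible tails) at roughly
one-fifth scale.  It is explicitly synthetic: its absolute energies mean
nothing, and passing tests on it demonstrate that the machinery
(restraints, umbrella sampling, WHAM, contact analysis) behaves correctly
and that the *direction* of physical contrasts — orientation restriction
weakening apparent binding, divalent ions condensing more strongly than
monovalent — emerges from the model.  It does not demonstrate quantitative
agreement with nucleosome-scale energies, which require crystal-structure
inputs and cluster-scale sampling.

The binding comparison runs two umbrella protocols on this fixture that
differ only in the device restraints.  Unrestrained: the second nucleosome
starts rim-to-face against the first (the contact-maximizing pose for a
free pair — the polyanionic rim against the basic face and its tails) and
is pulled outward window by window, each window inheriting the previous
one's relaxed configuration, as in a pulling experiment.  Restrained: the
first nucleosome is pinned and orientation-held, the second is confined to
the 15-nm arc of the origami-style device, and the two plane normals are
held mutually perpendicular and transverse to the approach — both the
face-contact and any coplanar-interlock mode are geometrically
inaccessible, mimicking the restricted unbinding pathway of the device.
Binding depths are read from the profiles with near-empty bins (fewer than
25 samples) treated as undefined, and a window whose histogram ends up
disconnected from all others — a rare sampling accident at this scale — is
dropped before reconstruction.  The outward-pulling order deliberately
retains contact hysteresis: the bound windows stay bound, which biases
both protocols identically and keeps the directional comparison stable at
desk-scale sampling; the absolute depths are not converged free energies.

WHAM is validated against analytic ground truth: umbrella samples are drawn
exactly (inverse CDF on a fine grid) from biased Boltzmann densities of a
double well with a 5 k_BT barrier (12 windows, 2e5 samples total) and of a
separable 2D quadratic potential.  The reconstruction is compared on the
window-covered CV range (the region the umbrella study targets); the
recovered RMSE is required to stay below 0.15 k_BT.

The condensation comparison places one rigid 20-bp duplex in a 216 nm^3
periodic box under 150 mM NaCl or 1 mM MgCl2 (the study's salt conditions,
scaled to a single short duplex), runs explicit-ion Langevin dynamics with
Ewald electrostatics, and compares cation bound fractions within 10 A of
the DNA.  Only the direction of the Mg2+ vs Na+ contrast is asserted.

The restrained-vs-unrestrained comparison itself is made between medians
over three independent replicas per condition (the same
independent-replica protocol used for profile error bars): single desk-scale
profiles carry k_BT-scale wiggles and occasional bound-state slips, and the
median is robust to one bad replica on either side.

## Problem sizes and determinism

Desk-scale runs use systems of 100-460 beads, 5 x 10^3 sampling steps for
condensation (after 1.5 x 10^3 equilibration), and 14 umbrella windows x
~3.6 x 10^3 steps per binding profile with 3 replicas per condition; these
sizes give stable directional results while keeping full workflows at the
minutes scale.  Every stochastic element (ion jitter, velocity draws,
thermostat noise, synthetic samplers) is seeded; identical seeds give
bit-identical trajectories and byte-identical output files.

## Ion counting conventions

Bulk counts are `round(c * V * N_A)` per dissolved salt unit; the
neutralization excess goes to Na+ in systems containing NaCl and to Mg2+ in
MgCl2-only systems (with a single Cl- absorbing the overshoot of an odd
charge).  This reproduces every published Mg2+ count and the MgCl2-system
Cl- counts exactly.  Monovalent counts in mixed systems are approximate:
the published single-nucleosome row is consistent with an alternative
bookkeeping in which Mg2+ substitutes Na+ charge instead of adding Cl-,
while the two-nucleosome rows follow the convention used here to within the
rounding of the bulk count (a few ions in ~2 x 10^4).  The discrepancy is
documented rather than special-cased.

## Known limitations

* The simplified DNA bonded model has no sequence-dependent mechanics; DNA
  stiffness contrasts (e.g. poly-dA:dT vs poly-dG:dC) are out of reach.
* The generalized ion-amino-acid parameters approximate all charged side
  chains with phosphate-tuned interactions, as in the source model.
* Linker-histone parameterization and histone modifications are not
  implemented.
* The Nose-Hoover thermostat acts through a single chain and is intended
  for fixture-scale checks; Langevin is the default sampler.
* The toy dinucleosome's wrap radius (15 A) bends DNA far more sharply than
  a real nucleosome; the wrap is therefore always frozen rigid, and outer
  bonded strain there is meaningless (and excluded from dynamics).
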