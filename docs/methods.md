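# Methods

This note documents the models, numerical choices and limitations of
`degradertcm` at the level a maintainer or reviewer needs; the README
covers usage.

## Model and assumptions

The pipeline is PROTAC-centric: it assumes the warhead and E3-ligand
binding poses are known and trustworthy (co-crystal, user-supplied, or
transferred from a co-crystallized analog over a maximum common
substructure of ≥ 3 heavy atoms), and that the linker — built once at
full length — carries enough geometric information to fix the reciprocal
orientation of the two proteins.  One model is produced per run, not an
ensemble.  Consequences of these assumptions:

* rigid linkers are the favorable regime; very flexible linkers make the
  single-conformer orientation less determined.  The linker-superposition
  RMSD of the two separately minimized linker copies is reported as
  `assembly_rmsd` and is the explicit diagnostic for this: near zero
  means the merge was geometrically forced, large values mean the two
  pocket environments pulled the linker apart and the merged orientation
  is soft.  A multi-seed ensemble (keep lowest `assembly_rmsd`) is
  available via the conformer seed.
* large protein conformational changes and weakly cooperative interfaces
  are out of reach; this is a rigid-body-plus-minimization method, not
  molecular dynamics.

## Pipeline stages and numerical choices

**Pose transfer.**  Kabsch superposition (SVD, proper rotations only;
degenerate/collinear point sets rejected at a relative second-singular-
value threshold of 1e-8).  MCS matching is made deterministic by scoring
all substructure-match pairs (≤ 64 each side) by fit RMSD, ties broken by
the lexicographically smallest index tuple.  Heavy atoms only; hydrogens
ride rigidly.

**Linker construction.**  Distance-geometry embedding (ETKDG, seeded;
up to 50 derived-seed retries) followed by a short force-field relaxation.
Junction open valences are preserved by deleting one placeholder hydrogen
per junction after embedding; its direction is kept as the open-valence
vector.  Attachment places the junction bond at the ideal length for its
element pair (tabulated; covalent-radii sum as fallback) and scans 12
evenly spaced torsions about the new bond, scoring each by summed squared
van-der-Waals overlap with the half-complex (pairs within three bonds of
the junction excluded); the minimum is kept.  If every candidate leaves a
heavy–heavy contact below 1.5 Å a warning is issued and the best
candidate is kept for minimization to resolve.

**Minimization engine.**  RDKit UFF by default (MMFF94 selectable); one
force field per run, energies in kcal/mol.  Absolute energies are
engine-dependent; only within-run comparisons are meaningful.  The
configured tolerance (default 0.1 kcal mol⁻¹ Å⁻¹) is an RMS-gradient
target over the mobile atoms, checked explicitly in bounded optimizer
chunks (the optimizer itself runs at its native, tighter step tolerance);
iteration cap 2000 (configurable).  Fixed atoms never move (bitwise);
restrained atoms are held by pure harmonic positional restraints, default
100 kcal mol⁻¹ Å⁻², under which restrained heavy atoms move ≲ 0.1 Å in
practice (contract: ≤ 0.3 Å).  Reported stage energies exclude restraint
terms.  If an optimizer call would end above its start energy, the input
coordinates are kept, so stage energies are non-increasing by
construction as well as in practice.

**Merge.**  Linker correspondence is an element-matched graph isomorphism
on heavy atoms anchored at the junction atoms, tried in both end
orientations (a symmetric linker admits the flip); the mapping with the
lowest heavy-atom fit RMSD wins, ties broken canonically and the
ambiguity logged.  The POI-side linker copy survives, fixing the POI
frame as the reference for downstream RMSDs; the E3-side half is moved as
a rigid body.

**Refinement.**  Clash = non-bonded heavy-atom pair (1-2 and 1-3
excluded) closer than 0.7 × Bondi vdW radii sum — a conventional
structure-preparation criterion, configurable.  Stage order is fixed:
clash-driven local rounds (mobile neighborhood 6 Å, ≤ 5 rounds), then
PROTAC-only (proteins bitwise fixed), then unrestrained.  QC re-runs the
clash detector on the final model independently of the minimizer.  The
manual "do the moieties still sit in their pockets" inspection is
replaced by a reported pose-retention RMSD of each moiety's heavy atoms
against its pre-refinement pose.

**Scoring.**  Interactions are enumerated per moiety–protein heavy-atom
pair within 4.0 Å and typed with priority salt bridge (opposite group
formal charges on an N/O pair ≤ 4.0 Å) > hydrogen bond (donor–acceptor
≤ 3.5 Å, D–H···A ≥ 120°) > nonbonded, each pair counted once.  The
per-interaction energy is 12-6 Lennard-Jones (σ from Bondi radii so the
minimum sits at the radii sum; well depths from the UFF element table;
geometric-mean mixing) plus Coulomb with distance-dependent dielectric
ε = 4r and stored partial charges (Gasteiger by default).  Hydrogens
bonded to N/O carry no LJ term — the standard polar-hydrogen treatment —
and take part in polar interactions through their charges.  Cross-protein
moiety contacts (warhead touching the E3 ligase) are counted by default;
`restrict_to_cognate` limits each moiety to its own receptor.  The score
is the exact sum of the two moiety terms; linker-mediated contacts are
excluded by construction, so perturbing only linker atoms cannot change
it.  Absolute values are engine-dependent and are **not** comparable
across engines — rankings within a series are the deliverable.  The
protein–protein interface summary counts typed POI↔E3L interactions and
reports the buried solvent-accessible surface,
(SASA(POI) + SASA(E3L) − SASA(both))/2, Shrake–Rupley with a 1.4 Å probe,
1000 sphere points, and the same Bondi radius table as the rest of the
package.

**Validation.**  One joint rigid superposition over the N/CA/C/O atoms of
both proteins (matched by chain + residue number; unmatched residues
skipped and counted) gives the protein backbone RMSD; the PROTAC
heavy-atom RMSD is measured in that same frame with no ligand re-fit, so
it reflects placement error, and is minimized over graph automorphisms of
the ligand.  "Crystal-like" means protein RMSD strictly below 10 Å.
Backbone-only (rather than all-atom) protein RMSD is a documented choice.

## The synthetic toy systems

The fixtures module generates everything the tests need without
downloads.  A receptor is two antiparallel ideal polyalanine α-helices
(φ = −57°, ψ = −47°, NH₂/COOH termini, built by natural-extension
internal coordinates) forming a groove; the guest moieties are tert-butyl
fragments; the linker is an extended alkane chain with one asymmetric
ether oxygen (all-carbon in the symmetric-linker flavor, default 8 chain
atoms).  The designed guest–receptor heavy-atom clearance is 3.6 Å —
just outside van der Waals contact for carbon, where a bound aliphatic
ligand actually sits — found by bisection on the helix gap.  The whole
assembled complex is then relaxed once, unrestrained, to the engine's
minimum (deterministic; helix templates are additionally pre-relaxed and
cached), and both half-complexes are carved from that single relaxed
geometry.  This makes the emitted ground truth a stationary point of the
engine, so the recovery tests measure assembly fidelity rather than
residual strain of hand-built internal coordinates.  The E3-side half is
finally displaced by a seeded rigid transform of configurable magnitude;
recovering the truth from that displacement is the core end-to-end test.

Flavors inject specific defects after relaxation: a side-chain (CB)
clash at 1.9 Å for local-refinement tests, a junction bond stretched to
≈ 2.2 Å for PROTAC-stage tests, an all-carbon linker for
mapping-ambiguity tests.

What the toys do *not* emulate: real folds, sequence diversity, polar
binding sites (the guests are alkanes, so scores are small LJ-dominated
numbers), solvent, and crystallographic noise.  Passing tests therefore
demonstrate the correctness of the geometry, bookkeeping, minimization
contracts and score algebra — not predictive accuracy on real degrader
series, which requires user-supplied structures.

## Degenerate inputs and tie-breaks

Collinear point sets and < 3-point fits are rejected; symmetric linkers
and symmetric ligand groups are handled by explicit enumeration with
canonical tie-breaks (lowest RMSD, then lexicographic); single-atom
linkers carry both junctions on one atom; attachment directions for
fully substituted or isolated atoms fall back to perpendicular/centroid
constructions.  All randomness (embedding, fixture generation) flows
from explicit integer seeds; derived seeds stay below 2³¹.  Identical
inputs and seeds give bitwise identical models.

## Problem sizes used in the shipped checks

The test-suite and acceptance-script runs use toy systems of ~340 atoms
(two 2×7-residue receptors plus a 58-atom degrader), 6–10 fixture seeds
per property, 50 instances for the superposition-kernel audit (coarse
10° grid refined locally to 1°), and rigid perturbations up to 30 Å —
sizes chosen so the whole battery re-runs from scratch in a few minutes
on one CPU, which matches the method's design point of running on
modest hardware.

## Known limitations

* UFF is generic: peptide torsional preferences and hydrogen bonding are
  crude; the engine is pluggable behind `MinimizationConfig.forcefield`.
* Scores are not binding free energies; no cooperativity (α) estimate,
  no FEP/MM-GBSA, no explicit solvent.
* PDB I/O is v3 fixed-column, single-model; no mmCIF, no altlocs, no
  covalent PROTACs.
* Docking is intentionally absent: pose provenance is co-crystal >
  user-supplied > MCS transfer.
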