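# degradertcm

Modeling and scoring of PROTAC-mediated ternary complexes.

PROTACs (degraders) are heterobifunctional molecules — a POI-binding
**warhead**, a **linker**, and an E3-ligase ligand (**L^E3**) — that induce
the formation of a POI–PROTAC–E3-ligase **ternary complex (TC)**, the
structural prerequisite for ubiquitination and degradation of the protein
of interest.  Knowing the 3D structure of the TC is central to degrader
design, but crystal structures are rare and exhaustive conformational
sampling is expensive.  `degradertcm` implements a deliberately lean,
PROTAC-centric alternative for structural bioinformaticians and
computational medicinal chemists: the linker itself is used as the
geometric constraint that determines the reciprocal orientation of the
two proteins.

## The method

Starting from a POI–warhead complex and an E3L–L^E3 complex (co-crystal
poses, user-supplied poses, or common-scaffold pose transfer):

1. **Linker construction** — one full-length 3D conformer of the linker is
   built de novo and attached separately to both binding poses, leaving
   the poses untouched (junction bond at ideal length, torsion chosen
   among 12 candidates to minimize steric overlap).
2. **Half-complex minimization** — each half is minimized with the linker
   free and protein + moiety heavy atoms harmonically restrained
   (100 kcal mol⁻¹ Å⁻²).
3. **Superposition and merge** — the two linker copies are superposed
   (Kabsch, heavy atoms, graph-isomorphism correspondence anchored at the
   junctions); the E3-side copy is deleted and the PROTAC reconnected.
   The fit RMSD is reported as `assembly_rmsd`.
4. **Staged refinement** — clash-driven local minimization rounds, then
   PROTAC-only minimization (proteins fixed), then unrestrained
   minimization; quality control re-checks that no residual clashes
   (heavy-atom pairs below 0.7 × van der Waals radii sum) remain.
5. **Scoring** — the complex is ranked by the interactions of the two
   protein-binding moieties only:

   `score = E_warhead + E_LE3`

   where each term sums per-interaction energies (typed H-bonds, salt
   bridges and nonbonded contacts; pairwise Lennard-Jones + Coulomb with
   distance-dependent dielectric ε = 4r) of that moiety with the protein
   component.  More negative ⇒ more stable TC; only orderings within a
   series are meaningful.

Validation against a reference complex reports the backbone RMSD of the
whole protein component after one joint superposition, the PROTAC
heavy-atom RMSD in that same frame, and the *crystal-like* classification
(protein RMSD strictly below 10 Å).

## Worked example

Everything below runs offline on fully synthetic toy systems (polyalanine
helix-pair receptors with tert-butyl guests and an aliphatic ether
linker) generated by the built-in fixtures module:

```bash
degradertcm fixtures --flavor clean --seed 5 --outdir fx/
degradertcm assemble --poi-half fx/clean_seed5_poi_side.pdb \
                     --e3-half fx/clean_seed5_e3_side.pdb \
                     --out fx/tc.pdb --seed 5
degradertcm refine fx/tc.pdb --out fx/tc_refined.pdb --report fx/report.json
degradertcm score  fx/tc_refined.pdb --out fx/score.json
```

which prints:

```
wrote clean fixture (seed 5) to fx
assembled TC (linker superposition RMSD 0.011 Å) -> fx/tc.pdb
refined -> fx/tc_refined.pdb; qc_pass=True, clashes 0 -> 0
score: total -0.04 kcal/mol (warhead -0.03, L^E3 -0.01) -> fx/score.json
```

The linker-superposition RMSD of 0.011 Å says the two separately
minimized linker copies stayed nearly congruent, so the merge is
well-determined; `qc_pass=True` means the refined model has zero residual
steric clashes; the score is the summed moiety interaction energy (tiny
here because the toy guests are plain alkanes with vanishing partial
charges — real degraders give large negative totals).  Against the
fixture's ground-truth complex,

```bash
degradertcm validate fx/tc_refined.pdb --reference fx/truth.pdb --out fx/metrics.json
# backbone RMSD 0.00 Å, PROTAC RMSD 0.01 Å, crystal-like: True
```

the model recovers the reference orientation to within hundredths of an
Ångström — the rigid perturbation the fixture applied to the E3 half is
fully removed by the linker superposition.

For real systems, supply your own PDB/SDF files (`degradertcm place`
poses a ligand onto a co-crystallized reference by maximum common
substructure); the tool never downloads structures.

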