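"""Binding-pose placement for the two protein-binding moieties.

The pipeline needs a POI–warhead complex and an E3-ligase–L^E3 complex
before any linker work can start.  Poses come from, in order of
preference: a co-crystal structure, a user-supplied posed ligand, or
template-based transfer onto a co-crystallized reference ligand sharing a
common scaffold (:func:`transfer_pose`).  Flexible docking is deliberately
out of scope.

This module also houses the rigid superposition kernel used pipeline-wide
(:func:`kabsch_fit`): the closed-form least-squares fit of one point set
onto another via SVD, constrained to proper rotations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .chem_model import (
    ChemModelError,
    MolecularStructure,
    clashing_pairs_between,
    mol_to_structure,
    structure_to_mol,
)

logger = logging.getLogger("degradertcm")


class PoseError(ValueError):
    """Raised for degenerate fits, missing scaffolds or clashing poses."""


@dataclass
class AtomMapping:
    """Atom correspondence used by a rigid fit: (mobile, reference) pairs.

    At least 3 pairs are required for any rigid fit; the pairs must be
    injective on both sides.
    """

    pairs: list
    source: str = "USER"  # IDENTITY | MCS | USER

    def __post_init__(self) -> None:
        mob = [p[0] for p in self.pairs]
        ref = [p[1] for p in self.pairs]
        if len(set(mob)) != len(mob) or len(set(ref)) != len(ref):
            raise PoseError("atom mapping must be injective on both sides")


@dataclass
class RigidTransform:
    """A proper rigid motion x -> R x + t with the post-fit RMSD attached."""

    rotation: np.ndarray
    translation: np.ndarray
    fit_rmsd: float = 0.0

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, float)
        self.translation = np.asarray(self.translation, float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise PoseError("rigid transform must be 3x3 rotation + 3-vector")
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        if err > 1e-6 or np.linalg.det(self.rotation) < 0:
            raise PoseError("rotation must be orthonormal with det +1")
        if self.fit_rmsd < 0:
            raise PoseError("fit_rmsd must be non-negative")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(rotation=np.eye(3), translation=np.zeros(3))


def kabsch_fit(mobile, reference) -> RigidTransform:
    """Least-squares proper rigid fit of ``mobile`` onto ``reference``.

    Both are (N, 3) arrays with N >= 3 and non-collinear points.  Returns
    the transform minimizing the RMSD of the transformed mobile set to the
    reference, with that RMSD recorded as ``fit_rmsd``.  Reflections are
    excluded (determinant sign corrected), so chirality is preserved.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise PoseError("mobile and reference must be matching (N,3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise PoseError("rigid fit requires at least 3 points")
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    p = mobile - cm
    q = reference - cr
    scale = max(np.linalg.norm(p, axis=1).max(), np.linalg.norm(q, axis=1).max(), 1.0)
    for pts in (p, q):
        sv = np.linalg.svd(pts, compute_uv=False)
        if sv[1] < 1e-8 * scale:
            raise PoseError("degenerate geometry: points are (near-)collinear")
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cr - rot @ cm
    moved = mobile @ rot.T + trans
    rmsd = float(np.sqrt(((moved - reference) ** 2).sum(axis=1).mean()))
    return RigidTransform(rotation=rot, translation=trans, fit_rmsd=rmsd)


# ---------------------------------------------------------------------------
# Maximum-common-substructure pose transfer
# ---------------------------------------------------------------------------

def mcs_atom_mapping(mobile: MolecularStructure,
                     reference: MolecularStructure) -> AtomMapping:
    """Heavy-atom mapping over the maximum common substructure.

    The MCS is found by RDKit FMCS; among the substructure matches of the
    MCS in each molecule, the pair of matches giving the lowest rigid-fit
    RMSD is chosen, ties broken by the lexicographically smallest index
    tuple — deterministic by construction.
    """
    from rdkit import Chem
    from rdkit.Chem import rdFMCS

    mob_mol = structure_to_mol(mobile)
    ref_mol = structure_to_mol(reference)
    mob_heavy = Chem.RemoveHs(mob_mol, sanitize=False)
    ref_heavy = Chem.RemoveHs(ref_mol, sanitize=False)
    for m in (mob_heavy, ref_heavy):
        Chem.FastFindRings(m)

    if Chem.MolToSmiles(mob_heavy) == Chem.MolToSmiles(ref_heavy):
        # identical molecular graphs: map by canonical atom ranking
        pass  # fall through to generic MCS; it returns the full graph

    res = rdFMCS.FindMCS([mob_heavy, ref_heavy], timeout=10,
                         matchValences=False, ringMatchesRingOnly=True)
    if res.canceled or res.numAtoms < 3:
        raise PoseError("no usable common scaffold (<3 heavy atoms in MCS)")
    patt = Chem.MolFromSmarts(res.smartsString)
    mob_matches = mob_heavy.GetSubstructMatches(patt, uniquify=True, maxMatches=64)
    ref_matches = ref_heavy.GetSubstructMatches(patt, uniquify=True, maxMatches=64)
    if not mob_matches or not ref_matches:
        raise PoseError("MCS match failed unexpectedly")

    # heavy-index -> original-index maps (RemoveHs keeps heavy-atom order)
    mob_heavy_idx = [i for i, a in enumerate(mobile.atoms) if a.is_heavy]
    ref_heavy_idx = [i for i, a in enumerate(reference.atoms) if a.is_heavy]
    mob_xyz = mobile.coords
    ref_xyz = reference.coords

    best = None
    for mm in sorted(mob_matches):
        for rm in sorted(ref_matches):
            pairs = [(mob_heavy_idx[a], ref_heavy_idx[b]) for a, b in zip(mm, rm)]
            fit = kabsch_fit(mob_xyz[[p[0] for p in pairs]],
                             ref_xyz[[p[1] for p in pairs]])
            key = (round(fit.fit_rmsd, 9), tuple(sorted(pairs)))
            if best is None or key < best[0]:
                best = (key, pairs)
    return AtomMapping(pairs=best[1], source="MCS")


def transfer_pose(mobile_ligand: MolecularStructure,
                  reference_ligand: MolecularStructure,
                  origin_tag: str = "") -> MolecularStructure:
    """Place ``mobile_ligand`` in the protein frame of ``reference_ligand``.

    The rigid transform is fit over the maximum-common-substructure atom
    pairs (heavy atoms only, >= 3 required); unmapped atoms — decorations
    absent from the reference — are carried along by the same transform.
    Returns a posed copy; hydrogens follow rigidly.
    """
    mapping = mcs_atom_mapping(mobile_ligand, reference_ligand)
    if len(mapping.pairs) < 3:
        raise PoseError("no usable common scaffold (<3 mapped atoms)")
    mob_xyz = mobile_ligand.coords
    ref_xyz = reference_ligand.coords
    fit = kabsch_fit(mob_xyz[[p[0] for p in mapping.pairs]],
                     ref_xyz[[p[1] for p in mapping.pairs]])
    posed = mobile_ligand.copy()
    posed.coords = fit.apply(mob_xyz)
    if origin_tag:
        for atom in posed.atoms:
            atom.origin_tag = origin_tag
    posed.meta["pose_transform"] = fit
    logger.info("transfer_pose: %d mapped atoms, fit RMSD %.4f Å",
                len(mapping.pairs), fit.fit_rmsd)
    return posed


def make_half_input(protein: MolecularStructure,
                    moiety: MolecularStructure,
                    protein_tag: str = "POI",
                    moiety_tag: str = "WARHEAD") -> MolecularStructure:
    """Merge a protein and a posed moiety into one tagged structure.

    The moiety must already sit in the protein frame; any heavy-atom pair
    between moiety and protein closer than the clash threshold (0.7 × vdW
    radii sum, the refinement criterion) aborts with the offending pairs
    listed — a clashing input pose is a user error, not something the
    pipeline should silently repair.
    """
    prot_heavy = protein.heavy_indices()
    moi_heavy = moiety.heavy_indices()
    clashes = clashing_pairs_between(
        moiety.coords[moi_heavy], [moiety.atoms[i].element for i in moi_heavy],
        protein.coords[prot_heavy], [protein.atoms[i].element for i in prot_heavy],
    )
    if clashes:
        listing = "; ".join(
            f"moiety atom {moi_heavy[i]} / protein atom {prot_heavy[j]} at {d:.2f} Å"
            for i, j, d in clashes[:10])
        raise PoseError(f"posed moiety clashes with protein: {listing}")
    tagged_protein = protein.copy()
    for atom in tagged_protein.atoms:
        atom.origin_tag = protein_tag
    tagged_moiety = moiety.copy()
    for atom in tagged_moiety.atoms:
        atom.origin_tag = moiety_tag
    merged = tagged_protein.merged_with(tagged_moiety)
    merged.meta["protein_atoms"] = list(range(protein.n_atoms))
    merged.meta["moiety_atoms"] = list(range(protein.n_atoms,
                                             protein.n_atoms + moiety.n_atoms))
    return merged
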