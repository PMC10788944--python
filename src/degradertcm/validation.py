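"""Validation of a modeled ternary complex against a reference structure.

Given a reference (typically crystallographic) complex the module computes
two numbers: the backbone RMSD of the whole protein component after a
single joint rigid superposition over both proteins, and the PROTAC
heavy-atom RMSD measured in that same frame (no ligand re-fit, so it
reflects placement error, not conformer error alone).  A model is called
*crystal-like* when its protein RMSD is strictly below 10 Å — the
conventional discrimination threshold for ternary-complex predictions.
"""

from __future__ import annotations

import logging

import numpy as np

from .chem_model import MolecularStructure
from .pose_placement import RigidTransform, kabsch_fit

logger = logging.getLogger("degradertcm")

BACKBONE_NAMES = ("N", "CA", "C", "O")
CRYSTAL_LIKE_THRESHOLD = 10.0  # Å, strictly below


class ValidationError(ValueError):
    """Raised for unmatchable structures or invalid inputs."""


def _structure_of(model) -> MolecularStructure:
    return model.structure if hasattr(model, "structure") else model


def _backbone_table(structure: MolecularStructure, indices=None) -> dict:
    """(chain, residue number, atom name) -> atom index over backbone atoms."""
    indices = range(structure.n_atoms) if indices is None else indices
    table = {}
    for i in indices:
        a = structure.atoms[i]
        if a.name in BACKBONE_NAMES and a.residue_name:
            table[(a.chain_id, a.residue_number, a.name)] = i
    return table


def backbone_superposition(model, reference) -> tuple:
    """Joint rigid fit of the model's backbone onto the reference's.

    Correspondence is resolved by chain ID + residue number over N, CA, C,
    O atoms of *both* proteins together; unmatched residues are skipped
    with a logged count.  Returns ``(RigidTransform, n_matched)``.
    """
    model_s = _structure_of(model)
    ref_s = _structure_of(reference)
    mtab = _backbone_table(model_s)
    rtab = _backbone_table(ref_s)
    keys = sorted(set(mtab) & set(rtab))
    skipped = len(set(mtab) ^ set(rtab))
    if skipped:
        logger.info("backbone superposition: %d unmatched backbone atoms skipped",
                    skipped)
    if len(keys) < 3:
        raise ValidationError(
            f"backbone correspondence has only {len(keys)} matched atoms (need >= 3)")
    mob = np.array([model_s.atoms[mtab[k]].coords for k in keys])
    ref = np.array([ref_s.atoms[rtab[k]].coords for k in keys])
    return kabsch_fit(mob, ref), len(keys)


def backbone_rmsd(model, reference) -> float:
    """Backbone RMSD (Å) of the whole protein component after one joint
    superposition over both proteins."""
    fit, _ = backbone_superposition(model, reference)
    return float(fit.fit_rmsd)


def _heavy_graph_mappings(model_lig: MolecularStructure,
                          ref_lig: MolecularStructure,
                          cap: int = 10000) -> list:
    """Element-matched heavy-atom graph isomorphisms model → reference."""
    import networkx as nx

    def heavy_graph(s):
        heavy = set(s.heavy_indices())
        g = nx.Graph()
        for i in heavy:
            g.add_node(i, element=s.atoms[i].element)
        for i, j, _ in s.bonds:
            if i in heavy and j in heavy:
                g.add_edge(i, j)
        return g

    gm = nx.algorithms.isomorphism.GraphMatcher(
        heavy_graph(model_lig), heavy_graph(ref_lig),
        node_match=nx.algorithms.isomorphism.categorical_node_match("element", ""))
    mappings = []
    for iso in gm.isomorphisms_iter():
        mappings.append(dict(iso))
        if len(mappings) >= cap:
            logger.warning("symmetry enumeration capped at %d mappings", cap)
            break
    return mappings


def protac_rmsd(model, reference_ligand: MolecularStructure,
                transform: RigidTransform | None = None,
                model_ligand_atoms=None) -> float:
    """PROTAC heavy-atom RMSD (Å) in the frame fixed by the backbone
    superposition.

    ``transform`` is the rigid motion from :func:`backbone_superposition`
    (identity if omitted, i.e. the structures are already in one frame);
    the ligand is *not* re-fit.  The model's PROTAC must be heavy-atom
    graph-isomorphic to the reference ligand; the minimum over symmetry
    automorphisms is reported.
    """
    model_s = _structure_of(model)
    if model_ligand_atoms is None:
        model_ligand_atoms = getattr(model, "protac_atoms", None)
    lig = (model_s.extract(model_ligand_atoms)
           if model_ligand_atoms is not None else model_s)
    mappings = _heavy_graph_mappings(lig, reference_ligand)
    if not mappings:
        raise ValidationError(
            "model PROTAC and reference ligand are not graph-isomorphic on heavy atoms")
    transform = transform or RigidTransform.identity()
    lig_xyz = transform.apply(lig.coords)
    ref_xyz = reference_ligand.coords
    best = None
    for mapping in mappings:
        pairs = sorted(mapping.items())
        d = lig_xyz[[p[0] for p in pairs]] - ref_xyz[[p[1] for p in pairs]]
        rmsd = float(np.sqrt((d ** 2).sum(axis=1).mean()))
        best = rmsd if best is None else min(best, rmsd)
    return best


def classify_crystal_like(rmsd: float) -> bool:
    """True iff the protein RMSD is strictly below the 10 Å threshold."""
    if rmsd < 0:
        raise ValidationError("RMSD cannot be negative")
    return rmsd < CRYSTAL_LIKE_THRESHOLD


def validate_against_reference(model, reference,
                               reference_ligand: MolecularStructure | None = None,
                               model_ligand_atoms=None) -> dict:
    """One-stop comparison of a modeled ternary complex to a reference.

    ``reference`` supplies the protein frame; ``reference_ligand`` the
    reference degrader pose (defaults to ``reference.protac_atoms`` when
    the reference is itself a ternary-complex model).  Returns protein
    backbone RMSD, PROTAC RMSD in the same frame, and the crystal-like
    classification.
    """
    fit, n_matched = backbone_superposition(model, reference)
    if reference_ligand is None:
        ref_s = _structure_of(reference)
        ref_idx = getattr(reference, "protac_atoms", None)
        if ref_idx is None:
            raise ValidationError("reference ligand not provided")
        reference_ligand = ref_s.extract(ref_idx)
    lig_rmsd = protac_rmsd(model, reference_ligand, transform=fit,
                           model_ligand_atoms=model_ligand_atoms)
    return {
        "backbone_rmsd_A": float(fit.fit_rmsd),
        "protac_rmsd_A": float(lig_rmsd),
        "n_matched_backbone_atoms": int(n_matched),
        "crystal_like": classify_crystal_like(fit.fit_rmsd),
    }
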