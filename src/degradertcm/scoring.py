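"""Interaction enumeration and the degrader ternary-complex score.

The score ranks degraders by the interactions established by the two
protein-binding moieties — the warhead and the E3 ligand — rather than by
the whole complex:

    score = E_warhead + E_LE3

where each term is the sum of per-interaction energies of that moiety with
the protein component of the ternary complex (linker-mediated contacts are
excluded by construction).  More negative means a more stable complex;
only orderings within a series are meaningful, since absolute values
depend on the energy model.

Interactions are typed LigPlot-style and deduplicated per atom pair with
priority SALT_BRIDGE > HBOND > NONBONDED:

* HBOND        — donor/acceptor N,O pair at <= 3.5 Å with a D–H···A angle
                 >= 120° for at least one donor hydrogen;
* SALT_BRIDGE  — N/O pair of oppositely charged groups at <= 4.0 Å;
* NONBONDED    — any remaining heavy-atom pair at <= 4.0 Å.

Per-interaction energies are pairwise 12-6 Lennard-Jones plus Coulomb with
a distance-dependent dielectric ε = 4r (in kcal/mol, charges in e, r in
Å); for polar interactions the hydrogens of the polar pair are included.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .chem_model import MolecularStructure, VDW_RADII

logger = logging.getLogger("degradertcm")

KIND_PRIORITY = ("SALT_BRIDGE", "HBOND", "NONBONDED")

#: Enumeration cutoff (Å) for nonbonded/salt-bridge pairs.
CONTACT_CUTOFF = 4.0
#: Donor–acceptor heavy-atom cutoff (Å) for hydrogen bonds.
HBOND_CUTOFF = 3.5
#: Minimum D–H···A angle (degrees).
HBOND_MIN_ANGLE = 120.0

#: Coulomb constant, kcal·Å/(mol·e²).
COULOMB_CONSTANT = 332.0637

# 12-6 Lennard-Jones well depths per element, kcal/mol (UFF); sigma is
# derived from the Bondi vdW radius so that r_min = sum of radii.
LJ_EPSILON = {
    "H": 0.044, "C": 0.105, "N": 0.069, "O": 0.060, "F": 0.050,
    "P": 0.305, "S": 0.274, "CL": 0.227, "BR": 0.251, "I": 0.339,
    "B": 0.180, "SI": 0.402, "SE": 0.291,
}
_SIXTH_ROOT_2 = 2.0 ** (1.0 / 6.0)


class ScoringError(ValueError):
    """Raised for overlapping atom selections or missing parameters."""


@dataclass
class Interaction:
    """One typed ligand-atom/protein-atom contact with its energy."""

    kind: str
    ligand_atom: int
    protein_atom: int
    distance: float
    energy: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in KIND_PRIORITY:
            raise ScoringError(f"unknown interaction kind {self.kind!r}")
        if self.distance <= 0:
            raise ScoringError("interaction distance must be positive")


@dataclass
class DegraderScore:
    """The two moiety terms of the score and their exact sum (kcal/mol)."""

    e_warhead: float
    e_le3: float
    total: float
    interactions_warhead: list = field(default_factory=list)
    interactions_le3: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"e_warhead_kcal_mol": self.e_warhead,
                "e_le3_kcal_mol": self.e_le3,
                "total_kcal_mol": self.total,
                "n_warhead_interactions": len(self.interactions_warhead),
                "n_le3_interactions": len(self.interactions_le3)}


@dataclass
class PpiSummary:
    """Protein–protein interface summary of a ternary complex."""

    hbonds: int
    salt_bridges: int
    nonbonded_contacts: int
    interface_residues: dict
    contact_area: float

    def to_dict(self) -> dict:
        return {"hbonds": self.hbonds, "salt_bridges": self.salt_bridges,
                "nonbonded_contacts": self.nonbonded_contacts,
                "interface_residues": {k: sorted(v) for k, v in
                                       self.interface_residues.items()},
                "contact_area_A2": self.contact_area}


def _structure_of(tc) -> MolecularStructure:
    return tc.structure if hasattr(tc, "structure") else tc


def _sigma(element: str) -> float:
    return 2.0 * VDW_RADII.get(element.upper(), 1.7) / _SIXTH_ROOT_2


def _epsilon(element: str) -> float:
    el = element.upper()
    if el not in LJ_EPSILON:
        raise ScoringError(f"no Lennard-Jones parameters for element {element!r}")
    return LJ_EPSILON[el]


def _is_polar_hydrogen(structure: MolecularStructure, idx: int, adj) -> bool:
    atom = structure.atoms[idx]
    if atom.is_heavy:
        return False
    return any(structure.atoms[k].element.upper() in ("N", "O")
               for k in adj[idx])


def pair_energy(structure: MolecularStructure, i: int, j: int, adj=None) -> float:
    """LJ + Coulomb (ε = 4r) energy of one atom pair, kcal/mol.

    Hydrogens bonded to N or O carry no Lennard-Jones term (the standard
    polar-hydrogen treatment: the proton is buried in its heavy atom's
    sphere and interacts electrostatically only).
    """
    ai, aj = structure.atoms[i], structure.atoms[j]
    r = float(np.linalg.norm(ai.coords - aj.coords))
    if r <= 0:
        raise ScoringError(f"coincident atoms {i} and {j}")
    adj = adj if adj is not None else structure.adjacency()
    if _is_polar_hydrogen(structure, i, adj) or _is_polar_hydrogen(structure, j, adj):
        lj = 0.0
    else:
        sigma = 0.5 * (_sigma(ai.element) + _sigma(aj.element))
        eps = float(np.sqrt(_epsilon(ai.element) * _epsilon(aj.element)))
        sr6 = (sigma / r) ** 6
        lj = 4.0 * eps * (sr6 * sr6 - sr6)
    coulomb = COULOMB_CONSTANT * ai.partial_charge * aj.partial_charge / (4.0 * r * r)
    return lj + coulomb


def _is_donor(structure: MolecularStructure, idx: int, adj) -> bool:
    atom = structure.atoms[idx]
    if atom.element.upper() not in ("N", "O"):
        return False
    return any(not structure.atoms[k].is_heavy for k in adj[idx])


def _is_acceptor(structure: MolecularStructure, idx: int) -> bool:
    return structure.atoms[idx].element.upper() in ("N", "O")


def _group_charge(structure: MolecularStructure, idx: int, adj) -> int:
    """Formal charge of the chemical group: the atom plus its neighbors
    (captures carboxylates/ammoniums where the charge sits one atom over)."""
    total = structure.atoms[idx].formal_charge
    for k in adj[idx]:
        total += structure.atoms[k].formal_charge
    return total


def _hbond_geometry_ok(structure: MolecularStructure, donor: int,
                       acceptor: int, adj) -> bool:
    d_pos = structure.atoms[donor].coords
    a_pos = structure.atoms[acceptor].coords
    for h in adj[donor]:
        if structure.atoms[h].is_heavy:
            continue
        h_pos = structure.atoms[h].coords
        v1 = d_pos - h_pos
        v2 = a_pos - h_pos
        cosang = float(np.dot(v1, v2) /
                       (np.linalg.norm(v1) * np.linalg.norm(v2) + 1e-12))
        angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        if angle >= HBOND_MIN_ANGLE:
            return True
    return False


def classify_pair(structure: MolecularStructure, lig: int, rec: int,
                  adj=None) -> str | None:
    """Interaction kind of one heavy-atom pair, or None if beyond cutoff.

    Applies the priority rule SALT_BRIDGE > HBOND > NONBONDED so each pair
    is reported once with its highest-priority kind.
    """
    adj = adj if adj is not None else structure.adjacency()
    d = float(np.linalg.norm(structure.atoms[lig].coords - structure.atoms[rec].coords))
    if d > CONTACT_CUTOFF:
        return None
    polar = (structure.atoms[lig].element.upper() in ("N", "O")
             and structure.atoms[rec].element.upper() in ("N", "O"))
    if polar:
        qa = _group_charge(structure, lig, adj)
        qb = _group_charge(structure, rec, adj)
        if qa * qb < 0:
            return "SALT_BRIDGE"
    if d <= HBOND_CUTOFF:
        if (_is_donor(structure, lig, adj) and _is_acceptor(structure, rec)
                and _hbond_geometry_ok(structure, lig, rec, adj)):
            return "HBOND"
        if (_is_donor(structure, rec, adj) and _is_acceptor(structure, lig)
                and _hbond_geometry_ok(structure, rec, lig, adj)):
            return "HBOND"
    return "NONBONDED"


def enumerate_interactions(tc, ligand_atoms, receptor_atoms) -> list:
    """Typed, deduplicated heavy-atom contacts between two selections.

    Raises on overlapping selections; warns when scoring an unrefined
    model.  Energies are attached via :func:`interaction_energy`.
    """
    structure = _structure_of(tc)
    ligand_atoms = list(ligand_atoms)
    receptor_atoms = list(receptor_atoms)
    if set(ligand_atoms) & set(receptor_atoms):
        raise ScoringError("ligand and receptor atom selections overlap")
    if hasattr(tc, "refined") and not tc.refined:
        warnings.warn("scoring an unrefined ternary-complex model", stacklevel=2)

    from scipy.spatial import cKDTree

    adj = structure.adjacency()
    lig_heavy = [i for i in ligand_atoms if structure.atoms[i].is_heavy]
    rec_heavy = [i for i in receptor_atoms if structure.atoms[i].is_heavy]
    if not lig_heavy or not rec_heavy:
        return []
    coords = structure.coords
    tree = cKDTree(coords[rec_heavy])
    out = []
    for li, neighbors in zip(lig_heavy,
                             tree.query_ball_point(coords[lig_heavy], CONTACT_CUTOFF)):
        for nj in neighbors:
            rj = rec_heavy[nj]
            kind = classify_pair(structure, li, rj, adj)
            if kind is None:
                continue
            d = float(np.linalg.norm(coords[li] - coords[rj]))
            inter = Interaction(kind=kind, ligand_atom=li, protein_atom=rj, distance=d)
            inter.energy = interaction_energy(inter, structure)
            out.append(inter)
    out.sort(key=lambda x: (x.ligand_atom, x.protein_atom))
    return out


def interaction_energy(inter: Interaction, tc) -> float:
    """Energy (kcal/mol) of one interaction under the pairwise model.

    For polar kinds (HBOND, SALT_BRIDGE) the hydrogens bonded to the two
    polar atoms take part as well, so the proton's Coulomb contribution is
    counted.
    """
    structure = _structure_of(tc)
    adj = structure.adjacency()
    i, j = inter.ligand_atom, inter.protein_atom
    members_i = [i]
    members_j = [j]
    if inter.kind in ("HBOND", "SALT_BRIDGE"):
        members_i += structure.bonded_hydrogens(i)
        members_j += structure.bonded_hydrogens(j)
    total = 0.0
    for a in members_i:
        for b in members_j:
            total += pair_energy(structure, a, b, adj)
    if not np.isfinite(total):
        raise ScoringError(f"non-finite energy for pair ({i}, {j})")
    return float(total)


def degradertcm_score(tc, restrict_to_cognate: bool = False) -> DegraderScore:
    """Sum the per-interaction energies of the two protein-binding moieties.

    ``E_warhead`` covers warhead ↔ (POI ∪ E3L) interactions and ``E_LE3``
    the analogous L^E3 term; linker-mediated interactions are excluded.
    With ``restrict_to_cognate=True`` each moiety is scored only against
    its own receptor (warhead↔POI, L^E3↔E3L); by default cross-protein
    contacts count too, since the moieties genuinely touch both proteins
    in compact complexes.
    """
    if not list(tc.warhead_atoms) or not list(tc.le3_atoms):
        raise ScoringError("warhead and L^E3 atom lists must be non-empty")
    proteins = tc.protein_atoms
    rec_w = list(tc.poi_atoms) if restrict_to_cognate else proteins
    rec_e = list(tc.e3l_atoms) if restrict_to_cognate else proteins
    inter_w = enumerate_interactions(tc, tc.warhead_atoms, rec_w)
    inter_e = enumerate_interactions(tc, tc.le3_atoms, rec_e)
    e_w = float(sum(x.energy for x in inter_w))
    e_e = float(sum(x.energy for x in inter_e))
    return DegraderScore(e_warhead=e_w, e_le3=e_e, total=e_w + e_e,
                         interactions_warhead=inter_w, interactions_le3=inter_e)


# ---------------------------------------------------------------------------
# Protein–protein interface summary
# ---------------------------------------------------------------------------

SASA_PROBE_RADIUS = 1.4  # Å
SASA_POINTS = 1000


def _to_atom_array(structure: MolecularStructure, indices):
    import biotite.structure as struc

    indices = list(indices)
    arr = struc.AtomArray(len(indices))
    arr.coord = np.array([structure.atoms[i].coords for i in indices], float)
    arr.element = np.array([structure.atoms[i].element.upper() for i in indices])
    arr.atom_name = np.array([structure.atoms[i].name or structure.atoms[i].element
                              for i in indices])
    arr.res_name = np.array([(structure.atoms[i].residue_name or "UNK")
                             for i in indices])
    arr.res_id = np.array([structure.atoms[i].residue_number or 1 for i in indices])
    arr.chain_id = np.array([(structure.atoms[i].chain_id or "X") for i in indices])
    arr.hetero = np.array([True] * len(indices))
    return arr


def _total_sasa(structure: MolecularStructure, indices) -> float:
    import biotite.structure as struc

    if not list(indices):
        return 0.0
    arr = _to_atom_array(structure, indices)
    radii = np.array([VDW_RADII.get(structure.atoms[i].element.upper(), 1.7)
                      for i in indices])
    values = struc.sasa(arr, probe_radius=SASA_PROBE_RADIUS,
                        point_number=SASA_POINTS, vdw_radii=radii)
    return float(np.nansum(values))


def ppi_summary(tc) -> PpiSummary:
    """Summarize the POI–E3-ligase interface of a ternary complex.

    Counts typed POI↔E3L interactions (PROTAC atoms excluded throughout),
    lists the residues contributing at least one interaction on each side,
    and reports the contact surface as the buried solvent-accessible area
    (SASA(POI) + SASA(E3L) − SASA(both)) / 2 with a 1.4 Å probe.
    """
    structure = _structure_of(tc)
    poi, e3l = list(tc.poi_atoms), list(tc.e3l_atoms)
    interactions = enumerate_interactions(tc, poi, e3l)
    counts = {"HBOND": 0, "SALT_BRIDGE": 0, "NONBONDED": 0}
    residues = {"POI": set(), "E3L": set()}

    def residue_label(idx):
        a = structure.atoms[idx]
        return f"{a.chain_id or 'X'}:{a.residue_name or 'UNK'}{a.residue_number}"

    for inter in interactions:
        counts[inter.kind] += 1
        residues["POI"].add(residue_label(inter.ligand_atom))
        residues["E3L"].add(residue_label(inter.protein_atom))

    sasa_poi = _total_sasa(structure, poi)
    sasa_e3l = _total_sasa(structure, e3l)
    sasa_both = _total_sasa(structure, poi + e3l)
    contact_area = max(0.0, 0.5 * (sasa_poi + sasa_e3l - sasa_both))
    return PpiSummary(
        hbonds=counts["HBOND"], salt_bridges=counts["SALT_BRIDGE"],
        nonbonded_contacts=counts["NONBONDED"],
        interface_residues={k: v for k, v in residues.items()},
        contact_area=contact_area,
    )
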