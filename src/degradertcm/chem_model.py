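"""Chemical data model and file I/O.

Everything downstream — pose transfer, linker assembly, refinement, scoring —
operates on one container, :class:`MolecularStructure`: an ordered atom list
plus an explicit covalent bond list.  Proteins, small molecules and whole
ternary complexes all use it; provenance of each atom inside a ternary
complex (which protein or which degrader fragment it came from) is carried
per-atom in ``origin_tag``.

The module also owns the degrader-specific bookkeeping: cutting a PROTAC
into its three building blocks — warhead, linker and E3 ligand (L^E3) —
across two user-specified acyclic single bonds (:func:`decompose_protac`),
with the two severed atom pairs recorded so the molecular graph can be
reassembled exactly.

File formats: PDB v3 (ATOM/HETATM/CONECT/TER/END), SDF V2000 and SMILES.
The PDB reader/writer is implemented here because we need three guarantees
that generic readers do not give: parse errors that name the offending line,
origin tags encoded in the chain/segment labels so ternary-complex
provenance survives a round trip, and CONECT records emitted for *all*
bonds so connectivity round-trips too.  SDF and SMILES go through RDKit.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger("degradertcm")

# ---------------------------------------------------------------------------
# Element tables
# ---------------------------------------------------------------------------

#: Covalent radii in Å (Cordero 2008); used for distance-based bond
#: perception and ideal junction bond lengths.
COVALENT_RADII = {
    "H": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "SI": 1.11, "P": 1.07, "S": 1.05, "CL": 1.02, "BR": 1.20, "I": 1.39,
    "SE": 1.20, "FE": 1.32, "ZN": 1.22, "NA": 1.66, "K": 2.03, "MG": 1.41,
    "CA": 1.76,
}

#: van der Waals radii in Å (Bondi 1964); used for clash detection and the
#: Lennard-Jones term of the interaction-energy model.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47, "P": 1.80,
    "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98, "B": 1.92, "SI": 2.10,
    "SE": 1.90, "FE": 2.00, "ZN": 1.39, "NA": 2.27, "K": 2.75, "MG": 1.73,
    "CA": 2.31,
}

#: Factor applied to the covalent-radii sum for distance-based bond
#: perception of ligands lacking CONECT records.
BOND_PERCEPTION_FACTOR = 1.25

#: Ideal single-bond lengths (Å) for junction-bond formation; falls back to
#: the covalent-radii sum for pairs not listed.
IDEAL_BOND_LENGTHS = {
    frozenset(["C", "C"]): 1.53,
    frozenset(["C", "N"]): 1.47,
    frozenset(["C", "O"]): 1.43,
    frozenset(["C", "S"]): 1.81,
    frozenset(["C", "H"]): 1.09,
    frozenset(["N", "H"]): 1.01,
    frozenset(["O", "H"]): 0.96,
}

#: Allowed provenance labels for atoms of a ternary complex.
ORIGIN_TAGS = ("POI", "E3L", "WARHEAD", "LINKER", "LE3", "SOLVENT")

# 4-character segment codes used to persist origin tags in PDB files
# (columns 73-76), and per-tag default chain identifiers.
_TAG_TO_SEG = {"POI": "POI", "E3L": "E3L", "WARHEAD": "WARH",
               "LINKER": "LINK", "LE3": "LE3", "SOLVENT": "SOLV"}
_SEG_TO_TAG = {v: k for k, v in _TAG_TO_SEG.items()}
_TAG_TO_CHAIN = {"POI": "A", "E3L": "B", "WARHEAD": "W",
                 "LINKER": "L", "LE3": "E", "SOLVENT": "S"}


class ChemModelError(ValueError):
    """Raised for invalid structures, bad decompositions or format limits."""


class PDBParseError(ChemModelError):
    """Raised when a PDB record cannot be parsed; names the line number."""


def ideal_bond_length(element_a: str, element_b: str) -> float:
    """Ideal single-bond length in Å for an element pair."""
    key = frozenset([element_a.upper(), element_b.upper()])
    if key in IDEAL_BOND_LENGTHS:
        return IDEAL_BOND_LENGTHS[key]
    ra = COVALENT_RADII.get(element_a.upper(), 0.77)
    rb = COVALENT_RADII.get(element_b.upper(), 0.77)
    return ra + rb


# ---------------------------------------------------------------------------
# Core types
# ---------------------------------------------------------------------------

@dataclass
class Atom:
    """A single atom with coordinates in Å and provenance labels.

    ``residue_name``/``residue_number``/``chain_id`` are empty/zero for bare
    small molecules.  ``origin_tag`` is one of :data:`ORIGIN_TAGS` (or empty
    before an atom is assigned to a ternary-complex component).
    """

    element: str
    coords: np.ndarray
    formal_charge: int = 0
    partial_charge: float = 0.0
    name: str = ""
    residue_name: str = ""
    residue_number: int = 0
    chain_id: str = ""
    origin_tag: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ChemModelError(f"atom coords must be a 3-vector, got shape {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ChemModelError("atom coords must be finite")
        el = self.element.strip()
        if not el or el.upper() not in VDW_RADII and el.upper() not in COVALENT_RADII and el.upper() != "D":
            raise ChemModelError(f"unknown element symbol {self.element!r}")
        self.element = el[0].upper() + el[1:].lower() if len(el) > 1 else el.upper()
        if self.origin_tag and self.origin_tag not in ORIGIN_TAGS:
            raise ChemModelError(f"unknown origin tag {self.origin_tag!r}")
        if not self.name:
            self.name = self.element

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"

    def copy(self) -> "Atom":
        return replace(self, coords=self.coords.copy())


@dataclass
class MolecularStructure:
    """An ordered atom list plus a unique, symmetric-free covalent bond list.

    Bonds are ``(i, j, order)`` with ``i < j`` after validation and each
    unordered pair stored once.  ``meta`` carries light bookkeeping (e.g.
    junction atom indices on decomposed fragments) and is never required
    for correctness of the graph itself.
    """

    atoms: list = field(default_factory=list)
    bonds: list = field(default_factory=list)
    title: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ----------------------------------------------------

    def validate(self) -> None:
        n = len(self.atoms)
        seen = set()
        norm = []
        for bond in self.bonds:
            i, j, order = bond
            if not (0 <= i < n and 0 <= j < n):
                raise ChemModelError(f"bond index out of range: {bond}")
            if i == j:
                raise ChemModelError(f"self-bond not allowed: {bond}")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ChemModelError(f"duplicate bond {key}")
            seen.add(key)
            norm.append((key[0], key[1], float(order)))
        self.bonds = norm

    # -- convenience ---------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.coords for a in self.atoms])

    @coords.setter
    def coords(self, value: np.ndarray) -> None:
        value = np.asarray(value, dtype=float)
        if value.shape != (len(self.atoms), 3):
            raise ChemModelError("coordinate array shape mismatch")
        for atom, xyz in zip(self.atoms, value):
            atom.coords = xyz.copy()

    @property
    def elements(self) -> list:
        return [a.element for a in self.atoms]

    def heavy_indices(self) -> list:
        return [i for i, a in enumerate(self.atoms) if a.is_heavy]

    def adjacency(self) -> dict:
        adj = {i: set() for i in range(len(self.atoms))}
        for i, j, _ in self.bonds:
            adj[i].add(j)
            adj[j].add(i)
        return adj

    def copy(self) -> "MolecularStructure":
        return MolecularStructure(
            atoms=[a.copy() for a in self.atoms],
            bonds=list(self.bonds),
            title=self.title,
            meta=dict(self.meta),
        )

    def extract(self, indices) -> "MolecularStructure":
        """Sub-structure over ``indices`` (order kept); records the mapping
        back to parent indices in ``meta['parent_indices']``."""
        indices = list(indices)
        index_map = {old: new for new, old in enumerate(indices)}
        atoms = [self.atoms[i].copy() for i in indices]
        bonds = [(index_map[i], index_map[j], o) for i, j, o in self.bonds
                 if i in index_map and j in index_map]
        sub = MolecularStructure(atoms=atoms, bonds=bonds, title=self.title)
        sub.meta["parent_indices"] = indices
        return sub

    def merged_with(self, other: "MolecularStructure") -> "MolecularStructure":
        """Concatenate two structures (no new bonds)."""
        offset = len(self.atoms)
        atoms = [a.copy() for a in self.atoms] + [a.copy() for a in other.atoms]
        bonds = list(self.bonds) + [(i + offset, j + offset, o) for i, j, o in other.bonds]
        return MolecularStructure(atoms=atoms, bonds=bonds, title=self.title or other.title)

    def add_bond(self, i: int, j: int, order: float = 1.0) -> None:
        self.bonds.append((i, j, order))
        self.validate()

    def bonded_hydrogens(self, index: int) -> list:
        adj = self.adjacency()
        return [k for k in adj[index] if not self.atoms[k].is_heavy]

    def graph(self):
        """The molecular graph as a networkx Graph with ``element`` node data."""
        import networkx as nx

        g = nx.Graph()
        for i, a in enumerate(self.atoms):
            g.add_node(i, element=a.element)
        for i, j, o in self.bonds:
            g.add_edge(i, j, order=o)
        return g


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _parse_element(record: str, name_field: str) -> str:
    el = record[76:78].strip() if len(record) >= 78 else ""
    if el and el.upper() in VDW_RADII:
        return el
    # fall back on the atom-name field: first alphabetic character(s)
    name = name_field.strip()
    if len(name) >= 2 and name[:2].upper() in ("CL", "BR", "FE", "ZN", "MG", "NA", "SE", "SI"):
        return name[:2]
    for ch in name:
        if ch.isalpha():
            return ch
    raise ValueError(f"cannot deduce element from atom name {name!r}")


def read_pdb(path, infer_bonds: str = "auto") -> MolecularStructure:
    """Read a PDB v3 file into a :class:`MolecularStructure`.

    One atom per ATOM/HETATM record; CONECT records become bonds (order 1,
    PDB carries no bond orders).  Chain and residue labels are preserved;
    origin tags are recovered from the segment-identifier column when
    present.  With ``infer_bonds='auto'`` and no CONECT records at all,
    bonds are perceived from distances (covalent-radii sum × 1.25) with a
    warning — a common deficiency of ligand PDB files.

    Raises :class:`PDBParseError` naming the line number for malformed
    records, and :class:`ChemModelError` for an empty file.
    """
    from collections import Counter

    atoms = []
    serial_to_index = {}
    bond_counts: Counter = Counter()  # directed (src, dst) multiplicities
    saw_conect = False
    title = ""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            rec = line[:6].strip()
            if rec == "TITLE":
                title = (title + " " + line[10:].strip()).strip()
            elif rec in ("ATOM", "HETATM"):
                try:
                    serial = int(line[6:11])
                    name = line[12:16]
                    res_name = line[17:20].strip()
                    chain = line[21].strip()
                    res_num = int(line[22:26])
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                    seg = line[72:76].strip() if len(line) >= 76 else ""
                    element = _parse_element(line, name)
                except (ValueError, IndexError) as exc:
                    raise PDBParseError(
                        f"{path}: malformed {rec} record at line {lineno}: {exc}"
                    ) from None
                atom = Atom(
                    element=element,
                    coords=np.array([x, y, z]),
                    name=name.strip(),
                    residue_name=res_name,
                    residue_number=res_num,
                    chain_id=chain,
                    origin_tag=_SEG_TO_TAG.get(seg, ""),
                )
                serial_to_index[serial] = len(atoms)
                atoms.append(atom)
            elif rec == "CONECT":
                saw_conect = True
                try:
                    fields = [line[6:11]] + [line[11 + 5 * k:16 + 5 * k] for k in range(4)]
                    serials = [int(f) for f in fields if f.strip()]
                except ValueError:
                    raise PDBParseError(
                        f"{path}: malformed CONECT record at line {lineno}"
                    ) from None
                if serials:
                    src = serials[0]
                    for dst in serials[1:]:
                        if src in serial_to_index and dst in serial_to_index:
                            a, b = serial_to_index[src], serial_to_index[dst]
                            if a != b:
                                bond_counts[(a, b)] += 1
    if not atoms:
        raise ChemModelError(f"{path}: no ATOM/HETATM records found")
    # duplicated CONECT entries encode bond order (PDB convention); the two
    # directions are written symmetrically, so take the larger multiplicity
    bonds = {}
    for (a, b), count in bond_counts.items():
        key = (min(a, b), max(a, b))
        bonds[key] = max(bonds.get(key, 0), count)
    structure = MolecularStructure(
        atoms=atoms,
        bonds=[(i, j, float(min(order, 3))) for (i, j), order in sorted(bonds.items())],
        title=title,
    )
    if not saw_conect and infer_bonds in ("auto", "always"):
        warnings.warn(
            f"{path}: no CONECT records; perceiving bonds from distances "
            f"(covalent-radii sum × {BOND_PERCEPTION_FACTOR})",
            stacklevel=2,
        )
        structure = perceive_bonds(structure)
    elif infer_bonds == "always":
        structure = perceive_bonds(structure)
    return structure


def perceive_bonds(structure: MolecularStructure) -> MolecularStructure:
    """Distance-based bond perception: bond any atom pair closer than
    ``BOND_PERCEPTION_FACTOR`` × (covalent-radii sum).  Existing bonds kept."""
    from scipy.spatial import cKDTree

    coords = structure.coords
    if len(coords) < 2:
        return structure
    radii = np.array([COVALENT_RADII.get(a.element.upper(), 0.77) for a in structure.atoms])
    cutoff = BOND_PERCEPTION_FACTOR * 2.0 * radii.max()
    tree = cKDTree(coords)
    existing = {(i, j) for i, j, _ in structure.bonds}
    bonds = list(structure.bonds)
    for i, j in sorted(tree.query_pairs(cutoff)):
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d < BOND_PERCEPTION_FACTOR * (radii[i] + radii[j]) and (i, j) not in existing:
            # never bond two hydrogens
            if structure.atoms[i].element == "H" and structure.atoms[j].element == "H":
                continue
            bonds.append((i, j, 1.0))
    out = structure.copy()
    out.bonds = bonds
    out.validate()
    return out


def write_pdb(structure: MolecularStructure, path) -> None:
    """Write a PDB v3 file.

    Origin tags are stored in the segment-identifier column (73–76) and, for
    atoms lacking an explicit chain, in per-tag default chain letters, so
    ternary-complex provenance survives a round trip.  CONECT records are
    written for every bond.  Raises for more than 99 999 atoms (format
    serial-number limit).
    """
    if structure.n_atoms > 99999:
        raise ChemModelError("PDB format limit: more than 99999 atoms")
    lines = []
    if structure.title:
        lines.append(f"TITLE     {structure.title[:60]}")
    for idx, atom in enumerate(structure.atoms):
        serial = idx + 1
        tag = atom.origin_tag
        chain = atom.chain_id or (_TAG_TO_CHAIN.get(tag, "X") if tag else "X")
        res_name = (atom.residue_name or ("LIG" if not tag or tag in
                    ("WARHEAD", "LINKER", "LE3") else "UNK"))[:3]
        res_num = atom.residue_number or 1
        seg = _TAG_TO_SEG.get(tag, "")
        record = "ATOM  " if atom.residue_name and atom.residue_name not in ("LIG", "UNL") else "HETATM"
        name = atom.name[:4]
        # PDB atom-name alignment: single-letter elements start in column 14
        name_field = f" {name:<3s}" if len(atom.element) == 1 and len(name) < 4 else f"{name:<4s}"
        x, y, z = atom.coords
        lines.append(
            f"{record}{serial:5d} {name_field}"
            f" {res_name:<3s} {chain:1s}{res_num:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}      "
            f"{seg:<4s}{atom.element.upper():>2s}"
        )
    # duplicated partner entries encode bond order (PDB convention)
    adj = {}
    for i, j, order in structure.bonds:
        mult = max(1, int(round(order))) if order != 1.5 else 1
        adj.setdefault(i, []).extend([j] * mult)
        adj.setdefault(j, []).extend([i] * mult)
    for i in sorted(adj):
        partners = sorted(adj[i])
        for k in range(0, len(partners), 4):
            chunk = partners[k:k + 4]
            lines.append("CONECT" + f"{i + 1:5d}" + "".join(f"{p + 1:5d}" for p in chunk))
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# RDKit bridge + SDF/SMILES
# ---------------------------------------------------------------------------

_BOND_ORDER_TO_RDKIT = None


def _bond_type(order: float):
    from rdkit import Chem

    global _BOND_ORDER_TO_RDKIT
    if _BOND_ORDER_TO_RDKIT is None:
        _BOND_ORDER_TO_RDKIT = {
            1.0: Chem.BondType.SINGLE, 2.0: Chem.BondType.DOUBLE,
            3.0: Chem.BondType.TRIPLE, 1.5: Chem.BondType.AROMATIC,
        }
    return _BOND_ORDER_TO_RDKIT.get(float(order), Chem.BondType.SINGLE)


def structure_to_mol(structure: MolecularStructure, sanitize: bool = True):
    """Convert to an RDKit Mol (explicit atoms only, no implicit hydrogens).

    Open valences become radical centers, which UFF types by element and
    hybridization; full sanitization is attempted first and relaxed to the
    minimal property computation if it fails (e.g. exotic valence states).
    """
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    rw = Chem.RWMol()
    for atom in structure.atoms:
        a = Chem.Atom(atom.element)
        a.SetFormalCharge(atom.formal_charge)
        a.SetNoImplicit(True)
        rw.AddAtom(a)
    for i, j, order in structure.bonds:
        rw.AddBond(i, j, _bond_type(order))
    mol = rw.GetMol()
    if sanitize:
        try:
            Chem.SanitizeMol(mol)
        except Exception:
            flags = (Chem.SanitizeFlags.SANITIZE_FINDRADICALS
                     | Chem.SanitizeFlags.SANITIZE_SETHYBRIDIZATION
                     | Chem.SanitizeFlags.SANITIZE_SETCONJUGATION
                     | Chem.SanitizeFlags.SANITIZE_SYMMRINGS)
            Chem.SanitizeMol(mol, flags)
    if structure.n_atoms:
        conf = Chem.Conformer(structure.n_atoms)
        for i, atom in enumerate(structure.atoms):
            conf.SetAtomPosition(i, Point3D(*map(float, atom.coords)))
        mol.AddConformer(conf, assignId=True)
    return mol


def mol_to_structure(mol, title: str = "") -> MolecularStructure:
    """Convert an RDKit Mol (with a conformer, or all-zero coordinates)."""
    from rdkit import Chem

    conf = mol.GetConformer() if mol.GetNumConformers() else None
    atoms = []
    for atom in mol.GetAtoms():
        pos = conf.GetAtomPosition(atom.GetIdx()) if conf else None
        coords = np.array([pos.x, pos.y, pos.z]) if pos is not None else np.zeros(3)
        atoms.append(Atom(element=atom.GetSymbol(), coords=coords,
                          formal_charge=atom.GetFormalCharge()))
    order_map = {Chem.BondType.SINGLE: 1.0, Chem.BondType.DOUBLE: 2.0,
                 Chem.BondType.TRIPLE: 3.0, Chem.BondType.AROMATIC: 1.5}
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx(),
              order_map.get(b.GetBondType(), 1.0)) for b in mol.GetBonds()]
    return MolecularStructure(atoms=atoms, bonds=bonds,
                              title=title or mol.GetProp("_Name") if mol.HasProp("_Name") else title)


def from_smiles(smiles: str, add_hydrogens: bool = False) -> MolecularStructure:
    """Parse a SMILES string (no 3D coordinates are generated)."""
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ChemModelError(f"invalid SMILES: {smiles!r}")
    if add_hydrogens:
        mol = Chem.AddHs(mol)
    return mol_to_structure(mol)


def read_sdf(path) -> MolecularStructure:
    """Read the first molecule of an SDF (V2000) file, hydrogens kept."""
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    for mol in supplier:
        if mol is not None:
            return mol_to_structure(mol)
    raise ChemModelError(f"{path}: no parsable molecule found")


def write_sdf(structure: MolecularStructure, path) -> None:
    from rdkit import Chem

    mol = structure_to_mol(structure)
    mol.SetProp("_Name", structure.title or "")
    with Chem.SDWriter(str(path)) as writer:
        writer.write(mol)


# ---------------------------------------------------------------------------
# Standardization: hydrogens + partial charges
# ---------------------------------------------------------------------------

def assign_partial_charges(structure: MolecularStructure) -> MolecularStructure:
    """Assign Gasteiger partial charges in place of whatever is stored.

    Atoms whose charge could not be computed (NaN from exotic types) fall
    back to their formal charge.
    """
    from rdkit.Chem import AllChem

    mol = structure_to_mol(structure)
    AllChem.ComputeGasteigerCharges(mol)
    out = structure.copy()
    for i, atom in enumerate(mol.GetAtoms()):
        q = atom.GetDoubleProp("_GasteigerCharge")
        if not math.isfinite(q):
            q = float(structure.atoms[i].formal_charge)
        out.atoms[i].partial_charge = q
    return out


def add_hydrogens(structure: MolecularStructure,
                  skip_indices=()) -> MolecularStructure:
    """Add explicit hydrogens with 3D positions (RDKit AddHs), standard
    neutral-pH protonation as encoded by formal charges already present.

    ``skip_indices`` marks atoms whose open valence must be preserved (e.g.
    fragment junction atoms): no hydrogens are added to them.
    """
    from rdkit import Chem

    mol = structure_to_mol(structure)
    skip = set(skip_indices)
    for atom in mol.GetAtoms():
        if atom.GetIdx() in skip:
            continue
        # let RDKit recompute implicit valence for non-junction atoms
        atom.SetNoImplicit(False)
        atom.SetNumRadicalElectrons(0)
    Chem.SanitizeMol(mol)
    mol = Chem.AddHs(mol, addCoords=True)
    out = mol_to_structure(mol, title=structure.title)
    # carry labels for the original atoms (AddHs appends, order preserved)
    for i, atom in enumerate(structure.atoms):
        new = out.atoms[i]
        new.name, new.residue_name = atom.name, atom.residue_name
        new.residue_number, new.chain_id = atom.residue_number, atom.chain_id
        new.origin_tag = atom.origin_tag
    for atom_new in out.atoms[len(structure.atoms):]:
        atom_new.origin_tag = ""
    return out


# ---------------------------------------------------------------------------
# Clash kernel (shared by pose placement and refinement)
# ---------------------------------------------------------------------------

#: Fraction of the van-der-Waals radii sum below which a heavy-atom pair
#: counts as a steric clash.
CLASH_VDW_FACTOR = 0.7


def clash_distance(element_a: str, element_b: str,
                   factor: float = CLASH_VDW_FACTOR) -> float:
    ra = VDW_RADII.get(element_a.upper(), 1.7)
    rb = VDW_RADII.get(element_b.upper(), 1.7)
    return factor * (ra + rb)


def clashing_pairs_between(coords_a, elements_a, coords_b, elements_b,
                           factor: float = CLASH_VDW_FACTOR):
    """All (i, j, distance) with distance < factor × vdW-radii sum between
    two coordinate sets (no exclusions; caller handles bonded pairs)."""
    from scipy.spatial import cKDTree

    coords_a = np.asarray(coords_a, float)
    coords_b = np.asarray(coords_b, float)
    if len(coords_a) == 0 or len(coords_b) == 0:
        return []
    ra = np.array([VDW_RADII.get(e.upper(), 1.7) for e in elements_a])
    rb = np.array([VDW_RADII.get(e.upper(), 1.7) for e in elements_b])
    cutoff = factor * (ra.max() + rb.max())
    tree = cKDTree(coords_b)
    out = []
    for i, neighbors in enumerate(tree.query_ball_point(coords_a, cutoff)):
        for j in neighbors:
            d = float(np.linalg.norm(coords_a[i] - coords_b[j]))
            if d < factor * (ra[i] + rb[j]):
                out.append((i, j, d))
    out.sort(key=lambda t: t[2])
    return out


# ---------------------------------------------------------------------------
# PROTAC decomposition
# ---------------------------------------------------------------------------

@dataclass
class ProtacDecomposition:
    """The warhead / linker / L^E3 triad of a degrader.

    ``junction_w`` is ``(warhead attachment atom, linker attachment atom)``
    and ``junction_e`` is ``(le3 attachment atom, linker attachment atom)``,
    both in the *local* indices of the respective fragments.  Each fragment's
    ``meta['parent_indices']`` maps back to the intact PROTAC, and the
    linker's ``meta['junctions']`` lists its two attachment atoms (warhead
    end first).  Open valences at attachment atoms are not capped.
    """

    warhead: MolecularStructure
    linker: MolecularStructure
    le3: MolecularStructure
    junction_w: tuple
    junction_e: tuple


def _bond_in_ring(structure: MolecularStructure, i: int, j: int) -> bool:
    """A bond is in a ring iff its removal leaves i and j connected."""
    adj = structure.adjacency()
    adj[i].discard(j)
    adj[j].discard(i)
    stack, seen = [i], {i}
    while stack:
        node = stack.pop()
        if node == j:
            return True
        for nb in adj[node]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return False


def _components(n_atoms: int, bonds) -> list:
    adj = {i: set() for i in range(n_atoms)}
    for i, j in bonds:
        adj[i].add(j)
        adj[j].add(i)
    seen = set()
    comps = []
    for start in range(n_atoms):
        if start in seen:
            continue
        comp, stack = [], [start]
        seen.add(start)
        while stack:
            node = stack.pop()
            comp.append(node)
            for nb in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        comps.append(sorted(comp))
    return comps


def decompose_protac(protac, cut_bond_w, cut_bond_e) -> ProtacDecomposition:
    """Cut a PROTAC into warhead, linker and L^E3 across two acyclic single
    bonds.

    ``protac`` may be a :class:`MolecularStructure` or a SMILES string.  The
    linker is the component containing one endpoint of each cut bond; the
    component on the other side of ``cut_bond_w`` is the warhead, the
    remaining one the E3 ligand.  Reassembling the three fragments across
    the two junctions reproduces the input molecular graph exactly.
    """
    if isinstance(protac, str):
        protac = from_smiles(protac, add_hydrogens=False)
    bond_keys = {(min(i, j), max(i, j)): (i, j, o) for i, j, o in protac.bonds}

    cuts = []
    for label, (a, b) in (("cut_bond_w", tuple(cut_bond_w)), ("cut_bond_e", tuple(cut_bond_e))):
        key = (min(a, b), max(a, b))
        if key not in bond_keys:
            raise ChemModelError(f"{label}: atoms {a}-{b} are not bonded")
        if bond_keys[key][2] != 1.0:
            raise ChemModelError(f"{label}: cut bond must be a single bond")
        if _bond_in_ring(protac, *key):
            raise ChemModelError(f"{label}: cut bond must be acyclic")
        cuts.append(key)
    if cuts[0] == cuts[1]:
        raise ChemModelError("the two cut bonds must be distinct")

    kept = [(i, j) for i, j, _ in protac.bonds if (i, j) not in cuts]
    comps = _components(protac.n_atoms, kept)
    if len(comps) != 3:
        raise ChemModelError(
            f"removing the two cut bonds yields {len(comps)} components, expected 3")

    def component_of(atom):
        for c in comps:
            if atom in set(c):
                return tuple(c)
        raise AssertionError

    (w_end_a, w_end_b), (e_end_a, e_end_b) = cuts
    # the linker component touches one endpoint of each cut
    linker_comp = None
    for c in comps:
        cs = set(c)
        if (w_end_a in cs or w_end_b in cs) and (e_end_a in cs or e_end_b in cs):
            linker_comp = tuple(c)
            break
    if linker_comp is None:
        raise ChemModelError(
            "cut bonds do not share a middle component; check warhead/linker/L^E3 topology")
    w_link_atom = w_end_a if w_end_a in set(linker_comp) else w_end_b
    w_moiety_atom = w_end_b if w_link_atom == w_end_a else w_end_a
    e_link_atom = e_end_a if e_end_a in set(linker_comp) else e_end_b
    e_moiety_atom = e_end_b if e_link_atom == e_end_a else e_end_a
    warhead_comp = component_of(w_moiety_atom)
    le3_comp = component_of(e_moiety_atom)
    if warhead_comp == le3_comp:
        raise ChemModelError("warhead and L^E3 cuts point into the same component")

    def build(comp, tag):
        sub = protac.extract(list(comp))
        for atom in sub.atoms:
            atom.origin_tag = tag
        return sub, {old: new for new, old in enumerate(comp)}

    warhead, w_map = build(warhead_comp, "WARHEAD")
    linker, l_map = build(linker_comp, "LINKER")
    le3, e_map = build(le3_comp, "LE3")
    linker.meta["junctions"] = (l_map[w_link_atom], l_map[e_link_atom])
    return ProtacDecomposition(
        warhead=warhead, linker=linker, le3=le3,
        junction_w=(w_map[w_moiety_atom], l_map[w_link_atom]),
        junction_e=(e_map[e_moiety_atom], l_map[e_link_atom]),
    )


def reassemble_protac(dec: ProtacDecomposition) -> MolecularStructure:
    """Rejoin the three fragments across the two junctions (graph identity
    with the input PROTAC up to atom reordering)."""
    merged = dec.warhead.merged_with(dec.linker).merged_with(dec.le3)
    off_l = dec.warhead.n_atoms
    off_e = off_l + dec.linker.n_atoms
    merged.add_bond(dec.junction_w[0], off_l + dec.junction_w[1])
    merged.add_bond(off_e + dec.junction_e[0], off_l + dec.junction_e[1])
    return merged
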