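"""Linker-constrained assembly of the ternary complex.

The degrader's linker is used as a geometric constraint: a single
full-length 3D conformer of the linker is built de novo, attached
separately to the POI–warhead and E3L–L^E3 complexes (leaving both binding
poses untouched), each half is minimized with the linker free, and the two
linker copies are then superposed to obtain the reciprocal orientation of
the two proteins.  The redundant (E3-side) linker copy is deleted and the
PROTAC reconnected, giving an approximate ternary-complex model whose
linker-superposition RMSD is recorded as ``assembly_rmsd`` — the explicit
diagnostic of how far the two separately minimized linker conformers
diverged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .chem_model import (
    ChemModelError,
    MolecularStructure,
    VDW_RADII,
    ideal_bond_length,
)
from .engine import MinimizationConfig, minimize
from .pose_placement import RigidTransform, kabsch_fit

logger = logging.getLogger("degradertcm")

SIDES = ("POI_SIDE", "E3_SIDE")


class AssemblyError(ValueError):
    """Raised for invalid half-complexes or impossible merges."""


@dataclass
class HalfComplex:
    """One protein with its bound moiety and the full-length linker attached.

    ``protein_atoms``, ``moiety_atoms`` and ``linker_atoms`` partition the
    atom indices of ``structure``; the linker is covalently bonded to the
    moiety at exactly one junction.  The free (unreacted) linker end is
    tracked so the merge step can form the second junction bond.
    """

    structure: MolecularStructure
    protein_atoms: list
    moiety_atoms: list
    linker_atoms: list
    side: str
    moiety_junction: int = -1        # moiety atom bonded to the linker
    linker_inner_junction: int = -1  # linker atom bonded to the moiety
    linker_open_junction: int = -1   # linker atom with the free valence

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise AssemblyError(f"side must be one of {SIDES}")
        parts = [set(self.protein_atoms), set(self.moiety_atoms), set(self.linker_atoms)]
        union = set().union(*parts)
        if sum(len(p) for p in parts) != len(union) or union != set(range(self.structure.n_atoms)):
            raise AssemblyError("protein/moiety/linker index lists must partition all atoms")
        moiety, linker = parts[1], parts[2]
        crossing = [
            (i, j) for i, j, _ in self.structure.bonds
            if (i in moiety and j in linker) or (i in linker and j in moiety)
        ]
        if len(crossing) != 1:
            raise AssemblyError(
                f"linker must bond the moiety at exactly one junction, found {len(crossing)}")

    def copy(self) -> "HalfComplex":
        return HalfComplex(
            structure=self.structure.copy(),
            protein_atoms=list(self.protein_atoms),
            moiety_atoms=list(self.moiety_atoms),
            linker_atoms=list(self.linker_atoms),
            side=self.side,
            moiety_junction=self.moiety_junction,
            linker_inner_junction=self.linker_inner_junction,
            linker_open_junction=self.linker_open_junction,
        )


@dataclass
class TernaryComplexModel:
    """Merged POI + E3 ligase + intact PROTAC with per-fragment provenance.

    The five index lists partition the atoms; the PROTAC subgraph
    (warhead ∪ linker ∪ L^E3) is connected with exactly two bonds crossing
    fragment boundaries.  ``assembly_rmsd`` is the linker-superposition fit
    RMSD from the merge.
    """

    structure: MolecularStructure
    poi_atoms: list
    e3l_atoms: list
    warhead_atoms: list
    linker_atoms: list
    le3_atoms: list
    assembly_rmsd: float = 0.0
    refined: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        groups = [self.poi_atoms, self.e3l_atoms, self.warhead_atoms,
                  self.linker_atoms, self.le3_atoms]
        union = set().union(*(set(g) for g in groups))
        if sum(len(g) for g in groups) != len(union) or union != set(range(self.structure.n_atoms)):
            raise AssemblyError("fragment index lists must partition all atoms")
        protac = set(self.warhead_atoms) | set(self.linker_atoms) | set(self.le3_atoms)
        frag_of = {}
        for name, grp in (("W", self.warhead_atoms), ("L", self.linker_atoms),
                          ("E", self.le3_atoms)):
            for i in grp:
                frag_of[i] = name
        crossing = [(i, j) for i, j, _ in self.structure.bonds
                    if i in frag_of and j in frag_of and frag_of[i] != frag_of[j]]
        if len(crossing) != 2:
            raise AssemblyError(
                f"PROTAC must have exactly two junction bonds, found {len(crossing)}")
        # connectivity of the PROTAC subgraph
        adj = {i: set() for i in protac}
        for i, j, _ in self.structure.bonds:
            if i in protac and j in protac:
                adj[i].add(j)
                adj[j].add(i)
        if protac:
            start = next(iter(protac))
            seen, stack = {start}, [start]
            while stack:
                node = stack.pop()
                for nb in adj[node]:
                    if nb not in seen:
                        seen.add(nb)
                        stack.append(nb)
            if seen != protac:
                raise AssemblyError("PROTAC subgraph must be connected")

    @property
    def protac_atoms(self) -> list:
        return sorted(set(self.warhead_atoms) | set(self.linker_atoms) | set(self.le3_atoms))

    @property
    def protein_atoms(self) -> list:
        return sorted(set(self.poi_atoms) | set(self.e3l_atoms))

    def copy(self) -> "TernaryComplexModel":
        return TernaryComplexModel(
            structure=self.structure.copy(),
            poi_atoms=list(self.poi_atoms), e3l_atoms=list(self.e3l_atoms),
            warhead_atoms=list(self.warhead_atoms),
            linker_atoms=list(self.linker_atoms), le3_atoms=list(self.le3_atoms),
            assembly_rmsd=self.assembly_rmsd, refined=self.refined,
        )


# ---------------------------------------------------------------------------
# Reconstruction from tagged structures (PDB round trips)
# ---------------------------------------------------------------------------

_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "P": 3, "H": 1}


def half_complex_from_structure(structure: MolecularStructure) -> HalfComplex:
    """Rebuild a :class:`HalfComplex` from origin tags (e.g. after PDB I/O).

    Junction bookkeeping is re-derived: the inner junction from the single
    moiety–linker bond, the open junction as the linker heavy atom with an
    unsatisfied valence (its free end).
    """
    groups = {"protein": [], "moiety": [], "linker": []}
    moiety_tag = None
    for i, atom in enumerate(structure.atoms):
        tag = atom.origin_tag
        if tag in ("POI", "E3L"):
            groups["protein"].append(i)
        elif tag in ("WARHEAD", "LE3"):
            groups["moiety"].append(i)
            moiety_tag = tag
        elif tag == "LINKER":
            groups["linker"].append(i)
        else:
            raise AssemblyError(f"atom {i} carries no usable origin tag ({tag!r})")
    if moiety_tag is None:
        raise AssemblyError("structure has no moiety (WARHEAD/LE3) atoms")
    side = "POI_SIDE" if moiety_tag == "WARHEAD" else "E3_SIDE"
    moiety, linker = set(groups["moiety"]), set(groups["linker"])
    junction_bonds = [(i, j) for i, j, _ in structure.bonds
                      if (i in moiety and j in linker) or (i in linker and j in moiety)]
    if len(junction_bonds) != 1:
        raise AssemblyError(
            f"expected one moiety–linker junction bond, found {len(junction_bonds)}")
    i, j = junction_bonds[0]
    moiety_junction, inner = (i, j) if i in moiety else (j, i)

    adj = structure.adjacency()
    deficits = []
    for k in groups["linker"]:
        atom = structure.atoms[k]
        if not atom.is_heavy:
            continue
        expected = _VALENCE.get(atom.element.upper(), 4)
        if len(adj[k]) < expected:
            deficits.append(k)
    open_candidates = [k for k in deficits if k != inner] or deficits
    if not open_candidates:
        raise AssemblyError("could not locate the linker's free (open-valence) end")
    return HalfComplex(
        structure=structure,
        protein_atoms=groups["protein"],
        moiety_atoms=groups["moiety"],
        linker_atoms=groups["linker"],
        side=side,
        moiety_junction=moiety_junction,
        linker_inner_junction=inner,
        linker_open_junction=open_candidates[0],
    )


def tc_from_structure(structure: MolecularStructure,
                      refined: bool = False) -> TernaryComplexModel:
    """Rebuild a :class:`TernaryComplexModel` from origin tags."""
    groups = {"POI": [], "E3L": [], "WARHEAD": [], "LINKER": [], "LE3": []}
    for i, atom in enumerate(structure.atoms):
        if atom.origin_tag not in groups:
            raise AssemblyError(f"atom {i} carries no usable origin tag")
        groups[atom.origin_tag].append(i)
    return TernaryComplexModel(
        structure=structure,
        poi_atoms=groups["POI"], e3l_atoms=groups["E3L"],
        warhead_atoms=groups["WARHEAD"], linker_atoms=groups["LINKER"],
        le3_atoms=groups["LE3"], refined=refined,
    )


# ---------------------------------------------------------------------------
# Linker conformer generation
# ---------------------------------------------------------------------------

def build_linker_3d(linker: MolecularStructure, seed: int,
                    junctions=None) -> MolecularStructure:
    """Build one low-energy 3D conformer of the linker fragment de novo.

    ``junctions`` are the two attachment-atom indices (warhead end first);
    they default to ``linker.meta['junctions']`` as recorded by
    ``decompose_protac``.  Hydrogens are added everywhere except at the two
    junction valences, which stay open; the direction each open valence
    points is recorded in ``meta['open_directions']``.  Embedding (ETKDG)
    is seeded and retried up to 50 times with derived seeds before giving
    up; output is deterministic for a fixed seed.
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem, rdForceFieldHelpers

    if linker.n_atoms < 1:
        raise AssemblyError("linker must have at least one atom")
    if junctions is None:
        junctions = linker.meta.get("junctions")
    if junctions is None:
        raise AssemblyError("junction atoms not specified and not found in meta")
    jw, je = int(junctions[0]), int(junctions[1])

    from .chem_model import structure_to_mol

    heavy = [i for i, a in enumerate(linker.atoms) if a.is_heavy]
    if set(heavy) != set(range(len(heavy))) or len(heavy) != linker.n_atoms:
        # keep it simple: the decomposed fragment carries heavy atoms first
        # (hydrogens, if any, are regenerated here anyway)
        linker = linker.extract(heavy)
        jw = heavy.index(junctions[0]) if junctions[0] in heavy else jw
        je = heavy.index(junctions[1]) if junctions[1] in heavy else je

    mol = structure_to_mol(linker, sanitize=True)
    for atom in mol.GetAtoms():
        atom.SetNoImplicit(False)
        atom.SetNumRadicalElectrons(0)
    Chem.SanitizeMol(mol)
    molh = Chem.AddHs(mol)

    params = AllChem.ETKDGv3()
    params.useRandomCoords = False
    ok = False
    for attempt in range(50):
        params.randomSeed = int((seed + attempt) % (2 ** 31 - 1))
        if AllChem.EmbedMolecule(molh, params) == 0:
            ok = True
            break
    if not ok:
        raise AssemblyError("linker embedding failed after 50 seeded retries")
    ff = rdForceFieldHelpers.UFFGetMoleculeForceField(molh)
    if ff is not None:
        ff.Minimize(maxIts=500, forceTol=1e-3)

    coords = molh.GetConformer().GetPositions().astype(float)
    # pick one hydrogen per junction occurrence to delete; its position
    # defines the open-valence direction
    h_neighbors = {}
    for j in (jw, je):
        h_neighbors.setdefault(j, sorted(
            nb.GetIdx() for nb in molh.GetAtomWithIdx(j).GetNeighbors()
            if nb.GetSymbol() == "H"))
    removed, directions = [], {}
    for end, j in (("w", jw), ("e", je)):
        pool = [h for h in h_neighbors[j] if h not in removed]
        if not pool:
            raise AssemblyError(f"junction atom {j} has no removable hydrogen (no open valence)")
        h = pool[-1]
        removed.append(h)
        vec = coords[h] - coords[j]
        directions[end] = vec / np.linalg.norm(vec)

    keep = [i for i in range(molh.GetNumAtoms()) if i not in removed]
    from .chem_model import Atom

    new_index = {old: new for new, old in enumerate(keep)}
    atoms = []
    for old in keep:
        rd_atom = molh.GetAtomWithIdx(old)
        atoms.append(Atom(element=rd_atom.GetSymbol(), coords=coords[old],
                          formal_charge=rd_atom.GetFormalCharge(),
                          origin_tag="LINKER"))
    bonds = []
    for b in molh.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i in new_index and j in new_index:
            bonds.append((new_index[i], new_index[j], 1.0 if b.GetBondTypeAsDouble() == 1.0
                          else b.GetBondTypeAsDouble()))
    out = MolecularStructure(atoms=atoms, bonds=bonds, title="linker")
    out.meta["junctions"] = (new_index[jw], new_index[je])
    out.meta["open_directions"] = (directions["w"], directions["e"])
    return out


# ---------------------------------------------------------------------------
# Attachment
# ---------------------------------------------------------------------------

def _graph_distances(structure: MolecularStructure, source: int, cutoff: int) -> dict:
    adj = structure.adjacency()
    dist = {source: 0}
    frontier = [source]
    for d in range(1, cutoff + 1):
        nxt = []
        for node in frontier:
            for nb in adj[node]:
                if nb not in dist:
                    dist[nb] = d
                    nxt.append(nb)
        frontier = nxt
    return dist


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation taking unit vector a onto unit vector b (Rodrigues)."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180° about any axis perpendicular to a
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return _axis_rotation(perp, np.pi)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _axis_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def open_valence_direction(structure: MolecularStructure, index: int) -> np.ndarray:
    """Direction of the open valence at an attachment atom: opposite the
    vector sum of its existing bond directions."""
    adj = structure.adjacency()
    pos = structure.atoms[index].coords
    vecs = []
    for nb in adj[index]:
        v = structure.atoms[nb].coords - pos
        n = np.linalg.norm(v)
        if n > 1e-8:
            vecs.append(v / n)
    if not vecs:
        centroid = structure.coords.mean(axis=0)
        v = pos - centroid
        return v / np.linalg.norm(v) if np.linalg.norm(v) > 1e-8 else np.array([1.0, 0.0, 0.0])
    s = -np.sum(vecs, axis=0)
    n = np.linalg.norm(s)
    if n < 1e-8:
        # fully symmetric substitution; fall back to a perpendicular
        s = np.cross(vecs[0], [0.0, 0.0, 1.0])
        n = np.linalg.norm(s)
        if n < 1e-8:
            s, n = np.array([1.0, 0.0, 0.0]), 1.0
    return s / n


N_TORSION_CANDIDATES = 12
HARD_CLASH_DISTANCE = 1.5  # Å, heavy–heavy


def torsion_candidate_scores(half: MolecularStructure,
                             linker3d: MolecularStructure,
                             junction,
                             linker_end: str = "") -> tuple:
    """Rigid placements of the linker at 12 evenly spaced torsions about the
    new junction bond, with a steric-overlap score for each.

    Returns ``(placements, scores)`` where ``placements[k]`` is the linker
    coordinate array for torsion ``k·30°`` and ``scores[k]`` the summed
    squared vdW overlap with the half-complex heavy atoms (pairs within
    three bonds of the new junction excluded).  Exposed separately so the
    torsion choice can be audited against brute force.
    """
    m_idx, l_idx = int(junction[0]), int(junction[1])
    junctions = linker3d.meta.get("junctions", (l_idx, l_idx))
    dirs = linker3d.meta.get("open_directions")
    if dirs is None:
        v = open_valence_direction(linker3d, l_idx)
    else:
        if linker_end == "w" or (not linker_end and junctions[0] == l_idx):
            v = np.asarray(dirs[0], float)
        else:
            v = np.asarray(dirs[1], float)

    m_pos = half.atoms[m_idx].coords
    u = open_valence_direction(half, m_idx)
    d_ideal = ideal_bond_length(half.atoms[m_idx].element, linker3d.atoms[l_idx].element)
    p = m_pos + d_ideal * u

    base_rot = _rotation_between(v, -u)
    l_pos = linker3d.atoms[l_idx].coords
    base_coords = (linker3d.coords - l_pos) @ base_rot.T + p

    # exclusion: pairs within 3 bonds through the new junction bond
    dist_l = _graph_distances(linker3d, l_idx, 2)
    dist_h = _graph_distances(half, m_idx, 2)
    half_heavy = half.heavy_indices()
    link_heavy = linker3d.heavy_indices()
    half_xyz = half.coords[half_heavy]
    half_r = np.array([VDW_RADII.get(half.atoms[i].element.upper(), 1.7) for i in half_heavy])
    link_r = np.array([VDW_RADII.get(linker3d.atoms[i].element.upper(), 1.7) for i in link_heavy])
    excluded = np.zeros((len(link_heavy), len(half_heavy)), bool)
    for ai, a in enumerate(link_heavy):
        for bi, b in enumerate(half_heavy):
            if a in dist_l and b in dist_h and dist_l[a] + 1 + dist_h[b] <= 3:
                excluded[ai, bi] = True

    placements, scores = [], []
    for k in range(N_TORSION_CANDIDATES):
        rot = _axis_rotation(u, 2.0 * np.pi * k / N_TORSION_CANDIDATES)
        xyz = (base_coords - p) @ rot.T + p
        lx = xyz[link_heavy]
        diff = lx[:, None, :] - half_xyz[None, :, :]
        dists = np.sqrt((diff ** 2).sum(axis=2))
        overlap = np.maximum(0.0, (link_r[:, None] + half_r[None, :]) - dists)
        overlap[excluded] = 0.0
        placements.append(xyz)
        scores.append(float((overlap ** 2).sum()))
    return placements, scores


def attach_linker(half: MolecularStructure, linker3d: MolecularStructure,
                  junction, seed: int = 0, side: str = "",
                  linker_end: str = "") -> HalfComplex:
    """Attach the 3D linker to a protein+moiety half at the given junction.

    ``junction`` is ``(moiety atom index in half, linker atom index in
    linker3d)``, both with open valences.  The linker is rigidly placed so
    the new junction bond has the ideal length for its element pair, and
    the torsion about that bond is chosen among 12 evenly spaced candidates
    to minimize steric overlap with the protein; moiety and protein
    coordinates are untouched.  If every candidate leaves a hard clash
    (< 1.5 Å heavy–heavy) a warning is issued and the best one kept —
    half-complex minimization will resolve it.

    ``seed`` is accepted for interface symmetry with the conformer builder;
    the attachment itself is fully deterministic.
    """
    placements, scores = torsion_candidate_scores(half, linker3d, junction, linker_end)
    best = int(np.argmin(scores))
    xyz = placements[best]

    # hard-clash audit of the chosen candidate
    half_heavy = half.heavy_indices()
    link_heavy = linker3d.heavy_indices()
    if len(half_heavy) and len(link_heavy):
        diff = xyz[link_heavy][:, None, :] - half.coords[half_heavy][None, :, :]
        dmin = float(np.sqrt((diff ** 2).sum(axis=2)).min())
        if dmin < HARD_CLASH_DISTANCE:
            warnings.warn(
                f"all torsion candidates leave a hard clash (min heavy–heavy "
                f"{dmin:.2f} Å); keeping the best candidate for minimization",
                stacklevel=2)

    m_idx, l_idx = int(junction[0]), int(junction[1])
    placed = linker3d.copy()
    placed.coords = xyz
    for atom in placed.atoms:
        atom.origin_tag = "LINKER"
    merged = half.merged_with(placed)
    offset = half.n_atoms
    merged.add_bond(m_idx, offset + l_idx)

    protein_atoms = half.meta.get("protein_atoms")
    moiety_atoms = half.meta.get("moiety_atoms")
    if protein_atoms is None or moiety_atoms is None:
        moiety_atoms = [i for i, a in enumerate(half.atoms)
                        if a.origin_tag in ("WARHEAD", "LE3")]
        protein_atoms = [i for i in range(half.n_atoms) if i not in set(moiety_atoms)]
    if not side:
        moiety_tag = half.atoms[m_idx].origin_tag
        side = "POI_SIDE" if moiety_tag != "LE3" else "E3_SIDE"

    junctions = linker3d.meta.get("junctions", (l_idx, l_idx))
    if junctions[0] == junctions[1]:
        open_local = junctions[0]
    else:
        open_local = junctions[1] if l_idx == junctions[0] else junctions[0]
    merged.meta = dict(half.meta)
    return HalfComplex(
        structure=merged,
        protein_atoms=list(protein_atoms),
        moiety_atoms=list(moiety_atoms),
        linker_atoms=list(range(offset, merged.n_atoms)),
        side=side,
        moiety_junction=m_idx,
        linker_inner_junction=offset + l_idx,
        linker_open_junction=offset + open_local,
    )


# ---------------------------------------------------------------------------
# Half-complex minimization
# ---------------------------------------------------------------------------

def minimize_half(half: HalfComplex,
                  config: MinimizationConfig | None = None) -> HalfComplex:
    """Minimize one half-complex with the linker free.

    Linker atoms and all hydrogens are free; protein and moiety heavy atoms
    are positionally restrained (harmonic, ``config.restraint_k``, default
    100 kcal/mol/Å²) so the binding poses are respected while the linker
    relaxes into a clash-free, solvent-facing orientation.
    """
    config = config or MinimizationConfig()
    s = half.structure
    linker = set(half.linker_atoms)
    restrained = [i for i in range(s.n_atoms)
                  if i not in linker and s.atoms[i].is_heavy]
    minimized, e0, e1 = minimize(s, fixed=(), restrained=restrained, config=config)
    logger.info("minimize_half(%s): %.2f -> %.2f kcal/mol", half.side, e0, e1)
    out = half.copy()
    out.structure = minimized
    return out


# ---------------------------------------------------------------------------
# Superposition and merge
# ---------------------------------------------------------------------------

def _anchored_linker_mappings(poi_half: HalfComplex, e3_half: HalfComplex,
                              max_mappings: int = 5000) -> list:
    """All graph isomorphisms between the two linker copies that send
    junction atoms to junction atoms, in either end orientation."""
    import networkx as nx

    def linker_graph(half):
        # heavy atoms only: hydrogens are deleted with the excess copy and
        # never enter the superposition, but their permutations would blow
        # up the isomorphism count
        idx = [i for i in half.linker_atoms if half.structure.atoms[i].is_heavy]
        g = nx.Graph()
        for i in idx:
            g.add_node(i, element=half.structure.atoms[i].element)
        index_set = set(idx)
        for i, j, _ in half.structure.bonds:
            if i in index_set and j in index_set:
                g.add_edge(i, j)
        return g

    g_poi = linker_graph(poi_half)
    g_e3 = linker_graph(e3_half)
    nm = nx.algorithms.isomorphism.categorical_node_match("element", "")
    matcher = nx.algorithms.isomorphism.GraphMatcher(g_poi, g_e3, node_match=nm)

    poi_w, poi_e = poi_half.linker_inner_junction, poi_half.linker_open_junction
    e3_w, e3_e = e3_half.linker_open_junction, e3_half.linker_inner_junction
    anchor_orientations = [
        {poi_w: e3_w, poi_e: e3_e},      # warhead end onto warhead end
        {poi_w: e3_e, poi_e: e3_w},      # flipped (symmetric linkers only)
    ]
    mappings = []
    for iso in matcher.isomorphisms_iter():
        for anchors in anchor_orientations:
            if all(iso.get(k) == v for k, v in anchors.items()):
                mappings.append(dict(iso))
                break
        if len(mappings) >= max_mappings:
            break
    return mappings


def superpose_and_merge(poi_half: HalfComplex,
                        e3_half: HalfComplex) -> TernaryComplexModel:
    """Merge the two half-complexes into one ternary-complex model.

    The linker atom correspondence is found by element-matched graph
    isomorphism anchored at the junction atoms; the whole E3-side half is
    transformed by the rigid fit of its linker heavy atoms onto the
    POI-side linker (so POI-side coordinates are bitwise unchanged, fixing
    the reference frame).  The E3-side linker copy — the excess atoms — is
    deleted, the L^E3–linker junction bond is formed to the surviving
    POI-side linker, and the fit RMSD is recorded as ``assembly_rmsd``.

    A symmetric linker can admit several anchored mappings; the one with
    the lowest fit RMSD is chosen (ties by canonical order) and the
    ambiguity is logged.
    """
    if poi_half.side != "POI_SIDE" or e3_half.side != "E3_SIDE":
        raise AssemblyError("expected one POI_SIDE and one E3_SIDE half")
    mappings = _anchored_linker_mappings(poi_half, e3_half)
    if not mappings:
        raise AssemblyError("linkers of the two halves are not graph-isomorphic "
                            "(anchored at the junction atoms)")

    poi_s, e3_s = poi_half.structure, e3_half.structure
    poi_link_heavy = [i for i in poi_half.linker_atoms if poi_s.atoms[i].is_heavy]
    best = None
    for mapping in mappings:
        ref = np.array([poi_s.atoms[i].coords for i in poi_link_heavy])
        mob = np.array([e3_s.atoms[mapping[i]].coords for i in poi_link_heavy])
        fit = kabsch_fit(mob, ref)
        key = (round(fit.fit_rmsd, 9),
               tuple(mapping[i] for i in sorted(mapping)))
        if best is None or key < best[0]:
            best = (key, mapping, fit)
    if len(mappings) > 1:
        logger.info("superpose_and_merge: %d anchored linker mappings "
                    "(symmetric linker); chose fit RMSD %.4f Å",
                    len(mappings), best[2].fit_rmsd)
    _, mapping, fit = best

    moved_e3 = e3_s.copy()
    moved_e3.coords = fit.apply(e3_s.coords)

    e3_linker = set(e3_half.linker_atoms)
    keep_e3 = [i for i in range(moved_e3.n_atoms) if i not in e3_linker]
    new_index = {old: poi_s.n_atoms + k for k, old in enumerate(keep_e3)}

    atoms = [a.copy() for a in poi_s.atoms] + [moved_e3.atoms[i].copy() for i in keep_e3]
    bonds = list(poi_s.bonds)
    for i, j, o in moved_e3.bonds:
        if i in new_index and j in new_index:
            bonds.append((new_index[i], new_index[j], o))
    merged = MolecularStructure(atoms=atoms, bonds=bonds,
                                title=poi_s.title or "ternary complex")
    # form the L^E3–linker junction bond to the surviving POI-side linker
    merged.add_bond(poi_half.linker_open_junction, new_index[e3_half.moiety_junction])

    tc = TernaryComplexModel(
        structure=merged,
        poi_atoms=list(poi_half.protein_atoms),
        warhead_atoms=list(poi_half.moiety_atoms),
        linker_atoms=list(poi_half.linker_atoms),
        e3l_atoms=[new_index[i] for i in e3_half.protein_atoms],
        le3_atoms=[new_index[i] for i in e3_half.moiety_atoms],
        assembly_rmsd=float(fit.fit_rmsd),
    )
    for group, tag in ((tc.poi_atoms, "POI"), (tc.e3l_atoms, "E3L"),
                       (tc.warhead_atoms, "WARHEAD"), (tc.linker_atoms, "LINKER"),
                       (tc.le3_atoms, "LE3")):
        for i in group:
            merged.atoms[i].origin_tag = tag
    return tc
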