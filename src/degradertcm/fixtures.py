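"""Seeded generator of fully synthetic toy systems.

Every pipeline stage is testable without downloading a single structure:
the generator builds, from ideal internal coordinates alone, a toy
receptor (two antiparallel polyalanine α-helices forming a groove), a
tert-butyl guest ligand seated clash-free in that groove, an aliphatic
ether linker in an extended conformation, and — most importantly — a
*consistent* ground-truth ternary complex: both half-complexes are carved
out of one global geometry, so superposing their (identical) linker copies
must reproduce the truth exactly, up to whatever rigid perturbation the
fixture spec applied to the E3-side half.

Polyalanine keeps force-field typing trivial and minimization fast; none
of this pretends to be a realistic protein fold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .chem_model import Atom, MolecularStructure
from .linker_assembly import HalfComplex, TernaryComplexModel
from .pose_placement import RigidTransform

FLAVORS = ("CLEAN", "CLASHED", "SYMMETRIC_LINKER", "STRAINED_JUNCTION")


@dataclass
class FixtureSpec:
    """Parameters of one synthetic toy system.

    pocket_depth  : designed guest–receptor heavy-atom clearance, Å.
    linker_length : number of linker chain heavy atoms.
    perturbation  : magnitude (Å) of the rigid ground-truth displacement
                    applied to the E3-side half for recovery tests.
    """

    seed: int = 0
    pocket_depth: float = 3.6
    linker_length: int = 8
    perturbation: float = 10.0
    flavor: str = "CLEAN"

    def __post_init__(self) -> None:
        if self.linker_length < 1:
            raise ValueError("linker_length must be >= 1")
        if self.perturbation < 0:
            raise ValueError("perturbation must be >= 0")
        if self.flavor not in FLAVORS:
            raise ValueError(f"flavor must be one of {FLAVORS}")


# ---------------------------------------------------------------------------
# Internal-coordinate geometry helpers
# ---------------------------------------------------------------------------

def _nerf(a, b, c, bond, angle_deg, torsion_deg):
    """Natural-extension-reference-frame placement of atom d after a-b-c."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([-bond * np.cos(angle),
                        bond * np.sin(angle) * np.cos(torsion),
                        bond * np.sin(angle) * np.sin(torsion)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _unit(v):
    return v / np.linalg.norm(v)


def _tetra_dirs(u, e1, e2, phase_deg=0.0, count=3):
    """``count`` unit vectors at 109.47° from u, spread evenly about u."""
    half = np.radians(109.47)
    out = []
    for k in range(count):
        phi = np.radians(phase_deg) + 2 * np.pi * k / count
        out.append(np.cos(half) * u + np.sin(half) * (np.cos(phi) * e1 + np.sin(phi) * e2))
    return out


def _frame(u):
    u = _unit(u)
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = _unit(np.cross(u, ref))
    e2 = np.cross(u, e1)
    return e1, e2


# ---------------------------------------------------------------------------
# Polyalanine helix
# ---------------------------------------------------------------------------

_PHI, _PSI, _OMEGA = -57.0, -47.0, 180.0


def _build_polyala_helix(n_res: int, chain_id: str, res_start: int,
                         tag: str) -> MolecularStructure:
    """Ideal α-helix of alanines (φ = −57°, ψ = −47°), explicit hydrogens,
    neutral termini (NH2 / COOH)."""
    bb = []  # (N, CA, C) coordinate triples
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([1.458, 0.0, 0.0])
    c0 = _nerf(np.array([-0.5, 1.0, 0.0]), n0, ca0, 1.525, 111.2, -150.0)
    bb.append((n0, ca0, c0))
    for _ in range(1, n_res):
        n_prev, ca_prev, c_prev = bb[-1]
        n_i = _nerf(n_prev, ca_prev, c_prev, 1.329, 116.2, _PSI)
        ca_i = _nerf(ca_prev, c_prev, n_i, 1.458, 121.7, _OMEGA)
        c_i = _nerf(c_prev, n_i, ca_i, 1.525, 111.2, _PHI)
        bb.append((n_i, ca_i, c_i))

    atoms, bonds = [], []

    def add(el, xyz, name):
        atoms.append(Atom(element=el, coords=np.asarray(xyz, float), name=name,
                          residue_name="ALA", residue_number=0, chain_id=chain_id,
                          origin_tag=tag))
        return len(atoms) - 1

    prev_c_idx = None
    for i, (n_xyz, ca_xyz, c_xyz) in enumerate(bb):
        i_n = add("N", n_xyz, "N")
        i_ca = add("C", ca_xyz, "CA")
        i_c = add("C", c_xyz, "C")
        o_xyz = _nerf(n_xyz, ca_xyz, c_xyz, 1.231, 120.8, _PSI + 180.0)
        i_o = add("O", o_xyz, "O")
        cb_xyz = _nerf(c_xyz, n_xyz, ca_xyz, 1.521, 110.5, -122.0)
        i_cb = add("C", cb_xyz, "CB")
        ha_dir = -_unit(_unit(n_xyz - ca_xyz) + _unit(c_xyz - ca_xyz)
                        + _unit(cb_xyz - ca_xyz))
        i_ha = add("H", ca_xyz + 1.09 * ha_dir, "HA")
        u = _unit(ca_xyz - cb_xyz)
        e1, e2 = _frame(u)
        hb_idx = [add("H", cb_xyz + 1.09 * d, f"HB{k + 1}")
                  for k, d in enumerate(_tetra_dirs(u, e1, e2))]
        bonds += [(i_n, i_ca, 1.0), (i_ca, i_c, 1.0), (i_c, i_o, 2.0),
                  (i_ca, i_cb, 1.0), (i_ca, i_ha, 1.0)]
        bonds += [(i_cb, h, 1.0) for h in hb_idx]

        if prev_c_idx is None:
            # N-terminus: NH2
            v = _unit(ca_xyz - n_xyz)
            e1n, e2n = _frame(v)
            for k, d in enumerate(_tetra_dirs(v, e1n, e2n, count=2)):
                bonds.append((i_n, add("H", n_xyz + 1.01 * d, "H" if k == 0 else "H2"), 1.0))
        else:
            bonds.append((prev_c_idx, i_n, 1.0))
            prev_c_xyz = atoms[prev_c_idx].coords
            h_dir = -_unit(_unit(ca_xyz - n_xyz) + _unit(prev_c_xyz - n_xyz))
            bonds.append((i_n, add("H", n_xyz + 1.01 * h_dir, "H"), 1.0))
        prev_c_idx = i_c
        for a in atoms:
            if a.residue_number == 0:
                a.residue_number = res_start + i

    # C-terminus: COOH
    n_last, ca_last, c_last = bb[-1]
    oxt_xyz = _nerf(n_last, ca_last, c_last, 1.34, 117.0, _PSI)
    i_oxt = add("O", oxt_xyz, "OXT")
    atoms[i_oxt].residue_number = res_start + n_res - 1
    i_c_last = next(k for k in range(len(atoms) - 1, -1, -1)
                    if atoms[k].name == "C" and atoms[k].residue_number == res_start + n_res - 1)
    bonds.append((i_c_last, i_oxt, 1.0))
    h_dir = _unit(oxt_xyz - c_last)
    e1o, e2o = _frame(h_dir)
    hxt_xyz = oxt_xyz + 0.96 * (np.cos(np.radians(70)) * h_dir
                                + np.sin(np.radians(70)) * e1o)
    i_hxt = add("H", hxt_xyz, "HXT")
    atoms[i_hxt].residue_number = res_start + n_res - 1
    bonds.append((i_oxt, i_hxt, 1.0))
    return MolecularStructure(atoms=atoms, bonds=bonds, title="polyala helix")


_RELAXED_HELIX_CACHE: dict = {}


def _relaxed_helix(n_res: int, chain_id: str, res_start: int,
                   tag: str) -> MolecularStructure:
    """Ideal-coordinate helix relaxed to its force-field minimum.

    The internal-coordinate build uses textbook bond lengths and angles,
    which differ slightly from the engine's equilibrium values; relaxing
    the isolated template once (deterministic, cached per size) makes the
    emitted ground truth a fixed point of unrestrained minimization, so
    recovery tests probe the assembly logic rather than the residual
    strain of the template.
    """
    if n_res not in _RELAXED_HELIX_CACHE:
        from .engine import MinimizationConfig, minimize as ff_minimize

        template = _build_polyala_helix(n_res, "A", 1, "POI")
        relaxed, _, _ = ff_minimize(
            template, config=MinimizationConfig(tol=0.02, max_iter=4000))
        _RELAXED_HELIX_CACHE[n_res] = relaxed.coords
    helix = _build_polyala_helix(n_res, chain_id, res_start, tag)
    helix.coords = _RELAXED_HELIX_CACHE[n_res].copy()
    return helix


def _canonical_helix(n_res: int, chain_id: str, res_start: int,
                     tag: str) -> MolecularStructure:
    """Helix rotated so its principal axis is +z, centered at the origin."""
    helix = _relaxed_helix(n_res, chain_id, res_start, tag)
    ca = np.array([a.coords for a in helix.atoms if a.name == "CA"])
    center = ca.mean(axis=0)
    centered = ca - center
    _, _, vt = np.linalg.svd(centered)
    axis = vt[0]
    if axis[2] < 0:
        axis = -axis
    rot = _rotation_taking(axis, np.array([0.0, 0.0, 1.0]))
    helix.coords = (helix.coords - center) @ rot.T
    return helix


def _rotation_taking(a, b):
    from .linker_assembly import _rotation_between

    return _rotation_between(np.asarray(a, float), np.asarray(b, float))


def _make_receptor(spec: FixtureSpec, chain_id: str, res_start: int, tag: str,
                   n_res: int = 7) -> MolecularStructure:
    """Two antiparallel helices at ±y forming a groove along x around the
    origin; gap calibrated below against the guest."""
    h1 = _canonical_helix(n_res, chain_id, res_start, tag)
    h2 = _canonical_helix(n_res, chain_id, res_start + n_res + 3, tag)
    flip = np.diag([1.0, -1.0, -1.0])  # antiparallel: rotate 180° about x
    h2.coords = h2.coords @ flip.T
    return h1, h2


# ---------------------------------------------------------------------------
# Guest ligand and PROTAC
# ---------------------------------------------------------------------------

def _build_tert_butyl(origin, open_dir, tag: str) -> MolecularStructure:
    """A tert-butyl fragment: central carbon with three methyls and one
    open valence pointing along ``open_dir`` from ``origin``."""
    open_dir = _unit(np.asarray(open_dir, float))
    atoms, bonds = [], []

    def add(el, xyz, name):
        atoms.append(Atom(element=el, coords=xyz, name=name, origin_tag=tag,
                          residue_name="LIG", residue_number=1,
                          chain_id="W" if tag == "WARHEAD" else "E"))
        return len(atoms) - 1

    c0 = add("C", np.asarray(origin, float), "C1")
    e1, e2 = _frame(open_dir)
    methyl_dirs = _tetra_dirs(open_dir, e1, e2)
    for k, d in enumerate(methyl_dirs):
        ck_xyz = atoms[c0].coords + 1.53 * d
        ck = add("C", ck_xyz, f"C{k + 2}")
        bonds.append((c0, ck, 1.0))
        u = _unit(atoms[c0].coords - ck_xyz)
        f1, f2 = _frame(u)
        for m, hd in enumerate(_tetra_dirs(u, f1, f2, phase_deg=60.0)):
            bonds.append((ck, add("H", ck_xyz + 1.09 * hd, f"H{k + 1}{m + 1}"), 1.0))
    out = MolecularStructure(atoms=atoms, bonds=bonds, title="tert-butyl guest")
    out.meta["attachment"] = c0
    return out


def _linker_elements(spec: FixtureSpec) -> list:
    n = spec.linker_length
    if spec.flavor == "SYMMETRIC_LINKER" or n < 4:
        return ["C"] * n
    elements = ["C"] * n
    elements[2] = "O"  # one ether oxygen, placed asymmetrically
    return elements


def _build_protac(spec: FixtureSpec):
    """The intact toy degrader in an extended conformation along +x.

    Returns ``(structure, warhead_idx, linker_idx, le3_idx, jw, je)`` where
    ``jw``/``je`` are the (moiety atom, linker atom) junction pairs.
    """
    warhead = _build_tert_butyl(np.zeros(3), np.array([1.0, 0.0, 0.0]), "WARHEAD")
    w_attach = warhead.meta["attachment"]

    elements = _linker_elements(spec)
    bond_len = {"C": 1.53, "O": 1.43}
    chain = [warhead.atoms[w_attach].coords + 1.53 * np.array([1.0, 0.0, 0.0])]
    a = warhead.atoms[1].coords          # a methyl carbon, for the NeRF frame
    b = warhead.atoms[w_attach].coords
    prev_prev, prev = a, b
    for k in range(1, len(elements)):
        blen = 0.5 * (bond_len[elements[k - 1]] + bond_len[elements[k]])
        nxt = _nerf(prev_prev, prev, chain[-1], blen, 112.7, 180.0)
        prev_prev, prev = prev, chain[-1]
        chain.append(nxt)
    # E3-ligand attachment point continues the chain
    le3_origin = _nerf(prev_prev, prev, chain[-1], 1.53, 112.7, 180.0)
    le3_dir = _unit(chain[-1] - le3_origin)
    le3 = _build_tert_butyl(le3_origin, le3_dir, "LE3")

    atoms = [a_.copy() for a_ in warhead.atoms]
    bonds = list(warhead.bonds)
    linker_idx = []
    for k, xyz in enumerate(chain):
        atoms.append(Atom(element=elements[k], coords=xyz, name=f"L{k + 1}",
                          origin_tag="LINKER", residue_name="LIG",
                          residue_number=1, chain_id="L"))
        idx = len(atoms) - 1
        linker_idx.append(idx)
        if k:
            bonds.append((linker_idx[k - 1], idx, 1.0))
    bonds.append((w_attach, linker_idx[0], 1.0))

    # linker hydrogens (CH2 only; the ether oxygen carries none)
    adj_pos = {}
    for k, idx in enumerate(linker_idx):
        nbrs = []
        nbrs.append(atoms[w_attach].coords if k == 0 else atoms[linker_idx[k - 1]].coords)
        nbrs.append(le3_origin if k == len(linker_idx) - 1 else atoms[linker_idx[k + 1]].coords)
        adj_pos[idx] = nbrs
    for k, idx in enumerate(linker_idx):
        if atoms[idx].element != "C":
            continue
        pos = atoms[idx].coords
        n1, n2 = adj_pos[idx]
        u = -_unit(_unit(n1 - pos) + _unit(n2 - pos))
        perp = _unit(np.cross(n1 - pos, n2 - pos))
        ch, sh = np.cos(np.radians(54.75)), np.sin(np.radians(54.75))
        for s, tag_h in ((1.0, "A"), (-1.0, "B")):
            h_xyz = pos + 1.09 * _unit(ch * u + s * sh * perp)
            atoms.append(Atom(element="H", coords=h_xyz, name=f"H{k + 1}{tag_h}",
                              origin_tag="LINKER", residue_name="LIG",
                              residue_number=1, chain_id="L"))
            bonds.append((idx, len(atoms) - 1, 1.0))
            linker_idx.append(len(atoms) - 1)

    offset = len(atoms)
    atoms += [a_.copy() for a_ in le3.atoms]
    bonds += [(i + offset, j + offset, o) for i, j, o in le3.bonds]
    e_attach = offset + le3.meta["attachment"]
    linker_last_heavy = [i for i in linker_idx if atoms[i].is_heavy][-1]
    bonds.append((linker_last_heavy, e_attach, 1.0))

    protac = MolecularStructure(atoms=atoms, bonds=bonds, title="toy degrader")
    warhead_idx = list(range(warhead.n_atoms))
    le3_idx = list(range(offset, len(atoms)))
    jw = (w_attach, linker_idx[0])
    je = (e_attach, linker_last_heavy)
    return protac, warhead_idx, sorted(linker_idx), le3_idx, jw, je


# ---------------------------------------------------------------------------
# Placement and calibration
# ---------------------------------------------------------------------------

def _min_heavy_distance(s1: MolecularStructure, xyz1, s2_xyz, s2_elements) -> float:
    heavy1 = [i for i, a in enumerate(s1.atoms) if a.is_heavy]
    h2 = [i for i, e in enumerate(s2_elements) if e.upper() != "H"]
    if not heavy1 or not h2:
        return np.inf
    d = xyz1[heavy1][:, None, :] - np.asarray(s2_xyz)[h2][None, :, :]
    return float(np.sqrt((d ** 2).sum(axis=2)).min())


def _place_groove(h1, h2, guest_xyz, guest_elements, center, clearance):
    """Position the two helices at ±y around ``center`` so the smallest
    heavy-atom distance to the guest equals ``clearance`` (bisection)."""
    def min_dist(offset):
        dmin = np.inf
        for helix, sign in ((h1, 1.0), (h2, -1.0)):
            xyz = helix.coords + center + np.array([0.0, sign * offset, 0.0])
            dmin = min(dmin, _min_heavy_distance(helix, xyz, guest_xyz, guest_elements))
        return dmin

    lo, hi = 2.0, 30.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if min_dist(mid) < clearance:
            lo = mid
        else:
            hi = mid
    offset = hi
    out1, out2 = h1.copy(), h2.copy()
    out1.coords = h1.coords + center + np.array([0.0, offset, 0.0])
    out2.coords = h2.coords + center + np.array([0.0, -offset, 0.0])
    return out1, out2


def _seeded_rigid_transform(rng, magnitude: float) -> RigidTransform:
    axis = _unit(rng.normal(size=3))
    angle = np.radians(min(25.0 * magnitude, 170.0)) if magnitude > 0 else 0.0
    from .linker_assembly import _axis_rotation

    rot = _axis_rotation(axis, angle) if angle else np.eye(3)
    trans = magnitude * _unit(rng.normal(size=3)) if magnitude > 0 else np.zeros(3)
    return RigidTransform(rotation=rot, translation=trans)


# ---------------------------------------------------------------------------
# Public generators
# ---------------------------------------------------------------------------

def make_toy_tc(spec: FixtureSpec):
    """Build one consistent toy ternary complex and its two half-complexes.

    The truth model is assembled analytically from one global geometry;
    the emitted E3-side half is then displaced by a seeded rigid transform
    of magnitude ``spec.perturbation`` (recorded in its
    ``structure.meta['truth']``), so pipeline recovery of the truth is a
    well-posed test.  Deterministic for a fixed spec.
    """
    rng = np.random.default_rng(spec.seed)
    protac, w_idx, l_idx, e_idx, jw, je = _build_protac(spec)

    guest_w = protac.extract(w_idx)
    guest_e = protac.extract(e_idx)
    w_center = guest_w.coords[[i for i, a in enumerate(guest_w.atoms) if a.is_heavy]].mean(axis=0)
    e_center = guest_e.coords[[i for i, a in enumerate(guest_e.atoms) if a.is_heavy]].mean(axis=0)

    # POI receptor around the warhead
    h1, h2 = _make_receptor(spec, "A", 1, "POI")
    shift = rng.uniform(-1.0, 1.0)
    for h in (h1, h2):
        h.coords = h.coords + np.array([0.0, 0.0, shift])
    env_xyz = protac.coords
    env_el = [a.element for a in protac.atoms]
    p1, p2 = _place_groove(h1, h2, env_xyz, env_el, w_center, spec.pocket_depth)

    # E3 receptor around the E3 ligand, rotated by a seeded angle about x
    g1, g2 = _make_receptor(spec, "B", 1, "E3L")
    angle = rng.uniform(0.0, 2 * np.pi)
    from .linker_assembly import _axis_rotation

    rot_x = _axis_rotation(np.array([1.0, 0.0, 0.0]), angle)
    for g in (g1, g2):
        g.coords = g.coords @ rot_x.T
    # rotate the offset direction too by applying the groove fit in the
    # rotated frame: search along the rotated ±y directions
    y_rot = rot_x @ np.array([0.0, 1.0, 0.0])

    def place_rotated(helix, sign, offset):
        out = helix.copy()
        out.coords = helix.coords + e_center + sign * offset * y_rot
        return out

    def min_dist_e(offset):
        dmin = np.inf
        for helix, sign in ((g1, 1.0), (g2, -1.0)):
            out = place_rotated(helix, sign, offset)
            dmin = min(dmin, _min_heavy_distance(out, out.coords, env_xyz, env_el))
        return dmin

    lo, hi = 2.0, 30.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if min_dist_e(mid) < spec.pocket_depth:
            lo = mid
        else:
            hi = mid
    q1 = place_rotated(g1, 1.0, hi)
    q2 = place_rotated(g2, -1.0, hi)

    poi_protein = p1.merged_with(p2)
    e3_protein = q1.merged_with(q2)

    # Relax the whole assembled complex once so the emitted ground truth
    # is (near) a stationary point of the engine: recovery tests then
    # measure assembly fidelity, not residual template strain.
    poi_protein, protac, e3_protein = _relax_global(poi_protein, protac, e3_protein)
    guest_w = protac.extract(w_idx)

    if spec.flavor == "CLASHED":
        poi_protein = _inject_clash(poi_protein, guest_w)

    # ---- truth ternary complex: POI, PROTAC, E3 -----------------------
    n_poi = poi_protein.n_atoms
    truth_struct = poi_protein.merged_with(protac).merged_with(e3_protein)
    off_e3 = n_poi + protac.n_atoms
    truth = TernaryComplexModel(
        structure=truth_struct,
        poi_atoms=list(range(n_poi)),
        warhead_atoms=[n_poi + i for i in w_idx],
        linker_atoms=[n_poi + i for i in l_idx],
        le3_atoms=[n_poi + i for i in e_idx],
        e3l_atoms=list(range(off_e3, truth_struct.n_atoms)),
        assembly_rmsd=0.0,
    )

    # ---- POI-side half: POI protein + warhead + linker ---------------
    poi_half = _carve_half(poi_protein, protac, w_idx, l_idx, jw, je,
                           side="POI_SIDE")
    if spec.flavor == "STRAINED_JUNCTION":
        _strain_junction(poi_half)

    # ---- E3-side half: E3 protein + L^E3 + linker, then perturb ------
    e3_half = _carve_half(e3_protein, protac, e_idx, l_idx, je, jw,
                          side="E3_SIDE")
    transform = _seeded_rigid_transform(rng, spec.perturbation)
    center = e3_half.structure.coords.mean(axis=0)
    e3_half.structure.coords = ((e3_half.structure.coords - center)
                                @ transform.rotation.T + center
                                + transform.translation)
    e3_half.structure.meta["truth"] = {
        "perturbation_A": spec.perturbation,
        "rotation": transform.rotation.tolist(),
        "translation": transform.translation.tolist(),
    }
    return poi_half, e3_half, truth


def _relax_global(poi_protein, protac, e3_protein):
    """Unrestrained minimization of the assembled truth geometry, scattered
    back into its three components (deterministic)."""
    from .engine import MinimizationConfig, minimize as ff_minimize

    merged = poi_protein.merged_with(protac).merged_with(e3_protein)
    relaxed, _, _ = ff_minimize(
        merged, config=MinimizationConfig(tol=0.02, max_iter=4000))
    xyz = relaxed.coords
    n1, n2 = poi_protein.n_atoms, protac.n_atoms
    poi_out, protac_out, e3_out = poi_protein.copy(), protac.copy(), e3_protein.copy()
    poi_out.coords = xyz[:n1]
    protac_out.coords = xyz[n1:n1 + n2]
    e3_out.coords = xyz[n1 + n2:]
    return poi_out, protac_out, e3_out


def _carve_half(protein: MolecularStructure, protac: MolecularStructure,
                moiety_idx, linker_idx, junction, far_junction,
                side: str) -> HalfComplex:
    """Extract protein + one moiety + the full linker from the global
    geometry, preserving coordinates exactly."""
    keep = list(moiety_idx) + list(linker_idx)
    sub = protac.extract(keep)
    local = {old: new for new, old in enumerate(keep)}
    n_prot = protein.n_atoms
    merged = protein.merged_with(sub)
    moiety_atoms = [n_prot + local[i] for i in moiety_idx]
    linker_atoms = [n_prot + local[i] for i in linker_idx]
    return HalfComplex(
        structure=merged,
        protein_atoms=list(range(n_prot)),
        moiety_atoms=moiety_atoms,
        linker_atoms=linker_atoms,
        side=side,
        moiety_junction=n_prot + local[junction[0]],
        linker_inner_junction=n_prot + local[junction[1]],
        linker_open_junction=n_prot + local[far_junction[1]],
    )


def _inject_clash(protein: MolecularStructure, guest: MolecularStructure):
    """Move the CB (with its hydrogens) nearest the guest to ~1.9 Å from
    the closest guest heavy atom — a resolvable side-chain clash."""
    guest_heavy_xyz = guest.coords[[i for i, a in enumerate(guest.atoms) if a.is_heavy]]
    cb_indices = [i for i, a in enumerate(protein.atoms) if a.name == "CB"]
    best = min(cb_indices, key=lambda i: np.min(
        np.linalg.norm(guest_heavy_xyz - protein.atoms[i].coords, axis=1)))
    cb_xyz = protein.atoms[best].coords
    target = guest_heavy_xyz[np.argmin(np.linalg.norm(guest_heavy_xyz - cb_xyz, axis=1))]
    direction = _unit(target - cb_xyz)
    new_cb = target - 1.9 * direction
    delta = new_cb - cb_xyz
    out = protein.copy()
    moved = [best] + out.bonded_hydrogens(best)
    for i in moved:
        out.atoms[i].coords = out.atoms[i].coords + delta
    return out


def _strain_junction(half: HalfComplex) -> None:
    """Stretch the moiety–linker junction bond by 0.7 Å (to ≈ 2.2 Å) by
    translating the whole linker along the bond direction."""
    s = half.structure
    m = s.atoms[half.moiety_junction].coords
    l = s.atoms[half.linker_inner_junction].coords
    delta = 0.7 * _unit(l - m)
    for i in half.linker_atoms:
        s.atoms[i].coords = s.atoms[i].coords + delta


def make_toy_half(spec: FixtureSpec, side: str = "POI_SIDE"):
    """One half-complex with its ground-truth record.

    Returns ``(half, truth_record)``; the record holds the true guest pose
    and, for the E3 side, the rigid perturbation that was applied.
    """
    poi_half, e3_half, truth = make_toy_tc(spec)
    half = poi_half if side == "POI_SIDE" else e3_half
    moiety_idx = truth.warhead_atoms if side == "POI_SIDE" else truth.le3_atoms
    record = {
        "seed": spec.seed,
        "flavor": spec.flavor,
        "side": side,
        "moiety_pose": [truth.structure.atoms[i].coords.tolist() for i in moiety_idx],
        "perturbation": half.structure.meta.get("truth"),
    }
    return half, record


def write_fixture(spec: FixtureSpec, outdir, side: str = "POI_SIDE") -> None:
    """Emit one half-complex as PDB plus its ground truth as JSON."""
    import pathlib

    from .chem_model import write_pdb

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    half, record = make_toy_half(spec, side)
    stem = f"{spec.flavor.lower()}_seed{spec.seed}_{side.lower()}"
    write_pdb(half.structure, outdir / f"{stem}.pdb")
    with open(outdir / f"{stem}.truth.json", "w") as fh:
        json.dump({"spec": asdict(spec), **record}, fh, indent=1)
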