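"""Staged refinement of the merged ternary-complex model.

The approximate model coming out of the linker merge is polished in a
fixed stage order: (1) clash-driven *local* minimization rounds — only the
neighborhoods of detected steric clashes are mobile; (2) a *PROTAC-only*
minimization that lets the degrader settle into the protein surfaces
without moving a single protein atom; (3) a final *unrestrained*
minimization of everything, which may (and is allowed to) move the two
proteins relative to each other.  Quality control re-checks, independently
of the minimizer, that no residual clashes remain.

A clash is a non-bonded heavy-atom pair (1-2 and 1-3 neighbors excluded)
closer than ``CLASH_VDW_FACTOR`` (0.7) times the sum of the two van der
Waals radii — a conventional structure-preparation criterion, configurable
via the ``factor`` arguments.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .chem_model import CLASH_VDW_FACTOR, MolecularStructure, VDW_RADII
from .engine import MinimizationConfig, minimize
from .linker_assembly import TernaryComplexModel

logger = logging.getLogger("degradertcm")

#: Default radius (Å) of the mobile neighborhood around each clash pair.
LOCAL_RADIUS = 6.0
#: Maximum number of clash-driven local minimization rounds.
MAX_LOCAL_ROUNDS = 5


@dataclass
class Clash:
    """A steric clash between two non-bonded heavy atoms."""

    atom_i: int
    atom_j: int
    distance: float
    threshold: float
    inter_group: bool = False

    def __post_init__(self) -> None:
        if self.atom_i == self.atom_j:
            raise ValueError("a clash needs two distinct atoms")
        if not self.distance < self.threshold:
            raise ValueError("clash distance must be below its threshold")


@dataclass
class RefinementReport:
    """Bookkeeping of a full refinement run.

    ``qc_pass`` is true iff no clash survives the final stage;
    ``protein_displacement`` is the maximum backbone-atom motion (Å) across
    the whole refinement; pose-retention RMSDs report how far the warhead
    and L^E3 heavy atoms drifted from their pre-refinement binding poses —
    the automated stand-in for eyeballing whether the moieties kept their
    poses.
    """

    stage_energies: list = field(default_factory=list)  # (name, start, end)
    clashes_before: int = 0
    clashes_after: int = 0
    qc_pass: bool = False
    protein_displacement: float = 0.0
    warhead_pose_rmsd: float = 0.0
    le3_pose_rmsd: float = 0.0
    notes: list = field(default_factory=list)

    def validate(self) -> None:
        if self.qc_pass != (self.clashes_after == 0):
            raise ValueError("qc_pass must mirror clashes_after == 0")
        for name, start, end in self.stage_energies:
            if end > start + 1e-9:
                raise ValueError(f"stage {name} increased the energy")

    def to_dict(self) -> dict:
        return {
            "stage_energies": [
                {"stage": n, "start_kcal_mol": s, "end_kcal_mol": e}
                for n, s, e in self.stage_energies],
            "clashes_before": self.clashes_before,
            "clashes_after": self.clashes_after,
            "qc_pass": self.qc_pass,
            "protein_displacement_A": self.protein_displacement,
            "warhead_pose_rmsd_A": self.warhead_pose_rmsd,
            "le3_pose_rmsd_A": self.le3_pose_rmsd,
            "notes": list(self.notes),
        }


def detect_clashes(structure: MolecularStructure,
                   factor: float = CLASH_VDW_FACTOR) -> list:
    """All clashing heavy-atom pairs, sorted by distance ascending.

    Bonded (1-2) and angle (1-3) pairs are excluded; ``inter_group`` marks
    pairs whose atoms carry different origin tags.
    """
    from scipy.spatial import cKDTree

    heavy = structure.heavy_indices()
    if len(heavy) < 2:
        return []
    coords = structure.coords[heavy]
    radii = np.array([VDW_RADII.get(structure.atoms[i].element.upper(), 1.7)
                      for i in heavy])
    adj = structure.adjacency()
    excluded = set()
    for i in range(structure.n_atoms):
        for j in adj[i]:
            excluded.add((min(i, j), max(i, j)))
            for k in adj[j]:
                if k != i:
                    excluded.add((min(i, k), max(i, k)))

    tree = cKDTree(coords)
    out = []
    for a, b in tree.query_pairs(float(factor * 2 * radii.max())):
        gi, gj = heavy[a], heavy[b]
        if (min(gi, gj), max(gi, gj)) in excluded:
            continue
        d = float(np.linalg.norm(coords[a] - coords[b]))
        thr = float(factor * (radii[a] + radii[b]))
        if d < thr:
            out.append(Clash(
                atom_i=min(gi, gj), atom_j=max(gi, gj), distance=d, threshold=thr,
                inter_group=(structure.atoms[gi].origin_tag
                             != structure.atoms[gj].origin_tag)))
    out.sort(key=lambda c: c.distance)
    return out


def _stage(tc: TernaryComplexModel, free, config) -> tuple:
    """Minimize with exactly ``free`` atoms mobile; everything else fixed."""
    free = set(free)
    fixed = [i for i in range(tc.structure.n_atoms) if i not in free]
    minimized, e0, e1 = minimize(tc.structure, fixed=fixed, config=config)
    out = tc.copy()
    out.structure = minimized
    return out, e0, e1


def refine_stage_local(tc: TernaryComplexModel, clashes,
                       radius: float = LOCAL_RADIUS,
                       config: MinimizationConfig | None = None,
                       energies=None) -> TernaryComplexModel:
    """Clash-driven local minimization rounds.

    Atoms within ``radius`` Å of any clashing atom are free, all others
    are held fixed; up to :data:`MAX_LOCAL_ROUNDS` rounds run, stopping as
    soon as no clash involves a mobile atom.  A warning is recorded if
    clashes persist after the last round (the later stages still run).
    With no clashes the input is returned untouched.
    """
    config = config or MinimizationConfig()
    clashes = list(clashes)
    if not clashes:
        return tc
    current = tc
    for round_no in range(MAX_LOCAL_ROUNDS):
        coords = current.structure.coords
        clash_atoms = sorted({c.atom_i for c in clashes} | {c.atom_j for c in clashes})
        centers = coords[clash_atoms]
        dists = np.sqrt(((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2))
        free = set(np.nonzero((dists <= radius).any(axis=1))[0].tolist())
        current, e0, e1 = _stage(current, free, config)
        if energies is not None:
            energies.append((f"local_round_{round_no + 1}", e0, e1))
        clashes = [c for c in detect_clashes(current.structure)
                   if c.atom_i in free or c.atom_j in free]
        if not clashes:
            break
    else:
        warnings.warn(
            f"local minimization left {len(clashes)} clash(es) after "
            f"{MAX_LOCAL_ROUNDS} rounds; continuing with later stages",
            stacklevel=2)
    return current


def refine_stage_protac(tc: TernaryComplexModel,
                        config: MinimizationConfig | None = None,
                        energies=None) -> TernaryComplexModel:
    """Minimize the PROTAC only, every protein atom fixed (bitwise)."""
    config = config or MinimizationConfig()
    free = set(tc.protac_atoms)
    out, e0, e1 = _stage(tc, free, config)
    if energies is not None:
        energies.append(("protac_only", e0, e1))
    return out


def refine_stage_free(tc: TernaryComplexModel,
                      config: MinimizationConfig | None = None,
                      energies=None,
                      reference: TernaryComplexModel | None = None):
    """Final unrestrained minimization and quality control.

    All atoms are free; reciprocal movement of the two proteins is
    permitted and measured.  Returns ``(refined model, report)`` with
    ``qc_pass`` set by an independent clash re-check.  ``reference`` (the
    model as it entered refinement) fixes the baseline for displacement and
    pose-retention metrics; it defaults to the input of this stage.
    """
    config = config or MinimizationConfig()
    reference = reference or tc
    energies = energies if energies is not None else []
    clashes_before = len(detect_clashes(reference.structure))

    out, e0, e1 = _stage(tc, range(tc.structure.n_atoms), config)
    energies.append(("unrestrained", e0, e1))
    out.refined = True

    remaining = detect_clashes(out.structure)
    ref_xyz = reference.structure.coords
    new_xyz = out.structure.coords

    backbone = [i for i in reference.protein_atoms
                if reference.structure.atoms[i].name in ("N", "CA", "C", "O")]
    if not backbone:
        backbone = [i for i in reference.protein_atoms
                    if reference.structure.atoms[i].is_heavy]
    displacement = float(np.linalg.norm(new_xyz[backbone] - ref_xyz[backbone],
                                        axis=1).max()) if backbone else 0.0

    def pose_rmsd(idx):
        heavy = [i for i in idx if reference.structure.atoms[i].is_heavy]
        if not heavy:
            return 0.0
        return float(np.sqrt(((new_xyz[heavy] - ref_xyz[heavy]) ** 2)
                             .sum(axis=1).mean()))

    report = RefinementReport(
        stage_energies=list(energies),
        clashes_before=clashes_before,
        clashes_after=len(remaining),
        qc_pass=len(remaining) == 0,
        protein_displacement=displacement,
        warhead_pose_rmsd=pose_rmsd(reference.warhead_atoms),
        le3_pose_rmsd=pose_rmsd(reference.le3_atoms),
    )
    report.validate()
    return out, report


def refine(tc: TernaryComplexModel,
           config: MinimizationConfig | None = None,
           skip_stages=()) -> tuple:
    """Full staged refinement: local → PROTAC-only → unrestrained → QC.

    ``skip_stages`` may contain ``'local'``, ``'protac'`` or ``'free'`` for
    ablation experiments; the stage order itself is fixed.  Returns
    ``(refined model, report)``.
    """
    config = config or MinimizationConfig()
    energies: list = []
    start = tc
    current = tc

    if "local" not in skip_stages:
        clashes = detect_clashes(current.structure)
        if clashes:
            current = refine_stage_local(current, clashes, config=config,
                                         energies=energies)
    if "protac" not in skip_stages:
        current = refine_stage_protac(current, config=config, energies=energies)
    if "free" not in skip_stages:
        current, report = refine_stage_free(current, config=config,
                                            energies=energies, reference=start)
    else:
        remaining = detect_clashes(current.structure)
        report = RefinementReport(
            stage_energies=list(energies),
            clashes_before=len(detect_clashes(start.structure)),
            clashes_after=len(remaining),
            qc_pass=len(remaining) == 0,
        )
        report.validate()
        current = current.copy()
        current.refined = True
    logger.info("refinement finished: qc_pass=%s, clashes %d -> %d",
                report.qc_pass, report.clashes_before, report.clashes_after)
    return current, report
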