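"""Molecular-mechanics engine.

A thin, pluggable wrapper around RDKit's force-field implementations (UFF by
default, MMFF94 optionally) exposing exactly what the pipeline needs: a
potential-energy evaluation and a minimizer that supports *fixed* atoms
(never move, bitwise) and harmonically *restrained* atoms.  Energies are in
kcal/mol and are comparable only within a single run under a single force
field — the engine is a run-level choice, not a per-call one.

The minimizer contract guarantees the final energy never exceeds the
initial one: if the optimizer terminates uphill (rare, but possible with
very tight iteration caps), the input coordinates are kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem_model import MolecularStructure, structure_to_mol


class EngineError(RuntimeError):
    """Raised when force-field setup fails (e.g. an atom cannot be typed)."""


@dataclass
class MinimizationConfig:
    """Settings shared by every minimization stage.

    restraint_k : harmonic positional restraint constant, kcal/mol/Å².
    tol         : RMS-gradient convergence tolerance, kcal/mol/Å.
    max_iter    : iteration cap per minimization call.
    forcefield  : 'UFF' or 'MMFF94'; fixed for a whole run.
    """

    restraint_k: float = 100.0
    tol: float = 0.1
    max_iter: int = 2000
    forcefield: str = "UFF"


def _get_forcefield(mol, forcefield: str):
    from rdkit.Chem import AllChem as rdForceFieldHelpers
    from rdkit.ForceField import rdForceField  # noqa: F401  (registers PyForceField)

    if forcefield.upper() == "UFF":
        ff = rdForceFieldHelpers.UFFGetMoleculeForceField(mol)
        if ff is None:
            raise EngineError("UFF typing failed for this structure")
        return ff, "UFF"
    if forcefield.upper() in ("MMFF", "MMFF94", "MMFF94S"):
        props = rdForceFieldHelpers.MMFFGetMoleculeProperties(mol)
        if props is None:
            raise EngineError("MMFF typing failed for this structure")
        ff = rdForceFieldHelpers.MMFFGetMoleculeForceField(mol, props)
        if ff is None:
            raise EngineError("MMFF setup failed for this structure")
        return ff, "MMFF"
    raise EngineError(f"unknown force field {forcefield!r}")


def _typed_mol(structure: MolecularStructure, forcefield: str):
    try:
        mol = structure_to_mol(structure)
    except Exception as exc:  # name the atom if we can
        raise EngineError(f"could not build force-field input: {exc}") from exc
    for atom in mol.GetAtoms():
        if atom.GetSymbol() not in ("H", "C", "N", "O", "F", "P", "S",
                                    "Cl", "Br", "I", "B", "Si", "Se"):
            raise EngineError(
                f"no force-field parameters for atom {atom.GetIdx()} "
                f"({atom.GetSymbol()})")
    return mol


def potential_energy(structure: MolecularStructure,
                     forcefield: str = "UFF") -> float:
    """Potential energy of the structure in kcal/mol."""
    mol = _typed_mol(structure, forcefield)
    ff, _ = _get_forcefield(mol, forcefield)
    return float(ff.CalcEnergy())


def minimize(structure: MolecularStructure,
             fixed=(),
             restrained=(),
             config: MinimizationConfig | None = None):
    """Minimize the structure under the configured force field.

    fixed      : atom indices that must not move at all (bitwise identical
                 coordinates on output).
    restrained : atom indices held by a harmonic positional restraint of
                 ``config.restraint_k`` kcal/mol/Å² to their input position.

    Returns ``(minimized structure, start energy, end energy)`` with
    ``end <= start`` guaranteed (input coordinates kept if the optimizer
    would end uphill).  Restraint energies are excluded from the reported
    start/end values so stages are comparable.
    """
    config = config or MinimizationConfig()
    mol = _typed_mol(structure, config.forcefield)
    coords_in = structure.coords

    ff, kind = _get_forcefield(mol, config.forcefield)
    e_start = float(ff.CalcEnergy())

    fixed = sorted(set(fixed))
    restrained = sorted(set(restrained) - set(fixed))
    for idx in fixed:
        ff.AddFixedPoint(int(idx))
    for idx in restrained:
        if kind == "UFF":
            ff.UFFAddPositionConstraint(int(idx), 0.0, float(config.restraint_k))
        else:
            ff.MMFFAddPositionConstraint(int(idx), 0.0, float(config.restraint_k))
    ff.Initialize()
    # config.tol is an RMS-gradient target (kcal/mol/Å) over the mobile
    # atoms, checked explicitly; the optimizer itself runs at its native
    # (tighter) per-step tolerance in bounded chunks.
    moving = [i for i in range(structure.n_atoms) if i not in set(fixed)]
    remaining = int(config.max_iter)
    while remaining > 0:
        chunk = min(remaining, 500)
        converged = ff.Minimize(maxIts=chunk, forceTol=1e-4)
        remaining -= chunk
        if moving:
            grad = np.asarray(ff.CalcGrad(), float).reshape(-1, 3)
            rms = float(np.sqrt((grad[moving] ** 2).sum(axis=1).mean()))
            if rms <= float(config.tol):
                break
        if converged == 0:
            break

    coords_out = mol.GetConformer().GetPositions().astype(float)
    if fixed:
        coords_out[fixed] = coords_in[fixed]  # guard against fp noise

    # re-evaluate without restraint terms so energies are comparable
    out = structure.copy()
    out.coords = coords_out
    mol_clean = structure_to_mol(out)  # must outlive the force field
    ff_clean, _ = _get_forcefield(mol_clean, config.forcefield)
    e_end = float(ff_clean.CalcEnergy())
    if e_end > e_start:
        return structure.copy(), e_start, e_start
    return out, e_start, e_end
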