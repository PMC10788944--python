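"""Interaction typing, the pairwise energy model, and the moiety score."""

import numpy as np
import pytest

import degradertcm as d
from degradertcm.chem_model import Atom, MolecularStructure
from degradertcm.scoring import (
    COULOMB_CONSTANT,
    CONTACT_CUTOFF,
    ScoringError,
    classify_pair,
    pair_energy,
    _sigma,
)


def structure_from(specs, bonds=()):
    """specs: list of (element, coords, formal_charge, partial_charge)."""
    atoms = []
    for el, xyz, fc, pc in specs:
        atoms.append(Atom(element=el, coords=np.asarray(xyz, float),
                          formal_charge=fc, partial_charge=pc))
    return MolecularStructure(atoms=atoms, bonds=[(i, j, 1.0) for i, j in bonds])


class TestClassification:
    def test_collinear_amide_hbond(self):
        # N–H···O=C, donor–acceptor 2.9 Å, perfectly collinear (angle 180°)
        s = structure_from([
            ("N", (0.0, 0.0, 0.0), 0, -0.4),
            ("H", (1.01, 0.0, 0.0), 0, 0.3),
            ("O", (2.9, 0.0, 0.0), 0, -0.4),
            ("C", (4.13, 0.0, 0.0), 0, 0.3),
        ], bonds=[(0, 1), (2, 3)])
        inter = d.enumerate_interactions(s, [0, 1], [2, 3])
        kinds = {(x.ligand_atom, x.protein_atom): x.kind for x in inter}
        assert kinds[(0, 2)] == "HBOND"

    def test_bent_geometry_is_not_an_hbond(self):
        # hydrogen pointing away: D–H···A angle ≈ 0°
        s = structure_from([
            ("N", (0.0, 0.0, 0.0), 0, 0.0),
            ("H", (-1.01, 0.0, 0.0), 0, 0.0),
            ("O", (2.9, 0.0, 0.0), 0, 0.0),
        ], bonds=[(0, 1)])
        inter = d.enumerate_interactions(s, [0, 1], [2])
        assert all(x.kind == "NONBONDED" for x in inter)

    def test_salt_bridge_priority_over_hbond(self):
        # carboxylate oxygen vs protonated amine nitrogen at 3.5 Å: the
        # pair qualifies as both H-bond and salt bridge; reported once as
        # the higher-priority salt bridge
        s = structure_from([
            ("N", (0.0, 0.0, 0.0), 1, 0.3),
            ("H", (1.01, 0.0, 0.0), 0, 0.33),
            ("O", (3.5, 0.0, 0.0), -1, -0.8),
            ("C", (4.73, 0.0, 0.0), 0, 0.4),
        ], bonds=[(0, 1), (2, 3)])
        inter = d.enumerate_interactions(s, [0, 1], [2, 3])
        by_pair = {}
        for x in inter:
            by_pair.setdefault((x.ligand_atom, x.protein_atom), []).append(x.kind)
        assert by_pair[(0, 2)] == ["SALT_BRIDGE"]

    def test_beyond_cutoff_empty(self):
        s = structure_from([("C", (0, 0, 0), 0, 0.0), ("C", (4.5, 0, 0), 0, 0.0)])
        assert d.enumerate_interactions(s, [0], [1]) == []

    def test_overlapping_selections_rejected(self):
        s = structure_from([("C", (0, 0, 0), 0, 0.0), ("C", (3, 0, 0), 0, 0.0)])
        with pytest.raises(ScoringError, match="overlap"):
            d.enumerate_interactions(s, [0, 1], [1])


class TestEnergyModel:
    def test_lj_zero_at_sigma_with_no_charges(self):
        sigma_cc = _sigma("C")  # mixing rule degenerates for a like pair
        s = structure_from([("C", (0, 0, 0), 0, 0.0),
                            ("C", (sigma_cc, 0, 0), 0, 0.0)])
        assert pair_energy(s, 0, 1) == pytest.approx(0.0, abs=1e-12)

    def test_coulomb_closed_form_with_distance_dependent_dielectric(self):
        """±1 e at 3.0 Å under ε = 4r: E_coul = −332.06/(4·3²) ≈ −9.22."""
        s_charged = structure_from([("N", (0, 0, 0), 1, 1.0),
                                    ("O", (3.0, 0, 0), -1, -1.0)])
        s_neutral = structure_from([("N", (0, 0, 0), 1, 0.0),
                                    ("O", (3.0, 0, 0), -1, 0.0)])
        coulomb = pair_energy(s_charged, 0, 1) - pair_energy(s_neutral, 0, 1)
        assert coulomb == pytest.approx(-COULOMB_CONSTANT / (4.0 * 9.0), rel=1e-9)
        assert coulomb == pytest.approx(-9.22, abs=0.01)

    def test_polar_interaction_includes_the_proton(self):
        s = structure_from([
            ("N", (0.0, 0.0, 0.0), 0, -0.4),
            ("H", (1.01, 0.0, 0.0), 0, 0.35),
            ("O", (2.9, 0.0, 0.0), 0, -0.5),
        ], bonds=[(0, 1)])
        inter, = [x for x in d.enumerate_interactions(s, [0, 1], [2])
                  if x.kind == "HBOND"]
        heavy_only = pair_energy(s, 0, 2)
        assert inter.energy == pytest.approx(
            heavy_only + pair_energy(s, 1, 2), rel=1e-9)
        assert inter.energy < heavy_only  # the proton term is attractive

    def test_hbond_tightening_lowers_energy(self):
        def energy_at(distance):
            s = structure_from([
                ("N", (0.0, 0.0, 0.0), 0, -0.4),
                ("H", (1.01, 0.0, 0.0), 0, 0.35),
                ("O", (distance, 0.0, 0.0), 0, -0.5),
            ], bonds=[(0, 1)])
            inter = d.enumerate_interactions(s, [0, 1], [2])
            return sum(x.energy for x in inter)

        assert energy_at(2.9) < energy_at(4.4)

    def test_enumeration_matches_brute_force_double_loop(self, refined_system):
        """Oracle equivalence on a full pipeline model: every heavy-atom
        pair within the cutoff, classified naively, appears exactly once."""
        tc = refined_system["refined"]
        s = tc.structure
        lig = [i for i in tc.warhead_atoms if s.atoms[i].is_heavy]
        rec = [i for i in tc.protein_atoms if s.atoms[i].is_heavy]
        adj = s.adjacency()
        expected = {}
        for i in lig:
            for j in rec:
                dist = np.linalg.norm(s.atoms[i].coords - s.atoms[j].coords)
                if dist <= CONTACT_CUTOFF:
                    expected[(i, j)] = classify_pair(s, i, j, adj)
        got = {(x.ligand_atom, x.protein_atom): x.kind
               for x in d.enumerate_interactions(tc, tc.warhead_atoms,
                                                 tc.protein_atoms)}
        assert got == expected


class TestDegraderScore:
    def test_additivity_exact(self, refined_system):
        score = d.degradertcm_score(refined_system["refined"])
        assert score.total == score.e_warhead + score.e_le3
        assert score.e_warhead == pytest.approx(
            sum(x.energy for x in score.interactions_warhead), abs=1e-9)

    def test_contact_free_moiety_scores_zero(self, refined_system):
        tc = refined_system["refined"].copy()
        for i in tc.warhead_atoms:
            tc.structure.atoms[i].coords = tc.structure.atoms[i].coords \
                + np.array([0.0, 200.0, 0.0])
        score = d.degradertcm_score(tc)
        assert score.e_warhead == 0.0

    def test_empty_moiety_rejected(self, refined_system):
        tc = refined_system["refined"].copy()
        tc.warhead_atoms, tc.linker_atoms = [], sorted(
            tc.linker_atoms + tc.warhead_atoms)
        with pytest.raises(ScoringError):
            d.degradertcm_score(tc)

    def test_linker_only_perturbation_leaves_score_unchanged(self, refined_system):
        base = d.degradertcm_score(refined_system["refined"]).total
        tc = refined_system["refined"].copy()
        rng = np.random.default_rng(1)
        for i in tc.linker_atoms:
            tc.structure.atoms[i].coords = tc.structure.atoms[i].coords \
                + rng.normal(0.0, 0.05, 3)
        assert d.degradertcm_score(tc).total == base

    def test_displaced_warhead_scores_worse(self, refined_system):
        """A warhead pushed 2 Å out of the toy pocket loses contacts; the
        seated pose must score lower (more negative = more stable)."""
        seated = d.degradertcm_score(refined_system["refined"]).total
        tc = refined_system["refined"].copy()
        for i in tc.warhead_atoms:
            tc.structure.atoms[i].coords = tc.structure.atoms[i].coords \
                + np.array([-2.0, 0.0, 0.0])  # out through the groove mouth
        displaced = d.degradertcm_score(tc).total
        assert seated < displaced


class TestPpiSummary:
    def test_far_apart_proteins_have_empty_interface(self):
        poi, e3, _ = d.make_toy_tc(d.FixtureSpec(seed=2))
        tc = d.superpose_and_merge(poi, e3)
        far = tc.copy()
        for i in far.e3l_atoms:
            far.structure.atoms[i].coords = far.structure.atoms[i].coords \
                + np.array([200.0, 0.0, 0.0])
        summary = d.ppi_summary(far)
        assert (summary.hbonds, summary.salt_bridges,
                summary.nonbonded_contacts) == (0, 0, 0)
        assert summary.contact_area == pytest.approx(0.0, abs=1.0)

    def test_designed_contacts_are_counted(self):
        """Two micro-chains with three designed heavy-atom contact pairs."""
        specs, bonds = [], []
        for k in range(3):
            specs.append(("C", (3.0 * k, 0.0, 0.0), 0, 0.0))
            specs.append(("C", (3.0 * k, 3.8, 0.0), 0, 0.0))
        s = structure_from(specs)
        for i, a in enumerate(s.atoms):
            a.origin_tag = "POI" if i % 2 == 0 else "E3L"
            a.residue_name, a.residue_number = "ALA", i // 2 + 1
            a.chain_id = "A" if i % 2 == 0 else "B"
        from degradertcm.linker_assembly import TernaryComplexModel

        # minimal TC shell: no degrader atoms needed for the PPI summary
        class Shell:
            structure = s
            poi_atoms = [0, 2, 4]
            e3l_atoms = [1, 3, 5]
            refined = True

        summary = d.ppi_summary(Shell())
        assert summary.nonbonded_contacts == 3
        assert summary.hbonds == summary.salt_bridges == 0
        assert len(summary.interface_residues["POI"]) == 3

    def test_contact_area_matches_grid_sasa_oracle(self, refined_system):
        """Buried-surface area vs an independent grid/sphere-sampling SASA
        (Shrake–Rupley reimplemented naively) within 5 %."""
        from degradertcm.chem_model import VDW_RADII

        tc = refined_system["refined"]
        s = tc.structure

        def naive_sasa(indices, probe=1.4, n_points=1200):
            # deterministic Fibonacci sphere sampling
            k = np.arange(n_points)
            phi = np.pi * (3.0 - np.sqrt(5.0)) * k
            z = 1.0 - 2.0 * (k + 0.5) / n_points
            r = np.sqrt(1.0 - z * z)
            pts = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
            idx = list(indices)
            centers = s.coords[idx]
            radii = np.array([VDW_RADII[s.atoms[i].element.upper()] for i in idx]) + probe
            total = 0.0
            for k, i in enumerate(idx):
                sphere = centers[k] + radii[k] * pts
                occluded = np.zeros(n_points, bool)
                for m in range(len(idx)):
                    if m == k:
                        continue
                    occluded |= (np.linalg.norm(sphere - centers[m], axis=1)
                                 < radii[m])
                total += (1.0 - occluded.mean()) * 4.0 * np.pi * radii[k] ** 2
            return total

        poi, e3l = tc.poi_atoms, tc.e3l_atoms
        oracle = 0.5 * (naive_sasa(poi) + naive_sasa(e3l) - naive_sasa(poi + e3l))
        summary = d.ppi_summary(tc)
        assert summary.contact_area == pytest.approx(oracle, rel=0.05, abs=2.0)
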