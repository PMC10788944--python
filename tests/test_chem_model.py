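"""Data model, PDB/SDF/SMILES I/O and PROTAC decomposition."""

import numpy as np
import pytest

import degradertcm as d
from degradertcm.chem_model import (
    Atom,
    ChemModelError,
    MolecularStructure,
    PDBParseError,
    decompose_protac,
    from_smiles,
    read_pdb,
    reassemble_protac,
    write_pdb,
)


def make_atoms(elements, coords, **kw):
    return [Atom(element=e, coords=np.asarray(c, float), **kw)
            for e, c in zip(elements, coords)]


class TestStructureInvariants:
    def test_rejects_out_of_range_and_self_bonds(self):
        atoms = make_atoms("CC", [(0, 0, 0), (1.5, 0, 0)])
        with pytest.raises(ChemModelError):
            MolecularStructure(atoms=atoms, bonds=[(0, 5, 1.0)])
        with pytest.raises(ChemModelError):
            MolecularStructure(atoms=atoms, bonds=[(1, 1, 1.0)])
        with pytest.raises(ChemModelError):
            MolecularStructure(atoms=atoms, bonds=[(0, 1, 1.0), (1, 0, 1.0)])

    def test_is_heavy_tracks_element(self):
        a, h = make_atoms(["C", "H"], [(0, 0, 0), (1, 0, 0)])
        assert a.is_heavy and not h.is_heavy

    def test_nonfinite_coords_rejected(self):
        with pytest.raises(ChemModelError):
            Atom(element="C", coords=np.array([np.nan, 0, 0]))


class TestPdbIO:
    def test_single_atom_record(self, tmp_path):
        path = tmp_path / "one.pdb"
        path.write_text(
            "HETATM    1  C1  LIG X   1       1.000   2.000   3.000"
            "  1.00  0.00           C\nEND\n")
        with pytest.warns(UserWarning):  # no CONECT: bond perception kicks in
            s = read_pdb(path)
        assert s.n_atoms == 1
        assert s.atoms[0].element == "C"
        np.testing.assert_allclose(s.atoms[0].coords, [1.0, 2.0, 3.0])

    def test_two_hetatm_one_conect(self, tmp_path):
        path = tmp_path / "pair.pdb"
        path.write_text(
            "HETATM    1  C1  LIG X   1       0.000   0.000   0.000"
            "  1.00  0.00           C\n"
            "HETATM    2  C2  LIG X   1       1.500   0.000   0.000"
            "  1.00  0.00           C\n"
            "CONECT    1    2\nEND\n")
        s = read_pdb(path)
        assert s.n_atoms == 2
        assert s.bonds == [(0, 1, 1.0)]

    def test_malformed_record_names_line(self, tmp_path):
        path = tmp_path / "bad.pdb"
        path.write_text(
            "HETATM    1  C1  LIG X   1       0.000   0.000   0.000"
            "  1.00  0.00           C\n"
            "HETATM    2  C2  LIG X   1       xxxxx   0.000   0.000"
            "  1.00  0.00           C\n")
        with pytest.raises(PDBParseError, match="line 2"):
            read_pdb(path)

    def test_empty_file_raises(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("")
        with pytest.raises(ChemModelError):
            read_pdb(path)

    def test_empty_structure_writes_header_only(self, tmp_path):
        path = tmp_path / "none.pdb"
        write_pdb(MolecularStructure(title="empty"), path)
        text = path.read_text()
        assert "ATOM" not in text and "HETATM" not in text

    def test_roundtrip_preserves_atoms_bonds_tags(self, tmp_path):
        poi, _, _ = d.make_toy_tc(d.FixtureSpec(seed=2))
        s = poi.structure
        path = tmp_path / "half.pdb"
        write_pdb(s, path)
        back = read_pdb(path)
        assert back.n_atoms == s.n_atoms
        assert back.elements == s.elements
        np.testing.assert_allclose(back.coords, s.coords, atol=5e-4)
        assert {(i, j) for i, j, _ in back.bonds} == {(i, j) for i, j, _ in s.bonds}
        assert [a.origin_tag for a in back.atoms] == [a.origin_tag for a in s.atoms]

    def test_tagged_tc_reads_back_with_distinct_chains(self, tmp_path):
        _, _, truth = d.make_toy_tc(d.FixtureSpec(seed=1))
        path = tmp_path / "tc.pdb"
        write_pdb(truth.structure, path)
        back = read_pdb(path)
        chains_by_tag = {}
        for atom in back.atoms:
            chains_by_tag.setdefault(atom.origin_tag, set()).add(atom.chain_id)
        for tag in ("POI", "E3L", "WARHEAD"):
            assert len(chains_by_tag[tag]) >= 1
        assert (chains_by_tag["POI"].isdisjoint(chains_by_tag["E3L"])
                and chains_by_tag["POI"].isdisjoint(chains_by_tag["WARHEAD"]))

    def test_reader_agrees_with_biotite(self, tmp_path):
        """Independent cross-check of the PDB reader against biotite."""
        import biotite.structure.io.pdb as pdb

        poi, _, _ = d.make_toy_tc(d.FixtureSpec(seed=4))
        path = tmp_path / "x.pdb"
        write_pdb(poi.structure, path)
        ours = read_pdb(path)
        theirs = pdb.PDBFile.read(str(path)).get_structure(model=1)
        assert ours.n_atoms == theirs.array_length()
        np.testing.assert_allclose(ours.coords, theirs.coord, atol=1e-3)
        assert [e.upper() for e in ours.elements] == list(theirs.element)

    def test_atom_limit(self):
        s = MolecularStructure(atoms=make_atoms("C", [(0, 0, 0)]))
        s.atoms = s.atoms * 100000
        with pytest.raises(ChemModelError, match="99999"):
            write_pdb(s, "/dev/null")


class TestDecomposition:
    def test_pentane_linear_cuts(self):
        dec = decompose_protac("CCCCC", (0, 1), (3, 4))
        assert (dec.warhead.n_atoms, dec.linker.n_atoms, dec.le3.n_atoms) == (1, 3, 1)
        assert dec.junction_w == (0, 0)
        assert dec.linker.meta["junctions"] == (0, 2)

    def test_ring_cut_rejected(self):
        # cyclohexane with a tail: cutting inside the ring must fail
        with pytest.raises(ChemModelError, match="acyclic"):
            decompose_protac("C1CCCCC1CCCC", (0, 1), (7, 8))

    def test_wrong_component_count_rejected(self):
        # both cuts on the same terminal bond side: yields 3 pieces only if
        # the middle exists; cutting adjacent bonds gives a 1-atom linker
        with pytest.raises(ChemModelError):
            decompose_protac("CCCCC", (0, 1), (0, 1))

    def test_cut_bond_must_exist(self):
        with pytest.raises(ChemModelError, match="not bonded"):
            decompose_protac("CCCCC", (0, 4), (2, 3))

    @pytest.mark.parametrize("seed", range(8))
    def test_reassembly_is_graph_identity_on_random_trees(self, seed):
        """Brute-force check: decompose + reassemble reproduces the input
        molecular graph (atom multiset + bond multiset) exactly."""
        import networkx as nx

        rng = np.random.default_rng(seed)
        n = int(rng.integers(7, 16))
        tree = nx.random_labeled_tree(n, seed=int(rng.integers(2 ** 31)))
        elements = rng.choice(["C", "N", "O"], size=n)
        atoms = make_atoms(elements, rng.normal(size=(n, 3)))
        s = MolecularStructure(atoms=atoms,
                               bonds=[(i, j, 1.0) for i, j in tree.edges])
        # choose two distinct non-adjacent edges so three components appear
        edges = list(tree.edges)
        rng.shuffle(edges)
        cut_pair = None
        for a in range(len(edges)):
            for b in range(a + 1, len(edges)):
                if not set(edges[a]) & set(edges[b]):
                    try:
                        dec = decompose_protac(s, edges[a], edges[b])
                        cut_pair = dec
                        break
                    except ChemModelError:
                        continue
            if cut_pair:
                break
        assert cut_pair is not None
        dec = cut_pair
        total = dec.warhead.n_atoms + dec.linker.n_atoms + dec.le3.n_atoms
        assert total == s.n_atoms
        re = reassemble_protac(dec)
        g1, g2 = s.graph(), re.graph()
        nm = nx.algorithms.isomorphism.categorical_node_match("element", "")
        assert nx.is_isomorphic(g1, g2, node_match=nm)

    def test_fragment_tags_assigned(self):
        dec = decompose_protac("CCOCCOCC", (1, 2), (5, 6))
        assert all(a.origin_tag == "WARHEAD" for a in dec.warhead.atoms)
        assert all(a.origin_tag == "LINKER" for a in dec.linker.atoms)
        assert all(a.origin_tag == "LE3" for a in dec.le3.atoms)


class TestSmilesSdf:
    def test_smiles_roundtrip_heavy_count(self):
        s = from_smiles("CC(=O)Nc1ccc(O)cc1")
        assert s.n_atoms == 11  # heavy atoms of paracetamol

    def test_invalid_smiles(self):
        with pytest.raises(ChemModelError):
            from_smiles("not_a_smiles((")

    def test_sdf_roundtrip(self, tmp_path):
        from degradertcm.chem_model import read_sdf, write_sdf

        s = from_smiles("CCO")
        path = tmp_path / "x.sdf"
        write_sdf(s, path)
        back = read_sdf(path)
        assert back.elements == s.elements
        assert len(back.bonds) == len(s.bonds)
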