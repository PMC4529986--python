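"""PDB ingestion, shape descriptor, SASA and surface/binding labels."""

import numpy as np
import pytest

from patchbind.fixtures import FixtureSpec, make_toy_complex
from patchbind.structure import (AtomRecord, ComplexModel, ResidueModel,
                                 annotate_complex, compute_sasa, label_binding,
                                 label_surface, load_complex,
                                 side_chain_center, _sphere_points)

from conftest import random_rigid


def residue(aa, atoms, chain="A", seq="1"):
    return ResidueModel(chain_id=chain, seq_index=seq, aa_type=aa,
                        atoms=[AtomRecord(n, e, c) for n, e, c in atoms])


BACKBONE_ATOMS = [
    ("N", "N", (1.2, 0.0, 0.8)),
    ("CA", "C", (0.0, 0.0, 0.0)),
    ("C", "C", (-1.2, 0.0, 0.9)),
    ("O", "O", (-1.8, 1.0, 1.2)),
]


class TestLoadComplex:
    def test_round_trips_fixture_coordinates(self):
        pdb, truth = make_toy_complex(FixtureSpec(seed=3), 0)
        cm = load_complex(pdb, ["A"], ["B"], source_id="t")
        residues = cm.protein_chains["A"]
        assert len(residues) == len(truth)
        # coordinates written at 3 decimals must round-trip exactly
        file_coords = {}
        for line in pdb.splitlines():
            if line.startswith("ATOM") and line[21] == "A":
                key = (line[22:26].strip(), line[12:16].strip())
                file_coords[key] = [float(line[30:38]), float(line[38:46]),
                                    float(line[46:54])]
        for res in residues:
            for atom in res.atoms:
                np.testing.assert_allclose(
                    atom.coord, file_coords[(res.seq_index, atom.name)],
                    atol=1e-4)  # parser stores float32

    def test_nucleotide_atoms_match_file(self):
        pdb, truth = make_toy_complex(FixtureSpec(seed=3), 1)
        n_rna_lines = sum(1 for line in pdb.splitlines()
                          if line.startswith("ATOM") and line[21] == "B")
        cm = load_complex(pdb, ["A"], ["B"])
        assert len(cm.nucleotide_atoms) == n_rna_lines
        assert n_rna_lines == 4 * truth["is_binding"].sum()

    def test_missing_backbone_atom_blocks_shape_descriptor(self):
        pdb, _ = make_toy_complex(FixtureSpec(seed=3), 0)
        # drop the O atom of residue 2
        lines = [l for l in pdb.splitlines()
                 if not (l.startswith("ATOM") and l[21] == "A"
                         and l[22:26].strip() == "2"
                         and l[12:16].strip() == "O")]
        cm = load_complex("\n".join(lines), ["A"], ["B"])
        res = cm.protein_chains["A"][1]
        assert res.seq_index == "2"
        assert not res.has_shape
        assert cm.protein_chains["A"][0].has_shape

    def test_unknown_chain_raises(self):
        pdb, _ = make_toy_complex(FixtureSpec(seed=3), 0)
        with pytest.raises(KeyError, match="Z"):
            load_complex(pdb, ["Z"], [])


class TestSideChainCenter:
    def test_single_heavy_atom_is_returned_directly(self):
        r = residue("A", BACKBONE_ATOMS + [("CB", "C", (1.0, 2.0, 3.0))])
        np.testing.assert_allclose(side_chain_center(r), [1.0, 2.0, 3.0])

    def test_mean_of_two_side_chain_atoms(self):
        r = residue("S", BACKBONE_ATOMS + [("CB", "C", (0.0, 0.0, 0.0)),
                                           ("OG", "O", (2.0, 0.0, 0.0))])
        np.testing.assert_allclose(side_chain_center(r), [1.0, 0.0, 0.0])

    def test_oxt_and_hydrogens_are_excluded(self):
        r = residue("S", BACKBONE_ATOMS + [("CB", "C", (2.0, 0.0, 0.0)),
                                           ("OXT", "O", (9.0, 9.0, 9.0)),
                                           ("HB2", "H", (8.0, 8.0, 8.0))])
        np.testing.assert_allclose(side_chain_center(r), [2.0, 0.0, 0.0])

    def test_glycine_uses_file_hydrogen_when_present(self):
        r = residue("G", BACKBONE_ATOMS + [("HA2", "H", (0.5, -0.5, -0.7))])
        np.testing.assert_allclose(side_chain_center(r), [0.5, -0.5, -0.7])

    def test_glycine_idealized_ha_geometry(self):
        r = residue("G", BACKBONE_ATOMS)
        ha = side_chain_center(r)
        ca = np.zeros(3)
        dist = np.linalg.norm(ha - ca)
        assert 1.0 <= dist <= 1.2
        # points away from the N/C bisector
        n = np.array(BACKBONE_ATOMS[0][2])
        c = np.array(BACKBONE_ATOMS[2][2])
        bisector = n / np.linalg.norm(n) + c / np.linalg.norm(c)
        assert np.dot(ha - ca, bisector) < 0

    def test_missing_side_chain_falls_back_to_ca(self, caplog):
        r = residue("L", BACKBONE_ATOMS)
        with caplog.at_level("WARNING"):
            np.testing.assert_allclose(side_chain_center(r), [0.0, 0.0, 0.0])
        assert "side-chain" in caplog.text


class TestSasa:
    def test_isolated_residue_is_fully_exposed(self):
        cm = ComplexModel("x", {"A": [residue("A", BACKBONE_ATOMS +
                                              [("CB", "C", (0.5, -1.2, -0.8))])]})
        areas = compute_sasa(cm)
        assert areas[("A", "1")] > 50.0  # every atom partially exposed
        label_surface(cm)
        assert cm.protein_chains["A"][0].is_surface

    def test_caged_residue_has_zero_area(self):
        # surround a lone carbon with a dense shell of atoms
        shell = 200
        pts = 4.0 * _sphere_points(shell)
        cage = residue("A", [(f"C{i}", "C", tuple(p)) for i, p in
                             enumerate(pts)], seq="2")
        target = residue("A", [("CA", "C", (0.0, 0.0, 0.0))], seq="1")
        cm = ComplexModel("x", {"A": [target, cage]})
        areas = compute_sasa(cm)
        assert areas[("A", "1")] == 0.0
        dense = compute_sasa(cm, n_sphere_points=10000)  # dense-point oracle
        assert dense[("A", "1")] == 0.0
        label_surface(cm)
        assert not cm.protein_chains["A"][0].is_surface

    def test_point_density_convergence(self):
        pdb, _ = make_toy_complex(FixtureSpec(seed=5, residues_per_protein=9,
                                              n_proteins=1), 0)
        cm = load_complex(pdb, ["A"], ["B"])
        a1 = np.array(list(compute_sasa(cm, n_sphere_points=960).values()))
        a2 = np.array(list(compute_sasa(cm, n_sphere_points=1920).values()))
        rel = np.abs(a1 - a2) / np.maximum(a2, 1e-9)
        assert rel.max() < 0.05

    def test_agrees_with_biopython_shrake_rupley(self):
        """Independent SASA oracle: same sign, strongly correlated areas."""
        import io

        from Bio.PDB import PDBParser
        from Bio.PDB.SASA import ShrakeRupley

        pdb, _ = make_toy_complex(FixtureSpec(seed=5), 0)
        protein_only = "\n".join(l for l in pdb.splitlines()
                                 if not (l.startswith("ATOM") and l[21] == "B"))
        cm = load_complex(protein_only, ["A"], [])
        ours = compute_sasa(cm)
        structure = PDBParser(QUIET=True).get_structure(
            "t", io.StringIO(protein_only))
        ShrakeRupley(probe_radius=1.4, n_points=960).compute(
            structure[0], level="R")
        theirs = {r.id[1]: r.sasa for r in structure[0]["A"]}
        a = np.array([ours[("A", str(i))] for i in sorted(theirs)])
        b = np.array([theirs[i] for i in sorted(theirs)])
        assert np.all((a > 0) == (b > 0))
        assert np.corrcoef(a, b)[0, 1] > 0.99

    def test_rigid_invariance_of_sasa(self, rng):
        pdb, _ = make_toy_complex(FixtureSpec(seed=5, residues_per_protein=9,
                                              n_proteins=1), 0)
        cm = load_complex(pdb, ["A"], ["B"])
        before = np.array(list(compute_sasa(cm).values()))
        rot, t = random_rigid(rng)
        for res in cm.residues():
            for atom in res.atoms:
                atom.coord = rot @ atom.coord + t
        after = np.array(list(compute_sasa(cm).values()))
        # the sphere point set is fixed in the lab frame, so per-residue areas
        # move only by sampling error under rotation; the sign (surface vs
        # buried), which is all the pipeline consumes, is exactly invariant
        np.testing.assert_allclose(after, before, rtol=0.05)
        assert np.array_equal(after > 0, before > 0)
        assert np.all(before >= 0)


class TestLabels:
    def _complex_with_contact(self, dist):
        # single-atom residue so the minimum distance is exactly `dist`
        res = residue("A", [("CA", "C", (0.0, 0.0, 0.0))])
        cm = ComplexModel("x", {"A": [res]},
                          [AtomRecord("P", "P", (0.0, 0.0, dist))])
        return cm

    def test_binding_boundary(self):
        cm = self._complex_with_contact(4.9)
        label_binding(cm)
        assert cm.protein_chains["A"][0].is_binding
        cm = self._complex_with_contact(5.1)
        label_binding(cm)
        assert not cm.protein_chains["A"][0].is_binding
        cm = self._complex_with_contact(5.0)
        label_binding(cm)  # inclusive boundary
        assert cm.protein_chains["A"][0].is_binding

    def test_apo_complex_all_nonbinding(self):
        cm = ComplexModel("x", {"A": [residue("A", BACKBONE_ATOMS)]})
        label_binding(cm)
        assert not any(r.is_binding for r in cm.residues())

    def test_labels_match_brute_force_scan(self):
        pdb, truth = make_toy_complex(FixtureSpec(seed=9), 2)
        cm = load_complex(pdb, ["A"], ["B"])
        label_binding(cm)
        rna = np.array([a.coord for a in cm.nucleotide_atoms])
        for res, expected in zip(cm.residues(), truth["is_binding"]):
            prot = res.all_coords()
            dmin = np.sqrt(((prot[:, None] - rna[None]) ** 2).sum(-1)).min()
            assert res.is_binding == (dmin <= 5.0) == expected

    def test_binding_monotone_in_cutoff(self):
        pdb, _ = make_toy_complex(FixtureSpec(seed=9), 0)
        cm = load_complex(pdb, ["A"], ["B"])
        sets = []
        for cutoff in (3.0, 5.0, 8.0, 15.0):
            label_binding(cm, cutoff=cutoff)
            sets.append({r.key for r in cm.residues() if r.is_binding})
        for small, large in zip(sets, sets[1:]):
            assert small <= large

    def test_labels_invariant_under_rigid_motion(self, rng):
        pdb, _ = make_toy_complex(FixtureSpec(seed=9), 0)
        cm = load_complex(pdb, ["A"], ["B"])
        annotate_complex(cm)
        before = [(r.is_surface, r.is_binding) for r in cm.residues()]
        rot, t = random_rigid(rng)
        for res in cm.residues():
            for atom in res.atoms:
                atom.coord = rot @ atom.coord + t
        for atom in cm.nucleotide_atoms:
            atom.coord = rot @ atom.coord + t
        annotate_complex(cm)
        after = [(r.is_surface, r.is_binding) for r in cm.residues()]
        assert before == after
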