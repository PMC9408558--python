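"""Structure reading, C-alpha extraction, mmCIF round-trips, transforms."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from abcconform.errors import (
    EmptySelectionError,
    EmptyStructureError,
    StructureParseError,
    TransformError,
)
from abcconform.structure_io import (
    ResidueLabel,
    Selection,
    apply_transform,
    extract_ca,
    read_structure,
    structure_from_coordinates,
    write_mmcif,
)
from abcconform.synthetic import MockSpec, make_mock_transporter

from conftest import coordinate_set


class TestReadStructure:
    def test_minimal_pdb(self, two_residue_pdb):
        st = read_structure(two_residue_pdb, format="pdb")
        assert len(st.chains) == 1
        assert len(st.chains["A"]) == 2
        assert [r.name for r in st.chains["A"]] == ["ALA", "GLY"]

    def test_mmcif_dialect_gives_identical_structure(
        self, two_residue_pdb, two_residue_cif
    ):
        a = read_structure(two_residue_pdb, format="pdb")
        b = read_structure(two_residue_cif, format="mmcif")
        assert a.chain_ids() == b.chain_ids()
        for res_a, res_b in zip(a.chains["A"], b.chains["A"]):
            assert res_a.name == res_b.name
            assert res_a.number == res_b.number
            assert set(res_a.atoms) == set(res_b.atoms)
            for name in res_a.atoms:
                np.testing.assert_allclose(
                    res_a.atoms[name], res_b.atoms[name], atol=1e-3
                )

    def test_multi_model_keeps_first_model_only(self, three_model_pdb):
        st = read_structure(three_model_pdb, format="pdb")
        assert st.n_residues == 2
        np.testing.assert_allclose(
            st.chains["A"][0].atoms["CA"], [0.0, 0.0, 0.0], atol=1e-6
        )

    def test_unreadable_file_raises_parse_error(self, tmp_path):
        bad = tmp_path / "bad.cif"
        bad.write_text("data_x\nloop_\n_atom_site.id\nnot-a-row extra tokens\n")
        with pytest.raises((StructureParseError, EmptyStructureError)):
            read_structure(bad, format="mmcif")

    def test_missing_file(self, tmp_path):
        with pytest.raises(StructureParseError):
            read_structure(tmp_path / "nope.pdb")

    def test_hetatm_only_chain_kept_as_metadata(self, tmp_path):
        text = (
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C\n"
            "HETATM    3  O   HOH B   1       9.000   9.000   9.000  1.00  0.00           O\n"
            "END\n"
        )
        path = tmp_path / "het.pdb"
        path.write_text(text)
        st = read_structure(path, format="pdb")
        assert st.chain_ids() == ["A"]
        assert "B" in st.het_chains


class TestExtractCa:
    def test_lengths_and_skip_tally(self, two_residue_pdb):
        st = read_structure(two_residue_pdb)
        cs = extract_ca(st)
        assert len(cs) == 2
        assert cs.n_skipped == 0

    def test_residue_without_ca_is_skipped_and_counted(self, tmp_path):
        text = (
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  N   GLY A   2       3.800   0.000   0.000  1.00  0.00           N\n"
            "ATOM      3  CA  SER A   3       7.600   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        path = tmp_path / "gap.pdb"
        path.write_text(text)
        cs = extract_ca(read_structure(path))
        assert len(cs) == 2
        assert cs.n_skipped == 1

    def test_chain_and_range_selection(self):
        st, truth = make_mock_transporter(MockSpec(seed=5))
        sel = Selection("B", (10, 20))
        cs = extract_ca(st, sel)
        assert len(cs) == 11
        assert all(lab.chain_id == "B" for lab in cs.labels)
        assert all(10 <= lab.residue_number <= 20 for lab in cs.labels)

    def test_empty_selection_raises(self, two_residue_pdb):
        st = read_structure(two_residue_pdb)
        with pytest.raises(EmptySelectionError):
            extract_ca(st, Selection("Z", None))


class TestWriteMmcif:
    def test_round_trip_preserves_labels_and_coords(self, tmp_path):
        st, _ = make_mock_transporter(MockSpec(seed=3, noise_sigma=0.2))
        out = tmp_path / "mock.cif"
        write_mmcif(st, out)
        back = read_structure(out, format="mmcif")
        cs_a, cs_b = extract_ca(st), extract_ca(back)
        assert cs_a.labels == cs_b.labels
        np.testing.assert_allclose(cs_a.coords, cs_b.coords, atol=1e-3)

    def test_multichar_chain_id_preserved(self, tmp_path):
        cs = coordinate_set(np.random.default_rng(0).normal(size=(5, 3)) * 10)
        st = structure_from_coordinates("t", {"AB": cs})
        out = tmp_path / "mc.cif"
        write_mmcif(st, out)
        back = read_structure(out, format="mmcif")
        assert back.chain_ids() == ["AB"]

    def test_refuses_empty_structure(self, tmp_path):
        with pytest.raises(EmptyStructureError):
            # Structure constructor itself refuses zero chains
            structure_from_coordinates("x", {})


class TestApplyTransform:
    def test_identity_is_noop(self, two_residue_pdb):
        st = read_structure(two_residue_pdb)
        moved = apply_transform(st, np.eye(3), np.zeros(3))
        np.testing.assert_allclose(
            extract_ca(moved).coords, extract_ca(st).coords, atol=1e-12
        )

    def test_translation_shifts_x(self, two_residue_pdb):
        st = read_structure(two_residue_pdb)
        moved = apply_transform(st, np.eye(3), np.array([1.0, 0.0, 0.0]))
        np.testing.assert_allclose(
            extract_ca(moved).coords[:, 0], extract_ca(st).coords[:, 0] + 1.0
        )

    def test_z_rotation_of_unit_x(self):
        cs = coordinate_set(np.array([[1.0, 0, 0], [0, 0, 0], [0, 0, 1.0]]))
        st = structure_from_coordinates("r", {"A": cs})
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = apply_transform(st, Rz, np.zeros(3))
        np.testing.assert_allclose(
            extract_ca(moved).coords[0], [0.0, 1.0, 0.0], atol=1e-12
        )

    def test_rejects_non_orthonormal_rotation(self, two_residue_pdb):
        st = read_structure(two_residue_pdb)
        with pytest.raises(TransformError):
            apply_transform(st, np.eye(3) * 2.0, np.zeros(3))

    def test_preserves_pairwise_distances(self):
        rng = np.random.default_rng(1)
        cs = coordinate_set(rng.normal(size=(20, 3)) * 15)
        st = structure_from_coordinates("d", {"A": cs})
        R = Rotation.random(random_state=7).as_matrix()
        moved = apply_transform(st, R, np.array([3.0, -2.0, 8.0]))
        a = extract_ca(st).coords
        b = extract_ca(moved).coords
        da = np.linalg.norm(a[:, None] - a[None], axis=-1)
        db = np.linalg.norm(b[:, None] - b[None], axis=-1)
        np.testing.assert_allclose(da, db, atol=1e-6)


def test_insertion_codes_sort_after_uninserted():
    a = ResidueLabel("A", 10)
    b = ResidueLabel("A", 10, "A")
    c = ResidueLabel("A", 10, "B")
    d = ResidueLabel("A", 11)
    assert sorted([d, c, b, a], key=lambda x: x.sort_key()) == [a, b, c, d]


def test_altloc_highest_occupancy_wins(tmp_path):
    text = (
        "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40  0.00           C\n"
        "ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.60  0.00           C\n"
        "ATOM      3  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C\n"
        "ATOM      4  CA  SER A   3       7.600   0.000   0.000  1.00  0.00           C\n"
        "END\n"
    )
    path = tmp_path / "alt.pdb"
    path.write_text(text)
    st = read_structure(path)
    np.testing.assert_allclose(st.chains["A"][0].atoms["CA"], [5.0, 0.0, 0.0])
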