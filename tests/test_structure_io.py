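"""structure_io: readers, bond graph, symmetry expansion, radii, cube/report IO."""

from __future__ import annotations

import gzip

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oxastack._elements import UnknownElementError
from oxastack.contact_screen import ContactRecord
from oxastack.grids import VolumetricGrid
from oxastack.structure_io import (
    AtomSite,
    CrystalStructure,
    StructureParseError,
    SymmetryOp,
    UnitCell,
    build_bond_graph,
    covalent_radius,
    expand_symmetry,
    invert_code,
    molecule_ids,
    read_cif,
    read_cube,
    read_pdb,
    read_report,
    read_structure,
    vdw_radius,
    write_cube,
    write_report,
)
from conftest import rigid_motion, sites_from

MINIMAL_CIF = """data_test
_cell_length_a 10.0
_cell_length_b 10.0
_cell_length_c 10.0
_cell_angle_alpha 90
_cell_angle_beta 90
_cell_angle_gamma 90
_symmetry_space_group_name_H-M 'P 1'
loop_
_atom_site_label
_atom_site_type_symbol
_atom_site_fract_x
_atom_site_fract_y
_atom_site_fract_z
C1 C 0.0 0.0 0.0
"""

TWO_RESIDUE_PDB = """\
ATOM      1  CG  PHE A   1       1.390   0.000   0.000  1.00  0.00           C
ATOM      2  CD1 PHE A   1       0.695   1.204   0.000  1.00  0.00           C
ATOM      3  CE1 PHE A   1      -0.695   1.204   0.000  1.00  0.00           C
ATOM      4  CZ  PHE A   1      -1.390   0.000   0.000  1.00  0.00           C
ATOM      5  CE2 PHE A   1      -0.695  -1.204   0.000  1.00  0.00           C
ATOM      6  CD2 PHE A   1       0.695  -1.204   0.000  1.00  0.00           C
HETATM    7  O1  LIG A 901       0.000   0.000   3.400  1.00  0.00           O
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.30  0.00           C
ATOM      2  CA BALA A   1       1.000   0.000   0.000  0.70  0.00           C
END
"""


class TestReadCif:
    def test_minimal_p1_origin_atom(self, tmp_path):
        p = tmp_path / "min.cif"
        p.write_text(MINIMAL_CIF)
        st_ = read_cif(p)
        assert len(st_) == 1
        np.testing.assert_allclose(st_.sites[0].cart, [0, 0, 0], atol=1e-12)
        assert st_.sites[0].element == "C"
        assert len(st_.ops) == 1

    def test_orthorhombic_orthogonalization(self, tmp_path):
        cif = MINIMAL_CIF.replace("_cell_length_b 10.0", "_cell_length_b 20.0") \
                         .replace("_cell_length_c 10.0", "_cell_length_c 30.0") \
                         .replace("C1 C 0.0 0.0 0.0", "C1 C 0.5 0.5 0.5")
        p = tmp_path / "ortho.cif"
        p.write_text(cif)
        st_ = read_cif(p)
        np.testing.assert_allclose(st_.sites[0].cart, [5.0, 10.0, 15.0], atol=1e-9)

    def test_space_group_from_name(self, tmp_path):
        cif = MINIMAL_CIF.replace("'P 1'", "'P 21/c'")
        p = tmp_path / "p21c.cif"
        p.write_text(cif)
        st_ = read_cif(p)
        assert len(st_.ops) == 4
        assert any(not op.is_identity for op in st_.ops)

    def test_missing_cell_tag_is_named_in_error(self, tmp_path):
        p = tmp_path / "bad.cif"
        p.write_text(MINIMAL_CIF.replace("_cell_length_b 10.0\n", ""))
        with pytest.raises(StructureParseError, match="_cell_length_b"):
            read_cif(p)

    def test_unknown_element_names_label(self, tmp_path):
        p = tmp_path / "bad_el.cif"
        p.write_text(MINIMAL_CIF.replace("C1 C ", "Q9 Xq "))
        with pytest.raises(StructureParseError, match="Q9"):
            read_cif(p)

    def test_gzipped_input(self, tmp_path):
        p = tmp_path / "min.cif.gz"
        with gzip.open(p, "wt") as fh:
            fh.write(MINIMAL_CIF)
        assert len(read_cif(p)) == 1

    def test_disorder_keeps_higher_occupancy(self, tmp_path):
        cif = MINIMAL_CIF.replace(
            "C1 C 0.0 0.0 0.0",
            "C1 C 0.0 0.0 0.0 0.3\nC1 C 0.1 0.1 0.1 0.7").replace(
            "_atom_site_fract_z",
            "_atom_site_fract_z\n_atom_site_occupancy")
        p = tmp_path / "dis.cif"
        p.write_text(cif)
        with pytest.warns(UserWarning, match="disordered"):
            st_ = read_cif(p)
        assert len(st_) == 1
        assert st_.sites[0].occupancy == 0.7

    def test_r_factor_parsed(self, tmp_path):
        p = tmp_path / "rf.cif"
        p.write_text(MINIMAL_CIF + "_refine_ls_R_factor_gt 0.041\n")
        assert read_cif(p).r_factor == pytest.approx(0.041)


class TestReadPdb:
    def test_two_residue_ligand_flagged(self, tmp_path):
        p = tmp_path / "two.pdb"
        p.write_text(TWO_RESIDUE_PDB)
        st_ = read_pdb(p)
        residues = {(s.residue, s.res_seq) for s in st_.sites}
        assert residues == {("PHE", 1), ("LIG", 901)}
        lig = [s for s in st_.sites if s.residue == "LIG"]
        assert all(s.is_hetero for s in lig)
        assert all(not s.is_hetero for s in st_.sites if s.residue == "PHE")

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(ALTLOC_PDB)
        st_ = read_pdb(p)
        assert len(st_) == 1
        assert st_.sites[0].occupancy == pytest.approx(0.7)
        assert st_.sites[0].cart[0] == pytest.approx(1.0)

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("END\n")
        with pytest.raises(StructureParseError):
            read_pdb(p)

    def test_read_structure_dispatch(self, tmp_path):
        p = tmp_path / "two.pdb"
        p.write_text(TWO_RESIDUE_PDB)
        assert len(read_structure(p)) == 7


class TestBondGraph:
    def test_far_atoms_unbonded(self):
        sites = sites_from([[0, 0, 0], [5, 0, 0]], ["C", "C"])
        assert build_bond_graph(sites).n_edges == 0

    def test_benzene_has_six_ring_edges(self, benzene_sites):
        g = build_bond_graph(benzene_sites)
        assert g.n_edges == 6
        for i in range(6):
            assert g.distance(i, (i + 1) % 6) == pytest.approx(1.39, abs=1e-9)

    def test_ch_bond(self):
        sites = sites_from([[0, 0, 0], [1.09, 0, 0]], ["C", "H"])
        assert build_bond_graph(sites).n_edges == 1

    def test_rigid_motion_invariance(self, naphthalene_sites):
        g0 = build_bond_graph(naphthalene_sites)
        rng = np.random.default_rng(42)
        rot, trans = rigid_motion(rng)
        moved = [AtomSite(label=s.label, element=s.element,
                          cart=rot @ s.cart + trans) for s in naphthalene_sites]
        g1 = build_bond_graph(moved)
        assert sorted(g0.graph.edges) == sorted(g1.graph.edges)

    def test_molecule_ids_two_fragments(self):
        sites = sites_from([[0, 0, 0], [1.4, 0, 0], [10, 0, 0]], ["C", "C", "C"])
        ids = molecule_ids(build_bond_graph(sites))
        assert ids[0] == ids[1] != ids[2]


def _p1_crystal(frac, cell=UnitCell(10, 10, 10), ops=None, element="C"):
    frac = np.atleast_2d(frac)
    sites = [AtomSite(label=f"{element}{i+1}", element=element,
                      frac=f, cart=cell.orthogonalize(f))
             for i, f in enumerate(frac)]
    return CrystalStructure("xtal", sites, cell=cell,
                            ops=ops or [SymmetryOp.from_triplet("x,y,z")])


class TestExpandSymmetry:
    def test_negative_cutoff_rejected(self):
        with pytest.raises(ValueError):
            expand_symmetry(_p1_crystal([0.5, 0.5, 0.5]), -1.0)

    def test_zero_cutoff_no_images(self):
        assert expand_symmetry(_p1_crystal([0.5, 0.5, 0.5]), 0.0) == []

    def test_p1_translation_images_enumerated(self):
        # single atom, 10 A cell: lattice images sit at 10 (face), 14.14
        # (edge) and 17.3 A (corner); brute-force enumeration of the 3^3
        # translations fixes the expected counts at each cutoff
        xt = _p1_crystal([0.0, 0.0, 0.0])
        assert expand_symmetry(xt, 2.0) == []
        face = expand_symmetry(xt, 10.5)
        assert len(face) == 6
        assert {im.code for im in face} == {
            (0, 1, 0, 0), (0, -1, 0, 0), (0, 0, 1, 0), (0, 0, -1, 0),
            (0, 0, 0, 1), (0, 0, 0, -1)}
        edge = expand_symmetry(xt, 14.5)
        assert len(edge) == 6 + 12
        for im in edge:
            assert np.linalg.norm(im.cart) <= 14.5 + 1e-9

    def test_inversion_op_image_position(self):
        ops = [SymmetryOp.from_triplet("x,y,z"), SymmetryOp.from_triplet("-x,-y,-z")]
        xt = _p1_crystal([0.1, 0.1, 0.1], ops=ops)
        images = expand_symmetry(xt, 5.0)
        inv = [im for im in images if im.code[0] == 1]
        assert inv
        cell = xt.cell
        fracs = {tuple(np.round(cell.fractionalize(im.cart), 6)) for im in inv}
        assert any(np.allclose(np.mod(f, 1.0), [0.9, 0.9, 0.9]) for f in fracs)

    def test_group_closure_of_parsed_ops(self, tmp_path):
        p = tmp_path / "p21c.cif"
        p.write_text(MINIMAL_CIF.replace("'P 1'", "'P 21/c'"))
        ops = read_cif(p).ops
        trips = {op.triplet for op in ops}
        import gemmi
        for a in ops:
            for b in ops:
                combined = gemmi.Op(a.triplet) * gemmi.Op(b.triplet)
                wrapped = combined.wrap()
                assert wrapped.triplet() in trips
            assert a._op.inverse().wrap().triplet() in trips

    def test_invert_code_round_trip(self):
        ops = [SymmetryOp.from_triplet("x,y,z"),
               SymmetryOp.from_triplet("-x,y+1/2,-z+1/2")]
        code = (1, 2, -1, 0)
        from oxastack.structure_io import compose_code
        assert compose_code(ops, code, invert_code(ops, code)) == (0, 0, 0, 0)


class TestRadii:
    @pytest.mark.parametrize("element,expected", [
        ("C", 1.70), ("N", 1.55), ("O", 1.52), ("H", 1.20), ("S", 1.80)])
    def test_bondi_vdw(self, element, expected):
        assert vdw_radius(element) == expected

    def test_covalent_sane(self):
        assert 0.6 < covalent_radius("C") < 0.9

    def test_unknown_element_named(self):
        with pytest.raises(UnknownElementError, match="Xx"):
            vdw_radius("Xx")


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    a=st.floats(3, 50), b=st.floats(3, 50), c=st.floats(3, 50),
    alpha=st.floats(60, 120), beta=st.floats(60, 120), gamma=st.floats(60, 120),
    fx=st.floats(-1, 2), fy=st.floats(-1, 2), fz=st.floats(-1, 2))
def test_orthogonalize_fractionalize_identity(a, b, c, alpha, beta, gamma,
                                              fx, fy, fz):
    """frac -> cart -> frac is the identity for arbitrary (valid) cells."""
    try:
        cell = UnitCell(a, b, c, alpha, beta, gamma)
        cart = cell.orthogonalize([fx, fy, fz])
    except ValueError:
        return
    if not np.all(np.isfinite(cart)):
        return
    back = cell.fractionalize(cart)
    np.testing.assert_allclose(back, [fx, fy, fz], atol=1e-10)


class TestCubeAndReports:
    def test_cube_round_trip_zeros(self, tmp_path):
        g = VolumetricGrid([0, 0, 0], np.eye(3) * 0.5, np.zeros((2, 2, 2)))
        p = tmp_path / "z.cube"
        write_cube(g, p)
        g2, atoms = read_cube(p)
        assert g2.dims == (2, 2, 2)
        np.testing.assert_allclose(g2.values, 0.0)
        assert atoms == []

    def test_cube_round_trip_random(self, tmp_path, benzene_sites):
        rng = np.random.default_rng(3)
        g = VolumetricGrid([-1, -2, 0.5], np.eye(3) * 0.3,
                           rng.normal(size=(4, 5, 7)))
        p = tmp_path / "r.cube"
        write_cube(g, p, atoms=benzene_sites)
        g2, atoms = read_cube(p)
        np.testing.assert_allclose(g2.values, g.values, rtol=1e-4, atol=1e-9)
        np.testing.assert_allclose(g2.origin, g.origin, atol=1e-5)
        assert len(atoms) == 6 and atoms[0][0] == 6

    def test_empty_csv_report_header_only(self, tmp_path):
        p = tmp_path / "empty.csv"
        write_report([], p, "csv", fieldnames=["a", "b"])
        assert p.read_text().strip() == "a,b"

    def test_contact_record_json_round_trip(self, tmp_path):
        rec = ContactRecord(
            structure="s", query_ring_class="oxadiazole-1,2,4",
            query_ring_id=0, query_atom_label="C3", query_atom_role="C3",
            query_element="C", partner_ring_class="phenyl", partner_ring_id=1,
            partner_ring_size=6, partner_atom_label="C1", partner_element="C",
            d1=3.85, a1=90.0, a2=90.0, symmetry_code=(0, 0, 0, 0))
        p = tmp_path / "rec.json"
        write_report([rec], p, "json")
        back = read_report(p, ContactRecord)
        assert back == [rec]
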