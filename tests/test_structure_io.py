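"""I/O: xyzr, PDB frames with radius assignment, meshes, result tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from poreflow import (
    AtomSet,
    RadiusTable,
    SurfaceMesh,
    read_mesh,
    read_pdb_frames,
    read_xyzr,
    write_mesh,
    write_xyzr,
    write_results,
)
from poreflow.errors import (
    EmptyStructureError,
    FormatError,
    ParseError,
    ValidationError,
)


# ---------------------------------------------------------------------------
# xyzr
# ---------------------------------------------------------------------------

class TestXyzr:
    def test_single_atom(self, tmp_path):
        p = tmp_path / "a.xyzr"
        p.write_text("0 0 0 1.5\n")
        atoms = read_xyzr(p)
        assert len(atoms) == 1
        np.testing.assert_allclose(atoms.centers[0], [0, 0, 0])
        assert atoms.radii[0] == 1.5
        assert atoms.labels is None

    def test_trailing_fields_and_comments_tolerated(self, tmp_path):
        p = tmp_path / "a.xyzr"
        p.write_text("# header\n1.0 2.0 3.0 1.4 extra stuff\n\n")
        atoms = read_xyzr(p)
        assert len(atoms) == 1
        np.testing.assert_allclose(atoms.centers[0], [1, 2, 3])

    def test_nonpositive_radius_rejected(self, tmp_path):
        p = tmp_path / "a.xyzr"
        p.write_text("0 0 0 -1\n")
        with pytest.raises(ValidationError, match="radius"):
            read_xyzr(p)

    @pytest.mark.parametrize("bad", ["0 0 0", "0 0 x 1"])
    def test_malformed_line_names_line_number(self, tmp_path, bad):
        p = tmp_path / "a.xyzr"
        p.write_text("0 0 0 1\n" + bad + "\n")
        with pytest.raises(ParseError, match="line 2"):
            read_xyzr(p)

    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        atoms = AtomSet(rng.normal(size=(20, 3)), rng.uniform(1, 2, 20))
        p = tmp_path / "rt.xyzr"
        write_xyzr(atoms, p)
        back = read_xyzr(p)
        np.testing.assert_allclose(back.centers, atoms.centers, atol=1e-6)
        np.testing.assert_allclose(back.radii, atoms.radii, atol=1e-6)


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _atom_line(serial, name, res, chain, resid, x, y, z, element):
    return (f"ATOM  {serial:5d} {name:<4s}{res:>4s}{chain}{resid:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}\n")


def _two_model_pdb(tmp_path):
    lines = []
    for m in (1, 2):
        lines.append(f"MODEL     {m}\n")
        lines.append(_atom_line(1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0 + m, "N"))
        lines.append(_atom_line(2, "CA", "ALA", "A", 1, 1.5, 0.0, 0.0 + m, "C"))
        lines.append(_atom_line(3, "O", "ALA", "A", 1, 2.5, 1.0, 0.0 + m, "O"))
        lines.append(_atom_line(4, "O", "HOH", "A", 2, 9.0, 9.0, 9.0, "O"))
        lines.append("ENDMDL\n")
    p = tmp_path / "two.pdb"
    p.write_text("".join(lines) + "END\n")
    return p


class TestPdbFrames:
    def test_waters_excluded_per_model(self, tmp_path):
        frames = read_pdb_frames(_two_model_pdb(tmp_path))
        assert len(frames) == 2
        assert all(len(f) == 3 for f in frames)
        # element radii from the bundled van der Waals table
        np.testing.assert_allclose(frames[0].radii, [1.55, 1.70, 1.52])
        assert list(frames[0].labels["res_name"]) == ["ALA"] * 3

    def test_model_less_file_is_one_frame(self, tmp_path):
        p = tmp_path / "one.pdb"
        p.write_text(
            _atom_line(1, "CA", "GLY", "A", 1, 0, 0, 0, "C")
            + _atom_line(2, "N", "GLY", "A", 1, 1, 0, 0, "N")
            + "END\n"
        )
        frames = read_pdb_frames(p)
        assert len(frames) == 1
        assert len(frames[0]) == 2

    def test_only_water_raises(self, tmp_path):
        p = tmp_path / "wet.pdb"
        p.write_text(_atom_line(1, "O", "HOH", "A", 1, 0, 0, 0, "O") + "END\n")
        with pytest.raises(EmptyStructureError):
            read_pdb_frames(p)

    def test_radius_assignment_is_pure(self, tmp_path):
        p = _two_model_pdb(tmp_path)
        t = RadiusTable()
        a = read_pdb_frames(p, table=t)
        b = read_pdb_frames(p, table=t)
        np.testing.assert_array_equal(a[0].centers, b[0].centers)
        np.testing.assert_array_equal(a[0].radii, b[0].radii)


class TestRadiusTable:
    def test_override_beats_element(self):
        t = RadiusTable(overrides={("ALA", "CA"): 2.1})
        assert t.lookup("ALA", "CA") == 2.1
        assert t.lookup("GLY", "CA") == 1.70

    def test_unknown_element_falls_back_to_default(self):
        t = RadiusTable(default=1.23)
        assert t.lookup("XXX", "QQ", element="Xx") == 1.23

    def test_from_csv(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text("res_name,atom_name,radius\nALA,CB,1.95\n")
        t = RadiusTable.from_csv(p)
        assert t.lookup("ALA", "CB") == 1.95


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------

TET_VERTS = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
TET_FACES = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])


class TestMeshIO:
    @pytest.mark.parametrize("suffix", [".off", ".ply"])
    def test_tetrahedron_round_trip(self, tmp_path, suffix):
        mesh = SurfaceMesh(TET_VERTS, TET_FACES)
        p = tmp_path / f"tet{suffix}"
        write_mesh(mesh, p)
        back = read_mesh(p)
        assert back.n_vertices == 4
        assert back.n_triangles == 4
        np.testing.assert_allclose(back.vertices, TET_VERTS, atol=1e-6)
        np.testing.assert_array_equal(back.triangles, TET_FACES)

    def test_off_quad_face_rejected(self, tmp_path):
        p = tmp_path / "quad.off"
        p.write_text("OFF\n4 1 0\n0 0 0\n1 0 0\n1 1 0\n0 1 0\n4 0 1 2 3\n")
        with pytest.raises(FormatError, match="triangle"):
            read_mesh(p)

    def test_off_bad_header_rejected(self, tmp_path):
        p = tmp_path / "bad.off"
        p.write_text("NOPE\n1 2 3\n")
        with pytest.raises(FormatError):
            read_mesh(p)


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

class _StubResult:
    def __init__(self, index, centerline=None):
        self.index = index
        self.status = "full_init"
        self.reason = None
        self.centerline = centerline
        self.sections = None
        self.channel_mesh = None


def _stub_centerline(n=7):
    from poreflow import Centerline

    pts = np.column_stack([np.zeros(n), np.zeros(n), np.linspace(0, 3, n)])
    z = np.zeros((n, 3))
    return Centerline(pts, np.linspace(0, 3, n), z, z, z, np.zeros(n),
                      np.zeros(n), np.zeros(n, bool), radius=np.ones(n))


class TestWriteResults:
    def test_centerline_row_count(self, tmp_path):
        files = write_results([_StubResult(0, _stub_centerline(7))], tmp_path)
        csv = tmp_path / "frame_000000_centerline.csv"
        assert csv in files
        assert len(pd.read_csv(csv)) == 7

    def test_three_frames_named_sequentially(self, tmp_path):
        results = [_StubResult(i, _stub_centerline()) for i in range(3)]
        write_results(results, tmp_path)
        for i in range(3):
            assert (tmp_path / f"frame_{i:06d}_centerline.csv").exists()

    def test_empty_results_error(self, tmp_path):
        with pytest.raises(ValidationError):
            write_results([], tmp_path)


class TestAtomSetInvariants:
    def test_mismatched_lengths(self):
        with pytest.raises(ValidationError):
            AtomSet(np.zeros((3, 3)), np.ones(2))

    def test_nonfinite_coordinates(self):
        with pytest.raises(ValidationError):
            AtomSet(np.array([[0, 0, np.nan]]), np.ones(1))

    def test_duplicate_atoms_rejected(self):
        with pytest.raises(ValidationError, match="coincident"):
            AtomSet(np.zeros((2, 3)), np.ones(2))
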