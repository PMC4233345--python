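"""File I/O and data-model invariants."""

import numpy as np
import pytest

from saskit import sasio
from saskit.sasio import (
    BeadModel,
    DensityGrid,
    SasFormatError,
    ScatteringCurve,
    ValidationError,
)

GLY3_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.451   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  N   GLY A   2       3.300   1.500   0.000  1.00  0.00           N
ATOM      5  CA  GLY A   2       4.200   2.600   0.000  1.00  0.00           C
ATOM      6  C   GLY A   2       5.600   2.000   0.000  1.00  0.00           C
ATOM      7  N   GLY A   3       6.600   2.900   0.000  1.00  0.00           N
ATOM      8  CA  GLY A   3       8.000   2.500   0.000  1.00  0.00           C
ATOM      9  C   GLY A   3       9.000   3.600   0.000  1.00  0.00           C
TER
END
"""


class TestCurveModel:
    def test_invariants_enforced(self):
        with pytest.raises(ValidationError):
            ScatteringCurve(s=[0.02, 0.01], I=[1.0, 2.0])          # decreasing s
        with pytest.raises(ValidationError):
            ScatteringCurve(s=[-0.01, 0.02], I=[1.0, 2.0])         # negative s
        with pytest.raises(ValidationError):
            ScatteringCurve(s=[0.01, 0.02], I=[1.0, 2.0], sigma=[1.0, 0.0])

    def test_negative_intensity_allowed(self):
        c = ScatteringCurve(s=[0.01, 0.02], I=[1.0, -0.5])
        assert c.I[1] == -0.5


class TestCurveIO:
    def test_three_column_parse(self, tmp_path):
        p = tmp_path / "a.dat"
        p.write_text("0.01 100 1\n0.02 90 1\n0.03 80 1\n")
        c = sasio.read_curve(p)
        assert len(c) == 3
        np.testing.assert_allclose(c.s, [0.01, 0.02, 0.03])
        np.testing.assert_allclose(c.sigma, [1, 1, 1])

    def test_header_becomes_label(self, tmp_path):
        p = tmp_path / "a.dat"
        p.write_text("Sample: lysozyme\n0.01 100 1\n0.02 90 1\n0.03 80 1\n")
        c = sasio.read_curve(p)
        assert c.label == "Sample: lysozyme"
        np.testing.assert_allclose(c.I, [100, 90, 80])

    def test_two_columns_no_sigma(self, tmp_path):
        p = tmp_path / "a.dat"
        p.write_text("0.01 100\n0.02 90\n")
        assert sasio.read_curve(p).sigma is None

    def test_descending_s_rejected(self, tmp_path):
        p = tmp_path / "a.dat"
        p.write_text("0.03 80 1\n0.02 90 1\n0.01 100 1\n")
        with pytest.raises(ValidationError):
            sasio.read_curve(p)

    def test_garbage_file_names_bad_line(self, tmp_path):
        p = tmp_path / "a.dat"
        p.write_text("not a number anywhere\nstill not\n")
        with pytest.raises(SasFormatError, match="not a number"):
            sasio.read_curve(p)

    def test_bad_rows_dropped(self, tmp_path):
        p = tmp_path / "a.dat"
        p.write_text("0.01 100 1\n0.02 -5 1\n0.03 80 0\n")
        c = sasio.read_curve(p)
        # negative I kept, sigma <= 0 dropped
        assert len(c) == 2
        assert c.I[1] == -5

    def test_round_trip(self, tmp_path, sphere30):
        rng = np.random.default_rng(0)
        c = sphere30.with_(sigma=0.01 * np.abs(sphere30.I) + 1e-5)
        p = tmp_path / "rt.dat"
        sasio.write_curve(c, p)
        c2 = sasio.read_curve(p)
        np.testing.assert_allclose(c2.s, c.s, rtol=1e-6)
        np.testing.assert_allclose(c2.I, c.I, rtol=1e-6)
        np.testing.assert_allclose(c2.sigma, c.sigma, rtol=1e-6)

    def test_write_rejects_non_curve(self, tmp_path):
        with pytest.raises(ValidationError):
            sasio.write_curve("not a curve", tmp_path / "x.dat")


class TestModelIO:
    def test_ca_only(self, tmp_path):
        p = tmp_path / "gly3.pdb"
        p.write_text(GLY3_PDB)
        m = sasio.read_model(p, mode="ca_only")
        assert len(m) == 3
        # order preserved: residue index increasing
        assert list(m.residue_index) == [1, 2, 3]

    def test_full_atom_counts_all_records(self, tmp_path):
        p = tmp_path / "gly3.pdb"
        p.write_text(GLY3_PDB)
        m = sasio.read_model(p, mode="full_atom")
        assert len(m) == GLY3_PDB.count("ATOM ")

    def test_multi_model_nmr_file(self, tmp_path):
        body = "".join(
            f"MODEL {k}\n" + GLY3_PDB.replace("END\n", "") + "ENDMDL\n"
            for k in (1, 2, 3)
        )
        p = tmp_path / "ens.pdb"
        p.write_text(body)
        models = sasio.read_models(p, mode="ca_only")
        assert len(models) == 3
        assert all(len(m) == 3 for m in models)

    def test_no_atoms_is_error(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("REMARK nothing here\nEND\n")
        with pytest.raises(SasFormatError):
            sasio.read_model(p)

    def test_model_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        m = BeadModel(coords=rng.uniform(-40, 40, (50, 3)))
        p = tmp_path / "m.pdb"
        sasio.write_model(m, p)
        m2 = sasio.read_model(p, mode="bead")
        np.testing.assert_allclose(m2.coords, m.coords, atol=1e-3)


class TestDensityIO:
    def test_round_trip_and_header(self, tmp_path):
        vals = np.zeros((4, 4, 4))
        vals[1, 2, 3] = 1.0
        g = DensityGrid(values=vals, voxel_size=2.0)
        p = tmp_path / "m.mrc"
        sasio.write_density(g, p)
        g2 = sasio.read_density(p)
        np.testing.assert_allclose(g2.voxel_size, [2.0, 2.0, 2.0])
        assert g2.values.max() == 1.0
        assert np.unravel_index(np.argmax(g2.values), g2.values.shape) == (1, 2, 3)

    def test_voxel_size_from_header(self, tmp_path):
        g = DensityGrid(values=np.ones((4, 4, 4)), voxel_size=[1.5, 1.5, 1.5])
        p = tmp_path / "m.mrc"
        sasio.write_density(g, p)
        np.testing.assert_allclose(sasio.read_density(p).voxel_size, 1.5)

    def test_truncated_file_is_format_error(self, tmp_path):
        g = DensityGrid(values=np.ones((8, 8, 8)), voxel_size=2.0)
        p = tmp_path / "m.mrc"
        sasio.write_density(g, p)
        data = p.read_bytes()
        p.write_bytes(data[: len(data) // 2])
        with pytest.raises(SasFormatError):
            sasio.read_density(p)
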