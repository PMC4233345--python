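"""Debye-sum intensities and curve fitting."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from saskit import formfit, synthio
from saskit.sasio import BeadModel, ScatteringCurve, ValidationError


class TestDebyeIntensity:
    def test_single_point_self_term(self):
        m = BeadModel(coords=[[1.0, 2.0, 3.0]], weight=[2.0])
        tc = formfit.debye_intensity(m, np.linspace(0, 0.5, 20))
        np.testing.assert_allclose(tc.I, 4.0)

    def test_two_point_closed_form(self):
        m = BeadModel(coords=[[0, 0, 0], [10.0, 0, 0]])
        s = np.array([0.0, 0.05, 0.1, 0.3])
        tc = formfit.debye_intensity(m, s)
        with np.errstate(invalid="ignore"):
            expected = 2.0 + 2.0 * np.where(s > 0, np.sin(10 * s) / (10 * s), 1.0)
        np.testing.assert_allclose(tc.I, expected, rtol=1e-12)

    def test_forward_scattering_identity(self, beads100):
        tc = formfit.debye_intensity(beads100, np.array([0.0, 0.01]))
        assert tc.I[0] == pytest.approx(beads100.weight.sum() ** 2, rel=1e-12)

    def test_histogram_path_matches_exact(self):
        m = synthio.random_bead_model(500, envelope_radius=40, seed=9)
        s = np.linspace(1e-3, 0.4, 60)
        exact = formfit.debye_intensity(m, s, exact=True)
        binned = formfit.debye_intensity(m, s, exact=False)
        assert np.max(np.abs(binned.I - exact.I) / exact.I) < 1e-3

    def test_rigid_motion_invariance(self, beads100):
        s = np.linspace(1e-3, 0.4, 50)
        base = formfit.debye_intensity(beads100, s)
        rng = np.random.default_rng(4)
        for _ in range(3):
            R = Rotation.random(rng=rng).as_matrix()
            moved = beads100.transformed(R, rng.uniform(-50, 50, 3))
            tc = formfit.debye_intensity(moved, s)
            assert np.max(np.abs(tc.I - base.I) / base.I) < 1e-10

    def test_positivity(self, beads100):
        s = np.linspace(1e-3, 1.0, 200)
        for kind in ("point", "gaussian_sphere", "hard_sphere_amplitude"):
            tc = formfit.debye_intensity(beads100, s, form_factor_kind=kind)
            assert np.all(tc.I > 0)

    def test_empty_grid_rejected(self, beads100):
        with pytest.raises(ValidationError):
            formfit.debye_intensity(beads100, np.array([]))


class TestRegrid:
    def test_reduces_to_max_points(self):
        s = np.linspace(1e-3, 0.5, 2000)
        rng = np.random.default_rng(0)
        I = 1000 * np.exp(-50 * s)
        c = ScatteringCurve(s=s, I=I, sigma=0.01 * I)
        r = formfit.regrid_for_fit(c, 256)
        assert len(r) <= 256
        # each output point stays inside the envelope of its source block
        edges = np.linspace(s[0], s[-1], 256 + 1)
        idx = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, 255)
        out = 0
        for b in range(256):
            m = idx == b
            if not np.any(m):
                continue
            assert I[m].min() - 1e-9 <= r.I[out] <= I[m].max() + 1e-9
            out += 1

    def test_short_curve_unchanged(self, sphere30):
        c = sphere30.crop(0.0, 0.1)
        assert formfit.regrid_for_fit(c, 256) is c

    def test_linear_curve_exact(self):
        s = np.linspace(0.0, 1.0, 1000)
        c = ScatteringCurve(s=s, I=3.0 + 2.0 * s)
        r = formfit.regrid_for_fit(c, 100)
        np.testing.assert_allclose(r.I, 3.0 + 2.0 * r.s, rtol=1e-12)


class TestFitToData:
    def test_exact_scale_and_background_recovery(self, beads100, s_grid):
        tc = formfit.debye_intensity(beads100, s_grid)
        exp = ScatteringCurve(s=s_grid, I=2.0 * tc.I + 5.0,
                              sigma=0.01 * np.abs(2.0 * tc.I + 5.0) + 1e-9)
        r = formfit.fit_to_data(tc, exp, background_bounds=(-10, 10))
        assert r.scale_c == pytest.approx(2.0, rel=1e-9)
        assert r.background == pytest.approx(5.0, rel=1e-9)
        assert r.chi2_reduced < 1e-18

    def test_chi2_distribution_under_true_noise(self, beads100):
        s = np.linspace(1e-3, 0.4, 500)
        tc = formfit.debye_intensity(beads100, s)
        rng = np.random.default_rng(17)
        chis = []
        for _ in range(50):
            sig = 0.01 * np.abs(tc.I) + 1e-9
            exp = ScatteringCurve(s=s, I=tc.I + rng.normal(0, sig), sigma=sig)
            chis.append(formfit.fit_to_data(tc, exp,
                                            background_bounds=(0.0, 0.0)).chi2_reduced)
        assert 0.7 < np.mean(chis) < 1.3

    def test_background_pinned_at_bound(self, beads100, s_grid):
        tc = formfit.debye_intensity(beads100, s_grid)
        exp = ScatteringCurve(s=s_grid, I=tc.I + 5.0,
                              sigma=0.01 * np.abs(tc.I) + 1e-9)
        free = formfit.fit_to_data(tc, exp, background_bounds=(-10, 10))
        pinned = formfit.fit_to_data(tc, exp, background_bounds=(0.0, 0.1))
        assert pinned.background == pytest.approx(0.1, abs=1e-9)
        assert pinned.chi2_reduced > free.chi2_reduced

    def test_regridded_matches_full_grid_fit(self, beads100):
        s = np.linspace(1e-3, 0.4, 3000)
        tc = formfit.debye_intensity(beads100, s)
        exp = ScatteringCurve(s=s, I=1.7 * tc.I + 2.0,
                              sigma=0.01 * np.abs(tc.I) + 1e-9)
        coarse = formfit.fit_to_data(tc, exp, background_bounds=(-5, 5),
                                     max_points=128)
        fine = formfit.fit_to_data(tc, exp, background_bounds=(-5, 5),
                                   max_points=10**6)
        assert coarse.scale_c == pytest.approx(fine.scale_c, rel=0.01)
        assert coarse.background == pytest.approx(fine.background, rel=0.01)

    def test_constant_theory_rejected(self, s_grid):
        tc = formfit.TheoreticalCurve(s=s_grid, I=np.ones_like(s_grid))
        exp = ScatteringCurve(s=s_grid, I=np.linspace(1, 2, len(s_grid)))
        with pytest.raises(ValidationError):
            formfit.fit_to_data(tc, exp)
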