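"""Concentration-series extrapolation to infinite dilution."""

import numpy as np
import pytest

from saskit import curves, dilution, synthio
from saskit.dilution import DilutionSeries, InconsistentSeriesError
from saskit.sasio import ScatteringCurve, ValidationError


def make_series(base, concs, k=0.05, noise=None, seed=0):
    return DilutionSeries(
        curves=tuple(synthio.noisy_series(base, concs, k=k, noise=noise, seed=seed))
    )


class TestFindFitRange:
    def test_noiseless_identical_shapes(self, sphere30):
        ser = make_series(sphere30, [1.0, 2.0], k=0.05)
        out = dilution.find_fit_range(ser)
        assert out.fit_range[1] == pytest.approx(sphere30.s[-1])
        # scales relative to the reference are ~1 (same shape, high angles match)
        np.testing.assert_allclose(out.scales, 1.0, atol=1e-6)

    def test_outlier_curve_flagged(self, sphere30):
        rng = np.random.default_rng(1)
        nm = synthio.NoiseModel(relative=0.01, floor=1e-3)
        good = synthio.noisy_series(sphere30, [1.0, 2.0], k=0.0, noise=nm, seed=1)
        alien = synthio.sphere_curve(18.0, sphere30.s, i0=1000.0)
        alien = nm.apply(alien, rng).with_(concentration=4.0, label="odd-one-out")
        ser = DilutionSeries(curves=(*good, alien))
        with pytest.raises(InconsistentSeriesError, match="odd-one-out"):
            dilution.find_fit_range(ser)

    def test_single_curve_rejected(self, sphere30):
        with pytest.raises(ValidationError):
            DilutionSeries(curves=(sphere30.with_(concentration=1.0),))


class TestExtrapolateZero:
    def test_noiseless_exact_intercept(self, sphere30):
        ser = dilution.find_fit_range(make_series(sphere30, [1.0, 2.0, 4.0]))
        rep = dilution.extrapolate_zero(ser)
        truth = np.interp(rep.i_zero_curve.s, sphere30.s, sphere30.I)
        assert np.max(np.abs(rep.i_zero_curve.I - truth) / truth) < 1e-10
        assert rep.rg_consistent

    def test_two_concentrations_suffice(self, sphere30):
        ser = dilution.find_fit_range(make_series(sphere30, [1.0, 3.0]))
        rep = dilution.extrapolate_zero(ser)
        truth = np.interp(rep.i_zero_curve.s, sphere30.s, sphere30.I)
        assert np.max(np.abs(rep.i_zero_curve.I - truth) / truth) < 1e-10

    def test_noisy_pointwise_coverage(self, sphere30):
        nm = synthio.NoiseModel(relative=0.01, floor=1e-3)
        ser = dilution.find_fit_range(
            make_series(sphere30, [1.0, 2.0, 4.0], noise=nm, seed=8))
        rep = dilution.extrapolate_zero(ser)
        truth = np.interp(rep.i_zero_curve.s, sphere30.s, sphere30.I)
        pull = np.abs(rep.i_zero_curve.I - truth) / rep.i_zero_curve.sigma
        assert np.mean(pull <= 3.0) >= 0.99
        assert rep.rg_consistent
        assert rep.error_ok

    def test_concentration_independent_series(self, sphere30):
        ser = dilution.find_fit_range(make_series(sphere30, [1.0, 2.0, 4.0], k=0.0))
        rep = dilution.extrapolate_zero(ser)
        assert np.max(np.abs(rep.b_curve.I)) < 1e-9 * np.max(sphere30.I)
        assert not np.any(rep.info_gain)

    def test_info_gain_flagged_at_low_angles(self, sphere30):
        nm = synthio.NoiseModel(relative=0.005, floor=1e-3)
        ser = dilution.find_fit_range(
            make_series(sphere30, [1.0, 2.0, 4.0], k=0.08, noise=nm, seed=3))
        rep = dilution.extrapolate_zero(ser)
        # the concentration effect lives at low angles: the extrapolated curve
        # must leave the envelope of the inputs somewhere in that region
        low = rep.i_zero_curve.s < 0.05
        assert np.any(rep.info_gain[low])

    def test_permutation_invariance(self, sphere30):
        cs = synthio.noisy_series(sphere30, [1.0, 2.0, 4.0], k=0.05)
        r1 = dilution.extrapolate_zero(
            dilution.find_fit_range(DilutionSeries(curves=tuple(cs))))
        r2 = dilution.extrapolate_zero(
            dilution.find_fit_range(DilutionSeries(curves=tuple(cs[::-1]))))
        np.testing.assert_allclose(r1.i_zero_curve.I, r2.i_zero_curve.I, rtol=1e-9)


class TestMergeExtrapolated:
    def test_k_zero_merge_equals_base(self, sphere30):
        ser = dilution.find_fit_range(make_series(sphere30, [1.0, 2.0], k=0.0))
        rep = dilution.extrapolate_zero(ser)
        merged, s_merge = dilution.merge_extrapolated(rep, ser)
        truth = np.interp(merged.s, sphere30.s, sphere30.I)
        assert np.max(np.abs(merged.I - truth) / truth) < 1e-9

    def test_merged_matches_base_below_and_above(self, sphere30):
        ser = dilution.find_fit_range(make_series(sphere30, [1.0, 2.0, 4.0], k=0.05))
        rep = dilution.extrapolate_zero(ser)
        merged, s_merge = dilution.merge_extrapolated(rep, ser)
        truth = np.interp(merged.s, sphere30.s, sphere30.I)
        below = merged.s <= s_merge
        assert np.max(np.abs(merged.I[below] - truth[below]) / truth[below]) < 1e-9
        # above the merge point the average retains a tiny residual
        # concentration effect, negligible at high angles
        above = merged.s > s_merge
        assert np.max(np.abs(merged.I[above] - truth[above]) / truth[above]) < 1e-3

    def test_merge_continuity(self, sphere30):
        nm = synthio.NoiseModel(relative=0.01, floor=1e-3)
        ser = dilution.find_fit_range(
            make_series(sphere30, [1.0, 2.0, 4.0], noise=nm, seed=5))
        rep = dilution.extrapolate_zero(ser)
        merged, s_merge = dilution.merge_extrapolated(rep, ser)
        # the discontinuity between the two branches evaluated at the merge
        # point itself is minimised by construction and must stay within the
        # noise scale of the extrapolated branch
        scaled = [curves.scale(c, k)
                  for c, k in zip(dilution._interp_all(ser), ser.scales)]
        avg = curves.average(scaled)
        k = int(np.searchsorted(rep.i_zero_curve.s, s_merge))
        jump = abs(rep.i_zero_curve.I[k] - avg.I[k])
        assert jump <= 3.0 * rep.i_zero_curve.sigma[k]
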