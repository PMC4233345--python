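"""Automatic scaling, consistency checking and extrapolation of a
concentration series to infinite dilution.

At moderate concentrations interparticle interference adds a term linear in
concentration to the measured profile, I(s, c) = I(s, 0)·(1 − c·B̃(s)) (the
"concentration effect"), concentrated at low angles.  The pipeline here:

1. :func:`find_fit_range` locates a high-angle window where all scaled
   profiles coincide (sample-identity check) and returns the per-curve
   scales onto the most concentrated profile.
2. :func:`extrapolate_zero` performs a pointwise weighted linear regression
   of scaled intensity against concentration; the intercept is the
   infinite-dilution curve I(s, 0), the slope the concentration-effect term
   B(s).  Diagnostics: the Rg of the extrapolated curve is checked against a
   straight-line extrapolation of the per-curve Rg² values to c = 0, the
   intercept errors are bounded against the input errors, and points where
   the extrapolated value genuinely leaves the envelope of the inputs are
   flagged as information gain.
3. :func:`merge_extrapolated` splices the extrapolated curve (low angles)
   with the inverse-variance average of the scaled inputs (high angles) at
   the point of least discontinuity inside the fit range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import curves as _curves
from .sasio import SasError, ScatteringCurve, ValidationError

__all__ = [
    "DilutionSeries",
    "ExtrapolationReport",
    "InconsistentSeriesError",
    "find_fit_range",
    "extrapolate_zero",
    "merge_extrapolated",
    "automerge",
]

RG_CONSISTENCY_TOL = 0.05     # relative Rg agreement required by the diagnostic
ERROR_INFLATION_KAPPA = 5.0   # intercept sigma may not exceed kappa x input sigma
INFO_GAIN_NSIGMA = 3.0        # numerical-error scale for the information-gain flag
PAIR_P_THRESHOLD = 0.01


class InconsistentSeriesError(SasError):
    """The profiles cannot be reconciled by scaling in any high-angle window."""


@dataclass(frozen=True)
class DilutionSeries:
    """A concentration series: curves with distinct positive concentrations."""

    curves: tuple[ScatteringCurve, ...]
    fit_range: tuple[float, float] | None = None
    scales: tuple[float, ...] | None = None

    def __post_init__(self):
        cs = tuple(self.curves)
        object.__setattr__(self, "curves", cs)
        if len(cs) < 2:
            raise ValidationError("a dilution series needs at least 2 curves")
        conc = [c.concentration for c in cs]
        if any(x is None or x <= 0 for x in conc):
            raise ValidationError("every curve needs a positive concentration")
        if len(set(conc)) < 2:
            raise ValidationError("at least 2 distinct concentrations required")

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c.concentration for c in self.curves])


@dataclass(frozen=True)
class ExtrapolationReport:
    i_zero_curve: ScatteringCurve
    b_curve: ScatteringCurve
    rg_extrapolated: float
    rg_linear_pred: float
    rg_consistent: bool
    info_gain: np.ndarray
    error_ok: bool
    fit_range: tuple[float, float]
    merge_point: float | None = None


def _interp_all(series: DilutionSeries) -> list[ScatteringCurve]:
    """Resample every curve onto the grid of the first one over the common overlap."""
    ref = series.curves[0]
    lo = max(c.s[0] for c in series.curves)
    hi = min(c.s[-1] for c in series.curves)
    if lo >= hi:
        raise ValidationError("curves do not share an overlapping s range")
    ref = ref.crop(lo, hi)
    out = []
    for c in series.curves:
        I = np.interp(ref.s, c.s, c.I)
        sig = np.interp(ref.s, c.s, c.sigma) if c.sigma is not None else None
        out.append(c.with_(s=ref.s, I=I, sigma=sig))
    return out


def find_fit_range(series: DilutionSeries, p_threshold: float = PAIR_P_THRESHOLD,
                   n_candidates: int = 12) -> DilutionSeries:
    """Find the widest high-angle window where all scaled profiles match.

    Candidate windows run from a scanned lower edge to the end of the common
    range.  In each window every curve is scaled onto the most concentrated
    one; the widest window where all pairwise reduced-χ² p-values pass is
    kept (ties towards higher s).  The returned scales are re-estimated over
    the upper half of the chosen window, where any residual concentration
    effect is smallest.  Curves failing the identity check in every window
    are named in the error.
    """
    aligned = _interp_all(series)
    conc = series.concentrations
    ref_idx = int(np.argmax(conc))
    s = aligned[0].s
    n = len(s)
    # lower edges from 30% to 85% of the common range (by index)
    edges = np.unique(np.linspace(int(0.30 * n), int(0.85 * n), n_candidates).astype(int))
    best = None
    worst_offenders: dict[int, int] = {}
    for e in edges:
        if n - e < 10:
            continue
        win = (s[e], s[-1])
        try:
            scales = []
            for c in aligned:
                r = _curves.compare(aligned[ref_idx], c, s_range=win)
                scales.append(r.scale_applied)
        except (ValidationError, _curves.GridMismatchError):
            continue
        ok = True
        bad: set[int] = set()
        for i in range(len(aligned)):
            for j in range(i + 1, len(aligned)):
                a = _curves.scale(aligned[i], scales[i]).crop(*win)
                b = _curves.scale(aligned[j], scales[j]).crop(*win)
                r = _curves.compare(a, b)
                if r.p_value < p_threshold:
                    ok = False
                    bad.update((i, j))
        if ok:
            best = (win, tuple(scales))
            break       # edges scan from widest to narrowest; first hit is widest
        for i in bad:
            worst_offenders[i] = worst_offenders.get(i, 0) + 1
    if best is None:
        if worst_offenders:
            top = max(worst_offenders.values())
            names = [series.curves[i].label or f"curve {i}"
                     for i, v in worst_offenders.items() if v == top]
            raise InconsistentSeriesError(
                "no window where all scaled profiles match; inconsistent: "
                + ", ".join(names)
            )
        raise InconsistentSeriesError("no usable high-angle window found")
    win, scales = best
    # final scales from the upper half of the window: the concentration
    # effect decays towards high angles, so this minimises its leakage
    tail = (0.5 * (win[0] + win[1]), win[1])
    try:
        scales = tuple(
            _curves.compare(aligned[ref_idx], c, s_range=tail).scale_applied
            for c in aligned
        )
    except (ValidationError, _curves.GridMismatchError):
        pass        # keep the full-window scales when the tail is too short
    return DilutionSeries(curves=series.curves, fit_range=win, scales=scales)


def extrapolate_zero(series: DilutionSeries) -> ExtrapolationReport:
    """Pointwise weighted linear regression of scaled I against c; the
    intercept is the infinite-dilution profile, the slope the
    concentration-effect term."""
    if series.fit_range is None or series.scales is None:
        series = find_fit_range(series)
    conc = series.concentrations
    if len(np.unique(conc)) < 2:
        raise ValidationError("regression needs at least 2 distinct concentrations")
    aligned = _interp_all(series)
    scaled = [_curves.scale(c, k) for c, k in zip(aligned, series.scales)]
    s = scaled[0].s
    Y = np.array([c.I for c in scaled])                       # (m, n)
    have_sigma = all(c.sigma is not None for c in scaled)
    W = (np.array([1.0 / c.sigma**2 for c in scaled])
         if have_sigma else np.ones_like(Y))

    c_col = conc[:, None]
    Sw = W.sum(axis=0)
    Sx = (W * c_col).sum(axis=0)
    Sxx = (W * c_col**2).sum(axis=0)
    Sy = (W * Y).sum(axis=0)
    Sxy = (W * c_col * Y).sum(axis=0)
    det = Sw * Sxx - Sx**2
    if np.any(det <= 0):
        raise ValidationError("degenerate regression (identical concentrations?)")
    slope = (Sw * Sxy - Sx * Sy) / det
    intercept = (Sxx * Sy - Sx * Sxy) / det
    var_intercept = Sxx / det
    var_slope = Sw / det
    if not have_sigma and len(scaled) > 2:
        # scale parameter variances by the residual variance
        resid = Y - (intercept + slope * c_col)
        s2 = (resid**2).sum(axis=0) / (len(scaled) - 2)
        var_intercept = var_intercept * s2
        var_slope = var_slope * s2

    sig_i = np.sqrt(var_intercept)
    i_zero = ScatteringCurve(
        s=s, I=intercept,
        sigma=sig_i if (have_sigma or len(scaled) > 2) and np.all(sig_i > 0) else None,
        concentration=0.0, label="extrapolated c=0",
    )
    b_curve = ScatteringCurve(s=s, I=slope, label="concentration-effect slope B(s)")
    b_curve = b_curve.with_(sigma=np.sqrt(var_slope) if np.all(var_slope > 0) else None)

    # Rg diagnostic: autorg on the extrapolated curve vs straight-line
    # extrapolation of the per-curve Rg^2 values to c = 0
    rg_extrap = _curves.autorg(i_zero).rg
    rg2 = np.array([_curves.autorg(c).rg ** 2 for c in scaled])
    A = np.vstack([np.ones_like(conc), conc]).T
    coef, *_ = np.linalg.lstsq(A, rg2, rcond=None)
    rg_pred = float(np.sqrt(max(coef[0], 0.0)))
    rg_consistent = abs(rg_extrap - rg_pred) <= RG_CONSISTENCY_TOL * max(rg_pred, 1e-300)

    # pointwise error inflation check
    error_ok = True
    if have_sigma:
        ref_sig = np.min(np.array([c.sigma for c in scaled]), axis=0)
        error_ok = bool(np.all(np.isfinite(sig_i))
                        and np.all(sig_i <= ERROR_INFLATION_KAPPA * ref_sig))

    # information gain: extrapolated point differs from every input beyond
    # the numerical error of the extrapolation
    min_diff = np.min(np.abs(Y - intercept), axis=0)
    tol = INFO_GAIN_NSIGMA * np.where(sig_i > 0, sig_i, 1e-300)
    info_gain = min_diff > np.maximum(tol, 1e-9 * np.abs(intercept))

    return ExtrapolationReport(
        i_zero_curve=i_zero, b_curve=b_curve,
        rg_extrapolated=float(rg_extrap), rg_linear_pred=rg_pred,
        rg_consistent=bool(rg_consistent), info_gain=info_gain,
        error_ok=error_ok, fit_range=series.fit_range,
    )


def merge_extrapolated(report: ExtrapolationReport,
                       series: DilutionSeries) -> tuple[ScatteringCurve, float]:
    """Merge the extrapolated curve with the average of the scaled inputs.

    The merge point is the s inside the fit range minimising the jump
    |I_extrapolated − I_averaged|/σ; the merged curve takes the extrapolated
    values below it and the pointwise average above.  Returns (curve, merge
    point).
    """
    if series.scales is None:
        series = find_fit_range(series)
    aligned = _interp_all(series)
    scaled = [_curves.scale(c, k) for c, k in zip(aligned, series.scales)]
    avg = _curves.average(scaled)
    izero = report.i_zero_curve
    s = izero.s
    lo, hi = report.fit_range
    inwin = (s >= lo) & (s <= hi)
    if not np.any(inwin):
        raise ValidationError("fit range contains no grid points")
    sig = izero.sigma if izero.sigma is not None else np.maximum(np.abs(izero.I), 1e-300) * 0.01
    jump = np.abs(izero.I - avg.I) / np.where(sig > 0, sig, 1e-300)
    idx = np.flatnonzero(inwin)
    m = idx[int(np.argmin(jump[idx]))]
    s_merge = float(s[m])

    take_low = s <= s_merge
    I = np.where(take_low, izero.I, avg.I)
    sigma = None
    if izero.sigma is not None and avg.sigma is not None:
        sigma = np.where(take_low, izero.sigma, avg.sigma)
    merged = ScatteringCurve(s=s, I=I, sigma=sigma, concentration=0.0,
                             label="merged infinite-dilution curve")
    return merged, s_merge


def automerge(curve_list, concentrations=None) -> tuple[ScatteringCurve, ExtrapolationReport]:
    """One-call pipeline: fit range → extrapolation → merge."""
    cs = list(curve_list)
    if concentrations is not None:
        cs = [c.with_(concentration=float(x)) for c, x in zip(cs, concentrations)]
    series = find_fit_range(DilutionSeries(curves=tuple(cs)))
    report = extrapolate_zero(series)
    merged, s_merge = merge_extrapolated(report, series)
    report = ExtrapolationReport(
        **{**report.__dict__, "merge_point": s_merge}
    )
    return merged, report
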