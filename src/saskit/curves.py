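"""Curve arithmetic, statistical comparison, averaging/merging and automatic
Guinier analysis.

The Guinier law I(s) ≈ I(0)·exp(−s²Rg²/3) holds at low angles for globular
particles; :func:`autorg` finds the closest-to-the-origin interval showing
valid Guinier behaviour and reports Rg, I(0) and the first good point used
by the downstream Porod analysis.  :func:`compare` implements the weighted
χ² similarity test between two profiles, :func:`merge` splices a low-angle
and a high-angle measurement, and scale/subtract/average propagate errors in
quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .sasio import SasError, ScatteringCurve, ValidationError

__all__ = [
    "GuinierResult",
    "NoGuinierRegionError",
    "GridMismatchError",
    "autorg",
    "scale",
    "subtract",
    "multiply",
    "average",
    "compare",
    "merge",
]


class NoGuinierRegionError(SasError):
    """No contiguous low-angle window shows valid Guinier behaviour.

    Typical causes: aggregation (intensity rising towards s = 0) or a badly
    subtracted buffer.
    """


class GridMismatchError(SasError):
    """Curves live on incompatible momentum-transfer grids."""


# quality weights for window selection: window length, closeness to the
# origin, and goodness of the linear fit.  The selection contract is
# "closest-to-origin valid interval"; the exact scoring is a package choice.
QUALITY_WEIGHTS = (0.4, 0.3, 0.3)
PVALUE_THRESHOLD = 1e-6


@dataclass(frozen=True)
class GuinierResult:
    """Result of an automatic Guinier fit."""

    rg: float
    i0: float
    first_point: int
    last_point: int
    rg_err: float
    i0_err: float
    quality: float
    srg_max: float

    def __post_init__(self):
        if self.rg <= 0:
            raise ValidationError("Rg must be positive")
        if self.first_point >= self.last_point:
            raise ValidationError("invalid Guinier interval")


def _wls_line(x, y, w):
    """Weighted least-squares line fit; returns slope, intercept, their
    variances, the weighted residual sum of squares and R²."""
    Sw = w.sum()
    xm = (w * x).sum() / Sw
    ym = (w * y).sum() / Sw
    dx = x - xm
    Sxx = (w * dx * dx).sum()
    slope = (w * dx * (y - ym)).sum() / Sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    chi2 = (w * resid * resid).sum()
    var_slope = 1.0 / Sxx
    var_intercept = 1.0 / Sw + xm * xm / Sxx
    # R^2 on the weighted model
    tss = (w * (y - ym) ** 2).sum()
    r2 = 1.0 - chi2 / tss if tss > 0 else 1.0
    return slope, intercept, var_slope, var_intercept, chi2, r2


def autorg(curve: ScatteringCurve, srg_limit: float = 1.3,
           min_window: int = 5) -> GuinierResult:
    """Automatically locate the Guinier region and fit Rg and I(0).

    Scans every contiguous window of at least ``min_window`` points in the
    low-angle region, fits ln I against s² by (weighted) least squares, and
    keeps windows with a negative slope, s·Rg ≤ ``srg_limit`` at the window
    end and (when σ is available) an acceptable fit p-value.  Among the
    admissible windows the one maximising a quality score rewarding long
    windows, early starts and high R² wins; its start index is the "first
    good point" used by the Porod analysis.

    Raises :class:`NoGuinierRegionError` when no window qualifies.
    """
    s, I = curve.s, curve.I
    # Guinier analysis needs positive intensities; keep the leading positive run
    pos = I > 0
    n_pos = int(np.argmin(pos)) if not pos.all() else len(I)
    if n_pos < min_window:
        raise NoGuinierRegionError("fewer than min_window positive low-angle points")
    s = s[:n_pos]
    I = I[:n_pos]
    sig = curve.sigma[:n_pos] if curve.sigma is not None else None

    x = s**2
    y = np.log(I)
    if sig is not None:
        w_all = (I / sig) ** 2          # var(ln I) = (sigma/I)^2
    else:
        w_all = np.ones_like(y)

    # initial Rg guess from expanding prefixes, to bound the search region
    rg_guess = None
    for j in range(min_window, n_pos + 1):
        sl, *_ = _wls_line(x[:j], y[:j], w_all[:j])
        if sl < 0:
            rg = np.sqrt(-3.0 * sl)
            if s[j - 1] * rg > srg_limit:
                break
            rg_guess = rg
    if rg_guess is None:
        # no decaying prefix at all; fall back to a generous cap
        rg_guess = srg_limit / max(s[min(min_window, n_pos) - 1], 1e-12)

    s_cap = 2.0 * srg_limit / rg_guess
    n_low = int(np.searchsorted(s, s_cap, side="right"))
    n_low = min(max(n_low, min_window), n_pos, 1000)

    x = x[:n_low]; y = y[:n_low]; w = w_all[:n_low]
    # prefix sums make every window fit O(1)
    z = np.zeros(1)
    cw = np.concatenate([z, np.cumsum(w)])
    cwx = np.concatenate([z, np.cumsum(w * x)])
    cwy = np.concatenate([z, np.cumsum(w * y)])
    cwxx = np.concatenate([z, np.cumsum(w * x * x)])
    cwxy = np.concatenate([z, np.cumsum(w * x * y)])
    cwyy = np.concatenate([z, np.cumsum(w * y * y)])
    w1, w2, w3 = QUALITY_WEIGHTS
    best = None
    for i in range(0, n_low - min_window + 1):
        j = np.arange(i + min_window - 1, n_low)
        Sw = cw[j + 1] - cw[i]
        Sx = cwx[j + 1] - cwx[i]
        Sy = cwy[j + 1] - cwy[i]
        Sxx = cwxx[j + 1] - cwxx[i]
        Sxy = cwxy[j + 1] - cwxy[i]
        Syy = cwyy[j + 1] - cwyy[i]
        det = Sw * Sxx - Sx * Sx
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = (Sw * Sxy - Sx * Sy) / det
            intercept = (Sy - slope * Sx) / Sw
            chi2 = np.maximum(Syy - intercept * Sy - slope * Sxy, 0.0)
            tss = Syy - Sy * Sy / Sw
            r2 = np.where(tss > 0, 1.0 - chi2 / np.maximum(tss, 1e-300), 1.0)
        rg = np.sqrt(np.maximum(-3.0 * slope, 0.0))
        ok = (slope < 0) & (det > 0) & (s[j] * rg <= srg_limit)
        npts = j - i + 1
        if sig is not None:
            pval = stats.chi2.sf(chi2, np.maximum(npts - 2, 1))
            ok &= (npts <= 2) | (pval >= PVALUE_THRESHOLD)
        if not np.any(ok):
            continue
        quality = np.where(
            ok,
            w1 * npts / n_low + w2 * (1.0 - i / n_low) + w3 * np.clip(r2, 0.0, 1.0),
            -np.inf,
        )
        k = int(np.argmax(quality))
        if best is None or quality[k] > best[0]:
            jj = int(j[k])
            best = (float(quality[k]), i, jj, float(slope[k]), float(intercept[k]),
                    float(Sw[k] / det[k]), float(Sxx[k] / det[k]), float(rg[k]))
    if best is None:
        raise NoGuinierRegionError(
            "no admissible Guinier window found (aggregation or bad subtraction?)"
        )
    quality, i, j, sl, ic, vs, vi, rg = best
    i0 = float(np.exp(ic))
    rg_err = float(3.0 * np.sqrt(vs) / (2.0 * rg))
    return GuinierResult(
        rg=rg, i0=i0, first_point=int(i), last_point=int(j),
        rg_err=rg_err, i0_err=float(i0 * np.sqrt(vi)),
        quality=float(min(quality, 1.0)), srg_max=float(s[j] * rg),
    )


# ---------------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------------


def _common_grid(a: ScatteringCurve, b: ScatteringCurve,
                 interpolate: bool = False) -> tuple[ScatteringCurve, ScatteringCurve]:
    """Put b on a's grid.  Grids must agree pointwise to 1e-6 relative unless
    ``interpolate``; interpolation is linear in s and never extrapolates (the
    result is cropped to the overlap)."""
    if a.s.shape == b.s.shape and np.allclose(a.s, b.s, rtol=1e-6, atol=0.0):
        return a, b
    if not interpolate:
        raise GridMismatchError(
            "curves are on different grids; pass interpolate=True to resample"
        )
    lo, hi = max(a.s[0], b.s[0]), min(a.s[-1], b.s[-1])
    if lo > hi:
        raise GridMismatchError("curves do not overlap in s")
    ac = a.crop(lo, hi)
    I = np.interp(ac.s, b.s, b.I)
    sig = np.interp(ac.s, b.s, b.sigma) if b.sigma is not None else None
    return ac, b.with_(s=ac.s, I=I, sigma=sig)


def scale(curve: ScatteringCurve, factor: float) -> ScatteringCurve:
    """Multiply I (and σ) by a positive constant."""
    if factor <= 0:
        raise ValidationError("scale factor must be positive")
    return curve.with_(
        I=curve.I * factor,
        sigma=None if curve.sigma is None else curve.sigma * factor,
    )


def subtract(a: ScatteringCurve, b: ScatteringCurve,
             interpolate: bool = False) -> ScatteringCurve:
    """a − b with σ propagated in quadrature."""
    a, b = _common_grid(a, b, interpolate)
    sig = None
    if a.sigma is not None and b.sigma is not None:
        sig = np.sqrt(a.sigma**2 + b.sigma**2)
    elif a.sigma is not None:
        sig = a.sigma.copy()
    elif b.sigma is not None:
        sig = b.sigma.copy()
    return a.with_(I=a.I - b.I, sigma=sig, label=f"{a.label} - {b.label}")


def multiply(a: ScatteringCurve, b: ScatteringCurve,
             interpolate: bool = False) -> ScatteringCurve:
    """Pointwise product a·b (σ propagated to first order)."""
    a, b = _common_grid(a, b, interpolate)
    sig = None
    if a.sigma is not None and b.sigma is not None:
        sig = np.sqrt((a.sigma * b.I) ** 2 + (b.sigma * a.I) ** 2)
    return a.with_(I=a.I * b.I, sigma=sig, label=f"{a.label} * {b.label}")


def average(curves, weights=None, interpolate: bool = False) -> ScatteringCurve:
    """Average curves: inverse-variance weighted when every curve has σ
    (and no explicit weights are given), else (weighted) arithmetic."""
    curves = list(curves)
    if not curves:
        raise ValidationError("no curves to average")
    ref = curves[0]
    aligned = [ref] + [_common_grid(ref, c, interpolate)[1] for c in curves[1:]]
    Is = np.array([c.I for c in aligned])
    have_sigma = all(c.sigma is not None for c in aligned)
    if weights is None and have_sigma:
        W = np.array([1.0 / c.sigma**2 for c in aligned])
        Wsum = W.sum(axis=0)
        I = (W * Is).sum(axis=0) / Wsum
        sig = 1.0 / np.sqrt(Wsum)
    else:
        w = np.ones(len(aligned)) if weights is None else np.asarray(weights, float)
        if w.shape != (len(aligned),):
            raise ValidationError("one weight per curve required")
        wn = w / w.sum()
        I = np.tensordot(wn, Is, axes=1)
        sig = None
        if have_sigma:
            sig = np.sqrt(np.tensordot(wn**2, np.array([c.sigma**2 for c in aligned]), axes=1))
    return ref.with_(I=I, sigma=sig, label=f"average of {len(aligned)}")


# ---------------------------------------------------------------------------
# comparison and merging
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompareResult:
    chi2_reduced: float
    p_value: float
    scale_applied: float
    n_points: int

    @property
    def similar(self) -> bool:
        """Curves declared similar when the χ² p-value is ≥ 0.01."""
        return self.p_value >= 0.01


def compare(a: ScatteringCurve, b: ScatteringCurve,
            s_range: tuple[float, float] | None = None,
            interpolate: bool = True) -> CompareResult:
    """Optimal scale between two curves and the reduced χ² of their identity.

    Finds c minimising Σ (I_a − c·I_b)²/(σ_a² + c²σ_b²) (iteratively
    reweighted linear solution), then reports the reduced χ² with N−1
    degrees of freedom and its survival p-value.
    """
    if s_range is not None:
        a = a.crop(*s_range)
        b = b.crop(*s_range)
    try:
        a, b = _common_grid(a, b, interpolate=interpolate)
    except GridMismatchError as exc:
        raise GridMismatchError(f"compare: {exc}") from exc
    n = len(a)
    if n < 10:
        raise ValidationError("compare needs at least 10 common points")
    va = a.sigma**2 if a.sigma is not None else np.ones(n)
    vb = b.sigma**2 if b.sigma is not None else np.zeros(n)
    c = float((a.I @ b.I) / max(b.I @ b.I, 1e-300))
    for _ in range(20):
        w = 1.0 / (va + c * c * vb)
        c_new = float((w * a.I * b.I).sum() / max((w * b.I * b.I).sum(), 1e-300))
        if abs(c_new - c) <= 1e-12 * max(abs(c), 1e-300):
            c = c_new
            break
        c = c_new
    # polish: the IRLS fixed point neglects the c-dependence of the weights;
    # a scalar minimisation restores exact a↔b symmetry of the optimum
    from scipy.optimize import minimize_scalar

    def objective(cc):
        return float(((a.I - cc * b.I) ** 2 / (va + cc * cc * vb)).sum())

    if c > 0:
        res = minimize_scalar(objective, bounds=(0.1 * c, 10.0 * c),
                              method="bounded",
                              options={"xatol": 1e-12 * c})
        if np.isfinite(res.fun) and res.fun <= objective(c):
            c = float(res.x)
    w = 1.0 / (va + c * c * vb)
    chi2_total = float((w * (a.I - c * b.I) ** 2).sum())
    dof = n - 1
    return CompareResult(
        chi2_reduced=chi2_total / dof,
        p_value=float(stats.chi2.sf(chi2_total, dof)),
        scale_applied=c,
        n_points=n,
    )


def merge(low: ScatteringCurve, high: ScatteringCurve,
          window: tuple[float, float] | None = None) -> ScatteringCurve:
    """Splice a low-angle and a high-angle curve.

    ``high`` is scaled onto ``low`` using the optimal scale found in the
    overlap ``window`` (default: the full overlap); the merged curve takes
    ``low``'s points below the window midpoint and the scaled ``high`` above
    it.  Where both curves sample the same s inside the window the values
    are blended with inverse-variance weights.
    """
    lo_s = max(low.s[0], high.s[0])
    hi_s = min(low.s[-1], high.s[-1])
    if lo_s > hi_s:
        raise GridMismatchError("merge: curves have disjoint s ranges")
    if window is None:
        window = (lo_s, hi_s)
    w_lo, w_hi = max(window[0], lo_s), min(window[1], hi_s)
    if w_lo > w_hi:
        raise GridMismatchError("merge: window outside the overlap")
    res = compare(low, high, s_range=(w_lo, w_hi), interpolate=True)
    high_sc = scale(high, res.scale_applied)
    mid = 0.5 * (w_lo + w_hi)

    take_low = low.s <= mid
    take_high = high_sc.s > mid
    s_parts = [low.s[take_low], high_sc.s[take_high]]
    I_parts = [low.I[take_low], high_sc.I[take_high]]
    have_sigma = low.sigma is not None and high.sigma is not None
    sig_parts = None
    if have_sigma:
        sig_parts = [low.sigma[take_low], high_sc.sigma[take_high]]

    # blend duplicated grid points inside the window
    s_all = np.concatenate(s_parts)
    I_all = np.concatenate(I_parts)
    order = np.argsort(s_all, kind="stable")
    s_all, I_all = s_all[order], I_all[order]
    sig_all = np.concatenate(sig_parts)[order] if have_sigma else None
    keep = np.ones(len(s_all), bool)
    for k in range(len(s_all) - 1):
        if not keep[k]:
            continue
        if s_all[k + 1] - s_all[k] <= 1e-6 * max(s_all[k + 1], 1e-300):
            if sig_all is not None:
                wa, wb = 1.0 / sig_all[k] ** 2, 1.0 / sig_all[k + 1] ** 2
                I_all[k] = (wa * I_all[k] + wb * I_all[k + 1]) / (wa + wb)
                sig_all[k] = 1.0 / np.sqrt(wa + wb)
            else:
                I_all[k] = 0.5 * (I_all[k] + I_all[k + 1])
            keep[k + 1] = False
    return ScatteringCurve(
        s=s_all[keep], I=I_all[keep],
        sigma=sig_all[keep] if sig_all is not None else None,
        label=f"merge({low.label}, {high.label})",
    )
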