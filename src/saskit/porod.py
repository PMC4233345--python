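"""Porod invariant, excluded volume and molecular-mass estimation.

For a homogeneous particle the high-angle intensity decays as Porod's law
I(s) → A + K/s⁴, where A is a residual constant from internal structure or
imperfect buffer subtraction.  Subtracting A yields the "shape scattering"
curve, whose invariant

    Q = ∫₀^∞ s²·[I(s) − A] ds

relates to the excluded (hydrated) particle volume V_P = 2π²·I(0)/Q — no
absolute intensity calibration needed.  For proteins the empirical ratio
MM/V_P ≈ 0.625 kDa per nm³ converts the Porod volume into a molecular mass.

The integral is assembled from three pieces: the Guinier model continuation
on [0, s_min], trapezoidal integration over the measured range, and the
analytic Porod tail K/s_max beyond the cutoff.  The default cutoff
s_max = 8/Rg approximately matches the second minimum of the Porod plot
s⁴I(s); a second-minimum detector is available as a fallback.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import curves as _curves
from .sasio import SasError, ScatteringCurve, ValidationError

__all__ = [
    "PorodResult",
    "PorodFitError",
    "estimate_background",
    "porod_volume",
    "autoporod",
    "MM_PER_NM3",
]

# empirical molecular mass per Porod volume for proteins, kDa per nm^3
MM_PER_NM3 = 0.625
DEFAULT_SMAX_RG = 8.0


class PorodFitError(SasError):
    """The curve shows no s⁻⁴ regime or the invariant is not positive."""


@dataclass(frozen=True)
class PorodResult:
    a_const: float
    q_invariant: float
    v_porod: float
    mm_kda: float
    s_min: float
    s_max: float
    tail_k: float
    guinier: "_curves.GuinierResult | None" = None
    a_clamped: bool = False

    def __post_init__(self):
        if self.q_invariant <= 0 or self.v_porod <= 0:
            raise PorodFitError("Porod invariant and volume must be positive")
        if self.s_min >= self.s_max:
            raise ValidationError("s_min must be below s_max")


def _to_inverse_angstrom(curve: ScatteringCurve) -> ScatteringCurve:
    """Porod/MM formulas need s in Å⁻¹; convert nm⁻¹ input by s/10."""
    if curve.unit == "nm":
        return curve.with_(s=curve.s / 10.0, unit="A")
    return curve


def estimate_background(curve: ScatteringCurve, rg: float,
                        tail_fraction: float = 0.5) -> tuple[float, float, bool]:
    """Fit I = A + K·s⁻⁴ over the highest-angle tail of the curve.

    The fit is a linear regression of I against s⁻⁴ over the last
    ``tail_fraction`` of the points, carried out in Porod-plot coordinates
    (s⁴·I against s⁴): form-factor oscillations around the Porod asymptote
    then average out over the tail instead of biasing the constant, and for
    data with relative errors the noise of s⁴·I is roughly uniform across
    the tail, so the equal-weight fit is close to inverse-variance optimal
    (an explicit 1/σ² weighting would let near-zero form-factor minima
    dominate and bias the constant).  The default tail covers half the
    working range so several oscillation periods contribute.  A is clamped
    (and the clamp reported) so that I − A stays positive over the fitted
    tail.  Returns (A, K, clamped).

    Raises :class:`PorodFitError` when the fitted K is negative (no s⁻⁴
    regime in the data).
    """
    if rg <= 0:
        raise ValidationError("rg must be positive")
    n = len(curve)
    ntail = max(int(np.ceil(tail_fraction * n)), 5)
    if ntail > n:
        raise ValidationError("curve too short for a Porod tail fit")
    s = curve.s[-ntail:]
    if s[0] * rg < 1.0:
        raise ValidationError("curve does not extend beyond the Guinier region")
    I = curve.I[-ntail:]
    # regress y = s^4 I on x = s^4: slope A, intercept K
    x = s**4.0
    y = x * I
    w = np.ones_like(x)
    Sw, Sx, Sy = w.sum(), (w * x).sum(), (w * y).sum()
    Sxx, Sxy = (w * x * x).sum(), (w * x * y).sum()
    det = Sw * Sxx - Sx * Sx
    A = (Sw * Sxy - Sx * Sy) / det
    K = (Sy - A * Sx) / Sw
    if K <= 0:
        raise PorodFitError("no s^-4 regime found (negative Porod amplitude)")
    clamped = False
    i_min = float(np.min(I))
    if A >= i_min:
        # keep the subtracted tail positive
        A = i_min - 0.05 * abs(i_min) - 1e-300
        clamped = True
    return float(A), float(K), clamped


def _second_minimum_cutoff(curve: ScatteringCurve, rg: float) -> float | None:
    """Locate the second local minimum of the Porod plot s⁴·I(s)."""
    s, I = curve.s, curve.I
    y = s**4 * I
    mins = []
    for k in range(1, len(y) - 1):
        if y[k] < y[k - 1] and y[k] <= y[k + 1] and s[k] * rg > 2.0:
            mins.append(k)
    if len(mins) >= 2:
        return float(s[mins[1]])
    return None


def porod_volume(curve: ScatteringCurve, guinier: "_curves.GuinierResult",
                 s_max: float | None = None, smax_rg: float = DEFAULT_SMAX_RG,
                 tail_fraction: float = 0.5) -> PorodResult:
    """Compute the Porod invariant, excluded volume and molecular mass.

    The working range starts at the Guinier fit's first good point and ends
    at min(``smax_rg``/Rg, end of data) unless ``s_max`` is given.  A and K
    come from :func:`estimate_background` on that range; the invariant sums
    the Guinier continuation below the first good point, the trapezoidal
    integral of s²(I − A) over the data, and the analytic tail K/s_max.
    """
    if guinier is None:
        raise ValidationError("a valid Guinier result is required")
    curve = _to_inverse_angstrom(curve)
    rg, i0 = guinier.rg, guinier.i0
    s_lo = curve.s[guinier.first_point]
    if s_max is None:
        s_max = min(smax_rg / rg, float(curve.s[-1]))
    if s_max <= s_lo:
        raise ValidationError("integration range is empty")
    work = curve.crop(s_lo, s_max)
    a_const, tail_k, clamped = estimate_background(work, rg, tail_fraction)

    s, I = work.s, work.I - a_const
    # Guinier continuation on [0, s_lo]
    sg = np.linspace(0.0, s_lo, 200)
    qg = np.trapezoid(sg**2 * i0 * np.exp(-(sg**2) * rg**2 / 3.0), sg)
    qd = np.trapezoid(s**2 * I, s)
    qt = tail_k / s[-1]
    q = float(qg + qd + qt)
    if q <= 0:
        raise PorodFitError("non-positive invariant after constant subtraction")
    v_porod = float(2.0 * np.pi**2 * i0 / q)
    mm = MM_PER_NM3 * v_porod / 1000.0
    return PorodResult(
        a_const=a_const, q_invariant=q, v_porod=v_porod, mm_kda=mm,
        s_min=float(s_lo), s_max=float(s[-1]), tail_k=tail_k,
        guinier=guinier, a_clamped=clamped,
    )


def autoporod(curve: ScatteringCurve, smax_rg: float = DEFAULT_SMAX_RG,
              smooth: bool = False, smooth_window: int = 11) -> PorodResult:
    """Unattended pipeline: Guinier fit → optional smoothing → Porod volume.

    Designed for automated processing chains; sub-step failures propagate
    with a stage label.
    """
    curve = _to_inverse_angstrom(curve)    # before autorg: Rg and 8/Rg in Å
    try:
        g = _curves.autorg(curve)
    except _curves.NoGuinierRegionError as exc:
        raise _curves.NoGuinierRegionError(f"autoporod/guinier stage: {exc}") from exc
    work = curve
    if smooth:
        from scipy.signal import savgol_filter

        win = min(smooth_window | 1, len(curve) // 2 * 2 - 1)
        if win >= 5:
            work = curve.with_(I=savgol_filter(curve.I, win, 3))
    try:
        return porod_volume(work, g, smax_rg=smax_rg)
    except (PorodFitError, ValidationError) as exc:
        raise PorodFitError(f"autoporod/porod stage: {exc}") from exc
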