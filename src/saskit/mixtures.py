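"""Mixture decomposition into component volume fractions.

For a polydisperse system without interparticle interactions the measured
profile is the volume-fraction-weighted sum of the component intensities,
I(s) = Σ_k v_k·I_k(s).  Given the component "form factors" (theoretical
curves from models, experimental curves of pure species, or regularized
profiles), the fractions are recovered by non-negative linear least squares
weighted by the experimental errors.  A two-state convenience wrapper
decomposes a curve into a full assembly and one of its sub-complexes — the
mixture core of equilibrium multimer/monomer and transient-complex
modelling, reliable for minor fractions roughly within 0.2–0.8 (monomer vs
multimer) or 0.15–0.90 (dissociated species).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import nnls

from . import formfit as _formfit
from .sasio import BeadModel, SasError, ScatteringCurve, ValidationError

__all__ = [
    "FormFactorSet",
    "MixtureFit",
    "FeasibilityWarning",
    "build_formfactors",
    "read_formfactors",
    "write_formfactors",
    "fit_fractions",
    "two_state_decompose",
    "MONOMER_FEASIBLE_RANGE",
    "DISSOCIATED_FEASIBLE_RANGE",
]

MONOMER_FEASIBLE_RANGE = (0.2, 0.8)
DISSOCIATED_FEASIBLE_RANGE = (0.15, 0.90)


class FeasibilityWarning(UserWarning):
    """An estimated fraction lies outside the reliable window."""


@dataclass(frozen=True)
class FormFactorSet:
    """K component intensities on one common grid."""

    s: np.ndarray
    components: np.ndarray            # (K, n)
    labels: tuple[str, ...]
    provenance: tuple[str, ...] = ()

    def __post_init__(self):
        s = np.asarray(self.s, float)
        comp = np.atleast_2d(np.asarray(self.components, float))
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "components", comp)
        if comp.shape[1] != s.size:
            raise ValidationError("components must share the grid length")
        if np.any(np.diff(s) <= 0):
            raise ValidationError("grid must be strictly increasing")
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(f"component {k + 1}" for k in range(comp.shape[0]))
            )

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def interpolated(self, s_new: np.ndarray) -> "FormFactorSet":
        s_new = np.asarray(s_new, float)
        if s_new[0] < self.s[0] - 1e-9 or s_new[-1] > self.s[-1] + 1e-9:
            raise ValidationError("requested grid extends beyond the form factors")
        comp = np.vstack([np.interp(s_new, self.s, c) for c in self.components])
        return replace(self, s=s_new, components=comp)


@dataclass(frozen=True)
class MixtureFit:
    """Volume fractions (non-negative, summing to 1) and overall scale."""

    fractions: np.ndarray
    overall_scale: float
    chi2_reduced: float
    fixed_mask: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self):
        f = np.asarray(self.fractions, float)
        object.__setattr__(self, "fractions", f)
        object.__setattr__(self, "fixed_mask", np.asarray(self.fixed_mask, bool))
        if np.any(f < -1e-12):
            raise ValidationError("fractions must be non-negative")
        if f.sum() > 0 and abs(f.sum() - 1.0) > 1e-9:
            raise ValidationError("fractions must sum to 1")


def build_formfactors(sources, s_grid=None,
                      form_factor_kind: str = "point") -> FormFactorSet:
    """Assemble a form-factor set from curves, models and multi-model lists.

    Each source is a :class:`ScatteringCurve` (used as-is), a
    :class:`BeadModel` (routed through the Debye sum) or a list of models
    (e.g. an NMR ensemble file: one component per model).  Curves are
    interpolated linearly onto the common grid — the intersection of all
    source ranges, or the given ``s_grid``.
    """
    sources = list(sources)
    if not sources:
        raise ValidationError("at least one source required")
    flat: list[tuple[str, object]] = []
    for src in sources:
        if isinstance(src, BeadModel):
            flat.append(("theoretical", src))
        elif isinstance(src, ScatteringCurve):
            flat.append(("experimental", src))
        elif isinstance(src, (list, tuple)) and all(isinstance(m, BeadModel) for m in src):
            flat.extend(("theoretical", m) for m in src)
        else:
            raise ValidationError(f"unsupported form-factor source: {type(src)!r}")

    if s_grid is None:
        curves = [obj for kind, obj in flat if kind == "experimental"]
        if curves:
            lo = max(c.s[0] for c in curves)
            hi = min(c.s[-1] for c in curves)
            if lo >= hi:
                raise ValidationError("form-factor source ranges do not intersect")
            ref = max(curves, key=len)
            s_grid = ref.s[(ref.s >= lo) & (ref.s <= hi)]
        else:
            s_grid = np.linspace(0.0, 0.5, 256)
    s_grid = np.asarray(s_grid, float)

    comps, labels, prov = [], [], []
    for kind, obj in flat:
        if kind == "theoretical":
            tc = _formfit.debye_intensity(obj, s_grid, form_factor_kind=form_factor_kind)
            comps.append(tc.I)
            labels.append(obj.label or f"model {len(labels) + 1}")
        else:
            if s_grid[0] < obj.s[0] - 1e-9 or s_grid[-1] > obj.s[-1] + 1e-9:
                raise ValidationError(
                    f"curve {obj.label!r} does not cover the common grid"
                )
            comps.append(np.interp(s_grid, obj.s, obj.I))
            labels.append(obj.label or f"curve {len(labels) + 1}")
        prov.append(kind)
    return FormFactorSet(s=s_grid, components=np.vstack(comps),
                         labels=tuple(labels), provenance=tuple(prov))


def write_formfactors(ff: FormFactorSet, path) -> None:
    """Write a form-factor file: column 1 = s, columns 2..K+1 = intensities."""
    with open(path, "w") as fh:
        fh.write("# form factors: " + ", ".join(ff.labels) + "\n")
        for i in range(ff.s.size):
            row = " ".join(f"{v:.8e}" for v in ff.components[:, i])
            fh.write(f"{ff.s[i]:.8e} {row}\n")


def read_formfactors(path) -> FormFactorSet:
    """Read a multi-column form-factor file ('#' lines are comments)."""
    labels: tuple[str, ...] = ()
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.lstrip().startswith("#"):
                if "form factors:" in line:
                    labels = tuple(x.strip() for x in line.split(":", 1)[1].split(","))
                continue
            vals = line.split()
            if len(vals) >= 2:
                rows.append([float(v) for v in vals])
    if not rows:
        raise ValidationError(f"{path}: no numeric rows")
    arr = np.asarray(rows)
    return FormFactorSet(s=arr[:, 0], components=arr[:, 1:].T, labels=labels)


def fit_fractions(ff: FormFactorSet, exp: ScatteringCurve,
                  fixed: dict[int, float] | None = None) -> MixtureFit:
    """Recover volume fractions by error-weighted non-negative least squares.

    Solves min_{w ≥ 0} Σ_s [(I_exp − Σ_k w_k I_k)/σ]² and reports normalised
    fractions v_k = w_k/Σw plus the overall scale Σw.  Components listed in
    ``fixed`` (index → fraction) are constrained to the given fractions: the
    fixed block enters as a single combined column tied to the free weights,
    which keeps the problem linear.
    """
    K = ff.n_components
    n = len(exp)
    if K > n:
        raise ValidationError("more components than data points")
    ffi = ff.interpolated(exp.s)
    sig = exp.sigma if exp.sigma is not None else np.ones(n)
    A = (ffi.components / sig).T          # (n, K)
    y = exp.I / sig

    fixed = dict(fixed or {})
    fixed_mask = np.zeros(K, bool)
    w_full = np.zeros(K)
    if fixed:
        if any(k < 0 or k >= K for k in fixed):
            raise ValidationError("fixed component index out of range")
        vf = np.array(list(fixed.values()))
        if np.any(vf < 0) or vf.sum() > 1 + 1e-9:
            raise ValidationError("fixed fractions must be in [0, 1] and sum to <= 1")
        fixed_mask[list(fixed)] = True
        F = 1.0 - vf.sum()
        Cfix = sum(v * A[:, k] for k, v in fixed.items())
        if F <= 0:
            # everything fixed: only the overall scale is free
            At = Cfix[:, None]
            w, _ = nnls(At, y)
            T = float(w[0])
            for k, v in fixed.items():
                w_full[k] = v * T
        else:
            free = np.flatnonzero(~fixed_mask)
            # substituting T = Σ w_free / F ties the fixed block to the free weights
            At = A[:, free] + (Cfix / F)[:, None]
            w, _ = nnls(At, y)
            w_full[free] = w
            T = float(w.sum() / F)
            for k, v in fixed.items():
                w_full[k] = v * T
    else:
        w_full, _ = nnls(A, y)

    total = float(w_full.sum())
    if total <= 0:
        warnings.warn("degenerate mixture fit: all weights zero", FeasibilityWarning)
        fractions = np.zeros(K)
    else:
        fractions = w_full / total
    resid = y - A @ w_full
    chi2 = float(resid @ resid) / max(n - 1, 1)
    return MixtureFit(fractions=fractions, overall_scale=total,
                      chi2_reduced=chi2, fixed_mask=fixed_mask, labels=ffi.labels)


def two_state_decompose(assembly: BeadModel, sub_selection,
                        exp: ScatteringCurve,
                        form_factor_kind: str = "point",
                        feasible_range: tuple[float, float] = DISSOCIATED_FEASIBLE_RANGE,
                        ) -> MixtureFit:
    """Decompose a curve into a full assembly and one of its sub-complexes.

    ``sub_selection`` is either a set of chain ids or a boolean/index array
    over the assembly's beads.  Debye curves of the full assembly and the
    subcomplex form a 2-component set; a :class:`FeasibilityWarning` is
    issued when the estimated dissociated (subcomplex) fraction falls
    outside ``feasible_range``.
    """
    if isinstance(sub_selection, (set, frozenset, list, tuple)) and all(
        isinstance(x, str) for x in sub_selection
    ):
        if assembly.chain_id is None:
            raise ValidationError("assembly has no chain labels")
        mask = np.array([c in set(sub_selection) for c in assembly.chain_id])
    else:
        sel = np.asarray(sub_selection)
        if sel.dtype == bool:
            mask = sel
        else:
            mask = np.zeros(len(assembly), bool)
            mask[sel] = True
    if not np.any(mask):
        raise ValidationError("empty subcomplex selection")
    if np.all(mask):
        raise ValidationError("subcomplex must be a proper subset of the assembly")
    sub = BeadModel(coords=assembly.coords[mask], weight=assembly.weight[mask],
                    radius=assembly.radius, label="subcomplex")
    ff = build_formfactors([assembly, sub], s_grid=exp.s,
                           form_factor_kind=form_factor_kind)
    fit = fit_fractions(ff, exp)
    v_sub = float(fit.fractions[1])
    if not (feasible_range[0] <= v_sub <= feasible_range[1]):
        warnings.warn(
            f"dissociated fraction {v_sub:.3f} outside the reliable window "
            f"[{feasible_range[0]}, {feasible_range[1]}]",
            FeasibilityWarning,
        )
    return fit
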