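"""Ensemble selection for flexible systems.

A flexible macromolecule in solution populates many conformations; its
scattering is the population average.  Given a large pool of candidate
theoretical curves (one per conformer), a genetic algorithm selects a
sub-ensemble (a multiset of pool members — the chromosome) whose unweighted
average curve fits the experimental data after scaling.  Repeats in the
multiset encode weights; the chromosome size itself mutates within bounds,
so the ensemble complexity adapts to the data.

The radius-of-gyration distribution of the selected ensemble, compared with
that of the full pool, diagnoses flexibility: a selected distribution as
broad as the pool's suggests a genuinely flexible system, a much narrower
one a rigid system, and the shift of its centre indicates compaction or
extension relative to the random-coil pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import formfit as _formfit
from .sasio import SasError, ScatteringCurve, ValidationError

__all__ = [
    "CurvePool",
    "EnsembleSolution",
    "GAParams",
    "select_ensemble",
    "flexibility_report",
]

FLEXIBLE_RATIO = 0.8
RIGID_RATIO = 0.3


@dataclass(frozen=True)
class CurvePool:
    """M candidate curves on one common grid with per-member Rg values."""

    s: np.ndarray
    curves: np.ndarray            # (M, n)
    rg: np.ndarray                # (M,)
    labels: tuple[str, ...] = ()

    def __post_init__(self):
        s = np.asarray(self.s, float)
        c = np.atleast_2d(np.asarray(self.curves, float))
        rg = np.asarray(self.rg, float)
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "curves", c)
        object.__setattr__(self, "rg", rg)
        if c.shape[1] != s.size:
            raise ValidationError("pool curves must share the grid")
        if rg.shape != (c.shape[0],):
            raise ValidationError("one Rg per pool member required")
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(f"member {k}" for k in range(c.shape[0]))
            )

    @property
    def size(self) -> int:
        return self.curves.shape[0]


@dataclass(frozen=True)
class GAParams:
    """Genetic-algorithm control parameters (defaults are package choices)."""

    population: int = 50
    generations: int = 200
    size_min: int = 5
    size_max: int = 50
    mutation_rate: float = 0.1
    elitism: int = 2
    plateau: int = 50          # stop after this many generations without gain
    fit_constant: bool = False
    local_search: bool = True  # refine the elite by single-gene steepest descent


@dataclass(frozen=True)
class EnsembleSolution:
    """A selected multiset of pool members and its fit quality."""

    members: tuple[int, ...]
    chi2_reduced: float
    scale: float
    background: float
    rg_selected: np.ndarray
    rg_pool: np.ndarray
    average_curve: ScatteringCurve
    generations_run: int = 0

    def __post_init__(self):
        if self.chi2_reduced < 0:
            raise ValidationError("chi^2 cannot be negative")
        object.__setattr__(self, "rg_selected", np.asarray(self.rg_selected, float))
        object.__setattr__(self, "rg_pool", np.asarray(self.rg_pool, float))


def _chromosome_fitness(chrom: np.ndarray, pool_curves: np.ndarray,
                        I_exp: np.ndarray, sig: np.ndarray,
                        fit_constant: bool) -> tuple[float, float, float]:
    """Reduced χ² of the scaled average of the chromosome's member curves."""
    avg = pool_curves[chrom].mean(axis=0)
    w = 1.0 / sig
    if fit_constant:
        A = np.column_stack([avg * w, w])
        coef, *_ = np.linalg.lstsq(A, I_exp * w, rcond=None)
        c, b = float(max(coef[0], 0.0)), float(coef[1])
    else:
        num = float((w * w * avg * I_exp).sum())
        den = float((w * w * avg * avg).sum())
        c, b = max(num / max(den, 1e-300), 0.0), 0.0
    resid = (I_exp - c * avg - b) / sig
    n = I_exp.size
    return float(resid @ resid) / max(n - 1, 1), c, b


def _chi2_of_sum(total: np.ndarray, k: int, I_exp: np.ndarray,
                 w2: np.ndarray) -> float:
    avg = total / k
    num = float((w2 * avg * I_exp).sum())
    den = float((w2 * avg * avg).sum())
    c = max(num / max(den, 1e-300), 0.0)
    resid2 = w2 * (I_exp - c * avg) ** 2
    return float(resid2.sum()) / max(I_exp.size - 1, 1)


def _local_improve(chrom: np.ndarray, pool_curves: np.ndarray,
                   I_exp: np.ndarray, sig: np.ndarray,
                   size_min: int, size_max: int,
                   max_passes: int = 20) -> np.ndarray:
    """Steepest descent over single-gene moves (replace, delete, insert).

    Each pass evaluates, fully vectorised, every replacement of one member
    by any pool member, every deletion and every insertion, and applies the
    best improving move; stops at a local optimum.
    """
    w2 = 1.0 / sig**2
    chrom = chrom.copy()
    n = I_exp.size

    def chi2_many(totals: np.ndarray, k: int) -> np.ndarray:
        avg = totals / k
        num = avg @ (w2 * I_exp)
        den = np.einsum("ij,ij->i", avg, w2 * avg)
        c = np.maximum(num / np.maximum(den, 1e-300), 0.0)
        resid = I_exp[None, :] - c[:, None] * avg
        return np.einsum("ij,ij->i", resid, w2 * resid) / max(n - 1, 1)

    for _ in range(max_passes):
        total = pool_curves[chrom].sum(axis=0)
        k = chrom.size
        best_chi2 = _chi2_of_sum(total, k, I_exp, w2)
        best_move = None
        # replacements: drop position i, add any member m
        for i in range(k):
            totals = total[None, :] - pool_curves[chrom[i]] + pool_curves
            chis = chi2_many(totals, k)
            m = int(np.argmin(chis))
            if chis[m] < best_chi2 - 1e-15:
                best_chi2 = float(chis[m])
                best_move = ("replace", i, m)
        if k > size_min:
            totals = total[None, :] - pool_curves[chrom]
            chis = chi2_many(totals, k - 1)
            i = int(np.argmin(chis))
            if chis[i] < best_chi2 - 1e-15:
                best_chi2 = float(chis[i])
                best_move = ("delete", i, None)
        if k < size_max:
            totals = total[None, :] + pool_curves
            chis = chi2_many(totals, k + 1)
            m = int(np.argmin(chis))
            if chis[m] < best_chi2 - 1e-15:
                best_chi2 = float(chis[m])
                best_move = ("insert", None, m)
        if best_move is None:
            break
        kind, i, m = best_move
        if kind == "replace":
            chrom[i] = m
        elif kind == "delete":
            chrom = np.delete(chrom, i)
        else:
            chrom = np.append(chrom, m)
        chrom = np.sort(chrom)
    return chrom


def _nnls_seed(pool_curves: np.ndarray, I_exp: np.ndarray, sig: np.ndarray,
               size_min: int, size_max: int) -> np.ndarray | None:
    """Chromosome from rounding the non-negative LS weights over the pool.

    The ensemble-average model is linear in the member weights, so NNLS over
    the whole pool gives the best unconstrained non-negative weighting; the
    chromosome size k whose largest-remainder rounding of those weights
    fits best becomes a seed for the genetic algorithm.
    """
    from scipy.optimize import nnls

    A = (pool_curves / sig).T
    w, _ = nnls(A, I_exp / sig)
    total = w.sum()
    if total <= 0:
        return None
    frac = w / total
    w2 = 1.0 / sig**2
    best = None
    for k in range(size_min, size_max + 1):
        raw = frac * k
        counts = np.floor(raw).astype(int)
        short = k - counts.sum()
        if short > 0:
            order = np.argsort(raw - counts)[::-1]
            counts[order[:short]] += 1
        chrom = np.sort(np.repeat(np.arange(frac.size), counts))
        if chrom.size != k:
            continue
        chi2 = _chi2_of_sum(pool_curves[chrom].sum(axis=0), k, I_exp, w2)
        if best is None or chi2 < best[0]:
            best = (chi2, chrom)
    return best[1] if best else None


def select_ensemble(pool: CurvePool, exp: ScatteringCurve,
                    ga_params: GAParams | None = None,
                    seed: int = 0) -> EnsembleSolution:
    """Select a sub-ensemble whose average curve fits the data.

    Genetic algorithm over multisets of pool indices: uniform crossover,
    point mutation (replace a member), and insert/delete size mutation
    within bounds; elitism preserves the best chromosomes, so the final χ²
    never exceeds the best of the initial random population.  The initial
    population is seeded with a chromosome obtained by rounding the
    non-negative least-squares weights over the whole pool, and the elite is
    polished by single-gene steepest descent each generation.  Fixed seed
    gives a bit-identical solution.
    """
    p = ga_params or GAParams()
    if pool.size < max(p.size_min, 10):
        raise ValidationError(
            f"pool of {pool.size} members is too small (need ≥ {max(p.size_min, 10)})"
        )
    if not np.allclose(pool.s.shape, exp.s.shape) or not np.allclose(
        pool.s, exp.s, rtol=1e-6, atol=0.0
    ):
        raise ValidationError("pool and experimental curve are on different grids")
    rng = np.random.default_rng(seed)
    I_exp = exp.I
    sig = exp.sigma if exp.sigma is not None else np.ones_like(I_exp)
    size_max = min(p.size_max, pool.size)
    size_min = min(p.size_min, size_max)

    def random_chrom() -> np.ndarray:
        k = int(rng.integers(size_min, size_max + 1))
        return np.sort(rng.integers(0, pool.size, k))

    def mutate(chrom: np.ndarray) -> np.ndarray:
        out = chrom.copy()
        for i in range(out.size):
            if rng.random() < p.mutation_rate:
                out[i] = rng.integers(0, pool.size)
        # size mutation: insert or delete one member within bounds
        if rng.random() < p.mutation_rate:
            if rng.random() < 0.5 and out.size < size_max:
                out = np.append(out, rng.integers(0, pool.size))
            elif out.size > size_min:
                out = np.delete(out, rng.integers(out.size))
        return np.sort(out)

    def crossover(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        merged = np.concatenate([a, b])
        take = rng.random(merged.size) < 0.5
        child = merged[take]
        if child.size < size_min or child.size > size_max:
            k = int(rng.integers(size_min, size_max + 1))
            child = rng.choice(merged, size=min(k, merged.size), replace=False)
        return np.sort(child)

    popn = [random_chrom() for _ in range(p.population)]
    if p.local_search:
        nnls_chrom = _nnls_seed(pool.curves, I_exp, sig, size_min, size_max)
        if nnls_chrom is not None:
            popn[0] = nnls_chrom
    scored = [(_chromosome_fitness(c, pool.curves, I_exp, sig, p.fit_constant), c)
              for c in popn]
    scored.sort(key=lambda t: t[0][0])
    best_chi2 = scored[0][0][0]
    stall = 0
    gen = 0
    for gen in range(1, p.generations + 1):
        if p.local_search and not p.fit_constant:
            refined = _local_improve(scored[0][1], pool.curves, I_exp, sig,
                                     size_min, size_max)
            fit = _chromosome_fitness(refined, pool.curves, I_exp, sig,
                                      p.fit_constant)
            if fit[0] < scored[0][0][0]:
                scored.insert(0, (fit, refined))
        elite = [c for _, c in scored[: p.elitism]]
        children = list(elite)
        # rank-based parent selection over the top half
        top = [c for _, c in scored[: max(p.population // 2, 2)]]
        while len(children) < p.population:
            a = top[int(rng.integers(len(top)))]
            b = top[int(rng.integers(len(top)))]
            children.append(mutate(crossover(a, b)))
        scored = [(_chromosome_fitness(c, pool.curves, I_exp, sig, p.fit_constant), c)
                  for c in children]
        scored.sort(key=lambda t: t[0][0])
        if scored[0][0][0] < best_chi2 - 1e-12:
            best_chi2 = scored[0][0][0]
            stall = 0
        else:
            stall += 1
            if stall >= p.plateau:
                break
    (chi2, c, b), chrom = scored[0]
    avg = pool.curves[chrom].mean(axis=0)
    return EnsembleSolution(
        members=tuple(int(i) for i in chrom),
        chi2_reduced=chi2, scale=c, background=b,
        rg_selected=pool.rg[chrom], rg_pool=pool.rg,
        average_curve=ScatteringCurve(s=pool.s, I=c * avg + b,
                                      label="selected-ensemble average"),
        generations_run=gen,
    )


@dataclass(frozen=True)
class FlexibilityReport:
    verdict: str                   # flexible | rigid | indeterminate
    variance_ratio: float
    rg_shift: float                # mean(selected) − mean(pool), Å
    direction: str                 # compact | extended | unchanged


def flexibility_report(solution: EnsembleSolution) -> FlexibilityReport:
    """Compare selected vs pool Rg distributions.

    Verdict ``flexible`` when the selected-ensemble Rg variance is ≥ 80% of
    the pool's (the selection did not narrow the distribution), ``rigid``
    when ≤ 30%, else ``indeterminate``.  The mean shift reports compaction
    (negative) or extension (positive) relative to the pool.
    """
    var_pool = float(np.var(solution.rg_pool))
    var_sel = float(np.var(solution.rg_selected))
    if var_pool <= 0:
        ratio = 1.0
        verdict = "indeterminate"
    else:
        ratio = var_sel / var_pool
        if ratio >= FLEXIBLE_RATIO:
            verdict = "flexible"
        elif ratio <= RIGID_RATIO:
            verdict = "rigid"
        else:
            verdict = "indeterminate"
    shift = float(np.mean(solution.rg_selected) - np.mean(solution.rg_pool))
    spread = float(np.std(solution.rg_pool)) or 1.0
    if shift < -0.1 * spread:
        direction = "compact"
    elif shift > 0.1 * spread:
        direction = "extended"
    else:
        direction = "unchanged"
    return FlexibilityReport(verdict=verdict, variance_ratio=ratio,
                             rg_shift=shift, direction=direction)
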