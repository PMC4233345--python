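"""Multi-model analysis: spatial discrepancy, superposition and clustering.

Shape reconstruction from a 1-D scattering curve is ambiguous, so multiple
independent reconstructions are compared.  The normalised spatial
discrepancy (NSD) between two point models a and b,

    NSD² = ½·[ 1/(N_a·d_b²)·Σ_{i∈a} min_{j∈b} r²_ij
             + 1/(N_b·d_a²)·Σ_{j∈b} min_{i∈a} r²_ij ],

with d_x the median nearest-neighbour distance within model x, is ~0 for
identical models and ≲1 for similar ones.  :func:`superpose` minimises the
NSD over rigid motions (optionally restricted by Pn/Pn2 symmetry, optionally
testing the mirror image); :func:`cluster_models` builds the pairwise
dissimilarity matrix, clusters it hierarchically and picks the number of
clusters by the Kelley penalty (normalised within-cluster spread plus k).
:func:`density_to_beads` converts a thresholded EM density map into a bead
model, optionally splitting surface from core beads for downstream
refinement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.ndimage import distance_transform_edt
from scipy.optimize import minimize
from scipy.spatial import cKDTree
from scipy.spatial.distance import squareform
from scipy.spatial.transform import Rotation

from .sasio import BeadModel, DensityGrid, SasError, ValidationError

__all__ = [
    "DistanceMatrix",
    "ClusterResult",
    "SuperpositionResult",
    "nsd",
    "superpose",
    "cluster_models",
    "density_to_beads",
]

ORIENTATION_GRID_SIZE = 432


class EmptyModelError(SasError):
    """No density above the requested threshold."""


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise dissimilarity matrix with a metric tag."""

    matrix: np.ndarray
    metric: str = "nsd"

    def __post_init__(self):
        m = np.asarray(self.matrix, float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValidationError("distance matrix must be square")
        if np.any(np.abs(np.diag(m)) > 1e-12):
            raise ValidationError("distance matrix must have a zero diagonal")
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValidationError("distance matrix must be symmetric")
        if np.any(m < -1e-12):
            raise ValidationError("distances must be non-negative")


@dataclass(frozen=True)
class ClusterResult:
    labels: np.ndarray             # cluster id per model, 0-based
    k_chosen: int
    kelley_penalty: dict[int, float]
    representatives: tuple[int, ...]
    distance: DistanceMatrix
    outlier_flags: np.ndarray      # True = flagged as unusually distant


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    nsd_min: float
    mirrored: bool = False
    converged: bool = True

    def apply(self, model: BeadModel) -> BeadModel:
        coords = model.coords.copy()
        if self.mirrored:
            coords = coords * np.array([1.0, 1.0, -1.0])
        return BeadModel(coords=coords @ self.rotation.T + self.translation,
                         weight=model.weight, radius=model.radius,
                         label=model.label)


def _median_nn(coords: np.ndarray) -> float:
    tree = cKDTree(coords)
    d, _ = tree.query(coords, k=2)
    return float(np.median(d[:, 1]))


def nsd(a: BeadModel, b: BeadModel) -> float:
    """Normalised spatial discrepancy at fixed pose (no alignment)."""
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("NSD needs at least 2 points per model "
                              "(nearest-neighbour scale undefined)")
    da = _median_nn(a.coords)
    db = _median_nn(b.coords)
    return _nsd_from_trees(a.coords, b.coords, da, db)


def _nsd_from_trees(ca: np.ndarray, cb: np.ndarray, da: float, db: float) -> float:
    ta = cKDTree(ca)
    tb = cKDTree(cb)
    d_ab, _ = tb.query(ca)      # every point of a to its nearest in b
    d_ba, _ = ta.query(cb)
    term_a = np.mean(d_ab**2) / db**2
    term_b = np.mean(d_ba**2) / da**2
    return float(np.sqrt(0.5 * (term_a + term_b)))


def _orientation_grid(n: int = ORIENTATION_GRID_SIZE) -> np.ndarray:
    """Deterministic quasi-uniform covering of SO(3) (as rotation matrices)."""
    # super-Fibonacci-style sequence on the quaternion 3-sphere
    phi = np.sqrt(2.0)
    psi = 1.533751168755204288118041   # plastic-number-based irrational
    i = np.arange(n)
    s = i + 0.5
    t = s / n
    d = 2.0 * np.pi * s
    r = np.sqrt(t)
    R = np.sqrt(1.0 - t)
    alpha = d / phi
    beta = d / psi
    q = np.column_stack([r * np.sin(alpha), r * np.cos(alpha),
                         R * np.sin(beta), R * np.cos(beta)])
    return Rotation.from_quat(q).as_matrix()


def _nsd_pose(a: BeadModel, cb: np.ndarray, da: float, db: float,
              R: np.ndarray, t: np.ndarray) -> float:
    return _nsd_from_trees(a.coords, cb @ R.T + t, da, db)


def superpose(a: BeadModel, b: BeadModel, symmetry: str = "P1",
              enantiomers: bool = False) -> SuperpositionResult:
    """Find the rigid motion of ``b`` minimising NSD against ``a``.

    ``P1``: full 6-parameter search (coarse deterministic orientation grid
    followed by local simplex refinement), optionally also testing the
    mirror image of ``b``.  ``Pn`` (e.g. ``P2``, ``P3`` ... with the n-fold
    axis along z for both models): only rotation about z and translation
    along z are adjusted, preserving the symmetry.  ``Pn2``: axis alignment
    only — the models are brought to a common axis position without any
    rotational search.
    """
    da = _median_nn(a.coords)
    db = _median_nn(b.coords)
    com_a = a.coords.mean(axis=0)

    def refine_p1(coords_b: np.ndarray) -> tuple[float, np.ndarray, np.ndarray, bool]:
        com_b = coords_b.mean(axis=0)
        centered = coords_b - com_b
        grid = _orientation_grid()
        scores = np.array([
            _nsd_from_trees(a.coords, centered @ R.T + com_a, da, db) for R in grid
        ])
        order = np.argsort(scores)[:3]
        best = (np.inf, None, None)
        for k in order:
            rot0 = Rotation.from_matrix(grid[k]).as_rotvec()
            x0 = np.concatenate([rot0, com_a])

            def cost(x):
                R = Rotation.from_rotvec(x[:3]).as_matrix()
                return _nsd_from_trees(a.coords, centered @ R.T + x[3:], da, db)

            res = minimize(cost, x0, method="Nelder-Mead",
                           options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 600})
            if res.fun < best[0]:
                R = Rotation.from_rotvec(res.x[:3]).as_matrix()
                # compose centering into the final transform: x → R(x−com_b)+t
                best = (float(res.fun), R, res.x[3:] - R @ com_b, bool(res.success))
        return best

    if symmetry == "P1":
        chi, R, t, ok = refine_p1(b.coords)
        mirrored = False
        if enantiomers:
            chi_m, R_m, t_m, ok_m = refine_p1(b.coords * np.array([1.0, 1.0, -1.0]))
            if chi_m < chi:
                chi, R, t, ok, mirrored = chi_m, R_m, t_m, ok_m, True
        return SuperpositionResult(rotation=R, translation=t, nsd_min=chi,
                                   mirrored=mirrored, converged=ok)

    if symmetry.startswith("P") and symmetry.endswith("2") and len(symmetry) > 2:
        # Pn2: align the symmetry axes (z by convention): translate centres only
        t = np.array([com_a[0] - b.coords[:, 0].mean(),
                      com_a[1] - b.coords[:, 1].mean(),
                      com_a[2] - b.coords[:, 2].mean()])
        chi = _nsd_pose(a, b.coords, da, db, np.eye(3), t)
        return SuperpositionResult(rotation=np.eye(3), translation=t, nsd_min=chi)

    if symmetry.startswith("P"):
        # Pn: rotation about z + translation along z; xy centres pre-aligned
        txy = np.array([com_a[0] - b.coords[:, 0].mean(),
                        com_a[1] - b.coords[:, 1].mean(), 0.0])

        def pose(phi, tz):
            c, s = np.cos(phi), np.sin(phi)
            R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
            t = txy + np.array([0.0, 0.0, tz])
            # rotate about the model's own z axis through its xy centre
            com_b = b.coords.mean(axis=0)
            tt = com_b + t - R @ com_b
            return R, tt

        def cost(x):
            R, t = pose(x[0], x[1])
            return _nsd_pose(a, b.coords, da, db, R, t)

        tz0 = com_a[2] - b.coords[:, 2].mean()
        best = (np.inf, None)
        for phi0 in np.linspace(0.0, 2 * np.pi, 24, endpoint=False):
            res = minimize(cost, np.array([phi0, tz0]), method="Nelder-Mead",
                           options={"xatol": 1e-5, "fatol": 1e-9, "maxiter": 400})
            if res.fun < best[0]:
                best = (float(res.fun), res.x)
        chi, x = best
        R, t = pose(x[0], x[1])
        return SuperpositionResult(rotation=R, translation=t, nsd_min=chi)

    raise ValueError(f"unknown symmetry {symmetry!r}")


def _rmsd_aligned(a: np.ndarray, b: np.ndarray) -> float:
    """R.m.s.d. after optimal (Kabsch) superposition of one-to-one models."""
    if a.shape != b.shape:
        raise ValidationError("r.m.s.d. requires one-to-one correspondence")
    pa = a - a.mean(axis=0)
    pb = b - b.mean(axis=0)
    H = pb.T @ pa
    U, S, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))])
    R = U @ D @ Vt
    diff = pa - pb @ R
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def pairwise_distances(models, metric: str = "nsd",
                       align_first: bool = True) -> DistanceMatrix:
    """Pairwise dissimilarity matrix over a list of models."""
    models = list(models)
    n = len(models)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "rmsd":
                d = _rmsd_aligned(models[i].coords, models[j].coords)
            elif align_first:
                d = superpose(models[i], models[j]).nsd_min
            else:
                d = nsd(models[i], models[j])
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(matrix=mat, metric=metric)


def cluster_models(models, metric: str = "nsd", align_first: bool = True,
                   distance: DistanceMatrix | None = None) -> ClusterResult:
    """Cluster models hierarchically; pick k by the Kelley penalty.

    Average-linkage merging of the pairwise NSD (or aligned r.m.s.d.)
    matrix.  For each candidate k, the average spread — the mean over
    clusters of ≥ 2 members of their mean intra-cluster distance — is
    normalised linearly onto [1, N−1] across k; the penalty is that
    normalised spread plus k, and the k with the minimal penalty is chosen
    (ties towards smaller k).  Per-cluster representatives minimise the mean
    distance to their cluster mates.
    """
    models = list(models)
    n = len(models)
    if n < 3:
        raise ValidationError("clustering needs at least 3 models")
    dm = distance or pairwise_distances(models, metric=metric, align_first=align_first)
    mat = dm.matrix
    if np.max(mat) <= 1e-9:
        labels = np.zeros(n, int)
        return ClusterResult(labels=labels, k_chosen=1, kelley_penalty={1: 1.0},
                             representatives=(0,), distance=dm,
                             outlier_flags=np.zeros(n, bool))
    Z = linkage(squareform(mat, checks=False), method="average")

    def spread_for(labels: np.ndarray) -> float:
        spreads = []
        for c in np.unique(labels):
            idx = np.flatnonzero(labels == c)
            if idx.size >= 2:
                sub = mat[np.ix_(idx, idx)]
                spreads.append(np.sum(sub) / (idx.size * (idx.size - 1)))
        return float(np.mean(spreads)) if spreads else 0.0

    ks = list(range(2, n))      # k = n (all singletons) has no defined spread
    partitions = {}
    spreads = {}
    for k in ks:
        lab = fcluster(Z, t=k, criterion="maxclust") - 1
        partitions[k] = lab
        spreads[k] = spread_for(lab)
    vals = np.array([spreads[k] for k in ks])
    lo, hi = vals.min(), vals.max()
    if hi > lo:
        norm = 1.0 + (vals - lo) * (n - 2) / (hi - lo)
    else:
        norm = np.ones_like(vals)
    penalty = {k: float(norm[i] + k) for i, k in enumerate(ks)}
    k_chosen = min(ks, key=lambda k: (penalty[k], k))
    labels = partitions[k_chosen]

    reps = []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if idx.size == 1:
            reps.append(int(idx[0]))
        else:
            sub = mat[np.ix_(idx, idx)]
            reps.append(int(idx[np.argmin(sub.mean(axis=1))]))

    mean_d = mat.sum(axis=1) / (n - 1)
    outliers = mean_d > mean_d.mean() + 2.0 * mean_d.std()
    return ClusterResult(labels=labels, k_chosen=int(k_chosen),
                         kelley_penalty=penalty, representatives=tuple(reps),
                         distance=dm, outlier_flags=outliers)


def density_to_beads(grid: DensityGrid, threshold: float,
                     surface_cutoff: float | None = None) -> BeadModel:
    """Convert a thresholded density map into a bead model.

    One bead per voxel with value ≥ threshold, placed at the voxel centre
    with radius half the voxel diagonal.  With ``surface_cutoff`` (in
    voxels), beads within that distance of the thresholded boundary are
    marked refinable while interior beads stay fixed — the usual starting
    point for constrained shape refinement.
    """
    mask = grid.values >= threshold
    if not np.any(mask):
        raise EmptyModelError(f"no voxels at or above threshold {threshold}")
    idx = np.argwhere(mask)
    coords = grid.origin + idx * grid.voxel_size
    radius = 0.5 * float(np.linalg.norm(grid.voxel_size))
    refinable = None
    if surface_cutoff is not None:
        # distance (in voxels) from each interior voxel to the background;
        # pad so the map border counts as background
        padded = np.pad(mask, 1)
        edt = distance_transform_edt(padded)[1:-1, 1:-1, 1:-1]
        surface = mask & (edt <= surface_cutoff)
        refinable = surface[tuple(idx.T)]
    return BeadModel(coords=coords, radius=max(radius, 1e-6),
                     refinable=refinable, label="density-derived beads")
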