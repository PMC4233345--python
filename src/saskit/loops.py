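"""Self-avoiding random Cα loop generation and a sorted linker library.

Missing linkers and disordered termini still scatter; placeholder loops let
a rigid-body model account for them without modelling side chains.  Loops
are grown as Cα-only traces: each residue sits exactly 3.8 Å from its
predecessor, every non-neighbouring pair must be more than 4 Å apart (the
steric clash rule), and the pseudo-bond angle θ and pseudo-dihedral γ at
each step must fall in an allowed region of the quasi-Ramachandran (θ, γ)
plot.  Generated loops of lengths 5–100 are binned by end-to-end distance
(2 Å bins) with typically 20 distinct traces per bin; a library query takes
two anchor points and rigidly places a stored trace of matching length and
end-to-end distance between them, returning a failure signal — not an
error — when no bin matches (the rejection test of anchored rigid-body
moves).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist

from .sasio import BeadModel, SasError, ValidationError

__all__ = [
    "CA_STEP",
    "CLASH_DISTANCE",
    "QuasiRamachandranMask",
    "CaTrace",
    "GrowthFailure",
    "LoopLibrary",
    "grow_loop",
    "build_library",
    "query_linker",
]

CA_STEP = 3.8          # Å between consecutive Cα atoms
CLASH_DISTANCE = 4.0   # Å minimum distance between non-neighbouring Cα atoms
MAX_LENGTH = 100
MIN_LIBRARY_LENGTH = 5
BIN_WIDTH = 2.0        # Å end-to-end distance discretisation
PER_BIN = 20
DISTINCT_RMSD = 0.5    # Å pairwise r.m.s.d. required between stored traces


class GrowthFailure(SasError):
    """The retry budget was exhausted while growing a loop."""


@dataclass(frozen=True)
class QuasiRamachandranMask:
    """Allowed (θ, γ) region for the Cα pseudo-angles.

    θ is the pseudo-bond angle at each interior residue (degrees), γ the
    pseudo-dihedral over four consecutive Cα atoms.  The allowed region is a
    θ band with one rectangular forbidden zone cut out; the published
    quasi-Ramachandran region is not reproduced exactly, so the zone is
    configurable.
    """

    theta_min: float = 75.0
    theta_max: float = 150.0
    forbidden_theta: tuple[float, float] = (75.0, 100.0)
    forbidden_gamma: tuple[float, float] = (-40.0, 40.0)

    def allows(self, theta: float, gamma: float | None) -> bool:
        if not (self.theta_min <= theta <= self.theta_max):
            return False
        if gamma is not None:
            if (self.forbidden_theta[0] <= theta <= self.forbidden_theta[1]
                    and self.forbidden_gamma[0] <= gamma <= self.forbidden_gamma[1]):
                return False
        return True


DEFAULT_MASK = QuasiRamachandranMask()


@dataclass(frozen=True)
class CaTrace:
    """An ordered Cα trace with fixed 3.8 Å pseudo-bonds."""

    coords: np.ndarray

    def __post_init__(self):
        xyz = np.asarray(self.coords, float)
        object.__setattr__(self, "coords", xyz)
        if xyz.ndim != 2 or xyz.shape[1] != 3 or xyz.shape[0] < 2:
            raise ValidationError("a trace needs at least 2 points")
        steps = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
        if np.any(np.abs(steps - CA_STEP) > 1e-6):
            raise ValidationError("consecutive distances must equal 3.8 Å")

    @property
    def n_residues(self) -> int:
        return self.coords.shape[0]

    @property
    def end_to_end(self) -> float:
        return float(np.linalg.norm(self.coords[-1] - self.coords[0]))

    def clash_free(self) -> bool:
        """True when every non-neighbouring pair is more than 4 Å apart."""
        n = self.n_residues
        if n < 3:
            return True
        d = pdist(self.coords)
        iu = np.triu_indices(n, k=1)
        nonneighbour = (iu[1] - iu[0]) > 1
        return bool(np.all(d[nonneighbour] > CLASH_DISTANCE))

    def pseudo_angles(self) -> tuple[np.ndarray, np.ndarray]:
        """Pseudo-bond angles θ (per interior residue) and dihedrals γ, degrees."""
        x = self.coords
        b = np.diff(x, axis=0)
        theta = np.array([])
        gamma = np.array([])
        if len(b) >= 2:
            u = b[:-1] / np.linalg.norm(b[:-1], axis=1)[:, None]
            v = b[1:] / np.linalg.norm(b[1:], axis=1)[:, None]
            cos = np.clip(np.sum(u * v, axis=1), -1.0, 1.0)
            theta = 180.0 - np.degrees(np.arccos(cos))   # angle at the vertex
        if len(b) >= 3:
            b0, b1, b2 = b[:-2], b[1:-1], b[2:]
            n0 = np.cross(b0, b1)
            n1 = np.cross(b1, b2)
            m = np.cross(n0, b1 / np.linalg.norm(b1, axis=1)[:, None])
            xg = np.sum(n0 * n1, axis=1)
            yg = np.sum(m * n1, axis=1)
            gamma = np.degrees(np.arctan2(yg, xg))
        return theta, gamma

    def angles_allowed(self, mask: QuasiRamachandranMask = DEFAULT_MASK) -> bool:
        theta, gamma = self.pseudo_angles()
        if theta.size == 0:
            return True
        g = ([None] + list(gamma)) if gamma.size else [None] * theta.size
        return all(mask.allows(t, gg) for t, gg in zip(theta, g))

    def as_model(self) -> BeadModel:
        return BeadModel(coords=self.coords, radius=1.9,
                         residue_index=np.arange(1, self.n_residues + 1))


def _angle_deg(a, b, c) -> float:
    """Pseudo-bond angle at b, degrees."""
    u = a - b
    v = c - b
    cos = np.clip((u @ v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def _dihedral_deg(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n0 = np.cross(b0, b1)
    n1 = np.cross(b1, b2)
    m = np.cross(n0, b1 / np.linalg.norm(b1))
    return float(np.degrees(np.arctan2(m @ n1, n0 @ n1)))


def grow_loop(n_residues: int, rng: np.random.Generator | int = 0,
              mask: QuasiRamachandranMask = DEFAULT_MASK,
              step_retries: int = 100, restarts: int = 50) -> CaTrace:
    """Grow one self-avoiding Cα trace by sequential random addition.

    Each new Cα is placed 3.8 Å from its predecessor in a direction sampled
    uniformly on the sphere and accepted only if the clash rule and the
    quasi-Ramachandran mask hold; on a dead end the last point is dropped
    (backtracking), and after ``restarts`` full restarts a
    :class:`GrowthFailure` is raised.
    """
    if not 2 <= n_residues <= MAX_LENGTH:
        raise ValidationError(f"loop length must be in [2, {MAX_LENGTH}]")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    for _ in range(restarts):
        pts = [np.zeros(3), np.array([0.0, 0.0, CA_STEP])]
        fails = 0
        while len(pts) < n_residues:
            placed = False
            for _ in range(step_retries):
                v = rng.normal(size=3)
                v *= CA_STEP / np.linalg.norm(v)
                cand = pts[-1] + v
                # clash rule against all non-neighbours
                if len(pts) >= 2:
                    d2 = np.sum((np.asarray(pts[:-1]) - cand) ** 2, axis=1)
                    if np.min(d2) <= CLASH_DISTANCE**2:
                        continue
                # pseudo-bond angle at the previous residue
                if len(pts) >= 2:
                    th = _angle_deg(pts[-2], pts[-1], cand)
                    ga = (_dihedral_deg(pts[-3], pts[-2], pts[-1], cand)
                          if len(pts) >= 3 else None)
                    if not mask.allows(th, ga):
                        continue
                pts.append(cand)
                placed = True
                break
            if not placed:
                if len(pts) > 2:
                    pts.pop()      # backtrack one step
                    fails += 1
                    if fails > 5 * n_residues:
                        break
                else:
                    break
        if len(pts) == n_residues:
            return CaTrace(coords=np.asarray(pts))
    raise GrowthFailure(f"could not grow a {n_residues}-residue loop")


def _kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """R.m.s.d. of two equal-length traces after optimal superposition."""
    pa = a - a.mean(axis=0)
    pb = b - b.mean(axis=0)
    H = pb.T @ pa
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    diff = pa - pb @ R
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def _bin_center(distance: float, bin_width: float = BIN_WIDTH) -> float:
    """Bins of the given width tiling [0, ∞) with centres at odd half-widths."""
    return (np.floor(distance / bin_width) + 0.5) * bin_width


@dataclass
class LoopLibrary:
    """Map (residue count, end-to-end bin centre) → stored traces."""

    bin_width: float = BIN_WIDTH
    per_bin: int = PER_BIN
    rng_seed: int = 0
    bins: dict[tuple[int, float], list[CaTrace]] = field(default_factory=dict)
    underfilled: set = field(default_factory=set)

    def lengths(self) -> list[int]:
        return sorted({L for L, _ in self.bins})

    def add(self, trace: CaTrace) -> bool:
        """File a trace into its bin; rejects full bins and non-distinct traces."""
        key = (trace.n_residues, _bin_center(trace.end_to_end, self.bin_width))
        stored = self.bins.setdefault(key, [])
        if len(stored) >= self.per_bin:
            return False
        if any(_kabsch_rmsd(trace.coords, t.coords) <= DISTINCT_RMSD for t in stored):
            return False
        stored.append(trace)
        return True

    def save(self, directory) -> None:
        """Serialise as a directory of Cα PDB files plus a JSON index.

        The PDB files are for visual inspection; the index stores the
        coordinates at full precision (PDB columns round to 1e-3 Å, which
        would break the 3.8 Å pseudo-bond invariant on reload).
        """
        from .sasio import write_model

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        index = {"bin_width": self.bin_width, "per_bin": self.per_bin,
                 "seed": self.rng_seed, "bins": []}
        for (L, ctr), traces in sorted(self.bins.items()):
            files, coords = [], []
            for i, t in enumerate(traces):
                name = f"loop_L{L:03d}_d{ctr:06.1f}_{i:02d}.pdb"
                write_model(t.as_model(), d / name)
                files.append(name)
                coords.append(t.coords.tolist())
            index["bins"].append({"length": L, "center": ctr, "count": len(traces),
                                  "files": files, "coords": coords})
        (d / "index.json").write_text(json.dumps(index))

    @classmethod
    def load(cls, directory) -> "LoopLibrary":
        d = Path(directory)
        index = json.loads((d / "index.json").read_text())
        lib = cls(bin_width=index["bin_width"], per_bin=index["per_bin"],
                  rng_seed=index.get("seed", 0))
        for entry in index["bins"]:
            key = (entry["length"], entry["center"])
            lib.bins[key] = [CaTrace(coords=np.asarray(c)) for c in entry["coords"]]
        return lib


def build_library(lengths=range(MIN_LIBRARY_LENGTH, MAX_LENGTH + 1),
                  per_bin: int = PER_BIN, bin_width: float = BIN_WIDTH,
                  rng_seed: int = 0, attempts_per_length: int = 1500,
                  mask: QuasiRamachandranMask = DEFAULT_MASK) -> LoopLibrary:
    """Generate a sorted loop library for the given lengths.

    For each length, loops are grown and filed into end-to-end distance bins
    until every reachable bin holds ``per_bin`` distinct traces or the
    generation budget runs out; bins that were reached but not filled are
    flagged in ``underfilled``.
    """
    lengths = sorted(set(int(x) for x in lengths))
    if not lengths or lengths[0] < 2 or lengths[-1] > MAX_LENGTH:
        raise ValidationError(f"lengths must lie within [2, {MAX_LENGTH}]")
    rng = np.random.default_rng(rng_seed)
    lib = LoopLibrary(bin_width=bin_width, per_bin=per_bin, rng_seed=rng_seed)
    for L in lengths:
        stall = 0
        for _ in range(attempts_per_length):
            try:
                t = grow_loop(L, rng, mask=mask)
            except GrowthFailure:
                continue
            if lib.add(t):
                stall = 0
            else:
                stall += 1
                if stall > attempts_per_length // 3:
                    break
        for (Lk, ctr), traces in lib.bins.items():
            if Lk == L and len(traces) < per_bin:
                lib.underfilled.add((Lk, ctr))
    return lib


def query_linker(library: LoopLibrary, n_residues: int,
                 anchor_a, anchor_b,
                 rng: np.random.Generator | int = 0) -> CaTrace | None:
    """Place a stored linker of the given length between two anchors.

    Looks up the end-to-end distance bin matching |anchor_a − anchor_b|,
    picks a random stored trace, and rigidly moves it so its first residue
    lands on ``anchor_a`` with the end-to-end vector pointing at
    ``anchor_b``.  Returns ``None`` (the rejection signal for anchored
    moves) when no bin matches; raises only when the length is absent from
    the library altogether.
    """
    if n_residues not in library.lengths():
        raise ValidationError(f"length {n_residues} not in library")
    a = np.asarray(anchor_a, float)
    b = np.asarray(anchor_b, float)
    dist = float(np.linalg.norm(b - a))
    key = (n_residues, _bin_center(dist, library.bin_width))
    traces = library.bins.get(key)
    if not traces:
        return None
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    t = traces[int(rng.integers(len(traces)))]
    # rotate the trace's end-to-end vector onto the anchor direction
    v = t.coords[-1] - t.coords[0]
    u = b - a
    vn = v / np.linalg.norm(v)
    un = u / np.linalg.norm(u)
    c = float(np.clip(vn @ un, -1.0, 1.0))
    if c > 1 - 1e-12:
        R = np.eye(3)
    elif c < -1 + 1e-12:
        # 180°: rotate about any axis orthogonal to vn
        axis = np.cross(vn, np.array([1.0, 0.0, 0.0]))
        if np.linalg.norm(axis) < 1e-8:
            axis = np.cross(vn, np.array([0.0, 1.0, 0.0]))
        axis /= np.linalg.norm(axis)
        R = 2.0 * np.outer(axis, axis) - np.eye(3)
    else:
        k = np.cross(vn, un)
        s = np.linalg.norm(k)
        K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        R = np.eye(3) + K + K @ K * ((1 - c) / s**2)
    moved = (t.coords - t.coords[0]) @ R.T + a
    return CaTrace(coords=moved)
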