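"""Data model and file I/O for small-angle scattering analysis.

Internal containers: :class:`ScatteringCurve` (1-D profiles), :class:`BeadModel`
(ordered 3-D point models with scattering weights) and :class:`DensityGrid`
(3-D scalar maps).  Readers normalise the common external formats — 2/3-column
ASCII ``.dat`` profiles, 4-column ``.fit`` files, fixed-column PDB coordinate
files (including multi-MODEL NMR ensembles) and MRC/CCP4 density maps — into
these containers; writers round-trip them.

The momentum transfer convention is s = 4π·sinθ/λ.  s is unit-agnostic
internally; the ``unit`` metadata field records Å⁻¹ vs nm⁻¹ where known, and
the Porod/molecular-mass code converts nm⁻¹ input by dividing s by 10.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SasError",
    "SasFormatError",
    "ValidationError",
    "ScatteringCurve",
    "BeadModel",
    "DensityGrid",
    "read_curve",
    "write_curve",
    "read_model",
    "read_models",
    "write_model",
    "read_density",
]


class SasError(Exception):
    """Base class for all saskit errors."""


class SasFormatError(SasError):
    """A file could not be parsed in the expected format."""


class ValidationError(SasError):
    """Data violates an invariant of the internal model."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScatteringCurve:
    """One 1-D scattering profile.

    Parameters
    ----------
    s : array
        Momentum transfer grid (length⁻¹), strictly increasing, all ≥ 0.
    I : array
        Intensity at each grid point (arbitrary units).  Negative values are
        allowed: buffer-subtracted data may dip below zero.
    sigma : array, optional
        1-σ uncertainty per point, same units as ``I``; all > 0 when present.
    concentration : float, optional
        Solute concentration (mg/ml) for dilution-series work.
    label : str
        Free-text label (sample name, header line, file stem).
    unit : str, optional
        Unit of s, ``"A"`` (Å⁻¹) or ``"nm"`` (nm⁻¹), when known.
    """

    s: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None = None
    concentration: float | None = None
    label: str = ""
    unit: str | None = None

    def __post_init__(self):
        s = np.asarray(self.s, dtype=float)
        I = np.asarray(self.I, dtype=float)
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "I", I)
        if s.ndim != 1 or s.size == 0:
            raise ValidationError("curve must contain at least one point")
        if I.shape != s.shape:
            raise ValidationError("s and I must have equal length")
        if np.any(s < 0):
            raise ValidationError("momentum transfer must be non-negative")
        if np.any(np.diff(s) <= 0):
            raise ValidationError("momentum transfer grid must be strictly increasing")
        if not np.all(np.isfinite(s)) or not np.all(np.isfinite(I)):
            raise ValidationError("non-finite values in curve")
        if self.sigma is not None:
            sig = np.asarray(self.sigma, dtype=float)
            object.__setattr__(self, "sigma", sig)
            if sig.shape != s.shape:
                raise ValidationError("sigma must match the grid length")
            if np.any(~np.isfinite(sig)) or np.any(sig <= 0):
                raise ValidationError("sigma values must be finite and > 0")

    def __len__(self) -> int:
        return self.s.size

    def with_(self, **kwargs) -> "ScatteringCurve":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def crop(self, s_min: float = -np.inf, s_max: float = np.inf) -> "ScatteringCurve":
        """Restrict the curve to grid points with ``s_min <= s <= s_max``."""
        m = (self.s >= s_min) & (self.s <= s_max)
        if not np.any(m):
            raise ValidationError("crop range contains no points")
        return self.with_(
            s=self.s[m], I=self.I[m],
            sigma=None if self.sigma is None else self.sigma[m],
        )


@dataclass(frozen=True)
class BeadModel:
    """Ordered 3-D point model with per-point scattering weight.

    Covers full-atom structures, Cα traces and dummy-bead models alike:
    ``coords`` (Å) are ordered as read, ``weight`` is the scattering length
    per point (arbitrary units), ``radius`` the bead radius in Å (scalar,
    uniform over the model), ``chain_id``/``residue_index`` carry the source
    labels and ``refinable`` flags beads free to move in downstream
    refinement (surface beads of a density-derived model, say).
    """

    coords: np.ndarray
    weight: np.ndarray | None = None
    radius: float = 1.9
    chain_id: tuple[str, ...] | None = None
    residue_index: np.ndarray | None = None
    refinable: np.ndarray | None = None
    label: str = ""

    def __post_init__(self):
        xyz = np.atleast_2d(np.asarray(self.coords, dtype=float))
        object.__setattr__(self, "coords", xyz)
        if xyz.ndim != 2 or xyz.shape[1] != 3 or xyz.shape[0] == 0:
            raise ValidationError("coords must be a non-empty (n, 3) array")
        if not np.all(np.isfinite(xyz)):
            raise ValidationError("coordinates must be finite")
        n = xyz.shape[0]
        w = self.weight
        if w is None:
            w = np.ones(n)
        w = np.asarray(w, dtype=float)
        if w.shape != (n,):
            raise ValidationError("weight must have one entry per point")
        if np.any(w < 0):
            raise ValidationError("weights must be non-negative")
        object.__setattr__(self, "weight", w)
        if self.radius <= 0:
            raise ValidationError("bead radius must be positive")
        if self.residue_index is not None:
            object.__setattr__(
                self, "residue_index", np.asarray(self.residue_index, dtype=int)
            )
        if self.refinable is not None:
            object.__setattr__(self, "refinable", np.asarray(self.refinable, dtype=bool))

    def __len__(self) -> int:
        return self.coords.shape[0]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "BeadModel":
        """Apply the rigid motion x → R·x + t."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        return replace(self, coords=self.coords @ R.T + t)

    @property
    def rg(self) -> float:
        """Weight-averaged radius of gyration (Å)."""
        w = self.weight / self.weight.sum()
        com = w @ self.coords
        return float(np.sqrt(np.sum(w * np.sum((self.coords - com) ** 2, axis=1))))


@dataclass(frozen=True)
class DensityGrid:
    """3-D scalar density map on a regular grid.

    ``values`` is indexed [ix, iy, iz]; ``voxel_size`` gives the edge length
    per axis (Å, all > 0); ``origin`` is the position of the centre of voxel
    (0, 0, 0) in Å.
    """

    values: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        vs = np.broadcast_to(np.asarray(self.voxel_size, dtype=float), (3,)).copy()
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "voxel_size", vs)
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        if v.ndim != 3:
            raise ValidationError("density values must be a 3-D array")
        if np.any(vs <= 0):
            raise ValidationError("voxel size must be positive on every axis")


# ---------------------------------------------------------------------------
# 1-D curve files
# ---------------------------------------------------------------------------


def _parse_float_row(tokens: Sequence[str]) -> list[float] | None:
    try:
        return [float(t) for t in tokens]
    except ValueError:
        return None


def read_curve(path: str | os.PathLike, format_hint: str | None = None) -> ScatteringCurve:
    """Read a 1-D profile from a 2/3-column ``.dat`` or 4-column ``.fit`` file.

    Columns are (s, I[, σ]) for ``.dat`` and (s, I_exp, σ, I_fit) for
    ``.fit``/``.fir`` (the fitted column is dropped here; use
    :func:`read_fit` to keep it).  Non-numeric leading lines become the
    label; trailing non-numeric lines are ignored.  Rows with s < 0 or
    σ ≤ 0 are rejected; negative intensities are kept.

    Raises :class:`SasFormatError` naming the first bad line when no numeric
    block is found, and :class:`ValidationError` when s is not strictly
    increasing.
    """
    path = Path(path)
    header: list[str] = []
    rows: list[list[float]] = []
    ncol = None
    first_bad = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            tokens = line.split()
            if not tokens:
                continue
            vals = _parse_float_row(tokens)
            if vals is None or len(vals) < 2:
                if not rows:
                    header.append(line.strip())
                    if first_bad is None:
                        first_bad = (lineno, line.strip())
                # footer lines after the numeric block are ignored
                continue
            if ncol is None:
                ncol = len(vals)
            rows.append(vals[:ncol])
    if not rows:
        where = f" (first non-numeric line {first_bad[0]}: {first_bad[1]!r})" if first_bad else ""
        raise SasFormatError(f"{path}: no numeric data columns found{where}")
    ncols = min(len(r) for r in rows)
    data = np.array([r[:ncols] for r in rows], dtype=float)
    s, I = data[:, 0], data[:, 1]
    sigma = None
    if ncols >= 3:
        sigma = data[:, 2]
    # drop invalid rows: s < 0, or non-positive sigma when sigma is present
    keep = s >= 0
    if sigma is not None:
        keep &= sigma > 0
    s, I = s[keep], I[keep]
    if sigma is not None:
        sigma = sigma[keep]
    label = "; ".join(h for h in header if h) or path.stem
    return ScatteringCurve(s=s, I=I, sigma=sigma, label=label)


def read_fit(path: str | os.PathLike) -> tuple[ScatteringCurve, np.ndarray]:
    """Read a 4-column .fit file; return (experimental curve, fitted I column)."""
    curve = read_curve(path)
    rows = []
    with open(path) as fh:
        for line in fh:
            vals = _parse_float_row(line.split())
            if vals and len(vals) >= 4:
                rows.append(vals[:4])
    if not rows:
        raise SasFormatError(f"{path}: not a 4-column fit file")
    arr = np.asarray(rows)
    return curve, arr[:, 3]


def write_curve(curve: ScatteringCurve, path: str | os.PathLike) -> None:
    """Write a curve as 2/3-column ASCII; round-trips to ≥ 6 significant digits."""
    if not isinstance(curve, ScatteringCurve):
        raise ValidationError("write_curve expects a ScatteringCurve")
    path = Path(path)
    with open(path, "w") as fh:
        if curve.label:
            fh.write(f"{curve.label}\n")
        for k in range(len(curve)):
            if curve.sigma is not None:
                fh.write(f"{curve.s[k]:.8e} {curve.I[k]:.8e} {curve.sigma[k]:.8e}\n")
            else:
                fh.write(f"{curve.s[k]:.8e} {curve.I[k]:.8e}\n")


# ---------------------------------------------------------------------------
# PDB coordinate files
# ---------------------------------------------------------------------------

_MODES = ("full_atom", "ca_only", "bead")


def _parse_pdb_models(path: Path, mode: str, keep_hydrogens: bool):
    models: list[dict] = []
    cur = {"coords": [], "chain": [], "resid": []}
    seen_model_record = False
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                if cur["coords"]:
                    models.append(cur)
                cur = {"coords": [], "chain": [], "resid": []}
                seen_model_record = True
            elif rec == "ENDMDL":
                if cur["coords"]:
                    models.append(cur)
                cur = {"coords": [], "chain": [], "resid": []}
            elif rec in ("ATOM", "HETATM"):
                name = line[12:16].strip()
                element = line[76:78].strip() if len(line) >= 78 else ""
                is_h = (element.upper() in ("H", "D")) if element else name.upper().startswith(("H", "D")) and not name.upper().startswith("HE")
                if is_h and not keep_hydrogens:
                    continue
                if mode == "ca_only" and name.upper() != "CA":
                    continue
                try:
                    x = float(line[30:38]); y = float(line[38:46]); z = float(line[46:54])
                except ValueError as exc:
                    raise SasFormatError(f"{path}: bad coordinate field in {line.rstrip()!r}") from exc
                cur["coords"].append((x, y, z))
                cur["chain"].append(line[21:22].strip() or "A")
                try:
                    cur["resid"].append(int(line[22:26]))
                except ValueError:
                    cur["resid"].append(len(cur["resid"]) + 1)
    if cur["coords"]:
        models.append(cur)
    return models, seen_model_record


def read_models(path: str | os.PathLike, mode: str = "full_atom",
                keep_hydrogens: bool = False) -> list[BeadModel]:
    """Read every MODEL block of a PDB file as a list of :class:`BeadModel`.

    ``mode`` selects the point set: ``full_atom`` keeps all ATOM/HETATM
    records, ``ca_only`` keeps CA records in chain/residue order and
    ``bead`` treats every record as a dummy bead of uniform weight.
    Hydrogen (and deuterium) records are skipped unless ``keep_hydrogens``.
    """
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}")
    path = Path(path)
    models, _ = _parse_pdb_models(path, mode, keep_hydrogens)
    if not models:
        raise SasFormatError(f"{path}: no ATOM/HETATM records found")
    out = []
    for i, m in enumerate(models):
        out.append(
            BeadModel(
                coords=np.asarray(m["coords"]),
                chain_id=tuple(m["chain"]),
                residue_index=np.asarray(m["resid"]),
                label=f"{path.stem}" + (f"#{i + 1}" if len(models) > 1 else ""),
            )
        )
    return out


def read_model(path: str | os.PathLike, mode: str = "full_atom",
               keep_hydrogens: bool = False) -> BeadModel:
    """Read the first (or only) model of a PDB file.

    Multi-model NMR files are supported through :func:`read_models`.
    """
    return read_models(path, mode=mode, keep_hydrogens=keep_hydrogens)[0]


def write_model(model: BeadModel, path: str | os.PathLike) -> None:
    """Write a model as PDB-like dummy-atom (CA) records.

    Coordinates round-trip to the PDB column precision of 1e-3 Å.
    """
    if not isinstance(model, BeadModel):
        raise ValidationError("write_model expects a BeadModel")
    path = Path(path)
    chains = model.chain_id or ("A",) * len(model)
    resid = model.residue_index
    with open(path, "w") as fh:
        fh.write("REMARK saskit dummy-atom model\n")
        for i, (x, y, z) in enumerate(model.coords):
            serial = (i % 99999) + 1
            res = int(resid[i]) if resid is not None else i + 1
            ch = chains[i] if i < len(chains) else "A"
            occ = model.weight[i]
            flag = 1.0 if model.refinable is not None and model.refinable[i] else 0.0
            fh.write(
                f"ATOM  {serial:5d}  CA  ALA {ch:1s}{res % 10000:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{flag:6.2f}\n"
            )
        fh.write("TER\nEND\n")


# ---------------------------------------------------------------------------
# density maps
# ---------------------------------------------------------------------------


def read_density(path: str | os.PathLike) -> DensityGrid:
    """Read an MRC/CCP4 density map; axis order is normalised to x, y, z."""
    import gemmi

    path = Path(path)
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError, SystemError) as exc:
        raise SasFormatError(f"{path}: cannot read MRC/CCP4 map ({exc})") from exc
    m.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    arr = np.array(m.grid, copy=True)
    cell = m.grid.unit_cell
    shape = np.array(arr.shape, dtype=float)
    voxel = np.array([cell.a, cell.b, cell.c]) / shape
    if np.any(voxel <= 0) or not np.all(np.isfinite(voxel)):
        raise SasFormatError(f"{path}: invalid voxel size in header")
    # origin of the map in Å: prefer explicit ORIGIN, else grid start offsets
    try:
        hdr_origin = np.array([m.header_float(50), m.header_float(51), m.header_float(52)])
    except Exception:
        hdr_origin = np.zeros(3)
    if np.allclose(hdr_origin, 0.0):
        start = np.array([m.header_i32(5), m.header_i32(6), m.header_i32(7)], dtype=float)
        hdr_origin = start * voxel
    return DensityGrid(values=np.nan_to_num(arr), voxel_size=voxel, origin=hdr_origin)


def write_density(grid: DensityGrid, path: str | os.PathLike) -> None:
    """Write a density grid as a CCP4/MRC map (mainly for fixtures/round-trips)."""
    import gemmi

    g = gemmi.FloatGrid(*grid.values.shape)
    n = np.array(grid.values.shape, dtype=float)
    a, b, c = (grid.voxel_size * n).tolist()
    g.set_unit_cell(gemmi.UnitCell(a, b, c, 90, 90, 90))
    arr = np.array(g, copy=False)
    arr[...] = grid.values
    m = gemmi.Ccp4Map()
    m.grid = g
    m.update_ccp4_header()
    m.set_header_float(50, float(grid.origin[0]))
    m.set_header_float(51, float(grid.origin[1]))
    m.set_header_float(52, float(grid.origin[2]))
    m.write_ccp4_map(str(path))
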