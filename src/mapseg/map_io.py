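"""Crystallographic volume and model I/O and the shared grid data model.

All modules in the package exchange density through :class:`MapGrid` (and its
0/1 and probability variants), which stores voxel values in a fixed internal
convention: ``values[i, j, k]`` is the density at fractional coordinate
``(i/nx, j/ny, k/nz)``, i.e. array axis 0 runs along the crystallographic
*a* axis.  Files written with any header axis order are permuted to this
convention on read.  Grids are periodic in all three axes.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "UnitCell",
    "MapGrid",
    "BinaryMask",
    "ProbabilityGrid",
    "AtomicModel",
    "MapIOError",
    "read_map",
    "write_map",
    "read_model",
    "grid_for_resolution",
    "load_vdw_table",
]

logger = logging.getLogger(__name__)


class MapIOError(ValueError):
    """Raised for unreadable, truncated or ill-formed map/model files."""


@dataclass(frozen=True)
class UnitCell:
    """Unit-cell parameters: lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")
        if self.volume <= 0:
            raise ValueError("cell parameters give non-positive volume")

    @property
    def volume(self) -> float:
        """Cell volume in cubic Angstrom."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if arg <= 0:
            return -1.0
        return self.a * self.b * self.c * math.sqrt(arg)

    @property
    def orth_matrix(self) -> np.ndarray:
        """3x3 matrix mapping fractional to orthogonal (Angstrom) coordinates."""
        al, be, ga = (math.radians(x) for x in (self.alpha, self.beta, self.gamma))
        ca, cb, cg, sg = math.cos(al), math.cos(be), math.cos(ga), math.sin(ga)
        v = math.sqrt(1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg)
        return np.array(
            [
                [self.a, self.b * cg, self.c * cb],
                [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
                [0.0, 0.0, self.c * v / sg],
            ]
        )

    @property
    def frac_matrix(self) -> np.ndarray:
        """Inverse of :attr:`orth_matrix` (orthogonal to fractional)."""
        return np.linalg.inv(self.orth_matrix)

    def to_gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    @classmethod
    def from_gemmi(cls, cell: gemmi.UnitCell) -> "UnitCell":
        return cls(cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma)


#: Identity symmetry operator (P1): 3x3 rotation and fractional translation.
IDENTITY_OP = (np.eye(3), np.zeros(3))


@dataclass
class MapGrid:
    """Real-space density sampled on a periodic unit-cell grid.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Density values; ``values[i, j, k]`` sits at fraction (i/nx, j/ny, k/nz).
    cell : UnitCell
    symmetry_ops : list of (rot, tran)
        Fractional-space symmetry operators; defaults to P1.
    spacing_target : float or None
        The Shannon-rate spacing (Angstrom) used to choose the dims, if any.
    """

    values: np.ndarray
    cell: UnitCell
    symmetry_ops: list = field(default_factory=lambda: [IDENTITY_OP])
    spacing_target: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("grid values must be a 3-d array with all dims >= 1")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_voxels(self) -> int:
        return int(self.values.size)

    def standardized(self) -> "MapGrid":
        """Copy with values scaled to zero mean and unit variance."""
        v = self.values.astype(np.float32)
        sd = float(v.std())
        v = (v - v.mean()) / (sd if sd > 0 else 1.0)
        return MapGrid(v, self.cell, list(self.symmetry_ops), self.spacing_target)


@dataclass
class BinaryMask(MapGrid):
    """Per-voxel 0/1 classification: 0 = protein, 1 = solvent."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = np.unique(self.values)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask values must be 0 (protein) or 1 (solvent)")
        self.values = self.values.astype(np.int8)

    @property
    def solvent_fraction(self) -> float:
        return float(self.values.mean())


@dataclass
class ProbabilityGrid(MapGrid):
    """Per-voxel solvent probability in [0, 1]."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")
        self.values = self.values.astype(np.float64)


@dataclass
class AtomicModel:
    """Atoms as (element, orthogonal position in Angstrom, vdW radius)."""

    elements: list[str]
    positions: np.ndarray  # (n_atoms, 3) orthogonal Angstrom
    radii: np.ndarray  # (n_atoms,) Angstrom
    cell: UnitCell

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.radii = np.atleast_1d(np.asarray(self.radii, dtype=float))
        if len(self.elements) and self.radii.min() <= 0:
            raise ValueError("atom radii must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)


def load_vdw_table() -> dict[str, float]:
    """The packaged element -> van der Waals radius table (Angstrom)."""
    text = resources.files("mapseg.data").joinpath("vdw_radii.json").read_text()
    raw = json.loads(text)
    return {k.upper(): float(v) for k, v in raw.items() if not k.startswith("_")}


def _ops_from_spacegroup(sg: gemmi.SpaceGroup | None) -> list:
    if sg is None:
        return [IDENTITY_OP]
    den = float(gemmi.Op.DEN)
    ops = []
    for op in sg.operations():
        ops.append((np.array(op.rot) / den, np.array(op.tran) / den))
    return ops


def read_map(path: str | Path) -> MapGrid:
    """Read a CCP4/MRC volume covering one full unit cell.

    The file's header axis order is honoured and the data are permuted to the
    internal convention (array axis 0 = crystallographic a).
    """
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, SystemError, OSError) as exc:
        raise MapIOError(f"cannot read CCP4/MRC map {path!r}: {exc}") from exc
    try:
        m.setup(float("nan"), gemmi.MapSetup.Full)
    except RuntimeError as exc:
        raise MapIOError(f"cannot regularize map {path!r} to a full cell: {exc}") from exc
    values = np.array(m.grid, copy=True)
    if np.isnan(values).any():
        raise MapIOError(f"map {path!r} does not cover a full unit cell")
    cell = UnitCell.from_gemmi(m.grid.unit_cell)
    ops = _ops_from_spacegroup(m.grid.spacegroup)
    return MapGrid(values, cell, ops)


def write_map(grid: MapGrid, path: str | Path) -> None:
    """Write a grid as a CCP4/MRC volume (mode 2, x fastest).

    Masks are serialized as real-valued 0/1 volumes for maximal downstream
    compatibility.
    """
    g = gemmi.FloatGrid(*grid.dims)
    g.set_unit_cell(grid.cell.to_gemmi())
    g.spacegroup = gemmi.find_spacegroup_by_name("P 1")
    np.array(g, copy=False)[...] = grid.values.astype(np.float32)
    m = gemmi.Ccp4Map()
    m.grid = g
    m.update_ccp4_header()
    try:
        m.write_ccp4_map(str(path))
    except (RuntimeError, OSError) as exc:
        raise MapIOError(f"cannot write map to {path!r}: {exc}") from exc


def read_model(
    path: str | Path,
    radii: dict[str, float] | None = None,
    default_radius: float = 1.8,
) -> AtomicModel:
    """Read a PDB or mmCIF coordinate file into an :class:`AtomicModel`.

    Van der Waals radii are looked up in the packaged table (or a caller
    supplied one); elements missing from the table receive ``default_radius``
    and a warning is logged.
    """
    table = radii if radii is not None else load_vdw_table()
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, SystemError, OSError, ValueError) as exc:
        raise MapIOError(f"cannot read coordinate file {path!r}: {exc}") from exc
    if not st.cell.is_crystal():
        raise MapIOError(f"{path!r} has no unit-cell record")
    elements: list[str] = []
    positions: list[list[float]] = []
    rads: list[float] = []
    for model in st:
        for chain in model:
            for res in chain:
                for atom in res:
                    el = atom.element.name.upper()
                    r = table.get(el)
                    if r is None:
                        logger.warning(
                            "element %s not in vdW table; using default radius %.2f A",
                            el, default_radius,
                        )
                        r = default_radius
                    elements.append(el)
                    positions.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    rads.append(r)
        break  # first model only
    if not elements:
        raise MapIOError(f"{path!r} contains no atoms")
    return AtomicModel(elements, np.array(positions), np.array(rads),
                       UnitCell.from_gemmi(st.cell))


def _smooth235(n: int) -> int:
    """Smallest integer >= n whose prime factors are all in {2, 3, 5}."""
    m = max(int(n), 1)
    while True:
        k = m
        for p in (2, 3, 5):
            while k % p == 0:
                k //= p
        if k == 1:
            return m
        m += 1


def grid_for_resolution(cell: UnitCell, d_high: float) -> tuple[int, int, int]:
    """Grid dims sampling the cell at the Shannon rate for resolution d_high.

    Spacing along each axis is at most ``d_high / 2``; dims are the smallest
    FFT-friendly (2,3,5-smooth) integers meeting that bound.
    """
    if d_high <= 0:
        raise ValueError("d_high must be positive")
    return tuple(
        _smooth235(math.ceil(2.0 * length / d_high))
        for length in (cell.a, cell.b, cell.c)
    )
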