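"""Cubic windows: random sampling with augmentation, tiling, reassembly.

The network consumes fixed-size cubic windows (default edge 48).  Training
windows are cut at uniformly random origins with periodic wrap, so overlaps
are allowed and the cell need not be tiled completely; inference tiles the
cell without overlap except at the far edges when a dimension is not
divisible by the window size, and predictions are averaged where tiles
overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .map_io import BinaryMask, MapGrid, ProbabilityGrid

__all__ = ["Window", "sample_windows", "augment_pair", "tile_map", "reassemble",
           "DEFAULT_WINDOW"]

DEFAULT_WINDOW = 48


@dataclass
class Window:
    """A w^3 block of densities, labels or probabilities cut from a grid."""

    values: np.ndarray
    origin: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("window values must be 3-d")
        if min(self.values.shape) < 8:
            raise ValueError("window edge must be >= 8")

    @property
    def w(self) -> int:
        return self.values.shape[0]

    @property
    def is_cubic(self) -> bool:
        return len(set(self.values.shape)) == 1


def _cut(values: np.ndarray, origin: tuple[int, int, int], w: int) -> np.ndarray:
    """Cut a w^3 block at ``origin`` with periodic wrap."""
    idx = [np.arange(o, o + w) % d for o, d in zip(origin, values.shape)]
    return values[np.ix_(*idx)]


def sample_windows(
    grid: MapGrid,
    mask: BinaryMask,
    n: int,
    seed: int = 0,
    w: int = DEFAULT_WINDOW,
    augment: bool = True,
) -> list[tuple[Window, Window]]:
    """Cut ``n`` random (density, label) window pairs at identical origins.

    Origins are uniform over the full grid (periodic wrap), so overlaps
    between windows are allowed.  When ``augment`` is set each pair is also
    passed through :func:`augment_pair`.  Deterministic given ``seed``.
    """
    if grid.dims != mask.dims:
        raise ValueError(f"map dims {grid.dims} != mask dims {mask.dims}")
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n):
        origin = tuple(int(rng.integers(0, d)) for d in grid.dims)
        pair = (Window(_cut(grid.values, origin, w), origin),
                Window(_cut(mask.values, origin, w), origin))
        if augment:
            pair = augment_pair(pair, int(rng.integers(0, 2**31 - 1)))
        pairs.append(pair)
    return pairs


def _apply_augmentation(values: np.ndarray, flips: tuple[bool, bool, bool],
                        rot: tuple[int, int, int] | None) -> np.ndarray:
    out = values
    flip_axes = [ax for ax, f in enumerate(flips) if f]
    if flip_axes:
        out = np.flip(out, axis=flip_axes)
    if rot is not None:
        k, ax1, ax2 = rot
        out = np.rot90(out, k=k, axes=(ax1, ax2))
    return np.ascontiguousarray(out)


def augment_pair(
    pair: tuple[Window, Window],
    seed: int = 0,
    full_rotation_group: bool = False,
) -> tuple[Window, Window]:
    """Random flips plus one 90-degree rotation, identical on both windows.

    A random subset of the three axes is flipped, then one of seven equally
    likely rotations is applied: the identity or a +/-90 degree turn about
    one of the three axes.  With ``full_rotation_group`` the rotation is
    instead a uniform draw of 0-3 quarter turns about one axis, which
    together with the flips spans the full cubic symmetry group.
    """
    dens, lab = pair
    if not (dens.is_cubic and lab.is_cubic):
        raise ValueError("augmentation requires cubic windows")
    rng = np.random.default_rng(seed)
    flips = tuple(bool(b) for b in rng.integers(0, 2, size=3))
    if full_rotation_group:
        axis = int(rng.integers(0, 3))
        k = int(rng.integers(0, 4))
    else:
        choice = int(rng.integers(0, 7))
        if choice == 0:
            axis, k = 0, 0
        else:
            axis = (choice - 1) // 2
            k = 1 if choice % 2 else 3
    planes = [(1, 2), (0, 2), (0, 1)]
    rot = None if k == 0 else (k, *planes[axis])
    return (
        Window(_apply_augmentation(dens.values, flips, rot), dens.origin),
        Window(_apply_augmentation(lab.values, flips, rot), lab.origin),
    )


def _tile_starts(dim: int, w: int) -> list[int]:
    starts = list(range(0, dim - w + 1, w))
    if starts[-1] + w < dim:
        starts.append(dim - w)  # final edge-aligned window
    return starts


def tile_map(grid: MapGrid, w: int = DEFAULT_WINDOW) -> list[Window]:
    """Cut the grid into non-overlapping w^3 tiles plus edge-aligned extras.

    Origins sit at multiples of ``w``; when a dimension is not divisible by
    ``w`` one extra window with origin ``dim - w`` is added on that axis, so
    every voxel is covered at least once.
    """
    for d in grid.dims:
        if d < w:
            raise ValueError(
                f"grid dim {d} is smaller than the window edge {w}; "
                "regrid the map to at least the window size"
            )
    windows = []
    for i in _tile_starts(grid.dims[0], w):
        for j in _tile_starts(grid.dims[1], w):
            for k in _tile_starts(grid.dims[2], w):
                windows.append(Window(grid.values[i:i + w, j:j + w, k:k + w], (i, j, k)))
    return windows


def reassemble(windows: list[Window], dims: tuple[int, int, int],
               grid_like: MapGrid | None = None) -> ProbabilityGrid:
    """Stitch predicted probability windows back into a full-cell grid.

    Voxels covered by several windows take the mean of the covering values.
    Raises if any voxel is left uncovered.
    """
    acc = np.zeros(dims)
    cnt = np.zeros(dims, dtype=np.int32)
    for win in windows:
        i, j, k = win.origin
        w = win.values.shape
        acc[i:i + w[0], j:j + w[1], k:k + w[2]] += win.values
        cnt[i:i + w[0], j:j + w[1], k:k + w[2]] += 1
    if (cnt == 0).any():
        raise ValueError("windows do not cover every voxel of the grid")
    probs = acc / cnt
    if grid_like is not None:
        return ProbabilityGrid(probs, grid_like.cell, list(grid_like.symmetry_ops))
    from .map_io import UnitCell
    return ProbabilityGrid(probs, UnitCell(1.0, 1.0, 1.0))
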