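"""Colony registration and binned density maps (BDMs).

Colonies are imaged (or generated) at arbitrary positions and orientations;
to pool them, every colony is first registered into the canonical shape
frame (centre at the origin, major axis along +x) by a rigid transform.
Flower petals are additionally rotated so the "inner" tip — the one facing
the flower centre — lands on the −x side, making all four petals of every
flower superimposable.

A BDM is then a 2D histogram, pooled over registered colonies, of where a
given cell class (T⁺, T⁻ or all) sits within the shape; per-bin counts are
normalised by the pooled cell count so fractions sum to one.  No symmetry
folding is applied: one-sided colonies keep their generated side, so maps
pooled over many colonies show both tips even when individual colonies are
one-sided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace
from typing import Sequence

import numpy as np

from .geometry import FlowerLayout, PatternShape, Point
from .synthetic import T_NEG, T_POS, Colony

__all__ = [
    "BinnedDensityMap",
    "RegistrationError",
    "register_colony",
    "register_petal",
    "compute_bdm",
]


class RegistrationError(ValueError):
    """Colony lacks the shape metadata needed to register it."""


def _transform_colony(colony: Colony, new_shape=None) -> Colony:
    """Rigidly map a colony's cells into its canonical frame."""
    shape = colony.shape
    xy = shape.to_canonical(colony.positions())
    cells = colony.cells.copy()
    cells["x_um"] = xy[:, 0]
    cells["y_um"] = xy[:, 1]
    return Colony(
        colony_id=colony.colony_id,
        shape=new_shape if new_shape is not None else shape.canonical(),
        cells=cells,
        metadata=dict(colony.metadata),
        seed=colony.seed,
    )


def register_colony(colony: Colony) -> Colony:
    """Register a colony into the canonical frame.

    Positions are translated so the shape centre maps to the origin and
    rotated so the major axis lies along +x (discs: translation only).
    The transform is rigid — pairwise distances are preserved to machine
    precision — and idempotent on already-canonical colonies.
    """
    if colony.shape is None:
        raise RegistrationError(f"colony {colony.colony_id} has no shape metadata")
    return _transform_colony(colony)


def register_petal(
    flower_colonies: Sequence[Colony],
    petal_index: int,
    layout: FlowerLayout,
    flower_centre: Point | None = None,
) -> Colony:
    """Register one petal of a flower with its inner tip at (−a, 0).

    ``flower_colonies`` are the (up to 4) petal colonies of one flower;
    the petal's own canonical frame is used, flipped by 180° if necessary
    so the tip nearer the flower centre maps to −x, superimposing all
    petals of all flowers.
    """
    if not 0 <= petal_index < layout.n_petals:
        raise IndexError(f"petal index {petal_index} out of range 0..{layout.n_petals - 1}")
    colony = flower_colonies[petal_index]
    shape = colony.shape
    fc = flower_centre or Point(0.0, 0.0)
    a = shape.semi_major
    co, so = math.cos(shape.orientation), math.sin(shape.orientation)
    tip_plus = (shape.centre.x + a * co, shape.centre.y + a * so)
    tip_minus = (shape.centre.x - a * co, shape.centre.y - a * so)
    d_plus = math.hypot(tip_plus[0] - fc.x, tip_plus[1] - fc.y)
    d_minus = math.hypot(tip_minus[0] - fc.x, tip_minus[1] - fc.y)
    registered = _transform_colony(colony)
    if d_plus < d_minus:  # inner tip currently at +x: rotate by 180 degrees
        cells = registered.cells
        cells["x_um"] = -cells["x_um"].to_numpy()
        cells["y_um"] = -cells["y_um"].to_numpy()
    return registered


# ---------------------------------------------------------------------------
# binned density maps


@dataclass
class BinnedDensityMap:
    """Pooled, binned, normalised localisation map of one cell class.

    ``counts[iy, ix]`` is the number of pooled cells in bin (ix, iy) of a
    regular ``bin_size`` µm grid covering the canonical shape bounding box;
    ``fractions`` divides by the pooled total.  Edge bins partially outside
    the shape are reported as-is; ``interior_mask()`` flags bins fully
    inside for statistics that need unbiased per-bin occupancy.
    """

    bin_size: float
    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray  # int, indexed [iy, ix]
    cell_class: str
    shape: PatternShape
    n_cells: int
    n_colonies: int

    @property
    def fractions(self) -> np.ndarray:
        if self.n_cells == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / float(self.n_cells)

    def interior_mask(self, clearance: float = 0.0) -> np.ndarray:
        """Bins whose four corners and centre all lie inside the shape."""
        from .geometry import contains

        ny, nx = self.counts.shape
        mask = np.zeros((ny, nx), dtype=bool)
        for iy in range(ny):
            for ix in range(nx):
                xs = (self.x_edges[ix] + clearance, self.x_edges[ix + 1] - clearance)
                ys = (self.y_edges[iy] + clearance, self.y_edges[iy + 1] - clearance)
                pts = [(x, y) for x in xs for y in ys]
                pts.append(((xs[0] + xs[1]) / 2, (ys[0] + ys[1]) / 2))
                mask[iy, ix] = all(contains(self.shape, Point(x, y)) for x, y in pts)
        return mask

    def add(self, other: "BinnedDensityMap") -> "BinnedDensityMap":
        """Pool two BDMs computed on the same grid (counts add elementwise)."""
        if self.counts.shape != other.counts.shape or self.bin_size != other.bin_size:
            raise ValueError("BDMs must share the same grid to be pooled")
        return dc_replace(
            self,
            counts=self.counts + other.counts,
            n_cells=self.n_cells + other.n_cells,
            n_colonies=self.n_colonies + other.n_colonies,
        )


def _grid_edges(shape: PatternShape, bin_size: float) -> tuple[np.ndarray, np.ndarray]:
    a, b = shape.semi_major, shape.semi_minor
    nx = int(math.ceil(2 * a / bin_size))
    ny = int(math.ceil(2 * b / bin_size))
    x_edges = -0.5 * nx * bin_size + bin_size * np.arange(nx + 1)
    y_edges = -0.5 * ny * bin_size + bin_size * np.arange(ny + 1)
    return x_edges, y_edges


def compute_bdm(
    colonies: Sequence[Colony],
    cell_class: str = "all",
    bin_size_um: float = 10.0,
    label_column: str = "t_label",
) -> BinnedDensityMap:
    """Binned density map of a cell class pooled over registered colonies.

    Colonies must already be in the canonical frame (see
    :func:`register_colony` / :func:`register_petal`).  ``cell_class`` is
    ``'T_pos'``, ``'T_neg'`` or ``'all'``.  Cells falling outside the grid
    (numerically on the boundary) are clipped into the edge bins so the
    fractions always sum to 1.
    """
    if bin_size_um <= 0:
        raise ValueError("bin size must be positive")
    if not colonies:
        raise ValueError("need at least one colony")
    if cell_class not in (T_POS, T_NEG, "all"):
        raise ValueError(f"unknown cell class {cell_class!r}")
    shape = colonies[0].shape.canonical()
    x_edges, y_edges = _grid_edges(shape, bin_size_um)
    counts = np.zeros((len(y_edges) - 1, len(x_edges) - 1), dtype=np.int64)
    n_cells = 0
    for colony in colonies:
        xy = colony.positions()
        if cell_class != "all":
            mask = colony.labels(label_column) == cell_class
            xy = xy[mask]
        if len(xy) == 0:
            continue
        x = np.clip(xy[:, 0], x_edges[0], np.nextafter(x_edges[-1], -np.inf))
        y = np.clip(xy[:, 1], y_edges[0], np.nextafter(y_edges[-1], -np.inf))
        h, _, _ = np.histogram2d(y, x, bins=[y_edges, x_edges])
        counts += h.astype(np.int64)
        n_cells += len(xy)
    return BinnedDensityMap(
        bin_size=bin_size_um,
        x_edges=x_edges,
        y_edges=y_edges,
        counts=counts,
        cell_class=cell_class,
        shape=shape,
        n_cells=n_cells,
        n_colonies=len(colonies),
    )
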