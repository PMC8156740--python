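"""2D binary cell lattice: construction, seeding patterns and neighborhood queries.

The simulated tissue is a rectangular grid of cells, each in one of two
states: 0 (healthy) or 1 (cancerous).  Grids are stored as small-integer
numpy arrays indexed ``(row, column)`` with 0-based coordinates and open
(non-periodic) boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

HEALTHY = 0
CANCER = 1

__all__ = [
    "HEALTHY",
    "CANCER",
    "CellGrid",
    "SeedSpec",
    "make_grid",
    "seed_grid",
    "neighbors4",
    "cancer_fraction",
    "grid_from_array",
]


@dataclass
class CellGrid:
    """A height x width lattice of binary cell states.

    ``states`` is an int8 array; entry 1 marks a cancerous cell, 0 a
    healthy one.
    """

    states: np.ndarray

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.ndim != 2:
            raise ValueError("cell grid must be a 2D array")
        if not np.isin(self.states, (0, 1)).all():
            raise ValueError("cell states must be 0 (healthy) or 1 (cancer)")

    @property
    def height(self) -> int:
        return self.states.shape[0]

    @property
    def width(self) -> int:
        return self.states.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.states.shape

    @property
    def n_sites(self) -> int:
        return self.states.size

    def cancer_count(self) -> int:
        return int(self.states.sum())

    def copy(self) -> "CellGrid":
        return CellGrid(self.states.copy())

    def sites(self) -> Iterator[tuple[int, int]]:
        h, w = self.shape
        return ((i, j) for i in range(h) for j in range(w))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CellGrid):
            return NotImplemented
        return self.shape == other.shape and bool((self.states == other.states).all())


@dataclass
class SeedSpec:
    """How to place the initial cancerous cells on an otherwise healthy grid.

    pattern
        ``single_center`` — one cancer cell at the grid center.
        ``block`` — a solid rectangle at ``origin`` with ``extent`` (h, w).
        ``blob`` — a 4-connected cluster of exactly ``count`` cells grown
        from the center by breadth-first accretion.
    """

    pattern: str = "single_center"
    count: int = 1
    origin: tuple[int, int] = (0, 0)
    extent: tuple[int, int] = (1, 1)

    _PATTERNS = ("single_center", "block", "blob")

    def __post_init__(self) -> None:
        if self.pattern not in self._PATTERNS:
            raise ValueError(
                f"unknown seed pattern {self.pattern!r}; expected one of {self._PATTERNS}"
            )


def make_grid(height: int, width: int, fill: int = HEALTHY) -> CellGrid:
    """Create a uniformly filled grid.

    Both dimensions must be at least 2: the cluster-variation machinery
    needs at least one full unit square of the lattice.
    """
    if height < 2 or width < 2:
        raise ValueError(f"grid must be at least 2x2, got {height}x{width}")
    if fill not in (HEALTHY, CANCER):
        raise ValueError(f"fill state must be 0 or 1, got {fill!r}")
    return CellGrid(np.full((height, width), fill, dtype=np.int8))


def grid_from_array(states: np.ndarray) -> CellGrid:
    """Wrap an existing 0/1 array as a grid (validated, copied)."""
    return CellGrid(np.array(states, dtype=np.int8, copy=True))


def _blob_sites(shape: tuple[int, int], count: int) -> np.ndarray:
    """Sites of a center-grown blob: the first ``count`` sites ordered by
    Manhattan distance from the grid center, row-major within each ring.

    A distance-ordered prefix is always 4-connected (every site at distance
    d has a neighbor at distance d-1 already included), so the blob is a
    single connected cluster of exactly ``count`` sites.
    """
    h, w = shape
    ci, cj = h // 2, w // 2
    ii, jj = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    dist = np.abs(ii - ci) + np.abs(jj - cj)
    order = np.lexsort((jj.ravel(), ii.ravel(), dist.ravel()))
    return order[:count]


def seed_grid(grid: CellGrid, spec: SeedSpec, rng: np.random.Generator | None = None) -> CellGrid:
    """Return a copy of ``grid`` with cancer cells placed per ``spec``.

    All three patterns are deterministic; ``rng`` is accepted for interface
    uniformity with stochastic seeding variants but is not consumed.
    """
    out = grid.copy()
    h, w = out.shape
    if spec.pattern == "single_center":
        out.states[h // 2, w // 2] = CANCER
    elif spec.pattern == "block":
        (r0, c0), (bh, bw) = spec.origin, spec.extent
        if r0 < 0 or c0 < 0 or r0 + bh > h or c0 + bw > w or bh < 1 or bw < 1:
            raise ValueError(f"block {spec.origin}+{spec.extent} does not fit in {h}x{w} grid")
        out.states[r0 : r0 + bh, c0 : c0 + bw] = CANCER
    elif spec.pattern == "blob":
        if not 1 <= spec.count <= out.n_sites:
            raise ValueError(f"blob count {spec.count} outside [1, {out.n_sites}]")
        flat = out.states.ravel()
        flat[_blob_sites(out.shape, spec.count)] = CANCER
    return out


def neighbors4(grid: CellGrid, site: tuple[int, int]) -> list[tuple[int, int]]:
    """Orthogonally adjacent in-bounds sites of ``site`` (2-4 of them)."""
    i, j = site
    h, w = grid.shape
    if not (0 <= i < h and 0 <= j < w):
        raise ValueError(f"site {site} outside {h}x{w} grid")
    out = []
    for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        ni, nj = i + di, j + dj
        if 0 <= ni < h and 0 <= nj < w:
            out.append((ni, nj))
    return out


def cancer_fraction(grid: CellGrid) -> float:
    """Proportion of cancerous sites, in [0, 1]."""
    return grid.cancer_count() / grid.n_sites
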