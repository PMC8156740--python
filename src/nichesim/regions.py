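"""Region graphs for the cluster variation method on the 2D lattice.

A region is a set of lattice sites.  For approximation order ``d`` the base
regions are:

* ``d=1`` — single sites (the mean-field limit);
* ``d=2`` — nearest-neighbor pairs (the Bethe approximation);
* ``d=3`` — right-angle triangles, two per unit square of the lattice
  (the B3 cluster of the Kikuchi-Brush hierarchy), sharing the square's
  anti-diagonal;
* ``full`` — a single region containing every site (the exact limit).

The region set is closed under pairwise intersection (intersections,
intersections of intersections, ...), and each region r carries a Möbius
overcounting number

    c_r = 1 - sum of c_s over all strict super-regions s of r,

which corrects the regional free-energy sum for overlap.  For any of the
supported orders the numbers satisfy the exact-counting condition
``sum over regions containing site i of c_r == 1`` at every site, so the
approximation is exact for independent sites.

Only fully in-bounds clusters are regions (open boundaries); boundary
sites simply have fewer super-regions and the Möbius recursion restores
exact counting automatically.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Region",
    "RegionGraph",
    "build_region_graph",
    "counting_numbers",
    "shape_key",
]

SUPPORTED_ORDERS = (1, 2, 3, "full")

# shape keys (site offsets relative to the cluster's bounding-box corner)
SITE = ((0, 0),)
HPAIR = ((0, 0), (0, 1))
VPAIR = ((0, 0), (1, 0))
ADIAG = ((0, 1), (1, 0))
TRI_UP = ((0, 0), (0, 1), (1, 0))  # corner at top-left of the unit square
TRI_LO = ((0, 1), (1, 0), (1, 1))  # corner at bottom-right


@dataclass(frozen=True)
class Region:
    """An immutable region: its sites (sorted), closure level and c-number.

    ``level`` 0 marks a base cluster; level k > 0 a k-th order
    intersection.
    """

    sites: tuple[tuple[int, int], ...]
    level: int
    counting: int

    @property
    def size(self) -> int:
        return len(self.sites)

    @property
    def shape(self) -> tuple[tuple[int, int], ...]:
        return shape_key(self.sites)


def shape_key(sites: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Canonical translation-invariant shape of a site set.

    Offsets are taken from the bounding-box corner and sorted row-major, so
    every translated instance of the same cluster shape maps to one key.
    """
    pts = sorted(sites)
    i0 = min(p[0] for p in pts)
    j0 = min(p[1] for p in pts)
    return tuple((i - i0, j - j0) for i, j in pts)


class RegionGraph:
    """Regions, containment structure and Möbius counting numbers.

    Internally regions are frozensets of flat site indices ``i*W + j``;
    the public accessors translate back to ``(i, j)`` coordinates.
    """

    def __init__(
        self,
        grid_shape: tuple[int, int],
        order_d: int | str,
        regions: dict[frozenset, int],
        supersets: dict[frozenset, list[frozenset]],
        counting: dict[frozenset, int],
    ):
        self.grid_shape = tuple(grid_shape)
        self.order_d = order_d
        self._regions = regions  # frozenset -> closure level
        self._supersets = supersets
        self._counting = counting

    # -- basic accessors ----------------------------------------------------

    def __len__(self) -> int:
        return len(self._regions)

    def _unflatten(self, fs: frozenset) -> tuple[tuple[int, int], ...]:
        w = self.grid_shape[1]
        return tuple(sorted((s // w, s % w) for s in fs))

    def regions(self) -> list[Region]:
        """All regions as sorted, immutable records."""
        out = [
            Region(self._unflatten(fs), lvl, self._counting[fs])
            for fs, lvl in self._regions.items()
        ]
        out.sort(key=lambda r: (-r.size, r.sites))
        return out

    def counting_of(self, sites: Iterable[tuple[int, int]]) -> int:
        w = self.grid_shape[1]
        fs = frozenset(i * w + j for i, j in sites)
        return self._counting[fs]

    def __contains__(self, sites) -> bool:
        w = self.grid_shape[1]
        return frozenset(i * w + j for i, j in sites) in self._regions

    # -- aggregates used by the energy evaluators ---------------------------

    def class_weights(self) -> dict[tuple, int]:
        """Total counting number per region-shape class.

        Under the translation-homogeneity treatment of the marginals, the
        CVM entropy is ``sum over classes of weight * S(class table)``, so
        these integer weights are all the evaluator needs from the graph.
        """
        w = self.grid_shape[1]
        out: dict[tuple, int] = defaultdict(int)
        for fs in self._regions:
            key = shape_key((s // w, s % w) for s in fs)
            out[key] += self._counting[fs]
        return dict(out)

    def site_counting_sums(self) -> np.ndarray:
        """Per-site sum of counting numbers over regions containing it.

        Equals 1 everywhere when the exact-counting condition holds.
        """
        h, wd = self.grid_shape
        sums = np.zeros(h * wd, dtype=np.int64)
        for fs, _ in self._regions.items():
            c = self._counting[fs]
            for s in fs:
                sums[s] += c
        return sums.reshape(h, wd)


def _base_regions(grid_shape: tuple[int, int], order_d) -> list[frozenset]:
    h, w = grid_shape
    if order_d == "full":
        return [frozenset(range(h * w))]
    if order_d == 1:
        return [frozenset((i * w + j,)) for i in range(h) for j in range(w)]
    if order_d == 2:
        pairs = []
        for i in range(h):
            for j in range(w - 1):
                pairs.append(frozenset((i * w + j, i * w + j + 1)))
        for i in range(h - 1):
            for j in range(w):
                pairs.append(frozenset((i * w + j, (i + 1) * w + j)))
        return pairs
    if order_d == 3:
        tris = []
        for i in range(h - 1):
            for j in range(w - 1):
                tl, tr = i * w + j, i * w + j + 1
                bl, br = (i + 1) * w + j, (i + 1) * w + j + 1
                tris.append(frozenset((tl, tr, bl)))
                tris.append(frozenset((tr, bl, br)))
        return tris
    raise ValueError(f"unsupported approximation order {order_d!r}; expected 1, 2, 3 or 'full'")


def _intersection_closure(base: list[frozenset]) -> dict[frozenset, int]:
    """Close the base-region set under pairwise intersection.

    Returns region -> closure level (0 for base regions).  Candidate pairs
    are restricted to regions sharing at least one site, which keeps the
    construction near-linear on the lattice.
    """
    regions: dict[frozenset, int] = {r: 0 for r in base}
    frontier = list(dict.fromkeys(base))
    level = 0
    while frontier:
        level += 1
        site_index: dict[int, list[frozenset]] = defaultdict(list)
        for r in regions:
            for s in r:
                site_index[s].append(r)
        new: set[frozenset] = set()
        for r in frontier:
            cands: set[frozenset] = set()
            for s in r:
                cands.update(site_index[s])
            cands.discard(r)
            for c in cands:
                inter = r & c
                if inter and inter != r and inter != c and inter not in regions:
                    new.add(inter)
        for r in new:
            regions[r] = level
        frontier = list(new)
    return regions


def _superset_map(regions: Mapping[frozenset, int]) -> dict[frozenset, list[frozenset]]:
    site_index: dict[int, list[frozenset]] = defaultdict(list)
    for r in regions:
        for s in r:
            site_index[s].append(r)
    supers: dict[frozenset, list[frozenset]] = {}
    for r in regions:
        anchor = next(iter(r))
        supers[r] = [c for c in site_index[anchor] if len(c) > len(r) and r < c]
    return supers


def _mobius_counting(
    regions: Mapping[frozenset, int],
    supersets: Mapping[frozenset, list[frozenset]],
) -> dict[frozenset, int]:
    counting: dict[frozenset, int] = {}
    for r in sorted(regions, key=len, reverse=True):
        counting[r] = 1 - sum(counting[s] for s in supersets[r])
    return counting


@lru_cache(maxsize=16)
def _build_cached(grid_shape: tuple[int, int], order_d) -> RegionGraph:
    base = _base_regions(grid_shape, order_d)
    regions = _intersection_closure(base)
    supersets = _superset_map(regions)
    counting = _mobius_counting(regions, supersets)
    graph = RegionGraph(grid_shape, order_d, regions, supersets, counting)
    sums = graph.site_counting_sums()
    if not (sums == 1).all():
        raise RuntimeError(
            "internal error: exact-counting condition violated "
            f"for shape {grid_shape}, order {order_d}"
        )
    return graph


def build_region_graph(grid_shape: tuple[int, int], order_d: int | str) -> RegionGraph:
    """Build the region graph for a lattice shape at the given order.

    ``order_d`` is 1, 2, 3 or ``"full"``.  Graphs are cached per
    (shape, order): they depend only on the lattice geometry, not on the
    cell states.
    """
    h, w = grid_shape
    if h < 2 or w < 2:
        raise ValueError(f"lattice must be at least 2x2, got {h}x{w}")
    if order_d not in SUPPORTED_ORDERS:
        raise ValueError(f"unsupported approximation order {order_d!r}; expected 1, 2, 3 or 'full'")
    return _build_cached((int(h), int(w)), order_d)


def counting_numbers(region_graph: RegionGraph) -> dict[tuple[tuple[int, int], ...], int]:
    """Recompute Möbius counting numbers from the containment structure.

    Returns a map from the region's sorted site tuple to its integer c_r.
    Raises if the stored superset map is inconsistent with set inclusion.
    """
    for r, sups in region_graph._supersets.items():
        for s in sups:
            if not r < s:
                raise ValueError("inconsistent containment: stored super-region is not a superset")
    counting = _mobius_counting(region_graph._regions, region_graph._supersets)
    return {region_graph._unflatten(fs): c for fs, c in counting.items()}
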