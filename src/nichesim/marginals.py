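"""Empirical cluster marginals under translation homogeneity.

For each region-shape class (site, pair by orientation, triangle by
orientation, ...) a single probability table over the 2^k binary
configurations of the k-site cluster is estimated as the relative
frequency of each configuration across *all* fully in-bounds translated
placements of that shape on the grid.  One table per shape class — not one
per region instance — is the classical cluster-variation treatment: it
makes entropy and interaction energy well-defined lattice totals and keeps
every evaluation O(N).

Configuration indexing: a shape is its sorted offset tuple (see
:func:`nichesim.regions.shape_key`); bit ``k`` of a configuration code is
the state of the shape's k-th offset, least significant bit first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .lattice import CellGrid, cancer_fraction
from .regions import HPAIR, SITE, VPAIR, RegionGraph, shape_key

__all__ = [
    "ClusterMarginals",
    "empirical_marginals",
    "meanfield_marginal",
    "product_marginals",
    "n_placements",
    "config_codes",
    "marginalize_table",
]

#: largest cluster size for which tables are stored densely
_MAX_DENSE = 16

ShapeKey = tuple[tuple[int, int], ...]
Table = np.ndarray | dict  # dense over 2^k configs, or sparse {code: prob}


def n_placements(grid_shape: tuple[int, int], shape: ShapeKey) -> int:
    """Number of fully in-bounds translated placements of ``shape``."""
    h, w = grid_shape
    mi = max(di for di, _ in shape)
    mj = max(dj for _, dj in shape)
    return max(0, h - mi) * max(0, w - mj)


def config_codes(states: np.ndarray, shape: ShapeKey) -> np.ndarray:
    """Configuration code of every placement of ``shape`` on ``states``.

    Returns an array of shape ``(H - max_di, W - max_dj)`` whose entry at
    (i, j) encodes the cluster configuration anchored at (i, j).
    """
    h, w = states.shape
    mi = max(di for di, _ in shape)
    mj = max(dj for _, dj in shape)
    h2, w2 = h - mi, w - mj
    codes = np.zeros((h2, w2), dtype=np.int64)
    for k, (di, dj) in enumerate(shape):
        codes += states[di : di + h2, dj : dj + w2].astype(np.int64) << k
    return codes


@dataclass
class ClusterMarginals:
    """Per-shape-class probability tables estimated from a grid.

    ``tables`` maps a shape key to a dense probability vector of length
    2^k (or, for clusters too large to enumerate, a sparse ``{code:
    prob}`` dict).  ``counts`` holds the raw placement counts behind each
    table and ``n_instances`` the number of placements.
    """

    order_d: int | str
    tables: dict[ShapeKey, Table]
    counts: dict[ShapeKey, Table] = field(default_factory=dict)
    n_instances: dict[ShapeKey, int] = field(default_factory=dict)

    def table(self, shape: ShapeKey) -> Table:
        return self.tables[shape]

    def validate(self, atol: float = 1e-12) -> None:
        """Check normalisation and range of every table."""
        for shape, t in self.tables.items():
            vals = t if isinstance(t, np.ndarray) else np.array(list(t.values()))
            if not np.isclose(vals.sum(), 1.0, atol=atol):
                raise ValueError(f"table for shape {shape} sums to {vals.sum()}, not 1")
            if (vals < -atol).any() or (vals > 1 + atol).any():
                raise ValueError(f"table for shape {shape} has probabilities outside [0, 1]")


def empirical_marginals(
    grid: CellGrid,
    region_graph: RegionGraph,
    pseudo_count: float = 0.0,
) -> ClusterMarginals:
    """Estimate cluster marginals for every shape class of ``region_graph``.

    Site and nearest-neighbor pair tables are always included (the
    interaction energy needs pair tables at every order).  Configurations
    never observed get probability 0; ``pseudo_count`` adds a uniform
    additive count for smoothing experiments (off by default, so small
    worked examples stay exact).
    """
    if region_graph.grid_shape != grid.shape:
        raise ValueError(
            f"region graph built for {region_graph.grid_shape}, grid is {grid.shape}"
        )
    shapes = set(region_graph.class_weights()) | {SITE, HPAIR, VPAIR}
    tables: dict[ShapeKey, Table] = {}
    counts: dict[ShapeKey, Table] = {}
    n_inst: dict[ShapeKey, int] = {}
    for shape in shapes:
        k = len(shape)
        if k <= _MAX_DENSE:
            codes = config_codes(grid.states, shape)
            cnt = np.bincount(codes.ravel(), minlength=2**k).astype(np.float64)
            cnt += pseudo_count
            tables[shape] = cnt / cnt.sum()
            counts[shape] = cnt
            n_inst[shape] = codes.size
        else:
            # a cluster this large has a single placement: the whole grid
            code = sum(
                int(grid.states[di, dj]) << idx for idx, (di, dj) in enumerate(shape)
            )
            tables[shape] = {code: 1.0}
            counts[shape] = {code: 1.0}
            n_inst[shape] = 1
    return ClusterMarginals(region_graph.order_d, tables, counts, n_inst)


def meanfield_marginal(grid: CellGrid) -> np.ndarray:
    """Shared single-site marginal ``[Q(0), Q(1)]`` of the mean-field family.

    ``Q(1)`` is the grid's cancer fraction.
    """
    p = cancer_fraction(grid)
    return np.array([1.0 - p, p])


def product_marginals(region_graph: RegionGraph, p: float) -> ClusterMarginals:
    """Independent-site (product-form) tables at cancer density ``p``.

    Every shape class of the region graph gets the table
    ``Q(cfg) = prod_k p^{bit_k} (1-p)^{1-bit_k}``.  Used to probe the
    exact-counting condition: for these tables the CVM entropy at any
    order equals the site-entropy total.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"density must be in [0, 1], got {p}")
    shapes = set(region_graph.class_weights()) | {SITE, HPAIR, VPAIR}
    tables: dict[ShapeKey, Table] = {}
    for shape in shapes:
        k = len(shape)
        if k > _MAX_DENSE:
            raise ValueError("product tables not supported for clusters larger than 16 sites")
        cfgs = np.arange(2**k)
        ones = np.array([bin(c).count("1") for c in cfgs])
        tables[shape] = (p**ones) * ((1 - p) ** (k - ones))
    return ClusterMarginals(region_graph.order_d, tables)


def marginalize_table(table: np.ndarray, shape: ShapeKey, drop: int) -> tuple[np.ndarray, ShapeKey]:
    """Sum a dense cluster table over the site at offset index ``drop``.

    Returns the reduced table together with its canonical shape key; the
    reduced table's bit order follows the canonical (re-sorted, re-anchored)
    offsets of the remaining sites.
    """
    k = len(shape)
    if not 0 <= drop < k:
        raise ValueError(f"drop index {drop} outside shape of size {k}")
    kept = [off for idx, off in enumerate(shape) if idx != drop]
    new_shape = shape_key(kept)
    # map each kept offset (in original order) to its bit in the new shape
    i0 = min(i for i, _ in kept)
    j0 = min(j for _, j in kept)
    renorm = [(i - i0, j - j0) for i, j in kept]
    bit_in_new = [new_shape.index(off) for off in renorm]
    out = np.zeros(2 ** (k - 1))
    kept_idx = [idx for idx in range(k) if idx != drop]
    for cfg in range(2**k):
        new_cfg = 0
        for pos, idx in enumerate(kept_idx):
            new_cfg |= ((cfg >> idx) & 1) << bit_in_new[pos]
        out[new_cfg] += table[cfg]
    return out, new_shape
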