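"""Free-energy evaluation: interaction energy, CVM entropy, mean-field and
exact (brute-force) references.

All free energies are Helmholtz-style lattice totals in natural units
(natural logarithms) at unit inverse temperature:

    F = U - S

where U is the internal (interaction) energy and S the entropy.  The
Hamiltonian is a nearest-neighbor pair sum with the convention

    u(1, 1) = -eps_in,   u(0, 0) = u(0, 1) = u(1, 0) = 0,

so a positive interaction parameter eps_in lowers the energy of
cancer-cancer contacts (favouring aggregation) and a negative one
penalises them (favouring mixed or healthy contacts).  The activation
energy is fixed at 0.

The CVM (Kikuchi) entropy is the counting-number-weighted sum of regional
entropies; under translation homogeneity it reduces to a sum over shape
classes of ``class weight x table entropy``.  Order 1 is the mean-field
limit, order 2 the Bethe approximation, order 3 the triangle (B3)
approximation used by the niche simulations, and order "full" the exact
entropy of the supplied full-configuration distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.special import logsumexp, xlogy

from .lattice import CellGrid, cancer_fraction
from .marginals import (
    ClusterMarginals,
    config_codes,
    empirical_marginals,
    n_placements,
)
from .regions import HPAIR, SITE, VPAIR, RegionGraph, build_region_graph

__all__ = [
    "FreeEnergyReport",
    "PairEnergyConvention",
    "interaction_energy",
    "entropy_cvm",
    "free_energy",
    "meanfield_free_energy",
    "exact_free_energy",
    "exact_state_energies",
    "exact_entropy",
    "variational_free_energy",
    "lattice_hamiltonian",
    "n_neighbor_pairs",
    "KikuchiEvaluator",
]

_MAX_EXACT_SITES = 16
_MAX_DENSE = 16


@dataclass(frozen=True)
class PairEnergyConvention:
    """Pairwise energies as a function of the interaction parameter."""

    eps_in: float

    @property
    def u11(self) -> float:
        return -self.eps_in

    u00 = u01 = u10 = 0.0

    def pair_table(self) -> np.ndarray:
        """Energy per pair configuration code (bit 0: first site, bit 1: second)."""
        u = np.zeros(4)
        u[3] = self.u11
        return u


@dataclass(frozen=True)
class FreeEnergyReport:
    """Internal energy, entropy and their difference, as lattice totals."""

    order_d: int | str
    internal_energy: float
    entropy: float
    interaction_param: float

    @property
    def free_energy(self) -> float:
        return self.internal_energy - self.entropy


def n_neighbor_pairs(grid_shape: tuple[int, int]) -> int:
    """Number of nearest-neighbor pairs on an open H x W lattice."""
    h, w = grid_shape
    return h * (w - 1) + (h - 1) * w


def _table_entropy(table) -> float:
    """-sum p ln p with 0 ln 0 = 0, for dense arrays or sparse dicts."""
    vals = table if isinstance(table, np.ndarray) else np.array(list(table.values()))
    return float(-xlogy(vals, vals).sum())


def interaction_energy(
    marginals: ClusterMarginals,
    convention: PairEnergyConvention,
    grid_shape: tuple[int, int],
) -> float:
    """Total interaction energy from the nearest-neighbor pair tables.

    U = sum over pair placements of the expected pair energy.  When the
    tables are empirical this equals the direct lattice sum of pair
    energies exactly.
    """
    u = convention.pair_table()
    total = 0.0
    for shape in (HPAIR, VPAIR):
        table = marginals.table(shape)
        total += n_placements(grid_shape, shape) * float(table @ u)
    return total


def entropy_cvm(marginals: ClusterMarginals, region_graph: RegionGraph) -> float:
    """CVM entropy: counting-weighted regional entropies, by shape class."""
    if marginals.order_d != region_graph.order_d:
        raise ValueError(
            f"marginals built at order {marginals.order_d!r}, "
            f"region graph at order {region_graph.order_d!r}"
        )
    total = 0.0
    for shape, weight in region_graph.class_weights().items():
        total += weight * _table_entropy(marginals.table(shape))
    return total


def meanfield_free_energy(
    grid_shape: tuple[int, int], cancer_count: int, eps_in: float
) -> FreeEnergyReport:
    """Mean-field free energy of a grid summarised by its cancer count.

    Under the fully factorised family with shared site marginal
    Q(1) = p, the pair expectation is the product form -eps_in p^2 and the
    entropy is N times the binary entropy of p.
    """
    n = grid_shape[0] * grid_shape[1]
    p = cancer_count / n
    u = n_neighbor_pairs(grid_shape) * (-eps_in * p * p)
    s = n * float(-xlogy(p, p) - xlogy(1 - p, 1 - p))
    return FreeEnergyReport(1, u, s, eps_in)


def free_energy(
    grid: CellGrid,
    order_d: int | str,
    eps_in: float,
    region_graph: RegionGraph | None = None,
) -> FreeEnergyReport:
    """Free energy of a grid configuration at the requested order.

    Order 1 evaluates the mean-field expression; orders 2, 3 and "full"
    evaluate interaction energy and CVM entropy from empirical cluster
    marginals.
    """
    if order_d == 1:
        return meanfield_free_energy(grid.shape, grid.cancer_count(), eps_in)
    rg = region_graph if region_graph is not None else build_region_graph(grid.shape, order_d)
    marg = empirical_marginals(grid, rg)
    u = interaction_energy(marg, PairEnergyConvention(eps_in), grid.shape)
    s = entropy_cvm(marg, rg)
    return FreeEnergyReport(order_d, u, s, eps_in)


# ---------------------------------------------------------------------------
# exact (brute-force) oracle for tiny lattices
# ---------------------------------------------------------------------------


def exact_state_energies(grid_shape: tuple[int, int], eps_in: float) -> np.ndarray:
    """Hamiltonian of all 2^N configurations of a tiny lattice.

    Configuration ``x`` is encoded row-major: bit ``i*W + j`` is the state
    of site (i, j).  H(x) = -eps_in times the number of cancer-cancer
    nearest-neighbor contacts.
    """
    h, w = grid_shape
    n = h * w
    if n > _MAX_EXACT_SITES:
        raise ValueError(f"exact enumeration limited to {_MAX_EXACT_SITES} sites, got {n}")
    codes = np.arange(2**n, dtype=np.int64)
    bits = ((codes[:, None] >> np.arange(n)) & 1).reshape(-1, h, w)
    contacts = (bits[:, :, :-1] * bits[:, :, 1:]).sum(axis=(1, 2))
    contacts += (bits[:, :-1, :] * bits[:, 1:, :]).sum(axis=(1, 2))
    return -eps_in * contacts.astype(np.float64)


def lattice_hamiltonian(grid: CellGrid, eps_in: float) -> float:
    """Direct pair-energy sum of one configuration (the exact U of a grid)."""
    s = grid.states.astype(np.int64)
    contacts = int((s[:, :-1] * s[:, 1:]).sum() + (s[:-1, :] * s[1:, :]).sum())
    return -eps_in * contacts


def exact_free_energy(grid_shape: tuple[int, int], eps_in: float, beta: float = 1.0) -> float:
    """Helmholtz free energy -ln Z by enumeration of all 2^N states."""
    energies = exact_state_energies(grid_shape, eps_in)
    return float(-logsumexp(-beta * energies))


def exact_entropy(q: np.ndarray) -> float:
    """Shannon entropy (nats) of an explicit distribution over states."""
    q = np.asarray(q, dtype=np.float64)
    return float(-xlogy(q, q).sum())


def variational_free_energy(
    q: np.ndarray, grid_shape: tuple[int, int], eps_in: float, beta: float = 1.0
) -> float:
    """U(Q) - S(Q) for an explicit distribution Q over all 2^N states.

    Always an upper bound on ``exact_free_energy`` (the gap is the KL
    divergence from Q to the Boltzmann distribution).
    """
    q = np.asarray(q, dtype=np.float64)
    energies = exact_state_energies(grid_shape, eps_in)
    if q.shape != energies.shape:
        raise ValueError(f"Q must have {energies.size} entries for shape {grid_shape}")
    return float(beta * (q @ energies)) - exact_entropy(q)


# ---------------------------------------------------------------------------
# incremental evaluator for the dynamics
# ---------------------------------------------------------------------------


class KikuchiEvaluator:
    """Maintains per-class configuration counts so that single-site flips
    update the free energy in O(1) lattice-independent work.

    The evaluator owns a mutable copy of the grid; :meth:`flip` toggles one
    site and updates every covering cluster's count (decrement the old
    configuration, increment the new), after which the free energy is
    recomputed from the small per-class tables.  A rejected flip is undone
    by flipping the same site again — counts are integers, so the state is
    restored exactly.
    """

    def __init__(
        self,
        grid: CellGrid,
        order_d: int | str = 3,
        eps_in: float = 0.0,
        region_graph: RegionGraph | None = None,
    ):
        self.grid = grid.copy()
        self.eps_in = float(eps_in)
        self.region_graph = (
            region_graph if region_graph is not None else build_region_graph(grid.shape, order_d)
        )
        if self.region_graph.grid_shape != grid.shape:
            raise ValueError("region graph shape does not match grid shape")
        self.order_d = self.region_graph.order_d
        weights = self.region_graph.class_weights()
        # dense shape classes; clusters too large to enumerate are point
        # masses with zero empirical entropy, so they never contribute
        self._shapes = sorted(
            (s for s in set(weights) | {SITE, HPAIR, VPAIR} if len(s) <= _MAX_DENSE),
            key=lambda s: (len(s), s),
        )
        self._weights = {s: weights.get(s, 0) for s in self._shapes}
        self._counts: dict[tuple, np.ndarray] = {}
        self._geom: dict[tuple, tuple[int, int, int, int]] = {}
        h, w = grid.shape
        for shape in self._shapes:
            codes = config_codes(self.grid.states, shape)
            self._counts[shape] = np.bincount(codes.ravel(), minlength=2 ** len(shape)).astype(
                np.int64
            )
            mi = max(di for di, _ in shape)
            mj = max(dj for _, dj in shape)
            self._geom[shape] = (mi, mj, h - mi, w - mj)
        self._pair_u = PairEnergyConvention(eps_in).pair_table()
        self._cancer = self.grid.cancer_count()

    @property
    def cancer_count(self) -> int:
        return self._cancer

    def internal_energy(self) -> float:
        total = 0.0
        for shape in (HPAIR, VPAIR):
            total += float(self._counts[shape] @ self._pair_u)
        return total

    def entropy(self) -> float:
        total = 0.0
        for shape in self._shapes:
            weight = self._weights[shape]
            if weight == 0:
                continue
            cnt = self._counts[shape]
            table = cnt / cnt.sum()
            total += weight * _table_entropy(table)
        return total

    def report(self) -> FreeEnergyReport:
        return FreeEnergyReport(self.order_d, self.internal_energy(), self.entropy(), self.eps_in)

    def free_energy(self) -> float:
        return self.internal_energy() - self.entropy()

    def flip(self, site: tuple[int, int]) -> None:
        """Toggle one site, updating all covering cluster counts."""
        i, j = site
        s = self.grid.states
        h, w = s.shape
        if not (0 <= i < h and 0 <= j < w):
            raise ValueError(f"site {site} outside {h}x{w} grid")
        for shape in self._shapes:
            mi, mj, hh, ww = self._geom[shape]
            cnt = self._counts[shape]
            for k, (di, dj) in enumerate(shape):
                oi, oj = i - di, j - dj
                if 0 <= oi < hh and 0 <= oj < ww:
                    code = 0
                    for k2, (d2i, d2j) in enumerate(shape):
                        code |= int(s[oi + d2i, oj + d2j]) << k2
                    cnt[code] -= 1
                    cnt[code ^ (1 << k)] += 1
        self._cancer += 1 if s[i, j] == 0 else -1
        s[i, j] ^= 1

    def delta_if_flipped(self, site: tuple[int, int]) -> float:
        """Free-energy change from flipping ``site``, leaving state unchanged."""
        f0 = self.free_energy()
        self.flip(site)
        f1 = self.free_energy()
        self.flip(site)
        return f1 - f0
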