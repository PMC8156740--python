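"""Greedy free-energy-descent dynamics of the cell lattice.

Each trial proposes ``J = max(1, round(alpha/100 * N))`` single-site state
changes toward the target state set by the tolerance (cancerous if
``tol > 0.5``, healthy otherwise).  Proposal sites are drawn either from
the border of the existing target-state cluster (LOCAL) or uniformly over
all flippable sites (GLOBAL); the noise parameter controls the mix.  A
proposed flip is retained only if it does not increase the overall Kikuchi
free energy and does not push the cancer fraction above the tolerance cap;
otherwise it is reverted.  The recorded free-energy sequence is therefore
non-increasing within a run.

Randomness: one generator drives the whole run; each flip consumes a
proposal-type draw followed by a site draw, so fixed seeds give bitwise
reproducible trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Union

import numpy as np
from scipy import ndimage

from .energy import FreeEnergyReport, KikuchiEvaluator, meanfield_free_energy
from .lattice import CANCER, HEALTHY, CellGrid
from .regions import RegionGraph

__all__ = [
    "Schedule",
    "SimParams",
    "TrialRecord",
    "Trajectory",
    "SaturationError",
    "flips_per_trial",
    "target_state",
    "propose_site",
    "accept_flip",
    "run_trial",
    "run_simulation",
]


class SaturationError(RuntimeError):
    """Raised when no site can move toward the target state."""


@dataclass(frozen=True)
class Schedule:
    """Linear ramp from ``start`` (trial 0) to ``end`` (last trial)."""

    start: float
    end: float
    kind: str = "linear"

    def __post_init__(self) -> None:
        if self.kind != "linear":
            raise ValueError(f"unsupported schedule kind {self.kind!r}")

    def value(self, trial: int, n_trials: int) -> float:
        if n_trials <= 1:
            return self.start
        frac = trial / (n_trials - 1)
        return self.start + (self.end - self.start) * frac


ParamOrSchedule = Union[float, Schedule]


def _value_at(x: ParamOrSchedule, trial: int, n_trials: int) -> float:
    return x.value(trial, n_trials) if isinstance(x, Schedule) else float(x)


@dataclass
class SimParams:
    """Simulation hyperparameters.

    tol
        Tolerance in [0, 1]: sets the flip target state (cancer if
        tol > 0.5) and caps the admissible cancer fraction.
    eps_in
        Interaction parameter of the pair Hamiltonian (natural units).
    alpha
        Growth rate: percent of N proposed per trial (scalar or ramp).
    noise
        In [0, 1]; probability that a proposal is GLOBAL rather than
        LOCAL in the default mode (scalar or ramp).
    rho
        Bernoulli parameter of the auxiliary cluster-membership variable;
        consumed only in ``literal`` proposal mode.
    proposal_mode
        ``uniform_noise`` (default) or ``literal``; see
        :func:`propose_site`.
    order_d
        CVM order for the accepted-flip free energy (3 = triangle
        clusters).
    """

    tol: float
    eps_in: float
    alpha: ParamOrSchedule
    noise: ParamOrSchedule
    rho: float = 0.2
    trials: int = 100
    seed: int | None = None
    proposal_mode: str = "uniform_noise"
    order_d: int | str = 3

    def __post_init__(self) -> None:
        for name in ("tol", "rho"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("noise",):
            v = getattr(self, name)
            lo = v.start if isinstance(v, Schedule) else v
            hi = v.end if isinstance(v, Schedule) else v
            if not (0.0 <= lo <= 1.0 and 0.0 <= hi <= 1.0):
                raise ValueError(f"{name} must stay in [0, 1], got {v}")
        a = self.alpha
        if (a.start if isinstance(a, Schedule) else a) <= 0 or (
            a.end if isinstance(a, Schedule) else a
        ) <= 0:
            raise ValueError(f"alpha must be positive, got {a}")
        if self.trials < 1:
            raise ValueError(f"trials must be >= 1, got {self.trials}")
        if self.proposal_mode not in ("uniform_noise", "literal"):
            raise ValueError(f"unknown proposal mode {self.proposal_mode!r}")


@dataclass
class TrialRecord:
    trial: int
    alpha_t: float
    noise_t: float
    proposals: int
    accepted: int
    kikuchi: FreeEnergyReport
    meanfield: FreeEnergyReport
    cancer_count: int


@dataclass
class Trajectory:
    """Per-trial records plus periodic grid snapshots of one run."""

    params: SimParams
    records: list[TrialRecord]
    snapshots: dict[int, CellGrid] = field(default_factory=dict)
    final_grid: CellGrid | None = None

    def to_dataframe(self):
        import pandas as pd

        rows = [
            {
                "trial": r.trial,
                "alpha_t": r.alpha_t,
                "noise_t": r.noise_t,
                "proposals": r.proposals,
                "accepted": r.accepted,
                "F_kikuchi": r.kikuchi.free_energy,
                "U": r.kikuchi.internal_energy,
                "S": r.kikuchi.entropy,
                "F_meanfield": r.meanfield.free_energy,
                "cancer_count": r.cancer_count,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows)


def flips_per_trial(alpha_t: float, n_sites: int) -> int:
    """Number of proposals in one trial: round(alpha/100 * N), at least 1.

    The floor keeps ramps whose early rates round to zero (e.g. 0.00061%
    of a 128x128 lattice) proposing one flip per trial.
    """
    if alpha_t <= 0:
        raise ValueError(f"alpha must be positive, got {alpha_t}")
    return max(1, int(np.rint(alpha_t / 100.0 * n_sites)))


def target_state(tol: float) -> int:
    """Target state of proposed flips: cancer iff the tolerance exceeds 1/2."""
    if not 0.0 <= tol <= 1.0:
        raise ValueError(f"tolerance must be in [0, 1], got {tol}")
    return CANCER if tol > 0.5 else HEALTHY


def _local_candidates(states: np.ndarray, target: int) -> np.ndarray | None:
    """Mask of flippable sites bordering (or failing that, nearest to) the
    target-state cluster; None if no target-state site exists."""
    target_mask = states == target
    if not target_mask.any():
        return None
    flippable = ~target_mask
    adj = np.zeros_like(target_mask)
    adj[1:, :] |= target_mask[:-1, :]
    adj[:-1, :] |= target_mask[1:, :]
    adj[:, 1:] |= target_mask[:, :-1]
    adj[:, :-1] |= target_mask[:, 1:]
    cands = adj & flippable
    if cands.any():
        return cands
    # no flippable site touches the cluster: take the nearest ones
    dist = ndimage.distance_transform_cdt(~target_mask, metric="taxicab")
    dmin = dist[flippable].min()
    return flippable & (dist == dmin)


def propose_site(
    grid: CellGrid,
    target: int,
    noise_t: float,
    rho: float,
    mode: str,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Draw one proposal site whose state differs from ``target``.

    In ``uniform_noise`` mode the proposal is GLOBAL (uniform over all
    flippable sites) with probability ``noise_t`` and LOCAL (uniform over
    flippable sites adjacent to the target-state cluster) otherwise.  In
    ``literal`` mode an auxiliary cluster-membership indicator
    v ~ Bernoulli(rho) is drawn and the proposal is LOCAL iff v >= noise_t.
    LOCAL falls back to GLOBAL when no target-state site exists yet.
    """
    states = grid.states
    flippable = states != target
    if not flippable.any():
        raise SaturationError("every site already holds the target state")
    if mode == "uniform_noise":
        go_global = rng.random() < noise_t
    elif mode == "literal":
        v = 1 if rng.random() < rho else 0
        go_global = not (v >= noise_t)
    else:
        raise ValueError(f"unknown proposal mode {mode!r}")
    cands = None
    if not go_global:
        cands = _local_candidates(states, target)
    if cands is None:
        cands = flippable
    flat = np.flatnonzero(cands.ravel())
    pick = int(flat[rng.integers(flat.size)])
    return divmod(pick, grid.width)


def accept_flip(delta_f: float, new_fraction: float, tol: float, *, adds_cancer: bool) -> bool:
    """Greedy acceptance: keep a flip iff it does not raise the Kikuchi
    free energy and, when it adds a cancer cell, does not push the cancer
    fraction above the tolerance cap.

    Ties (delta_f == 0) are accepted so exactly-neutral early moves are
    not frozen.  Cancer-removing flips are never blocked by the cap.
    """
    if delta_f > 0:
        return False
    if adds_cancer and new_fraction > tol:
        return False
    return True


def _step(
    evaluator: KikuchiEvaluator,
    params: SimParams,
    noise_t: float,
    target: int,
    f_current: float,
    rng: np.random.Generator,
) -> tuple[float, bool]:
    """One propose/evaluate/accept-or-revert step.  Returns (F, accepted)."""
    site = propose_site(evaluator.grid, target, noise_t, params.rho, params.proposal_mode, rng)
    evaluator.flip(site)
    f_new = evaluator.free_energy()
    new_fraction = evaluator.cancer_count / evaluator.grid.n_sites
    if accept_flip(
        f_new - f_current, new_fraction, params.tol, adds_cancer=(target == CANCER)
    ):
        return f_new, True
    evaluator.flip(site)
    return f_current, False


def run_trial(
    grid: CellGrid,
    params: SimParams,
    trial_index: int,
    rng: np.random.Generator,
    evaluator: KikuchiEvaluator | None = None,
) -> tuple[CellGrid, TrialRecord]:
    """Run one trial of J sequential greedy steps; returns the updated grid
    and its record.  Pass a persistent evaluator to avoid rebuilding the
    cluster counts between trials."""
    ev = evaluator if evaluator is not None else KikuchiEvaluator(
        grid, params.order_d, params.eps_in
    )
    n = ev.grid.n_sites
    alpha_t = _value_at(params.alpha, trial_index, params.trials)
    noise_t = _value_at(params.noise, trial_index, params.trials)
    target = target_state(params.tol)
    j = flips_per_trial(alpha_t, n)
    proposals = accepted = 0
    f_current = ev.free_energy()
    for _ in range(j):
        try:
            f_current, ok = _step(ev, params, noise_t, target, f_current, rng)
        except SaturationError:
            break
        proposals += 1
        accepted += int(ok)
    record = TrialRecord(
        trial=trial_index,
        alpha_t=alpha_t,
        noise_t=noise_t,
        proposals=proposals,
        accepted=accepted,
        kikuchi=ev.report(),
        meanfield=meanfield_free_energy(ev.grid.shape, ev.cancer_count, params.eps_in),
        cancer_count=ev.cancer_count,
    )
    return ev.grid.copy(), record


def run_simulation(
    initial_grid: CellGrid,
    params: SimParams,
    snapshot_every: int | None = None,
    region_graph: RegionGraph | None = None,
) -> Trajectory:
    """Simulate ``params.trials`` trials from ``initial_grid``.

    Free energies (Kikuchi at ``params.order_d`` and mean-field) are
    recorded after every trial.  Snapshots of the grid are stored every
    ``snapshot_every`` trials (plus the final state) when requested.
    """
    rng = np.random.default_rng(params.seed)
    ev = KikuchiEvaluator(initial_grid, params.order_d, params.eps_in, region_graph)
    records: list[TrialRecord] = []
    snapshots: dict[int, CellGrid] = {}
    for t in range(params.trials):
        _, record = run_trial(initial_grid, params, t, rng, evaluator=ev)
        records.append(record)
        if snapshot_every is not None and t % snapshot_every == 0:
            snapshots[t] = ev.grid.copy()
    final = ev.grid.copy()
    if snapshot_every is not None:
        snapshots[params.trials - 1] = final.copy()
    return Trajectory(params=params, records=records, snapshots=snapshots, final_grid=final)
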