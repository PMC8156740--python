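# Methods

## Model

The tissue is a closed H×W lattice (default 128×128, N = 16384) of binary
cells, 0 = healthy, 1 = cancerous, with open (non-periodic) boundaries and
4-neighbour adjacency.  Energies are dimensionless (natural units) at unit
inverse temperature; all logarithms are natural, so entropies are in nats
and free energies are lattice totals, not per-site averages.

The Hamiltonian is a nearest-neighbour pair sum with activation energy
fixed at zero and pair energies

    u(1,1) = −ε_IN,  u(0,0) = u(0,1) = u(1,0) = 0.

This sign convention is the one consistent with all three simulated
niches: positive ε_IN lowers the energy of cancer–cancer contacts
(growth, metastasis), negative ε_IN penalises them so conversions toward
healthy tissue release energy (apoptosis).

### Free energies

* **Exact** (oracle, lattices ≤ 16 sites): F_H = −ln Σ_x e^(−H(x)) by full
  enumeration; also the variational form U(Q) − S(Q) for an explicit
  distribution Q over all 2^N states, which upper-bounds F_H for every
  normalised Q.
* **Mean field** (order 1): a single shared site marginal with
  Q(1) = cancer fraction p; U = (#pairs)·(−ε_IN p²),
  S = N·(−p ln p − (1−p) ln(1−p)).
* **Bethe** (order 2): base regions are all nearest-neighbour pairs; the
  Möbius recursion gives each site the counting number 1 − degree.
* **Kikuchi** (order 3): base regions are right-angle triangles, two per
  unit square sharing the anti-diagonal (the B3 cluster).  Intersections
  contribute pair regions (anti-diagonal plus the pairs shared between
  adjacent triangles) with c = −1 and interior sites with c = +1.
* **Full**: one region containing every site; the entropy term is exact
  for whatever full-configuration distribution is supplied.

The region set is constructed generically: base clusters, closed under
pairwise intersection, then counting numbers by the Möbius recursion
c_r = 1 − Σ_{s ⊃ r} c_s from the largest regions down.  Only fully
in-bounds clusters are regions; boundary sites simply have fewer
super-regions, and the construction verifies the exact-counting condition
Σ_{r ∋ i} c_r = 1 at every site (so all orders are exact for independent
sites).  Region graphs depend only on lattice geometry and are cached.

### Cluster marginals

Marginals are *empirical statistics of the current configuration* under a
translation-homogeneity assumption: one probability table per cluster
shape class (site; horizontal/vertical/anti-diagonal pair; the two
triangle orientations), estimated over all in-bounds placements of the
shape.  This is the classical cluster-variation treatment; it makes U and
S well-defined totals (class weight × table entropy, summed over classes)
and every evaluation O(N).  0·ln 0 is taken as 0, and no pseudo-count
smoothing is applied by default (an additive pseudo-count is available
for robustness experiments).  The Lagrange-multiplier normalisation terms
of a fully variational treatment play no computational role here: the
empirical tables are normalised by construction, and no minimisation over
Q is performed.  The dynamics (below) minimise the free energy over
*configurations*, not over distributions.

## Dynamics

One *trial* proposes J = max(1, round(α/100 · N)) single-site flips,
sequentially.  The flip target is fixed by the tolerance: cancer if
tol > 0.5, healthy otherwise.  Each proposal site is drawn

* **LOCAL** — uniformly among flippable sites 4-adjacent to the existing
  cluster of target-state sites (falling back to the nearest flippable
  sites, or to GLOBAL when no target-state site exists); or
* **GLOBAL** — uniformly among all flippable sites.

In the default `uniform_noise` mode the proposal is GLOBAL with
probability n_t (the noise parameter) and LOCAL otherwise, so n = 0 gives
purely localised growth, n = 0.25 dispersive growth, and a decaying noise
schedule is meaningful.  A `literal` mode is kept behind a flag: an
auxiliary cluster-membership indicator v ~ Bernoulli(ρ) is drawn and the
proposal is LOCAL iff v ≥ n_t.  The literal reading makes n = 0 and
n = 0.25 behave identically (a binary v exceeds both), which contradicts
the intended localised/dispersive distinction — hence the default.  ρ
defaults to 0.2 and is consumed only in literal mode.

A flip is **accepted** iff the Kikuchi free-energy change ΔF ≤ 0 *and*,
when the flip adds a cancer cell, the new cancer fraction does not exceed
the tolerance.  Ties are accepted so exactly-neutral early moves are not
frozen; the cap never blocks removals (during apoptosis the fraction
stays far above the near-zero tolerance until the cluster is gone).
Rejected flips are reverted exactly.  Because acceptance is per-flip and
greedy, the recorded free-energy sequence is non-increasing — there is no
temperature or stochastic acceptance.

ΔF is computed incrementally: the evaluator maintains integer
configuration counts per shape class and a flip touches at most ~10
covering clusters, so each step costs O(1) in the lattice size.  A
dedicated test verifies the incremental ΔF equals a from-scratch
re-evaluation to 1e-9.

Per-flip randomness is two draws (proposal type, then site) from a single
`numpy` Generator, so a fixed seed reproduces trajectories bitwise.

## Parameters and presets

| parameter | meaning | range / default |
|---|---|---|
| tol | target state selector and cancer-fraction cap | [0,1] |
| ε_IN | pair interaction (nats per cancer–cancer contact) | any real |
| α | growth rate, % of N proposed per trial | > 0; J clamped ≥ 1 |
| n_t | GLOBAL-proposal probability | [0,1], scalar or linear ramp |
| ρ | Bernoulli parameter of the literal proposal mode | 0.2 |
| trials | number of trials | 100 |

Presets (128×128, ρ = 0.2, 100 trials):

| scenario | tol | ε_IN | α (%) | noise | seed geometry |
|---|---|---|---|---|---|
| local_growth_dispersive | 0.60000 | 2.77259 | 0.00610 | 0.25 | 1 cell at centre |
| local_growth_localised  | 0.60000 | 2.77259 | 0.00610 | 0.00 | 1 cell at centre |
| metastasis              | 0.60000 | 1.88001 | 0.00061→0.00610 | 0.30→0.25 | 12×12 block |
| apoptosis_small         | 0.00001 | −1.42670 | 0.00610 | 0.25 | 41-cell blob |
| apoptosis_large         | 0.00001 | −1.42670 | 0.00610 | 0.25 | 172-cell blob |

Choices made where the scenario definitions leave freedom:

* the single seed cell sits at (⌊H/2⌋, ⌊W/2⌋);
* the metastasis primary site is a 12×12 block at rows/cols 20–31 — small
  relative to the lattice and fully interior; it is configurable;
* blob seeds grow from the centre by breadth-first accretion in Manhattan
  rings with row-major tie-breaking, so a given count yields one
  reproducible 4-connected cluster;
* the large apoptosis cluster is 172 cells, used literally even though it
  is nearer 1.05 % than 1 % of the lattice;
* linear ramps interpolate from the value at trial 0 to the value at the
  final trial.

On non-default lattice sizes the presets rescale seed geometry (blob
counts, block position/size) to preserve the initial cancer *fraction*;
the end-to-end phenomenology tests use a 64×64 lattice over 60 trials
with ten seeds, which keeps the full suite fast while leaving each
trajectory qualitatively identical to the full-size runs (which the
acceptance script and one full-scale test still execute at 128×128 × 100
trials).

## What the simulations do and do not show

The generator and dynamics emulate the *study conditions*: binary cell
states, nearest-neighbour pair interactions, single-flip greedy descent,
and the preset parameterisations above.  They do not emulate real tissue:
there are no intermediate cell types, no cell division or migration (a
metastatic cell "appears" distally rather than travelling), no external
fields or vasculature, and no stochastic acceptance.  Passing tests
therefore demonstrate properties of the free-energy formulation —
exactness limits, monotone descent, the divergence between Kikuchi and
mean-field trajectories during apoptosis — not biological validity.

## Numerical notes and limitations

* Entropy of each region table uses 0·ln 0 = 0; tables are exact rational
  counts divided by placement counts, so small-patch worked examples are
  reproduced exactly.
* The exact oracle enumerates at most 2^16 states; larger requests raise
  a capacity error rather than approximating silently.
* The Kikuchi entropy is not guaranteed an upper bound on the exact
  entropy (counting numbers are negative for intersections), and no
  overall joint distribution consistent with the cluster tables need
  exist; the variational-bound guarantee is only asserted for explicit
  full distributions via the oracle.
* With a tiny tolerance and a compact cluster, removals of cells with a
  single cancer neighbour can be free-energy-unfavourable (the entropy
  loss outweighs one contact energy), so apoptosis can stall on sparse
  remnants within the 100-trial window; cancer counts still decline
  monotonically, which is the behaviour of record.
* Greedy per-flip acceptance was chosen over batch acceptance of all J
  flips: batch semantics would need an unstated partial-revert rule, and
  the per-flip reading yields the monotone descent that the recorded
  trajectories display.
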