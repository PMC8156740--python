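import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nichesim.energy import (
    KikuchiEvaluator,
    PairEnergyConvention,
    entropy_cvm,
    exact_entropy,
    exact_free_energy,
    free_energy,
    interaction_energy,
    lattice_hamiltonian,
    meanfield_free_energy,
    n_neighbor_pairs,
    variational_free_energy,
)
from nichesim.lattice import grid_from_array, make_grid
from nichesim.marginals import ClusterMarginals, empirical_marginals, product_marginals
from nichesim.regions import build_region_graph, shape_key


def _random_states(rng, h, w, p=0.4):
    return (rng.random((h, w)) < p).astype(int)


class TestInteractionEnergy:
    def test_all_healthy_is_zero(self):
        grid = make_grid(4, 4, 0)
        marg = empirical_marginals(grid, build_region_graph((4, 4), 2))
        assert interaction_energy(marg, PairEnergyConvention(2.77259), (4, 4)) == 0.0

    def test_all_cancer_2x2(self):
        grid = make_grid(2, 2, 1)
        marg = empirical_marginals(grid, build_region_graph((2, 2), 2))
        assert interaction_energy(marg, PairEnergyConvention(1.0), (2, 2)) == pytest.approx(-4.0)

    def test_all_cancer_full_lattice_closed_form(self):
        grid = make_grid(128, 128, 1)
        marg = empirical_marginals(grid, build_region_graph((128, 128), 2))
        expected = -2.77259 * (2 * 128 * 127)
        assert n_neighbor_pairs((128, 128)) == 2 * 128 * 127
        got = interaction_energy(marg, PairEnergyConvention(2.77259), (128, 128))
        assert got == pytest.approx(expected)

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000), eps=st.sampled_from([-1.4267, 1.0, 1.88001, 2.77259]))
    def test_pair_marginal_route_equals_direct_lattice_sum(self, seed, eps):
        """Expected pair energy under empirical tables equals the direct
        Hamiltonian of the configuration, exactly."""
        rng = np.random.default_rng(seed)
        grid = grid_from_array(_random_states(rng, 6, 7))
        marg = empirical_marginals(grid, build_region_graph((6, 7), 2))
        via_marginals = interaction_energy(marg, PairEnergyConvention(eps), (6, 7))
        assert via_marginals == pytest.approx(lattice_hamiltonian(grid, eps), abs=1e-10)


class TestExactOracle:
    def test_one_pair_no_interaction(self):
        assert exact_free_energy((1, 2), 0.0) == pytest.approx(-np.log(4))

    def test_one_pair_unit_interaction(self):
        # states 00, 01, 10 have H = 0; state 11 has H = -1
        assert exact_free_energy((1, 2), 1.0) == pytest.approx(-np.log(3 + np.e))

    def test_2x2_no_interaction(self):
        assert exact_free_energy((2, 2), 0.0) == pytest.approx(-np.log(16))

    def test_capacity_limit(self):
        with pytest.raises(ValueError):
            exact_free_energy((5, 4), 1.0)

    @settings(max_examples=40, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        eps=st.sampled_from([-1.4267, 0.0, 1.88, 2.77259]),
        shape=st.sampled_from([(1, 2), (2, 2)]),
    )
    def test_variational_bound(self, seed, eps, shape):
        """U(Q) - S(Q) >= -ln Z for any normalised Q (the gap is a KL
        divergence)."""
        rng = np.random.default_rng(seed)
        n_states = 2 ** (shape[0] * shape[1])
        q = rng.dirichlet(np.ones(n_states))
        assert variational_free_energy(q, shape, eps) >= exact_free_energy(shape, eps) - 1e-12


class TestCvmEntropy:
    def test_point_mass_marginals_zero_entropy(self):
        grid = make_grid(5, 5, 1)
        rg = build_region_graph((5, 5), 3)
        assert entropy_cvm(empirical_marginals(grid, rg), rg) == pytest.approx(0.0)

    @pytest.mark.parametrize("d", [2, 3])
    def test_product_marginals_reduce_to_site_entropy(self, d):
        """For independent sites at density p the counting numbers per site
        sum to 1, so the CVM entropy at any order is N times the binary
        entropy of p."""
        p = 0.3
        rg = build_region_graph((8, 8), d)
        s = entropy_cvm(product_marginals(rg, p), rg)
        expected = 64 * (-p * np.log(p) - (1 - p) * np.log(1 - p))
        assert s == pytest.approx(expected, abs=1e-9)

    def test_full_order_equals_brute_force_entropy(self, rng):
        """With the single all-site region the CVM entropy is the exact
        entropy of the supplied full-configuration distribution."""
        for shape in [(2, 2), (3, 3)]:
            n = shape[0] * shape[1]
            rg = build_region_graph(shape, "full")
            full_shape = shape_key([(i, j) for i in range(shape[0]) for j in range(shape[1])])
            for _ in range(20):
                q = rng.dirichlet(np.ones(2**n))
                marg = ClusterMarginals("full", {full_shape: q})
                assert entropy_cvm(marg, rg) == pytest.approx(exact_entropy(q), abs=1e-9)

    def test_order_mismatch_rejected(self):
        rg2 = build_region_graph((4, 4), 2)
        rg3 = build_region_graph((4, 4), 3)
        marg = empirical_marginals(make_grid(4, 4), rg2)
        with pytest.raises(ValueError):
            entropy_cvm(marg, rg3)


class TestFreeEnergy:
    @pytest.mark.parametrize("d", [1, 2, 3, "full"])
    def test_all_healthy_grid_is_zero(self, d):
        report = free_energy(make_grid(4, 4), d, 2.77259)
        assert report.internal_energy == 0.0
        assert report.entropy == pytest.approx(0.0)
        assert report.free_energy == pytest.approx(0.0)

    def test_meanfield_closed_form(self, rng):
        grid = grid_from_array(_random_states(rng, 8, 8, p=0.3))
        p = grid.cancer_count() / 64
        report = free_energy(grid, 1, 1.88001)
        assert report.internal_energy == pytest.approx(n_neighbor_pairs((8, 8)) * -1.88001 * p * p)
        assert report.entropy == pytest.approx(64 * (-p * np.log(p) - (1 - p) * np.log(1 - p)))
        assert report.free_energy == report.internal_energy - report.entropy

    def test_full_order_entropy_is_empirical_point_mass(self, random_grid):
        # one observed configuration: the empirical full-state distribution
        # is degenerate, so S = 0 and F = U
        report = free_energy(random_grid, "full", 1.0)
        assert report.entropy == 0.0
        assert report.internal_energy == pytest.approx(lattice_hamiltonian(random_grid, 1.0))


class TestKikuchiEvaluator:
    @settings(max_examples=10, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matches_full_evaluation(self, seed):
        rng = np.random.default_rng(seed)
        grid = grid_from_array(_random_states(rng, 8, 8))
        ev = KikuchiEvaluator(grid, 3, eps_in=1.88001)
        full = free_energy(grid, 3, 1.88001)
        assert ev.free_energy() == pytest.approx(full.free_energy, abs=1e-9)
        assert ev.internal_energy() == pytest.approx(full.internal_energy, abs=1e-9)

    @settings(max_examples=10, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_incremental_flip_equals_reevaluation(self, seed):
        """The O(1) count update after a single flip reproduces a from-
        scratch evaluation of the flipped grid."""
        rng = np.random.default_rng(seed)
        grid = grid_from_array(_random_states(rng, 8, 8))
        ev = KikuchiEvaluator(grid, 3, eps_in=-1.42670)
        site = (int(rng.integers(8)), int(rng.integers(8)))
        flipped = grid.copy()
        flipped.states[site] ^= 1
        delta_full = (
            free_energy(flipped, 3, -1.42670).free_energy
            - free_energy(grid, 3, -1.42670).free_energy
        )
        assert ev.delta_if_flipped(site) == pytest.approx(delta_full, abs=1e-9)
        # state untouched after the probe
        assert (ev.grid.states == grid.states).all()
        assert ev.free_energy() == pytest.approx(free_energy(grid, 3, -1.42670).free_energy)

    def test_cancer_count_tracking(self):
        ev = KikuchiEvaluator(make_grid(4, 4), 2, eps_in=1.0)
        assert ev.cancer_count == 0
        ev.flip((1, 1))
        assert ev.cancer_count == 1
        ev.flip((1, 1))
        assert ev.cancer_count == 0


def test_meanfield_report_from_count():
    rep = meanfield_free_energy((128, 128), 0, -1.4267)
    assert rep.free_energy == 0.0
    rep = meanfield_free_energy((128, 128), 8192, 1.0)
    assert rep.internal_energy == pytest.approx(32512 * -0.25)
    assert rep.entropy == pytest.approx(16384 * np.log(2))
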