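import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import bloomnet as bn
from bloomnet import PlotMetadata, PlotNetwork

from conftest import brute_force_nodf


def _net(matrix, plants_bloomed=None):
    matrix = np.asarray(matrix)
    m, n = matrix.shape
    return PlotNetwork(
        matrix=matrix,
        plants=[f"pl{i}" for i in range(m)],
        insects=[f"in{j}" for j in range(n)],
        meta=PlotMetadata("t", "b", "C",
                          plants_bloomed=plants_bloomed or min(7, m),
                          display=100.0),
    )


class TestConnectance:
    def test_direct_arithmetic(self):
        # L=10 over 5 bloomed plants and a 92-species pool
        b = np.zeros((5, 10), dtype=int)
        b[0, :6] = 1
        b[1:5, np.arange(4)] = 0
        b[1, 6], b[2, 7], b[3, 8], b[4, 9] = 1, 1, 1, 1
        net = _net(b, plants_bloomed=5)
        assert net.n_links == 10
        assert bn.connectance_experiment_wide(net, 92) == pytest.approx(10 / 460)

    def test_complete_network_reaches_one(self):
        assert bn.connectance_experiment_wide(_net([[3]], plants_bloomed=1), 1) == 1.0

    def test_zero_bloomed_plants_error(self):
        net = _net([[1]])
        object.__setattr__(net.meta, "plants_bloomed", 0)
        with pytest.raises(ValueError, match="connectance"):
            bn.connectance_experiment_wide(net, 92)

    def test_monotone_in_links(self):
        rng = np.random.default_rng(5)
        base = (rng.random((4, 6)) < 0.4).astype(int)
        base[base.sum(1) == 0, 0] = 1
        base[0, base.sum(0) == 0] = 1
        net = _net(base)
        c0 = bn.connectance_experiment_wide(net, 50)
        empty = np.argwhere(base == 0)
        if len(empty):
            added = base.copy()
            added[tuple(empty[0])] = 1
            c1 = bn.connectance_experiment_wide(_net(added), 50)
            assert c1 >= c0


class TestDegrees:
    def test_worked_toy(self):
        uw, w = bn.degrees(_net([[2, 4], [1, 0]]))
        assert (uw, w) == (0.75, 1.75)

    def test_perfect_matching_symmetry(self):
        k = 5
        uw, w = bn.degrees(_net(np.eye(k, dtype=int)))
        assert uw == w == 0.5

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(17)
        a = rng.integers(0, 4, size=(5, 8))
        a[a.sum(1) == 0, 0] = 1
        a[0, a.sum(0) == 0] = 1
        net = _net(a)
        links = sum(1 for i in range(5) for j in range(8) if a[i, j] > 0)
        total = sum(int(a[i, j]) for i in range(5) for j in range(8))
        uw, w = bn.degrees(net)
        assert uw == links / 13 and w == total / 13


class TestNodf:
    def test_perfectly_nested(self):
        assert bn.nodf(np.array([[1, 1], [1, 0]])) == 100.0

    def test_checkerboard(self):
        assert bn.nodf(np.eye(2, dtype=int)) == 0.0

    def test_all_zero_error(self):
        with pytest.raises(ValueError):
            bn.nodf(np.zeros((2, 2)))

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            b = (rng.random((4, 6)) < 0.5).astype(int)
            if b.sum() == 0:
                continue
            assert bn.nodf(b) == pytest.approx(brute_force_nodf(b))

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.integers(0, 2**12 - 1))
    def test_permutation_invariance(self, bits):
        b = np.array([(bits >> k) & 1 for k in range(12)]).reshape(3, 4)
        if b.sum() == 0:
            return
        rng = np.random.default_rng(bits)
        perm = b[rng.permutation(3)][:, rng.permutation(4)]
        assert bn.nodf(perm) == pytest.approx(bn.nodf(b))


def _enumerate_max_nodf(m, n, links):
    """Independent exhaustive search over all feasible binary matrices."""
    best = None
    for combo in itertools.combinations(range(m * n), links):
        b = np.zeros(m * n, dtype=int)
        b[list(combo)] = 1
        b = b.reshape(m, n)
        if (b.sum(1) == 0).any() or (b.sum(0) == 0).any():
            continue
        val = brute_force_nodf(b)
        best = val if best is None else max(best, val)
    return best


class TestMaxNodf:
    def test_full_matrix_unique_configuration(self):
        assert bn.max_nodf(3, 4, 12) == pytest.approx(bn.nodf(np.ones((3, 4))))

    def test_exhaustive_3x3_l5(self):
        assert bn.max_nodf(3, 3, 5) == pytest.approx(_enumerate_max_nodf(3, 3, 5))

    @pytest.mark.parametrize("m,n", [(2, 3), (3, 3), (3, 4)])
    def test_heuristic_equals_enumeration(self, m, n):
        for links in range(max(m, n), m * n + 1):
            heur = bn.max_nodf(m, n, links, exhaustive=False)
            assert heur == pytest.approx(_enumerate_max_nodf(m, n, links)), (
                m, n, links
            )

    def test_upper_bounds_observed(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            b = (rng.random((4, 5)) < 0.5).astype(int)
            b[b.sum(1) == 0, 0] = 1
            b[0, b.sum(0) == 0] = 1
            assert bn.max_nodf(4, 5, int(b.sum())) >= bn.nodf(b) - 1e-9

    def test_infeasible_links_error(self):
        with pytest.raises(ValueError):
            bn.max_nodf(3, 4, 3)
        with pytest.raises(ValueError):
            bn.max_nodf(3, 4, 13)


class TestNodfc:
    def test_ratio_identity_at_own_fill(self):
        b = np.array([[1, 1, 1], [1, 1, 0], [1, 0, 0]])
        links = int(b.sum())
        expected = (bn.nodf(b) / bn.max_nodf(3, 3, links)) / (
            (links / 9) * np.log(3)
        )
        assert bn.nodfc(b) == pytest.approx(expected)
        assert bn.nodf(b) == pytest.approx(bn.max_nodf(3, 3, links))

    def test_transposition_invariance(self):
        rng = np.random.default_rng(9)
        b = (rng.random((3, 5)) < 0.6).astype(int)
        b[b.sum(1) == 0, 0] = 1
        b[0, b.sum(0) == 0] = 1
        assert bn.nodfc(b) == pytest.approx(bn.nodfc(b.T))

    def test_heuristic_agrees_with_exhaustive_normalization(self):
        rng = np.random.default_rng(13)
        for _ in range(5):
            b = (rng.random((3, 4)) < 0.6).astype(int)
            b[b.sum(1) == 0, 0] = 1
            b[0, b.sum(0) == 0] = 1
            links = int(b.sum())
            heur = bn.max_nodf(3, 4, links, exhaustive=False)
            exact = bn.max_nodf(3, 4, links, exhaustive=True)
            assert heur == pytest.approx(exact)


class TestModularity:
    def test_single_module_q_is_zero(self):
        a = np.array([[3, 1], [2, 5]])
        q = bn.barber_q(a, np.zeros(2, dtype=int), np.zeros(2, dtype=int))
        assert q == pytest.approx(0.0)

    def test_two_equal_blocks_reach_half(self):
        net = bn.make_fixture_networks("modular", (4, 6))
        q, (rl, cl) = bn.bipartite_modularity(net, seed=2)
        assert q == pytest.approx(0.5)
        # planted partition recovered: first half of rows/cols together
        assert len(set(rl[:2])) == 1 and len(set(rl[2:])) == 1
        assert rl[0] != rl[2]

    def test_optimizer_never_below_single_module(self, small_networks):
        some = list(small_networks.values())[:3]
        for net in some:
            q, _ = bn.bipartite_modularity(net, seed=0, restarts=5)
            assert q >= 0.0

    def test_optimizer_matches_direct_formula(self):
        net = bn.make_fixture_networks("modular", (4, 6))
        q, (rl, cl) = bn.bipartite_modularity(net, seed=0)
        assert q == pytest.approx(bn.barber_q(net.matrix, rl, cl))

    def test_seeded_determinism(self):
        net = bn.make_fixture_networks("random", (5, 8), seed=3)
        q1, p1 = bn.bipartite_modularity(net, seed=42)
        q2, p2 = bn.bipartite_modularity(net, seed=42)
        assert q1 == q2
        np.testing.assert_array_equal(p1[0], p2[0])

    @settings(deadline=None, derandomize=True, max_examples=15)
    @given(st.integers(1, 6))
    def test_q_invariant_under_weight_scaling(self, scale):
        net = bn.make_fixture_networks("random", (4, 6), seed=8)
        q1, (rl, cl) = bn.bipartite_modularity(net, seed=1)
        q2 = bn.barber_q(net.matrix * scale, rl, cl)
        assert q2 == pytest.approx(q1)


class TestComputeAll:
    def test_toy_row_is_consistent(self):
        net = _net([[2, 4], [1, 0]], plants_bloomed=3)
        pm = bn.compute_all(net, i_total=10, seed=0)
        assert pm.links == 3
        assert pm.abundance == 7
        assert pm.species_total == 4
        assert pm.unweighted_degree * pm.species_total == pytest.approx(pm.links)
        assert pm.weighted_degree * pm.species_total == pytest.approx(pm.abundance)
        assert pm.connectance == pytest.approx(3 / 30)

    def test_full_synthetic_experiment_has_no_missing_values(self, small_networks):
        rows = [
            bn.compute_all(net, i_total=90, seed=1, restarts=5).as_dict()
            for net in list(small_networks.values())[:6]
        ]
        for row in rows:
            for key, val in row.items():
                if isinstance(val, float):
                    assert np.isfinite(val), (row["plot_id"], key)
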