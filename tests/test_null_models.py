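import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

import bloomnet as bn
from bloomnet import PlotMetadata, PlotNetwork


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


def _enumerate_tables(r, c):
    """All non-negative integer tables with the given margins, with their
    Fisher-Yates probabilities (the distribution Patefield samples)."""
    r, c = list(r), list(c)
    m, n = len(r), len(c)
    tables = []

    def rec(row, partial, remaining_cols):
        if row == m:
            if all(x == 0 for x in remaining_cols):
                tables.append([list(x) for x in partial])
            return
        for cells in itertools.product(*[range(min(r[row], rc) + 1)
                                         for rc in remaining_cols]):
            if sum(cells) != r[row]:
                continue
            rec(row + 1, partial + [cells],
                [rc - x for rc, x in zip(remaining_cols, cells)])

    rec(0, [], c)
    n_total = sum(r)
    log_const = (
        sum(math.lgamma(x + 1) for x in r)
        + sum(math.lgamma(x + 1) for x in c)
        - math.lgamma(n_total + 1)
    )
    probs = [
        math.exp(log_const - sum(math.lgamma(x + 1) for row in t for x in row))
        for t in tables
    ]
    return tables, np.asarray(probs)


class TestPatefieldSampler:
    def test_single_cell_table(self):
        rng = np.random.default_rng(0)
        np.testing.assert_array_equal(
            bn.patefield_sample([5], [5], rng), [[5]]
        )

    def test_margins_conserved_on_1000_draws(self):
        rng = np.random.default_rng(1)
        r = np.array([7, 3, 9, 1])
        c = np.array([4, 4, 3, 3, 3, 3])
        for _ in range(1000):
            t = bn.patefield_sample(r, c, rng)
            np.testing.assert_array_equal(t.sum(axis=1), r)
            np.testing.assert_array_equal(t.sum(axis=0), c)

    def test_margin_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            bn.patefield_sample([2, 2], [3, 3], np.random.default_rng(0))

    def test_distribution_matches_enumeration_2x2(self):
        # margins r=[2,2], c=[2,2]: three feasible tables indexed by a11
        tables, probs = _enumerate_tables([2, 2], [2, 2])
        assert len(tables) == 3
        rng = np.random.default_rng(7)
        counts = np.zeros(3)
        for _ in range(30_000):
            a11 = bn.patefield_sample([2, 2], [2, 2], rng)[0][0]
            counts[a11] += 1
        expected = np.array(
            [probs[tables.index(t)] for t in ([[0, 2], [2, 0]],
                                              [[1, 1], [1, 1]],
                                              [[2, 0], [0, 2]])]
        )
        chi2, p = sps.chisquare(counts, 30_000 * expected)
        assert p > 1e-3


class TestNullEnsemble:
    def test_degenerate_single_cell_flagged(self):
        ens = bn.null_ensemble(_net([[5]], plants_bloomed=1), n_null=20,
                               seed=0, i_total=5,
                               which=("connectance", "weighted_degree"))
        assert set(ens.degenerate) == {"connectance", "weighted_degree"}
        zs = bn.z_scores({"plot_id": "t", "connectance": 0.2,
                          "weighted_degree": 2.5}, ens)
        assert zs.z["connectance"] is None

    def test_requested_number_of_draws(self):
        ens = bn.null_ensemble(_net([[2, 1], [1, 3]]), n_null=50, seed=0,
                               i_total=10, which=("nodf", "connectance"))
        assert all(len(v) == 50 for v in ens.draws.values())

    def test_weighted_degree_is_margin_determined(self, small_networks):
        net = list(small_networks.values())[0]
        ens = bn.null_ensemble(net, n_null=40, seed=2, i_total=90,
                               which=("weighted_degree", "unweighted_degree"))
        assert "weighted_degree" in ens.degenerate
        assert "unweighted_degree" not in ens.degenerate

    def test_null_mean_matches_exhaustive_expectation(self):
        # tiny margins: enumerate every feasible table exactly
        r, c = [2, 1], [1, 2]
        tables, probs = _enumerate_tables(r, c)
        exact = 0.0
        for t, p in zip(tables, probs):
            links = sum(1 for row in t for x in row if x > 0)
            exact += p * links / 4  # S = 4 species in every table
        net = _net([[1, 1], [0, 1]])
        ens = bn.null_ensemble(net, n_null=4000, seed=5, i_total=10,
                               which=("unweighted_degree",))
        assert ens.mean["unweighted_degree"] == pytest.approx(exact, abs=0.01)

    def test_seeded_reproducibility(self):
        net = _net([[3, 1, 0], [0, 2, 2], [1, 0, 4]])
        a = bn.null_ensemble(net, n_null=30, seed=9, i_total=10)
        b = bn.null_ensemble(net, n_null=30, seed=9, i_total=10)
        for m in a.draws:
            np.testing.assert_array_equal(a.draws[m], b.draws[m])


class TestZScores:
    def test_observed_at_mean_and_one_sd(self):
        draws = {"nodf": np.array([10.0, 20.0, 30.0, 40.0])}
        ens = bn.NullEnsemble("t", 4, draws, observed={"nodf": 25.0})
        mu, sd = 25.0, np.std(draws["nodf"], ddof=1)
        assert bn.z_scores({"plot_id": "t", "nodf": mu}, ens).z["nodf"] == 0.0
        assert bn.z_scores(
            {"plot_id": "t", "nodf": mu + sd}, ens
        ).z["nodf"] == pytest.approx(1.0)

    def test_plot_id_mismatch_raises(self):
        ens = bn.NullEnsemble("t", 2, {"nodf": np.array([1.0, 2.0])},
                              observed={"nodf": 1.5})
        with pytest.raises(ValueError, match="mismatch"):
            bn.z_scores({"plot_id": "other", "nodf": 1.5}, ens)

    def test_connectance_z_has_dispersion_under_fixed_margins(self):
        rng = np.random.default_rng(11)
        a = rng.integers(0, 3, size=(4, 6))
        a[a.sum(1) == 0, 0] = 1
        a[0, a.sum(0) == 0] = 1
        ens = bn.null_ensemble(_net(a), n_null=200, seed=3, i_total=20,
                               which=("connectance",))
        assert np.std(ens.draws["connectance"]) > 0


class TestNullDeparture:
    def test_interval_excluding_zero(self):
        assert bn.null_departure(np.array([1.5, 2.0, 2.5])) is True

    def test_interval_straddling_zero(self):
        assert bn.null_departure(np.array([-1.0, 1.0])) is False

    def test_matches_hand_rule_on_fixed_vectors(self):
        for z in ([0.5, 0.6, 0.7], [-3.0, -2.0, -2.5], [0.1, -0.1, 0.3]):
            z = np.asarray(z)
            hand = (z.mean() - z.std(ddof=1) > 0) or (z.mean() + z.std(ddof=1) < 0)
            assert bn.null_departure(z) == hand

    def test_planted_antinested_signal_departs(self):
        # perfectly modular (anti-nested) networks have NODF 0; fixed-margin
        # nulls break the blocks apart, so every z is strongly negative and
        # the treatment-level departure rule must fire
        zvals = []
        for seed, dims in enumerate([(4, 6), (4, 8), (6, 6)]):
            net = bn.make_fixture_networks("modular", dims, seed=seed)
            ens = bn.null_ensemble(net, n_null=100, seed=seed, i_total=10,
                                   which=("nodf",))
            obs = bn.nodf(net.matrix)
            zvals.append((obs - ens.mean["nodf"]) / ens.sd["nodf"])
        assert all(z < 0 for z in zvals)
        assert bn.null_departure(np.asarray(zvals)) is True
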