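"""Tests for trajectory alignment, Kendall matrices and the synchrony test."""

import itertools

import numpy as np
import pytest

from glacialsfs.core import NeTrajectory
from glacialsfs.simdata import simulate_trajectory_set
from glacialsfs.synchrony import (
    AlignedTrajectories,
    align_on_grid,
    delta_ne_smoothed,
    kendall_matrix,
    synchrony_randomization,
    trajectory_to_steps,
)


def traj(bounds_ne):
    """Helper: NeTrajectory from [(t_lo, t_hi, ne), ...]."""
    arr = np.asarray(bounds_ne, dtype=float)
    return NeTrajectory(t_lo=arr[:, 0], t_hi=arr[:, 1], ne=arr[:, 2])


def kendall_tau_b_oracle(x, y):
    """Exhaustive concordant/discordant pair enumeration (tau-b)."""
    n = len(x)
    nc = nd = tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        dx = np.sign(x[j] - x[i])
        dy = np.sign(y[j] - y[i])
        if dx == 0 and dy == 0:
            tx += 1
            ty += 1
        elif dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx == dy:
            nc += 1
        else:
            nd += 1
    n0 = n * (n - 1) / 2
    den = math_sqrt((n0 - tx) * (n0 - ty))
    return np.nan if den == 0 else (nc - nd) / den


def math_sqrt(v):
    return v**0.5


class TestTrajectoryToSteps:
    def test_midpoints_with_most_recent_dropped(self):
        steps = trajectory_to_steps(traj([(0, 10, 5e4), (10, 30, 8e4)]))
        assert steps.shape == (1, 2)
        assert steps[0, 0] == 20.0 and steps[0, 1] == 8e4

    def test_equal_ne_intervals_keep_their_midpoints(self):
        steps = trajectory_to_steps(traj([(0, 2, 1e4), (2, 6, 1e4), (6, 10, 1e4)]))
        assert np.allclose(steps[:, 0], [4.0, 8.0])
        assert np.allclose(steps[:, 1], 1e4)

    def test_single_interval_errors(self):
        with pytest.raises(ValueError):
            trajectory_to_steps(traj([(0, 10, 1e4)]))


class TestAlignOnGrid:
    def test_single_species_identity(self):
        steps = np.array([[5.0, 1e4], [15.0, 2e4], [40.0, 3e4]])
        al = align_on_grid([steps])
        assert np.array_equal(al.grid, steps[:, 0])
        assert np.array_equal(al.ne[0], steps[:, 1])

    def test_identical_midpoints_keep_own_values(self):
        a = np.array([[5.0, 1e4], [15.0, 2e4]])
        b = np.array([[5.0, 9e3], [15.0, 3e4]])
        al = align_on_grid([a, b])
        assert np.array_equal(al.ne[0], a[:, 1])
        assert np.array_equal(al.ne[1], b[:, 1])

    def test_equidistant_query_resolves_to_older_midpoint(self):
        a = np.array([[10.0, 1e4], [30.0, 5e4]])
        b = np.array([[20.0, 7e7]])  # grid point 20 equidistant from 10 and 30
        al = align_on_grid([a, b])
        gi = list(al.grid).index(20.0)
        assert al.ne[0, gi] == 5e4  # older midpoint (t=30) wins the tie

    def test_idempotent_on_aligned_data(self):
        rng = np.random.default_rng(3)
        steps = [
            np.column_stack([np.sort(rng.uniform(1, 100, 8)), rng.uniform(1e3, 1e5, 8)])
            for _ in range(3)
        ]
        al1 = align_on_grid(steps)
        al2 = align_on_grid(
            [np.column_stack([al1.grid, al1.ne[i]]) for i in range(3)]
        )
        assert np.array_equal(al1.grid, al2.grid)
        assert np.array_equal(al1.ne, al2.ne)

    def test_every_value_comes_from_a_source_step(self):
        rng = np.random.default_rng(4)
        steps = [
            np.column_stack([np.sort(rng.uniform(1, 100, 6)), rng.uniform(1e3, 1e5, 6)])
            for _ in range(2)
        ]
        al = align_on_grid(steps)
        for i in range(2):
            assert set(al.ne[i]) <= set(steps[i][:, 1])


class TestKendallMatrix:
    def grid(self, *series):
        series = [np.asarray(s, dtype=float) for s in series]
        return AlignedTrajectories(
            np.arange(1.0, len(series[0]) + 1), np.stack(series),
            [f"s{i}" for i in range(len(series))],
        )

    def test_identical_series_tau_one(self):
        al = self.grid([1, 3, 2, 5], [1, 3, 2, 5])
        assert kendall_matrix(al)[0, 1] == pytest.approx(1.0)

    def test_reversed_ranks_tau_minus_one(self):
        al = self.grid([1, 2, 3, 4], [4, 3, 2, 1])
        assert kendall_matrix(al)[0, 1] == pytest.approx(-1.0)

    def test_matches_enumeration_oracle_on_toys(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.integers(0, 3, 5).astype(float)
            y = rng.integers(0, 3, 5).astype(float)
            al = self.grid(x, y)
            got = kendall_matrix(al)[0, 1]
            want = kendall_tau_b_oracle(x, y)
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0])
        y = np.array([2.0, 7.0, 1.0, 8.0, 2.5])
        a = kendall_matrix(self.grid(x, y))[0, 1]
        b = kendall_matrix(self.grid(np.exp(x), y**3))[0, 1]
        assert a == pytest.approx(b)

    def test_constant_series_gives_nan(self):
        al = self.grid([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(kendall_matrix(al)[0, 1])


class TestDeltaSmoothing:
    def aligned(self, ne_rows):
        ne = np.asarray(ne_rows, dtype=float)
        return AlignedTrajectories(
            np.arange(1.0, ne.shape[1] + 1), ne, [f"s{i}" for i in range(ne.shape[0])]
        )

    def test_constant_series_all_zero(self):
        sm = delta_ne_smoothed(self.aligned([np.full(20, 1e4)]), w=5)
        assert np.allclose(sm, 0.0)

    def test_series_increasing_toward_past_gives_negative_delta(self):
        # Ne(t) < Ne(t+1): lower toward the present, delta = Ne(t)-Ne(t+1) < 0
        sm = delta_ne_smoothed(self.aligned([np.arange(1.0, 21.0)]), w=4)
        assert np.all(sm < 0)

    def test_linear_series_slope(self):
        s = 7.0
        sm = delta_ne_smoothed(self.aligned([100 + s * np.arange(30.0)]), w=6)
        assert np.allclose(sm, -s)

    def test_window_count_drops_partial_edges(self):
        sm = delta_ne_smoothed(self.aligned([np.arange(1.0, 11.0)]), w=4)
        assert sm.shape[-1] == 9 - 4 + 1  # 9 deltas, full windows only

    def test_short_grid_rejected(self):
        with pytest.raises(ValueError):
            delta_ne_smoothed(self.aligned([np.arange(5.0)]), w=10)


class TestSynchronyRandomization:
    def make_aligned(self, k=4, G=400, shared=None, seed=0):
        grid = np.linspace(1e3, 1e6, G)
        trajs = simulate_trajectory_set(
            k, grid, shared_decreases=shared or [], noise=0.1, seed=seed
        )
        steps = [trajectory_to_steps(t) for t in trajs]
        return align_on_grid(steps)

    def test_permutation_preserves_delta_multiset(self):
        al = self.make_aligned(seed=11)
        delta = al.ne[:, :-1] - al.ne[:, 1:]
        rng = np.random.default_rng(1)
        perm = delta[0, rng.permutation(delta.shape[1])]
        assert np.array_equal(np.sort(perm), np.sort(delta[0]))

    def test_engineered_shared_decrease_detected(self):
        al = self.make_aligned(shared=[(100, 250)], seed=12)
        res = synchrony_randomization(al, w=50, n_perm=500, seed=13)
        assert res.observed_max_species == al.n_species
        assert res.significant_longest_run
        assert res.significant  # primary decision

    def test_null_data_usually_not_significant(self):
        hits = 0
        for s in range(10):
            al = self.make_aligned(seed=100 + s)
            res = synchrony_randomization(al, w=50, n_perm=300, seed=200 + s)
            hits += res.significant_longest_run
        assert hits <= 2

    def test_constant_series_degenerate_null(self):
        ne = np.tile(np.full(120, 5e4), (2, 1))
        al = AlignedTrajectories(np.arange(1.0, 121.0), ne, ["a", "b"])
        with pytest.warns(UserWarning):
            res = synchrony_randomization(al, w=10, n_perm=50, seed=3)
        assert res.observed_max_species == 0
        assert not res.significant

    def test_named_group_presets(self):
        al = self.make_aligned(k=6, seed=14)
        al.species = list(
            ("F. sylvatica", "Q. petraea", "P. abies", "B. pendula",
             "P. sylvestris", "P. nigra")
        )
        res = synchrony_randomization(al, group="temperate", w=50, n_perm=120, seed=15)
        assert res.n_perm == 120
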