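"""Zero reference, basin/saddle analysis and Boltzmann marginalization."""

import numpy as np
import pytest

from memfes.core import ThermoContext, ZeroReferenceError
from memfes.landscape import (
    FESGrid,
    barrier,
    find_minima,
    marginalize,
    minimax_saddle,
    profile_barrier,
    set_zero_reference,
)
from tests.conftest import make_flat_square_grid, random_gaussian_landscape


def exhaustive_minimax(values, grid, a_idx, b_idx):
    """Oracle: enumerate all simple 8-connected paths on a tiny grid and
    return the minimum over paths of the maximum F."""
    best = [np.inf]

    def dfs(node, visited, cur_max):
        cur_max = max(cur_max, values[node])
        if cur_max >= best[0]:
            return
        if node == b_idx:
            best[0] = cur_max
            return
        for nb in grid.neighbors8(*node):
            if nb not in visited:
                dfs(nb, visited | {nb}, cur_max)

    dfs(a_idx, {a_idx}, -np.inf)
    return best[0]


class TestZeroReference:
    def test_reference_node_becomes_zero_and_differences_preserved(self, fixture_fes):
        ref = (1.0, 2.0)
        shifted = set_zero_reference(fixture_fes, ref)
        assert shifted.value_at(ref) == pytest.approx(0.0, abs=1e-9)
        d_orig = fixture_fes.values[3, 5] - fixture_fes.values[40, 50]
        d_new = shifted.values[3, 5] - shifted.values[40, 50]
        assert d_new == pytest.approx(d_orig, abs=1e-12)
        assert shifted.reference is not None

    def test_reference_at_global_minimum_makes_all_nonnegative(self, fixture_fes):
        gmin = np.unravel_index(np.argmin(fixture_fes.values), fixture_fes.values.shape)
        ref = fixture_fes.grid.node_point(gmin)
        shifted = set_zero_reference(fixture_fes, ref)
        assert shifted.values.min() >= -1e-12

    def test_unexplored_reference_rejected(self, small_grid, thermo300):
        vals = np.zeros(small_grid.bins)
        explored = np.ones(small_grid.bins, dtype=bool)
        explored[0, 0] = False
        fes = FESGrid(grid=small_grid, values=vals, thermo=thermo300, explored=explored)
        bad_ref = fes.grid.node_point((0, 0))
        with pytest.raises(ZeroReferenceError):
            set_zero_reference(fes, bad_ref)


class TestFindMinima:
    def test_single_gaussian_well_found_at_center(self, thermo300):
        grid = make_flat_square_grid(21, extent=1.0)
        X, Y = grid.mesh()
        F = -8.0 * np.exp(-((X - 0.5) ** 2 + (Y - 0.5) ** 2) / (2 * 0.15**2))
        fes = FESGrid(grid=grid, values=F, thermo=thermo300)
        basins = find_minima(fes, depth_threshold=1.0)
        assert len(basins) == 1
        assert basins[0].label == "A"
        assert np.allclose(basins[0].location, [0.5, 0.5], atol=grid.widths[0])

    def test_flat_grid_has_no_basins(self, thermo300):
        grid = make_flat_square_grid(10)
        fes = FESGrid(grid=grid, values=np.zeros(grid.bins), thermo=thermo300)
        assert find_minima(fes, 0.0) == []

    def test_invariant_under_global_shift(self, fixture_fes):
        basins = find_minima(fixture_fes, 1.0)
        shifted = FESGrid(
            grid=fixture_fes.grid,
            values=fixture_fes.values + 123.4,
            thermo=fixture_fes.thermo,
        )
        basins2 = find_minima(shifted, 1.0)
        assert [b.node for b in basins] == [b.node for b in basins2]
        for b1, b2 in zip(basins, basins2):
            assert b2.free_energy - b1.free_energy == pytest.approx(123.4, abs=1e-9)

    def test_shallow_noise_minima_filtered_by_depth(self, thermo300):
        grid = make_flat_square_grid(21)
        rng = np.random.default_rng(5)
        X, Y = grid.mesh()
        F = -8.0 * np.exp(-((X - 0.6) ** 2 + (Y - 0.6) ** 2) / (2 * 0.02)) \
            + 0.05 * rng.standard_normal(grid.bins)
        fes = FESGrid(grid=grid, values=F, thermo=thermo300)
        deep = find_minima(fes, depth_threshold=1.0)
        assert len(deep) == 1


class TestMinimaxSaddle:
    def test_flat_grid_saddle_equals_flat_value(self, thermo300):
        grid = make_flat_square_grid(8)
        fes = FESGrid(grid=grid, values=np.full(grid.bins, 3.3), thermo=thermo300)
        _, v = minimax_saddle(fes, (0.1, 0.1), (1.0, 1.0))
        assert v == pytest.approx(3.3)

    def test_degenerate_endpoints(self, thermo300):
        grid = make_flat_square_grid(8)
        vals = np.arange(64, dtype=float).reshape(8, 8)
        fes = FESGrid(grid=grid, values=vals, thermo=thermo300)
        pt = grid.node_point((3, 4))
        _, v = minimax_saddle(fes, pt, pt)
        assert v == pytest.approx(vals[3, 4])

    def test_notch_in_ridge_is_the_crossing(self, thermo300):
        grid = make_flat_square_grid(12)
        vals = np.zeros((12, 12))
        vals[6, :] = 10.0
        vals[6, 8] = 2.0
        fes = FESGrid(grid=grid, values=vals, thermo=thermo300)
        node, v = minimax_saddle(fes, grid.node_point((2, 2)), grid.node_point((10, 3)))
        assert v == pytest.approx(2.0)
        assert tuple(grid.nearest_node(node)) == (6, 8)

    def test_agrees_with_exhaustive_enumeration_on_tiny_grids(self, thermo300):
        rng = np.random.default_rng(17)
        for _ in range(5):
            grid = make_flat_square_grid(4)
            vals = rng.uniform(0, 10, (4, 4))
            fes = FESGrid(grid=grid, values=vals, thermo=thermo300)
            a_idx, b_idx = (0, 0), (3, 3)
            _, v = minimax_saddle(fes, grid.node_point(a_idx), grid.node_point(b_idx))
            assert v == pytest.approx(exhaustive_minimax(vals, grid, a_idx, b_idx))

    def test_shift_equivariance(self, thermo300):
        rng = np.random.default_rng(23)
        grid = make_flat_square_grid(9)
        vals = rng.uniform(0, 5, (9, 9))
        a, b = grid.node_point((1, 1)), grid.node_point((7, 6))
        f1 = FESGrid(grid=grid, values=vals, thermo=thermo300)
        f2 = FESGrid(grid=grid, values=vals + 42.0, thermo=thermo300)
        _, v1 = minimax_saddle(f1, a, b)
        _, v2 = minimax_saddle(f2, a, b)
        assert v2 - 42.0 == pytest.approx(v1, abs=1e-12)


class TestBarrier:
    def test_zero_for_identical_points(self, fixture_fes):
        assert barrier(fixture_fes, (0.5, 1.0), (0.5, 1.0)) == 0.0

    def test_antisymmetry(self, fixture_fes):
        a, b = (-2.8, 0.8), (0.0, 4.0)
        assert barrier(fixture_fes, a, b) == pytest.approx(
            -barrier(fixture_fes, b, a), abs=1e-12
        )


class TestMarginalize:
    def test_constant_grid_gives_flat_profile(self, small_grid, thermo300):
        fes = FESGrid(grid=small_grid, values=np.full(small_grid.bins, 7.0), thermo=thermo300)
        prof = marginalize(fes, 0)
        assert np.ptp(prof.F) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("keep", [0, 1])
    def test_separable_landscape_recovers_kept_factor(self, small_grid, thermo300, keep):
        f = 3.0 * np.sin(small_grid.centers(0))
        g = 2.0 * (small_grid.centers(1) - 1.0) ** 2
        fes = FESGrid(grid=small_grid, values=f[:, None] + g[None, :], thermo=thermo300)
        prof = marginalize(fes, keep)
        kept = f if keep == 0 else g
        err = (prof.F - prof.F[0]) - (kept - kept[0])
        assert np.abs(err).max() < 1e-8

    def test_self_normalization_on_random_landscapes(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            fes = random_gaussian_landscape(rng, n=12)
            for keep in (0, 1):
                prof = marginalize(fes, keep)
                assert prof.normalization() == pytest.approx(1.0, abs=1e-6)

    def test_low_temperature_limit_tracks_column_minima(self, small_grid):
        rng = np.random.default_rng(2)
        vals = rng.uniform(0, 20, small_grid.bins)
        cold = ThermoContext(temperature=1.0, bias_factor=10.0)
        fes = FESGrid(grid=small_grid, values=vals, thermo=cold)
        prof = marginalize(fes, 0)
        m = vals.min(axis=1)
        err = (prof.F - prof.F[0]) - (m - m[0])
        assert np.abs(err).max() < 0.05  # kB*T ln-terms at T=1 K are tiny

    def test_axis_by_name(self, small_grid, thermo300):
        fes = FESGrid(grid=small_grid, values=np.zeros(small_grid.bins), thermo=thermo300)
        assert marginalize(fes, "z").name == "z"


class TestProfileBarrier:
    def _quadratic_profile(self, thermo300):
        grid = make_flat_square_grid(40, extent=2.0)
        k, s0 = 3.0, 1.0
        f = k * (grid.centers(0) - s0) ** 2
        fes = FESGrid(grid=grid, values=np.tile(f[:, None], (1, 40)), thermo=thermo300)
        return marginalize(fes, 0), k, s0

    def test_zero_for_equal_points(self, thermo300):
        prof, _, _ = self._quadratic_profile(thermo300)
        assert profile_barrier(prof, 0.7, 0.7) == 0.0

    def test_quadratic_matches_closed_form_off_node(self, thermo300):
        prof, k, s0 = self._quadratic_profile(thermo300)
        a, b = 0.33, 1.61  # off-node coordinates
        expected = k * (b - s0) ** 2 - k * (a - s0) ** 2
        got = profile_barrier(prof, a, b)
        assert got == pytest.approx(expected, abs=2 * k * prof.bin_width**2 + 1e-3)

    def test_antisymmetry(self, thermo300):
        prof, _, _ = self._quadratic_profile(thermo300)
        assert profile_barrier(prof, 0.2, 1.4) == pytest.approx(
            -profile_barrier(prof, 1.4, 0.2), abs=1e-12
        )

    def test_out_of_range_rejected(self, thermo300):
        prof, _, _ = self._quadratic_profile(thermo300)
        with pytest.raises(Exception, match="outside"):
            profile_barrier(prof, 0.5, 99.0)
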