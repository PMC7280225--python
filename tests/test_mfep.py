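"""Path initialization, string refinement and transition-state location."""

import io

import numpy as np
import pytest

from memfes.core import CVSpace, GridSpec, MemfesError, ThermoContext
from memfes.landscape import FESGrid, find_minima, minimax_node_path
from memfes.mfep import (
    Path,
    initial_path,
    locate_ts,
    path_table,
    read_path_table,
    refine_mfep,
    write_path_table,
)
from tests.conftest import make_flat_square_grid, random_gaussian_landscape


def valley_fes(a=0.5, b=0.5):
    """F = (z - b - a*psi)^2: analytic valley floor along z = b + a*psi."""
    space = CVSpace(ranges=((-np.pi, np.pi), (0.0, 2.0)))
    grid = GridSpec(cv_space=space, bins=(128, 80))
    X, Y = grid.mesh()
    F = (Y - b - a * X) ** 2
    return FESGrid(grid=grid, values=F, thermo=ThermoContext()), a, b


class TestInitialPath:
    def test_identical_endpoints_give_single_point(self, fixture_fes):
        p = initial_path(fixture_fes, np.array([0.3, 1.0]), np.array([0.3, 1.0]))
        assert len(p) == 1

    def test_flat_grid_gives_straight_segment(self, thermo300):
        grid = make_flat_square_grid(20)
        fes = FESGrid(grid=grid, values=np.zeros(grid.bins), thermo=thermo300)
        a, b = np.array([0.1, 0.2]), np.array([1.0, 0.9])
        p = initial_path(fes, a, b)
        # collinearity: every point on the a-b chord
        t = (p.points - a) / (b - a)
        assert np.allclose(t[:, 0], t[:, 1], atol=1e-9)

    def test_notch_ridge_path_crosses_the_notch(self, thermo300):
        grid = make_flat_square_grid(12)
        vals = np.zeros((12, 12))
        vals[6, :] = 10.0
        vals[6, 8] = 2.0
        fes = FESGrid(grid=grid, values=vals, thermo=thermo300)
        p = initial_path(fes, grid.node_point((2, 2)), grid.node_point((10, 3)))
        notch = grid.node_point((6, 8))
        d = np.linalg.norm(p.points - notch, axis=1)
        assert d.min() < np.hypot(*grid.widths)

    def test_periodic_seam_crossing_stays_continuous(self, fixture_fes):
        # extended pair sits on both sides of +-pi; the path between them
        # crosses the seam without a 2 pi jump
        basins = find_minima(fixture_fes, 1.0)
        ext = [b for b in basins if abs(b.location[0]) > 2.0]
        p = initial_path(fixture_fes, ext[0], ext[1])
        assert np.abs(np.diff(p.points[:, 0])).max() < 0.5


class TestRefine:
    def test_valley_path_settles_on_analytic_floor(self):
        fes, a, b = valley_fes()
        p0 = initial_path(fes, np.array([0.0, 0.5]), np.array([1.0, 1.0]))
        p = refine_mfep(fes, p0, step=5e-3, tol=1e-5)
        dev = np.abs(p.points[:, 1] - b - a * p.points[:, 0])
        assert dev.max() < max(fes.grid.widths)

    def test_already_refined_path_is_fixed_point(self):
        fes, _, _ = valley_fes()
        p0 = initial_path(fes, np.array([0.0, 0.5]), np.array([1.0, 1.0]))
        p1 = refine_mfep(fes, p0, step=5e-3, tol=1e-5)
        p2 = refine_mfep(fes, p1, step=5e-3, tol=1e-4)
        assert p2.converged and p2.iterations <= 2

    def test_endpoints_are_pinned(self, fixture_fes):
        basins = find_minima(fixture_fes, 1.0)
        p0 = initial_path(fixture_fes, basins[0], basins[1])
        p = refine_mfep(fixture_fes, p0)
        assert np.allclose(p.points[0], p0.points[0], atol=1e-12)
        assert np.allclose(p.points[-1], p0.points[-1], atol=1e-12)

    def test_refinement_does_not_raise_the_maximum(self, thermo300):
        rng = np.random.default_rng(31)
        for _ in range(5):
            fes = random_gaussian_landscape(rng, n=15)
            basins = find_minima(fes, 0.5)
            if len(basins) < 2:
                continue
            _, _, minimax_val = minimax_node_path(
                fes, basins[0].location, basins[1].location
            )
            p = refine_mfep(fes, initial_path(fes, basins[0], basins[1]), step=2e-4)
            interp_tol = 0.5 * np.ptp(fes.values) * max(fes.grid.widths)
            assert p.F_along.max() <= minimax_val + interp_tol

    def test_ts_energy_at_least_endpoint_energy(self, fixture_fes):
        basins = find_minima(fixture_fes, 1.0)
        p = refine_mfep(fixture_fes, initial_path(fixture_fes, basins[0], basins[2]))
        assert p.F_along[p.ts_index] >= max(p.F_along[0], p.F_along[-1])

    def test_excessive_step_is_a_stability_error(self, fixture_fes):
        from memfes.core import StabilityError

        basins = find_minima(fixture_fes, 1.0)
        p0 = initial_path(fixture_fes, basins[0], basins[1])
        with pytest.raises(StabilityError):
            refine_mfep(fixture_fes, p0, step=10.0)

    def test_too_short_path_rejected(self, fixture_fes):
        p = Path(points=np.zeros((2, 2)), F_along=np.zeros(2), ts_index=0)
        with pytest.raises(MemfesError):
            refine_mfep(fixture_fes, p)


class TestLocateTS:
    def _symmetric_path(self):
        s = np.linspace(0.0, 1.0, 41)
        pts = np.stack([s, np.zeros_like(s)], axis=1)
        F = 5.0 * np.sin(np.pi * s) ** 2  # symmetric hump, max 5.0 at midpoint
        return Path(points=pts, F_along=F, ts_index=20, converged=True)

    def test_symmetric_hump_ts_at_midpoint(self):
        ts = locate_ts(self._symmetric_path())
        assert ts.point[0] == pytest.approx(0.5, abs=0.02)
        assert ts.free_energy == pytest.approx(5.0, abs=0.01)
        assert not ts.monotone_warning

    def test_monotone_ramp_warns_and_returns_high_end(self):
        s = np.linspace(0.0, 1.0, 11)
        p = Path(points=np.stack([s, s], axis=1), F_along=3.0 * s,
                 ts_index=10, converged=True)
        ts = locate_ts(p)
        assert ts.monotone_warning
        assert ts.free_energy == pytest.approx(3.0)

    def test_unconverged_path_requires_force(self):
        p = self._symmetric_path()
        p.converged = False
        with pytest.raises(MemfesError):
            locate_ts(p)
        assert locate_ts(p, force=True).free_energy == pytest.approx(5.0, abs=0.01)

    def test_fixture_extended_folded_ts_at_constructed_ridge(self, fixture_fes):
        # TS between the extended basin A and folded B sits on the interface
        # band level (~ -6.5 kJ/mol vs bulk water) near psi ~ -2
        basins = find_minima(fixture_fes, 1.0)
        a = next(b for b in basins if b.label == "A")
        bb = next(b for b in basins if b.label == "B")
        p = refine_mfep(fixture_fes, initial_path(fixture_fes, a, bb))
        ts = locate_ts(p, force=True)
        assert ts.free_energy == pytest.approx(-6.5, abs=0.3)
        assert -2.2 < ts.point[0] < -1.7


class TestPathTable:
    def test_single_point_path(self):
        p = Path(points=np.array([[0.1, 1.0]]), F_along=np.array([2.0]), ts_index=0)
        df = path_table(p)
        assert len(df) == 1 and df["arclength"].iloc[0] == 0.0

    def test_arclength_strictly_increasing(self, fixture_fes):
        basins = find_minima(fixture_fes, 1.0)
        p = refine_mfep(fixture_fes, initial_path(fixture_fes, basins[0], basins[1]))
        s = path_table(p)["arclength"].to_numpy()
        assert np.all(np.diff(s) > 0)

    def test_text_roundtrip(self, fixture_fes):
        basins = find_minima(fixture_fes, 1.0)
        p = refine_mfep(fixture_fes, initial_path(fixture_fes, basins[0], basins[1]))
        buf = io.StringIO()
        write_path_table(p, buf)
        buf.seek(0)
        p2 = read_path_table(buf)
        assert np.allclose(p.points, p2.points, rtol=1e-9)
        assert np.allclose(p.F_along, p2.F_along, rtol=1e-9)
        assert p2.ts_index == p.ts_index
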