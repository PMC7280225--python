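"""Well-tempered metadynamics bias evaluation and FES reconstruction.

The accumulated bias is a sum of deposited Gaussians,

    V(s) = sum_k h_k * exp(-sum_i d_i(s, c_k)^2 / (2 sigma_{k,i}^2)),

with the distance d periodic-aware on the torsion axis.  The tempering
rule scales each new hill as w = w0 * exp(-V(s)/(kB * dT)) with
dT = (gamma - 1) T, and the converged estimator of the free energy is

    F(s) = -((T + dT)/dT) * V(s) = -(gamma/(gamma-1)) * V(s).

The reconstruction uses the final accumulated bias (no time-dependent
offset correction), which is what a sum-of-hills pass over a HILLS file
yields; see docs for the implied limitation.  Gaussians are truncated
at 5 sigma per axis (relative error < 4e-6).
"""

from __future__ import annotations

import numpy as np

from .core import ConfigError, GridShapeError, GridSpec, ThermoContext
from .hills_io import HillSeries
from .landscape import FESGrid

#: Per-axis Gaussian truncation radius, in units of sigma.
GAUSSIAN_CUTOFF_SIGMA = 5.0


def bias_at(series: HillSeries, point, ctx: ThermoContext | None = None) -> float:
    """Accumulated bias energy (kJ/mol) at a single CV point.

    An empty series contributes zero bias.  The result is invariant
    under adding full periods to the torsion coordinate of the query.
    """
    n = len(series)
    if n == 0:
        return 0.0
    space = series.cv_space
    pt = space.wrap(np.asarray(point, dtype=float))
    d = space.diff(pt[None, :], series.centers)
    inside = np.all(np.abs(d) <= GAUSSIAN_CUTOFF_SIGMA * series.widths, axis=1)
    if not inside.any():
        return 0.0
    d = d[inside]
    w = series.widths[inside]
    arg = np.sum(d * d / (2.0 * w * w), axis=1)
    return float(np.sum(series.heights[inside] * np.exp(-arg)))


def next_hill_height(
    series: HillSeries, point, w0: float, ctx: ThermoContext
) -> float:
    """Tempered height for the next deposition at ``point``.

    w = w0 * exp(-V(point) / (kB * delta_T)); strictly decreasing under
    repeated deposition at a fixed point, bounded below by zero.
    """
    if w0 <= 0:
        raise ConfigError(f"initial hill height w0 must be positive, got {w0}")
    if ctx.bias_factor <= 1:
        raise ConfigError("bias factor must exceed 1")  # unreachable via ThermoContext
    v = bias_at(series, point, ctx)
    return w0 * float(np.exp(-v / (ctx.kB * ctx.delta_T)))


def _bias_on_grid(series: HillSeries, grid: GridSpec, first: int = 0, last: int | None = None) -> np.ndarray:
    """Accumulated bias of hills[first:last] on every grid node.

    Each hill touches only the nodes within its 5-sigma box (periodic
    wrap on the torsion axis), so cost scales with hills x patch size.
    """
    n0, n1 = grid.bins
    V = np.zeros((n0, n1))
    if len(series) == 0:
        return V
    last = len(series) if last is None else last
    c0 = grid.centers(0)
    c1 = grid.centers(1)
    w0ax, w1ax = grid.widths
    space = grid.cv_space
    for k in range(first, last):
        cx, cy = series.centers[k]
        sx, sy = series.widths[k]
        h = series.heights[k]
        # index windows covering +-5 sigma around the center
        if space.periodic[0]:
            lo0, _ = space.ranges[0]
            i_c = (cx - (lo0 + 0.5 * w0ax)) / w0ax
            r0 = int(np.ceil(GAUSSIAN_CUTOFF_SIGMA * sx / w0ax))
            if 2 * r0 + 1 >= n0:
                idx0 = np.arange(n0)
            else:
                idx0 = (np.arange(int(np.floor(i_c)) - r0, int(np.ceil(i_c)) + r0 + 1)) % n0
            d0 = space.diff(
                np.stack([c0[idx0], np.zeros(len(idx0))], axis=1),
                np.array([cx, 0.0]),
            )[:, 0]
        else:
            i_lo = int(np.floor((cx - GAUSSIAN_CUTOFF_SIGMA * sx - c0[0]) / w0ax))
            i_hi = int(np.ceil((cx + GAUSSIAN_CUTOFF_SIGMA * sx - c0[0]) / w0ax))
            idx0 = np.arange(max(i_lo, 0), min(i_hi + 1, n0))
            d0 = c0[idx0] - cx
        j_lo = int(np.floor((cy - GAUSSIAN_CUTOFF_SIGMA * sy - c1[0]) / w1ax))
        j_hi = int(np.ceil((cy + GAUSSIAN_CUTOFF_SIGMA * sy - c1[0]) / w1ax))
        idx1 = np.arange(max(j_lo, 0), min(j_hi + 1, n1))
        if len(idx0) == 0 or len(idx1) == 0:
            continue
        d1 = c1[idx1] - cy
        g0 = np.exp(-(d0 * d0) / (2.0 * sx * sx))
        g1 = np.exp(-(d1 * d1) / (2.0 * sy * sy))
        V[np.ix_(idx0, idx1)] += h * np.outer(g0, g1)
    return V


def reconstruct_fes(
    series: HillSeries, grid: GridSpec, ctx: ThermoContext
) -> FESGrid:
    """Free energy surface from the final accumulated bias.

    F(s) = -(gamma/(gamma-1)) * V(s) at every grid node; the result is
    un-referenced (no zero has been chosen).  An empty series yields an
    all-zero grid.
    """
    if grid.cv_space.names != series.cv_space.names or tuple(
        grid.cv_space.periodic
    ) != tuple(series.cv_space.periodic):
        raise GridShapeError(
            f"grid CV space {grid.cv_space.names} incompatible with series "
            f"CV space {series.cv_space.names}"
        )
    V = _bias_on_grid(series, grid)
    F = -ctx.wt_prefactor * V
    return FESGrid(grid=grid, values=F, thermo=ctx, explored=np.ones(grid.bins, dtype=bool))


def convergence_profile(
    series: HillSeries, grid: GridSpec, ctx: ThermoContext, n_blocks: int
) -> list[tuple[float, float]]:
    """Block-wise convergence diagnostic.

    The hill stream is split into ``n_blocks`` contiguous blocks; each
    block yields its own FES estimate, and consecutive estimates are
    compared by RMSD over grid nodes after removing each estimate's
    mean (free energies are defined up to a constant).  For a converged
    well-tempered run, hill heights decay, so late-block RMSD falls
    below early-block RMSD.  Returns (time of later block's last hill,
    RMSD) pairs, one per consecutive block pair.
    """
    if n_blocks < 2:
        raise ConfigError(f"n_blocks must be at least 2, got {n_blocks}")
    if len(series) < n_blocks:
        raise ConfigError(
            f"need at least as many hills ({len(series)}) as blocks ({n_blocks})"
        )
    bounds = np.linspace(0, len(series), n_blocks + 1).astype(int)
    estimates = []
    for b in range(n_blocks):
        V = _bias_on_grid(series, grid, first=bounds[b], last=bounds[b + 1])
        F = -ctx.wt_prefactor * V
        estimates.append((float(series.times[bounds[b + 1] - 1]), F))
    out = []
    for (t_prev, f_prev), (t_cur, f_cur) in zip(estimates, estimates[1:]):
        a = f_prev - f_prev.mean()
        b = f_cur - f_cur.mean()
        rmsd = float(np.sqrt(np.mean((a - b) ** 2)))
        out.append((t_cur, rmsd))
    return out
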