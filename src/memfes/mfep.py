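"""Minimum free energy paths on a 2D landscape.

A path between two basins is seeded with the minimax (lowest-crossing)
grid path and refined with the zero-temperature string method: interior
points relax down the component of the free-energy gradient
perpendicular to the path, endpoints stay pinned, and the path is
reparametrized to uniform arc length after every sweep.  The transition
state is the interior free-energy maximum along the converged path,
refined off-node by a parabolic fit.

Torsion coordinates are kept unwrapped (continuous) along the path and
wrapped only for grid lookups, so paths may cross the +-pi seam.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Union

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .core import MemfesError, StabilityError
from .landscape import Basin, FESGrid, minimax_node_path

DEFAULT_N_POINTS = 100
DEFAULT_STEP = 5e-4  # CV-units^2 mol/kJ: displacement = step * grad_perp
DEFAULT_TOL = 1e-4
DEFAULT_MAX_ITER = 5000


@dataclass
class Path:
    """Ordered CV points with free energies along them.

    ``points[:, 0]`` (torsion) is unwrapped; ``ts_index`` marks the
    interior maximum of ``F_along``.
    """

    points: np.ndarray
    F_along: np.ndarray
    ts_index: int
    converged: bool = False
    iterations: int = 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        self.F_along = np.asarray(self.F_along, dtype=float)
        if len(self.points) != len(self.F_along):
            raise MemfesError("points and F_along must have equal length")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def arc_length(self) -> np.ndarray:
        """Cumulative arc length from the first point (unwrapped metric)."""
        if len(self.points) < 2:
            return np.zeros(len(self.points))
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def barrier_from_start(self) -> float:
        return float(self.F_along[self.ts_index] - self.F_along[0])


class TransitionState(NamedTuple):
    point: np.ndarray
    free_energy: float
    kind: str
    monotone_warning: bool = False


def _as_point(x) -> np.ndarray:
    if isinstance(x, Basin):
        return np.asarray(x.location, dtype=float)
    return np.asarray(x, dtype=float).reshape(2)


def _unwrap_along(points: np.ndarray, fes: FESGrid) -> np.ndarray:
    out = np.array(points, dtype=float, copy=True)
    for ax in range(2):
        if fes.grid.cv_space.periodic[ax]:
            out[:, ax] = np.unwrap(out[:, ax], period=fes.grid.cv_space.span(ax))
    return out


def _resample(points: np.ndarray, n: int) -> np.ndarray:
    """Uniform arc-length resampling through a cubic spline in each coordinate."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(np.maximum(seg, 1e-12))])
    target = np.linspace(0.0, s[-1], n)
    if len(points) < 4:
        out = np.stack(
            [np.interp(target, s, points[:, ax]) for ax in range(2)], axis=1
        )
    else:
        out = np.stack(
            [CubicSpline(s, points[:, ax])(target) for ax in range(2)], axis=1
        )
    out[0] = points[0]
    out[-1] = points[-1]
    return out


def _interior_argmax(F: np.ndarray) -> int:
    if len(F) <= 2:
        return int(np.argmax(F))
    return 1 + int(np.argmax(F[1:-1]))


def initial_path(
    fes: FESGrid,
    a: Union[Basin, np.ndarray],
    b: Union[Basin, np.ndarray],
    n_points: int = DEFAULT_N_POINTS,
) -> Path:
    """Seed path a -> b: the minimax grid path, densified to uniform spacing.

    When the straight (torsion-geodesic) segment already achieves the
    minimax crossing level, it is preferred for smoothness — on a flat
    landscape this yields the geodesic segment.
    """
    pa, pb = _as_point(a), _as_point(b)
    space = fes.grid.cv_space
    if np.allclose(space.wrap(pa), space.wrap(pb)):
        pt = space.wrap(pa)
        return Path(points=pt[None, :], F_along=np.array([fes.interpolate(pt)]), ts_index=0)
    node_path, _, saddle_value = minimax_node_path(fes, pa, pb)
    # straight periodic-geodesic candidate
    d = space.diff(pb, pa)
    straight = pa[None, :] + np.linspace(0.0, 1.0, n_points)[:, None] * d[None, :]
    if np.max(fes.interpolate(space.wrap(straight))) <= saddle_value + 1e-9:
        pts = straight
    else:
        nodes = np.array([fes.grid.node_point(idx) for idx in node_path])
        nodes = _unwrap_along(nodes, fes)
        nodes[0] = nodes[0] + space.diff(pa, nodes[0])
        nodes[-1] = nodes[-1] + space.diff(pb, nodes[-1])
        pts = _resample(nodes, n_points)
    F = fes.interpolate(space.wrap(pts))
    return Path(points=pts, F_along=F, ts_index=_interior_argmax(F))


def refine_mfep(
    fes: FESGrid,
    path: Path,
    step: float = DEFAULT_STEP,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> Path:
    """Zero-temperature string relaxation of a path.

    Interior points move by ``-step * grad_perp(F)`` (bilinear-
    interpolated central-difference gradient, component perpendicular to
    the local tangent); endpoints are pinned; the path is reparametrized
    to uniform arc length each iteration.  Converged when the largest
    point displacement in an iteration falls below ``tol``; hitting
    ``max_iter`` is reported via ``converged=False``, not an error.
    """
    if len(path) < 3:
        raise MemfesError("refinement needs a path with at least 3 points")
    if step <= 0:
        raise MemfesError(f"step must be positive, got {step}")
    space = fes.grid.cv_space
    bin_diag = float(np.hypot(*fes.grid.widths))
    pts = np.array(path.points, dtype=float, copy=True)
    n = len(pts)
    converged = False
    it = 0
    best_total = np.inf
    stall = 0
    for it in range(1, max_iter + 1):
        old = pts.copy()
        g = fes.gradient_at(space.wrap(pts))
        tang = np.zeros_like(pts)
        tang[1:-1] = pts[2:] - pts[:-2]
        norms = np.linalg.norm(tang[1:-1], axis=1, keepdims=True)
        tang[1:-1] /= np.maximum(norms, 1e-12)
        g_par = np.sum(g * tang, axis=1, keepdims=True) * tang
        g_perp = g - g_par
        disp = step * g_perp
        max_disp = float(np.max(np.linalg.norm(disp[1:-1], axis=1)))
        if max_disp > 2.0 * bin_diag:
            raise StabilityError(
                f"step {step} moved a point {max_disp:.3g} CV-units in one "
                f"iteration (> 2 bin diagonals {2 * bin_diag:.3g}); reduce step"
            )
        pts[1:-1] -= disp[1:-1]
        # keep the bounded axis inside its range
        for ax in range(2):
            if not space.periodic[ax]:
                lo, hi = space.ranges[ax]
                pts[1:-1, ax] = np.clip(pts[1:-1, ax], lo, hi)
        pts = _resample(pts, n)
        total = float(np.max(np.linalg.norm(pts - old, axis=1)))
        if total < tol:
            converged = True
            break
        # near the fixed point the discretized gradient makes the sweep
        # oscillate instead of contract; halve the step when no progress
        if total < best_total:
            best_total = total
            stall = 0
        else:
            stall += 1
            if stall >= 25:
                step *= 0.5
                stall = 0
    F = fes.interpolate(space.wrap(pts))
    return Path(
        points=pts,
        F_along=F,
        ts_index=_interior_argmax(F),
        converged=converged,
        iterations=it,
    )


def locate_ts(path: Path, kind: str = "local", force: bool = False) -> TransitionState:
    """Transition state: interior argmax of F along the path.

    A parabolic fit over the argmax and its two neighbours refines the
    location and energy off-node.  If F is monotone along the path (no
    interior maximum) the higher endpoint is returned with
    ``monotone_warning=True``.
    """
    if not path.converged and not force and len(path) > 1:
        raise MemfesError(
            "path has not converged; pass force=True to locate the TS anyway"
        )
    F = path.F_along
    n = len(F)
    if n == 1:
        return TransitionState(path.points[0], float(F[0]), kind, False)
    dF = np.diff(F)
    if np.all(dF >= 0) or np.all(dF <= 0):
        k = int(np.argmax([F[0], F[-1]])) * (n - 1)
        return TransitionState(path.points[k], float(F[k]), kind, True)
    k = _interior_argmax(F)
    s = path.arc_length
    s0, s1, s2 = s[k - 1], s[k], s[k + 1]
    f0, f1, f2 = F[k - 1], F[k], F[k + 1]
    # parabola through three (s, F) samples; vertex clamped to the bracket
    denom = (s0 - s1) * (s0 - s2) * (s1 - s2)
    if abs(denom) < 1e-15:
        return TransitionState(path.points[k], float(f1), kind, False)
    a_c = (s2 * (f1 - f0) + s1 * (f0 - f2) + s0 * (f2 - f1)) / denom
    b_c = (s2 * s2 * (f0 - f1) + s1 * s1 * (f2 - f0) + s0 * s0 * (f1 - f2)) / denom
    if a_c >= 0:  # not concave; keep the node
        s_star, f_star = s1, f1
    else:
        s_star = float(np.clip(-b_c / (2 * a_c), s0, s2))
        c_c = f1 - a_c * s1 * s1 - b_c * s1
        f_star = a_c * s_star * s_star + b_c * s_star + c_c
    pt = np.stack(
        [np.interp(s_star, s, path.points[:, ax]) for ax in range(2)]
    )
    return TransitionState(pt, float(f_star), kind, False)


def path_table(path: Path) -> pd.DataFrame:
    """One record per path point: index, torsion, z, F, cumulative arc length."""
    s = path.arc_length
    return pd.DataFrame(
        {
            "index": np.arange(len(path)),
            "psi": path.points[:, 0],
            "z": path.points[:, 1],
            "F": path.F_along,
            "arclength": s,
        }
    )


def write_path_table(path: Path, stream) -> None:
    path_table(path).to_csv(stream, sep="\t", index=False, float_format="%.12g")


def read_path_table(stream) -> Path:
    df = pd.read_csv(stream, sep="\t")
    pts = np.stack([df["psi"].to_numpy(), df["z"].to_numpy()], axis=1)
    F = df["F"].to_numpy()
    return Path(points=pts, F_along=F, ts_index=_interior_argmax(F), converged=True)
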