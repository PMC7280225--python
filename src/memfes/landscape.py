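"""2D free-energy landscape analysis.

Holds the free energy surface F(psi, z) on a uniform grid, applies the
bulk-solvent zero-reference convention, locates stable-state basins and
the lowest crossing (minimax) saddles between them, computes signed
barriers, and marginalizes the surface to a 1D profile by Boltzmann
integration over the discarded collective variable:

    F(s1) = -(1/beta) * ln[ int exp(-beta F(s1,s2)) ds2
                            / int int exp(-beta F(s1,s2)) ds1 ds2 ]

Only free-energy *differences* are physical; every operation here
preserves pairwise differences exactly.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .core import (
    ConnectivityError,
    GridShapeError,
    GridSpec,
    MemfesError,
    ThermoContext,
    ZeroReferenceError,
)

#: Free-energy margin (kJ/mol) added above the explored maximum when
#: capping unexplored nodes for path search and marginalization.
UNEXPLORED_CAP_MARGIN = 20.0


@dataclass
class FESGrid:
    """Free energy values (kJ/mol) on the nodes (bin centers) of a 2D CV grid.

    ``explored`` flags nodes that carry information; unexplored nodes are
    never treated as zero — they are capped above the explored maximum
    wherever a finite value is needed.  ``reference`` records where (and
    why) F was pinned to zero, if at all.
    """

    grid: GridSpec
    values: np.ndarray
    thermo: ThermoContext = field(default_factory=ThermoContext)
    reference: Optional[tuple[np.ndarray, str]] = None
    explored: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.bins:
            raise GridShapeError(
                f"values shape {self.values.shape} does not match grid bins {self.grid.bins}"
            )
        if self.explored is None:
            self.explored = np.isfinite(self.values)
        else:
            self.explored = np.asarray(self.explored, dtype=bool)
            if self.explored.shape != self.values.shape:
                raise GridShapeError("explored mask shape mismatch")
        if not np.all(np.isfinite(self.values[self.explored])):
            raise MemfesError("explored nodes must have finite free energies")

    # -- node access ---------------------------------------------------

    def node_value(self, idx: Sequence[int]) -> float:
        return float(self.values[idx[0], idx[1]])

    def value_at(self, point) -> float:
        """F at the grid node containing ``point`` (no interpolation)."""
        return self.node_value(self.grid.nearest_node(point))

    def is_explored_at(self, point) -> bool:
        i, j = self.grid.nearest_node(point)
        return bool(self.explored[i, j])

    def capped_values(self, margin: float = UNEXPLORED_CAP_MARGIN) -> np.ndarray:
        """Values with unexplored nodes replaced by max(explored) + margin."""
        if self.explored.all():
            return self.values.copy()
        if not self.explored.any():
            raise MemfesError("grid has no explored nodes")
        cap = float(self.values[self.explored].max()) + margin
        out = self.values.copy()
        out[~self.explored] = cap
        return out

    # -- interpolation -------------------------------------------------

    def interpolate(self, points) -> np.ndarray:
        """Bilinear interpolation of F at arbitrary CV points (periodic-aware)."""
        return _bilinear(self.grid, self.capped_values(), points)

    def gradient_at(self, points) -> np.ndarray:
        """Interpolated central-difference gradient (dF/dpsi, dF/dz) at CV points."""
        cache = getattr(self, "_grad_cache", None)
        if cache is None:
            cache = _node_gradient(self.grid, self.capped_values())
            object.__setattr__(self, "_grad_cache", cache)
        g0, g1 = cache
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.stack(
            [_bilinear(self.grid, g0, pts), _bilinear(self.grid, g1, pts)], axis=-1
        )
        return out if np.asarray(points).ndim > 1 else out[0]


def _bilinear(grid: GridSpec, values: np.ndarray, points) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    scalar = np.asarray(points).ndim == 1
    idx = []
    frac = []
    for ax in range(2):
        c = grid.centers(ax)
        n = grid.bins[ax]
        w = grid.widths[ax]
        x = pts[:, ax]
        if grid.cv_space.periodic[ax]:
            t = (x - c[0]) / w
            i0 = np.floor(t).astype(int)
            f = t - i0
            i0 %= n
            i1 = (i0 + 1) % n
        else:
            t = (x - c[0]) / w
            i0 = np.clip(np.floor(t).astype(int), 0, n - 2)
            f = np.clip(t - i0, 0.0, 1.0)
            i1 = i0 + 1
        idx.append((i0, i1))
        frac.append(f)
    (i0, i1), (j0, j1) = idx
    fx, fy = frac
    v = (
        values[i0, j0] * (1 - fx) * (1 - fy)
        + values[i1, j0] * fx * (1 - fy)
        + values[i0, j1] * (1 - fx) * fy
        + values[i1, j1] * fx * fy
    )
    return float(v[0]) if scalar else v


def _node_gradient(grid: GridSpec, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference gradient per axis; periodic wrap on periodic axes,
    one-sided differences at non-periodic edges."""
    grads = []
    for ax in range(2):
        w = grid.widths[ax]
        if grid.cv_space.periodic[ax]:
            g = (np.roll(values, -1, axis=ax) - np.roll(values, 1, axis=ax)) / (2 * w)
        else:
            g = np.gradient(values, w, axis=ax)
        grads.append(g)
    return grads[0], grads[1]


# ---------------------------------------------------------------------
# zero reference


def set_zero_reference(fes: FESGrid, ref, note: str = "") -> FESGrid:
    """Return a copy shifted so F = 0 at the node containing ``ref``.

    Pairwise differences are untouched; only the additive gauge changes.
    """
    idx = fes.grid.nearest_node(ref)
    if not fes.explored[idx[0], idx[1]]:
        raise ZeroReferenceError(
            f"reference point {tuple(np.asarray(ref, float))} falls on an unexplored node {idx}"
        )
    shift = fes.node_value(idx)
    return replace(
        fes,
        values=fes.values - shift,
        reference=(np.asarray(ref, dtype=float), note or "user reference"),
        explored=fes.explored.copy(),
    )


# ---------------------------------------------------------------------
# basins


@dataclass(frozen=True)
class Basin:
    """A stable state: strict local minimum of the FES with a label (A, B, ...)."""

    location: np.ndarray
    free_energy: float
    label: str
    node: tuple[int, int] = (0, 0)


def _strict_local_minima(grid: GridSpec, values: np.ndarray) -> list[tuple[int, int]]:
    n0, n1 = grid.bins
    out = []
    for i in range(n0):
        for j in range(n1):
            v = values[i, j]
            if all(v < values[ii, jj] for ii, jj in grid.neighbors8(i, j)):
                out.append((i, j))
    return out


def _minima_depths(grid: GridSpec, values: np.ndarray) -> dict[tuple[int, int], float]:
    """Persistence of every local minimum by a watershed union-find sweep.

    Nodes are flooded in order of increasing F; when the component born
    at a minimum first touches a component with a lower birth level, the
    current level is that minimum's escape (minimax) level.  Returns
    minimum node -> depth (escape level - own F); the global minimum
    gets infinite depth.
    """
    n0, n1 = grid.bins
    flat_vals = values.ravel()
    order = np.argsort(flat_vals, kind="stable")
    comp = np.full(n0 * n1, -1, dtype=np.int64)
    parent: dict[int, int] = {}
    depths: dict[int, float] = {}

    def find(r: int) -> int:
        while parent[r] != r:
            parent[r] = parent[parent[r]]
            r = parent[r]
        return r

    for flat in order:
        i, j = divmod(int(flat), n1)
        v = flat_vals[flat]
        roots = set()
        for ii, jj in grid.neighbors8(i, j):
            c = comp[ii * n1 + jj]
            if c >= 0:
                roots.add(find(int(c)))
        if not roots:
            comp[flat] = flat
            parent[int(flat)] = int(flat)
            continue
        best = min(roots, key=lambda r: (flat_vals[r], r))
        comp[flat] = best
        for r in roots - {best}:
            depths[r] = float(v - flat_vals[r])
            parent[r] = best
    out = {}
    for r in parent:
        if find(r) == r:  # survived to the end: global minimum
            depths.setdefault(r, np.inf)
    for r, d in depths.items():
        out[(r // n1, r % n1)] = d
    return out


def find_minima(fes: FESGrid, depth_threshold: float = 1.0) -> list[Basin]:
    """Strict 8-neighbourhood local minima deeper than ``depth_threshold``.

    Depth of a minimum is its minimax escape level — the lowest maximum-F
    over grid paths leading to any strictly lower node — minus its own F.
    The global minimum has infinite depth.  Basins are sorted by F
    ascending and labelled A, B, C, ... in that order.
    """
    if depth_threshold < 0:
        raise MemfesError("depth_threshold must be non-negative")
    values = fes.capped_values()
    minima = _strict_local_minima(fes.grid, values)
    depths = _minima_depths(fes.grid, values)
    kept: list[tuple[float, tuple[int, int]]] = []
    for (i, j) in minima:
        if depths.get((i, j), 0.0) > depth_threshold:
            kept.append((float(values[i, j]), (i, j)))
    kept.sort(key=lambda t: (t[0], t[1]))
    return [
        Basin(
            location=fes.grid.node_point(idx),
            free_energy=v,
            label=chr(ord("A") + k),
            node=idx,
        )
        for k, (v, idx) in enumerate(kept)
    ]


# ---------------------------------------------------------------------
# minimax (widest-path) search


def _minimax_dijkstra(
    grid: GridSpec,
    values: np.ndarray,
    start: tuple[int, int],
    targets: Optional[np.ndarray] = None,
):
    """Label-setting search minimizing the maximum F along 8-connected paths.

    Ties are broken by path length (hops), then by lexicographic node
    order, so the result is deterministic.  Returns (dist, hops, parent);
    ``parent`` maps node -> predecessor for path reconstruction.  If
    ``targets`` (boolean mask) is given, the search stops once every
    reachable target is finalized or the first target is popped.
    """
    n0, n1 = grid.bins
    dist = np.full((n0, n1), np.inf)
    hops = np.full((n0, n1), np.inf)
    parent: dict[tuple[int, int], tuple[int, int]] = {}
    done = np.zeros((n0, n1), dtype=bool)
    si, sj = start
    dist[si, sj] = values[si, sj]
    hops[si, sj] = 0
    heap: list[tuple[float, float, int, int]] = [(dist[si, sj], 0.0, si, sj)]
    while heap:
        d, h, i, j = heapq.heappop(heap)
        if done[i, j]:
            continue
        done[i, j] = True
        if targets is not None and targets[i, j]:
            break
        for ii, jj in grid.neighbors8(i, j):
            if done[ii, jj]:
                continue
            nd = max(d, values[ii, jj])
            nh = h + 1
            cur_parent = parent.get((ii, jj), (np.inf, np.inf))
            if (nd, nh, (i, j)) < (dist[ii, jj], hops[ii, jj], cur_parent):
                dist[ii, jj] = nd
                hops[ii, jj] = nh
                parent[(ii, jj)] = (i, j)
                heapq.heappush(heap, (nd, nh, ii, jj))
    return dist, hops, parent


def minimax_node_path(
    fes: FESGrid, a, b
) -> tuple[list[tuple[int, int]], tuple[int, int], float]:
    """Node path a -> b minimizing the path maximum of F.

    Returns (node index path, saddle node, saddle value); the saddle is
    the node realizing the path maximum (the lowest crossing level).
    """
    values = fes.capped_values()
    ia = fes.grid.nearest_node(a)
    ib = fes.grid.nearest_node(b)
    if not fes.explored[ia[0], ia[1]] or not fes.explored[ib[0], ib[1]]:
        raise MemfesError("both endpoints must lie on explored nodes")
    if ia == ib:
        return [ia], ia, values[ia[0], ia[1]]
    target_mask = np.zeros(fes.grid.bins, dtype=bool)
    target_mask[ib[0], ib[1]] = True
    dist, _, parent = _minimax_dijkstra(fes.grid, values, ia, targets=target_mask)
    if not np.isfinite(dist[ib[0], ib[1]]):
        raise ConnectivityError(f"no grid path connects {ia} to {ib}")
    path = [ib]
    while path[-1] != ia:
        path.append(parent[path[-1]])
    path.reverse()
    # saddle: node of maximum F; ties resolved toward the first occurrence
    vals = [values[i, j] for i, j in path]
    k = int(np.argmax(vals))
    return path, path[k], float(vals[k])


def minimax_saddle(fes: FESGrid, a, b) -> tuple[np.ndarray, float]:
    """Lowest crossing point between two CV points.

    Over all 8-connected grid paths a -> b, take the path whose maximum F
    is smallest; return that maximum's node (as a CV point) and value.
    """
    _, node, value = minimax_node_path(fes, a, b)
    return fes.grid.node_point(node), value


def barrier(fes: FESGrid, start, crossing) -> float:
    """Signed free-energy difference F(crossing) - F(start) at grid nodes."""
    for p in (start, crossing):
        if not fes.is_explored_at(p):
            raise MemfesError(f"point {tuple(np.asarray(p, float))} is unexplored")
    return fes.value_at(crossing) - fes.value_at(start)


# ---------------------------------------------------------------------
# marginalization


@dataclass
class Profile1D:
    """Boltzmann-marginalized free energy over a single CV.

    Self-normalized by construction: sum(exp(-beta F) * bin_width) = 1.
    ``rezero_*`` helpers change only the reporting gauge, tracked in
    ``offset`` so the normalized form can always be recovered.
    """

    axis: int
    name: str
    centers: np.ndarray
    F: np.ndarray
    thermo: ThermoContext
    periodic: bool = False
    bin_width: float = 0.0
    offset: float = 0.0

    def normalization(self) -> float:
        beta = self.thermo.beta
        return float(np.sum(np.exp(-beta * (self.F + self.offset))) * self.bin_width)

    def value_at(self, s: float) -> float:
        """F at an arbitrary coordinate by linear interpolation between bin centers."""
        c, f = self.centers, self.F
        if self.periodic:
            period = self.bin_width * len(c)
            s = c[0] + np.mod(s - c[0], period)
            c = np.concatenate([c, [c[0] + period]])
            f = np.concatenate([f, [f[0]]])
        else:
            lo = c[0] - 0.5 * self.bin_width
            hi = c[-1] + 0.5 * self.bin_width
            if s < lo - 1e-9 or s > hi + 1e-9:
                raise MemfesError(f"{self.name}={s} outside profile range [{lo}, {hi}]")
        return float(np.interp(s, c, f))

    def rezero_at(self, s: float) -> "Profile1D":
        """Shift so F(s) = 0 (e.g. bulk-water z reference)."""
        shift = self.value_at(s)
        return replace(self, F=self.F - shift, offset=self.offset + shift)

    def rezero_min(self) -> "Profile1D":
        """Shift so the profile minimum is 0 (convention for torsion profiles)."""
        shift = float(self.F.min())
        return replace(self, F=self.F - shift, offset=self.offset + shift)


def marginalize(fes: FESGrid, keep_axis: int | str) -> Profile1D:
    """Integrate out one CV by Boltzmann weighting (midpoint quadrature).

    F(s1) = -(1/beta) ln[ sum_j exp(-beta F(s1, s2_j)) ds2 / Z ] with
    Z the double sum; the output satisfies sum(exp(-beta F) ds1) = 1
    to machine precision.  Unexplored nodes enter at the cap level and
    contribute essentially nothing.
    """
    if isinstance(keep_axis, str):
        try:
            keep_axis = fes.grid.cv_space.names.index(keep_axis)
        except ValueError:
            raise MemfesError(f"unknown CV name {keep_axis!r}") from None
    if keep_axis not in (0, 1):
        raise MemfesError(f"keep_axis must be 0 or 1, got {keep_axis}")
    other = 1 - keep_axis
    beta = fes.thermo.beta
    W = fes.capped_values()
    if not np.all(np.isfinite(W)):
        raise MemfesError("non-finite free energies remain after capping")
    A = -beta * W
    d_other = fes.grid.widths[other]
    d_keep = fes.grid.widths[keep_axis]
    log_num = logsumexp(A, axis=other) + np.log(d_other)
    log_den = logsumexp(log_num) + np.log(d_keep)
    F = -(log_num - log_den) / beta
    return Profile1D(
        axis=keep_axis,
        name=fes.grid.cv_space.names[keep_axis],
        centers=fes.grid.centers(keep_axis),
        F=F,
        thermo=fes.thermo,
        periodic=fes.grid.cv_space.periodic[keep_axis],
        bin_width=d_keep,
    )


def profile_barrier(profile: Profile1D, a: float, b: float) -> float:
    """Signed barrier F(b) - F(a) on a 1D profile, linear interpolation off-node."""
    return profile.value_at(b) - profile.value_at(a)
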