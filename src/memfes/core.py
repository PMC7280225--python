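"""Shared physical and geometric primitives for CV-space free-energy analysis.

The two collective variables used throughout are a periodic molecular
torsion (dihedral, radians) and a bounded membrane-normal distance
(nm).  Everything downstream — bias evaluation, landscape analysis,
path refinement — works on a uniform grid over this 2D CV box.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

#: Boltzmann constant in kJ/(mol K) (CODATA), the energy unit of the package.
KB_KJ_PER_MOL_K = 0.008314462618

TWO_PI = 2.0 * np.pi


class MemfesError(Exception):
    """Base class for package errors."""


class FormatError(MemfesError):
    """A text input does not follow the expected dialect."""


class GridShapeError(MemfesError):
    """A grid is incomplete or incompatible with an operation."""


class OrderingError(MemfesError):
    """Time stamps are not non-decreasing."""


class ZeroReferenceError(MemfesError):
    """The requested zero-reference point is unusable (e.g. unexplored)."""


class ConfigError(MemfesError):
    """Invalid configuration value or unknown key."""


class StabilityError(MemfesError):
    """A numerical integration or relaxation step exceeded its stability bound."""


class ConnectivityError(MemfesError):
    """Two points cannot be joined through the explored region."""


@dataclass(frozen=True)
class ThermoContext:
    """Thermodynamic context: temperature, Boltzmann constant, bias factor.

    ``bias_factor`` is the well-tempered gamma; the tempering temperature
    boost is ``delta_T = (gamma - 1) * T`` and the FES estimator prefactor
    is ``(T + delta_T)/delta_T = gamma/(gamma - 1)``.  ``beta`` is always
    derived from ``T`` and ``kB``, never stored.
    """

    temperature: float = 303.15
    bias_factor: float = 10.0
    kB: float = KB_KJ_PER_MOL_K

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ConfigError(f"temperature must be positive, got {self.temperature}")
        if self.kB <= 0:
            raise ConfigError(f"kB must be positive, got {self.kB}")
        if self.bias_factor <= 1:
            raise ConfigError(
                f"bias_factor must exceed 1 for well-tempered runs, got {self.bias_factor}"
            )

    @property
    def beta(self) -> float:
        return 1.0 / (self.kB * self.temperature)

    @property
    def kBT(self) -> float:
        return self.kB * self.temperature

    @property
    def delta_T(self) -> float:
        return (self.bias_factor - 1.0) * self.temperature

    @property
    def wt_prefactor(self) -> float:
        """(T + delta_T)/delta_T — maps final bias to free energy."""
        return self.bias_factor / (self.bias_factor - 1.0)


@dataclass(frozen=True)
class CVSpace:
    """Two collective variables with names, periodicity flags and ranges.

    A periodic axis must span exactly one period; its coordinates are
    canonically wrapped into ``(lo, hi]``.
    """

    names: tuple[str, str] = ("psi", "z")
    periodic: tuple[bool, bool] = (True, False)
    ranges: tuple[tuple[float, float], tuple[float, float]] = (
        (-np.pi, np.pi),
        (0.0, 4.5),
    )

    def __post_init__(self) -> None:
        for (lo, hi) in self.ranges:
            if not hi > lo:
                raise ConfigError(f"empty CV range ({lo}, {hi})")

    def span(self, axis: int) -> float:
        lo, hi = self.ranges[axis]
        return hi - lo

    def wrap_axis(self, axis: int, x):
        """Wrap coordinates of one axis into (lo, hi] if periodic; else pass through."""
        if not self.periodic[axis]:
            return x
        lo, hi = self.ranges[axis]
        p = hi - lo
        return hi - np.mod(hi - np.asarray(x), p)

    def wrap(self, points):
        """Wrap an (..., 2) array of CV points into canonical ranges."""
        pts = np.array(points, dtype=float, copy=True)
        for ax in range(2):
            if self.periodic[ax]:
                pts[..., ax] = self.wrap_axis(ax, pts[..., ax])
        return pts

    def diff(self, a, b):
        """Minimum-image difference a - b, periodic-aware per axis."""
        d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
        d = np.array(d, copy=True)
        for ax in range(2):
            if self.periodic[ax]:
                p = self.span(ax)
                d[..., ax] -= p * np.round(d[..., ax] / p)
        return d

    def contains(self, points, atol: float = 1e-9) -> bool:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        for ax in range(2):
            if self.periodic[ax]:
                continue
            lo, hi = self.ranges[ax]
            if np.any(pts[:, ax] < lo - atol) or np.any(pts[:, ax] > hi + atol):
                return False
        return True


@dataclass(frozen=True)
class GridSpec:
    """Uniform rectangular grid over a CV space; node values live on bin centers."""

    cv_space: CVSpace
    bins: tuple[int, int]

    def __post_init__(self) -> None:
        if any(b < 2 for b in self.bins):
            raise ConfigError(f"each axis needs at least 2 bins, got {self.bins}")

    @property
    def widths(self) -> tuple[float, float]:
        return tuple(self.cv_space.span(ax) / self.bins[ax] for ax in range(2))

    def centers(self, axis: int) -> np.ndarray:
        lo, hi = self.cv_space.ranges[axis]
        n = self.bins[axis]
        w = (hi - lo) / n
        return lo + (np.arange(n) + 0.5) * w

    def edges(self, axis: int) -> np.ndarray:
        lo, hi = self.cv_space.ranges[axis]
        return np.linspace(lo, hi, self.bins[axis] + 1)

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.centers(0), self.centers(1), indexing="ij")

    def nearest_node(self, point) -> tuple[int, int]:
        """Index of the grid node (bin) containing/closest to a CV point."""
        pt = self.cv_space.wrap(np.asarray(point, dtype=float))
        idx = []
        for ax in range(2):
            lo, _ = self.cv_space.ranges[ax]
            i = int(np.floor((pt[ax] - lo) / self.widths[ax]))
            if self.cv_space.periodic[ax]:
                i %= self.bins[ax]
            else:
                i = min(max(i, 0), self.bins[ax] - 1)
            idx.append(i)
        return tuple(idx)

    def node_point(self, idx: Sequence[int]) -> np.ndarray:
        return np.array([self.centers(0)[idx[0]], self.centers(1)[idx[1]]])

    def neighbors8(self, i: int, j: int):
        """Indices of the 8-connected neighbours, periodic-aware; yields (i, j) pairs."""
        n0, n1 = self.bins
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == 0 and dj == 0:
                    continue
                ii, jj = i + di, j + dj
                if self.cv_space.periodic[0]:
                    ii %= n0
                elif not 0 <= ii < n0:
                    continue
                if self.cv_space.periodic[1]:
                    jj %= n1
                elif not 0 <= jj < n1:
                    continue
                yield ii, jj

    def compatible_with(self, other: "GridSpec", atol: float = 1e-9) -> bool:
        if self.bins != other.bins:
            return False
        a, b = self.cv_space, other.cv_space
        if a.periodic != b.periodic:
            return False
        return all(
            abs(a.ranges[ax][0] - b.ranges[ax][0]) < atol
            and abs(a.ranges[ax][1] - b.ranges[ax][1]) < atol
            for ax in range(2)
        )


def default_grid(z_max: float = 4.5, bins_psi: int = 144, bins_z: int = 120) -> GridSpec:
    """Default analysis grid: ~0.044 rad torsion resolution, ~z_max/bins nm in z."""
    space = CVSpace(ranges=((-np.pi, np.pi), (0.0, z_max)))
    return GridSpec(cv_space=space, bins=(bins_psi, bins_z))
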