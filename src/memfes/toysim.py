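"""Synthetic-data generation: analytic 2D potentials, a membrane-binding
fixture landscape, and overdamped Langevin dynamics with well-tempered
metadynamics.

Ground-truth potentials are closed-form sums of (i) cosine series in the
periodic torsion, (ii) polynomials in the membrane-normal distance z and
(iii) 2D Gaussian wells/ridges (periodic-aware in the torsion), so value
and gradient are exact everywhere.  The simulator emits standard
HILLS/COLVAR containers so the analysis pipeline consumes synthetic and
real data identically.

The fixture landscape encodes the printed features of melatonin at a
cholesterol-free DMPC bilayer: four interface basins (extended pair at
torsion ~ +-2.8 rad, folded pair at +-1.17 rad, all near z ~ 0.8 nm), a
flat bulk-water shelf at F = 0 beyond z = 3 nm, a 25.3 kJ/mol
interface-to-water rise and a 40 kJ/mol membrane-center wall.  The
extended pair sits at the measured dihedral (2.96 +- 0.18 rad rounds to
pi in contour plots); placing the two wells strictly inside +-pi keeps
them distinct minima on the periodic axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import (
    CVSpace,
    GridSpec,
    MemfesError,
    StabilityError,
    ThermoContext,
)
from .hills_io import CVTrajectory, HillSeries
from .landscape import FESGrid

# ---------------------------------------------------------------------
# analytic potential terms


@dataclass(frozen=True)
class CosineTerm:
    """a * cos(k * (psi - phase)) — periodic torsion term."""

    amplitude: float
    multiplicity: int
    phase: float = 0.0

    def value(self, pts: np.ndarray, space: CVSpace) -> np.ndarray:
        return self.amplitude * np.cos(self.multiplicity * (pts[..., 0] - self.phase))

    def gradient(self, pts: np.ndarray, space: CVSpace) -> np.ndarray:
        g = np.zeros_like(pts)
        g[..., 0] = -self.amplitude * self.multiplicity * np.sin(
            self.multiplicity * (pts[..., 0] - self.phase)
        )
        return g


@dataclass(frozen=True)
class PolynomialZ:
    """sum_i c_i * z**i — wells and walls on the bounded axis."""

    coeffs: tuple[float, ...]

    def value(self, pts: np.ndarray, space: CVSpace) -> np.ndarray:
        return np.polynomial.polynomial.polyval(pts[..., 1], self.coeffs)

    def gradient(self, pts: np.ndarray, space: CVSpace) -> np.ndarray:
        g = np.zeros_like(pts)
        dcoeffs = np.polynomial.polynomial.polyder(self.coeffs)
        g[..., 1] = np.polynomial.polynomial.polyval(pts[..., 1], dcoeffs)
        return g


@dataclass(frozen=True)
class Gaussian2D:
    """height * exp(-dpsi^2/2s0^2 - dz^2/2s1^2); negative height = well.

    The torsion offset uses the minimum image; widths well below one
    period keep the term smooth across the seam.
    """

    center: tuple[float, float]
    sigma: tuple[float, float]
    height: float

    def _offsets(self, pts: np.ndarray, space: CVSpace) -> np.ndarray:
        return space.diff(pts, np.asarray(self.center, dtype=float))

    def value(self, pts: np.ndarray, space: CVSpace) -> np.ndarray:
        d = self._offsets(pts, space)
        s0, s1 = self.sigma
        arg = d[..., 0] ** 2 / (2 * s0 * s0) + d[..., 1] ** 2 / (2 * s1 * s1)
        return self.height * np.exp(-arg)

    def gradient(self, pts: np.ndarray, space: CVSpace) -> np.ndarray:
        d = self._offsets(pts, space)
        s0, s1 = self.sigma
        e = self.value(pts, space)
        g = np.empty_like(pts)
        g[..., 0] = e * (-d[..., 0] / (s0 * s0))
        g[..., 1] = e * (-d[..., 1] / (s1 * s1))
        return g


@dataclass(frozen=True)
class AnalyticPotential:
    """Closed-form 2D potential: value and gradient exact everywhere,
    periodic in the torsion with period 2 pi."""

    cv_space: CVSpace
    terms: tuple = ()

    def value(self, points) -> np.ndarray | float:
        pts = np.asarray(points, dtype=float)
        scalar = pts.ndim == 1
        p = np.atleast_2d(pts)
        v = np.zeros(p.shape[:-1])
        for t in self.terms:
            v = v + t.value(p, self.cv_space)
        return float(v[0]) if scalar else v.reshape(pts.shape[:-1])

    def gradient(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        scalar = pts.ndim == 1
        p = np.atleast_2d(pts)
        g = np.zeros_like(p)
        for t in self.terms:
            g = g + t.gradient(p, self.cv_space)
        return g[0] if scalar else g.reshape(pts.shape)


def potential_gradient(pot: AnalyticPotential, point) -> np.ndarray:
    """Analytic gradient of the potential at a CV point."""
    return pot.gradient(point)


# ---------------------------------------------------------------------
# fixture landscape

#: Construction constants of the membrane-binding fixture (kJ/mol, rad, nm).
FIXTURE_WELLS = (  # (psi, z) centers of the four interface basins A..D
    (-2.8, 0.79),
    (-1.17, 0.80),
    (1.17, 0.80),
    (2.8, 0.80),
)
FIXTURE_WELL_F = (-25.3, -24.9, -24.5, -24.1)  # basin free energies vs bulk water
FIXTURE_WELL_SIGMA = (0.25, 0.25)
FIXTURE_BAND = (-6.5, 0.85, 0.45)  # interface band: depth, z0, sigma_z
FIXTURE_WALL_SIGMA = 0.30
FIXTURE_CENTER_BARRIER = 40.0  # F(z=0) - F(basin A)
FIXTURE_IFACE_WATER_BARRIER = 25.3  # F(psi_A, 4 nm) - F(basin A)


def melatonin_like_potential(z_max: float = 4.5) -> AnalyticPotential:
    """Analytic fixture potential with the four-basin membrane landscape.

    Well depths and the wall amplitude are solved (small linear system +
    two fixed-point sweeps) so that F at the well centers and at the
    membrane center hit the construction targets exactly, despite the
    overlap of neighbouring terms.
    """
    space = CVSpace(ranges=((-math.pi, math.pi), (0.0, z_max)))
    centers = np.asarray(FIXTURE_WELLS, dtype=float)
    targets = np.asarray(FIXTURE_WELL_F, dtype=float)
    s0, s1 = FIXTURE_WELL_SIGMA
    band_amp, band_z0, band_sz = FIXTURE_BAND

    def band(z):
        return band_amp * np.exp(-((z - band_z0) ** 2) / (2 * band_sz**2))

    def wall(z, W):
        return W * np.exp(-(z**2) / (2 * FIXTURE_WALL_SIGMA**2))

    # overlap matrix between well centers (periodic torsion distance)
    d = space.diff(centers[:, None, :], centers[None, :, :])
    M = np.exp(-(d[..., 0] ** 2) / (2 * s0 * s0) - (d[..., 1] ** 2) / (2 * s1 * s1))

    W = FIXTURE_CENTER_BARRIER + targets[0]  # first guess, refined below
    depths = np.zeros(4)
    for _ in range(4):
        bg = band(centers[:, 1]) + wall(centers[:, 1], W)
        depths = np.linalg.solve(M, targets - bg)
        # F at (psi_A, 0) must equal targets[0] + center barrier
        p0 = np.array([centers[0, 0], 0.0])
        dd = space.diff(p0[None, :], centers)
        well_at_0 = float(
            np.sum(
                depths
                * np.exp(-(dd[:, 0] ** 2) / (2 * s0 * s0) - (dd[:, 1] ** 2) / (2 * s1 * s1))
            )
        )
        W = FIXTURE_CENTER_BARRIER + targets[0] - float(band(0.0)) - well_at_0

    terms = [
        Gaussian2D(center=(0.0, band_z0), sigma=(1e6, band_sz), height=band_amp),
        Gaussian2D(center=(0.0, 0.0), sigma=(1e6, FIXTURE_WALL_SIGMA), height=W),
    ]
    for (c, h) in zip(centers, depths):
        terms.append(Gaussian2D(center=tuple(c), sigma=(s0, s1), height=float(h)))
    return AnalyticPotential(cv_space=space, terms=tuple(terms))


def make_melatonin_like_fes(
    grid: GridSpec, thermo: Optional[ThermoContext] = None
) -> FESGrid:
    """Evaluate the fixture potential on a grid (bulk water at F = 0).

    The grid must cover the torsion over a full period and z up to at
    least 4.5 nm so all constructed features fit.
    """
    lo, hi = grid.cv_space.ranges[1]
    if not (grid.cv_space.periodic[0] and lo <= 0.0 and hi >= 4.5):
        raise MemfesError(
            "fixture needs a periodic torsion axis and z covering [0, 4.5] nm; "
            f"got periodic={grid.cv_space.periodic[0]}, z range=({lo}, {hi})"
        )
    pot = melatonin_like_potential(z_max=hi)
    X, Y = grid.mesh()
    pts = np.stack([X, Y], axis=-1)
    F = pot.value(pts)
    return FESGrid(
        grid=grid,
        values=F,
        thermo=thermo or ThermoContext(),
        explored=np.ones(grid.bins, dtype=bool),
    )


def double_well_potential(
    barrier: float = 10.0, z0: float = 2.0, k_z: float = 25.0, z_max: float = 4.0
) -> AnalyticPotential:
    """Periodic double well in the torsion with harmonic confinement in z.

    U = (barrier/2) (1 - cos 2 psi) + (k_z/2)(z - z0)^2: minima at
    psi = 0 and pi, barrier tops at +-pi/2 of exactly ``barrier`` kJ/mol.
    """
    space = CVSpace(ranges=((-math.pi, math.pi), (0.0, z_max)))
    terms = (
        CosineTerm(amplitude=-barrier / 2.0, multiplicity=2),
        PolynomialZ(coeffs=(barrier / 2.0 + k_z * z0 * z0 / 2.0, -k_z * z0, k_z / 2.0)),
    )
    return AnalyticPotential(cv_space=space, terms=terms)


# ---------------------------------------------------------------------
# Langevin + well-tempered metadynamics


@dataclass(frozen=True)
class MetadParams:
    """Deposition parameters: initial height w0 (kJ/mol), per-CV sigma,
    pace (steps between depositions) and bias factor gamma."""

    w0: float = 1.2
    sigma: tuple[float, float] = (0.35, 0.1)
    pace: int = 500
    bias_factor: float = 10.0

    def __post_init__(self) -> None:
        if self.w0 <= 0 or any(s <= 0 for s in self.sigma) or self.pace <= 0:
            raise MemfesError("metadynamics parameters must be positive")
        if self.bias_factor <= 1:
            raise MemfesError("bias factor must exceed 1")


def langevin_wtmetad(
    pot: AnalyticPotential,
    ctx: ThermoContext,
    mp: MetadParams,
    n_steps: int,
    dt: float,
    seed: int,
    diffusion: tuple[float, float] = (0.1, 0.1),
    start: Optional[Sequence[float]] = None,
    record_stride: int = 10,
    biased: bool = True,
) -> tuple[CVTrajectory, HillSeries]:
    """Overdamped Langevin dynamics with on-the-fly hill deposition.

    Update: x <- x - D beta grad(U + V) dt + sqrt(2 D dt) eta, with the
    torsion wrapped and z reflected at the box walls.  Hills are
    deposited every ``pace`` steps with the well-tempered height rule.
    A single counter-based noise stream (Philox) keyed by ``seed`` makes
    trajectory and hills bit-reproducible given (seed, params).
    """
    space = pot.cv_space
    rng = np.random.Generator(np.random.Philox(seed))
    noise = rng.standard_normal((n_steps, 2))
    D = np.asarray(diffusion, dtype=float)
    beta = ctx.beta
    amp = np.sqrt(2.0 * D * dt)
    kB_dT = ctx.kB * (mp.bias_factor - 1.0) * ctx.temperature
    inv2s2 = 1.0 / (2.0 * np.asarray(mp.sigma) ** 2)
    a1, a2 = inv2s2
    s1, s2 = mp.sigma
    z_lo, z_hi = space.ranges[1]
    psi_period = space.span(0)
    periodic0 = space.periodic[0]

    if start is None:
        x0 = 0.5 * (space.ranges[0][0] + space.ranges[0][1])
        x1 = 0.5 * (z_lo + z_hi)
    else:
        x0, x1 = float(start[0]), float(start[1])

    n_hills_max = n_steps // mp.pace if biased else 0
    hc1 = np.empty(n_hills_max)
    hc2 = np.empty(n_hills_max)
    hh = np.empty(n_hills_max)
    ht = np.empty(n_hills_max)
    m = 0

    n_rec = n_steps // record_stride
    rec_t = np.empty(n_rec)
    rec_x = np.empty((n_rec, 2))
    rec_v = np.empty(n_rec)
    r = 0

    max_step = 5.0 * np.asarray(mp.sigma)

    def bias_terms(px: float, pz: float):
        if m == 0:
            return 0.0, 0.0, 0.0
        d1 = px - hc1[:m]
        if periodic0:
            d1 -= psi_period * np.round(d1 / psi_period)
        d2 = pz - hc2[:m]
        e = hh[:m] * np.exp(-(d1 * d1 * a1 + d2 * d2 * a2))
        v = float(e.sum())
        return v, float(-2.0 * a1 * (e @ d1)), float(-2.0 * a2 * (e @ d2))

    pt = np.empty(2)
    for i in range(n_steps):
        pt[0], pt[1] = x0, x1
        gU = pot.gradient(pt)
        if biased and m:
            _, gV0, gV1 = bias_terms(x0, x1)
        else:
            gV0 = gV1 = 0.0
        dx0 = -D[0] * beta * (gU[0] + gV0) * dt + amp[0] * noise[i, 0]
        dx1 = -D[1] * beta * (gU[1] + gV1) * dt + amp[1] * noise[i, 1]
        if abs(dx0) > max_step[0] or abs(dx1) > max_step[1]:
            raise StabilityError(
                f"divergent step at t={i * dt:.6g}: |dx|=({abs(dx0):.3g}, "
                f"{abs(dx1):.3g}) exceeds 5 sigma; reduce dt={dt}"
            )
        x0 += dx0
        x1 += dx1
        # torsion wraps; bounded axes reflect at the box walls
        if periodic0:
            if x0 > space.ranges[0][1] or x0 <= space.ranges[0][0]:
                x0 = space.ranges[0][1] - (space.ranges[0][1] - x0) % psi_period
        else:
            if x0 < space.ranges[0][0]:
                x0 = 2 * space.ranges[0][0] - x0
            elif x0 > space.ranges[0][1]:
                x0 = 2 * space.ranges[0][1] - x0
        if x1 < z_lo:
            x1 = 2 * z_lo - x1
        elif x1 > z_hi:
            x1 = 2 * z_hi - x1
        if biased and (i + 1) % mp.pace == 0 and m < n_hills_max:
            v, _, _ = bias_terms(x0, x1)
            hc1[m] = x0
            hc2[m] = x1
            hh[m] = mp.w0 * math.exp(-v / kB_dT)
            ht[m] = (i + 1) * dt
            m += 1
        if (i + 1) % record_stride == 0 and r < n_rec:
            rec_t[r] = (i + 1) * dt
            rec_x[r, 0] = x0
            rec_x[r, 1] = x1
            rec_v[r] = bias_terms(x0, x1)[0] if biased else 0.0
            r += 1

    traj = CVTrajectory(
        times=rec_t[:r],
        values=rec_x[:r],
        bias_energy=rec_v[:r] if biased else None,
        names=space.names,
    )
    series = HillSeries(
        space,
        times=ht[:m],
        centers=np.stack([hc1[:m], hc2[:m]], axis=1),
        widths=np.tile(np.asarray(mp.sigma), (m, 1)),
        heights=hh[:m],
        bias_factors=np.full(m, mp.bias_factor),
    )
    return traj, series
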