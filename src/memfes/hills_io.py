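"""Plain-text I/O: HILLS and COLVAR files (PLUMED ``#! FIELDS`` dialect)
and sum_hills-style 2D free-energy grids.

Columns are whitespace-separated, scientific notation accepted; the
header token order defines the CV order.  Angles are wrapped into
(-pi, pi] at read time so downstream math sees one canonical
representation.  Times are carried opaquely (ps by convention).
"""

from __future__ import annotations

import math
from contextlib import contextmanager
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Optional, TextIO

import numpy as np

from .core import (
    CVSpace,
    FormatError,
    GridShapeError,
    GridSpec,
    MemfesError,
    OrderingError,
    ThermoContext,
)
from .landscape import FESGrid, Profile1D

#: CV names treated as periodic torsions with range (-pi, pi] when the
#: file does not declare an explicit range.
_PERIODIC_NAMES = {"psi", "phi", "theta", "chi", "omega", "dihedral", "torsion"}

_FLOAT_FMT = "%.12g"


@contextmanager
def _as_text_stream(stream, mode: str) -> Iterator[TextIO]:
    if isinstance(stream, (str, Path)):
        with open(stream, mode, encoding="utf-8") as fh:
            yield fh
    else:
        yield stream


def _parse_special(token: str) -> float:
    if token == "pi":
        return math.pi
    if token == "-pi":
        return -math.pi
    return float(token)


# ---------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class HillRecord:
    """One deposited Gaussian: time (ps), CV center, per-CV sigma, height
    (kJ/mol) and the well-tempered bias factor gamma."""

    time: float
    center: tuple[float, float]
    width: tuple[float, float]
    height: float
    bias_factor: float

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.width):
            raise MemfesError(f"hill widths must be strictly positive, got {self.width}")
        if self.height < 0:
            raise MemfesError(f"hill height must be non-negative, got {self.height}")
        if self.bias_factor <= 1:
            raise MemfesError(
                f"bias factor must exceed 1 for well-tempered hills, got {self.bias_factor}"
            )


class HillSeries:
    """Time-ordered Gaussians of a metadynamics run, stored columnar.

    Centers are canonically wrapped into the CV ranges.  Provides array
    views (``times``, ``centers`` (n, 2), ``widths``, ``heights``,
    ``bias_factors``) for vectorized bias evaluation.
    """

    def __init__(
        self,
        cv_space: CVSpace,
        times=None,
        centers=None,
        widths=None,
        heights=None,
        bias_factors=None,
    ) -> None:
        self.cv_space = cv_space
        n = 0 if times is None else len(times)
        self.times = np.asarray(times if times is not None else [], dtype=float)
        self.centers = cv_space.wrap(
            np.asarray(centers if centers is not None else [], dtype=float).reshape(n, 2)
        )
        self.widths = np.asarray(widths if widths is not None else [], dtype=float).reshape(n, 2)
        self.heights = np.asarray(heights if heights is not None else [], dtype=float)
        self.bias_factors = np.asarray(
            bias_factors if bias_factors is not None else [], dtype=float
        )
        if not (len(self.times) == len(self.heights) == len(self.bias_factors) == n):
            raise MemfesError("hill series columns must have equal length")
        if n:
            if np.any(np.diff(self.times) < 0):
                raise OrderingError("hill times must be non-decreasing")
            if np.any(self.widths <= 0):
                raise MemfesError("hill widths must be strictly positive")
            if np.any(self.heights < 0):
                raise MemfesError("hill heights must be non-negative")
            if np.any(self.bias_factors <= 1):
                raise MemfesError("bias factors must exceed 1")

    @classmethod
    def from_records(cls, records: list[HillRecord], cv_space: CVSpace) -> "HillSeries":
        return cls(
            cv_space,
            times=[r.time for r in records],
            centers=[r.center for r in records],
            widths=[r.width for r in records],
            heights=[r.height for r in records],
            bias_factors=[r.bias_factor for r in records],
        )

    @property
    def records(self) -> list[HillRecord]:
        return [
            HillRecord(
                time=float(self.times[k]),
                center=tuple(self.centers[k]),
                width=tuple(self.widths[k]),
                height=float(self.heights[k]),
                bias_factor=float(self.bias_factors[k]),
            )
            for k in range(len(self))
        ]

    def __len__(self) -> int:
        return len(self.times)

    def __getitem__(self, k: int) -> HillRecord:
        return self.records[k] if isinstance(k, slice) else HillRecord(
            time=float(self.times[k]),
            center=tuple(self.centers[k]),
            width=tuple(self.widths[k]),
            height=float(self.heights[k]),
            bias_factor=float(self.bias_factors[k]),
        )


@dataclass
class CVTrajectory:
    """CV time series (COLVAR): frame times, CV points, optional bias energy."""

    times: np.ndarray
    values: np.ndarray
    bias_energy: Optional[np.ndarray] = None
    names: tuple[str, str] = ("psi", "z")

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float).reshape(len(self.times), 2)
        if self.bias_energy is not None:
            self.bias_energy = np.asarray(self.bias_energy, dtype=float)
            if len(self.bias_energy) != len(self.times):
                raise MemfesError("bias column length mismatch")

    def __len__(self) -> int:
        return len(self.times)


# ---------------------------------------------------------------------
# header parsing


def _slurp(stream) -> list[str]:
    with _as_text_stream(stream, "r") as fh:
        return fh.read().splitlines()


def _read_header(lines: list[str]) -> tuple[list[str], dict[str, tuple[float, float]]]:
    """Return (field names, CV ranges declared via SET min/max lines)."""
    fields: Optional[list[str]] = None
    setvals: dict[str, float] = {}
    for line in lines:
        stripped = line.strip()
        if not stripped.startswith("#!"):
            continue
        tokens = stripped[2:].split()
        if tokens and tokens[0] == "FIELDS" and fields is None:
            fields = tokens[1:]
        elif tokens and tokens[0] == "SET" and len(tokens) == 3:
            setvals[tokens[1]] = _parse_special(tokens[2])
    if fields is None:
        raise FormatError("missing '#! FIELDS' header line")
    ranges: dict[str, tuple[float, float]] = {}
    for key, lo in setvals.items():
        if key.startswith("min_"):
            name = key[4:]
            hi = setvals.get("max_" + name)
            if hi is not None:
                ranges[name] = (lo, hi)
    return fields, ranges


def _iter_data_rows(lines: list[str]) -> Iterator[tuple[int, list[str]]]:
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        yield lineno, stripped.split()


def _infer_cv_space(
    names: tuple[str, str],
    declared: dict[str, tuple[float, float]],
    centers: np.ndarray,
    widths: np.ndarray,
) -> CVSpace:
    periodic = []
    ranges = []
    for ax, name in enumerate(names):
        if name in declared:
            lo, hi = declared[name]
            periodic.append(True)  # PLUMED declares min/max only for periodic CVs
            ranges.append((lo, hi))
        elif name.split(".")[-1] in _PERIODIC_NAMES:
            periodic.append(True)
            ranges.append((-math.pi, math.pi))
        else:
            hi = 0.5 if len(centers) == 0 else float(
                np.max(centers[:, ax] + 5 * widths[:, ax])
            )
            hi = max(0.5, math.ceil(hi * 2) / 2)
            periodic.append(False)
            ranges.append((0.0, hi))
    return CVSpace(names=names, periodic=tuple(periodic), ranges=tuple(ranges))


# ---------------------------------------------------------------------
# HILLS


def read_hills(stream, cv_space: Optional[CVSpace] = None) -> HillSeries:
    """Parse a PLUMED-style HILLS file into a :class:`HillSeries`.

    Expected fields: ``time <cv1> <cv2> sigma_<cv1> sigma_<cv2> height
    biasf``.  Comment lines (``#!``) are skipped; centers are wrapped
    into the CV ranges.  Raises :class:`FormatError` for a malformed
    header or non-numeric cell and :class:`OrderingError` for
    decreasing times.
    """
    lines = _slurp(stream)
    fields, declared = _read_header(lines)
    if not fields or fields[0] != "time":
        raise FormatError(f"HILLS header must start with 'time', got {fields[:1]}")
    if len(fields) < 3:
        raise FormatError("HILLS header missing the two CV columns")
    cv_names = (fields[1], fields[2])
    wanted = ("sigma_" + cv_names[0], "sigma_" + cv_names[1], "height", "biasf")
    for want in wanted:
        if want not in fields:
            raise FormatError(f"HILLS header missing column '{want}'")
    i_sig = (fields.index(wanted[0]), fields.index(wanted[1]))
    i_height = fields.index("height")
    i_biasf = fields.index("biasf")
    rows = []
    for lineno, cells in _iter_data_rows(lines):
        if len(cells) < len(fields):
            raise FormatError(
                f"line {lineno}: expected {len(fields)} columns, found {len(cells)}"
            )
        try:
            rows.append([float(c) for c in cells[: len(fields)]])
        except ValueError as exc:
            raise FormatError(f"line {lineno}: non-numeric cell ({exc})") from None
    data = np.asarray(rows, dtype=float).reshape(len(rows), len(fields))
    times = data[:, 0]
    if len(times) and np.any(np.diff(times) < 0):
        k = int(np.argmax(np.diff(times) < 0)) + 1
        raise OrderingError(f"hill times decrease at data row {k + 1}")
    centers = data[:, 1:3]
    widths = data[:, list(i_sig)]
    if cv_space is None:
        cv_space = _infer_cv_space(cv_names, declared, centers, widths)
    return HillSeries(
        cv_space,
        times=times,
        centers=centers,
        widths=widths,
        heights=data[:, i_height],
        bias_factors=data[:, i_biasf],
    )


def write_hills(series: HillSeries, stream) -> None:
    """Emit the dialect :func:`read_hills` accepts; full round-trip fidelity."""
    s = series.cv_space
    n1, n2 = s.names
    with _as_text_stream(stream, "w") as fh:
        fh.write(f"#! FIELDS time {n1} {n2} sigma_{n1} sigma_{n2} height biasf\n")
        for ax, name in enumerate(s.names):
            if s.periodic[ax]:
                lo, hi = s.ranges[ax]
                fh.write(f"#! SET min_{name} {_FLOAT_FMT % lo}\n")
                fh.write(f"#! SET max_{name} {_FLOAT_FMT % hi}\n")
        for k in range(len(series)):
            row = (
                series.times[k],
                series.centers[k, 0],
                series.centers[k, 1],
                series.widths[k, 0],
                series.widths[k, 1],
                series.heights[k],
                series.bias_factors[k],
            )
            fh.write(" ".join(_FLOAT_FMT % v for v in row) + "\n")


# ---------------------------------------------------------------------
# COLVAR


def read_colvar(stream, cv_space: Optional[CVSpace] = None) -> CVTrajectory:
    """Parse a COLVAR time series: fields ``time <cv1> <cv2> [*bias*]``.

    A trailing column whose name contains ``bias`` is read as the bias
    energy; its absence is not an error.
    """
    lines = _slurp(stream)
    fields, _declared = _read_header(lines)
    if len(fields) < 3 or fields[0] != "time":
        raise FormatError("COLVAR header must be 'time <cv1> <cv2> [bias]'")
    cv_names = (fields[1], fields[2])
    i_bias = next((k for k, f in enumerate(fields) if "bias" in f and k >= 3), None)
    rows = []
    for lineno, cells in _iter_data_rows(lines):
        if len(cells) < len(fields):
            raise FormatError(
                f"line {lineno}: expected {len(fields)} columns, found {len(cells)}"
            )
        try:
            rows.append([float(c) for c in cells[: len(fields)]])
        except ValueError as exc:
            raise FormatError(f"line {lineno}: non-numeric cell ({exc})") from None
    data = np.asarray(rows, dtype=float).reshape(len(rows), len(fields))
    times = data[:, 0]
    if len(times) and np.any(np.diff(times) < 0):
        k = int(np.argmax(np.diff(times) < 0)) + 1
        raise OrderingError(f"frame times decrease at data row {k + 1}")
    return CVTrajectory(
        times=times,
        values=data[:, 1:3],
        bias_energy=data[:, i_bias] if i_bias is not None else None,
        names=cv_names,
    )


def write_colvar(traj: CVTrajectory, stream) -> None:
    n1, n2 = traj.names
    cols = f"time {n1} {n2}" + (" bias" if traj.bias_energy is not None else "")
    with _as_text_stream(stream, "w") as fh:
        fh.write(f"#! FIELDS {cols}\n")
        for k in range(len(traj)):
            row = [traj.times[k], traj.values[k, 0], traj.values[k, 1]]
            if traj.bias_energy is not None:
                row.append(traj.bias_energy[k])
            fh.write(" ".join(_FLOAT_FMT % v for v in row) + "\n")


# ---------------------------------------------------------------------
# FES grids


def read_fes_grid(
    stream,
    cv_space: Optional[CVSpace] = None,
    thermo: Optional[ThermoContext] = None,
) -> FESGrid:
    """Read a sum_hills-like grid: one row per node ``cv1 cv2 F``, cv1
    varying fastest, blank lines between cv2 blocks ignored.

    Non-finite F marks a node unexplored.  An incomplete rectangular
    grid raises :class:`GridShapeError`.  Without an explicit
    ``cv_space``, the first axis is taken periodic iff its centers tile
    a 2*pi period.
    """
    rows = []
    for lineno, cells in _iter_data_rows(_slurp(stream)):
        if len(cells) < 3:
            raise FormatError(f"line {lineno}: expected at least 3 columns")
        try:
            rows.append([float(c) for c in cells[:3]])
        except ValueError as exc:
            raise FormatError(f"line {lineno}: non-numeric cell ({exc})") from None
    if not rows:
        raise FormatError("empty FES grid file")
    data = np.asarray(rows, dtype=float)
    u0 = np.unique(np.round(data[:, 0], 9))
    u1 = np.unique(np.round(data[:, 1], 9))
    n0, n1 = len(u0), len(u1)
    if n0 * n1 != len(data):
        raise GridShapeError(
            f"incomplete grid: expected {n0}x{n1} = {n0 * n1} nodes, found {len(data)}"
        )
    # rows are cv1-fastest: reshape as (n1 blocks) x (n0 rows)
    F = data[:, 2].reshape(n1, n0).T
    w0 = float(u0[1] - u0[0]) if n0 > 1 else 1.0
    w1 = float(u1[1] - u1[0]) if n1 > 1 else 1.0
    if cv_space is None:
        span0 = float(u0[-1] - u0[0]) + w0
        periodic0 = abs(span0 - 2 * math.pi) < 1e-6
        cv_space = CVSpace(
            names=("psi", "z") if periodic0 else ("s1", "s2"),
            periodic=(periodic0, False),
            ranges=(
                (float(u0[0]) - w0 / 2, float(u0[-1]) + w0 / 2),
                (float(u1[0]) - w1 / 2, float(u1[-1]) + w1 / 2),
            ),
        )
    grid = GridSpec(cv_space=cv_space, bins=(n0, n1))
    return FESGrid(
        grid=grid,
        values=np.where(np.isfinite(F), F, np.nan),
        thermo=thermo or ThermoContext(),
        explored=np.isfinite(F),
    )


def write_fes_grid(fes: FESGrid, stream) -> None:
    """Write the 3-column grid text, cv1 fastest, blank line between cv2 blocks."""
    c0 = fes.grid.centers(0)
    c1 = fes.grid.centers(1)
    with _as_text_stream(stream, "w") as fh:
        fh.write(f"#! FIELDS {fes.grid.cv_space.names[0]} {fes.grid.cv_space.names[1]} file.free\n")
        for j, y in enumerate(c1):
            for i, x in enumerate(c0):
                v = fes.values[i, j] if fes.explored[i, j] else float("nan")
                fh.write(f"{_FLOAT_FMT % x} {_FLOAT_FMT % y} {_FLOAT_FMT % v}\n")
            if j < len(c1) - 1:
                fh.write("\n")


def write_profile(profile: Profile1D, stream) -> None:
    """Write a 1D profile as 2-column text (coordinate, F in kJ/mol)."""
    with _as_text_stream(stream, "w") as fh:
        fh.write(f"#! FIELDS {profile.name} file.free\n")
        for x, f in zip(profile.centers, profile.F):
            fh.write(f"{_FLOAT_FMT % x} {_FLOAT_FMT % f}\n")
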