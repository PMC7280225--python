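"""End-to-end workflow: bias input -> FES -> basins -> paths -> barriers.

``run_pipeline`` chains reconstruction (when the input is a hill stream
or a simulation recipe), zero-referencing at the bulk-water state,
basin detection, per-pair minimum free energy paths with transition
states, Boltzmann marginalization along both CVs, and a set of named
barrier observables.  The same transition is reported both as a 2D
path barrier and as a 1D profile barrier where both exist — they are
different observables and are never averaged.

All numbers in the JSON report are serialized at 6 significant digits,
so identical inputs give byte-identical reports.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path as FsPath
from typing import Any, Optional

import numpy as np

from . import hills_io, landscape, mfep, toysim, wtmetad
from .core import ConfigError, GridSpec, ThermoContext, default_grid
from .landscape import FESGrid, Profile1D

log = logging.getLogger("memfes")

DEFAULTS: dict[str, Any] = {
    "label": "system",
    "input": {"hills": None, "fes": None, "recipe": None},
    "thermo": {"T": 303.15, "gamma": 10.0},
    "grid": {"bins_psi": 144, "bins_z": 120, "z_max": 4.5},
    "metad": {"w0": 1.2, "sigma_psi": 0.35, "sigma_z": 0.1, "pace": 500},
    "simulate": {"n_steps": 200000, "dt": 0.05, "seed": 1, "diffusion": 0.1,
                 "barrier": 10.0},
    "reference": {"psi": 0.0, "z": 4.0},
    "minima": {"depth_threshold": 1.0},
    "pairs": "all",
    "convergence_blocks": 5,
    "output": {"dir": None},
}

_RECIPES = ("melatonin_fixture", "double_well")


def validate_config(config: Optional[dict]) -> dict:
    """Merge a user config over the defaults.

    Unknown keys are rejected by name; every default actually used is
    recorded in the returned dict under ``defaults_filled`` and logged.
    """
    config = config or {}
    if not isinstance(config, dict):
        raise ConfigError(f"config must be a mapping, got {type(config).__name__}")
    filled: list[str] = []
    out: dict[str, Any] = {}
    for key, default in DEFAULTS.items():
        if isinstance(default, dict):
            sub = config.get(key, {})
            if not isinstance(sub, dict):
                raise ConfigError(f"config section '{key}' must be a mapping")
            for bad in set(sub) - set(default):
                raise ConfigError(f"unknown config key '{key}.{bad}'")
            merged = {}
            for k, v in default.items():
                if k in sub:
                    merged[k] = sub[k]
                else:
                    merged[k] = v
                    filled.append(f"{key}.{k}")
            out[key] = merged
        else:
            if key in config:
                out[key] = config[key]
            else:
                out[key] = default
                filled.append(key)
    for bad in set(config) - set(DEFAULTS):
        raise ConfigError(f"unknown config key '{bad}'")

    if out["thermo"]["gamma"] <= 1:
        raise ConfigError(f"thermo.gamma must exceed 1, got {out['thermo']['gamma']}")
    if out["thermo"]["T"] <= 0:
        raise ConfigError(f"thermo.T must be positive, got {out['thermo']['T']}")
    for k in ("bins_psi", "bins_z"):
        if int(out["grid"][k]) < 2:
            raise ConfigError(f"grid.{k} must be at least 2, got {out['grid'][k]}")
    if out["grid"]["z_max"] <= 0:
        raise ConfigError("grid.z_max must be positive")
    if out["minima"]["depth_threshold"] < 0:
        raise ConfigError("minima.depth_threshold must be non-negative")
    recipe = out["input"]["recipe"]
    if recipe is not None and recipe not in _RECIPES:
        raise ConfigError(f"unknown recipe '{recipe}'; choose from {_RECIPES}")
    out["defaults_filled"] = sorted(filled)
    for name in filled:
        log.debug("config default used: %s", name)
    return out


@dataclass
class MFEPSummary:
    pair: str
    ts_point: tuple[float, float]
    ts_free_energy: float
    kind: str
    barrier_from_first: float
    barrier_from_second: float
    converged: bool
    iterations: int
    monotone_warning: bool


@dataclass
class BarrierReport:
    """Everything the analysis measured, reproducible from the stored FES."""

    label: str
    zero_reference: dict
    basins: list[dict]
    mfep: list[MFEPSummary]
    named_barriers: dict
    convergence: list[dict]
    defaults_filled: list[str]

    def to_dict(self) -> dict:
        d = asdict(self)
        return _round_floats(d, 6)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _round_floats(obj, sig: int):
    if isinstance(obj, float):
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    return obj


def _build_fes(cfg: dict) -> tuple[FESGrid, Optional[hills_io.HillSeries], dict]:
    """Resolve the FES from file, hill stream or recipe; returns artifacts
    produced along the way for optional writing."""
    thermo = ThermoContext(temperature=cfg["thermo"]["T"], bias_factor=cfg["thermo"]["gamma"])
    grid = default_grid(
        z_max=cfg["grid"]["z_max"],
        bins_psi=int(cfg["grid"]["bins_psi"]),
        bins_z=int(cfg["grid"]["bins_z"]),
    )
    inp = cfg["input"]
    extras: dict = {}
    if inp["fes"] is not None:
        log.info("reading FES grid from %s (reconstruction skipped)", inp["fes"])
        fes = hills_io.read_fes_grid(inp["fes"], thermo=thermo)
        return fes, None, extras
    if inp["hills"] is not None:
        log.info("reconstructing FES from hills %s", inp["hills"])
        series = hills_io.read_hills(inp["hills"])
        grid = GridSpec(cv_space=series.cv_space, bins=grid.bins)
        return wtmetad.reconstruct_fes(series, grid, thermo), series, extras
    recipe = inp["recipe"]
    if recipe == "melatonin_fixture":
        log.info("building analytic membrane fixture landscape")
        return toysim.make_melatonin_like_fes(grid, thermo), None, extras
    if recipe == "double_well":
        sim = cfg["simulate"]
        pot = toysim.double_well_potential(barrier=sim["barrier"])
        mp = toysim.MetadParams(
            w0=cfg["metad"]["w0"],
            sigma=(cfg["metad"]["sigma_psi"], cfg["metad"]["sigma_z"]),
            pace=int(cfg["metad"]["pace"]),
            bias_factor=cfg["thermo"]["gamma"],
        )
        log.info("running Langevin + well-tempered metadynamics (seed %s)", sim["seed"])
        traj, series = toysim.langevin_wtmetad(
            pot,
            thermo,
            mp,
            n_steps=int(sim["n_steps"]),
            dt=sim["dt"],
            seed=int(sim["seed"]),
            diffusion=(sim["diffusion"], sim["diffusion"]),
        )
        extras["trajectory"] = traj
        grid = GridSpec(cv_space=pot.cv_space, bins=grid.bins)
        return wtmetad.reconstruct_fes(series, grid, thermo), series, extras
    raise ConfigError("config must name input.hills, input.fes or input.recipe")


def _profile_max_between(profile: Profile1D, a: float, b: float) -> float:
    """Largest profile value on the direct segment between two coordinates."""
    lo, hi = sorted((a, b))
    mask = (profile.centers >= lo) & (profile.centers <= hi)
    vals = [profile.value_at(lo), profile.value_at(hi)]
    if mask.any():
        vals.append(float(profile.F[mask].max()))
    return max(vals)


def run_pipeline(config: Optional[dict]) -> BarrierReport:
    """Execute the full analysis chain and return the barrier report.

    Raises a diagnostic error when no basins survive the depth
    threshold.  If ``output.dir`` is set, writes the FES grid, 1D
    profiles, per-pair path tables and the JSON report there.
    """
    cfg = validate_config(config)
    fes, series, extras = _build_fes(cfg)

    ref = (cfg["reference"]["psi"], cfg["reference"]["z"])
    fes = landscape.set_zero_reference(fes, ref, note="bulk-water reference")

    threshold = cfg["minima"]["depth_threshold"]
    basins = landscape.find_minima(fes, depth_threshold=threshold)
    if not basins:
        raise ConfigError(
            f"no basins found with depth threshold {threshold} kJ/mol; "
            "lower minima.depth_threshold or check the input surface"
        )
    by_label = {b.label: b for b in basins}

    pairs_cfg = cfg["pairs"]
    if pairs_cfg == "all":
        pairs = [
            (a.label, b.label) for a, b in itertools.combinations(basins, 2)
        ]
    else:
        pairs = []
        for token in (pairs_cfg if isinstance(pairs_cfg, list) else str(pairs_cfg).split(",")):
            a, _, b = token.strip().partition(":")
            if a not in by_label or b not in by_label:
                raise ConfigError(
                    f"pair '{token}' names unknown basins; found {sorted(by_label)}"
                )
            pairs.append((a, b))

    paths: dict[str, mfep.Path] = {}
    summaries: list[MFEPSummary] = []
    ts_list = []
    for a_lbl, b_lbl in pairs:
        a, b = by_label[a_lbl], by_label[b_lbl]
        path = mfep.refine_mfep(fes, mfep.initial_path(fes, a, b))
        ts = mfep.locate_ts(path, force=True)
        key = f"{a_lbl}:{b_lbl}"
        paths[key] = path
        ts_list.append((key, ts, path, a, b))
    ts_max = max((t.free_energy for _, t, _, _, _ in ts_list), default=None)
    for key, ts, path, a, b in ts_list:
        kind = "global" if ts.free_energy == ts_max else "local"
        ts_pt = fes.grid.cv_space.wrap(ts.point)
        summaries.append(
            MFEPSummary(
                pair=key,
                ts_point=(float(ts_pt[0]), float(ts_pt[1])),
                ts_free_energy=ts.free_energy,
                kind=kind,
                barrier_from_first=ts.free_energy - a.free_energy,
                barrier_from_second=ts.free_energy - b.free_energy,
                converged=path.converged,
                iterations=path.iterations,
                monotone_warning=ts.monotone_warning,
            )
        )

    profile_z = landscape.marginalize(fes, 1).rezero_at(cfg["reference"]["z"])
    profile_psi = landscape.marginalize(fes, 0).rezero_min()

    named: dict[str, Optional[float]] = {}
    deepest = basins[0]
    psi_a, z_a = float(deepest.location[0]), float(deepest.location[1])
    named["interface_to_water_2d"] = landscape.barrier(
        fes, deepest.location, (psi_a, cfg["reference"]["z"])
    )
    named["interface_to_water_1d"] = landscape.profile_barrier(
        profile_z, z_a, cfg["reference"]["z"]
    )
    z_center = fes.grid.centers(1)[0]
    named["interface_to_center_2d"] = landscape.barrier(
        fes, deepest.location, (psi_a, z_center)
    )

    extended = [b for b in basins if abs(b.location[0]) > np.pi / 2]
    folded = [b for b in basins if abs(b.location[0]) <= np.pi / 2]
    if extended and folded:
        e, f = extended[0], folded[0]
        key = f"{e.label}:{f.label}" if f"{e.label}:{f.label}" in paths else f"{f.label}:{e.label}"
        if key not in paths:
            path = mfep.refine_mfep(fes, mfep.initial_path(fes, e, f))
            paths[key] = path
        ts = mfep.locate_ts(paths[key], force=True)
        named["folded_extended_2d"] = ts.free_energy - e.free_energy
        named["folded_extended_1d"] = _profile_max_between(
            profile_psi, e.location[0], f.location[0]
        ) - profile_psi.value_at(e.location[0])
        named["psi0_crossing_1d"] = profile_psi.value_at(0.0) - profile_psi.value_at(
            f.location[0]
        )
    else:
        named["folded_extended_2d"] = None
        named["folded_extended_1d"] = None
        named["psi0_crossing_1d"] = None

    convergence = []
    n_blocks = int(cfg["convergence_blocks"])
    if series is not None and len(series) >= n_blocks >= 2:
        prof = wtmetad.convergence_profile(
            series, fes.grid, fes.thermo, n_blocks=n_blocks
        )
        convergence = [{"time": t, "rmsd": r} for t, r in prof]

    report = BarrierReport(
        label=str(cfg["label"]),
        zero_reference={
            "psi": cfg["reference"]["psi"],
            "z": cfg["reference"]["z"],
            "note": "bulk-water reference",
        },
        basins=[
            {
                "label": b.label,
                "psi": float(b.location[0]),
                "z": float(b.location[1]),
                "free_energy": b.free_energy,
            }
            for b in basins
        ],
        mfep=summaries,
        named_barriers=named,
        convergence=convergence,
        defaults_filled=cfg["defaults_filled"],
    )

    out_dir = cfg["output"]["dir"]
    if out_dir is not None:
        out = FsPath(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        hills_io.write_fes_grid(fes, out / "fes.dat")
        hills_io.write_profile(profile_z, out / "profile_z.dat")
        hills_io.write_profile(profile_psi, out / "profile_psi.dat")
        for key, path in paths.items():
            mfep.write_path_table(path, out / f"path_{key.replace(':', '_')}.tsv")
        if series is not None:
            hills_io.write_hills(series, out / "HILLS")
        if "trajectory" in extras:
            hills_io.write_colvar(extras["trajectory"], out / "COLVAR")
        (out / "report.json").write_text(report.to_json() + "\n", encoding="utf-8")
        log.info("artifacts written to %s", out)
    return report
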