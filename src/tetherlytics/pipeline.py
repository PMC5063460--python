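"""End-to-end pipeline: configuration, stage orchestration, manifest.

A pipeline run executes any subset of the stages

    simulate -> profiles -> diffusion -> wham -> energetics -> circuit

as configured in a TOML file (or an equivalent dict).  Every stage
records its outputs in a manifest with SHA-256 checksums and the
parameters used, so a rerun with an identical configuration reproduces
identical checksums for the deterministic stages.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import energetics as en
from . import io as tio
from . import synthetic_data as syn
from .core import SlabDomain
from .diffusion import lateral_diffusion_msd, perpendicular_diffusion, round_trip_times
from .electrical import (
    TETHAPOD_FREQUENCIES,
    CircuitParams,
    DriveWaveform,
    impedance,
    simulate_current,
)
from .profiles import AnalysisConfig, compute_density, free_energy_from_density

logger = logging.getLogger("tetherlytics")

STAGE_ORDER = ("simulate", "profiles", "diffusion", "wham", "energetics", "circuit")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Validated pipeline configuration."""

    stages: dict
    seed: int = 0
    out_dir: Path = Path("out")
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, cfg: dict, base_dir: Path | None = None) -> "PipelineConfig":
        stages = {k: v for k, v in cfg.items() if k in STAGE_ORDER}
        unknown = set(cfg) - set(STAGE_ORDER) - {"seed", "out_dir", "log_level"}
        if unknown:
            raise PipelineError(f"unknown configuration keys: {sorted(unknown)}")
        out_dir = Path(cfg.get("out_dir", "out"))
        if base_dir is not None and not out_dir.is_absolute():
            out_dir = base_dir / out_dir
        return cls(stages=stages, seed=int(cfg.get("seed", 0)), out_dir=out_dir,
                   log_level=cfg.get("log_level", "INFO"))

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        import tomllib

        path = Path(path)
        with path.open("rb") as fh:
            return cls.from_dict(tomllib.load(fh), base_dir=path.parent)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _require(cond: bool, what: str) -> None:
    if not cond:
        raise PipelineError(f"unmet stage requirement: {what}")


def validate_manifest(manifest: dict, base: Path) -> None:
    """Check that every input/output a manifest references still exists."""
    for stage, info in manifest.get("stages", {}).items():
        for f in list(info.get("inputs", [])) + list(info.get("outputs", [])):
            p = Path(f)
            if not p.is_absolute():
                p = base / p
            if not p.exists():
                raise PipelineError(
                    f"manifest references a missing file for stage "
                    f"{stage!r}: {f}"
                )


def run_pipeline(config: PipelineConfig | dict) -> dict:
    """Execute the configured stages and return the output manifest."""
    if isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)

    manifest: dict = {
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            json.dumps({k: v for k, v in sorted(config.stages.items())},
                       sort_keys=True, default=str).encode()
        ).hexdigest(),
        "stages": {},
    }
    ctx: dict = {}

    for stage in STAGE_ORDER:
        if stage not in config.stages:
            continue
        params = dict(config.stages[stage])
        t0 = time.perf_counter()
        outputs, inputs = _STAGES[stage](params, config, ctx, out)
        wall = time.perf_counter() - t0
        logger.info("stage=%s seed=%d wall=%.3fs params=%s",
                    stage, config.seed, wall, params)
        manifest["stages"][stage] = {
            "params": params,
            "inputs": [str(p) for p in inputs],
            "outputs": [str(p) for p in outputs],
            "checksums": {str(p): _sha256(Path(p)) for p in outputs},
            "wall_s": round(wall, 6),
        }

    manifest_path = out / "manifest.json"
    with manifest_path.open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# stage implementations

def _stage_simulate(params, config, ctx, out):
    dom = SlabDomain(z_b=params.get("z_b", 0.0), z_t=params.get("z_t", 5.0),
                     L_x=params.get("L_x", 10.8), L_y=params.get("L_y", 10.8))
    spec = syn.LangevinSpec(
        domain=dom,
        free_energy=None,
        diffusion_z=params.get("diffusion_z", 1.0),
        diffusion_xy=params.get("diffusion_xy", 1.0),
        temperature=params.get("temperature", 320.0),
        n_particles=int(params.get("n_particles", 100)),
        dt=params.get("dt", 1e-3),
        n_steps=int(params.get("n_steps", 1000)),
        save_every=int(params.get("save_every", 1)),
        seed=config.seed,
        species=params.get("species", "W"),
    )
    traj = syn.simulate_overdamped(spec)
    path = out / params.get("out", "trajectory.txt")
    tio.write_trajectory(traj, path)
    ctx["trajectory"] = traj
    return [path], []


def _load_traj(params, ctx, out):
    if "traj" in params:
        p = Path(params["traj"])
        _require(p.exists(), f"trajectory file {p} does not exist")
        return tio.read_trajectory(p), [p]
    _require("trajectory" in ctx, "no trajectory: run the simulate stage "
             "first or pass traj = <path>")
    return ctx["trajectory"], []


def _stage_profiles(params, config, ctx, out):
    traj, inputs = _load_traj(params, ctx, out)
    cfg = AnalysisConfig(
        temperature=params.get("temperature", 320.0),
        bin_width=params.get("bin_width", 0.05),
        bulk_bounds=tuple(params["bulk_bounds"]) if "bulk_bounds" in params else None,
        seed=config.seed,
    )
    density = compute_density(traj, params.get("species", "W"), cfg)
    F = free_energy_from_density(density, cfg)
    path = out / params.get("out", "profiles.tsv")
    tio.write_profiles(density, F, path)
    ctx.update(density=density, free_energy=F, analysis_config=cfg)
    return [path], inputs


def _stage_diffusion(params, config, ctx, out):
    traj, inputs = _load_traj(params, ctx, out)
    mode = params.get("mode", "msd")
    outputs = []
    if mode in ("msd", "both"):
        res = lateral_diffusion_msd(
            traj, params.get("species", "W"),
            fit_window=tuple(params.get("fit_window", (1.0, 10.0))),
            seed=config.seed,
        )
        path = out / params.get("out_msd", "lateral_diffusion.tsv")
        with path.open("w") as fh:
            fh.write("# species\tregion\tD_par_nm2_per_us\terr\n")
            fh.write(f"{res.species}\t{res.region or 'all'}\t"
                     f"{res.D_par!r}\t{res.uncertainty!r}\n")
        outputs.append(path)
        ctx["lateral"] = res
    if mode in ("rtt", "both"):
        _require("free_energy" in ctx, "round-trip analysis needs the "
                 "profiles stage (free energy) first")
        rt = round_trip_times(traj, bins=int(params.get("bins", 50)),
                              z_star=params.get("z_star"))
        D = perpendicular_diffusion(rt, ctx["free_energy"],
                                    ctx["analysis_config"])
        path = out / params.get("out_rtt", "perpendicular_diffusion.tsv")
        tio.write_rtt(rt, D, path)
        outputs.append(path)
        ctx["rtt"], ctx["D_zz"] = rt, D
    return outputs, inputs


def _stage_wham(params, config, ctx, out):
    inputs = []
    if "windows" in params:
        import glob as _glob

        paths = sorted(Path(p) for p in _glob.glob(params["windows"]))
        _require(bool(paths), f"no umbrella window files match "
                 f"{params['windows']!r}")
        windows = [tio.read_window(p) for p in paths]
        inputs = paths
    else:
        _require("window_list" in ctx, "no umbrella windows: pass "
                 "windows = <glob> or generate them upstream")
        windows = ctx["window_list"]
    pmf = en.wham(windows,
                  temperature=params.get("temperature", 320.0),
                  rel_tol=params.get("rel_tol", 1e-4),
                  bin_width=params.get("bin_width", 0.05))
    path = out / params.get("out", "pmf.tsv")
    tio.write_pmf(pmf, path)
    ctx["pmf"] = pmf
    return [path], inputs


def _stage_energetics(params, config, ctx, out):
    inputs = []
    if "pmf" in params:
        p = Path(params["pmf"])
        _require(p.exists(), f"PMF file {p} does not exist")
        pmf = tio.read_pmf(p)
        inputs = [p]
    else:
        _require("pmf" in ctx, "no PMF: run the wham stage first or pass "
                 "pmf = <path>")
        pmf = ctx["pmf"]
    region = tuple(params.get("solvated_region", (3.5, np.inf)))
    results = {
        "desorption_kJ_per_mol": en.desorption_energy(pmf, region),
        "flipflop_barrier_kJ_per_mol": en.flipflop_barrier(
            pmf, center=params.get("bilayer_center", 0.0)),
    }
    if "area_per_lipid" in params:
        model = en.defect_density(results["flipflop_barrier_kJ_per_mol"],
                                  params["area_per_lipid"],
                                  params.get("temperature", 320.0))
        results["defect_density_per_nm2"] = model.rho0
    path = out / params.get("out", "energetics.json")
    with path.open("w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
    ctx["energetics"] = results
    return [path], inputs


def _stage_circuit(params, config, ctx, out):
    cp = CircuitParams(
        R_e=params.get("R_e", 1e3), C_m=params.get("C_m", 1.25e-8),
        G_m=params.get("G_m", 1e-6), q=params.get("q", 1e-7),
        p=params.get("p", 0.86), A_m=params.get("A_m", 2.1e-6),
    )
    action = params.get("action", "impedance")
    outputs = []
    if action in ("impedance", "both"):
        freqs = np.asarray(params.get("frequencies", TETHAPOD_FREQUENCIES))
        spec = impedance(cp, freqs)
        path = out / params.get("out_spectrum", "impedance.csv")
        tio.write_spectrum(spec, path)
        ctx["spectrum"] = spec
        outputs.append(path)
    if action in ("simulate", "both"):
        drive = DriveWaveform.ramp(
            slope=params.get("ramp_slope", 100.0),
            rise_time=params.get("rise_time", 5e-3),
        )
        trace = simulate_current(cp, drive, dt=params.get("dt", 1e-5))
        path = out / params.get("out_trace", "current.csv")
        tio.write_trace(trace, path)
        ctx["trace"] = trace
        outputs.append(path)
    _require(bool(outputs), f"unknown circuit action {action!r}")
    return outputs, []


_STAGES = {
    "simulate": _stage_simulate,
    "profiles": _stage_profiles,
    "diffusion": _stage_diffusion,
    "wham": _stage_wham,
    "energetics": _stage_energetics,
    "circuit": _stage_circuit,
}
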