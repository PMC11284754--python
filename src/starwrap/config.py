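"""Run configuration, presets, and the experiment orchestration layer.

Configs are flat TOML files with dotted sections; every run directory
receives the fully materialized config so a run can be reproduced
without the original file.  (config, master_seed) -> bit-identical
trajectories on the same build.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .dynamics import BondKinetics, IntegratorConfig
from .forcefield import ForceField, MorseParams
from .np_geometry import NanoparticleSpec

__all__ = [
    "MembraneConfig",
    "RunConfig",
    "load_config",
    "materialize_config",
    "run_experiment",
    "table2_experiment",
    "emit_run_report",
    "TABLE2_LAYOUTS",
]

#: (n_patches, ligands_per_patch) sphere layouts, constant 280-ligand budget.
TABLE2_LAYOUTS = [(56, 5), (40, 7), (35, 8), (28, 10), (20, 14), (14, 20), (10, 28)]


@dataclass(frozen=True)
class MembraneConfig:
    n_lipids_x: int = 27
    n_lipids_y: int = 27
    area_per_lipid: float = 1.13
    receptor_fraction: float = 0.5
    equilibration_tau: float = 1000.0
    box_xy: tuple[float, float] | None = None


@dataclass(frozen=True)
class RunConfig:
    particle: NanoparticleSpec = field(default_factory=NanoparticleSpec)
    membrane: MembraneConfig = field(default_factory=MembraneConfig)
    forcefield: ForceField = field(default_factory=ForceField)
    integrator: IntegratorConfig = field(default_factory=IntegratorConfig)
    kinetics: BondKinetics = field(default_factory=BondKinetics)
    replicas: int = 5
    master_seed: int = 0
    horizon_tau: float = 2000.0
    sample_every: int = 100           # steps between observable samples
    traj_every: int = 1000            # steps between head-position frames
    standoff: float = 1.0
    barostat_during_wrapping: bool = True
    completion_threshold: float = 0.9
    completion_hold: float = 100.0    # tau
    scale_preset: str = "reduced"


def _paper_preset() -> RunConfig:
    """Full-protocol scale: 10,452 lipids in a 77 x 77 box, 5 x 1e4 tau."""
    return RunConfig(
        membrane=MembraneConfig(
            n_lipids_x=78, n_lipids_y=67, box_xy=(77.0, 77.0),
            equilibration_tau=1000.0,
        ),
        particle=NanoparticleSpec(),
        replicas=5,
        horizon_tau=10_000.0,
        scale_preset="paper",
    )


def _reduced_preset() -> RunConfig:
    """Desk scale: ~30 x 30 sigma membrane, particle shrunk to 6-sigma
    maximum radius with proportional tips, shorter horizon."""
    return RunConfig(
        membrane=MembraneConfig(n_lipids_x=27, n_lipids_y=27),
        particle=NanoparticleSpec(
            core_radius=3.5, tip_length=2.5, basal_tip_radius=1.5,
            tip_radius=0.75, sphere_radius=6.0, bead_spacing=0.6,
            ligand_depth=1.5, ligands_per_site=4, n_patches=35, tip_count=35,
        ),
        replicas=5,
        horizon_tau=2000.0,
        scale_preset="reduced",
    )


_PRESETS = {"paper": _paper_preset, "reduced": _reduced_preset}


def _apply_section(obj, section: dict, name: str):
    known = {f.name for f in dataclasses.fields(obj)}
    unknown = set(section) - known
    if unknown:
        raise ValueError(f"unknown config key(s) in [{name}]: {sorted(unknown)}")
    fixed = dict(section)
    if "box_xy" in fixed and fixed["box_xy"] is not None:
        fixed["box_xy"] = tuple(fixed["box_xy"])
    return replace(obj, **fixed)


def load_config(path) -> RunConfig:
    """Parse a TOML run config; unknown keys are rejected by name.

    An empty file resolves to the all-defaults reduced preset.  A
    ``scale_preset`` key selects the base preset before overrides apply.
    """
    raw = Path(path).read_bytes()
    data = tomllib.loads(raw.decode())
    preset = data.pop("scale_preset", "reduced")
    if preset not in _PRESETS:
        raise ValueError(f"unknown scale_preset {preset!r}")
    cfg = _PRESETS[preset]()

    top_known = {f.name for f in dataclasses.fields(RunConfig)}
    sections = {}
    top = {}
    for key, val in data.items():
        if isinstance(val, dict):
            sections[key] = val
        else:
            top[key] = val
    unknown = set(top) - top_known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    cfg = replace(cfg, **top)

    for name, section in sections.items():
        if name == "particle":
            spec = _apply_section(cfg.particle, section, name)
            cfg = replace(cfg, particle=spec)
        elif name == "membrane":
            cfg = replace(cfg, membrane=_apply_section(cfg.membrane, section, name))
        elif name == "integrator":
            cfg = replace(cfg, integrator=_apply_section(cfg.integrator, section, name))
        elif name == "kinetics":
            cfg = replace(cfg, kinetics=_apply_section(cfg.kinetics, section, name))
        elif name == "forcefield":
            ff = cfg.forcefield
            morse_over = {k[6:]: v for k, v in section.items() if k.startswith("morse_")}
            plain = {k: v for k, v in section.items() if not k.startswith("morse_")}
            known = {"epsilon", "k_fene", "fene_rmax", "k_angle", "theta0", "wc"}
            unknown = set(plain) - known
            if unknown:
                raise ValueError(f"unknown config key(s) in [forcefield]: {sorted(unknown)}")
            if "wc" in plain:
                ff = ff.with_wc(plain.pop("wc"))
            if plain:
                ff = replace(ff, **plain)
            if morse_over:
                ff = replace(ff, morse=replace(ff.morse, **morse_over))
            cfg = replace(cfg, forcefield=ff)
        else:
            raise ValueError(f"unknown config section [{name}]")
    return cfg


def materialize_config(cfg: RunConfig) -> dict:
    """Fully explicit, JSON-serializable view of a config."""

    def clean(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {str(k): clean(v) for k, v in obj.items()}
        if isinstance(obj, (tuple, list)):
            return [clean(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    out = clean(cfg)
    out["forcefield"] = cfg.forcefield.to_flat_dict()
    return out


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(materialize_config(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_experiment(cfg: RunConfig, out_dir, label: str = "run") -> dict:
    """Run all replicas of one layout and write traces + summary."""
    from .dynamics import run_wrapping
    from .observables import wrapping_time

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.json").write_text(
        json.dumps(materialize_config(cfg), indent=2, sort_keys=True)
    )
    from .membrane_builder import save_checkpoint

    tw = []
    for rep in range(cfg.replicas):
        trace = run_wrapping(cfg, replica_id=rep)
        trace.to_frame().to_csv(out_dir / f"{label}_replica{rep}.csv", index=False)
        final = trace.meta.get("final_state")
        if final is not None:
            save_checkpoint(final, out_dir / f"{label}_replica{rep}_final.npz")
        t = wrapping_time(trace, cfg.completion_threshold, cfg.completion_hold)
        tw.append(t)
    summary = {
        "label": label,
        "config_hash": config_hash(cfg),
        "master_seed": cfg.master_seed,
        "completion_threshold": cfg.completion_threshold,
        "completion_hold": cfg.completion_hold,
        "bond_check_interval": cfg.integrator.bond_check_interval,
        "wrapping_times": tw,
        "n_completed": sum(t is not None for t in tw),
    }
    (out_dir / f"{label}_summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def table2_experiment(cfg: RunConfig, out_dir) -> "pd.DataFrame":
    """Star baseline plus the seven sphere patch layouts.

    Returns a table with one row per sphere layout: patch count, ligands
    per patch, center separation, per-replica wrapping times, and the
    sphere/star wrapping-time ratio (NaN when the sphere never wraps).
    """
    import pandas as pd

    from .np_geometry import generate_particle, patch_separation
    from .observables import relative_wrapping_time

    out_dir = Path(out_dir)
    star_cfg = replace(cfg, particle=replace(cfg.particle, shape="star"))
    star = run_experiment(star_cfg, out_dir, label="star35")
    star_tw = star["wrapping_times"]

    rows = []
    for n_patches, per_patch in TABLE2_LAYOUTS:
        sphere_spec = replace(
            cfg.particle, shape="sphere", n_patches=n_patches,
            ligands_per_site=per_patch,
        )
        sp_cfg = replace(cfg, particle=sphere_spec)
        res = run_experiment(sp_cfg, out_dir, label=f"sphere{n_patches}x{per_patch}")
        sep = patch_separation(generate_particle(sphere_spec, seed=0))
        try:
            ratio = relative_wrapping_time(res["wrapping_times"], star_tw)
        except ValueError:
            ratio = None
        rows.append({
            "patches": n_patches,
            "ligands_per_patch": per_patch,
            "total_ligands": n_patches * per_patch,
            "sep_dist_sigma": sep,
            "wrapping_times": res["wrapping_times"],
            "ratio_vs_star": np.nan if ratio is None else ratio,
        })
    df = pd.DataFrame(rows)
    df.to_csv(out_dir / "table2.csv", index=False)
    return df


def emit_run_report(run_dir) -> dict:
    """Summarize a completed (or failed) run directory.

    Collects the materialized config, per-layout summaries and a stable
    content hash; writes ``report.json`` next to the inputs and returns
    the report dict.
    """
    run_dir = Path(run_dir)
    if not run_dir.is_dir():
        raise FileNotFoundError(f"run directory {run_dir} does not exist")
    cfg_path = run_dir / "config.json"
    report = {"run_dir": str(run_dir)}
    if cfg_path.exists():
        cfg = json.loads(cfg_path.read_text())
        report["config"] = cfg
        report["bond_check_interval"] = cfg["integrator"]["bond_check_interval"]
        report["completion_threshold"] = cfg["completion_threshold"]
    summaries = sorted(run_dir.glob("*_summary.json"))
    report["runs"] = [json.loads(p.read_text()) for p in summaries]
    # hash only run content, not the directory location
    blob = json.dumps(
        {k: v for k, v in report.items() if k != "run_dir"}, sort_keys=True
    ).encode()
    report["report_hash"] = hashlib.sha256(blob).hexdigest()[:16]
    (run_dir / "report.json").write_text(json.dumps(report, indent=2))
    return report
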