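"""End-to-end pipeline runs driven by a YAML manifest.

A manifest declares an ordered list of stages (generate → umbrella →
WHAM → features → kinetics, or series → flip-flop, or image → GP), an
output directory and per-stage seeds.  Stages form a linear DAG through
named upstream references; every stochastic stage must carry an explicit
seed, outputs are never overwritten without ``force``, and each output
file carries a provenance header with the config digest and seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import yaml

from . import io as sio
from .datatypes import ProfileFeatures
from .kinetics import detect_flipflops, kinetics_table
from .langevin import LangevinSpec, simulate_langevin
from .pmf import bootstrap_pmf, profile_features, wham
from .potentials import BilayerPotential
from .synthetic import sample_umbrella_windows
from .gp import gp_map

STOCHASTIC_KINDS = {"simulate", "umbrella", "wham"}  # wham: bootstrap seed
_KNOWN_KINDS = STOCHASTIC_KINDS | {"features", "kinetics", "flipflop", "gp"}


class ManifestError(ValueError):
    pass


def _digest(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _file_digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:12]


def validate_manifest(manifest: dict) -> list[dict]:
    """Check the manifest before any stage runs; returns the stage list."""
    stages = manifest.get("stages")
    if not stages:
        raise ManifestError("manifest has no stages")
    names = set()
    for st in stages:
        kind = st.get("kind")
        name = st.get("name", kind)
        if kind not in _KNOWN_KINDS:
            raise ManifestError(f"stage {name!r}: unknown kind {kind!r}")
        if kind in STOCHASTIC_KINDS and "seed" not in st:
            raise ManifestError(f"stochastic stage {name!r} is missing an explicit seed")
        upstream = st.get("input")
        if upstream is not None and upstream not in names:
            raise ManifestError(
                f"stage {name!r} references upstream {upstream!r} which does not precede it"
            )
        if name in names:
            raise ManifestError(f"duplicate stage name {name!r}")
        names.add(name)
    return stages


def _potential_from_config(cfg: dict) -> BilayerPotential:
    return BilayerPotential(
        z_eq=float(cfg["z_eq"]),
        dG_center=float(cfg["dG_center"]),
        dG_desorb=float(cfg["dG_desorb"]),
        wall_halfwidth=float(cfg.get("wall_halfwidth", 0.5)),
        well_curvature=float(cfg.get("well_curvature", 60.0)),
        form=cfg.get("form", "cosine-blend"),
    )


def run_pipeline(manifest, out_dir=None, force: bool = False) -> dict:
    """Execute a pipeline manifest (dict or path to YAML); returns the run report.

    The report lists, per stage, its inputs, outputs, content digests and
    wall time.  A failed stage halts the run with the stage name in the
    error message.  Re-running with identical config and seeds reproduces
    byte-identical numeric outputs.
    """
    if not isinstance(manifest, dict):
        manifest = yaml.safe_load(Path(manifest).read_text())
    stages = validate_manifest(manifest)
    out_dir = Path(out_dir or manifest.get("out_dir", "steroflip-run"))
    out_dir.mkdir(parents=True, exist_ok=True)
    # digest the stage configuration only: the output location must not
    # change the provenance identity of numerically identical runs
    cfg_digest = _digest(stages)
    report = {"config_digest": cfg_digest, "stages": []}
    artifacts: dict[str, object] = {}

    for st in stages:
        kind = st["kind"]
        name = st.get("name", kind)
        t0 = time.perf_counter()
        outputs = []
        try:
            upstream = artifacts.get(st.get("input"))
            meta = {"stage": name, "config_digest": cfg_digest, "seed": st.get("seed", "")}
            if kind == "simulate":
                pot = _potential_from_config(st["potential"])
                spec = LangevinSpec(
                    potential=pot,
                    n_steps=int(st["n_steps"]),
                    z0=float(st["z0"]),
                    seed=int(st["seed"]),
                    temperature=float(st.get("temperature", 310.0)),
                    diffusion_coeff=float(st.get("diffusion_coeff", 1.0)),
                    dt=float(st.get("dt", 1e-3)),
                )
                series = simulate_langevin(spec)
                path = out_dir / f"{name}.tsv"
                _check_overwrite(path, force, name)
                sio.write_series(series, path, extra_meta=meta)
                outputs.append(path)
                artifacts[name] = series
            elif kind == "umbrella":
                pot = _potential_from_config(st["potential"])
                windows = sample_umbrella_windows(
                    pot,
                    k_bias=float(st.get("k_bias", 750.0)),
                    temperature=float(st.get("temperature", 310.0)),
                    dt=float(st.get("dt", 1e-4)),
                    run_time=float(st.get("run_time", 50.0)),
                    equilibration_time=float(st.get("equilibration_time", 10.0)),
                    seed=int(st["seed"]),
                )
                wdir = out_dir / name
                _check_overwrite(wdir / "windows.yaml", force, name)
                manifest_path = sio.write_umbrella_set(windows, wdir)
                outputs.append(manifest_path)
                artifacts[name] = windows
            elif kind == "wham":
                windows = upstream
                if windows is None:
                    windows = sio.read_umbrella_set(st["manifest"])
                n_boot = int(st.get("n_boot", 200))
                profile = bootstrap_pmf(
                    windows,
                    n_boot=n_boot,
                    seed=int(st["seed"]),
                    bin_width=float(st.get("bin_width", 0.05)),
                    temperature=float(st.get("temperature", 310.0)),
                )
                path = out_dir / f"{name}.tsv"
                _check_overwrite(path, force, name)
                sio.write_profile(profile, path)
                outputs.append(path)
                artifacts[name] = profile
            elif kind == "features":
                profile = upstream
                if profile is None:
                    profile = sio.read_profile(st["profile"])
                feats = profile_features(profile, water_region=float(st["water_region"]))
                path = out_dir / f"{name}.json"
                _check_overwrite(path, force, name)
                path.write_text(json.dumps({**meta, **feats.__dict__}, indent=1))
                outputs.append(path)
                artifacts[name] = feats
            elif kind == "kinetics":
                feats = upstream
                if feats is None:
                    feats = ProfileFeatures(**json.loads(Path(st["features"]).read_text()))
                result = kinetics_table(
                    feats,
                    t_d_range=tuple(st["t_d_range"]),
                    temperature=float(st.get("temperature", 310.0)),
                    mode=st.get("mode", "approx"),
                )
                path = out_dir / f"{name}.tsv"
                _check_overwrite(path, force, name)
                _write_kinetics_tsv(result, path, meta)
                outputs.append(path)
                artifacts[name] = result
            elif kind == "flipflop":
                series = upstream
                if series is None:
                    series = sio.read_series(st["series"])
                events = detect_flipflops(
                    series, z_low=float(st["z_low"]), z_high=float(st["z_high"])
                )
                path = out_dir / f"{name}.tsv"
                _check_overwrite(path, force, name)
                lines = [f"{sio.MAGIC} flipflops"] + [f"#{k}: {v}" for k, v in meta.items()]
                lines.append("event_time_ns\tdirection")
                lines += [f"{t:.17g}\t{d:+d}" for t, d in zip(events.event_times, events.directions)]
                path.write_text("\n".join(lines) + "\n")
                outputs.append(path)
                artifacts[name] = events
            elif kind == "gp":
                pair = sio.read_gp_tiff(st["image"], g_factor=st.get("g_factor"))
                result = gp_map(pair, mask_threshold=st.get("mask_threshold"))
                path = out_dir / f"{name}.json"
                _check_overwrite(path, force, name)
                path.write_text(
                    json.dumps(
                        {**meta, "field_mean": result.field_mean,
                         "n_pixels": result.n_pixels, "g_factor": result.g_factor},
                        indent=1,
                    )
                )
                outputs.append(path)
                artifacts[name] = result
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        report["stages"].append(
            {
                "name": name,
                "kind": kind,
                "seed": st.get("seed"),
                "input": st.get("input"),
                "outputs": [str(p) for p in outputs],
                "digests": {p.name: _file_digest(p) for p in outputs},
                "wall_time_s": round(time.perf_counter() - t0, 3),
            }
        )
    report_path = out_dir / "run_report.json"
    report_path.write_text(json.dumps(report, indent=1))
    return report


def _check_overwrite(path: Path, force: bool, stage: str):
    if path.exists() and not force:
        raise FileExistsError(
            f"stage {stage!r}: output {path} exists; pass force to overwrite"
        )


def _write_kinetics_tsv(result, path: Path, meta: dict):
    from .kinetics import round_sig

    lines = [f"{sio.MAGIC} kinetics"] + [f"#{k}: {v}" for k, v in meta.items()]
    lines.append(f"#mode: {result.mode}")
    lines.append("quantity\tlow\thigh\tlow_2sf\thigh_2sf")
    rows = [
        ("dG_center_kJmol", result.dG_center, result.dG_center),
        ("t_d_ns", *result.t_d_range),
        ("k_d_s-1", *result.k_d_range),
        ("k_f_s-1", *result.k_f_range),
        ("k_flip_s-1", *result.k_flip_range),
    ]
    for qty, lo, hi in rows:
        lines.append(
            f"{qty}\t{lo:.17g}\t{hi:.17g}\t{round_sig(lo):.6g}\t{round_sig(hi):.6g}"
        )
    path.write_text("\n".join(lines) + "\n")
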