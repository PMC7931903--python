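"""File-based pipeline stages with run manifests.

Each stage reads its inputs from disk, calls the in-memory workflow
functions, writes its artifacts to an output directory, and drops a
``manifest.json`` (config hash, seeds, timings, file inventory,
package version) sufficient to re-run the stage.
"""

from __future__ import annotations

import hashlib
import json
import pickle
import time
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from . import __version__
from .errors import InterfaceError
from .evaluate import GridDomain, continental_total
from .grid import build_grid
from .mcmc import MCMCConfig, STATUS_ACCEPTED
from .params import PARAM_NAMES, ParameterSet, default_bounds, default_params
from .profiles import read_profiles
from .synthetic import SyntheticWorld, SyntheticWorldConfig, generate_world, read_world, write_world
from .upscale import ContinentalParameterDistribution, EmulatorSpec
from . import workflow

STAGES = ("simulate-data", "assimilate", "upscale", "map", "evaluate")


def _config_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _write_manifest(out: Path, stage: str, config: dict, seed, t_start: float, inputs, outputs):
    manifest = {
        "stage": stage,
        "package_version": __version__,
        "config": config,
        "config_hash": _config_hash(config),
        "seed": seed,
        "elapsed_s": round(time.time() - t_start, 2),
        "inputs": [str(p) for p in inputs],
        "outputs": [str(p) for p in outputs],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise InterfaceError(
            f"missing upstream artifact {path}; run the '{stage}' stage first"
        )
    return path


def stage_simulate(config: dict, seed: int, out_dir) -> SyntheticWorld:
    t0 = time.time()
    out = Path(out_dir)
    wc = SyntheticWorldConfig(**{**config, "seed": seed})
    world = generate_world(wc)
    write_world(world, out)
    _write_manifest(out, "simulate-data", config, seed, t0, [], sorted(out.glob("*")))
    return world


def _mcmc_config(section: dict, defaults: MCMCConfig) -> MCMCConfig:
    known = {k: v for k, v in section.items() if k in MCMCConfig.__dataclass_fields__}
    merged = {**{f: getattr(defaults, f) for f in MCMCConfig.__dataclass_fields__}, **known}
    return MCMCConfig(**merged)


def stage_assimilate(world_dir, config: dict, seed: int, out_dir) -> None:
    """Run the site-by-site and/or one-batch scheme and persist results."""
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    world = read_world(_require(Path(world_dir), "simulate-data"))
    scheme = config.get("scheme", "site")
    rng = np.random.default_rng(seed)
    bounds = default_bounds()
    outputs = []
    if scheme in ("site", "both"):
        site_cfg = _mcmc_config(config, workflow.SITE_CONFIG)
        da = workflow.assimilate_sites(
            world.profiles,
            world.forcings,
            config=site_cfg,
            bounds=bounds,
            rng=rng,
            n_site_draws=config.get("n_site_draws", 500),
        )
        df = da.summary_frame()
        df.to_csv(out / "site_results.csv", index=False)
        outputs.append(out / "site_results.csv")
        post_dir = out / "posteriors"
        post_dir.mkdir(exist_ok=True)
        for rec in da.usable_records():
            pd.DataFrame(rec.result.posterior_samples, columns=list(PARAM_NAMES)).to_csv(
                post_dir / f"{rec.profile.site_id}.csv", index=False
            )
        outputs.append(post_dir)
    if scheme in ("batch", "both"):
        batch_cfg = _mcmc_config(config, workflow.BATCH_CONFIG)
        res = workflow.assimilate_batch(
            world.profiles, world.forcings, config=batch_cfg, bounds=bounds, rng=rng
        )
        summary = {"status": res.status, "acceptance_rates": res.acceptance_rates}
        if res.status == STATUS_ACCEPTED:
            pd.DataFrame(res.posterior_samples, columns=list(PARAM_NAMES)).to_csv(
                out / "batch_posterior.csv", index=False
            )
            outputs.append(out / "batch_posterior.csv")
            if res.gr is not None:
                summary["gelman_rubin"] = dict(zip(PARAM_NAMES, np.asarray(res.gr).tolist()))
        (out / "batch_summary.json").write_text(json.dumps(summary, indent=2))
        outputs.append(out / "batch_summary.json")
    _write_manifest(out, "assimilate", config, seed, t0, [Path(world_dir)], outputs)


def stage_upscale(world_dir, da_dir, config: dict, seed: int, out_dir) -> None:
    """Build the requested continental parameterization artifact."""
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    method = config.get("method", "nn")
    world = read_world(_require(Path(world_dir), "simulate-data"))
    da_dir = Path(da_dir)
    bounds = default_bounds()
    outputs = []
    if method == "onebatch":
        src = _require(da_dir / "batch_posterior.csv", "assimilate --scheme batch")
        pool = pd.read_csv(src)[list(PARAM_NAMES)].to_numpy()
        pd.DataFrame(pool, columns=list(PARAM_NAMES)).to_csv(out / "pool.csv", index=False)
        outputs.append(out / "pool.csv")
    elif method in ("random", "nn"):
        src = _require(da_dir / "site_results.csv", "assimilate --scheme site")
        df = pd.read_csv(src)
        usable = df[df["usable"]]
        if method == "random":
            pool = usable[[f"mle_{n}" for n in PARAM_NAMES]].to_numpy()
            pd.DataFrame(pool, columns=list(PARAM_NAMES)).to_csv(out / "pool.csv", index=False)
            outputs.append(out / "pool.csv")
        else:
            spec_kwargs = {
                k: v for k, v in config.items() if k in EmulatorSpec.__dataclass_fields__
            }
            spec = EmulatorSpec(**{"seed": seed, **spec_kwargs})
            cov = world.covariates.set_index("site_id")
            targets = usable.set_index("site_id")[[f"mean_{n}" for n in PARAM_NAMES]]
            X = cov.loc[targets.index, [c for c in cov.columns if c.startswith("cov_")]].to_numpy()
            from .upscale import ParameterEmulator

            emu = ParameterEmulator(
                bounds=bounds, spec=spec, categorical_cols=world.categorical_columns()
            )
            emu.fit(X, targets.to_numpy(), min_train_sites=config.get("min_train_sites", 50))
            with open(out / "emulator.pkl", "wb") as fh:
                pickle.dump(emu, fh)
            outputs.append(out / "emulator.pkl")
    else:
        raise InterfaceError(f"unknown upscaling method {method!r}")
    _write_manifest(out, "upscale", config, seed, t0, [da_dir], outputs)


def stage_map(world_dir, upscale_dir, config: dict, seed: int, out_dir) -> xr.Dataset:
    """Apply a parameterization over the grid and write the stock map."""
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    world = read_world(_require(Path(world_dir), "simulate-data"))
    method = config.get("method", "nn")
    rng = np.random.default_rng(seed)
    bounds = default_bounds()
    if method == "default":
        ds = workflow.map_constant(world.domain, world.grid_forcing)
    elif method in ("onebatch", "random"):
        src = _require(Path(upscale_dir) / "pool.csv", "upscale")
        pool = pd.read_csv(src)[list(PARAM_NAMES)].to_numpy()
        dist = ContinentalParameterDistribution(pool=pool, bounds=bounds)
        ds = workflow.map_distribution(
            world.domain, world.grid_forcing, dist, n_draws=config.get("n_draws", 1000), rng=rng
        )
    elif method == "nn":
        src = _require(Path(upscale_dir) / "emulator.pkl", "upscale --method nn")
        with open(src, "rb") as fh:
            emu = pickle.load(fh)
        ds = workflow.map_emulator(world.domain, world.grid_forcing, world.grid_covariates, emu)
    else:
        raise InterfaceError(f"unknown mapping method {method!r}")
    ds.to_netcdf(out / "soc_map.nc", engine="scipy")
    totals = {
        name: continental_total(ds[f"stock_{name}"].to_numpy(), world.domain)
        for name in workflow.DEPTH_INTERVALS_M
    }
    (out / "totals_pg.json").write_text(json.dumps(totals, indent=2))
    _write_manifest(
        out, "map", config, seed, t0, [Path(upscale_dir)], [out / "soc_map.nc", out / "totals_pg.json"]
    )
    return ds


def stage_evaluate(world_dir, da_dir, upscale_dirs: dict, config: dict, seed: int, out_dir) -> dict:
    """Site-level evaluation of every requested method."""
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    world = read_world(_require(Path(world_dir), "simulate-data"))
    rng = np.random.default_rng(seed)
    bounds = default_bounds()
    n_draws = config.get("n_draws", 1000)
    group = world.vegtype if config.get("group_by_vegtype", True) else None
    reports = {}
    rows = []
    for method, up_dir in upscale_dirs.items():
        if method == "default":
            preds = workflow.predict_profiles_constant(world.profiles, world.forcings)
        elif method in ("onebatch", "random"):
            pool = pd.read_csv(_require(Path(up_dir) / "pool.csv", "upscale"))[list(PARAM_NAMES)].to_numpy()
            dist = ContinentalParameterDistribution(pool=pool, bounds=bounds)
            preds = workflow.predict_profiles_distribution(
                world.profiles, world.forcings, dist, n_draws=n_draws, rng=rng
            )
        elif method == "nn":
            with open(_require(Path(up_dir) / "emulator.pkl", "upscale"), "rb") as fh:
                emu = pickle.load(fh)
            preds = workflow.predict_profiles_emulator(
                world.profiles, world.forcings, world.covariate_matrix(), emu
            )
        else:
            raise InterfaceError(f"unknown evaluation method {method!r}")
        res = workflow.evaluate_predictions(world.profiles, preds, groups=group)
        overall = res[0] if isinstance(res, tuple) else res
        reports[method] = overall.to_dict()
        rows.append({"method": method, **overall.to_dict()})
        if isinstance(res, tuple):
            for g, rep in res[1].items():
                rows.append({"method": method, **rep.to_dict()})
    pd.DataFrame(rows).to_csv(out / "evaluation.csv", index=False)
    (out / "evaluation.json").write_text(json.dumps(reports, indent=2, default=float))
    _write_manifest(out, "evaluate", config, seed, t0, [Path(da_dir)], [out / "evaluation.csv"])
    return reports


def run_pipeline(config: dict, out_dir, seed: int | None = None) -> dict:
    """Run all stages from one structured config; fails fast with
    stage-attributed errors."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = seed if seed is not None else int(config.get("seed", 0))
    stage_simulate(config.get("world", {}), seed, out / "world")
    assim_cfg = {**config.get("assimilate", {})}
    assim_cfg.setdefault("scheme", "both")
    stage_assimilate(out / "world", assim_cfg, seed + 1, out / "assimilation")
    methods = config.get("upscale", {}).get("methods", ["onebatch", "random", "nn"])
    up_dirs = {"default": out / "upscale" / "default"}
    (out / "upscale" / "default").mkdir(parents=True, exist_ok=True)
    for m in methods:
        up_cfg = {**config.get("upscale", {}), "method": m}
        up_cfg.pop("methods", None)
        stage_upscale(out / "world", out / "assimilation", up_cfg, seed + 2, out / "upscale" / m)
        up_dirs[m] = out / "upscale" / m
    for m in ["default"] + list(methods):
        map_cfg = {**config.get("map", {}), "method": m}
        stage_map(out / "world", up_dirs[m], map_cfg, seed + 3, out / "maps" / m)
    reports = stage_evaluate(
        out / "world", out / "assimilation", up_dirs, config.get("evaluate", {}), seed + 4, out / "evaluation"
    )
    return reports
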