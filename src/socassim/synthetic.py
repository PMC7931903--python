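"""Synthetic observation world with known ground truth.

Generates everything the pipeline consumes — depth-resolved SOC
profiles, per-site and gridded forcings, 60 environmental covariates —
from a known parameter field, so that calibration, upscaling and
mapping can be exercised and verified end to end without any external
data.

What it emulates (and what it does not): irregular profile layering to
a few metres, multiplicative 30%-CV observation noise, smooth spatially
correlated covariates with a few categorical masks, and true model
parameters that are either constant or driven by a handful of the
covariates. It does not emulate database quality flags, horizon
nomenclature, measurement-method mixtures, or correlated (non-local)
observation errors.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .column import Forcing, ModelConstants, ColumnModel
from .errors import InterfaceError
from .evaluate import GridDomain
from .grid import SoilGrid, build_grid
from .params import N_PARAMS, PARAM_NAMES, ParameterBounds, ParameterSet, default_bounds
from .profiles import SOCProfile, read_profiles, write_profiles

__all__ = ["SyntheticWorldConfig", "SyntheticWorld", "generate_world", "write_world", "read_world"]

#: normalized centre of the true parameter field; deliberately not the
#: nominal default parameterization, which plays the "uncalibrated model"
TRUTH_CENTER = np.array(
    [0.45, 0.55, 0.50, 0.45, 0.55, 0.45, 0.50, 0.45, 0.55, 0.50, 0.45, 0.55]
)


@dataclass(frozen=True)
class SyntheticWorldConfig:
    """Knobs of the synthetic world (defaults are the study conditions)."""

    n_sites: int = 300
    lat_min: float = 32.0
    lat_max: float = 46.0
    lon_min: float = -112.0
    lon_max: float = -86.0
    resolution: float = 0.5
    mode: str = "covariate"          # "constant" or "covariate"
    n_covariates: int = 60
    n_informative: int = 5
    n_categorical: int = 4
    effect_scale: float = 0.12       # covariate-driven parameter spread (normalized)
    param_noise_sd: float = 0.02     # site-level non-covariate parameter scatter
    noise_cv: float = 0.3            # multiplicative observation noise CV
    noise_floor: float = 0.01        # noise factor floor (fraction of value)
    single_layer_fraction: float = 0.05
    max_obs_layers: int = 10
    npp_range: tuple = (300.0, 800.0)   # g C m^-2 yr^-1
    temp_range: tuple = (4.0, 18.0)     # degC
    log10_psi_range: tuple = (-2.0, 0.5)  # log10(-psi/MPa)
    seed: int = 0


@dataclass
class SyntheticWorld:
    """All artifacts of one generated world."""

    config: SyntheticWorldConfig
    grid: SoilGrid
    domain: GridDomain
    profiles: list
    forcings: list                       # per-site Forcing
    covariates: pd.DataFrame             # site_id, lat, lon, cov_00..cov_59
    truth: pd.DataFrame                  # site_id + native parameter columns
    vegtype: np.ndarray                  # per-site categorical grouping key
    grid_covariates: xr.Dataset
    grid_forcing: xr.Dataset
    grid_truth: xr.Dataset

    @property
    def covariate_columns(self):
        return [c for c in self.covariates.columns if c.startswith("cov_")]

    def covariate_matrix(self) -> np.ndarray:
        return self.covariates[self.covariate_columns].to_numpy()

    def truth_matrix(self) -> np.ndarray:
        return self.truth[list(PARAM_NAMES)].to_numpy()

    def categorical_columns(self) -> tuple:
        """Indices of the categorical covariates in the matrix."""
        n = self.config.n_covariates
        return tuple(range(n - self.config.n_categorical, n))

    def site_forcing(self, i: int) -> Forcing:
        return self.forcings[i]


class _SmoothFieldBank:
    """Random smooth surfaces over the domain (sum of low-frequency waves)."""

    def __init__(self, cfg: SyntheticWorldConfig, rng: np.random.Generator, n_fields: int):
        self.cfg = cfg
        self.n_fields = n_fields
        self.freq = rng.uniform(0.5, 2.5, size=(n_fields, 3, 2))
        self.phase = rng.uniform(0, 2 * np.pi, size=(n_fields, 3))
        self.amp = rng.uniform(0.5, 1.0, size=(n_fields, 3))

    def evaluate(self, lat, lon) -> np.ndarray:
        """Field values, shape (*points, n_fields); inputs broadcast."""
        cfg = self.cfg
        latn = (np.asarray(lat) - cfg.lat_min) / (cfg.lat_max - cfg.lat_min)
        lonn = (np.asarray(lon) - cfg.lon_min) / (cfg.lon_max - cfg.lon_min)
        out = np.zeros(latn.shape + (self.n_fields,))
        for k in range(3):
            arg = (
                2 * np.pi
                * (
                    latn[..., None] * self.freq[None, :, k, 0]
                    + lonn[..., None] * self.freq[None, :, k, 1]
                )
                + self.phase[None, :, k]
            )
            out += self.amp[None, :, k] * np.cos(arg)
        return out / np.sqrt(np.sum(self.amp**2, axis=1))[None, :]


def _categorize(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    return np.digitize(values, edges).astype(float)


def generate_world(
    config: SyntheticWorldConfig = SyntheticWorldConfig(),
    bounds: ParameterBounds | None = None,
    constants: ModelConstants = ModelConstants(),
    theta_star: np.ndarray | None = None,
) -> SyntheticWorld:
    """Generate a fully self-consistent world from ``config``.

    Profiles are produced by running the steady-state column model with
    each site's true parameters and forcing, sampling the modeled SOC
    at the site's (irregular) observation depths, and applying
    multiplicative truncated-Gaussian noise. A configurable fraction of
    sites receives single-layer profiles to exercise the exclusion
    filter. ``theta_star`` (normalized) overrides the truth centre in
    "constant" mode.
    """
    cfg = config
    bounds = bounds or default_bounds()
    rng = np.random.default_rng(cfg.seed)
    grid = build_grid()

    # --- domain -------------------------------------------------------
    half = cfg.resolution / 2
    lats = np.arange(cfg.lat_min + half, cfg.lat_max, cfg.resolution)
    lons = np.arange(cfg.lon_min + half, cfg.lon_max, cfg.resolution)
    mask = np.ones((lats.size, lons.size), dtype=bool)
    domain = GridDomain(lats=lats, lons=lons, mask=mask, resolution=cfg.resolution)

    # --- covariate and forcing fields ---------------------------------
    n_smooth = cfg.n_covariates - cfg.n_categorical
    cov_bank = _SmoothFieldBank(cfg, rng, n_smooth)
    cat_bank = _SmoothFieldBank(cfg, rng, cfg.n_categorical)
    frc_bank = _SmoothFieldBank(cfg, rng, 3)  # npp, temperature, moisture

    glat, glon = np.meshgrid(lats, lons, indexing="ij")
    cov_grid_smooth = cov_bank.evaluate(glat, glon)
    # standardize smooth covariates by their grid statistics
    cs_mean = cov_grid_smooth.reshape(-1, n_smooth).mean(axis=0)
    cs_std = cov_grid_smooth.reshape(-1, n_smooth).std(axis=0)
    cs_std[cs_std == 0] = 1.0
    cat_fields_grid = cat_bank.evaluate(glat, glon)
    cat_edges = [
        np.quantile(cat_fields_grid[..., j], [0.25, 0.5, 0.75]) for j in range(cfg.n_categorical)
    ]
    frc_grid = frc_bank.evaluate(glat, glon)

    def covariates_at(lat, lon):
        smooth = (cov_bank.evaluate(lat, lon) - cs_mean) / cs_std
        cats = cat_bank.evaluate(lat, lon)
        cat_codes = np.stack(
            [_categorize(cats[..., j], cat_edges[j]) for j in range(cfg.n_categorical)],
            axis=-1,
        )
        return np.concatenate([smooth, cat_codes], axis=-1)

    def forcing_fields_at(lat, lon):
        f = frc_bank.evaluate(lat, lon)  # roughly in [-1, 1]
        z = np.clip((f + 1.0) / 2.0, 0.0, 1.0)
        npp_yr = cfg.npp_range[0] + z[..., 0] * (cfg.npp_range[1] - cfg.npp_range[0])
        temp = cfg.temp_range[0] + z[..., 1] * (cfg.temp_range[1] - cfg.temp_range[0])
        lpsi = cfg.log10_psi_range[0] + z[..., 2] * (
            cfg.log10_psi_range[1] - cfg.log10_psi_range[0]
        )
        return npp_yr / 365.0, temp, -(10.0**lpsi)

    # --- true parameter field -----------------------------------------
    center = TRUTH_CENTER.copy() if theta_star is None else np.asarray(theta_star, dtype=float)
    if center.shape != (N_PARAMS,):
        raise InterfaceError(f"theta_star must have shape ({N_PARAMS},)")
    informative = rng.choice(n_smooth, size=cfg.n_informative, replace=False)
    weights = rng.uniform(-1.0, 1.0, size=(N_PARAMS, cfg.n_informative))
    weights /= np.linalg.norm(weights, axis=1, keepdims=True)

    def truth_normalized(cov_matrix, noise_rng=None):
        if cfg.mode == "constant":
            base = np.tile(center, (cov_matrix.shape[0], 1))
        elif cfg.mode == "covariate":
            drive = cov_matrix[:, informative] @ weights.T * cfg.effect_scale
            base = center[None, :] + drive
            if noise_rng is not None and cfg.param_noise_sd > 0:
                base = base + cfg.param_noise_sd * noise_rng.standard_normal(base.shape)
        else:
            raise InterfaceError(f"unknown truth mode {cfg.mode!r}")
        return np.clip(base, 0.03, 0.97)

    # --- sites --------------------------------------------------------
    site_lat = rng.uniform(cfg.lat_min, cfg.lat_max, cfg.n_sites)
    site_lon = rng.uniform(cfg.lon_min, cfg.lon_max, cfg.n_sites)
    site_cov = covariates_at(site_lat, site_lon)
    theta_norm = truth_normalized(site_cov, noise_rng=rng)
    theta_native = bounds.denormalize(theta_norm)
    npp_d, temp, psi = forcing_fields_at(site_lat, site_lon)
    vegtype = site_cov[:, n_smooth].astype(int)  # first categorical covariate

    # observation layer-count distribution on [1, max_obs_layers]; the
    # 2+ layer weights put the mean near 8 layers per profile, matching
    # the ~9 layers/profile of large harmonized soil-profile databases
    base_probs = np.array(
        [0.01, 0.02, 0.03, 0.05, 0.08, 0.13, 0.22, 0.25, 0.21]
    )[: cfg.max_obs_layers - 1]
    base_probs = base_probs / base_probs.sum() * (1.0 - cfg.single_layer_fraction)
    layer_probs = np.concatenate([[cfg.single_layer_fraction], base_probs])

    profiles, forcings = [], []
    n_layers = grid.n_layers
    for i in range(cfg.n_sites):
        forcing = Forcing(
            npp=float(npp_d[i]),
            soil_temperature=np.full(n_layers, temp[i]),
            soil_water_potential=np.full(n_layers, psi[i]),
        )
        model = ColumnModel(forcing, grid=grid, constants=constants)
        conc = model.soc_profile(ParameterSet.from_array(theta_native[i]))
        n_obs = int(rng.choice(np.arange(1, layer_probs.size + 1), p=layer_probs))
        depth_max = rng.uniform(1.5, 3.8)
        fractions = rng.dirichlet(np.ones(n_obs))
        edges = np.concatenate([[0.0], np.cumsum(fractions)]) * depth_max
        mids = 0.5 * (edges[:-1] + edges[1:])
        clean = np.interp(mids, grid.node_depth, conc)
        if cfg.noise_cv > 0:
            factor = np.maximum(
                1.0 + cfg.noise_cv * rng.standard_normal(n_obs), cfg.noise_floor
            )
        else:
            factor = np.ones(n_obs)
        profiles.append(
            SOCProfile(
                site_id=f"site_{i:05d}",
                lat=float(site_lat[i]),
                lon=float(site_lon[i]),
                layer_top=edges[:-1],
                layer_bottom=edges[1:],
                soc_obs=clean * factor,
            )
        )
        forcings.append(forcing)

    site_ids = [p.site_id for p in profiles]
    cov_cols = [f"cov_{j:02d}" for j in range(cfg.n_covariates)]
    covariates = pd.DataFrame(site_cov, columns=cov_cols)
    covariates.insert(0, "site_id", site_ids)
    covariates.insert(1, "lat", site_lat)
    covariates.insert(2, "lon", site_lon)
    truth = pd.DataFrame(theta_native, columns=list(PARAM_NAMES))
    truth.insert(0, "site_id", site_ids)

    # --- gridded companions -------------------------------------------
    grid_cov_all = covariates_at(glat, glon)
    gnpp, gtemp, gpsi = forcing_fields_at(glat, glon)
    coords = {"lat": lats, "lon": lons}
    grid_covariates = xr.Dataset(
        {c: (("lat", "lon"), grid_cov_all[..., j]) for j, c in enumerate(cov_cols)},
        coords=coords,
    )
    grid_forcing = xr.Dataset(
        {
            "npp": (("lat", "lon"), gnpp),
            "soil_temperature": (
                ("lat", "lon", "layer"),
                np.repeat(gtemp[..., None], n_layers, axis=-1),
            ),
            "soil_water_potential": (
                ("lat", "lon", "layer"),
                np.repeat(gpsi[..., None], n_layers, axis=-1),
            ),
            "land_mask": (("lat", "lon"), mask.astype("int8")),
        },
        coords={**coords, "layer": np.arange(1, n_layers + 1)},
    )
    gcov_flat = grid_cov_all.reshape(-1, cfg.n_covariates)
    gtruth = bounds.denormalize(truth_normalized(gcov_flat)).reshape(
        lats.size, lons.size, N_PARAMS
    )
    grid_truth = xr.Dataset(
        {name: (("lat", "lon"), gtruth[..., j]) for j, name in enumerate(PARAM_NAMES)},
        coords=coords,
    )
    return SyntheticWorld(
        config=cfg,
        grid=grid,
        domain=domain,
        profiles=profiles,
        forcings=forcings,
        covariates=covariates,
        truth=truth,
        vegtype=vegtype,
        grid_covariates=grid_covariates,
        grid_forcing=grid_forcing,
        grid_truth=grid_truth,
    )


# ---------------------------------------------------------------------
# fixture round-trip
# ---------------------------------------------------------------------

def write_world(world: SyntheticWorld, out_dir) -> None:
    """Write a world to the on-disk formats the pipeline stages consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_profiles(world.profiles, out / "profiles.csv")
    n_layers = world.grid.n_layers
    rows = []
    for p, f in zip(world.profiles, world.forcings):
        row = {"site_id": p.site_id, "npp_gc_m2_day": f.npp}
        for L in range(n_layers):
            row[f"temp_c_{L + 1:02d}"] = f.soil_temperature[L]
            row[f"psi_mpa_{L + 1:02d}"] = f.soil_water_potential[L]
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "forcing_sites.csv", index=False)
    world.covariates.to_csv(out / "covariates_sites.csv", index=False)
    truth = world.truth.copy()
    truth["vegtype"] = world.vegtype
    truth.to_csv(out / "truth_sites.csv", index=False)
    world.grid_covariates.to_netcdf(out / "grid_covariates.nc", engine="scipy")
    world.grid_forcing.to_netcdf(out / "grid_forcing.nc", engine="scipy")
    world.grid_truth.to_netcdf(out / "grid_truth.nc", engine="scipy")
    meta = asdict(world.config)
    meta["config_hash"] = hashlib.sha256(
        json.dumps(meta, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    (out / "world.json").write_text(json.dumps(meta, indent=2, default=str))


def read_world(in_dir) -> SyntheticWorld:
    """Read back a written world (lossless within float round-trip)."""
    src = Path(in_dir)
    meta = json.loads((src / "world.json").read_text())
    meta.pop("config_hash", None)
    for key in ("npp_range", "temp_range", "log10_psi_range"):
        meta[key] = tuple(meta[key])
    cfg = SyntheticWorldConfig(**meta)
    profiles = read_profiles(src / "profiles.csv")
    frc = pd.read_csv(src / "forcing_sites.csv").set_index("site_id")
    grid = build_grid()
    n_layers = grid.n_layers
    forcings = []
    for p in profiles:
        row = frc.loc[p.site_id]
        forcings.append(
            Forcing(
                npp=float(row["npp_gc_m2_day"]),
                soil_temperature=row[[f"temp_c_{L + 1:02d}" for L in range(n_layers)]].to_numpy(dtype=float),
                soil_water_potential=row[[f"psi_mpa_{L + 1:02d}" for L in range(n_layers)]].to_numpy(dtype=float),
            )
        )
    covariates = pd.read_csv(src / "covariates_sites.csv")
    truth = pd.read_csv(src / "truth_sites.csv")
    vegtype = truth.pop("vegtype").to_numpy()
    grid_covariates = xr.load_dataset(src / "grid_covariates.nc", engine="scipy")
    grid_forcing = xr.load_dataset(src / "grid_forcing.nc", engine="scipy")
    grid_truth = xr.load_dataset(src / "grid_truth.nc", engine="scipy")
    lats = grid_covariates["lat"].to_numpy()
    lons = grid_covariates["lon"].to_numpy()
    domain = GridDomain(
        lats=lats,
        lons=lons,
        mask=grid_forcing["land_mask"].to_numpy().astype(bool),
        resolution=cfg.resolution,
    )
    return SyntheticWorld(
        config=cfg,
        grid=grid,
        domain=domain,
        profiles=profiles,
        forcings=forcings,
        covariates=covariates,
        truth=truth,
        vegtype=vegtype,
        grid_covariates=grid_covariates,
        grid_forcing=grid_forcing,
        grid_truth=grid_truth,
    )
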