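"""End-to-end workflow stages: assimilate, upscale, map, evaluate.

These functions operate on in-memory objects (a SyntheticWorld or the
equivalent profiles/forcings/covariates read from files) and are the
substance behind the command-line stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .assimilate import SITE_CONFIG, BATCH_CONFIG, SiteMisfit, assimilate_batch, assimilate_site, filter_profiles
from .column import ColumnModel, Forcing, ModelConstants
from .errors import InterfaceError
from .evaluate import GridDomain, depth_interval_stock, eval_metrics, fixed_line_r2
from .grid import SoilGrid, build_grid
from .mcmc import MCMCConfig, MCMCResult, STATUS_ACCEPTED
from .params import PARAM_NAMES, ParameterBounds, ParameterSet, default_bounds, default_params
from .upscale import (
    ContinentalParameterDistribution,
    EmulatorSpec,
    ParameterEmulator,
    predict_with_sampling,
    summarize_posterior,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SiteRecord",
    "SiteAssimilation",
    "assimilate_sites",
    "upscale_random_sampling",
    "upscale_one_batch",
    "train_parameter_emulator",
    "predict_profiles_constant",
    "predict_profiles_distribution",
    "predict_profiles_emulator",
    "map_distribution",
    "map_emulator",
    "evaluate_predictions",
    "DEPTH_INTERVALS_M",
]

#: depth intervals (m) reported on SOC maps
DEPTH_INTERVALS_M = {"0-30cm": (0.0, 0.3), "30-100cm": (0.3, 1.0), "100-200cm": (1.0, 2.0)}


@dataclass
class SiteRecord:
    """Per-site outcome of the site-by-site scheme."""

    profile: object
    forcing: Forcing
    result: MCMCResult
    posterior_mean: np.ndarray | None = None
    posterior_mle: np.ndarray | None = None
    prediction: np.ndarray | None = None   # ensemble-mean SOC at obs depths
    r2: float = np.nan

    @property
    def usable(self) -> bool:
        """Accepted by the rate gate and non-negative fixed-line R^2."""
        return (
            self.result.status == STATUS_ACCEPTED
            and np.isfinite(self.r2)
            and self.r2 >= 0
        )


@dataclass
class SiteAssimilation:
    """Pooled site-by-site results."""

    records: list

    def usable_records(self):
        return [r for r in self.records if r.usable]

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "site_id": r.profile.site_id,
                "status": r.result.status,
                "r2": r.r2,
                "usable": r.usable,
            }
            rates = r.result.acceptance_rates
            row["acceptance_rate"] = rates[r.result.selected_chain] if rates and r.result.selected_chain is not None else np.nan
            row["gr_max"] = float(np.max(r.result.gr)) if r.result.gr is not None else np.nan
            for j, name in enumerate(PARAM_NAMES):
                row[f"mean_{name}"] = r.posterior_mean[j] if r.posterior_mean is not None else np.nan
                row[f"mle_{name}"] = r.posterior_mle[j] if r.posterior_mle is not None else np.nan
            rows.append(row)
        return pd.DataFrame(rows)


def assimilate_sites(
    profiles,
    forcings,
    config: MCMCConfig = SITE_CONFIG,
    bounds: ParameterBounds | None = None,
    constants: ModelConstants = ModelConstants(),
    rng: np.random.Generator | None = None,
    n_site_draws: int = 500,
    min_mle_samples: int = 100,
    compute_mle: bool = True,
) -> SiteAssimilation:
    """Site-by-site assimilation with post-hoc prediction and filtering.

    For each accepted site, SOC at the observation depths is predicted
    as the mean over ``n_site_draws`` posterior draws, the fixed-line
    R^2 against the observations is computed, and profiles with
    negative R^2 are marked unusable (excluded from upscaling).
    """
    bounds = bounds or default_bounds()
    rng = rng if rng is not None else np.random.default_rng()
    records = []
    for profile, forcing in zip(profiles, forcings):
        result = assimilate_site(
            profile, forcing, config=config, bounds=bounds, constants=constants, rng=rng
        )
        rec = SiteRecord(profile=profile, forcing=forcing, result=result)
        if result.status == STATUS_ACCEPTED:
            samples = result.posterior_samples
            rec.posterior_mean = samples.mean(axis=0)
            if compute_mle:
                try:
                    summ = summarize_posterior(
                        samples, bounds=bounds, min_samples=min(min_mle_samples, len(samples))
                    )
                    rec.posterior_mle = summ.mle
                except Exception:
                    logger.warning("posterior summary failed for %s", profile.site_id)
                    rec.posterior_mle = rec.posterior_mean
            n_draws = min(n_site_draws, len(samples))
            idx = rng.integers(0, len(samples), size=n_draws)
            misfit = SiteMisfit(profile, forcing, constants=constants)
            preds = np.array([misfit.predicted(samples[k]) for k in idx])
            rec.prediction = preds.mean(axis=0)
            try:
                rec.r2 = fixed_line_r2(profile.soc_obs, rec.prediction)
            except InterfaceError:
                rec.r2 = np.nan
        records.append(rec)
    return SiteAssimilation(records=records)


# ---------------------------------------------------------------------
# upscaling routes
# ---------------------------------------------------------------------

def upscale_random_sampling(site_da: SiteAssimilation, bounds: ParameterBounds | None = None) -> ContinentalParameterDistribution:
    """Assemble usable-site GEV-mode MLEs into continental pools."""
    bounds = bounds or default_bounds()
    mles = [r.posterior_mle for r in site_da.usable_records() if r.posterior_mle is not None]
    if not mles:
        raise InterfaceError("no usable site results to assemble")
    return ContinentalParameterDistribution(pool=np.asarray(mles), bounds=bounds)


def upscale_one_batch(batch_result: MCMCResult, bounds: ParameterBounds | None = None) -> ContinentalParameterDistribution:
    """Continental distribution = the one-batch posterior samples."""
    bounds = bounds or default_bounds()
    if batch_result.status != STATUS_ACCEPTED:
        raise InterfaceError(f"batch result not usable (status {batch_result.status})")
    return ContinentalParameterDistribution(pool=batch_result.posterior_samples, bounds=bounds)


def train_parameter_emulator(
    covariates: np.ndarray,
    site_da: SiteAssimilation,
    spec: EmulatorSpec = EmulatorSpec(),
    bounds: ParameterBounds | None = None,
    categorical_cols=(),
    min_train_sites: int = 50,
) -> ParameterEmulator:
    """Train the covariate->parameter network on usable sites only.

    ``covariates`` is (n_sites, 60) aligned with ``site_da.records``;
    targets are the site posterior means.
    """
    bounds = bounds or default_bounds()
    covariates = np.asarray(covariates, dtype=float)
    if covariates.shape[0] != len(site_da.records):
        raise InterfaceError("covariates must align with assimilation records")
    keep = [i for i, r in enumerate(site_da.records) if r.usable]
    X = covariates[keep]
    y = np.asarray([site_da.records[i].posterior_mean for i in keep])
    emu = ParameterEmulator(bounds=bounds, spec=spec, categorical_cols=categorical_cols)
    emu.fit(X, y, min_train_sites=min_train_sites)
    return emu


# ---------------------------------------------------------------------
# site-level predictions for evaluation
# ---------------------------------------------------------------------

def _predict_at_obs(profile, forcing, thetas, constants) -> np.ndarray:
    model = ColumnModel(forcing, constants=constants)
    depths = profile.midpoints
    if thetas.ndim == 1:
        return model.soc_at_depths(ParameterSet.from_array(thetas), depths)
    preds = [model.soc_at_depths(ParameterSet.from_array(t), depths) for t in thetas]
    return np.mean(preds, axis=0)


def predict_profiles_constant(profiles, forcings, params: ParameterSet | None = None, constants=ModelConstants()):
    """SOC at observation depths under one fixed parameterization."""
    theta = (params or default_params()).as_array()
    return [_predict_at_obs(p, f, theta, constants) for p, f in zip(profiles, forcings)]


def predict_profiles_distribution(
    profiles,
    forcings,
    dist: ContinentalParameterDistribution,
    n_draws: int = 1000,
    rng: np.random.Generator | None = None,
    constants=ModelConstants(),
):
    """Ensemble-mean SOC at observation depths; the same parameter draws
    are reused at every site, as in continental mapping."""
    rng = rng if rng is not None else np.random.default_rng()
    thetas = dist.draw(n_draws, rng)
    return [_predict_at_obs(p, f, thetas, constants) for p, f in zip(profiles, forcings)]


def predict_profiles_emulator(profiles, forcings, covariates, emulator: ParameterEmulator, constants=ModelConstants()):
    """Per-site deterministic prediction from emulated parameters."""
    params = emulator.predict(np.asarray(covariates, dtype=float))
    return [
        _predict_at_obs(p, f, params[i], constants)
        for i, (p, f) in enumerate(zip(profiles, forcings))
    ]


# ---------------------------------------------------------------------
# gridded mapping
# ---------------------------------------------------------------------

def _grid_forcing_at(grid_forcing: xr.Dataset, i: int, j: int) -> Forcing:
    return Forcing(
        npp=float(grid_forcing["npp"][i, j]),
        soil_temperature=grid_forcing["soil_temperature"][i, j].to_numpy(),
        soil_water_potential=grid_forcing["soil_water_potential"][i, j].to_numpy(),
    )


def _stock_dataset(domain: GridDomain, grid: SoilGrid, conc_mean, conc_q5=None, conc_q95=None) -> xr.Dataset:
    """Integrate per-cell concentration profiles into interval stocks."""
    coords = {"lat": domain.lats, "lon": domain.lons}
    data = {}
    for name, interval in DEPTH_INTERVALS_M.items():
        for label, conc in (("", conc_mean), ("_q5", conc_q5), ("_q95", conc_q95)):
            if conc is None:
                continue
            field = np.full(domain.mask.shape, np.nan)
            for i, j in zip(*np.nonzero(domain.mask)):
                if np.all(np.isfinite(conc[i, j])):
                    field[i, j] = depth_interval_stock(conc[i, j], grid, interval)
            data[f"stock_{name}{label}"] = (("lat", "lon"), field)
    return xr.Dataset(data, coords=coords)


def map_distribution(
    domain: GridDomain,
    grid_forcing: xr.Dataset,
    dist: ContinentalParameterDistribution,
    n_draws: int = 1000,
    rng: np.random.Generator | None = None,
    grid: SoilGrid | None = None,
    constants=ModelConstants(),
) -> xr.Dataset:
    """SOC stock map under a spatially constant parameter distribution.

    Draws once, reuses the same draws in every land cell, and reports
    the ensemble mean with 5%/95% envelope stocks per depth interval.
    """
    rng = rng if rng is not None else np.random.default_rng()
    grid = grid or build_grid()
    thetas = dist.draw(n_draws, rng)
    shape = domain.mask.shape + (grid.n_layers,)
    mean = np.full(shape, np.nan)
    q5 = np.full(shape, np.nan)
    q95 = np.full(shape, np.nan)
    for i, j in zip(*np.nonzero(domain.mask)):
        m, lo, hi = predict_with_sampling(
            dist, _grid_forcing_at(grid_forcing, i, j), thetas=thetas, grid=grid, constants=constants
        )
        mean[i, j], q5[i, j], q95[i, j] = m, lo, hi
    return _stock_dataset(domain, grid, mean, q5, q95)


def map_emulator(
    domain: GridDomain,
    grid_forcing: xr.Dataset,
    grid_covariates: xr.Dataset,
    emulator: ParameterEmulator,
    grid: SoilGrid | None = None,
    constants=ModelConstants(),
) -> xr.Dataset:
    """SOC stock map from spatially heterogeneous emulated parameters."""
    grid = grid or build_grid()
    cov_names = sorted(v for v in grid_covariates.data_vars if v.startswith("cov_"))
    cov = np.stack([grid_covariates[v].to_numpy() for v in cov_names], axis=-1)
    flat = cov.reshape(-1, cov.shape[-1])
    params = emulator.predict(flat).reshape(domain.mask.shape[0], domain.mask.shape[1], -1)
    conc = np.full(domain.mask.shape + (grid.n_layers,), np.nan)
    for i, j in zip(*np.nonzero(domain.mask)):
        theta = params[i, j]
        if not np.all(np.isfinite(theta)):
            continue
        model = ColumnModel(_grid_forcing_at(grid_forcing, i, j), grid=grid, constants=constants)
        conc[i, j] = model.soc_profile(ParameterSet.from_array(theta))
    return _stock_dataset(domain, grid, conc)


def map_constant(
    domain: GridDomain,
    grid_forcing: xr.Dataset,
    params: ParameterSet | None = None,
    grid: SoilGrid | None = None,
    constants=ModelConstants(),
) -> xr.Dataset:
    """SOC stock map under a single fixed parameterization (default run)."""
    grid = grid or build_grid()
    params = params or default_params()
    conc = np.full(domain.mask.shape + (grid.n_layers,), np.nan)
    for i, j in zip(*np.nonzero(domain.mask)):
        model = ColumnModel(_grid_forcing_at(grid_forcing, i, j), grid=grid, constants=constants)
        conc[i, j] = model.soc_profile(params)
    return _stock_dataset(domain, grid, conc)


# ---------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------

def evaluate_predictions(profiles, predictions, groups=None):
    """Pooled layer-level evaluation of predictions vs observations.

    ``predictions`` holds per-profile modeled SOC at the observation
    depths; ``groups`` (optional) is a per-profile categorical label
    (e.g. vegetation type), expanded to layers for stratified reports.
    """
    obs = np.concatenate([p.soc_obs for p in profiles])
    pred = np.concatenate([np.asarray(z, dtype=float) for z in predictions])
    if groups is None:
        return eval_metrics(obs, pred)
    layer_groups = np.concatenate(
        [np.repeat(g, p.n_obs) for g, p in zip(groups, profiles)]
    )
    return eval_metrics(obs, pred, groups=layer_groups)
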