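"""Evaluation statistics, depth-interval stocks and map diagnostics.

The headline statistic is the fixed-line coefficient of determination:
R^2 of the regression of modeled on observed SOC with slope pinned to
1 and intercept to 0,

    R^2 = 1 - sum (x_i - z_i)^2 / sum (x_i - mean(x))^2,

which is negative when predictions do worse than simply using the
observation mean. Pearson r and RMSE complete the report, optionally
stratified by a categorical grouping (vegetation type).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InterfaceError
from .grid import SoilGrid

__all__ = [
    "GridDomain",
    "EvalReport",
    "fixed_line_r2",
    "eval_metrics",
    "depth_interval_stock",
    "continental_total",
    "deviation_map",
]

EARTH_RADIUS_M = 6_371_000.0


@dataclass(frozen=True)
class GridDomain:
    """Regular lat/lon grid of cell centers with a land mask.

    ``lats``/``lons`` are 1-D cell-center coordinates at ``resolution``
    degree spacing; ``mask`` is (n_lat, n_lon) boolean (True = land).
    Cell areas are cosine-latitude weighted.
    """

    lats: np.ndarray
    lons: np.ndarray
    mask: np.ndarray
    resolution: float = 0.5

    def __post_init__(self):
        lats = np.asarray(self.lats, dtype=float)
        lons = np.asarray(self.lons, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != (lats.size, lons.size):
            raise InterfaceError("mask shape must be (n_lat, n_lon)")
        object.__setattr__(self, "lats", lats)
        object.__setattr__(self, "lons", lons)
        object.__setattr__(self, "mask", mask)

    def cell_area(self) -> np.ndarray:
        """Cell area in m^2, shape (n_lat, n_lon)."""
        dphi = np.deg2rad(self.resolution)
        area_lat = EARTH_RADIUS_M**2 * dphi * dphi * np.cos(np.deg2rad(self.lats))
        return np.repeat(area_lat[:, None], self.lons.size, axis=1)

    def cell_index(self, lat: float, lon: float):
        """Indices of the cell containing a point.

        Cells are half-open boxes [c - res/2, c + res/2) in both
        coordinates, so a point on a shared edge deterministically
        belongs to the cell whose box starts there.
        """
        half = self.resolution / 2.0
        i = np.searchsorted(self.lats + half, lat, side="right")
        j = np.searchsorted(self.lons + half, lon, side="right")
        if not (0 <= i < self.lats.size and 0 <= j < self.lons.size):
            raise InterfaceError(f"point ({lat}, {lon}) outside the domain")
        return int(i), int(j)


@dataclass(frozen=True)
class EvalReport:
    """Fit statistics of modeled vs observed SOC."""

    r2_fixed: float
    r: float
    rmse: float
    n: int
    group: object = None
    mean_obs: float = np.nan
    mean_pred: float = np.nan
    half_sd_obs: float = np.nan
    half_sd_pred: float = np.nan

    def to_dict(self):
        return {
            "group": self.group,
            "n": self.n,
            "r2_fixed": self.r2_fixed,
            "r": self.r,
            "rmse": self.rmse,
            "mean_obs": self.mean_obs,
            "mean_pred": self.mean_pred,
            "half_sd_obs": self.half_sd_obs,
            "half_sd_pred": self.half_sd_pred,
        }


def fixed_line_r2(obs, pred) -> float:
    """Coefficient of determination against the identity line."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.size < 2 or obs.shape != pred.shape:
        raise InterfaceError("need >= 2 paired values")
    ss_tot = np.sum((obs - obs.mean()) ** 2)
    if ss_tot == 0:
        raise InterfaceError("zero observation variance: fixed-line R^2 undefined")
    return float(1.0 - np.sum((obs - pred) ** 2) / ss_tot)


def _metrics(obs, pred, group=None) -> EvalReport:
    n = obs.size
    rmse = float(np.sqrt(np.mean((pred - obs) ** 2)))
    if n < 2 or np.std(obs) == 0:
        return EvalReport(np.nan, np.nan, rmse if n else np.nan, n, group)
    r = float(stats.pearsonr(obs, pred).statistic) if np.std(pred) > 0 else np.nan
    return EvalReport(
        r2_fixed=fixed_line_r2(obs, pred),
        r=r,
        rmse=rmse,
        n=n,
        group=group,
        mean_obs=float(obs.mean()),
        mean_pred=float(pred.mean()),
        half_sd_obs=0.5 * float(obs.std(ddof=1)),
        half_sd_pred=0.5 * float(pred.std(ddof=1)),
    )


def eval_metrics(obs, pred, groups=None):
    """Overall (and optionally per-group) evaluation statistics.

    Returns a single EvalReport, or (overall, per_group_dict) when a
    categorical stratum such as vegetation type is supplied. Group
    summaries carry means with +-0.5 standard deviation half-widths.
    Groups with fewer than 2 members are reported with missing
    statistics.
    """
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape:
        raise InterfaceError("obs and pred must be paired")
    overall = _metrics(obs, pred)
    if groups is None:
        return overall
    groups = np.asarray(groups)
    per_group = {}
    for g in pd.unique(groups):
        sel = groups == g
        per_group[g] = _metrics(obs[sel], pred[sel], group=g)
    return overall, per_group


def depth_interval_stock(conc, grid: SoilGrid, interval) -> float:
    """Integrate a per-layer concentration profile over a depth interval.

    conc in kg C m^-3 per model layer; interval (a, b) in m. Partial
    layers contribute by their overlap with [a, b]; b beyond the
    column bottom is truncated. Returns kg C m^-2.
    """
    a, b = float(interval[0]), float(interval[1])
    if a < 0 or a >= b:
        raise InterfaceError(f"need 0 <= a < b, got ({a}, {b})")
    conc = np.asarray(conc, dtype=float)
    if conc.shape != (grid.n_layers,):
        raise InterfaceError("concentration profile does not match the grid")
    top = grid.layer_top()
    bottom = grid.interface_depth
    overlap = np.clip(np.minimum(bottom, b) - np.maximum(top, a), 0.0, None)
    return float(np.sum(conc * overlap))


def continental_total(stock_field: np.ndarray, domain: GridDomain) -> float:
    """Total stock over land cells in Pg C (1 Pg = 1e15 g).

    ``stock_field`` is per-cell stock in kg C m^-2, shape matching the
    domain mask; masked-out or NaN cells are ignored.
    """
    stock = np.asarray(stock_field, dtype=float)
    if stock.shape != domain.mask.shape:
        raise InterfaceError("stock field shape does not match the domain")
    area = domain.cell_area()
    valid = domain.mask & np.isfinite(stock)
    return float(np.sum(stock[valid] * area[valid]) * 1e3 / 1e15)  # kg -> g -> Pg


def deviation_map(observed, modeled):
    """Quantile-scaled deviation (modeled - observed), clipped to [-1, 1].

    Positive deviations are divided by the 95% quantile of the positive
    deviations, negative ones by the absolute 5% quantile of the
    negative deviations (linear-interpolation sample quantiles). A
    branch with no members is left unscaled.
    """
    observed = np.asarray(observed, dtype=float)
    modeled = np.asarray(modeled, dtype=float)
    dev = modeled - observed
    out = dev.astype(float).copy()
    pos = dev > 0
    neg = dev < 0
    if np.any(pos):
        q95 = np.quantile(dev[pos], 0.95)
        if q95 > 0:
            out[pos] = dev[pos] / q95
    if np.any(neg):
        q5 = abs(np.quantile(dev[neg], 0.05))
        if q5 > 0:
            out[neg] = dev[neg] / q5
    return np.clip(out, -1.0, 1.0)
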