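"""Depth-resolved SOC observation profiles and their flat-file format.

A profile is one site's set of (layer_top, layer_bottom, SOC
concentration) observations. Observation uncertainty is taken as 30%
of the reported value, the conventional assumption when a soil
database carries no quantitative error estimate.

The exchange format is a flat CSV with columns
``site_id, lat, lon, layer_top_m, layer_bottom_m, soc_kg_m3``
(one row per observed layer), mirroring a typical WoSIS-style profile
export.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InterfaceError

__all__ = ["SOCProfile", "read_profiles", "write_profiles", "SIGMA_FRACTION"]

#: observation standard deviation as a fraction of the reported value
SIGMA_FRACTION = 0.3

PROFILE_COLUMNS = ["site_id", "lat", "lon", "layer_top_m", "layer_bottom_m", "soc_kg_m3"]


@dataclass(frozen=True)
class SOCProfile:
    """One site's depth-resolved SOC observations.

    layer_top / layer_bottom in m, soc_obs in kg C m^-3. ``sigma`` is
    always 0.3 * soc_obs. Layers must be sorted by top depth and
    non-overlapping.
    """

    site_id: object
    lat: float
    lon: float
    layer_top: np.ndarray
    layer_bottom: np.ndarray
    soc_obs: np.ndarray

    def __post_init__(self):
        top = np.atleast_1d(np.asarray(self.layer_top, dtype=float))
        bot = np.atleast_1d(np.asarray(self.layer_bottom, dtype=float))
        obs = np.atleast_1d(np.asarray(self.soc_obs, dtype=float))
        if not (top.shape == bot.shape == obs.shape):
            raise InterfaceError("layer arrays must share a common length")
        if np.any(top < 0) or np.any(bot <= top):
            raise InterfaceError("need 0 <= layer_top < layer_bottom per layer")
        if np.any(np.diff(top) <= 0):
            raise InterfaceError("layers must be sorted by top depth")
        if np.any(bot[:-1] > top[1:] + 1e-12):
            raise InterfaceError("layers must not overlap")
        object.__setattr__(self, "layer_top", top)
        object.__setattr__(self, "layer_bottom", bot)
        object.__setattr__(self, "soc_obs", obs)

    @property
    def n_obs(self) -> int:
        return self.soc_obs.size

    @property
    def sigma(self) -> np.ndarray:
        return SIGMA_FRACTION * self.soc_obs

    @property
    def midpoints(self) -> np.ndarray:
        """Observation-layer midpoint depths (m)."""
        return 0.5 * (self.layer_top + self.layer_bottom)

    def assimilable(self) -> bool:
        """Profiles with a single observation cannot constrain the model."""
        return self.n_obs >= 2


def write_profiles(profiles, path) -> None:
    """Write profiles to the flat CSV exchange format."""
    rows = []
    for p in profiles:
        for t, b, c in zip(p.layer_top, p.layer_bottom, p.soc_obs):
            rows.append((p.site_id, p.lat, p.lon, t, b, c))
    pd.DataFrame(rows, columns=PROFILE_COLUMNS).to_csv(path, index=False)


def read_profiles(path, strict: bool = False):
    """Read profiles from CSV; returns a list of SOCProfile.

    Rows of each site are sorted by top depth before construction
    unless ``strict`` is set, in which case unsorted input raises.
    """
    df = pd.read_csv(path)
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise InterfaceError(f"profile file {path} missing columns {missing}")
    profiles = []
    for site_id, g in df.groupby("site_id", sort=True):
        if strict and np.any(np.diff(g["layer_top_m"].to_numpy()) <= 0):
            raise InterfaceError(f"site {site_id}: layers not sorted by top depth")
        g = g.sort_values("layer_top_m")
        profiles.append(
            SOCProfile(
                site_id=site_id,
                lat=float(g["lat"].iloc[0]),
                lon=float(g["lon"].iloc[0]),
                layer_top=g["layer_top_m"].to_numpy(),
                layer_bottom=g["layer_bottom_m"].to_numpy(),
                soc_obs=g["soc_kg_m3"].to_numpy(),
            )
        )
    return profiles
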