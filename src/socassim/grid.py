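"""Exponential vertical soil grid and the litter/SOC pool layout.

The soil column is discretized into layers whose thickness grows
exponentially with depth, the standard land-model choice that resolves
the carbon-rich topsoil finely while still reaching several metres.
With the default 10 layers the column spans 3.8 m, from a 1.75 cm
surface layer to a 1.51 m bottom layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SoilGrid", "PoolLayout", "build_grid"]

#: ordered pool names within one layer
POOL_NAMES = (
    "cwd",
    "metabolic_litter",
    "cellulose_litter",
    "lignin_litter",
    "fast_soc",
    "slow_soc",
    "passive_soc",
)

LITTER_POOLS = (0, 1, 2, 3)
SOC_POOLS = (4, 5, 6)


@dataclass(frozen=True)
class SoilGrid:
    """Vertical discretization of the soil column.

    Attributes
    ----------
    n_layers : int
        Number of soil layers.
    node_depth : ndarray, shape (n_layers,)
        Depth of each layer's node (m), where state variables live.
    thickness : ndarray, shape (n_layers,)
        Layer thickness dz (m); strictly increasing with depth.
    interface_depth : ndarray, shape (n_layers,)
        Depth of each layer's bottom interface (m); cumulative thickness.
    """

    n_layers: int
    node_depth: np.ndarray
    thickness: np.ndarray
    interface_depth: np.ndarray

    @property
    def total_depth(self) -> float:
        return float(self.interface_depth[-1])

    def layer_top(self) -> np.ndarray:
        """Top interface depth of each layer (m)."""
        return self.interface_depth - self.thickness


def build_grid(n_layers: int = 10) -> SoilGrid:
    """Build the exponential vertical grid.

    Node depths follow z_i = 0.025 * (exp(0.5*(i - 0.5)) - 1) for
    i = 1..n; thicknesses are half the distance between the two
    neighbouring nodes (an extended node below the column closes the
    last layer).

    Parameters
    ----------
    n_layers : int
        Number of layers; must be >= 2.

    Raises
    ------
    ValueError
        If ``n_layers < 2``.
    """
    if n_layers < 2:
        raise ValueError(f"n_layers must be >= 2, got {n_layers}")
    # extended node sequence i = 1 .. n+1
    i = np.arange(1, n_layers + 2)
    z = 0.025 * (np.exp(0.5 * (i - 0.5)) - 1.0)
    dz = np.empty(n_layers)
    dz[0] = 0.5 * (z[0] + z[1])
    dz[1:] = 0.5 * (z[2 : n_layers + 1] - z[0 : n_layers - 1])
    node = z[:n_layers].copy()
    return SoilGrid(
        n_layers=n_layers,
        node_depth=node,
        thickness=dz,
        interface_depth=np.cumsum(dz),
    )


@dataclass(frozen=True)
class PoolLayout:
    """Index bookkeeping for the per-layer carbon pools.

    Seven pools per layer (four litter: coarse woody debris, metabolic,
    cellulose, lignin; three SOC: fast, slow, passive), layer-major
    ordering, so the default 10-layer column has 70 state variables.
    """

    n_layers: int = 10
    pool_names: tuple = field(default=POOL_NAMES)

    @property
    def n_pools_per_layer(self) -> int:
        return len(self.pool_names)

    @property
    def state_dim(self) -> int:
        return self.n_pools_per_layer * self.n_layers

    def index(self, pool: int, layer: int) -> int:
        """Flat state index of ``pool`` (0..6) in ``layer`` (0-based)."""
        npl = self.n_pools_per_layer
        if not (0 <= pool < npl):
            raise IndexError(f"pool index {pool} out of range 0..{npl - 1}")
        if not (0 <= layer < self.n_layers):
            raise IndexError(f"layer index {layer} out of range 0..{self.n_layers - 1}")
        return layer * npl + pool

    def pool_slice(self, pool: int) -> slice:
        """Strided slice selecting ``pool`` across all layers."""
        return slice(pool, self.state_dim, self.n_pools_per_layer)
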