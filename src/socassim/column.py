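"""Steady-state multi-pool vertical soil carbon column model.

Carbon dynamics of the 70-pool column (7 pools x 10 layers by default)
follow the matrix balance

    dX/dt = B u + A xi K X - V X

where ``B`` (m^-1) partitions the column carbon input ``u``
(g C m^-2 day^-1) among litter pools and depth, ``A`` holds the
transfer fractions among pools within a layer (with -1 on the
diagonal, so ``A xi K`` is a net loss operator), ``xi`` is the product
of temperature, moisture and depth scalars on decomposition, ``K`` the
base decomposition rates (day^-1), and ``V`` (day^-1) the diffusive
vertical mixing (bioturbation) between adjacent layers. At steady
state the pool vector is the solution of the linear system

    (-A xi K + V) X = B u.

Carbon input, temperature, moisture and mixing are treated as
time-invariant (mean-annual) forcings, which is what makes the
analytical steady state usable in place of model spin-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InterfaceError, InvalidParameterError, NumericalFailureError, StepSizeError
from .grid import LITTER_POOLS, PoolLayout, SoilGrid, build_grid
from .params import ParameterSet

__all__ = [
    "Forcing",
    "ModelConstants",
    "MatrixSet",
    "environmental_scalars",
    "assemble_matrices",
    "steady_state",
    "transient_step",
    "soc_concentration_profile",
    "ColumnModel",
]


@dataclass(frozen=True)
class Forcing:
    """Time-invariant (mean annual) forcing of one soil column.

    npp : column carbon input, g C m^-2 day^-1 (NPP-derived).
    soil_temperature : per-layer temperature, degrees C.
    soil_water_potential : per-layer matric potential, MPa (<= 0).
    """

    npp: float
    soil_temperature: np.ndarray
    soil_water_potential: np.ndarray

    def __post_init__(self):
        t = np.atleast_1d(np.asarray(self.soil_temperature, dtype=float))
        psi = np.atleast_1d(np.asarray(self.soil_water_potential, dtype=float))
        if t.shape != psi.shape:
            raise InterfaceError("temperature and water potential layer counts differ")
        if self.npp < 0:
            raise InterfaceError(f"npp must be nonnegative, got {self.npp}")
        if np.any(psi > 0):
            raise InterfaceError("soil water potential must be <= 0 (MPa)")
        object.__setattr__(self, "soil_temperature", t)
        object.__setattr__(self, "soil_water_potential", psi)


@dataclass(frozen=True)
class ModelConstants:
    """Fixed (non-calibrated) constants of the column model.

    Defaults follow the CLM-family decomposition cascade; all are
    configuration, not code, and can be overridden wholesale.
    """

    q10: float = 1.5                  # temperature sensitivity of decomposition
    t_ref: float = 25.0               # reference temperature, degC
    psi_min: float = -10.0            # dry limit of the moisture scalar, MPa
    psi_max: float = -0.01            # wet (saturation) reference, MPa
    diffusivity: float = 1e-4 / 365.0  # bioturbation diffusivity, m^2 day^-1 (1 cm^2 yr^-1)
    z_input: float = 0.5              # e-folding depth of litter input, m
    # partition of column input among (CWD, metabolic, cellulose, lignin) litter
    litter_input_fractions: tuple = (0.25, 0.35, 0.25, 0.15)
    # fixed litter -> litter/SOC routing fractions
    cwd_to_cellulose: float = 0.76
    cwd_to_lignin: float = 0.24
    metabolic_to_fast: float = 0.45
    cellulose_to_fast: float = 0.50
    lignin_to_slow: float = 0.50


@dataclass(frozen=True)
class MatrixSet:
    """Dense matrices of the column balance at one site.

    A : (n, n) transfer matrix, -1 diagonal, nonnegative off-diagonals.
    K : (n, n) diagonal base decomposition rates, day^-1.
    Xi : (n, n) diagonal environmental scalar, each entry in [0, 1].
    V : (n, n) vertical mixing operator, day^-1.
    B : (n,) input partition, m^-1.
    u : scalar column input, g C m^-2 day^-1.
    """

    A: np.ndarray
    K: np.ndarray
    Xi: np.ndarray
    V: np.ndarray
    B: np.ndarray
    u: float
    grid: SoilGrid = field(repr=False, default=None)
    layout: PoolLayout = field(repr=False, default=None)

    def decay_operator(self) -> np.ndarray:
        """The positive-loss operator M = -A Xi K + V of the steady state.

        Cached: repeated tendency evaluations (explicit integration)
        reuse the assembled operator.
        """
        M = getattr(self, "_decay_cache", None)
        if M is None:
            M = -self.A @ (self.Xi @ self.K) + self.V
            object.__setattr__(self, "_decay_cache", M)
        return M

    def tendency(self, X: np.ndarray) -> np.ndarray:
        """dX/dt = B u + A Xi K X - V X."""
        return self.B * self.u - self.decay_operator() @ X


def environmental_scalars(
    forcing: Forcing,
    grid: SoilGrid,
    params: ParameterSet,
    constants: ModelConstants = ModelConstants(),
):
    """Per-layer temperature, moisture and depth scalars on decomposition.

    xi_T = Q10^((T - T_ref)/10), clipped to [0, 1];
    xi_W = log(psi_min/psi) / log(psi_min/psi_max), clipped to [0, 1];
    xi_D = exp(-z_node / efolding).

    Returns (xi_t, xi_w, xi_d), each shape (n_layers,).
    """
    if params.efolding <= 0:
        raise InvalidParameterError(f"efolding must be > 0, got {params.efolding}")
    t = forcing.soil_temperature
    if t.shape[0] != grid.n_layers:
        raise InterfaceError(
            f"forcing has {t.shape[0]} layers, grid has {grid.n_layers}"
        )
    xi_t = np.clip(constants.q10 ** ((t - constants.t_ref) / 10.0), 0.0, 1.0)
    psi = np.minimum(forcing.soil_water_potential, constants.psi_max)
    xi_w = np.log(constants.psi_min / psi) / np.log(constants.psi_min / constants.psi_max)
    xi_w = np.clip(xi_w, 0.0, 1.0)
    xi_d = np.exp(-grid.node_depth / params.efolding)
    return xi_t, xi_w, xi_d


def _mixing_matrix(grid: SoilGrid, layout: PoolLayout, diffusivity: float) -> np.ndarray:
    """Finite-volume diffusion operator on the nonuniform grid.

    Tridiagonal per pool across layers, zero-flux top and bottom
    boundaries; conserves thickness-weighted column carbon exactly:
    sum_i dz_i V[i, j] = 0 for every column j.
    """
    n = layout.state_dim
    V = np.zeros((n, n))
    if diffusivity == 0.0:
        return V
    dz = grid.thickness
    d_node = np.diff(grid.node_depth)  # node-to-node spacing
    npl = layout.n_pools_per_layer
    for L in range(grid.n_layers):
        o = L * npl
        if L < grid.n_layers - 1:
            g = diffusivity / d_node[L]
            for p in range(npl):
                V[o + p, o + p] += g / dz[L]
                V[o + p, o + npl + p] -= g / dz[L]
                V[o + npl + p, o + npl + p] += g / dz[L + 1]
                V[o + npl + p, o + p] -= g / dz[L + 1]
    return V


def _transfer_matrix(params: ParameterSet, layout: PoolLayout, constants: ModelConstants) -> np.ndarray:
    """Within-layer transfer matrix A (block diagonal, -1 diagonal)."""
    n = layout.state_dim
    A = -np.eye(n)
    npl = layout.n_pools_per_layer
    for L in range(layout.n_layers):
        o = L * npl
        A[o + 2, o + 0] = constants.cwd_to_cellulose
        A[o + 3, o + 0] = constants.cwd_to_lignin
        A[o + 4, o + 1] = constants.metabolic_to_fast
        A[o + 4, o + 2] = constants.cellulose_to_fast
        A[o + 5, o + 3] = constants.lignin_to_slow
        A[o + 5, o + 4] = params.fs1s2
        A[o + 6, o + 4] = params.fs1s3
        A[o + 4, o + 5] = params.fs2s1
        A[o + 6, o + 5] = params.fs2s3
        A[o + 4, o + 6] = params.fs3s1
    return A


def _k_per_pool(params: ParameterSet) -> np.ndarray:
    """Base decomposition rate (day^-1) for the 7 pools of one layer."""
    taus = np.array(
        [
            params.tau4cwd,
            params.tau4l1,
            params.tau4l2l3,
            params.tau4l2l3,
            params.tau4s1,
            params.tau4s2,
            params.tau4s3,
        ]
    )
    return 1.0 / (365.0 * taus)


def _input_vector(grid: SoilGrid, layout: PoolLayout, constants: ModelConstants) -> np.ndarray:
    """Input partition B (m^-1): litter split, exponential depth profile,
    normalized so sum_i B_i dz_i = 1."""
    beta = np.exp(-grid.node_depth / constants.z_input)
    beta /= np.sum(beta * grid.thickness)
    B = np.zeros(layout.state_dim)
    npl = layout.n_pools_per_layer
    for L in range(grid.n_layers):
        o = L * npl
        for p, frac in zip(LITTER_POOLS, constants.litter_input_fractions):
            B[o + p] = frac * beta[L]
    return B


def assemble_matrices(
    params: ParameterSet,
    forcing: Forcing,
    grid: SoilGrid | None = None,
    layout: PoolLayout | None = None,
    constants: ModelConstants = ModelConstants(),
    bounds=None,
) -> MatrixSet:
    """Assemble the dense matrices of the column balance for one site."""
    grid = grid or build_grid()
    layout = layout or PoolLayout(n_layers=grid.n_layers)
    params.validate(bounds)
    xi_t, xi_w, xi_d = environmental_scalars(forcing, grid, params, constants)
    xi_layer = xi_t * xi_w * xi_d
    k_pool = _k_per_pool(params)
    npl = layout.n_pools_per_layer
    K = np.diag(np.tile(k_pool, grid.n_layers))
    Xi = np.diag(np.repeat(xi_layer, npl))
    A = _transfer_matrix(params, layout, constants)
    V = _mixing_matrix(grid, layout, constants.diffusivity)
    B = _input_vector(grid, layout, constants)
    return MatrixSet(A=A, K=K, Xi=Xi, V=V, B=B, u=float(forcing.npp), grid=grid, layout=layout)


def steady_state(ms: MatrixSet) -> np.ndarray:
    """Analytical steady-state pool vector.

    Solves (-A Xi K + V) X = B u by a dense linear solve and verifies
    the balance residual to 1e-8 relative to the input term.
    """
    M = ms.decay_operator()
    rhs = ms.B * ms.u
    try:
        X = np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError as exc:
        raise NumericalFailureError(
            f"steady-state system is singular: {exc}",
            condition_number=np.inf,
        ) from exc
    scale = np.max(np.abs(rhs))
    resid = np.max(np.abs(rhs - M @ X))
    if scale > 0 and resid > 1e-8 * scale:
        cond = np.linalg.cond(M)
        raise NumericalFailureError(
            f"steady-state residual {resid:.3e} exceeds 1e-8 * {scale:.3e}",
            condition_number=cond,
        )
    return X


def transient_step(ms: MatrixSet, X: np.ndarray, dt: float) -> np.ndarray:
    """One explicit Euler step of the column balance (oracle utility)."""
    X_new = X + dt * ms.tendency(X)
    floor = -1e-9 * max(1.0, float(np.max(np.abs(X), initial=0.0)))
    if np.any(X_new < floor):
        raise StepSizeError(
            f"explicit step dt={dt} produced negative pools; reduce dt"
        )
    return X_new


def soc_concentration_profile(X: np.ndarray, layout: PoolLayout) -> np.ndarray:
    """Per-layer SOC concentration, kg C m^-3.

    Sums the fast, slow and passive SOC pools (litter excluded) and
    converts g -> kg.
    """
    X = np.asarray(X, dtype=float)
    if X.shape != (layout.state_dim,):
        raise InterfaceError(f"expected state of length {layout.state_dim}")
    soc = X[layout.pool_slice(4)] + X[layout.pool_slice(5)] + X[layout.pool_slice(6)]
    return soc / 1000.0


class ColumnModel:
    """Fast repeated steady-state evaluation at a fixed site.

    Caches everything that does not depend on the calibrated
    parameters (mixing operator, input partition, temperature and
    moisture scalars, transfer template) so a single parameter
    evaluation is one small dense solve. This is the hot path of the
    MCMC likelihood.
    """

    def __init__(
        self,
        forcing: Forcing,
        grid: SoilGrid | None = None,
        layout: PoolLayout | None = None,
        constants: ModelConstants = ModelConstants(),
    ):
        self.grid = grid or build_grid()
        self.layout = layout or PoolLayout(n_layers=self.grid.n_layers)
        self.constants = constants
        self.forcing = forcing
        t = forcing.soil_temperature
        if t.shape[0] != self.grid.n_layers:
            raise InterfaceError(
                f"forcing has {t.shape[0]} layers, grid has {self.grid.n_layers}"
            )
        self._xi_tw = np.clip(
            constants.q10 ** ((t - constants.t_ref) / 10.0), 0.0, 1.0
        ) * np.clip(
            np.log(constants.psi_min / np.minimum(forcing.soil_water_potential, constants.psi_max))
            / np.log(constants.psi_min / constants.psi_max),
            0.0,
            1.0,
        )
        self._V = _mixing_matrix(self.grid, self.layout, constants.diffusivity)
        self._B_u = _input_vector(self.grid, self.layout, constants) * float(forcing.npp)
        # transfer template with placeholder fs entries; filled per call
        self._A = _transfer_matrix(ParameterSet(), self.layout, constants)
        npl = self.layout.n_pools_per_layer
        offs = np.arange(self.layout.n_layers) * npl
        self._fs_rows = np.concatenate([offs + r for r in (5, 6, 4, 6, 4)])
        self._fs_cols = np.concatenate([offs + c for c in (4, 4, 5, 5, 6)])
        self._npl = npl

    def steady_state(self, params: ParameterSet) -> np.ndarray:
        """Steady-state pool vector (g C m^-3) for one parameter set."""
        n_layers = self.grid.n_layers
        xi = self._xi_tw * np.exp(-self.grid.node_depth / params.efolding)
        xik = np.repeat(xi, self._npl) * np.tile(_k_per_pool(params), n_layers)
        A = self._A
        fs = np.repeat(
            np.array([params.fs1s2, params.fs1s3, params.fs2s1, params.fs2s3, params.fs3s1]),
            n_layers,
        )
        A[self._fs_rows, self._fs_cols] = fs
        M = -A * xik[None, :] + self._V
        try:
            return np.linalg.solve(M, self._B_u)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - pathological
            raise NumericalFailureError(str(exc)) from exc

    def soc_profile(self, params: ParameterSet) -> np.ndarray:
        """Per-layer SOC concentration, kg C m^-3."""
        return soc_concentration_profile(self.steady_state(params), self.layout)

    def soc_at_depths(self, params: ParameterSet, depths: np.ndarray) -> np.ndarray:
        """SOC concentration interpolated to arbitrary depths (m).

        Linear interpolation between node depths; constant
        extrapolation above the first and below the last node.
        """
        conc = self.soc_profile(params)
        return np.interp(np.asarray(depths, dtype=float), self.grid.node_depth, conc)
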