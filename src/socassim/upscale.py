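"""Parameter upscaling: one-batch, random-sampling and NN emulation.

Three routes turn calibration results into a continental
parameterization:

* **one-batch** — the posterior samples of the single all-profiles
  inversion are used everywhere (spatially constant parameters).
* **random-sampling** — per-site posterior modes (MLEs of a
  generalized-extreme-value fit to each parameter's samples) are
  assembled across sites into continental per-parameter pools, from
  which parameter draws are taken (spatially constant distribution).
* **neural networking** — a feed-forward network (four hidden layers
  of 256/512/512/256 ReLU units) maps 60 environmental covariates to
  the site posterior means, and then predicts spatially heterogeneous
  parameters anywhere covariates exist.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.neural_network import MLPRegressor

from .column import ColumnModel, Forcing, ModelConstants
from .errors import InsufficientDataError, InterfaceError, NumericalFailureError
from .grid import SoilGrid
from .params import N_PARAMS, ParameterBounds, ParameterSet

logger = logging.getLogger(__name__)

__all__ = [
    "PosteriorSummary",
    "summarize_posterior",
    "gev_mode",
    "ContinentalParameterDistribution",
    "predict_with_sampling",
    "EmulatorSpec",
    "ParameterEmulator",
    "predict_parameters",
]


@dataclass(frozen=True)
class PosteriorSummary:
    """Per-parameter summary of a posterior sample."""

    mean: np.ndarray
    variance: np.ndarray
    mle: np.ndarray          # mode of the fitted GEV per parameter
    quantiles: dict          # {q: ndarray}


def gev_mode(c: float, loc: float, scale: float) -> float:
    """Mode of a generalized-extreme-value density (scipy shape c)."""
    if abs(c) < 1e-9:
        return loc
    if 1.0 - c <= 0:  # heavy upper-bounded tail; no interior mode formula
        return np.nan
    return loc + scale * (1.0 - (1.0 - c) ** c) / c


def _sample_mode(x: np.ndarray, max_fit_samples: int = 400) -> float:
    """GEV-fit mode of a 1-D sample, KDE-mode fallback.

    The ML fit cost grows with the sample, so very long chains are
    thinned deterministically before fitting; the mode estimate is
    insensitive to this.
    """
    if x.size > max_fit_samples:
        x = x[:: int(np.ceil(x.size / max_fit_samples))]
    try:
        c, loc, scale = stats.genextreme.fit(x)
        m = gev_mode(c, loc, scale)
        if np.isfinite(m):
            return float(m)
        raise ValueError("no interior GEV mode")
    except Exception:
        logger.warning("GEV fit failed; falling back to kernel-density mode")
        kde = stats.gaussian_kde(x)
        grid = np.linspace(x.min(), x.max(), 512)
        return float(grid[np.argmax(kde(grid))])


def summarize_posterior(
    samples: np.ndarray,
    bounds: ParameterBounds | None = None,
    quantiles=(0.05, 0.5, 0.95),
    min_samples: int = 100,
) -> PosteriorSummary:
    """Mean, variance, quantiles, and GEV-mode MLE of posterior samples.

    ``samples`` is (n, d) (or 1-D for a single parameter) of
    post-burn-in draws; at least ``min_samples`` are required.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim == 1:
        samples = samples[:, None]
    n, d = samples.shape
    if n < min_samples:
        raise InsufficientDataError(f"need >= {min_samples} posterior samples, got {n}")
    mean = samples.mean(axis=0)
    var = samples.var(axis=0, ddof=1)
    qs = {q: np.quantile(samples, q, axis=0) for q in quantiles}
    mle = np.empty(d)
    for j in range(d):
        x = samples[:, j]
        if np.ptp(x) == 0:  # degenerate: every draw identical
            mle[j] = x[0]
            continue
        mle[j] = _sample_mode(x)
    if bounds is not None:
        mle = np.clip(mle, bounds.lower, bounds.upper)
    return PosteriorSummary(mean=mean, variance=var, mle=mle, quantiles=qs)


@dataclass
class ContinentalParameterDistribution:
    """Continental per-parameter sample pools.

    ``pool`` is (n, d): assembled site MLEs (random-sampling route) or
    one-batch posterior samples. Draws resample each parameter's pool
    independently, matching the per-parameter continental PDFs, and
    are clipped to bounds.
    """

    pool: np.ndarray
    bounds: ParameterBounds

    def __post_init__(self):
        self.pool = np.asarray(self.pool, dtype=float)
        if self.pool.ndim != 2:
            raise InterfaceError("pool must be 2-D (samples, parameters)")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        m, d = self.pool.shape
        idx = rng.integers(0, m, size=(n, d))
        out = self.pool[idx, np.arange(d)]
        return np.clip(out, self.bounds.lower, self.bounds.upper)


def predict_with_sampling(
    dist: ContinentalParameterDistribution,
    forcing: Forcing,
    n_draws: int = 1000,
    rng: np.random.Generator | None = None,
    grid: SoilGrid | None = None,
    constants: ModelConstants = ModelConstants(),
    thetas: np.ndarray | None = None,
    max_failed_fraction: float = 0.01,
):
    """Ensemble steady-state prediction at one site.

    Draws ``n_draws`` parameter sets (1,000 for continental maps, 500
    for site-level predictions by convention), runs the steady state
    for each, and returns (mean, q5, q95) per layer in kg C m^-3.
    Pre-drawn ``thetas`` can be supplied so the same draws are reused
    across sites, as the mapping workflow requires.
    """
    if thetas is None:
        rng = rng if rng is not None else np.random.default_rng()
        thetas = dist.draw(n_draws, rng)
    model = ColumnModel(forcing, grid=grid, constants=constants)
    profiles = []
    failed = 0
    for th in thetas:
        try:
            profiles.append(model.soc_profile(ParameterSet.from_array(th)))
        except NumericalFailureError:
            failed += 1
    if failed > max_failed_fraction * len(thetas):
        raise NumericalFailureError(
            f"{failed}/{len(thetas)} ensemble draws failed the forward solve"
        )
    arr = np.asarray(profiles)
    return arr.mean(axis=0), np.quantile(arr, 0.05, axis=0), np.quantile(arr, 0.95, axis=0)


@dataclass(frozen=True)
class EmulatorSpec:
    """Architecture and training protocol of the parameter emulator.

    The regularization field records the intended stochastic
    regularization strength; the scikit-learn backend applies it as an
    L2 penalty (``alpha``).
    """

    hidden: tuple = (256, 512, 512, 256)
    dropout: float = 0.2
    activation: str = "relu"
    epochs: int = 400
    batch_size: int = 64
    train_fraction: float = 0.8
    validation_split: float = 0.2
    alpha: float = 1e-2  # L2 weight penalty standing in for stochastic dropout
    learning_rate_init: float = 1e-3
    seed: int = 0


class ParameterEmulator:
    """Covariates -> calibrated-parameter regressor (fit/predict).

    Inputs are the 60 environmental covariates (z-scored with
    training-set statistics; declared categorical columns are one-hot
    encoded). Targets are site posterior means, range-normalized to
    [0, 1]; predictions are clipped to [0, 1] and de-normalized, so
    they always respect the parameter bounds.
    """

    def __init__(
        self,
        bounds: ParameterBounds,
        spec: EmulatorSpec = EmulatorSpec(),
        categorical_cols=(),
    ):
        self.bounds = bounds
        self.spec = spec
        self.categorical_cols = tuple(categorical_cols)
        self.net_ = None

    # -- preprocessing -------------------------------------------------
    def _encode(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.n_features_in_ is not None and X.shape[1] != self.n_features_in_:
            raise InterfaceError(
                f"expected {self.n_features_in_} covariates, got {X.shape[1]}"
            )
        num_cols = [j for j in range(X.shape[1]) if j not in self.categorical_cols]
        parts = [X[:, num_cols]]
        for j in self.categorical_cols:
            cats = self._categories[j]
            onehot = (X[:, j][:, None] == cats[None, :]).astype(float)
            parts.append(onehot)
        return np.hstack(parts)

    def _standardize(self, Xe: np.ndarray) -> np.ndarray:
        return (Xe - self._x_mean) / self._x_std

    # -- fitting -------------------------------------------------------
    def fit(self, covariates, targets, min_train_sites: int = 50):
        """Train on site covariates and native-unit posterior means.

        Splits 80/20 into train+validation and held-out test; within
        the training portion a further ``validation_split`` fraction is
        held out to track validation loss per epoch. Stores the test
        indices and the loss history.
        """
        X = np.asarray(covariates, dtype=float)
        y_nat = np.asarray(targets, dtype=float)
        if X.shape[0] != y_nat.shape[0]:
            raise InterfaceError("covariates and targets must align by site")
        n = X.shape[0]
        self.n_features_in_ = X.shape[1]
        self._categories = {
            j: np.unique(X[:, j]) for j in self.categorical_cols
        }
        rng = np.random.default_rng(self.spec.seed)
        perm = rng.permutation(n)
        n_train = int(round(self.spec.train_fraction * n))
        if n_train < min_train_sites:
            raise InsufficientDataError(
                f"need >= {min_train_sites} training sites, got {n_train}"
            )
        self.train_indices_ = perm[:n_train]
        self.test_indices_ = perm[n_train:]
        n_val = int(round(self.spec.validation_split * n_train))
        val_idx = self.train_indices_[:n_val]
        fit_idx = self.train_indices_[n_val:]

        Xe = self._encode(X)
        self._x_mean = Xe[fit_idx].mean(axis=0)
        self._x_std = Xe[fit_idx].std(axis=0)
        self._x_std[self._x_std == 0] = 1.0
        Xs = self._standardize(Xe)
        y = self.bounds.normalize(y_nat)

        spec = self.spec
        self.net_ = MLPRegressor(
            hidden_layer_sizes=spec.hidden,
            activation=spec.activation,
            solver="adam",
            alpha=spec.alpha,
            batch_size="auto",  # we batch manually in the epoch loop
            learning_rate_init=spec.learning_rate_init,
            max_iter=1,
            shuffle=False,
            random_state=spec.seed,
            warm_start=False,
        )
        # manual epoch loop (fixed epoch count, no early stopping) so the
        # train/validation loss history can be recorded per epoch
        Xf, yf = Xs[fit_idx], y[fit_idx]
        order = np.arange(Xf.shape[0])
        bs = min(spec.batch_size, Xf.shape[0])
        self.loss_history_ = {"train": [], "validation": []}
        for _ in range(spec.epochs):
            rng.shuffle(order)
            for start in range(0, order.size, bs):
                sel = order[start : start + bs]
                self.net_.partial_fit(Xf[sel], yf[sel])
            self.loss_history_["train"].append(
                float(np.mean((self.net_.predict(Xf) - yf) ** 2))
            )
            if val_idx.size:
                self.loss_history_["validation"].append(
                    float(np.mean((self.net_.predict(Xs[val_idx]) - y[val_idx]) ** 2))
                )
        if self.test_indices_.size:
            yp = self._predict_normalized(Xs[self.test_indices_])
            self.test_loss_ = float(np.mean((yp - y[self.test_indices_]) ** 2))
        else:
            self.test_loss_ = np.nan
        return self

    def _predict_normalized(self, Xs: np.ndarray) -> np.ndarray:
        out = self.net_.predict(Xs)
        if out.ndim == 1:
            out = out[:, None]
        return np.clip(out, 0.0, 1.0)

    def predict(self, covariates) -> np.ndarray:
        """Predict native-unit parameters; NaN covariate rows (masked
        grid cells) yield NaN parameter rows."""
        if self.net_ is None:
            raise InterfaceError("emulator is not fitted")
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        ok = np.all(np.isfinite(X), axis=1)
        out = np.full((X.shape[0], N_PARAMS), np.nan)
        if np.any(ok):
            Xs = self._standardize(self._encode(X[ok]))
            out[ok] = self.bounds.denormalize(self._predict_normalized(Xs))
        return out


def predict_parameters(emulator: ParameterEmulator, covariates) -> np.ndarray:
    """Per-site or per-cell parameter prediction (thin wrapper)."""
    return emulator.predict(covariates)
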