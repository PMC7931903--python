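"""Adaptive Metropolis sampler and convergence diagnostics.

The sampler runs in two phases. A *test* run proposes uniformly,
theta_new = theta + r (theta_max - theta_min)/D with r ~ U[-0.5, 0.5]
per coordinate (D = 5 makes the maximum step 1/10 of the prior range).
The accepted test samples seed the proposal covariance C0 of the
*formal* run, a Gaussian random walk whose covariance switches at
iteration t0 to s_d cov(chain history) + s_d eps I with the classic
scaling s_d = 2.38^2/d that targets ~0.234 acceptance in high
dimension. Acceptance uses the misfit directly:
p = min(1, exp(-(phi_new - phi_old))).

All sampling happens on the range-normalized [0, 1]^d scale; the
user-supplied misfit callable receives native-unit parameter vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import NumericalFailureError

logger = logging.getLogger(__name__)

__all__ = [
    "MCMCConfig",
    "ChainRecord",
    "MCMCResult",
    "accept_probability",
    "propose_uniform",
    "propose_adaptive",
    "AdaptiveMetropolis",
    "run_chains",
    "gelman_rubin",
]

STATUS_ACCEPTED = "accepted"
STATUS_REJECTED_RATE = "rejected_acceptance_rate"
STATUS_INVALID_PROFILE = "invalid_profile"


@dataclass(frozen=True)
class MCMCConfig:
    """Tuning knobs of the two-phase adaptive Metropolis run."""

    D: float = 5.0            # uniform-proposal step divisor
    n_test: int = 20_000      # test-run iterations
    n_formal: int = 30_000    # formal-run iterations
    n_chains: int = 3         # independent parallel chains
    t0: int = 1_000           # adaptation start index in the formal run
    epsilon: float = 1e-8     # covariance jitter (normalized scale)
    accept_min: float = 0.15
    accept_max: float = 0.50
    adapt: bool = True        # adapt covariance after t0 (False: keep C0)
    adapt_scale: bool = True  # Robbins-Monro global step-size stabilization
    scale_target: float = 0.234  # acceptance rate the scale stabilizes toward
    reflect_bounds: bool = True  # reflect out-of-bounds proposals (else reject)
    n_retries: int = 1        # seeded retries when all chains fail the rate gate
    record_states: bool = False  # also keep the full chain (with repeats)

    def __post_init__(self):
        if not (0.0 < self.accept_min < self.accept_max < 1.0):
            raise ValueError("need 0 < accept_min < accept_max < 1")
        if self.n_formal <= 0:
            raise ValueError("n_formal must be positive")

    def with_counts(self, n_test: int, n_formal: int) -> "MCMCConfig":
        return replace(self, n_test=n_test, n_formal=n_formal)


def sd_scale(d: int) -> float:
    """Proposal covariance scaling s_d = 2.38^2/d."""
    return 2.38**2 / d


def accept_probability(phi_new: float, phi_old: float) -> float:
    """Metropolis acceptance probability min(1, exp(-(phi_new - phi_old)))."""
    delta = phi_new - phi_old
    return 1.0 if delta <= 0 else float(np.exp(-delta))


def _reflect_unit(u: np.ndarray) -> np.ndarray:
    """Reflect coordinates into [0, 1] (handles multiple bounces)."""
    u = np.mod(u, 2.0)
    return np.where(u > 1.0, 2.0 - u, u)


def propose_uniform(theta_prev, lower, upper, D: float, rng, reflect: bool = True):
    """Uniform random-walk proposal, native units.

    theta_new = theta_prev + r (upper - lower)/D, r ~ U[-0.5, 0.5].
    Out-of-bounds coordinates are reflected back into the range (or the
    raw proposal is returned when ``reflect`` is False, for use with a
    reject-at-bounds policy).
    """
    theta_prev = np.asarray(theta_prev, dtype=float)
    rng_step = rng.uniform(-0.5, 0.5, size=theta_prev.shape)
    theta = theta_prev + rng_step * (np.asarray(upper) - np.asarray(lower)) / D
    if reflect:
        lo = np.asarray(lower, dtype=float)
        rangev = np.asarray(upper, dtype=float) - lo
        theta = lo + _reflect_unit((theta - lo) / rangev) * rangev
    return theta


def propose_adaptive(history, theta_prev, epsilon: float, rng, C0=None, t0: int = 0):
    """Gaussian proposal with history-adapted covariance, native units.

    Before ``t0`` samples of history the covariance is exactly ``C0``;
    afterwards it is s_d cov(history) + s_d eps I with s_d = 2.38^2/d.
    Falls back to C0 when the adapted covariance is not positive
    definite.
    """
    theta_prev = np.asarray(theta_prev, dtype=float)
    d = theta_prev.size
    history = np.asarray(history, dtype=float)
    if history.shape[0] >= max(t0, 2):
        C = sd_scale(d) * np.cov(history, rowvar=False).reshape(d, d) + sd_scale(d) * epsilon * np.eye(d)
    else:
        C = np.asarray(C0, dtype=float)
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        logger.warning("adapted covariance not positive definite; falling back to C0")
        L = np.linalg.cholesky(np.asarray(C0, dtype=float))
    return theta_prev + L @ rng.standard_normal(d)


@dataclass(eq=False)
class ChainRecord:
    """Accepted samples and bookkeeping of one formal-phase chain."""

    accepted: np.ndarray          # (n_accepted, d), native units
    misfits: np.ndarray           # misfit at each accepted sample
    acceptance_rate: float        # fraction of formal proposals accepted
    n_iterations: int
    rate_ok: bool = True
    states: np.ndarray | None = None  # full formal chain incl. repeats (optional)

    def post_burn_in(self) -> np.ndarray:
        """Second half of the accepted formal samples."""
        n = self.accepted.shape[0]
        return self.accepted[n - n // 2 :]


@dataclass(eq=False)
class MCMCResult:
    """Pooled outcome of the parallel chains at one site (or batch)."""

    chains: list                       # list[ChainRecord]
    status: str
    gr: np.ndarray | None = None       # per-parameter Gelman-Rubin statistic
    posterior_samples: np.ndarray | None = None  # post-burn-in, selected chain
    selected_chain: int | None = None
    site_id: object = None

    @property
    def acceptance_rates(self):
        return [c.acceptance_rate for c in self.chains]

    def posterior_mean(self) -> np.ndarray:
        if self.posterior_samples is None or len(self.posterior_samples) == 0:
            raise ValueError("no posterior samples available")
        return self.posterior_samples.mean(axis=0)


class _RunningCov:
    """Welford-style running mean/covariance of the chain states."""

    def __init__(self, d: int):
        self.n = 0
        self.mean = np.zeros(d)
        self._m2 = np.zeros((d, d))

    def update(self, x: np.ndarray):
        self.n += 1
        delta = x - self.mean
        self.mean += delta / self.n
        self._m2 += np.outer(delta, x - self.mean)

    def cov(self) -> np.ndarray:
        return self._m2 / (self.n - 1)


class AdaptiveMetropolis:
    """Two-phase adaptive Metropolis sampler on a bounded parameter box.

    Parameters
    ----------
    misfit : callable
        phi(theta) with theta in native units; lower is better. The
        acceptance rule is min(1, exp(-(phi_new - phi_old))).
    lower, upper : array_like, shape (d,)
        Parameter bounds. Sampling happens on the normalized scale.
    config : MCMCConfig
    """

    def __init__(self, misfit, lower, upper, config: MCMCConfig = MCMCConfig()):
        self.lower = np.asarray(lower, dtype=float)
        self.upper = np.asarray(upper, dtype=float)
        if self.lower.shape != self.upper.shape or np.any(self.upper <= self.lower):
            raise ValueError("invalid bounds")
        self.d = self.lower.size
        self.range = self.upper - self.lower
        self.config = config
        self._misfit_native = misfit

    def _phi(self, u: np.ndarray) -> float:
        return float(self._misfit_native(self.lower + u * self.range))

    def run_chain(self, rng: np.random.Generator, u0=None, C0=None) -> ChainRecord:
        """Run test + formal phases; returns the formal-phase record."""
        cfg = self.config
        u = rng.uniform(0.2, 0.8, self.d) if u0 is None else np.asarray(u0, dtype=float)
        phi = self._phi(u)

        # ---- test phase: uniform proposals, accepted samples seed C0
        test_accepted = []
        for _ in range(cfg.n_test):
            u_new = u + rng.uniform(-0.5, 0.5, self.d) / cfg.D
            if cfg.reflect_bounds:
                u_new = _reflect_unit(u_new)
            elif np.any(u_new < 0) or np.any(u_new > 1):
                continue
            phi_new = self._phi(u_new)
            if np.isnan(phi_new):
                logger.warning("NaN misfit at proposal; rejecting")
                continue
            if accept_probability(phi_new, phi) >= rng.uniform():
                u, phi = u_new, phi_new
                test_accepted.append(u.copy())

        sd = sd_scale(self.d)
        if C0 is None:
            # seed the formal covariance from the settled part of the test
            # run (second half of its accepted samples), so the approach
            # trajectory from the random start does not inflate C0
            settled = np.asarray(test_accepted[len(test_accepted) // 2 :])
            if settled.shape[0] >= max(self.d + 1, 10):
                C0 = sd * np.cov(settled, rowvar=False).reshape(
                    self.d, self.d
                ) + sd * cfg.epsilon * np.eye(self.d)
            else:
                # too few accepted test samples: fall back to the uniform
                # step's variance (range/D step has variance 1/(12 D^2))
                C0 = (1.0 / (12.0 * cfg.D**2)) * np.eye(self.d)
        try:
            L0 = np.linalg.cholesky(C0)
        except np.linalg.LinAlgError:
            raise NumericalFailureError("initial proposal covariance not positive definite")

        # ---- formal phase: Gaussian proposals, adapting after t0.
        # The running covariance collects chain states only after the
        # initial period [0, t0), so the approach drift under C0 cannot
        # permanently inflate the adapted proposal.
        accepted = []
        misfits = []
        states = [] if cfg.record_states else None
        n_accepted = 0
        running = _RunningCov(self.d)
        L = L0
        eps_term = sd * cfg.epsilon * np.eye(self.d)
        n_min = max(cfg.t0, self.d + 2)
        # Robbins-Monro stabilization of a global proposal scale toward the
        # target acceptance rate: rescues runs whose C0 badly over- or
        # under-estimates the posterior scale (common when the posterior is
        # much sharper than the prior explored by the test phase)
        log_lam = 0.0
        stabilize = cfg.adapt and cfg.adapt_scale  # never rescale a fixed proposal
        for t in range(cfg.n_formal):
            if cfg.adapt and running.n >= n_min:
                if running.n == n_min or t % 50 == 0:
                    # refresh the factorization periodically; the running
                    # covariance itself is updated every iteration
                    try:
                        L = np.linalg.cholesky(sd * running.cov() + eps_term)
                    except np.linalg.LinAlgError:
                        logger.warning("adapted covariance not PD at t=%d; using C0", t)
                        L = L0
            lam = np.exp(0.5 * log_lam) if stabilize else 1.0
            u_new = u + lam * (L @ rng.standard_normal(self.d))
            if cfg.reflect_bounds:
                u_new = _reflect_unit(u_new)
            out_of_bounds = False
            if not cfg.reflect_bounds and (np.any(u_new < 0) or np.any(u_new > 1)):
                out_of_bounds = True
            p_acc = 0.0
            if not out_of_bounds:
                phi_new = self._phi(u_new)
                if np.isnan(phi_new):
                    logger.warning("NaN misfit at proposal; rejecting")
                else:
                    p_acc = accept_probability(phi_new, phi)
                    if p_acc >= rng.uniform():
                        u, phi = u_new, phi_new
                        n_accepted += 1
                        accepted.append(self.lower + u * self.range)
                        misfits.append(phi)
            if stabilize:
                log_lam += (t + 1) ** -0.6 * (p_acc - cfg.scale_target)
            if t >= cfg.t0:
                running.update(u)
            if states is not None:
                states.append(self.lower + u * self.range)
        rate = n_accepted / cfg.n_formal
        return ChainRecord(
            accepted=np.asarray(accepted).reshape(-1, self.d),
            misfits=np.asarray(misfits),
            acceptance_rate=rate,
            n_iterations=cfg.n_formal,
            rate_ok=cfg.accept_min <= rate <= cfg.accept_max,
            states=np.asarray(states) if states is not None else None,
        )


def run_chains(misfit, lower, upper, config: MCMCConfig, rng: np.random.Generator) -> MCMCResult:
    """Run ``config.n_chains`` independent chains and pool the result.

    Chains whose formal-phase acceptance rate falls outside
    (accept_min, accept_max) are flagged; when no chain passes the
    gate the pooled result carries ``rejected_acceptance_rate``.
    Posterior samples come from one uniformly-selected passing chain
    (seeded); the Gelman-Rubin statistic is computed across passing
    chains when at least two are available.
    """
    sampler = AdaptiveMetropolis(misfit, lower, upper, config)
    chains = [sampler.run_chain(rng) for _ in range(config.n_chains)]
    valid = [c for c in chains if c.rate_ok and c.accepted.shape[0] >= 2]
    if not valid:
        return MCMCResult(chains=chains, status=STATUS_REJECTED_RATE)
    post = [c.post_burn_in() for c in valid]
    gr = None
    if len(post) >= 2 and min(p.shape[0] for p in post) >= 2:
        gr = gelman_rubin(post)
    pick = int(rng.integers(len(valid)))
    selected = next(i for i, c in enumerate(chains) if c is valid[pick])
    return MCMCResult(
        chains=chains,
        status=STATUS_ACCEPTED,
        gr=gr,
        posterior_samples=post[pick],
        selected_chain=selected,
    )


def gelman_rubin(chains) -> np.ndarray:
    """Per-parameter Gelman-Rubin statistic of parallel chains.

    With K chains of common length N (longer chains are truncated to
    the shortest), between- and within-run variances are

        B_i = N/(K-1) sum_k (mean_ik - grand_i)^2
        W_i = 1/(K(N-1)) sum_k sum_n (c_ink - mean_ik)^2

    and GR_i = (W_i (N-1)/N + B_i/N) / W_i, which approaches 1 at
    convergence.
    """
    arrs = []
    for c in chains:
        a = np.asarray(c, dtype=float)
        arrs.append(a.reshape(-1, 1) if a.ndim == 1 else a)
    K = len(arrs)
    if K < 2:
        raise ValueError("need at least 2 chains")
    N = min(a.shape[0] for a in arrs)
    if N < 2:
        raise ValueError("need at least 2 samples per chain")
    stack = np.stack([a[-N:] for a in arrs])  # (K, N, d)
    chain_means = stack.mean(axis=1)          # (K, d)
    grand = chain_means.mean(axis=0)
    B = N / (K - 1) * np.sum((chain_means - grand) ** 2, axis=0)
    W = np.sum((stack - chain_means[:, None, :]) ** 2, axis=(0, 1)) / (K * (N - 1))
    if np.any(W == 0):
        raise NumericalFailureError("degenerate chains: zero within-run variance")
    return (W * (N - 1) / N + B / N) / W
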