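"""Calibratable parameters of the soil carbon column model.

Twelve parameters are exposed to calibration: six base turnover times
(years) — one per litter class group and SOC pool —, five inter-SOC
transfer fractions, and the e-folding depth (m) of the depth scalar on
decomposition. Each parameter carries a prior range; MCMC sampling and
emulator training operate on the range-normalized [0, 1] scale.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import numpy as np

__all__ = ["ParameterBounds", "ParameterSet", "PARAM_NAMES", "default_bounds", "default_params"]

PARAM_NAMES = (
    "tau4cwd",
    "tau4l1",
    "tau4l2l3",
    "tau4s1",
    "tau4s2",
    "tau4s3",
    "fs1s2",
    "fs1s3",
    "fs2s1",
    "fs2s3",
    "fs3s1",
    "efolding",
)

N_PARAMS = len(PARAM_NAMES)


@dataclass(frozen=True)
class ParameterBounds:
    """Per-parameter prior range [lower, upper] in native units."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        lo = np.asarray(self.lower, dtype=float)
        up = np.asarray(self.upper, dtype=float)
        if lo.shape != (N_PARAMS,) or up.shape != (N_PARAMS,):
            raise ValueError(f"bounds must have shape ({N_PARAMS},)")
        if not np.all(up > lo):
            raise ValueError("every upper bound must exceed its lower bound")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", up)

    @property
    def range(self) -> np.ndarray:
        return self.upper - self.lower

    def normalize(self, theta: np.ndarray) -> np.ndarray:
        return (np.asarray(theta, dtype=float) - self.lower) / self.range

    def denormalize(self, u: np.ndarray) -> np.ndarray:
        return self.lower + np.asarray(u, dtype=float) * self.range

    def contains(self, theta: np.ndarray) -> bool:
        theta = np.asarray(theta, dtype=float)
        return bool(np.all(theta >= self.lower) and np.all(theta <= self.upper))


def default_bounds() -> ParameterBounds:
    """Default prior ranges.

    Turnover times bracket the nominal CLM-family values by roughly a
    factor of 3-5 on each side; transfer-fraction ranges are chosen so
    that per-donor transfer sums stay below 1 (nonnegative respired
    fraction) for any in-bounds draw.
    """
    lower = np.array(
        [1.0, 0.02, 0.1, 0.05, 1.0, 50.0, 0.1, 0.001, 0.1, 0.001, 0.1, 0.05]
    )
    upper = np.array(
        [20.0, 0.2, 1.0, 1.0, 50.0, 1000.0, 0.8, 0.1, 0.8, 0.1, 0.8, 2.0]
    )
    return ParameterBounds(lower, upper)


@dataclass(frozen=True)
class ParameterSet:
    """One point in parameter space (native units).

    tau4* are base turnover times in years (decomposition rate
    k = 1/(365 tau) per day); fs* are the SOC-to-SOC transfer fractions
    fast->slow, fast->passive, slow->fast, slow->passive, passive->fast;
    efolding is the depth attenuation length (m) of decomposition.
    """

    tau4cwd: float = 4.1
    tau4l1: float = 0.066
    tau4l2l3: float = 0.25
    tau4s1: float = 0.17
    tau4s2: float = 6.1
    tau4s3: float = 270.0
    fs1s2: float = 0.30
    fs1s3: float = 0.01
    fs2s1: float = 0.42
    fs2s3: float = 0.03
    fs3s1: float = 0.45
    efolding: float = 0.5

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, theta: np.ndarray) -> "ParameterSet":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (N_PARAMS,):
            raise ValueError(f"expected shape ({N_PARAMS},), got {theta.shape}")
        return cls(**dict(zip(PARAM_NAMES, theta.tolist())))

    def validate(self, bounds: ParameterBounds | None = None) -> None:
        """Raise ValueError on out-of-bounds or inconsistent values."""
        theta = self.as_array()
        if bounds is not None and not bounds.contains(theta):
            bad = [
                n
                for n, v, lo, up in zip(PARAM_NAMES, theta, bounds.lower, bounds.upper)
                if not (lo <= v <= up)
            ]
            raise ValueError(f"parameters out of bounds: {bad}")
        fracs = {n: getattr(self, n) for n in PARAM_NAMES if n.startswith("fs")}
        for n, v in fracs.items():
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{n}={v} outside [0, 1)")
        if self.fs1s2 + self.fs1s3 > 1.0 or self.fs2s1 + self.fs2s3 > 1.0:
            raise ValueError("per-donor transfer fractions sum above 1")
        if self.efolding <= 0:
            raise ValueError(f"efolding must be positive, got {self.efolding}")
        for n in ("tau4cwd", "tau4l1", "tau4l2l3", "tau4s1", "tau4s2", "tau4s3"):
            if getattr(self, n) <= 0:
                raise ValueError(f"{n} must be positive")

    def replace(self, **kwargs) -> "ParameterSet":
        return replace(self, **kwargs)


def default_params() -> ParameterSet:
    """Nominal (uncalibrated) parameter values, CLM-family defaults."""
    return ParameterSet()


def _field_names():  # pragma: no cover - sanity hook
    return tuple(f.name for f in fields(ParameterSet))


assert _field_names() == PARAM_NAMES
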