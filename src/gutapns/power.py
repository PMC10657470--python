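"""Power of a one-sample Spearman correlation test.

The closed form applies the Fisher z approximation to the correlation
coefficient — the same approximation the classical power packages use
for Spearman, treating atanh(r) as normal with variance 1/(n-3):

    power = Phi(sqrt(n-3)·atanh(rho) - z_{1-a/2})
          + Phi(-sqrt(n-3)·atanh(rho) - z_{1-a/2})

A Monte Carlo mode is the ground truth for that approximation: it draws
bivariate-normal samples calibrated so the *population Spearman*
correlation equals ``rho`` (Pearson r = 2·sin(pi·rho/6)) and counts
rejections of the Spearman test at level alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["PowerSpec", "spearman_power", "minimum_n"]

_MIN_N = 4


@dataclass(frozen=True)
class PowerSpec:
    rho: float
    n: int
    alpha: float = 0.05
    method: str = "fisher_z"
    n_sims: int = 10_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if not -1.0 < self.rho < 1.0:
            raise ValueError(f"rho must be in (-1, 1), got {self.rho}")
        if self.n < _MIN_N:
            raise ValueError(f"n must be >= {_MIN_N}, got {self.n}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.method not in ("fisher_z", "simulation"):
            raise ValueError(f"unknown method {self.method!r}")


def _fisher_z_power(rho: float, n: int, alpha: float) -> float:
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    shift = math.sqrt(n - 3) * math.atanh(rho)
    return float(stats.norm.cdf(shift - z_crit) + stats.norm.cdf(-shift - z_crit))


def _simulated_power(spec: PowerSpec) -> float:
    rng = np.random.default_rng(spec.seed)
    # Pearson r giving population Spearman == rho under bivariate normality
    r = 2.0 * math.sin(math.pi * spec.rho / 6.0)
    cov = np.array([[1.0, r], [r, 1.0]])
    hits = 0
    for _ in range(spec.n_sims):
        xy = rng.multivariate_normal([0.0, 0.0], cov, size=spec.n)
        res = stats.spearmanr(xy[:, 0], xy[:, 1])
        if res.pvalue <= spec.alpha:
            hits += 1
    return hits / spec.n_sims


def spearman_power(spec: PowerSpec | None = None, **kwargs) -> float:
    """Power in [0, 1] for the Spearman test under ``spec``.

    Accepts either a :class:`PowerSpec` or its fields as keyword
    arguments, e.g. ``spearman_power(rho=0.5, n=51)``.
    """
    if spec is None:
        spec = PowerSpec(**kwargs)
    if spec.method == "fisher_z":
        return _fisher_z_power(spec.rho, spec.n, spec.alpha)
    return _simulated_power(spec)


def minimum_n(rho: float, alpha: float = 0.05, target_power: float = 0.8,
              n_max: int = 100_000) -> int:
    """Smallest n whose Fisher-z power reaches ``target_power``."""
    if not 0.0 < target_power < 1.0:
        raise ValueError("target_power must be in (0, 1)")
    if abs(rho) <= 0 or not -1.0 < rho < 1.0:
        raise ValueError("rho must be nonzero and in (-1, 1)")
    if _fisher_z_power(rho, n_max, alpha) < target_power:
        raise ValueError(f"target power {target_power} unreachable below n={n_max}")
    lo, hi = _MIN_N, n_max  # power is nondecreasing in n
    if _fisher_z_power(rho, lo, alpha) >= target_power:
        return lo
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if _fisher_z_power(rho, mid, alpha) >= target_power:
            hi = mid
        else:
            lo = mid
    return hi
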