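"""Discretized cell-cycle phase-duration laws and age-dependent exit probabilities.

A cell-cycle phase (G1, S or G2M) has a stochastic duration described by a
right-skewed continuous law, parameterized by its mean and coefficient of
variation.  The population simulation works on a discrete age grid with step
``delta_h`` hours: a cell that has spent ``k`` steps in a phase sits in age
compartment ``k`` (1-based), and completes the phase at age ``k`` with an
age-dependent exit probability ``beta(k)`` derived from the duration law.

The discretized mass vector ``mass[k-1]`` is the probability that a cell's
phase duration rounds to ``k`` grid steps, so the discretized mean matches
the continuous mean (durations shorter than half a step are folded into the
first compartment; at least one step is always spent in a phase).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "AgeGrid",
    "PhaseDurationSpec",
    "DurationDistribution",
    "build_duration_distribution",
    "exit_probabilities",
    "convolve",
    "mass_mean_h",
    "mass_cv",
]

#: cumulative mass that the truncated grid must cover
TRUNCATION_QUANTILE = 0.9999


@dataclass(frozen=True)
class AgeGrid:
    """Discrete age grid: compartments of ``delta_h`` hours, at most ``n_max`` of them.

    Compartment ``k`` (1-based) represents ages ``[(k-1)*delta_h, k*delta_h)``.
    ``n_max`` is a cap: each duration distribution is truncated at the first
    compartment where its cumulative mass reaches ``TRUNCATION_QUANTILE``,
    which must not exceed ``n_max``.
    """

    delta_h: float = 0.5
    n_max: int = 1024

    def __post_init__(self) -> None:
        if self.delta_h <= 0:
            raise ValueError(f"delta_h must be > 0, got {self.delta_h}")
        if self.n_max < 2:
            raise ValueError(f"n_max must be >= 2, got {self.n_max}")


@dataclass(frozen=True)
class PhaseDurationSpec:
    """Mean/CV parameterization of a phase-duration law.

    Parameters
    ----------
    mean_h : float
        Average phase duration in hours.
    cv : float
        Coefficient of variation (SD / mean).  ``cv == 0`` is an exact
        deterministic duration.
    family : {"lognormal", "gamma"}
        Continuous family used for discretization.  Both are standard
        right-skewed intermitotic-time models fully determined by (mean, CV).
    """

    mean_h: float
    cv: float
    family: str = "lognormal"

    def __post_init__(self) -> None:
        if self.mean_h <= 0:
            raise ValueError(f"mean_h must be > 0, got {self.mean_h}")
        if self.cv < 0:
            raise ValueError(f"cv must be >= 0, got {self.cv}")
        if self.family not in ("lognormal", "gamma"):
            raise ValueError(f"unknown family {self.family!r}")

    def frozen(self):
        """The scipy frozen distribution for this spec (cv > 0 only)."""
        if self.cv == 0:
            raise ValueError("cv=0 has no continuous density")
        if self.family == "lognormal":
            sigma2 = np.log1p(self.cv**2)
            mu = np.log(self.mean_h) - sigma2 / 2.0
            return stats.lognorm(s=np.sqrt(sigma2), scale=np.exp(mu))
        shape = 1.0 / self.cv**2
        return stats.gamma(a=shape, scale=self.mean_h / shape)


@dataclass(frozen=True)
class DurationDistribution:
    """Discretized duration law: per-age mass and per-age exit probability."""

    mass: np.ndarray
    beta: np.ndarray
    grid: AgeGrid = field(default_factory=AgeGrid)

    def __post_init__(self) -> None:
        mass = np.asarray(self.mass, dtype=float)
        if mass.ndim != 1 or mass.size < 1:
            raise ValueError("mass must be a non-empty 1-D vector")
        if np.any(mass < 0):
            raise ValueError("mass must be non-negative")
        if abs(mass.sum() - 1.0) > 1e-9:
            raise ValueError(f"mass must sum to 1, got {mass.sum()}")
        beta = np.asarray(self.beta, dtype=float)
        if beta.shape != mass.shape:
            raise ValueError("beta and mass must have the same shape")
        if np.any(beta < 0) or np.any(beta > 1):
            raise ValueError("beta must lie in [0, 1]")
        if beta[-1] != 1.0:
            raise ValueError("beta must force exit at truncation (beta[-1] == 1)")

    @property
    def n_compartments(self) -> int:
        return self.mass.size

    def mean_h(self) -> float:
        return mass_mean_h(self.mass, self.grid.delta_h)

    def cv(self) -> float:
        return mass_cv(self.mass)


def mass_mean_h(mass: np.ndarray, delta_h: float) -> float:
    """Mean duration (hours) of a discretized mass vector."""
    k = np.arange(1, np.asarray(mass).size + 1)
    return float(np.sum(k * mass) * delta_h)


def mass_cv(mass: np.ndarray) -> float:
    """Coefficient of variation of a discretized mass vector."""
    k = np.arange(1, np.asarray(mass).size + 1)
    m = np.sum(k * mass)
    var = np.sum((k - m) ** 2 * mass)
    return float(np.sqrt(var) / m)


def build_duration_distribution(
    spec: PhaseDurationSpec, grid: AgeGrid
) -> DurationDistribution:
    """Discretize a phase-duration law on an age grid.

    ``mass[k-1]`` is the probability that the duration rounds to ``k`` steps
    (``P(T in [(k-1/2)*delta, (k+1/2)*delta))``, with all mass below half a
    step folded into the first compartment).  The grid is truncated at the
    first compartment covering ``TRUNCATION_QUANTILE`` of the law, with the
    residual tail folded into the last compartment, then renormalized.
    """
    if spec.mean_h < grid.delta_h:
        raise ValueError(
            f"grid too coarse: mean_h={spec.mean_h} < delta_h={grid.delta_h}"
        )
    d = grid.delta_h
    if spec.cv == 0:
        k0 = max(1, round(spec.mean_h / d))
        if k0 > grid.n_max:
            raise ValueError("deterministic duration exceeds grid truncation")
        mass = np.zeros(k0)
        mass[-1] = 1.0
        return DurationDistribution(mass=mass, beta=exit_probabilities(mass), grid=grid)

    frozen = spec.frozen()
    n_trunc = int(np.ceil(frozen.ppf(TRUNCATION_QUANTILE) / d - 0.5))
    n_trunc = max(n_trunc, 2)
    if n_trunc > grid.n_max:
        raise ValueError(
            f"truncation needs {n_trunc} compartments, grid caps at {grid.n_max}"
        )
    # compartment k collects durations rounding to k steps: [(k-1/2)d, (k+1/2)d),
    # with sub-half-step durations folded into k=1
    edges = (np.arange(1, n_trunc + 1) + 0.5) * d
    cdf = frozen.cdf(edges)
    mass = np.diff(np.concatenate([[0.0], cdf]))
    mass[-1] += 1.0 - cdf[-1]  # fold residual tail
    mass /= mass.sum()
    return DurationDistribution(mass=mass, beta=exit_probabilities(mass), grid=grid)


def exit_probabilities(mass: np.ndarray) -> np.ndarray:
    """Per-age exit probabilities from a normalized duration mass.

    ``beta[k-1] = mass[k-1] / (1 - sum_{j<k} mass[j-1])``: the chance that a
    cell still in the phase at age ``k`` completes it at that age.  Where the
    residual mass is zero the cell cannot still be there, and ``beta`` is set
    to 1 (forced exit); the last compartment always has ``beta == 1``.
    """
    mass = np.asarray(mass, dtype=float)
    if np.any(mass < 0):
        raise ValueError("mass must be non-negative")
    residual = 1.0 - np.concatenate([[0.0], np.cumsum(mass)[:-1]])
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(residual > 1e-15, mass / residual, 1.0)
    beta = np.clip(beta, 0.0, 1.0)
    beta[-1] = 1.0
    return beta


def mass_from_beta(beta: np.ndarray) -> np.ndarray:
    """Inverse of :func:`exit_probabilities`:
    ``mass[k] = beta[k] * prod_{j<k} (1 - beta[j])``."""
    beta = np.asarray(beta, dtype=float)
    survive = np.concatenate([[1.0], np.cumprod(1.0 - beta)[:-1]])
    return beta * survive


def convolve(mass_a: np.ndarray, mass_b: np.ndarray, delta_h_a: float | None = None,
             delta_h_b: float | None = None) -> np.ndarray:
    """Distribution of the sum of two independent discretized durations.

    Compartment indices are 1-based step counts, so the sum of a ``k_a``-step
    and a ``k_b``-step duration lands in compartment ``k_a + k_b``
    (0-based array index ``k_a + k_b - 1``).
    """
    if delta_h_a is not None and delta_h_b is not None and delta_h_a != delta_h_b:
        raise ValueError("cannot convolve masses on mismatched grids")
    a = np.asarray(mass_a, dtype=float)
    b = np.asarray(mass_b, dtype=float)
    for v in (a, b):
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValueError("convolve requires normalized masses")
    out = np.concatenate([[0.0], np.convolve(a, b)])
    return out / out.sum()
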