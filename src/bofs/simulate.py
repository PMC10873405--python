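"""Synthetic data generation for feature-selection benchmarking.

Datasets mimic a sparse high-dimensional regression design: covariates are
i.i.d. standard normal, ``X_i ~ N(0, I_p)``, and only the first ``p0``
columns (the *causal prefix*) carry signal. Two effect models are provided:

linear
    ``Y = X[:, causal] @ w + eps`` with ``eps ~ N(0, noise_sd^2)`` and effect
    sizes ``w_i = (-1)^{U_i} * (5*ln(n)/sqrt(n) + |Z_i|)`` where
    ``U_i ~ Bernoulli(0.5)`` and ``Z_i ~ N(0,1)``.  The additive floor
    ``5*ln(n)/sqrt(n)`` (natural log) keeps every causal effect detectable at
    sample size ``n``.

nonlinear
    ``Y = sum_{j in first p1} sin(X_j) + 1.8 * sum_{j in last p1} cos(X_j)
    + eps`` with ``p1 = p0/2`` and a small noise level (sd 0.1 by default).
    The cosine half is an even function of its covariate and so carries no
    linear (marginal-correlation) signal -- a deliberately hard case for
    linear selectors.

Binary outcomes are produced by dichotomizing the continuous outcome at its
sample median (values equal to the median map to class 1), which balances
the classes to within one sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional

import numpy as np

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "draw_linear_weights",
    "simulate_dataset",
    "binarize_at_median",
    "signal_floor",
]


def signal_floor(n: int) -> float:
    """Minimum absolute effect size ``5*ln(n)/sqrt(n)`` for sample size n."""
    return 5.0 * np.log(n) / np.sqrt(n)


@dataclass(frozen=True)
class SimulationConfig:
    """Generating configuration for one synthetic dataset.

    Parameters
    ----------
    n, p : int
        Sample and feature counts.
    p0 : int
        Number of causal features; for the nonlinear model p0 must be even
        (the sine and cosine sums each use p1 = p0/2 features).
    effect_model : {"linear", "nonlinear"}
    outcome_type : {"continuous", "binary"}
        Binary outcomes are the continuous ones dichotomized at the median.
    noise_sd : float, optional
        Standard deviation of the additive noise. Defaults to 1.0 for the
        linear model and 0.1 for the nonlinear model.
    seed : int
        Seed of the generator; one seed drives covariates, weights and noise
        through independent substreams.
    random_causal_placement : bool
        If True, causal columns are a random subset instead of the prefix
        ``0..p0-1`` (robustness-testing option; default False).
    """

    n: int = 1000
    p: int = 5000
    p0: int = 100
    effect_model: Literal["linear", "nonlinear"] = "linear"
    outcome_type: Literal["continuous", "binary"] = "continuous"
    noise_sd: Optional[float] = None
    seed: int = 0
    random_causal_placement: bool = False

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")
        if not (0 < self.p0 <= self.p):
            raise ValueError(f"require 0 < p0 <= p, got p0={self.p0}, p={self.p}")
        if self.effect_model not in ("linear", "nonlinear"):
            raise ValueError(f"unknown effect_model {self.effect_model!r}")
        if self.outcome_type not in ("continuous", "binary"):
            raise ValueError(f"unknown outcome_type {self.outcome_type!r}")
        if self.effect_model == "nonlinear" and self.p0 % 2:
            raise ValueError("nonlinear model requires even p0 (p1 = p0/2)")
        if self.noise_sd is None:
            object.__setattr__(
                self, "noise_sd", 1.0 if self.effect_model == "linear" else 0.1
            )
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be > 0, got {self.noise_sd}")


@dataclass
class SimulatedDataset:
    """A simulated design matrix with outcome and ground-truth causal set."""

    X: np.ndarray
    y: np.ndarray
    causal_indices: np.ndarray
    weights: Optional[np.ndarray]
    config: SimulationConfig
    #: continuous outcome prior to any dichotomization
    y_continuous: np.ndarray = field(repr=False, default=None)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def draw_linear_weights(
    n: int, p0: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Draw the p0 causal effect sizes of the linear model.

    Each weight is ``(-1)^U * (5*ln(n)/sqrt(n) + |Z|)`` with U a fair coin
    and Z standard normal, so every magnitude sits above the detectability
    floor ``5*ln(n)/sqrt(n)``.
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    if p0 < 1:
        raise ValueError(f"p0 must be >= 1, got {p0}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    signs = np.where(rng.random(p0) < 0.5, -1.0, 1.0)
    magnitudes = signal_floor(n) + np.abs(rng.standard_normal(p0))
    return signs * magnitudes


def binarize_at_median(y: np.ndarray) -> np.ndarray:
    """Dichotomize a real vector at its sample median.

    Values >= the median map to 1, values below to 0. For continuous draws
    (no ties at the median) the classes are balanced to within one sample.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size < 2:
        raise ValueError("y must be a vector of length >= 2")
    return (y >= np.median(y)).astype(int)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate one dataset under the given configuration.

    The config seed is split into three independent substreams (covariates,
    weights, noise) so the same seed reproduces the dataset bit-for-bit.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_x, rng_w, rng_eps = (np.random.default_rng(s) for s in ss.spawn(3))

    X = rng_x.standard_normal((config.n, config.p))
    if config.random_causal_placement:
        causal = np.sort(rng_w.choice(config.p, size=config.p0, replace=False))
    else:
        causal = np.arange(config.p0)

    eps = rng_eps.normal(0.0, config.noise_sd, size=config.n)
    weights = None
    if config.effect_model == "linear":
        weights = draw_linear_weights(config.n, config.p0, rng_w)
        y = X[:, causal] @ weights + eps
    else:
        p1 = config.p0 // 2
        y = (
            np.sin(X[:, causal[:p1]]).sum(axis=1)
            + 1.8 * np.cos(X[:, causal[p1:]]).sum(axis=1)
            + eps
        )

    y_cont = y
    if config.outcome_type == "binary":
        y = binarize_at_median(y_cont)

    return SimulatedDataset(
        X=X,
        y=y,
        causal_indices=causal,
        weights=weights,
        config=config,
        y_continuous=y_cont,
    )


def scaled_config(config: SimulationConfig, scale: float) -> SimulationConfig:
    """Shrink n, p and p0 of a config proportionally (desk-scale runs).

    p0 is kept even so the nonlinear model stays valid.
    """
    if not (0 < scale <= 1):
        raise ValueError("scale must be in (0, 1]")
    p0 = max(2, int(round(config.p0 * scale)))
    p0 -= p0 % 2
    return replace(
        config,
        n=max(10, int(round(config.n * scale))),
        p=max(p0, int(round(config.p * scale))),
        p0=p0,
    )
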