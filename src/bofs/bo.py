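"""Bayesian optimization over box-bounded hyper-parameter spaces.

The optimizer maximizes a black-box objective with a Gaussian-process
surrogate and an upper-confidence-bound (UCB) acquisition,

    AC(x) = mu(x) + kappa * sigma(x),

where mu and sigma are the GP posterior mean and standard deviation and
kappa trades exploitation against exploration.  Each iteration draws a
fresh pool of uniform candidates in the (normalized) box, scores them with
the acquisition, and evaluates the objective at the argmax.

Surrogate conventions (fixed, documented, not fitted):

* inputs are rescaled to the unit cube (log-scaled parameters on log10
  scale) before entering the kernel;
* squared-exponential kernel with unit variance and lengthscale 0.2 of the
  normalized range;
* observed objectives are z-scored before GP fitting so the unit-variance
  prior is appropriate regardless of the objective's scale;
* a 1e-8 jitter is added to the covariance diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Literal, Sequence, Tuple

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "Parameter",
    "HyperParameterSpace",
    "Evaluation",
    "BOTrace",
    "gp_posterior",
    "acquisition_ucb",
    "bo_optimize",
]

JITTER = 1e-8
DEFAULT_KAPPA = 2.0
DEFAULT_LENGTHSCALE = 0.2  # fraction of each parameter's normalized range


@dataclass(frozen=True)
class Parameter:
    name: str
    lower: float
    upper: float
    scale: Literal["linear", "log"] = "linear"
    kind: Literal["continuous", "integer"] = "continuous"

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"{self.name}: require lower < upper")
        if self.scale == "log" and self.lower <= 0:
            raise ValueError(f"{self.name}: log scale requires lower > 0")


@dataclass(frozen=True)
class HyperParameterSpace:
    """An ordered box of named parameters."""

    parameters: Tuple[Parameter, ...]

    def __post_init__(self) -> None:
        names = [p.name for p in self.parameters]
        if len(set(names)) != len(names):
            raise ValueError("parameter names must be unique")

    @classmethod
    def from_dict(cls, definition: Dict[str, tuple]) -> "HyperParameterSpace":
        """Build from ``{name: (lower, upper[, scale[, kind]])}``."""
        return cls(tuple(Parameter(name, *args) for name, args in definition.items()))

    @property
    def names(self) -> List[str]:
        return [p.name for p in self.parameters]

    @property
    def dim(self) -> int:
        return len(self.parameters)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """n uniform points in the normalized unit cube."""
        return rng.random((n, self.dim))

    def denormalize(self, u: np.ndarray) -> np.ndarray:
        """Map unit-cube rows to native parameter values (incl. rounding)."""
        u = np.atleast_2d(u)
        out = np.empty_like(u, dtype=float)
        for j, par in enumerate(self.parameters):
            if par.scale == "log":
                lo, hi = np.log10(par.lower), np.log10(par.upper)
                vals = 10 ** (lo + u[:, j] * (hi - lo))
            else:
                vals = par.lower + u[:, j] * (par.upper - par.lower)
            if par.kind == "integer":
                vals = np.clip(np.round(vals), par.lower, par.upper)
            out[:, j] = vals
        return out

    def to_dict(self, point: Sequence[float]) -> Dict[str, float]:
        return {
            p.name: (int(v) if p.kind == "integer" else float(v))
            for p, v in zip(self.parameters, point)
        }

    def contains(self, point: Sequence[float]) -> bool:
        return all(
            p.lower <= v <= p.upper for p, v in zip(self.parameters, point)
        )


@dataclass(frozen=True)
class Evaluation:
    """One observed (point, objective) pair; higher objective is better."""

    point: Tuple[float, ...]
    objective: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.objective):
            raise ValueError("objective must be finite")


@dataclass
class BOTrace:
    """History of a Bayesian-optimization run."""

    evaluations: List[Evaluation]
    space: HyperParameterSpace
    kappa: float
    n_iterations: int
    seed: int

    @property
    def objectives(self) -> np.ndarray:
        return np.array([e.objective for e in self.evaluations])

    @property
    def best_index(self) -> int:
        return int(np.argmax(self.objectives))

    @property
    def best_objective(self) -> float:
        return float(self.objectives[self.best_index])

    @property
    def best_point(self) -> Dict[str, float]:
        return self.space.to_dict(self.evaluations[self.best_index].point)

    def best_so_far(self) -> np.ndarray:
        return np.maximum.accumulate(self.objectives)

    def to_frame(self):
        import pandas as pd

        rows = []
        best = -np.inf
        for i, ev in enumerate(self.evaluations):
            best = max(best, ev.objective)
            row = {"iteration": i}
            row.update(self.space.to_dict(ev.point))
            row["objective"] = ev.objective
            row["best_so_far"] = best
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> Dict:
        return {
            "best_point": self.best_point,
            "best_objective": self.best_objective,
            "kappa": self.kappa,
            "n_iterations": self.n_iterations,
            "n_evaluations": len(self.evaluations),
            "seed": self.seed,
        }


def _sq_exp_kernel(
    A: np.ndarray, B: np.ndarray, lengthscale: float, variance: float
) -> np.ndarray:
    d2 = (
        np.sum(A**2, axis=1)[:, None]
        + np.sum(B**2, axis=1)[None, :]
        - 2.0 * A @ B.T
    )
    return variance * np.exp(-0.5 * np.maximum(d2, 0.0) / lengthscale**2)


def gp_posterior(
    X_obs: np.ndarray,
    y_obs: np.ndarray,
    X_new: np.ndarray,
    lengthscale: float = DEFAULT_LENGTHSCALE,
    kernel_variance: float = 1.0,
    noise_variance: float = 1e-6,
) -> Tuple[np.ndarray, np.ndarray]:
    """Gaussian-process regression posterior at new points.

    Zero-mean prior with squared-exponential kernel
    ``k(x, x') = v * exp(-|x-x'|^2 / (2 l^2))``.  Returns the posterior mean
    and standard deviation at each row of ``X_new``.

    Raises ``np.linalg.LinAlgError`` if the covariance is singular beyond
    what the diagonal jitter can absorb.
    """
    X_obs = np.atleast_2d(np.asarray(X_obs, dtype=float))
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    y_obs = np.asarray(y_obs, dtype=float).ravel()
    if X_obs.shape[0] == 0:
        raise ValueError("need at least one observation")
    if lengthscale <= 0 or kernel_variance <= 0 or noise_variance < 0:
        raise ValueError("kernel parameters must be positive (noise >= 0)")

    K = _sq_exp_kernel(X_obs, X_obs, lengthscale, kernel_variance)
    K[np.diag_indices_from(K)] += noise_variance + JITTER
    Ks = _sq_exp_kernel(X_obs, X_new, lengthscale, kernel_variance)

    L = cho_factor(K, lower=True)
    alpha = cho_solve(L, y_obs)
    mean = Ks.T @ alpha
    v = cho_solve(L, Ks)
    var = kernel_variance - np.einsum("ij,ij->j", Ks, v)
    sd = np.sqrt(np.maximum(var, 0.0))
    return mean, sd


def acquisition_ucb(
    mean: np.ndarray, sd: np.ndarray, kappa: float = DEFAULT_KAPPA
) -> np.ndarray:
    """Upper-confidence-bound scores ``mu + kappa * sigma`` elementwise."""
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if mean.shape != sd.shape:
        raise ValueError("mean and sd must have the same shape")
    if np.any(sd < 0):
        raise ValueError("sd must be non-negative")
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    return mean + kappa * sd


def bo_optimize(
    objective: Callable[[Dict[str, float]], float],
    space: HyperParameterSpace,
    n_iterations: int = 100,
    n_candidates_per_iteration: int = 500,
    n_initial: int = 5,
    kappa: float = DEFAULT_KAPPA,
    seed: int = 0,
) -> BOTrace:
    """Maximize ``objective`` over ``space`` with GP-UCB.

    The objective receives a ``{name: value}`` dict and must return a finite
    score (higher is better); loss-type objectives should be negated by the
    caller.  ``n_initial`` uniform evaluations seed the surrogate; each of
    the ``n_iterations`` rounds then evaluates the acquisition argmax over a
    fresh pool of uniform candidates (ties broken by lowest index).  The run
    aborts if more than half of all attempted evaluations fail or return
    non-finite values.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if n_initial < 1:
        raise ValueError("n_initial must be >= 1")
    rng = np.random.default_rng(seed)

    points_u: List[np.ndarray] = []
    evals: List[Evaluation] = []
    n_failures = 0

    def _evaluate(u: np.ndarray) -> None:
        nonlocal n_failures
        native = space.denormalize(u)[0]
        try:
            score = float(objective(space.to_dict(native)))
        except Exception:
            score = np.nan
        if not np.isfinite(score):
            n_failures += 1
            n_total = len(evals) + n_failures
            if n_failures > 0.5 * max(n_total, 2 * n_initial):
                raise RuntimeError(
                    f"objective failed or was non-finite on {n_failures} of "
                    f"{n_total} evaluations; aborting"
                )
            return
        points_u.append(u)
        evals.append(Evaluation(tuple(native), score))

    for u in space.sample(n_initial, rng):
        _evaluate(u)

    for _ in range(n_iterations):
        cand_u = space.sample(n_candidates_per_iteration, rng)
        if evals:
            y = np.array([e.objective for e in evals])
            y_sd = y.std()
            y_n = (y - y.mean()) / (y_sd if y_sd > 0 else 1.0)
            mean, sd = gp_posterior(np.vstack(points_u), y_n, cand_u)
            scores = acquisition_ucb(mean, sd, kappa)
            pick = int(np.argmax(scores))  # argmax takes the first maximum
        else:
            pick = 0
        _evaluate(cand_u[pick])

    if not evals:
        raise RuntimeError("no successful objective evaluations")
    return BOTrace(
        evaluations=evals,
        space=space,
        kappa=kappa,
        n_iterations=n_iterations,
        seed=seed,
    )
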