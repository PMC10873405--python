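"""Sparse partial least squares discriminant analysis (sPLSda).

Latent components T = X@alpha and H = Y@beta are chosen to maximize
cov^2(T, H) subject to unit-norm weight vectors, with the feature-side
vector alpha soft-thresholded to a per-component sparsity budget.  A
continuous response is first discretized into equal-frequency categories
(50 by default) and one-hot encoded, turning the regression task into the
discriminant-analysis form the method expects; a binary response is used
as two classes directly.

Per component the dominant singular-vector pair of the cross-covariance
X^T Y gives (alpha, beta); alpha is thresholded to keep its largest
entries, X is deflated by the fitted component, and the next component is
extracted.  Features are ranked by the component in which they first
enter a support, ties within a component by |loading|.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import List

import numpy as np

from .filters import discretize_equal_frequency
from .results import SelectionResult, marginal_abs_correlation

__all__ = ["SPLSComponents", "select_splsda", "soft_threshold_to_support"]

DEFAULT_N_CATEGORIES = 50
DEFAULT_N_COMPONENTS = 5


@dataclass
class SPLSComponents:
    """Weights and scores of one sparse-PLS component."""

    alpha: np.ndarray  # feature-side weights after thresholding, unit norm
    beta: np.ndarray  # response-side weights, unit norm
    T: np.ndarray  # latent score X @ alpha
    H: np.ndarray  # latent score Y @ beta
    sparsity: int

    def __post_init__(self) -> None:
        if np.count_nonzero(self.alpha) > self.sparsity:
            raise ValueError("support exceeds the sparsity budget")


def soft_threshold_to_support(u: np.ndarray, k: int) -> np.ndarray:
    """Soft-threshold a vector so at most k entries stay nonzero.

    The threshold is the (k+1)-th largest magnitude; surviving entries are
    shrunk toward zero by it and the result is renormalized to unit norm.
    """
    u = np.asarray(u, dtype=float)
    if k >= len(u):
        theta = 0.0
    else:
        theta = np.partition(np.abs(u), -k - 1)[-k - 1]
    v = np.sign(u) * np.maximum(np.abs(u) - theta, 0.0)
    norm = np.linalg.norm(v)
    return v / norm if norm > 0 else v


def _one_hot_response(y: np.ndarray, n_categories: int) -> np.ndarray:
    codes = discretize_equal_frequency(np.asarray(y).ravel(), n_categories)
    K = int(codes.max() + 1)
    Y = np.zeros((len(codes), K))
    Y[np.arange(len(codes)), codes] = 1.0
    return Y - Y.mean(axis=0)


def select_splsda(
    X: np.ndarray,
    y: np.ndarray,
    n_s: int,
    n_categories: int = DEFAULT_N_CATEGORIES,
    n_components: int = DEFAULT_N_COMPONENTS,
    per_component_sparsity: int | None = None,
) -> SelectionResult:
    """Rank features by order of entry into sparse-PLS component supports.

    The per-component sparsity defaults to ceil(n_s / n_components).
    Components are extracted until n_s distinct features have entered a
    support (overlapping supports trigger extra components, capped); any
    remainder is completed by absolute marginal correlation.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    n, p = X.shape
    if n_s > p:
        raise ValueError(f"n_s={n_s} exceeds feature count p={p}")
    k = per_component_sparsity or max(1, ceil(n_s / n_components))

    Xd = X - X.mean(axis=0)
    sd = Xd.std(axis=0)
    sd[sd == 0] = 1.0
    Xd = Xd / sd
    Y = _one_hot_response(y, n_categories)

    ranked: List[int] = []
    scores: List[float] = []
    seen = np.zeros(p, dtype=bool)
    components: List[SPLSComponents] = []
    max_components = max(n_components, 2 * ceil(p / k))
    for _ in range(max_components):
        if len(ranked) >= n_s:
            break
        M = Xd.T @ Y / n
        U, s, Vt = np.linalg.svd(M, full_matrices=False)
        if s[0] <= 1e-12:
            break
        alpha = soft_threshold_to_support(U[:, 0], k)
        beta = Vt[0]
        T = Xd @ alpha
        components.append(
            SPLSComponents(alpha=alpha, beta=beta, T=T, H=Y @ beta, sparsity=k)
        )
        support = np.flatnonzero(alpha)
        support = support[np.argsort(-np.abs(alpha[support]), kind="stable")]
        for j in support:
            if not seen[j] and len(ranked) < n_s:
                seen[j] = True
                ranked.append(int(j))
                scores.append(float(abs(alpha[j])))
        tt = float(T @ T)
        if tt <= 1e-12:
            break
        Xd = Xd - np.outer(T, T @ Xd) / tt

    if len(ranked) < n_s:
        r = marginal_abs_correlation(X, y)
        rest = np.argsort(-r, kind="stable")
        rest = rest[~seen[rest]][: n_s - len(ranked)]
        ranked.extend(int(j) for j in rest)
        scores.extend(float(v) for v in r[rest])

    return SelectionResult(
        method="splsda",
        tuner="none",
        ranked_indices=np.array(ranked, dtype=int),
        scores=np.array(scores),
        hyperparams={
            "n_categories": n_categories,
            "n_components": n_components,
            "per_component_sparsity": k,
        },
        n_requested=n_s,
    )
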