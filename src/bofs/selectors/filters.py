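"""Filter-based selectors: marginal-correlation screening and MRMR.

Sure independence screening (SIS) ranks features by the magnitude of
their Pearson correlation with the outcome.  Minimum-redundancy-maximum-
relevance (MRMR) greedily picks the feature maximizing

    MI(y, x_i) - (1/|S|) * sum_{j in S} MI(x_i, x_j)

where S is the already-selected set and MI is mutual information of the
equal-frequency discretized variables (natural-log units).
"""

from __future__ import annotations

import numpy as np

from .results import SelectionResult, marginal_abs_correlation

__all__ = ["select_sis", "select_mrmr", "discretize_equal_frequency", "discrete_mi"]


def select_sis(X: np.ndarray, y: np.ndarray, n_s: int) -> SelectionResult:
    """Rank features by |Pearson correlation| with y, ties by lower index."""
    p = X.shape[1]
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    if n_s > p:
        raise ValueError(f"n_s={n_s} exceeds feature count p={p}")
    r = marginal_abs_correlation(X, y)
    order = np.argsort(-r, kind="stable")[:n_s]
    return SelectionResult(
        method="sis", tuner="none", ranked_indices=order, scores=r[order],
        n_requested=n_s,
    )


def discretize_equal_frequency(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Map a vector to integer codes with (near) equal-count bins.

    Vectors with at most ``n_bins`` distinct values (e.g. binary labels)
    are label-encoded as-is.
    """
    x = np.asarray(x).ravel()
    uniq = np.unique(x)
    if len(uniq) <= n_bins:
        return np.searchsorted(uniq, x)
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(qs, x, side="right")


def discrete_mi(a: np.ndarray, b: np.ndarray, k_a: int, k_b: int) -> float:
    """Mutual information (nats) of two integer-coded vectors."""
    n = len(a)
    joint = np.bincount(a * k_b + b, minlength=k_a * k_b).reshape(k_a, k_b)
    pij = joint / n
    pi = pij.sum(axis=1, keepdims=True)
    pj = pij.sum(axis=0, keepdims=True)
    mask = pij > 0
    return float(np.sum(pij[mask] * np.log(pij[mask] / (pi @ pj)[mask])))


def select_mrmr(
    X: np.ndarray, y: np.ndarray, n_s: int, n_bins: int = 10
) -> SelectionResult:
    """Greedy MRMR selection on discretized variables.

    The first pick maximizes relevance MI(y, x); each later pick maximizes
    relevance minus the mean redundancy to the selected set.  Scores are
    the MRMR criterion value at the time of selection (they may decrease
    across picks by construction of the greedy path).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    n, p = X.shape
    if n_s > p:
        raise ValueError(f"n_s={n_s} exceeds feature count p={p}")

    D = np.empty((n, p), dtype=np.int64)
    k_cols = np.empty(p, dtype=np.int64)
    for j in range(p):
        D[:, j] = discretize_equal_frequency(X[:, j], n_bins)
        k_cols[j] = D[:, j].max() + 1
    dy = discretize_equal_frequency(y, n_bins)
    k_y = int(dy.max() + 1)

    relevance = np.array(
        [discrete_mi(D[:, j], dy, int(k_cols[j]), k_y) for j in range(p)]
    )
    selected: list[int] = []
    scores: list[float] = []
    red_sum = np.zeros(p)
    available = np.ones(p, dtype=bool)
    for step in range(n_s):
        if step == 0:
            crit = relevance.copy()
        else:
            crit = relevance - red_sum / len(selected)
        crit[~available] = -np.inf
        pick = int(np.argmax(crit))  # first maximum wins ties
        selected.append(pick)
        scores.append(float(crit[pick]))
        available[pick] = False
        kp = int(k_cols[pick])
        dp = D[:, pick]
        for j in np.flatnonzero(available):
            red_sum[j] += discrete_mi(dp, D[:, j], kp, int(k_cols[j]))
    return SelectionResult(
        method="mrmr",
        tuner="none",
        ranked_indices=np.array(selected),
        scores=np.array(scores),
        hyperparams={"n_bins": n_bins},
        n_requested=n_s,
    )
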