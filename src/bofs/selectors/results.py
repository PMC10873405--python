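from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

__all__ = ["SelectionResult", "marginal_abs_correlation"]


def marginal_abs_correlation(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """|Pearson correlation| of each column of X with y.

    Zero-variance columns (or a zero-variance y) get a correlation of 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.abs(Xc.T @ yc) / np.where(denom > 0, denom, np.inf)
    return np.nan_to_num(r, nan=0.0)


@dataclass
class SelectionResult:
    """An ordered feature ranking produced by one selector.

    ``ranked_indices`` holds feature indices best-first; ``scores`` the
    per-feature ranking score (non-increasing within each ranking tier).
    ``hyperparams`` records the hyper-parameter values actually used, and
    ``trace`` the Bayesian-optimization history when a BO tuner produced
    them.
    """

    method: str
    tuner: str
    ranked_indices: np.ndarray
    scores: np.ndarray
    hyperparams: Dict[str, float] = field(default_factory=dict)
    n_requested: int = 0
    trace: Optional[object] = None

    def __post_init__(self) -> None:
        self.ranked_indices = np.asarray(self.ranked_indices, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if len(np.unique(self.ranked_indices)) != len(self.ranked_indices):
            raise ValueError("ranked_indices must be unique")
        if len(self.scores) != len(self.ranked_indices):
            raise ValueError("scores and ranked_indices must align")

    def top(self, k: int) -> np.ndarray:
        """The first min(k, available) ranked indices."""
        return self.ranked_indices[:k]

    def __len__(self) -> int:
        return len(self.ranked_indices)
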