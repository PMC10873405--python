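"""Gradient-boosting feature selection via split-gain importances.

A boosted tree ensemble scores a candidate split by the gain

    Gain = 1/2 * [ G_L^2/(H_L+lambda) + G_R^2/(H_R+lambda)
                   - (G_L+G_R)^2/(H_L+H_R+lambda) ] - gamma

where G and H are sums of first- and second-order loss gradients in the
left/right children and gamma, lambda penalize tree complexity.  A
feature's importance is its total gain accumulated over every split in
the ensemble.  ``xgb_gain`` implements the formula directly (useful for
validating the semantics); ``select_xgboost`` delegates the ensemble fit
to the xgboost library and ranks by its total-gain importances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import xgboost

from .results import SelectionResult, marginal_abs_correlation

__all__ = ["SplitStats", "xgb_gain", "select_xgboost", "XGB_DEFAULTS"]

#: library-documented defaults, used by the DE (default-setting) variant
XGB_DEFAULTS: Dict[str, float] = {
    "learning_rate": 0.3,
    "max_depth": 6,
    "subsample": 1.0,
    "colsample_bytree": 1.0,
    "gamma": 0.0,
    "reg_lambda": 1.0,
}

N_BOOST_ROUNDS = 100


@dataclass(frozen=True)
class SplitStats:
    """Gradient statistics of one candidate split."""

    G_L: float
    G_R: float
    H_L: float
    H_R: float
    lam: float = 1.0
    gamma: float = 0.0

    def __post_init__(self) -> None:
        if self.H_L < 0 or self.H_R < 0:
            raise ValueError("second-order gradient sums must be >= 0")
        if self.lam < 0 or self.gamma < 0:
            raise ValueError("lambda and gamma must be >= 0")


def xgb_gain(stats: SplitStats) -> float:
    """Objective improvement of a split given its gradient statistics."""
    s = stats
    return 0.5 * (
        s.G_L**2 / (s.H_L + s.lam)
        + s.G_R**2 / (s.H_R + s.lam)
        - (s.G_L + s.G_R) ** 2 / (s.H_L + s.H_R + s.lam)
    ) - s.gamma


def select_xgboost(
    X: np.ndarray,
    y: np.ndarray,
    hyperparams: Optional[Dict[str, float]] = None,
    n_s: int = 100,
    family: str = "gaussian",
    seed: int = 0,
    tuner: str = "none",
) -> SelectionResult:
    """Rank features by total split gain of a boosted ensemble.

    Features that are never split (zero gain) are appended after the
    gain-ranked ones, ordered by absolute marginal correlation with y,
    and the ranking is truncated to ``n_s``.
    """
    y = np.asarray(y, dtype=float).ravel()
    if np.ptp(y) == 0:
        raise ValueError("outcome is constant; boosting fit is degenerate")
    p = X.shape[1]
    if n_s > p:
        raise ValueError(f"n_s={n_s} exceeds feature count p={p}")
    params = dict(XGB_DEFAULTS)
    if hyperparams:
        params.update(hyperparams)
    params["max_depth"] = int(params["max_depth"])

    cls = xgboost.XGBClassifier if family == "binomial" else xgboost.XGBRegressor
    model = cls(
        n_estimators=N_BOOST_ROUNDS,
        random_state=seed,
        n_jobs=1,
        tree_method="hist",
        verbosity=0,
        **params,
    )
    model.fit(X, y.astype(int) if family == "binomial" else y)
    raw = model.get_booster().get_score(importance_type="total_gain")
    gains = np.zeros(p)
    for key, val in raw.items():
        gains[int(key[1:])] = val

    if n_s == 0:
        return SelectionResult(
            method="xgboost", tuner=tuner, ranked_indices=np.empty(0, dtype=int),
            scores=np.empty(0), hyperparams=params, n_requested=0,
        )
    split_feats = np.flatnonzero(gains > 0)
    order1 = split_feats[np.argsort(-gains[split_feats], kind="stable")]
    if len(order1) >= n_s:
        idx = order1[:n_s]
        scores = gains[idx]
    else:
        r = marginal_abs_correlation(X, y)
        used = np.zeros(p, dtype=bool)
        used[order1] = True
        rest = np.argsort(-r, kind="stable")
        rest = rest[~used[rest]][: n_s - len(order1)]
        idx = np.concatenate([order1, rest])
        scores = np.concatenate([gains[order1], r[rest]])
    return SelectionResult(
        method="xgboost",
        tuner=tuner,
        ranked_indices=idx,
        scores=scores,
        hyperparams=params,
        n_requested=n_s,
    )
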