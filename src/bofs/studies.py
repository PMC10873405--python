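"""Reference study configurations at desk scale.

The headline comparison — Bayesian-optimized lasso / elastic net versus
their cross-validation-tuned counterparts — is run here at half the
full simulation scale (n=500, p=2500, p0=500, selection sizes
{50,100,250,500}, 5 repetitions, 50 BO iterations) so a complete study
finishes in minutes on one CPU.  The full-scale configuration
(n=1000, p=5000, p0 up to 1000, 20 repetitions, 100 BO iterations)
remains available through ``run_simulation_study`` directly.
"""

from __future__ import annotations

from typing import Sequence, Tuple

import pandas as pd

from .benchmark import run_simulation_study

__all__ = ["SCALED", "scaled_study", "mean_recall"]

#: desk-scale study constants (half the full design)
SCALED = {
    "n": 500,
    "p": 2500,
    "p0": 500,
    "n_s_grid": (50, 100, 250, 500),
    "repeats": 5,
    "bo_iterations": 50,
}


def scaled_study(
    effect_model: str,
    methods: Sequence[Tuple[str, str]],
    base_seed: int = 0,
    outcome_type: str = "continuous",
) -> pd.DataFrame:
    """Run the scaled recall study for the given selection variants."""
    return run_simulation_study(
        p0_grid=[SCALED["p0"]],
        n_s_grid=list(SCALED["n_s_grid"]),
        methods=list(methods),
        effect_model=effect_model,
        outcome_type=outcome_type,
        n=SCALED["n"],
        p=SCALED["p"],
        repeats=SCALED["repeats"],
        base_seed=base_seed,
        bo_settings={"n_iterations": SCALED["bo_iterations"]},
    )


def mean_recall(records: pd.DataFrame, method: str, tuner: str, n_s: int) -> float:
    """Mean recall (over repetitions) of one variant at one selection size."""
    sub = records[
        (records["method"] == method)
        & (records["tuner"] == tuner)
        & (records["n_s"] == n_s)
    ]
    if sub.empty:
        raise ValueError(f"no records for {method}/{tuner} at n_s={n_s}")
    return float(sub["recall"].mean())
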