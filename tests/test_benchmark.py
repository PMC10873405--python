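"""Recall-rate study orchestration and the prediction stage."""

import numpy as np
import pandas as pd
import pytest

import bofs.benchmark as bm
from bofs import (
    SimulationConfig,
    recall_rate,
    run_prediction_study,
    run_simulation_study,
    simulate_dataset,
    summarize,
)
from bofs.selectors.results import SelectionResult


class TestRecallRate:
    def test_enumerated_sets(self):
        assert recall_rate({1, 2, 3}, {1, 2, 3}) == 1.0
        assert recall_rate({4, 5}, {1, 2}) == 0.0
        assert recall_rate(
            set(range(1, 51)) | set(range(1001, 1051)), set(range(1, 101))
        ) == 0.5

    def test_monotone_in_selected_set(self, rng):
        causal = set(rng.choice(1000, 50, replace=False).tolist())
        ranking = rng.permutation(1000)
        recalls = [recall_rate(ranking[:k], causal) for k in range(0, 1001, 100)]
        assert all(b >= a for a, b in zip(recalls, recalls[1:]))

    def test_empty_causal_rejected(self):
        with pytest.raises(ValueError):
            recall_rate({1}, set())


def _oracle_select(method, tuner, X, y, n_s, family="gaussian", seed=0,
                   bo_settings=None):
    """Test hook: 'selector' that returns the causal prefix."""
    idx = np.arange(n_s)
    return SelectionResult(method=method, tuner=tuner, ranked_indices=idx,
                           scores=np.ones(n_s), n_requested=n_s)


class TestSimulationStudy:
    def test_row_accounting(self):
        tbl = run_simulation_study(
            p0_grid=[4], n_s_grid=[4], methods=[("sis", "none")],
            n=40, p=20, repeats=2, base_seed=0,
        )
        assert len(tbl) == 2
        assert set(tbl.columns) >= {"method", "tuner", "p0", "n_s", "repetition",
                                    "seed", "recall", "runtime_seconds"}

    def test_oracle_selector_scores_perfect_recall(self, monkeypatch):
        monkeypatch.setattr(bm, "select", _oracle_select)
        tbl = run_simulation_study(
            p0_grid=[4], n_s_grid=[4], methods=[("lasso", "CV")],
            n=30, p=10, repeats=3, base_seed=1,
        )
        assert (tbl["recall"] == 1.0).all()

    def test_everything_selected_gives_full_recall(self):
        tbl = run_simulation_study(
            p0_grid=[6], n_s_grid=[20], methods=[("sis", "none")],
            n=50, p=20, repeats=2, base_seed=2,
        )
        assert (tbl["recall"] == 1.0).all()

    def test_recall_monotone_in_selection_size(self):
        tbl = run_simulation_study(
            p0_grid=[6], n_s_grid=[2, 5, 10, 20], methods=[("sis", "none")],
            n=60, p=20, repeats=2, base_seed=3,
        )
        for rep, grp in tbl.groupby("repetition"):
            r = grp.sort_values("n_s")["recall"].to_numpy()
            assert np.all(np.diff(r) >= 0)

    def test_study_is_deterministic(self):
        kwargs = dict(
            p0_grid=[4], n_s_grid=[4, 8], methods=[("sis", "none"), ("lasso", "CV")],
            n=40, p=16, repeats=2, base_seed=7,
        )
        a = run_simulation_study(**kwargs)
        b = run_simulation_study(**kwargs)
        pd.testing.assert_frame_equal(
            a.drop(columns="runtime_seconds"),
            b.drop(columns="runtime_seconds"),
            atol=1e-9, check_exact=False,
        )  # runtime is recorded but never asserted

    def test_selector_failure_recorded_not_raised(self, monkeypatch):
        def broken(*args, **kwargs):
            raise RuntimeError("synthetic failure")

        monkeypatch.setattr(bm, "select", broken)
        tbl = run_simulation_study(
            p0_grid=[4], n_s_grid=[4], methods=[("lasso", "CV")],
            n=30, p=10, repeats=2, base_seed=4,
        )
        assert tbl["recall"].isna().all()
        assert (tbl["error"].str.contains("synthetic failure")).all()

    def test_scale_factor_shrinks_problem(self):
        tbl = run_simulation_study(
            p0_grid=[100], n_s_grid=[100], methods=[("sis", "none")],
            n=100, p=200, repeats=4, base_seed=5, scale=0.5,
        )
        assert tbl["p0"].unique().tolist() == [50]
        assert tbl["n_s"].unique().tolist() == [50]
        assert tbl["repetition"].nunique() == 2


class TestPredictionStudy:
    def test_row_accounting(self, small_linear_dataset):
        ds = small_linear_dataset
        tbl = run_prediction_study(
            ds.X, ds.y, selectors=[("sis", "none"), ("lasso", "CV")],
            predictors=["lasso"], n_s=10, repeats=3, base_seed=0,
        )
        assert len(tbl) == 6

    def test_oracle_features_predict_noise_free_outcome(self, monkeypatch):
        monkeypatch.setattr(bm, "select", _oracle_select)
        ds = simulate_dataset(
            SimulationConfig(n=300, p=30, p0=5, effect_model="linear",
                             noise_sd=1e-6, seed=11)
        )
        tbl = run_prediction_study(
            ds.X, ds.y, selectors=[("lasso", "CV")], predictors=["lasso"],
            n_s=5, repeats=2, base_seed=1,
        )
        assert (tbl["pearson_r"] > 0.99).all()
        assert (tbl["mse"] < 0.05 * ds.y.var()).all()

    def test_permuted_outcome_has_no_signal(self, rng):
        X = rng.standard_normal((150, 20))
        y = rng.standard_normal(150)  # independent of X by construction
        tbl = run_prediction_study(
            X, y, selectors=[("sis", "none")], predictors=["lasso"],
            n_s=5, repeats=10, base_seed=2,
        )
        assert abs(tbl["pearson_r"].mean()) < 0.25

    def test_selection_sees_training_data_only(self, monkeypatch):
        seen = []

        def spy(method, tuner, X, y, n_s, **kwargs):
            seen.append(X.shape[0])
            return _oracle_select(method, tuner, X, y, n_s)

        monkeypatch.setattr(bm, "select", spy)
        ds = simulate_dataset(SimulationConfig(n=100, p=20, p0=4, seed=3))
        run_prediction_study(
            ds.X, ds.y, selectors=[("sis", "none")], predictors=["lasso"],
            n_s=4, repeats=1, base_seed=3, split_fraction=0.7,
        )
        assert seen == [70]


class TestSummarize:
    def test_single_record(self):
        df = pd.DataFrame([
            {"method": "sis", "tuner": "none", "p0": 4, "n_s": 2, "recall": 0.5}
        ])
        out = summarize(df)
        assert out["recall_mean"].iloc[0] == 0.5
        assert out["n_valid"].iloc[0] == 1

    def test_mean_of_two(self):
        df = pd.DataFrame([
            {"method": "sis", "tuner": "none", "p0": 4, "n_s": 2, "recall": 0.2},
            {"method": "sis", "tuner": "none", "p0": 4, "n_s": 2, "recall": 0.4},
        ])
        assert summarize(df)["recall_mean"].iloc[0] == pytest.approx(0.3)

    def test_na_excluded_and_counted(self):
        df = pd.DataFrame([
            {"method": "sis", "tuner": "none", "p0": 4, "n_s": 2, "recall": 0.6},
            {"method": "sis", "tuner": "none", "p0": 4, "n_s": 2, "recall": np.nan},
        ])
        out = summarize(df)
        assert out["recall_mean"].iloc[0] == pytest.approx(0.6)
        assert out["n_valid"].iloc[0] == 1
        assert out["n_total"].iloc[0] == 2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize(pd.DataFrame())

    def test_plot_writes_file(self, tmp_path):
        df = pd.DataFrame([
            {"method": "sis", "tuner": "none", "p0": 4, "n_s": k, "recall": r}
            for k, r in [(2, 0.2), (4, 0.5), (2, 0.3), (4, 0.6)]
        ])
        out = tmp_path / "curves.png"
        bm.plot_recall_curves(summarize(df), str(out))
        assert out.stat().st_size > 0
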