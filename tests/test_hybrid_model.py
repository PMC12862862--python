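"""Hybrid model contracts: fusion algebra, branch behaviour, evaluation
metrics, and the temporal-leakage guards."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pni.config import BoostBranchConfig, HybridConfig, TemporalBranchConfig
from pni.hybrid import (
    boost_predict,
    confusion_metrics,
    evaluate,
    fuse_attention,
    rank_auc,
    train_boost_branch,
    train_hybrid,
)
from pni.hybrid.model import ModelError
from pni.panel import AthletePanel, PanelError
from pni.preprocessing import PreprocessError, make_temporal_split


def desk_hybrid(seed=0):
    cfg = HybridConfig.desk_scale(seed)
    cfg.temporal = TemporalBranchConfig(
        embed_dim=8, layer_sizes=(8,), bidirectional=(False,), dropout=0.0,
        max_epochs=30, early_stop_patience=10, seed=seed)
    cfg.boost = BoostBranchConfig(n_estimators=50, max_depth=3, seed=seed)
    cfg.fusion_dim = 4
    return cfg


def two_signal_panel(seed=0, n=90, t=12):
    """Panel with a temporal trend signal and a static interaction signal
    driving the outcome feature ``y``."""
    rng = np.random.default_rng(seed)
    rows = []
    slope = rng.standard_normal(n) * 0.1
    u = rng.standard_normal(n)
    v = rng.standard_normal(n)
    y = 2.0 * slope * t + 0.8 * u * v + 0.1 * rng.standard_normal(n)
    for i in range(n):
        for j in range(t):
            rows.append({
                "athlete_id": f"A{i:03d}", "group": "balanced", "time_index": j,
                "x_trend": slope[i] * j + 0.05 * rng.standard_normal(),
                "x_u": u[i] + 0.05 * rng.standard_normal(),
                "x_v": v[i] + 0.05 * rng.standard_normal(),
                "noise": rng.standard_normal(),
                "y": y[i] + 0.05 * rng.standard_normal(),
            })
    return AthletePanel(pd.DataFrame(rows))


class TestFusion:
    def test_equal_logits_give_midpoint(self, rng):
        h1 = rng.standard_normal((6, 3))
        h2 = rng.standard_normal((6, 3))
        z, alpha = fuse_attention(h1, h2, np.zeros((6, 2)))
        assert np.allclose(alpha, 0.5)
        assert np.allclose(z, (h1 + h2) / 2)

    def test_log3_logits_give_three_quarters(self):
        h1 = np.ones((1, 1))
        h2 = np.zeros((1, 1))
        # W chosen so logits are (ln 3, 0) for this input
        W = np.array([[np.log(3.0), 0.0], [0.0, 0.0]])
        _, alpha = fuse_attention(h1, h2, W)
        assert np.allclose(alpha, [[0.75, 0.25]])

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ModelError):
            fuse_attention(rng.standard_normal((4, 3)),
                           rng.standard_normal((4, 2)), np.zeros((5, 2)))

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_attention_always_on_simplex(self, seed):
        rng = np.random.default_rng(seed)
        h1 = rng.standard_normal((5, 4)) * 10
        h2 = rng.standard_normal((5, 4)) * 10
        _, alpha = fuse_attention(h1, h2, rng.standard_normal((8, 2)))
        assert np.all(alpha >= 0)
        assert np.allclose(alpha.sum(1), 1.0)


class TestBoostBranch:
    def test_pure_noise_labels_give_no_validation_skill(self, rng):
        n = 300
        X = pd.DataFrame(rng.standard_normal((n, 5)))
        y = rng.standard_normal(n)
        models = train_boost_branch(X.iloc[:200], y[:200],
                                    BoostBranchConfig(n_estimators=50, max_depth=3))
        pred = boost_predict(models, X.iloc[200:])[:, 0]
        resid = y[200:] - pred
        r2 = 1 - (resid ** 2).sum() / ((y[200:] - y[200:].mean()) ** 2).sum()
        assert r2 < 0.1

    def test_step_function_recovered_on_training_data(self):
        X = pd.DataFrame({"x": np.linspace(-1, 1, 100)})
        y = (X["x"] > 0).astype(float).to_numpy()
        models = train_boost_branch(X, y, BoostBranchConfig(n_estimators=200, max_depth=2))
        pred = boost_predict(models, X)[:, 0]
        assert np.array_equal(pred > 0.5, y > 0.5)
        assert np.abs(pred - y).max() < 0.05

    def test_full_subsample_is_deterministic(self, rng):
        X = pd.DataFrame(rng.standard_normal((50, 3)))
        y = rng.standard_normal(50)
        cfg = BoostBranchConfig(n_estimators=30, subsample=1.0, seed=5)
        p1 = boost_predict(train_boost_branch(X, y, cfg), X)
        p2 = boost_predict(train_boost_branch(X, y, cfg), X)
        assert np.array_equal(p1, p2)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ModelError, match="mismatch"):
            train_boost_branch(pd.DataFrame(rng.standard_normal((10, 2))),
                               rng.standard_normal(8), BoostBranchConfig())


class TestEvaluate:
    def test_confusion_arithmetic(self):
        sens, spec = confusion_metrics(tp=41, fn=4, tn=38, fp=7)
        assert sens == pytest.approx(0.911, abs=5e-4)
        assert spec == pytest.approx(0.844, abs=5e-4)

    def test_perfect_predictions(self, rng):
        y = rng.standard_normal(50)
        labels = y > 0
        rep = evaluate(y, y, class_scores=y, class_labels=labels)
        assert rep.rmse["y0"] == 0.0
        assert rep.r_squared["y0"] == 1.0
        assert rep.auc == 1.0

    def test_random_scores_give_half_auc(self, rng):
        n = 10_000
        labels = np.arange(n) % 2 == 0
        scores = rng.standard_normal(n)
        assert rank_auc(scores, labels) == pytest.approx(0.5, abs=0.02)

    def test_single_class_labels_warn_and_yield_na(self, rng):
        y = rng.standard_normal(20)
        with pytest.warns(UserWarning, match="single-class"):
            rep = evaluate(y, y, class_scores=y, class_labels=np.ones(20, bool))
        assert rep.auc is None

    def test_mape_excludes_near_zero_truth(self):
        rep = evaluate(np.array([1.0, 0.05]), np.array([2.0, 0.01]))
        # only the first pair contributes: |1-2|/2 = 50%
        assert rep.mape["y0"] == pytest.approx(50.0)


class TestTrainHybrid:
    def test_hybrid_not_worse_than_both_branches(self):
        panel = two_signal_panel(seed=1)
        plan = make_temporal_split(panel, 0.8, 3, 4, val_window=1, seed=1)
        model = train_hybrid(panel, plan, desk_hybrid(1), outcomes=["y"])
        mean_rmse = model.cv_report.groupby("model")["rmse"].mean()
        assert mean_rmse["hybrid"] <= min(mean_rmse["temporal"], mean_rmse["boost"]) + 0.02

    def test_shuffled_time_order_triggers_leakage_guard(self):
        panel = two_signal_panel(seed=2)
        plan = make_temporal_split(panel, 0.8, 3, 4, val_window=1, seed=2)
        shuffled = panel.data.copy()
        shuffled["time_index"] = np.random.default_rng(0).permutation(
            shuffled["time_index"].to_numpy())
        # duplicate (athlete, time) pairs are caught by the panel itself,
        # or chronological guards by the trainer
        with pytest.raises((PanelError, PreprocessError)):
            bad = AthletePanel(shuffled)
            train_hybrid(bad, plan, desk_hybrid(), outcomes=["y"])

    def test_gap_violating_plan_rejected(self):
        panel = two_signal_panel(seed=3)
        plan = make_temporal_split(panel, 0.8, 3, 4, val_window=1, seed=3)
        plan.folds[0].valid_times = (plan.folds[0].train_times[1], plan.folds[0].train_times[1] + 1)
        with pytest.raises(PreprocessError, match="gap"):
            train_hybrid(panel, plan, desk_hybrid(), outcomes=["y"])

    def test_test_athlete_outcomes_never_read(self):
        """Scrambling the held-out athletes' outcomes leaves the fitted
        model (and its predictions for training athletes) unchanged."""
        panel = two_signal_panel(seed=4)
        plan = make_temporal_split(panel, 0.8, 3, 4, val_window=1, seed=4)
        scrambled = panel.copy()
        test_rows = scrambled.data["athlete_id"].isin(set(plan.test_athletes))
        rng = np.random.default_rng(9)
        scrambled.data.loc[test_rows, "y"] = rng.standard_normal(int(test_rows.sum())) * 100

        m1 = train_hybrid(panel, plan, desk_hybrid(5), outcomes=["y"])
        m2 = train_hybrid(scrambled, plan, desk_hybrid(5), outcomes=["y"])
        pd.testing.assert_frame_equal(m1.cv_report, m2.cv_report)
        for k in m1.fusion.p:
            assert np.array_equal(m1.fusion.p[k], m2.fusion.p[k])
        for k in m1.temporal.params:
            assert np.array_equal(m1.temporal.params[k], m2.temporal.params[k])
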