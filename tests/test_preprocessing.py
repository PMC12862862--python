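"""Cleaning pipeline contracts: outlier screen, MICE, scaling, engineering,
temporal split."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pni.config import PreprocessConfig
from pni.panel import AthletePanel
from pni.preprocessing import (
    PreprocessError,
    engineer_features,
    fit_normalizer,
    impute_chained,
    make_temporal_split,
    normalize_features,
    screen_outliers,
    weekly_average,
)


def _panel_from_matrix(values: np.ndarray, feature: str = "x") -> AthletePanel:
    """n athletes x T matrix -> panel with a single feature."""
    n, t = values.shape
    rows = []
    for i in range(n):
        for j in range(t):
            rows.append({"athlete_id": f"A{i:03d}", "group": "balanced",
                         "time_index": j, feature: values[i, j]})
    return AthletePanel(pd.DataFrame(rows))


class TestOutlierScreen:
    def test_constant_feature_yields_no_flags(self):
        panel = _panel_from_matrix(np.full((5, 4), 3.0))
        out, flags = screen_outliers(panel, PreprocessConfig())
        assert len(flags) == 0
        assert not out.data["x"].isna().any()

    def test_gross_outlier_flagged(self, rng):
        vals = rng.standard_normal((100, 10))
        vals[3, 5] = 10.0
        out, flags = screen_outliers(_panel_from_matrix(vals), PreprocessConfig())
        # oracle: recompute pooled mean/SD including the outlier
        flat = vals.ravel()
        assert abs(10.0 - flat.mean()) > 3 * flat.std(ddof=1)
        assert ("A003", 5, "x") in set(map(tuple, flags[["athlete_id", "time_index",
                                                         "feature"]].to_numpy()))

    def test_threshold_is_strict(self, rng):
        """A value just inside k SDs is retained; just outside is flagged."""
        # bounded base sample: no natural 3-SD exceedances
        base = rng.uniform(-2, 2, 400)
        base = (base - base.mean()) / base.std(ddof=1)
        for bump, expect_flag in ((2.9, False), (3.5, True)):
            vals = np.concatenate([base, [bump]])
            ratio = abs(bump - vals.mean()) / vals.std(ddof=1)
            assert (ratio > 3) == expect_flag  # construction sanity
            panel = _panel_from_matrix(vals.reshape(1, -1))
            _, flags = screen_outliers(panel, PreprocessConfig())
            assert (len(flags) > 0) == expect_flag


class TestImputation:
    def test_identity_on_complete_panel(self, clean_panel, preprocess_config):
        out = impute_chained(clean_panel, preprocess_config)
        pd.testing.assert_frame_equal(out.data, clean_panel.data)

    def test_beats_mean_imputation_on_correlated_features(self, rng):
        n = 400
        a = rng.standard_normal(n)
        b = 0.8 * a + np.sqrt(1 - 0.64) * rng.standard_normal(n)
        df = pd.DataFrame({"athlete_id": [f"A{i:03d}" for i in range(n // 40) for _ in range(40)],
                           "time_index": list(range(40)) * (n // 40),
                           "a": a, "b": b})
        mask = rng.random(n) < 0.1
        truth = df.loc[mask, "b"].copy()
        df.loc[mask, "b"] = np.nan
        panel = AthletePanel(df)
        out = impute_chained(panel, PreprocessConfig())
        rmse_mice = np.sqrt(((out.data.loc[mask, "b"] - truth) ** 2).mean())
        rmse_mean = np.sqrt(((df["b"].mean() - truth) ** 2).mean())
        assert rmse_mice < rmse_mean

    def test_seeded_reproducibility(self, degraded_panel, preprocess_config):
        screened, _ = screen_outliers(degraded_panel, preprocess_config)
        a = impute_chained(screened, preprocess_config)
        b = impute_chained(screened, preprocess_config)
        pd.testing.assert_frame_equal(a.data, b.data)
        assert not a.data[a.feature_names].isna().any().any()

    def test_observed_cells_unchanged(self, degraded_panel, preprocess_config):
        screened, _ = screen_outliers(degraded_panel, preprocess_config)
        out = impute_chained(screened, preprocess_config)
        feats = screened.feature_names
        obs = screened.data[feats].notna()
        orig = screened.data[feats].to_numpy()
        new = out.data[feats].to_numpy()
        assert np.array_equal(orig[obs.to_numpy()], new[obs.to_numpy()])

    def test_inclusion_limit_enforced(self, rng):
        df = pd.DataFrame({"athlete_id": ["A0"] * 10, "time_index": range(10),
                           "a": [np.nan] * 5 + list(rng.standard_normal(5)),
                           "b": rng.standard_normal(10)})
        with pytest.raises(PreprocessError, match="20%"):
            impute_chained(AthletePanel(df), PreprocessConfig())


class TestNormalization:
    def test_normal_feature_not_logged(self, rng):
        vals = rng.standard_normal((50, 8)) + 10
        panel = _panel_from_matrix(vals)
        params = fit_normalizer(panel, PreprocessConfig(rescale_0_10=()))
        assert params.scalers["x"].mode == "zscore"

    def test_lognormal_feature_logged_and_skew_reduced(self, rng):
        vals = np.exp(rng.standard_normal((50, 8)) * 1.2)
        panel = _panel_from_matrix(vals)
        cfg = PreprocessConfig(rescale_0_10=())
        out, params = normalize_features(panel, cfg)
        assert params.scalers["x"].mode == "log_then_zscore"
        assert abs(stats.skew(out.data["x"])) < abs(stats.skew(vals.ravel()))

    def test_constant_feature_zscores_to_zero_with_warning(self):
        panel = _panel_from_matrix(np.full((5, 4), 2.0))
        with pytest.warns(UserWarning, match="constant"):
            out, _ = normalize_features(panel, PreprocessConfig(rescale_0_10=()))
        assert np.allclose(out.data["x"], 0.0)

    def test_psych_scales_rescaled_to_0_10(self, clean_panel, preprocess_config):
        out, _ = normalize_features(clean_panel, preprocess_config)
        for f in ("fatigue", "stress", "resilience"):
            assert out.data[f].min() >= -1e-9
            assert out.data[f].max() <= 10 + 1e-9

    def test_idempotent_on_normalized_panel(self, clean_panel, preprocess_config):
        once, _ = normalize_features(clean_panel, preprocess_config)
        twice, _ = normalize_features(once, preprocess_config)
        diff = (once.data[once.feature_names] - twice.data[twice.feature_names]).abs()
        assert diff.to_numpy().max() < 1e-10

    def test_scaling_fit_on_training_athletes_only(self, clean_panel, preprocess_config):
        ids = sorted(clean_panel.athlete_ids)
        train = ids[: len(ids) // 2]
        params = fit_normalizer(clean_panel, preprocess_config, train_athletes=train)
        sub = clean_panel.data[clean_panel.data["athlete_id"].isin(train)]
        s = params.scalers["il6"]
        ref = sub["il6"].to_numpy()
        if s.mode == "log_then_zscore":
            ref = np.log(ref)
        assert s.mean == pytest.approx(ref.mean())
        assert s.sd == pytest.approx(ref.std(ddof=1))


class TestEngineering:
    def test_interaction_is_cellwise_product(self, clean_panel):
        out = engineer_features(clean_panel,
                                interactions=[("protein_g_per_kg", "training_load")])
        got = out.data["ix_protein_g_per_kg_x_training_load"]
        expect = clean_panel.data["protein_g_per_kg"] * clean_panel.data["training_load"]
        assert np.allclose(got, expect)

    def test_seasonal_terms_at_time_zero(self, clean_panel):
        out = engineer_features(clean_panel)
        at0 = out.at_time(0)
        assert np.allclose(at0["season_sin"], 0.0)
        assert np.allclose(at0["season_cos"], 1.0)

    def test_composite_of_identical_zscored_columns_is_the_column(self, rng):
        z = rng.standard_normal(40)
        z = (z - z.mean()) / z.std()
        df = pd.DataFrame({"athlete_id": [f"A{i}" for i in range(40)],
                           "time_index": 0, "u": z, "v": z})
        out = engineer_features(AthletePanel(df), composites={"c": ["u", "v"]})
        assert np.allclose(out.data["c"], out.data["u"], atol=1e-12)

    def test_unknown_column_rejected(self, clean_panel):
        with pytest.raises(PreprocessError, match="unknown"):
            engineer_features(clean_panel, interactions=[("nope", "fatigue")])

    def test_weekly_average_collapses_pairs(self):
        df = pd.DataFrame({"athlete_id": ["A"] * 4, "time_index": [0, 1, 2, 3],
                           "x": [1.0, 3.0, 5.0, 7.0]})
        agg = weekly_average(df, ["x"], factor=2)
        assert agg["x"].tolist() == [2.0, 6.0]


class TestTemporalSplit:
    def test_published_split_sizes(self, default_panel):
        plan = make_temporal_split(default_panel, 0.8, 5, 4, seed=0)
        assert len(plan.train_athletes) == 160
        assert len(plan.test_athletes) == 40
        assert not set(plan.train_athletes) & set(plan.test_athletes)

    def test_fold_windows_match_documented_formula(self, default_panel):
        plan = make_temporal_split(default_panel, 0.8, 5, 4, val_window=3, seed=0)
        starts = [f.valid_times[0] for f in plan.folds]
        assert starts == [8, 11, 14, 17, 20]
        for f in plan.folds:
            assert f.train_times == (0, f.valid_times[0] - 4)

    def test_gap_invariant_holds_for_every_fold(self, clean_panel):
        plan = make_temporal_split(clean_panel, 0.8, 3, 4, val_window=1, seed=1)
        for f in plan.folds:
            assert f.train_times[1] - 1 + plan.gap_steps <= f.valid_times[0] - 1

    def test_stratified_by_group(self, default_panel):
        plan = make_temporal_split(default_panel, 0.8, 5, 4, seed=3)
        meta = default_panel.meta()
        test_groups = meta.loc[plan.test_athletes, "group"].value_counts()
        assert sorted(test_groups.tolist()) == [13, 13, 14]

    def test_too_small_series_rejected_with_arithmetic(self, clean_panel):
        with pytest.raises(PreprocessError, match="T=12"):
            make_temporal_split(clean_panel, 0.8, 5, 4, val_window=3)

    def test_roundtrip_json(self, default_panel, tmp_path):
        plan = make_temporal_split(default_panel, 0.8, 5, 4, seed=0)
        plan.to_json(tmp_path / "plan.json")
        from pni.preprocessing import SplitPlan
        back = SplitPlan.from_json(tmp_path / "plan.json")
        assert back.train_athletes == plan.train_athletes
        assert [f.valid_times for f in back.folds] == [f.valid_times for f in plan.folds]
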