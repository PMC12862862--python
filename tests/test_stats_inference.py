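"""Inference toolkit: correlation, lag scan, CCA, mediation, ARIMA,
threshold-crossing lags."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pni.panel import AthletePanel
from pni.stats_inference import (
    InferenceError,
    MediationResult,
    PathEstimate,
    correlate,
    first_canonical_correlation,
    fit_arima,
    fit_mediation_serial,
    lag_correlation_scan,
    proportion_mediated,
    threshold_crossing_lag,
)
from pni.synthetic_cohort import simulate_serial_mediation


def panel_from_series(A: np.ndarray, B: np.ndarray) -> AthletePanel:
    n, t = A.shape
    rows = []
    for i in range(n):
        for j in range(t):
            rows.append({"athlete_id": f"A{i:03d}", "time_index": j,
                         "a": A[i, j], "b": B[i, j]})
    return AthletePanel(pd.DataFrame(rows))


class TestCorrelate:
    def test_perfect_linearity(self):
        r, p = correlate([1, 2, 3], [2, 4, 6])
        assert r == pytest.approx(1.0)

    def test_hand_computed_pearson(self):
        # sums of Eq-style deviations give r = 4 / sqrt(5 * 5) = 0.8
        r, _ = correlate([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8)

    def test_spearman_saturates_on_monotone_nonlinear(self):
        x = np.linspace(1, 5, 20)
        y = np.exp(x)
        rs, _ = correlate(x, y, method="spearman")
        rp, _ = correlate(x, y, method="pearson")
        assert rs == pytest.approx(1.0)
        assert rp < 1.0

    def test_zero_variance_warns_nan(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            r, p = correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(r)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10 ** 6), st.floats(0.1, 10), st.floats(-5, 5))
    def test_pearson_invariant_to_positive_affine_maps(self, seed, scale, shift):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(20)
        y = rng.standard_normal(20)
        r1, _ = correlate(x, y)
        r2, _ = correlate(scale * x + shift, y)
        assert r1 == pytest.approx(r2, abs=1e-9)


class TestLagScan:
    def test_noise_free_shift_peaks_at_construction(self, rng):
        base = rng.standard_normal((10, 30))
        A = base[:, :24]
        B = np.roll(base, 3, axis=1)[:, :24]  # b(t) = a(t-3)
        scan = lag_correlation_scan(panel_from_series(A, B), "a", "b",
                                    max_lag=6, n_boot=20, seed=0)
        assert scan.peak_lag == 3
        # Fisher-z pooling clips perfect correlations just below 1
        assert scan.peak_r == pytest.approx(1.0, abs=1e-4)

    def test_independent_noise_has_no_material_peak(self, rng):
        A = rng.standard_normal((200, 24))
        B = rng.standard_normal((200, 24))
        scan = lag_correlation_scan(panel_from_series(A, B), "a", "b",
                                    max_lag=6, n_boot=20, seed=1)
        assert abs(scan.peak_r) < 0.1

    def test_lag_zero_equals_series_correlation_single_athlete(self, rng):
        a = rng.standard_normal(24)
        b = 0.6 * a + 0.8 * rng.standard_normal(24)
        scan = lag_correlation_scan(panel_from_series(a[None], b[None]), "a", "b",
                                    max_lag=4, n_boot=10, seed=2)
        r0 = scan.r[scan.lags == 0][0]
        assert r0 == pytest.approx(np.corrcoef(a, b)[0, 1], abs=1e-12)

    def test_max_lag_bounded(self, rng):
        A = rng.standard_normal((5, 10))
        with pytest.raises(InferenceError, match="max_lag"):
            lag_correlation_scan(panel_from_series(A, A), "a", "b", max_lag=5)


class TestCanonicalCorrelation:
    def test_identical_blocks_give_unity(self, rng):
        X = rng.standard_normal((100, 4))
        r1, shared = first_canonical_correlation(X, X.copy())
        assert r1 == pytest.approx(1.0, abs=1e-8)
        assert shared == pytest.approx(100.0, abs=1e-6)

    def test_one_dimensional_blocks_reduce_to_pearson(self, rng):
        x = rng.standard_normal(200)
        y = -0.7 * x + 0.5 * rng.standard_normal(200)
        r1, _ = first_canonical_correlation(x, y)
        assert r1 == pytest.approx(abs(np.corrcoef(x, y)[0, 1]), abs=1e-10)

    def test_independent_blocks_below_permutation_null(self, rng):
        X = rng.standard_normal((200, 4))
        Y = rng.standard_normal((200, 4))
        r1, _ = first_canonical_correlation(X, Y)
        null = []
        for _ in range(200):
            perm = rng.permutation(len(Y))
            null.append(first_canonical_correlation(X, Y[perm])[0])
        assert r1 < np.percentile(null, 97.5)


class TestMediation:
    def test_planted_coefficients_recovered_with_ci_coverage(self):
        data = simulate_serial_mediation(0.5, 0.6, 0.4, 0.2, n=2000, b1=0.3,
                                         noise_sd=0.5, seed=7)
        res = fit_mediation_serial(data, "exposure", ["m1", "m2"], "outcome",
                                   n_boot=1000, seed=0)
        assert res.indirect_serial == pytest.approx(0.12, abs=0.02)
        lo, hi = res.ci["ind_serial"]
        assert lo <= 0.12 <= hi

    def test_null_b_paths_cover_zero(self):
        """With both b-paths zero, indirect-effect CIs cover 0 at close to
        nominal rate (each single CI misses ~5% of the time)."""
        covered = 0
        reps = 10
        for rep in range(reps):
            data = simulate_serial_mediation(0.5, 0.6, 0.0, 0.3, n=800,
                                             b1=0.0, noise_sd=1.0, seed=80 + rep)
            res = fit_mediation_serial(data, "exposure", ["m1", "m2"],
                                       "outcome", n_boot=400, seed=rep)
            covered += all(res.ci[k][0] <= 0.0 <= res.ci[k][1]
                           for k in ("ind_simple", "ind_serial"))
        assert covered >= 7

    def test_seeded_bootstrap_reproducible(self):
        data = simulate_serial_mediation(0.4, 0.5, 0.3, 0.1, n=300, seed=9)
        r1 = fit_mediation_serial(data, "exposure", ["m1", "m2"], "outcome",
                                  n_boot=200, seed=5)
        r2 = fit_mediation_serial(data, "exposure", ["m1", "m2"], "outcome",
                                  n_boot=200, seed=5)
        assert r1.ci == r2.ci

    def test_effect_decomposition_identity(self):
        """total ~= direct + all indirect paths on linear-Gaussian data."""
        data = simulate_serial_mediation(0.5, 0.6, 0.4, 0.2, n=5000, b1=0.3,
                                         noise_sd=1.0, seed=10)
        res = fit_mediation_serial(data, "exposure", ["m1", "m2"], "outcome",
                                   n_boot=0)
        gap = res.total.coef - (res.direct.coef + res.indirect_total)
        assert abs(gap) < 0.02

    def test_single_mediator_special_case(self):
        data = simulate_serial_mediation(0.5, 0.0, 0.0, 0.2, n=2000, b1=0.4,
                                         noise_sd=0.5, seed=11)
        res = fit_mediation_serial(data, "exposure", ["m1"], "outcome",
                                   n_boot=300, seed=2)
        assert res.indirect_simple == pytest.approx(0.2, abs=0.03)
        assert res.indirect_serial == 0.0

    def test_bootstrap_ci_coverage_near_nominal(self):
        """~95% of BC bootstrap CIs cover the planted serial effect."""
        hits = 0
        reps = 120
        for rep in range(reps):
            data = simulate_serial_mediation(0.5, 0.6, 0.4, 0.2, n=200, b1=0.3,
                                             noise_sd=0.8, seed=1000 + rep)
            res = fit_mediation_serial(data, "exposure", ["m1", "m2"],
                                       "outcome", n_boot=300, seed=rep)
            lo, hi = res.ci["ind_serial"]
            hits += lo <= 0.12 <= hi
        assert 0.88 <= hits / reps <= 0.995

    def test_collinear_mediators_rejected(self, rng):
        x = rng.standard_normal(200)
        m = 0.5 * x
        data = pd.DataFrame({"exposure": x, "m1": m, "m2": m,
                             "outcome": rng.standard_normal(200)})
        with pytest.raises(InferenceError, match="collinear"):
            fit_mediation_serial(data, "exposure", ["m1", "m2"], "outcome",
                                 n_boot=10)


class TestProportionMediated:
    @pytest.mark.parametrize("indirects,total,expected", [
        ((0.22, 0.35), 0.81, 70.4),
        ((0.19, 0.19), 0.67, 56.7),
        ((0.15, 0.12), 0.58, 46.6),
    ])
    def test_published_decomposition_arithmetic(self, indirects, total, expected):
        res = MediationResult(
            a1=PathEstimate(0, 0), b1=PathEstimate(0, 0),
            direct=PathEstimate(total - sum(indirects), 0),
            total=PathEstimate(total, 0),
            indirect_simple=indirects[0], indirect_serial=indirects[1])
        assert round(proportion_mediated(res), 1) == expected

    def test_zero_indirect_gives_zero(self):
        res = MediationResult(a1=PathEstimate(0, 0), b1=PathEstimate(0, 0),
                              direct=PathEstimate(0.5, 0), total=PathEstimate(0.5, 0))
        assert proportion_mediated(res) == 0.0

    def test_null_total_effect_warns_nan(self):
        res = MediationResult(a1=PathEstimate(0, 0), b1=PathEstimate(0, 0),
                              direct=PathEstimate(0, 0), total=PathEstimate(0, 0),
                              indirect_simple=0.1)
        with pytest.warns(UserWarning, match="total"):
            assert np.isnan(proportion_mediated(res))


class TestArima:
    def test_ar1_order_and_coefficient_recovery(self):
        """Simulated AR(1), phi = 0.8: the selected model is always a
        stationary autoregression (d = 0, p >= 1), exactly (1,0,0) in a
        majority of seeds, and the AR(1) coefficient is recovered."""
        exact = 0
        ar_structure = 0
        for seed in range(8):
            rng = np.random.default_rng(seed)
            y = np.empty(500)
            y[0] = rng.standard_normal()
            for t in range(1, 500):
                y[t] = 0.8 * y[t - 1] + rng.standard_normal()
            fit = fit_arima(y)
            ar_structure += fit.order[1] == 0 and fit.order[0] >= 1
            if fit.order == (1, 0, 0):
                exact += 1
                assert 0.7 <= fit.ar_params[0] <= 0.9
        assert ar_structure >= 6  # a phi=0.8 series can look near-unit-root
        assert exact >= 4         # exact order in a majority of seeds

    def test_white_noise_selects_empty_model(self, rng):
        y = rng.standard_normal(400)
        fit = fit_arima(y)
        assert fit.order == (0, 0, 0)

    def test_random_walk_selects_differencing(self, rng):
        y = np.cumsum(rng.standard_normal(400))
        fit = fit_arima(y)
        assert fit.order[1] == 1

    def test_selected_aic_within_tie_window_of_minimum(self, rng):
        y = rng.standard_normal(100)
        fit = fit_arima(y)
        assert fit.aic <= min(fit.aic_table.values()) + 2.0

    def test_short_series_rejected(self, rng):
        with pytest.raises(InferenceError, match="length"):
            fit_arima(rng.standard_normal(10))


class TestThresholdCrossing:
    def test_constructed_lag(self):
        months = np.arange(0, 13.0)
        a = np.clip((months - 2.0) / 4.0, 0, 1)   # crosses 0.5 at month 4
        b = np.clip((months - 3.5) / 4.0, 0, 1)   # crosses 0.5 at month 5.5
        assert threshold_crossing_lag(months, a, b, 0.5) == pytest.approx(1.5)

    def test_identical_trajectories_give_zero(self):
        months = np.arange(0, 13.0)
        a = months / 12.0
        assert threshold_crossing_lag(months, a, a, 0.5) == 0.0

    def test_never_crossing_warns_none(self):
        months = np.arange(0, 13.0)
        a = months / 12.0
        b = np.zeros_like(months)
        with pytest.warns(UserWarning, match="never crosses"):
            assert threshold_crossing_lag(months, a, b, 0.5) is None
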