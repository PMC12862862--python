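"""Correlation, lag-scan, canonical-correlation, mediation and ARIMA machinery.

Implements the inferential toolkit for the nutrition-psychology-immunity
analyses: Pearson/Spearman correlation, within-athlete lag-correlation scans
(positive lag = first series leads), the leading canonical correlation
between two variable blocks, regression-based serial mediation with
bias-corrected bootstrap confidence intervals and the product-of-coefficients
indirect effects, AIC-selected ARIMA fits, and threshold-crossing lags
between normalised trajectories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class InferenceError(ValueError):
    pass


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def correlate(x, y, method: str = "pearson") -> tuple[float, float]:
    """Correlation coefficient and p-value.

    Pearson for linear association; Spearman (rank-transform then Pearson)
    for monotone association.  Zero-variance input yields (nan, nan) with a
    warning.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 3:
        raise InferenceError("inputs must be equal-length with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise InferenceError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero-variance input; correlation undefined")
        return float("nan"), float("nan")
    if method == "pearson":
        r = stats.pearsonr(x, y)
    elif method == "spearman":
        r = stats.spearmanr(x, y)
    else:
        raise InferenceError(f"unknown method {method!r}")
    return float(r.statistic), float(r.pvalue)


# ---------------------------------------------------------------------------
# lag correlation scan
# ---------------------------------------------------------------------------

@dataclass
class LagScanResult:
    lags: np.ndarray           # bi-weekly steps; positive = series A leads
    months: np.ndarray
    r: np.ndarray              # Fisher-z pooled within-athlete correlation
    ci_low: np.ndarray
    ci_high: np.ndarray
    peak_lag: int
    peak_lag_months: float
    peak_r: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag_steps": self.lags, "lag_months": self.months,
                             "r": self.r, "ci_low": self.ci_low,
                             "ci_high": self.ci_high})


def _fisher_mean(rs: np.ndarray) -> float:
    rs = rs[np.isfinite(rs)]
    if rs.size == 0:
        return float("nan")
    z = np.arctanh(np.clip(rs, -0.999999, 0.999999))
    return float(np.tanh(z.mean()))


def lag_correlation_scan(panel, series_a: str, series_b: str, max_lag: int,
                         n_boot: int = 500, seed: int = 0,
                         min_overlap: int = 5) -> LagScanResult:
    """Within-athlete lagged correlation of two feature trajectories.

    For each lag l in [-max_lag, max_lag] correlates a(t) with b(t + l)
    within each athlete and pools across athletes by Fisher-z averaging;
    95% CIs come from a bootstrap over athletes.  Positive peak lag means
    psychological (series A) changes precede series B.
    """
    A = panel.series(series_a).to_numpy()
    B = panel.series(series_b).to_numpy()
    n, t = A.shape
    if max_lag >= t / 2:
        raise InferenceError(f"max_lag {max_lag} must be < T/2 = {t / 2}")
    rng = np.random.default_rng(seed)
    lags = np.arange(-max_lag, max_lag + 1)
    months_per_step = 12.0 / (t - 1)

    per_athlete = np.full((lags.size, n), np.nan)
    for k, lag in enumerate(lags):
        if lag >= 0:
            a, b = A[:, : t - lag], B[:, lag:]
        else:
            a, b = A[:, -lag:], B[:, : t + lag]
        if a.shape[1] < min_overlap:
            warnings.warn(f"lag {lag}: insufficient overlap, skipped")
            continue
        for i in range(n):
            ai, bi = a[i], b[i]
            ok = np.isfinite(ai) & np.isfinite(bi)
            if ok.sum() < min_overlap or np.ptp(ai[ok]) == 0 or np.ptp(bi[ok]) == 0:
                continue
            per_athlete[k, i] = np.corrcoef(ai[ok], bi[ok])[0, 1]

    r = np.array([_fisher_mean(per_athlete[k]) for k in range(lags.size)])
    boot = np.empty((n_boot, lags.size))
    for b_ in range(n_boot):
        idx = rng.integers(0, n, n)
        boot[b_] = [_fisher_mean(per_athlete[k, idx]) for k in range(lags.size)]
    ci_low = np.nanpercentile(boot, 2.5, axis=0)
    ci_high = np.nanpercentile(boot, 97.5, axis=0)
    k_peak = int(np.nanargmax(r))
    return LagScanResult(lags=lags, months=lags * months_per_step, r=r,
                         ci_low=ci_low, ci_high=ci_high,
                         peak_lag=int(lags[k_peak]),
                         peak_lag_months=float(lags[k_peak] * months_per_step),
                         peak_r=float(r[k_peak]))


# ---------------------------------------------------------------------------
# canonical correlation
# ---------------------------------------------------------------------------

def first_canonical_correlation(block_x, block_y, ridge: float = 0.0) -> tuple[float, float]:
    """Leading canonical correlation between two variable blocks.

    Whitening formulation: r1 is the largest singular value of
    ``Sxx^{-1/2} Sxy Syy^{-1/2}``.  Returns (r1, shared variance % = 100 r1^2).
    Singular within-block covariance triggers ridge regularisation with a
    warning.
    """
    X = np.asarray(block_x, float)
    Y = np.asarray(block_y, float)
    if X.ndim == 1:
        X = X[:, None]
    if Y.ndim == 1:
        Y = Y[:, None]
    n = X.shape[0]
    if n <= max(X.shape[1], Y.shape[1]):
        raise InferenceError("need more observations than block dimensions")
    X = X - X.mean(0)
    Y = Y - Y.mean(0)
    Sxx = X.T @ X / (n - 1)
    Syy = Y.T @ Y / (n - 1)
    Sxy = X.T @ Y / (n - 1)
    if ridge == 0.0 and (np.linalg.cond(Sxx) > 1e10 or np.linalg.cond(Syy) > 1e10):
        warnings.warn("singular within-block covariance; applying ridge 1e-6")
        ridge = 1e-6
    if ridge:
        Sxx = Sxx + ridge * np.eye(Sxx.shape[0]) * np.trace(Sxx) / Sxx.shape[0]
        Syy = Syy + ridge * np.eye(Syy.shape[0]) * np.trace(Syy) / Syy.shape[0]

    def inv_sqrt(S):
        vals, vecs = np.linalg.eigh(S)
        vals = np.clip(vals, 1e-12, None)
        return vecs @ np.diag(vals ** -0.5) @ vecs.T

    M = inv_sqrt(Sxx) @ Sxy @ inv_sqrt(Syy)
    r1 = float(np.clip(np.linalg.svd(M, compute_uv=False)[0], 0.0, 1.0))
    return r1, 100.0 * r1 ** 2


# ---------------------------------------------------------------------------
# serial mediation
# ---------------------------------------------------------------------------

@dataclass
class PathEstimate:
    coef: float
    se: float


@dataclass
class MediationResult:
    """Path coefficients and indirect-effect decomposition of the serial
    chain exposure -> m1 -> m2 -> outcome (m2 optional)."""

    a1: PathEstimate
    b1: PathEstimate
    direct: PathEstimate               # c'
    total: PathEstimate                # c
    a2: PathEstimate | None = None     # m1 -> m2
    b2: PathEstimate | None = None     # m2 -> outcome
    d2: PathEstimate | None = None     # exposure -> m2 (controlling m1)
    indirect_simple: float = 0.0       # a1 * b1
    indirect_serial: float = 0.0       # a1 * a2 * b2
    indirect_other: float = 0.0        # d2 * b2
    ci: dict = field(default_factory=dict)
    n: int = 0
    n_boot: int = 0

    @property
    def indirect_total(self) -> float:
        return self.indirect_simple + self.indirect_serial + self.indirect_other


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Coefficients and SEs of OLS with intercept prepended."""
    Z = np.column_stack([np.ones(len(X)), X])
    if np.linalg.cond(Z.T @ Z) > 1e6:
        raise InferenceError("collinear design (condition number > 1e6)")
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    resid = y - Z @ beta
    dof = max(len(y) - Z.shape[1], 1)
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(Z.T @ Z)
    return beta[1:], np.sqrt(np.diag(cov))[1:]


def _paths(x, m1, m2, y) -> dict[str, float]:
    out = {}
    b, _ = _ols(m1, x[:, None])
    out["a1"] = b[0]
    if m2 is not None:
        b, _ = _ols(m2, np.column_stack([m1, x]))
        out["a2"], out["d2"] = b[0], b[1]
        b, _ = _ols(y, np.column_stack([x, m1, m2]))
        out["c_prime"], out["b1"], out["b2"] = b
    else:
        b, _ = _ols(y, np.column_stack([x, m1]))
        out["c_prime"], out["b1"] = b
    b, _ = _ols(y, x[:, None])
    out["c"] = b[0]
    out["ind_simple"] = out["a1"] * out["b1"]
    out["ind_serial"] = out["a1"] * out.get("a2", 0.0) * out.get("b2", 0.0)
    out["ind_other"] = out.get("d2", 0.0) * out.get("b2", 0.0)
    return out


def _bc_ci(boot: np.ndarray, point: float, alpha: float = 0.05) -> tuple[float, float]:
    """Bias-corrected percentile bootstrap interval."""
    boot = boot[np.isfinite(boot)]
    if boot.size == 0:
        return float("nan"), float("nan")
    prop = np.clip((boot < point).mean(), 1e-6, 1 - 1e-6)
    z0 = stats.norm.ppf(prop)
    za = stats.norm.ppf([alpha / 2, 1 - alpha / 2])
    lo, hi = stats.norm.cdf(2 * z0 + za) * 100.0
    return tuple(np.percentile(boot, [lo, hi]))


def fit_mediation_serial(data: pd.DataFrame, exposure: str, mediators: list[str],
                         outcome: str, n_boot: int = 5000, seed: int = 0) -> MediationResult:
    """Serial mediation by OLS path regressions and coefficient products.

    ``mediators`` holds one (simple mediation) or two (serial chain) column
    names.  Indirect effects are products of path coefficients; CIs are
    bias-corrected percentile bootstrap over ``n_boot`` resamples.
    """
    if len(mediators) not in (1, 2):
        raise InferenceError("mediators must list one or two columns")
    cols = [exposure, *mediators, outcome]
    df = data[cols].dropna()
    if len(df) < 30:
        raise InferenceError(f"need n >= 30 complete cases, got {len(df)}")
    x = df[exposure].to_numpy(float)
    m1 = df[mediators[0]].to_numpy(float)
    m2 = df[mediators[1]].to_numpy(float) if len(mediators) == 2 else None
    y = df[outcome].to_numpy(float)

    # point estimates with SEs
    a1c, a1s = _ols(m1, x[:, None])
    est = {"a1": PathEstimate(float(a1c[0]), float(a1s[0]))}
    if m2 is not None:
        b, s = _ols(m2, np.column_stack([m1, x]))
        est["a2"], est["d2"] = PathEstimate(float(b[0]), float(s[0])), PathEstimate(float(b[1]), float(s[1]))
        b, s = _ols(y, np.column_stack([x, m1, m2]))
        est["direct"] = PathEstimate(float(b[0]), float(s[0]))
        est["b1"] = PathEstimate(float(b[1]), float(s[1]))
        est["b2"] = PathEstimate(float(b[2]), float(s[2]))
    else:
        b, s = _ols(y, np.column_stack([x, m1]))
        est["direct"] = PathEstimate(float(b[0]), float(s[0]))
        est["b1"] = PathEstimate(float(b[1]), float(s[1]))
    b, s = _ols(y, x[:, None])
    est["total"] = PathEstimate(float(b[0]), float(s[0]))

    point = _paths(x, m1, m2, y)

    rng = np.random.default_rng(seed)
    n = len(df)
    keys = ("ind_simple", "ind_serial", "ind_other", "c", "c_prime")
    if n_boot == 0:
        return MediationResult(
            a1=est["a1"], b1=est["b1"], direct=est["direct"], total=est["total"],
            a2=est.get("a2"), b2=est.get("b2"), d2=est.get("d2"),
            indirect_simple=float(point["ind_simple"]),
            indirect_serial=float(point["ind_serial"]),
            indirect_other=float(point["ind_other"]),
            ci={}, n=n, n_boot=0)
    boot = {k: np.empty(n_boot) for k in keys}
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            p = _paths(x[idx], m1[idx], None if m2 is None else m2[idx], y[idx])
        except InferenceError:
            p = {k: np.nan for k in keys}
        for k in keys:
            boot[k][i] = p.get(k, np.nan)
    ci = {k: _bc_ci(boot[k], point[k]) for k in keys}

    return MediationResult(
        a1=est["a1"], b1=est["b1"], direct=est["direct"], total=est["total"],
        a2=est.get("a2"), b2=est.get("b2"), d2=est.get("d2"),
        indirect_simple=float(point["ind_simple"]),
        indirect_serial=float(point["ind_serial"]),
        indirect_other=float(point["ind_other"]),
        ci=ci, n=n, n_boot=n_boot)


def proportion_mediated(result: MediationResult, tol: float = 1e-8) -> float:
    """Share of the total effect carried by the indirect paths, in percent."""
    total = result.total.coef
    if abs(total) < tol:
        warnings.warn("total effect ~ 0; proportion mediated undefined")
        return float("nan")
    return 100.0 * (result.indirect_simple + result.indirect_serial) / total


# ---------------------------------------------------------------------------
# ARIMA
# ---------------------------------------------------------------------------

@dataclass
class ArimaFit:
    order: tuple[int, int, int]
    ar_params: np.ndarray
    ma_params: np.ndarray
    intercept: float
    aic: float
    residuals: np.ndarray
    aic_table: dict[tuple[int, int, int], float]


def fit_arima(series, order_grid=None, tie_window: float = 2.0) -> ArimaFit:
    """Maximum-likelihood ARIMA fits over a (p, d, q) grid, AIC-selected.

    Orders within ``tie_window`` of the minimum AIC are treated as
    equivalent and the most parsimonious one wins (the conventional
    "difference of less than 2 AIC units" equivalence).  Non-convergent
    orders are skipped with a warning; if every order fails, an error is
    raised.
    """
    from statsmodels.tsa.arima.model import ARIMA

    y = np.asarray(series, float)
    if y.size < 30:
        raise InferenceError(f"series length {y.size} < 30")
    if order_grid is None:
        order_grid = [(p, d, q) for p in range(3) for d in range(2) for q in range(3)]
    table: dict[tuple[int, int, int], float] = {}
    fits = {}
    for order in order_grid:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = ARIMA(y, order=order, trend="c" if order[1] == 0 else "n").fit()
            if not np.isfinite(fit.aic):
                raise ValueError("non-finite AIC")
            table[tuple(order)] = float(fit.aic)
            fits[tuple(order)] = fit
        except Exception as exc:  # statsmodels raises several exception types
            warnings.warn(f"ARIMA{tuple(order)} failed ({exc}); skipped")
    if not table:
        raise InferenceError("no ARIMA order converged")
    best_aic = min(table.values())
    near = [o for o in table if table[o] <= best_aic + tie_window]
    best = min(near, key=lambda o: (sum(o), table[o]))
    fit = fits[best]
    params = fit.params
    names = fit.param_names
    ar = np.array([params[i] for i, nm in enumerate(names) if nm.startswith("ar.")])
    ma = np.array([params[i] for i, nm in enumerate(names) if nm.startswith("ma.")])
    const = next((params[i] for i, nm in enumerate(names) if nm in ("const", "intercept")), 0.0)
    return ArimaFit(order=best, ar_params=ar, ma_params=ma, intercept=float(const),
                    aic=table[best], residuals=np.asarray(fit.resid), aic_table=table)


# ---------------------------------------------------------------------------
# threshold-crossing lag
# ---------------------------------------------------------------------------

def _first_crossing(months: np.ndarray, traj: np.ndarray, threshold: float) -> float | None:
    for i in range(1, len(traj)):
        if traj[i - 1] < threshold <= traj[i]:
            frac = (threshold - traj[i - 1]) / (traj[i] - traj[i - 1])
            return float(months[i - 1] + frac * (months[i] - months[i - 1]))
    if traj[0] >= threshold:
        return float(months[0])
    return None


def threshold_crossing_lag(months, traj_a, traj_b, threshold: float) -> float | None:
    """Months by which trajectory B reaches ``threshold`` after trajectory A.

    Both trajectories are normalised improvement curves on the same monthly
    grid; crossings are linearly interpolated.  Returns None when either
    trajectory never crosses.
    """
    months = np.asarray(months, float)
    ca = _first_crossing(months, np.asarray(traj_a, float), threshold)
    cb = _first_crossing(months, np.asarray(traj_b, float), threshold)
    if ca is None or cb is None:
        warnings.warn("a trajectory never crosses the threshold")
        return None
    return cb - ca
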