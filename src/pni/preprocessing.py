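"""Cleaning, normalisation, feature engineering and temporal splitting.

Pipeline order (fixed): 3-SD outlier screen (flagged cells become missing)
-> chained-equations imputation -> Shapiro-Wilk-gated log transform and
scaling -> feature engineering.  Scaling parameters are always estimated on
training athletes only and applied unchanged to test athletes.

The temporal split reconciles the 80/20 holdout with forward-chaining
cross-validation: athletes are split 80/20 (stratified by dietary group),
and within training athletes five chronologically ordered folds validate on
later time windows separated from their training window by a two-month gap.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .config import PreprocessConfig
from .panel import AthletePanel

#: one year expressed in bi-weekly assessment steps (seasonal terms)
STEPS_PER_YEAR = 26.0


class PreprocessError(ValueError):
    pass


# ---------------------------------------------------------------------------
# outlier screen
# ---------------------------------------------------------------------------

def screen_outliers(panel: AthletePanel, config: PreprocessConfig) -> tuple[AthletePanel, pd.DataFrame]:
    """Flag cells more than ``outlier_k`` SDs from the pooled feature mean.

    The comparison is strict (> k SD; a value at exactly k SDs is retained)
    and flagged cells are set to missing so imputation refills them.
    Constant features (SD = 0) produce no flags.
    """
    out = panel.copy()
    df = out.data
    flags = []
    for f in out.feature_names:
        col = df[f]
        obs = col.dropna()
        if len(obs) == 0:
            raise PreprocessError(f"feature {f!r} has no observed values")
        if len(obs) < 2:
            continue
        mu, sd = obs.mean(), obs.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            continue
        hit = (col - mu).abs() > config.outlier_k * sd
        for r in np.flatnonzero(hit.to_numpy()):
            flags.append((df.at[r, "athlete_id"], df.at[r, "time_index"], f,
                          float(df.at[r, f])))
            df.at[r, f] = np.nan
    flag_df = pd.DataFrame(flags, columns=["athlete_id", "time_index", "feature", "value"])
    out.attrs["outlier_flags"] = len(flag_df)
    return out, flag_df


# ---------------------------------------------------------------------------
# chained-equations imputation
# ---------------------------------------------------------------------------

def impute_chained(panel: AthletePanel, config: PreprocessConfig) -> AthletePanel:
    """Complete the panel by Multiple Imputation by Chained Equations.

    Chained Bayesian-ridge regressions (one completed dataset, seeded).
    Observed cells are left untouched.  A feature missing in more than half
    of all cells is warned about and effectively falls back to its
    mean-initialised imputation.
    """
    from sklearn.experimental import enable_iterative_imputer  # noqa: F401
    from sklearn.impute import IterativeImputer

    out = panel.copy()
    feats = out.feature_names
    frac = out.missing_fraction_per_athlete()
    if (frac >= 0.2).any():
        bad = frac[frac >= 0.2].index.tolist()
        raise PreprocessError(
            f"athletes exceed the 20% missing-value inclusion limit: {bad[:5]}")
    X = out.data[feats].to_numpy(float)
    if not np.isnan(X).any():
        return out
    col_frac = np.isnan(X).mean(axis=0)
    for j in np.flatnonzero(col_frac > 0.5):
        warnings.warn(f"feature {feats[j]!r} is {col_frac[j]:.0%} missing; "
                      "imputation falls back toward the mean")
    imputer = IterativeImputer(max_iter=config.mice_iterations,
                               random_state=config.mice_seed,
                               sample_posterior=False, keep_empty_features=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        completed = imputer.fit_transform(X)
    observed = ~np.isnan(X)
    completed[observed] = X[observed]
    out.data[feats] = completed
    out.attrs["imputed_cells"] = int((~observed).sum())
    return out


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

@dataclass
class FeatureScaler:
    mode: str            # "zscore" | "log_then_zscore" | "rescale_0_10" | "constant"
    mean: float = 0.0
    sd: float = 1.0
    lo: float = 0.0
    hi: float = 1.0


@dataclass
class NormalizationParams:
    scalers: dict[str, FeatureScaler]

    def transform(self, panel: AthletePanel) -> AthletePanel:
        out = panel.copy()
        for f, s in self.scalers.items():
            if f not in out.data.columns:
                continue
            col = out.data[f].to_numpy(float)
            if s.mode == "constant":
                out.data[f] = np.zeros_like(col)
            elif s.mode == "rescale_0_10":
                out.data[f] = 10.0 * (col - s.lo) / (s.hi - s.lo)
            else:
                if s.mode == "log_then_zscore":
                    if np.nanmin(col) <= 0:
                        raise PreprocessError(
                            f"log transform requested for {f!r} but values <= 0 present")
                    col = np.log(col)
                out.data[f] = (col - s.mean) / s.sd
        return out


def fit_normalizer(panel: AthletePanel, config: PreprocessConfig,
                   train_athletes=None) -> NormalizationParams:
    """Estimate scaling parameters on training athletes only.

    A feature is log-transformed before z-scoring when it (i) fails the
    Shapiro-Wilk test at ``shapiro_alpha``, (ii) is right/left skewed beyond
    ``skew_gate`` (guarding against trivially significant p-values at large
    n), and (iii) is strictly positive.  Features listed in
    ``config.rescale_0_10`` are min-max rescaled to the 0-10 scale instead.
    """
    df = panel.data
    if train_athletes is not None:
        df = df[df["athlete_id"].isin(set(train_athletes))]
    scalers: dict[str, FeatureScaler] = {}
    for f in panel.feature_names:
        vals = df[f].dropna().to_numpy(float)
        if vals.size == 0:
            raise PreprocessError(f"feature {f!r} has no observed values")
        if np.ptp(vals) == 0:
            warnings.warn(f"constant feature {f!r}; z-score defined as all zeros")
            scalers[f] = FeatureScaler("constant")
            continue
        if f in config.rescale_0_10:
            scalers[f] = FeatureScaler("rescale_0_10", lo=float(vals.min()),
                                       hi=float(vals.max()))
            continue
        sample = vals if vals.size <= 4500 else np.random.default_rng(0).choice(
            vals, 4500, replace=False)
        p_norm = stats.shapiro(sample).pvalue
        skew = stats.skew(vals)
        if p_norm < config.shapiro_alpha and abs(skew) > config.skew_gate and vals.min() > 0:
            logged = np.log(vals)
            scalers[f] = FeatureScaler("log_then_zscore", mean=float(logged.mean()),
                                       sd=float(logged.std(ddof=1)))
        else:
            scalers[f] = FeatureScaler("zscore", mean=float(vals.mean()),
                                       sd=float(vals.std(ddof=1)))
    return NormalizationParams(scalers)


def normalize_features(panel: AthletePanel, config: PreprocessConfig,
                       train_athletes=None) -> tuple[AthletePanel, NormalizationParams]:
    """Fit scaling on training athletes and apply it to the whole panel."""
    if panel.data[panel.feature_names].isna().any().any():
        raise PreprocessError("normalize_features requires a complete panel; impute first")
    params = fit_normalizer(panel, config, train_athletes)
    return params.transform(panel), params


# ---------------------------------------------------------------------------
# feature engineering
# ---------------------------------------------------------------------------

def engineer_features(panel: AthletePanel,
                      interactions: list[tuple[str, str]] | None = None,
                      composites: dict[str, list[str]] | None = None,
                      season_period: float = STEPS_PER_YEAR) -> AthletePanel:
    """Add interaction, seasonal and composite-index columns.

    Interactions are cellwise products of a nutrition column and a
    training-phase column; seasonal terms are sin/cos of the annual cycle in
    ``time_index``; composite indices are means of z-scored member columns.
    Original columns are preserved.
    """
    out = panel.copy()
    df = out.data
    for a, b in interactions or []:
        for c in (a, b):
            if c not in df.columns:
                raise PreprocessError(f"unknown column {c!r} in interaction config")
        df[f"ix_{a}_x_{b}"] = df[a] * df[b]
    phase = 2.0 * np.pi * df["time_index"].to_numpy(float) / season_period
    df["season_sin"] = np.sin(phase)
    df["season_cos"] = np.cos(phase)
    for name, members in (composites or {}).items():
        missing = [m for m in members if m not in df.columns]
        if missing:
            raise PreprocessError(f"unknown columns {missing} in composite {name!r}")
        zs = []
        for m in members:
            col = df[m].to_numpy(float)
            sd = col.std()
            zs.append((col - col.mean()) / (sd if sd > 0 else 1.0))
        df[name] = np.mean(zs, axis=0)
    return out


def weekly_average(frame: pd.DataFrame, value_columns: list[str],
                   time_column: str = "time_index", factor: int = 2) -> pd.DataFrame:
    """Collapse a finer-grained time series to averages of ``factor``
    consecutive assessments (e.g. daily logs to weekly means)."""
    g = frame.copy()
    g["_bin"] = g[time_column] // factor
    keys = [c for c in ("athlete_id", "_bin") if c in g.columns]
    agg = g.groupby(keys, as_index=False)[value_columns].mean()
    return agg.rename(columns={"_bin": time_column})


# ---------------------------------------------------------------------------
# temporal split
# ---------------------------------------------------------------------------

@dataclass
class Fold:
    train_times: tuple[int, int]   # [start, end) exclusive
    gap_times: tuple[int, int]
    valid_times: tuple[int, int]   # [start, end) exclusive


@dataclass
class SplitPlan:
    train_athletes: list[str]
    test_athletes: list[str]
    folds: list[Fold]
    gap_steps: int

    def validate(self) -> "SplitPlan":
        if set(self.train_athletes) & set(self.test_athletes):
            raise PreprocessError("train and test athlete sets overlap")
        for f in self.folds:
            if f.train_times[1] - 1 + self.gap_steps > f.valid_times[0] - 1:
                raise PreprocessError(
                    f"fold violates the temporal gap: train ends at "
                    f"{f.train_times[1] - 1}, validation starts at {f.valid_times[0]}, "
                    f"gap {self.gap_steps}")
        return self

    def to_json(self, path: str | Path) -> None:
        payload = {"train_athletes": list(self.train_athletes),
                   "test_athletes": list(self.test_athletes),
                   "gap_steps": self.gap_steps,
                   "folds": [{"train": f.train_times, "gap": f.gap_times,
                              "valid": f.valid_times} for f in self.folds]}
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitPlan":
        p = json.loads(Path(path).read_text())
        folds = [Fold(tuple(f["train"]), tuple(f["gap"]), tuple(f["valid"]))
                 for f in p["folds"]]
        return cls(p["train_athletes"], p["test_athletes"], folds,
                   p["gap_steps"]).validate()


def make_temporal_split(panel: AthletePanel, train_frac: float = 0.8,
                        n_folds: int = 5, gap_steps: int = 4,
                        val_window: int = 3, seed: int = 0,
                        min_train_len: int = 2) -> SplitPlan:
    """80/20 athlete holdout plus forward-chaining time folds.

    The athlete holdout is stratified by dietary group; folds use contiguous
    validation windows of ``val_window`` steps ending one step before the
    series end, each trained on all time points up to ``gap_steps`` before
    the window (so the training window always precedes validation by at
    least the gap — two months at bi-weekly sampling and ``gap_steps=4``).
    """
    t = panel.n_timepoints
    first_start = t - val_window * n_folds - 1
    if first_start - gap_steps < min_train_len:
        raise PreprocessError(
            f"T={t} cannot host {n_folds} folds of window {val_window} with "
            f"gap {gap_steps}: first validation start would be {first_start}, "
            f"leaving {first_start - gap_steps} < {min_train_len} training steps")

    meta = panel.meta()
    rng = np.random.default_rng(seed)
    n = len(meta)
    n_test_target = int(round((1.0 - train_frac) * n))
    test: list[str] = []
    if "group" in meta.columns:
        shares = []
        for g, sub in meta.groupby("group", sort=True):
            ids = sub.index.to_numpy()
            exact = (1.0 - train_frac) * len(ids)
            shares.append((g, ids, int(np.floor(exact)), exact - np.floor(exact)))
        remainder = n_test_target - sum(s[2] for s in shares)
        shares.sort(key=lambda s: -s[3])
        for i, (g, ids, k, _) in enumerate(shares):
            k += 1 if i < remainder else 0
            test.extend(rng.permutation(ids)[:k].tolist())
    else:
        test = rng.permutation(meta.index.to_numpy())[:n_test_target].tolist()
    train = sorted(set(meta.index) - set(test))

    folds = []
    for i in range(n_folds):
        start = first_start + i * val_window
        folds.append(Fold(train_times=(0, start - gap_steps),
                          gap_times=(start - gap_steps, start),
                          valid_times=(start, start + val_window)))
    return SplitPlan(sorted(train), sorted(test), folds, gap_steps).validate()
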