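"""Shapley-value attribution for fitted predictors.

Permutation-sampling estimator: for every instance, Monte-Carlo draws pair a
background row with a random feature ordering; walking from the background
to the instance one feature at a time telescopes the prediction difference
into per-feature attributions.  By construction each draw's attributions sum
exactly to f(x) - f(background draw), so local accuracy (efficiency) holds
up to Monte-Carlo error in the background expectation, and the symmetry and
null-player axioms hold in expectation.

The attribution target in the pipeline is the hybrid model's fused
regression head for the primary psychological outcome, viewed as a function
of the per-athlete static feature table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class AttributionError(ValueError):
    pass


@dataclass
class ImportanceTable:
    """Global mean-|Shapley| importances plus per-instance signed values."""

    importance: pd.Series          # feature -> mean |phi|, descending
    values: pd.DataFrame           # instances x features, signed
    base_values: np.ndarray        # per-instance MC background expectation
    predictions: np.ndarray

    @property
    def ranking(self) -> list[str]:
        return self.importance.index.tolist()

    def efficiency_gap(self) -> np.ndarray:
        """Per-instance |sum(phi) - (f(x) - base)|; ~0 by construction."""
        return np.abs(self.values.sum(axis=1).to_numpy()
                      + self.base_values - self.predictions)


def shap_importance(predict_fn, data: pd.DataFrame,
                    background: pd.DataFrame | None = None,
                    n_samples: int = 128, seed: int = 0,
                    background_size: int = 50,
                    groups: dict[str, list[str]] | None = None) -> ImportanceTable:
    """Monte-Carlo permutation Shapley values for ``predict_fn`` on ``data``.

    ``n_samples`` is the number of (background row, permutation) draws per
    instance; each costs (players + 1) model evaluations.  ``background``
    defaults to a fixed subsample of ``data`` of size ``background_size``.
    ``groups`` optionally defines coalition players spanning several columns
    (e.g. a feature's baseline, window-mean and slope views attributed as
    one unit); by default every column is its own player.
    """
    if not isinstance(data, pd.DataFrame):
        data = pd.DataFrame(np.asarray(data, float))
    feats = list(data.columns)
    col_index = {c: i for i, c in enumerate(feats)}
    if groups is None:
        players = list(feats)
        member_idx = [[col_index[c]] for c in feats]
    else:
        players = list(groups)
        for name, cols in groups.items():
            unknown = [c for c in cols if c not in col_index]
            if unknown:
                raise AttributionError(f"group {name!r} names unknown columns {unknown}")
        member_idx = [[col_index[c] for c in groups[p]] for p in players]
    d = len(players)
    if n_samples < d + 2:
        raise AttributionError(
            f"n_samples={n_samples} too small; need at least n_players + 2 = {d + 2}")
    rng = np.random.default_rng(seed)
    X = data.to_numpy(float)
    n = len(X)
    if background is None:
        idx = rng.choice(n, size=min(background_size, n), replace=False)
        B = X[np.sort(idx)]
    else:
        B = background.to_numpy(float) if isinstance(background, pd.DataFrame) else np.asarray(background, float)

    phi = np.zeros((n, d))
    base = np.zeros(n)
    for _ in range(n_samples):
        b = B[rng.integers(0, len(B))]
        perm = rng.permutation(d)
        Z = np.tile(b, (n, 1))
        prev = np.asarray(predict_fn(Z), float).reshape(n)
        base += prev
        for j in perm:
            Z[:, member_idx[j]] = X[:, member_idx[j]]
            cur = np.asarray(predict_fn(Z), float).reshape(n)
            phi[:, j] += cur - prev
            prev = cur
    phi /= n_samples
    base /= n_samples
    pred = np.asarray(predict_fn(X), float).reshape(n)
    values = pd.DataFrame(phi, index=data.index, columns=players)
    importance = values.abs().mean(axis=0).sort_values(ascending=False)
    return ImportanceTable(importance=importance, values=values,
                           base_values=base, predictions=pred)


@dataclass
class DependencyResult:
    feature: str
    colour_feature: str | None
    records: pd.DataFrame          # feature_value, shap_value, colour_value
    spearman_trend: float | None
    trend_p: float | None


def shap_dependency(predict_fn, data: pd.DataFrame, feature: str,
                    colour_feature: str | None = None,
                    table: ImportanceTable | None = None,
                    n_samples: int = 128, seed: int = 0) -> DependencyResult:
    """Per-instance dependency of one feature's Shapley value on its value.

    Reuses a precomputed :class:`ImportanceTable` when given.  Reports a
    Spearman monotone-trend statistic; a constant feature yields NA with a
    warning.
    """
    if feature not in data.columns:
        raise AttributionError(f"feature {feature!r} not in data")
    if table is None:
        table = shap_importance(predict_fn, data, n_samples=n_samples, seed=seed)
    records = pd.DataFrame({
        "feature_value": data[feature].to_numpy(float),
        "shap_value": table.values[feature].to_numpy(),
    })
    if colour_feature is not None:
        records["colour_value"] = data[colour_feature].to_numpy(float)
    if np.ptp(records["feature_value"].to_numpy()) == 0:
        warnings.warn(f"constant feature {feature!r}; dependency trend undefined")
        trend, p = None, None
    else:
        r = stats.spearmanr(records["feature_value"], records["shap_value"])
        trend, p = float(r.statistic), float(r.pvalue)
    return DependencyResult(feature=feature, colour_feature=colour_feature,
                            records=records, spearman_trend=trend, trend_p=p)


def linear_shap_oracle(coefs: np.ndarray, X: np.ndarray,
                       background_mean: np.ndarray) -> np.ndarray:
    """Closed-form Shapley values of a linear model with independent
    features: phi_j = beta_j (x_j - E[x_j])."""
    return np.asarray(coefs) * (np.asarray(X, float) - np.asarray(background_mean))
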