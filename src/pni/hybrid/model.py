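"""Hybrid temporal/boosting predictor with attention-weighted fusion.

Two branches see different views of each athlete: the temporal branch (a
stacked LSTM) consumes the bi-weekly feature sequences, while the boosting
branch (XGBoost) consumes a static table of baseline values plus temporal
aggregates (window means and slopes).  Their representations are fused by a
learned attention over the concatenated projections,

    z = alpha_1 h_LSTM + alpha_2 h_XGB,   alpha = softmax(W [h1; h2]),

with a linear head per outcome on z.  Branches are trained separately and
frozen; the fusion projection, attention and heads are then trained on the
branch outputs.  All cross-validation respects the forward-chaining split
plan: training windows precede validation windows by at least the
configured gap, and test athletes' outcomes are never touched in training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ..config import BoostBranchConfig, HybridConfig, TemporalBranchConfig
from ..panel import AthletePanel
from ..preprocessing import PreprocessError, SplitPlan
from .lstm import TemporalNet


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# data views
# ---------------------------------------------------------------------------

def build_sequences(panel: AthletePanel, athletes, t_range: tuple[int, int],
                    features: list[str] | None = None) -> np.ndarray:
    """(n, T_window, D) tensor for the given athletes and time window."""
    feats = features or panel.feature_names
    sub = panel.data[panel.data["athlete_id"].isin(set(athletes))]
    sub = sub[(sub["time_index"] >= t_range[0]) & (sub["time_index"] < t_range[1])]
    sub_panel = AthletePanel(sub.copy())
    X = sub_panel.tensor(feats)
    if np.isnan(X).any():
        raise ModelError("sequences contain missing values; impute first")
    return X


def window_target(panel: AthletePanel, athletes, outcome: str,
                  t_range: tuple[int, int]) -> np.ndarray:
    """Mean outcome over a future time window, one value per athlete."""
    sub = panel.data[panel.data["athlete_id"].isin(set(athletes))]
    sub = sub[(sub["time_index"] >= t_range[0]) & (sub["time_index"] < t_range[1])]
    return sub.groupby("athlete_id", sort=True)[outcome].mean().to_numpy()


def make_static_features(panel: AthletePanel, athletes,
                         t_range: tuple[int, int]) -> pd.DataFrame:
    """Per-athlete static table: baseline values + window means and slopes."""
    feats = panel.feature_names
    sub = panel.data[panel.data["athlete_id"].isin(set(athletes))]
    base = sub[sub["time_index"] == sub["time_index"].min()]
    base = base.set_index("athlete_id")[feats].sort_index()
    win = sub[(sub["time_index"] >= t_range[0]) & (sub["time_index"] < t_range[1])]
    means = win.groupby("athlete_id", sort=True)[feats].mean()

    def _slope(g):
        t = g["time_index"].to_numpy(float)
        t = t - t.mean()
        denom = (t ** 2).sum()
        out = {}
        for f in feats:
            v = g[f].to_numpy(float)
            out[f] = (t * (v - v.mean())).sum() / denom if denom > 0 else 0.0
        return pd.Series(out)

    slopes = win.groupby("athlete_id", sort=True).apply(_slope, include_groups=False)
    table = pd.concat({"base": base, "mean": means, "slope": slopes}, axis=1)
    table.columns = [f"{a}_{b}" for a, b in table.columns]
    return table


# ---------------------------------------------------------------------------
# branches
# ---------------------------------------------------------------------------

def train_temporal_branch(X: np.ndarray, y: np.ndarray,
                          config: TemporalBranchConfig,
                          val_frac: float = 0.2) -> tuple[TemporalNet, dict]:
    """Fit the stacked-LSTM branch with an internal early-stopping split."""
    y2 = y[:, None] if y.ndim == 1 else y
    net = TemporalNet(X.shape[2], y2.shape[1], config)
    n = len(X)
    if val_frac > 0 and n >= 10:
        rng = np.random.default_rng(config.seed + 7)
        idx = rng.permutation(n)
        n_val = max(int(round(val_frac * n)), 1)
        vi, ti = idx[:n_val], idx[n_val:]
        history = net.fit(X[ti], y2[ti], X[vi], y2[vi])
    else:
        history = net.fit(X, y2)
    return net, history


def train_boost_branch(X_static: pd.DataFrame, y: np.ndarray,
                       config: BoostBranchConfig) -> list:
    """Fit one gradient-boosting regressor per outcome column."""
    import xgboost as xgb

    y2 = y[:, None] if y.ndim == 1 else y
    if len(X_static) != len(y2):
        raise ModelError(f"feature/label length mismatch: {len(X_static)} vs {len(y2)}")
    models = []
    for j in range(y2.shape[1]):
        m = xgb.XGBRegressor(
            n_estimators=config.n_estimators, max_depth=config.max_depth,
            learning_rate=config.learning_rate, subsample=config.subsample,
            random_state=config.seed, n_jobs=1, tree_method="hist",
            verbosity=0)
        m.fit(X_static.to_numpy(), y2[:, j])
        models.append(m)
    return models


def boost_predict(models: list, X_static: pd.DataFrame) -> np.ndarray:
    return np.column_stack([m.predict(X_static.to_numpy()) for m in models])


# ---------------------------------------------------------------------------
# attention fusion
# ---------------------------------------------------------------------------

def fuse_attention(h_lstm: np.ndarray, h_boost: np.ndarray,
                   W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Attention-weighted convex combination of two projected branch outputs.

    ``h_lstm`` and ``h_boost`` must share a common dimension k; ``W`` maps
    the concatenation (2k) to two attention logits.  Returns (z, alpha) with
    alpha rows on the 2-simplex.
    """
    if h_lstm.shape != h_boost.shape:
        raise ModelError(
            f"branch outputs must share a dimension after projection: "
            f"{h_lstm.shape} vs {h_boost.shape}")
    concat = np.concatenate([h_lstm, h_boost], axis=1)
    if W.shape != (concat.shape[1], 2):
        raise ModelError(f"W must be ({concat.shape[1]}, 2), got {W.shape}")
    logits = concat @ W
    logits = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    alpha = e / e.sum(axis=1, keepdims=True)
    z = alpha[:, :1] * h_lstm + alpha[:, 1:] * h_boost
    return z, alpha


class FusionHead:
    """Trainable projection + attention + linear heads on frozen branches."""

    def __init__(self, d1: int, d2: int, k: int, n_out: int, seed: int = 0,
                 lr: float = 0.01, epochs: int = 600, weight_decay: float = 1e-4,
                 gate_decay: float = 3e-2):
        rng = np.random.default_rng(seed)
        # identity-block initialisation: the fusion starts at the (attention-
        # weighted) average of the standardised branch outputs, so training
        # only has to reweight the branches rather than rediscover them
        def _ident(d, k_):
            m = 0.01 * rng.standard_normal((d, k_))
            for i in range(min(d, k_)):
                m[i, i] += 1.0
            return m

        self.p = {
            "P1": _ident(d1, k),
            "P2": _ident(d2, k),
            "W": np.zeros((2 * k, 2)),
            "w": _ident(k, n_out),
            "b": np.zeros(n_out),
        }
        # the attention gate is regularised much harder than the linear
        # parts: input-dependent gating extrapolates poorly from small
        # stacking samples, so it must earn its keep
        self.lr, self.epochs, self.wd = lr, epochs, weight_decay
        self.gate_wd = gate_decay

    def _core(self, h1, h2):
        g1, g2 = h1 @ self.p["P1"], h2 @ self.p["P2"]
        z, alpha = fuse_attention(g1, g2, self.p["W"])
        return g1, g2, z, alpha, z @ self.p["w"] + self.p["b"]

    def _forward(self, h1, h2):
        if hasattr(self, "_h1_stats"):
            h1 = (h1 - self._h1_stats[0]) / self._h1_stats[1]
            h2 = (h2 - self._h2_stats[0]) / self._h2_stats[1]
        return self._core(h1, h2)

    def predict(self, h1, h2):
        out = self._forward(h1, h2)[4]
        if hasattr(self, "_y_mean"):
            out = out * self._y_sd + self._y_mean
        return out

    def attention(self, h1, h2):
        return self._forward(h1, h2)[3]

    #: selection margins: a more flexible fusion variant must beat the
    #: simpler one by this factor in internal CV to be kept
    _MARGINS = {"boost": 1.0, "temporal": 1.0, "stack": 1.2, "gated": 1.5}

    def _passthrough_params(self, init: dict, which: str) -> dict:
        """Exact single-branch passthrough: the fusion reproduces the raw
        branch prediction (gate saturated, head undoing the internal
        standardisation)."""
        p = {k_: np.zeros_like(p_) for k_, p_ in init.items()}
        k = init["P1"].shape[1]
        n_out = init["w"].shape[1]
        mu_h, sd_h = (self._h1_stats if which == "temporal" else self._h2_stats)
        key = "P1" if which == "temporal" else "P2"
        for i in range(min(n_out, k)):
            p[key][i, i] = 1.0
            # z = 0.5 * h_s, so the head slope doubles the standardised value
            p["w"][i, i] = 2.0 * sd_h[i] / self._y_sd[i]
        p["b"] = (mu_h[:n_out] - self._y_mean) / self._y_sd
        return p

    def fit(self, h1, h2, y, seed: int = 0, patience: int = 60,
            gate: str = "auto"):
        """Train projections, gate and heads on (frozen) branch outputs.

        Four variants are considered — boost-only, temporal-only, constant-
        attention stack, and input-dependent (gated) attention — and an
        internal 4-fold cross-validation over the stacking rows selects one,
        with complexity margins so the flexible variants must demonstrably
        help.  Single-branch variants are the attention fusion with the
        other projection pinned at zero, i.e. the gate saturated at one
        branch.  ``gate="on"`` forces the gated variant; ``gate="off"``
        excludes it.
        """
        y = y[:, None] if y.ndim == 1 else y
        # standardise targets and branch inputs internally (scale-free
        # optimisation); predict() restores the outcome scale
        self._y_mean, ysd = y.mean(0), y.std(0)
        self._y_sd = np.where(ysd > 0, ysd, 1.0)
        y = (y - self._y_mean) / self._y_sd
        self._h1_stats = (h1.mean(0), np.where(h1.std(0) > 0, h1.std(0), 1.0))
        self._h2_stats = (h2.mean(0), np.where(h2.std(0) > 0, h2.std(0), 1.0))
        h1 = (h1 - self._h1_stats[0]) / self._h1_stats[1]
        h2 = (h2 - self._h2_stats[0]) / self._h2_stats[1]
        n_all = len(h1)
        init = {k_: p_.copy() for k_, p_ in self.p.items()}
        # input-dependent gating is opt-in: with the stacking sample sizes
        # typical here (tens of athletes) a trained gate is statistically
        # unsupportable and extrapolates poorly, so the default keeps the
        # attention weights constant (W = 0 -> alpha = (1/2, 1/2))
        if gate == "on":
            modes = ["gated"]
        elif gate == "full":
            modes = ["boost", "temporal", "stack", "gated"]
        else:
            modes = ["boost", "temporal", "stack"]

        chosen = "stack"
        if len(modes) > 1 and n_all >= 24:
            rng = np.random.default_rng(seed + 101)
            order = rng.permutation(n_all)
            folds = np.array_split(order, 4)
            losses = {}
            for mode in modes:
                fold_losses = []
                for va in folds:
                    tr = np.setdiff1d(np.arange(n_all), va)
                    self.p = self._mode_init(init, mode)
                    if mode in ("boost", "temporal"):
                        self.p = self._passthrough_params(init, mode)
                    else:
                        self._fit_loop(h1[tr], h2[tr], y[tr], mode)
                    resid = self._core(h1[va], h2[va])[4] - y[va]
                    fold_losses.append(float((resid ** 2).mean()))
                losses[mode] = np.mean(fold_losses) * self._MARGINS[mode]
            chosen = min(losses, key=losses.get)
        elif len(modes) == 1:
            chosen = modes[0]

        if chosen in ("boost", "temporal"):
            self.p = self._passthrough_params(init, chosen)
        else:
            self.p = self._mode_init(init, chosen)
            self._fit_loop(h1, h2, y, chosen)
        self.mode = chosen
        return self

    @staticmethod
    def _mode_init(init: dict, mode: str) -> dict:
        p = {k_: p_.copy() for k_, p_ in init.items()}
        if mode == "boost":
            p["P1"][:] = 0.0
        elif mode == "temporal":
            p["P2"][:] = 0.0
        return p

    def _fit_loop(self, h1, h2, y, mode: str) -> None:
        frozen = {"boost": {"P1", "W"}, "temporal": {"P2", "W"},
                  "stack": {"W"}, "gated": set()}[mode]
        p = self.p
        m = {k_: np.zeros_like(v) for k_, v in p.items()}
        v = {k_: np.zeros_like(v_) for k_, v_ in p.items()}
        b1, b2, eps = 0.9, 0.999, 1e-8
        for step in range(1, self.epochs + 1):
            g1, g2, z, alpha, yhat = self._core(h1, h2)
            err = yhat - y
            dy = 2.0 * err / err.size
            grads = {}
            grads["w"] = z.T @ dy
            grads["b"] = dy.sum(0)
            dz = dy @ p["w"].T
            dalpha = np.column_stack([(dz * g1).sum(1), (dz * g2).sum(1)])
            dg1 = alpha[:, :1] * dz
            dg2 = alpha[:, 1:] * dz
            # softmax backward
            dlogit = alpha * (dalpha - (dalpha * alpha).sum(1, keepdims=True))
            concat = np.concatenate([g1, g2], axis=1)
            grads["W"] = concat.T @ dlogit
            dconcat = dlogit @ p["W"].T
            k = g1.shape[1]
            dg1 = dg1 + dconcat[:, :k]
            dg2 = dg2 + dconcat[:, k:]
            grads["P1"] = h1.T @ dg1
            grads["P2"] = h2.T @ dg2
            lr_t = self.lr * np.sqrt(1 - b2 ** step) / (1 - b1 ** step)
            for k_, g in grads.items():
                if k_ in frozen:
                    continue
                m[k_] = b1 * m[k_] + (1 - b1) * g
                v[k_] = b2 * v[k_] + (1 - b2) * g ** 2
                # decoupled weight decay (AdamW); the attention gate is
                # shrunk much harder than the linear parts
                wd_k = self.gate_wd if k_ == "W" else (0.0 if k_ == "b" else self.wd)
                p[k_] -= lr_t * m[k_] / (np.sqrt(v[k_]) + eps) + self.lr * wd_k * p[k_]


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    rmse: dict[str, float] = field(default_factory=dict)
    r_squared: dict[str, float] = field(default_factory=dict)
    mape: dict[str, float] = field(default_factory=dict)
    auc: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    threshold: float | None = None
    per_fold: pd.DataFrame | None = None


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the normalised Mann-Whitney rank statistic (ties get 1/2)."""
    labels = np.asarray(labels, bool)
    n1, n0 = int(labels.sum()), int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise ModelError("AUC undefined for single-class labels")
    ranks = stats.rankdata(scores)
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def youden_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Threshold maximising sensitivity + specificity - 1 (positive: score >= t)."""
    labels = np.asarray(labels, bool)
    cand = np.unique(scores)
    best_t, best_j = cand[0], -np.inf
    for t in cand:
        pred = scores >= t
        sens = (pred & labels).sum() / max(labels.sum(), 1)
        spec = (~pred & ~labels).sum() / max((~labels).sum(), 1)
        j = sens + spec - 1.0
        if j > best_j:
            best_j, best_t = j, t
    return float(best_t)


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> tuple[float, float]:
    """(sensitivity, specificity) from confusion counts."""
    return tp / (tp + fn), tn / (tn + fp)


def evaluate(predictions: np.ndarray, truth: np.ndarray,
             outcomes: list[str] | None = None,
             class_scores: np.ndarray | None = None,
             class_labels: np.ndarray | None = None,
             threshold: float | None = None,
             mape_floor: float = 0.1) -> EvalReport:
    """Regression metrics per outcome plus optional responder classification.

    MAPE excludes truth values with magnitude below ``mape_floor``.  AUC is
    the rank statistic; sensitivity/specificity are computed at ``threshold``
    (default: Youden-optimal on the supplied scores).  Single-class labels
    yield NA classification metrics with a warning.
    """
    pred = np.atleast_2d(np.asarray(predictions, float).T).T
    true = np.atleast_2d(np.asarray(truth, float).T).T
    if pred.shape != true.shape:
        raise ModelError(f"shape mismatch: {pred.shape} vs {true.shape}")
    names = outcomes or [f"y{j}" for j in range(pred.shape[1])]
    rep = EvalReport()
    for j, name in enumerate(names):
        err = pred[:, j] - true[:, j]
        rep.rmse[name] = float(np.sqrt((err ** 2).mean()))
        ss_tot = ((true[:, j] - true[:, j].mean()) ** 2).sum()
        rep.r_squared[name] = float(1.0 - (err ** 2).sum() / ss_tot) if ss_tot > 0 else float("nan")
        big = np.abs(true[:, j]) >= mape_floor
        rep.mape[name] = (float(100.0 * np.abs(err[big] / true[:, j][big]).mean())
                          if big.any() else float("nan"))
    if class_labels is not None:
        labels = np.asarray(class_labels, bool)
        if labels.all() or (~labels).all():
            warnings.warn("single-class labels; classification metrics undefined")
        else:
            rep.auc = rank_auc(class_scores, labels)
            t = threshold if threshold is not None else youden_threshold(class_scores, labels)
            pred_pos = class_scores >= t
            rep.sensitivity, rep.specificity = confusion_metrics(
                int((pred_pos & labels).sum()), int((~pred_pos & labels).sum()),
                int((~pred_pos & ~labels).sum()), int((pred_pos & ~labels).sum()))
            rep.threshold = float(t)
    return rep


# ---------------------------------------------------------------------------
# end-to-end hybrid
# ---------------------------------------------------------------------------

@dataclass
class TrainedHybrid:
    config: HybridConfig
    plan: SplitPlan
    outcomes: list[str]
    primary: str
    temporal: TemporalNet
    boost: list
    fusion: FusionHead
    features: list[str]
    input_range: tuple[int, int]
    target_range: tuple[int, int]
    responder_threshold: float | None
    cv_report: pd.DataFrame

    def predict(self, panel: AthletePanel, athletes) -> pd.DataFrame:
        athletes = sorted(athletes)
        X = build_sequences(panel, athletes, self.input_range, self.features)
        Xs = make_static_features(panel, athletes, self.input_range)
        h1 = self.temporal.predict(X)
        h2 = boost_predict(self.boost, Xs)
        yhat = self.fusion.predict(h1, h2)
        return pd.DataFrame(yhat, index=athletes, columns=self.outcomes)

    def attention_weights(self, panel: AthletePanel, athletes) -> np.ndarray:
        athletes = sorted(athletes)
        X = build_sequences(panel, athletes, self.input_range, self.features)
        Xs = make_static_features(panel, athletes, self.input_range)
        return self.fusion.attention(self.temporal.predict(X),
                                     boost_predict(self.boost, Xs))


def fit_branches_and_fusion(X: np.ndarray, S: pd.DataFrame, y: np.ndarray,
                            config: HybridConfig, crossfit: int = 5):
    """Fit both branches on all rows and the fusion on cross-fitted outputs.

    The fusion head is trained on out-of-fold branch outputs (stacking
    hygiene): otherwise it learns to trust whichever branch overfits its
    training athletes and degrades out of sample.  With fewer than 12 rows
    the cross-fit falls back to in-sample outputs.
    """
    n, n_out = len(X), y.shape[1]
    net, _ = train_temporal_branch(X, y, config.temporal)
    boosters = train_boost_branch(S, y, config.boost)
    if n >= 12 and crossfit >= 2:
        rng = np.random.default_rng(config.seed + 13)
        splits = np.array_split(rng.permutation(n), crossfit)
        h1 = np.empty((n, n_out))
        h2 = np.empty((n, n_out))
        for va in splits:
            tr = np.setdiff1d(np.arange(n), va)
            net_k, _ = train_temporal_branch(X[tr], y[tr], config.temporal)
            boost_k = train_boost_branch(S.iloc[tr], y[tr], config.boost)
            h1[va] = net_k.predict(X[va])
            h2[va] = boost_predict(boost_k, S.iloc[va])
    else:
        h1, h2 = net.predict(X), boost_predict(boosters, S)
    fusion = FusionHead(h1.shape[1], h2.shape[1], config.fusion_dim,
                        n_out, seed=config.seed,
                        lr=config.fusion_lr, epochs=config.fusion_epochs)
    fusion.fit(h1, h2, y)
    return net, boosters, fusion


def fit_window_model(panel: AthletePanel, athletes, input_range: tuple[int, int],
                     target_range: tuple[int, int], config: HybridConfig,
                     outcomes: list[str]):
    """Fit both branches + fusion for one (input window, target window) pair.

    Returns (temporal net, boosters, fusion head, static table).  Used for
    the final refit and for the early-identification view (predicting the
    12-month window from the first assessments).
    """
    athletes = sorted(athletes)
    y = np.column_stack([window_target(panel, athletes, o, target_range)
                         for o in outcomes])
    X = build_sequences(panel, athletes, input_range, panel.feature_names)
    S = make_static_features(panel, athletes, input_range)
    net, boosters, fusion = fit_branches_and_fusion(X, S, y, config)
    return net, boosters, fusion, S


def _check_chronology(panel: AthletePanel) -> None:
    t = panel.data.groupby("athlete_id")["time_index"].apply(
        lambda s: bool(np.all(np.diff(s.to_numpy()) > 0)))
    if not t.all():
        raise PreprocessError("time_index is not strictly increasing within athletes")


def train_hybrid(panel: AthletePanel, plan: SplitPlan, config: HybridConfig,
                 outcomes: list[str] | None = None, primary: str = "fatigue",
                 responder_labels: pd.Series | None = None) -> TrainedHybrid:
    """Train both branches, the fusion layer and the responder threshold.

    Per fold, branches are fitted on ~80% of training athletes using features
    from the fold's training window and targets from its validation window
    (always at least the temporal gap later); the held-out athletes provide
    out-of-sample fold RMSEs for the hybrid and for each single branch.  The
    final model is refitted on all training athletes with the last fold's
    window geometry.  Test athletes never contribute targets.
    """
    plan.validate()
    _check_chronology(panel)
    t_max = int(panel.time_indices.max())
    for f in plan.folds:
        if f.valid_times[1] - 1 > t_max:
            raise PreprocessError(f"fold validates at {f.valid_times} beyond T={t_max + 1}")
    outcomes = outcomes or [primary]
    feats = panel.feature_names
    train_ids = sorted(plan.train_athletes)
    rng = np.random.default_rng(config.seed)
    n_folds = len(plan.folds)
    order = rng.permutation(len(train_ids))
    holdout = np.array_split(order, n_folds)

    rows = []
    oof_scores: list[np.ndarray] = []
    oof_labels: list[np.ndarray] = []
    track_responders = responder_labels is not None and primary in outcomes
    if track_responders:
        base_primary = (panel.data[panel.data["time_index"] == 0]
                        .set_index("athlete_id")[primary])
    for k, fold in enumerate(plan.folds):
        va_ids = [train_ids[i] for i in np.sort(holdout[k])]
        tr_ids = sorted(set(train_ids) - set(va_ids))
        ytr = np.column_stack([window_target(panel, tr_ids, o, fold.valid_times)
                               for o in outcomes])
        yva = np.column_stack([window_target(panel, va_ids, o, fold.valid_times)
                               for o in outcomes])
        Xtr = build_sequences(panel, tr_ids, fold.train_times, feats)
        Xva = build_sequences(panel, va_ids, fold.train_times, feats)
        Str = make_static_features(panel, tr_ids, fold.train_times)
        Sva = make_static_features(panel, va_ids, fold.train_times)

        net, boosters, fusion = fit_branches_and_fusion(Xtr, Str, ytr, config)
        h1_va = net.predict(Xva)
        h2_va = boost_predict(boosters, Sva)
        pred_h = fusion.predict(h1_va, h2_va)
        pred_t = net.predict(Xva)
        pred_b = h2_va
        for name, pred in (("hybrid", pred_h), ("temporal", pred_t), ("boost", pred_b)):
            rmse = float(np.sqrt(((pred - yva) ** 2).mean()))
            rows.append({"fold": k, "model": name, "rmse": rmse})

        # only late folds approximate the final model's target geometry, so
        # restrict threshold selection to validation windows near the series
        # end (the 12-month assessment the responder label refers to)
        late = {f.valid_times for f in plan.folds[-2:]}
        if track_responders and fold.valid_times in late:
            j = outcomes.index(primary)
            oof_scores.append(-(base_primary.loc[va_ids].to_numpy() - pred_h[:, j]))
            oof_labels.append((~responder_labels.loc[va_ids].astype(bool)).to_numpy())

    cv = pd.DataFrame(rows)

    # final refit on all training athletes, last-fold geometry
    last = plan.folds[-1]
    net, boosters, fusion, _ = fit_window_model(
        panel, train_ids, last.train_times, last.valid_times, config, outcomes)

    # responder threshold: Youden-optimal on the out-of-fold validation
    # scores (higher score = less predicted improvement = non-responder)
    threshold = None
    if oof_scores:
        scores = np.concatenate(oof_scores)
        labels = np.concatenate(oof_labels)
        if 0 < labels.sum() < len(labels):
            threshold = youden_threshold(scores, labels)

    return TrainedHybrid(config=config, plan=plan, outcomes=list(outcomes),
                         primary=primary, temporal=net, boost=boosters,
                         fusion=fusion, features=list(feats),
                         input_range=last.train_times,
                         target_range=last.valid_times,
                         responder_threshold=threshold, cv_report=cv)
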