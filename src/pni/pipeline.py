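"""End-to-end reproducible pipeline runs.

Stage order: generate -> degrade -> preprocess (outlier screen, imputation,
normalisation, feature engineering) -> temporal split -> hybrid model ->
attribution -> mediation -> lag scan -> subgroup analysis.  Every stage
seeds its randomness from the run configuration; outputs are tidy CSVs plus
a JSON summary and a manifest (config hash, seeds, timings, file
inventory).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import GROUPS, PSYCH_CORE, FEATURES_BY_NAME, PipelineConfig, month_of_index
from .hybrid import boost_predict, evaluate, train_hybrid
from .interpretability import shap_importance
from .panel import AthletePanel
from .preprocessing import (
    engineer_features,
    impute_chained,
    make_temporal_split,
    normalize_features,
    screen_outliers,
)
from .stats_inference import (
    fit_mediation_serial,
    first_canonical_correlation,
    lag_correlation_scan,
    proportion_mediated,
    threshold_crossing_lag,
)
from .subgroup_analysis import (
    characterize_tertiles,
    compare_groups,
    fit_random_intercept,
    summarize_change,
)
from .synthetic_cohort import degrade_panel, generate_baseline, generate_trajectories

PSYCH_BLOCK = list(PSYCH_CORE)
IMMUNE_BLOCK = ["il6", "tnf_alpha", "crp", "iga"]
DIET_CODE = {"high_carb": 0.0, "high_protein": 0.5, "balanced": 1.0}


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    timings: dict[str, float] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def to_json(self, path: Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


def _hash_config(config: PipelineConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer, np.floating)):
            return float(o)
        return str(o)
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def improvement_scores(panel: AthletePanel, features: list[str],
                       t0: int | None = None, t1: int | None = None) -> pd.Series:
    """Per-athlete composite improvement: mean over features of the
    direction-aligned baseline-to-endpoint change in baseline-SD units."""
    df = panel.data
    times = np.sort(df["time_index"].unique())
    t0 = times[0] if t0 is None else t0
    t1 = times[-1] if t1 is None else t1
    base = df[df["time_index"] == t0].set_index("athlete_id")
    end = df[df["time_index"] == t1].set_index("athlete_id")
    parts = []
    for f in features:
        d = FEATURES_BY_NAME[f].direction or 1
        sd = float(base[f].std(ddof=1)) or 1.0
        parts.append(d * (end[f] - base[f]) / sd)
    return pd.concat(parts, axis=1).mean(axis=1)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> RunManifest:
    """Execute every stage and write reports; returns the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=_hash_config(config), seed=config.seed,
                           version=__version__)
    t_start = time.time()

    def tick(stage):
        manifest.timings[stage] = round(time.time() - t_start, 2)

    def save(df: pd.DataFrame, name: str):
        path = out / name
        df.to_csv(path, index=False, float_format="%.6g")
        manifest.outputs.append(name)

    spec = config.cohort
    spec.validate()

    # -- generate ------------------------------------------------------
    baseline = generate_baseline(spec)
    clean = generate_trajectories(baseline, spec)
    panel = degrade_panel(clean, spec)
    panel.to_csv(out / "panel.csv")
    manifest.outputs += ["panel.csv", "panel.json"]
    tick("generate")

    # -- preprocess ----------------------------------------------------
    screened, flags = screen_outliers(panel, config.preprocess)
    completed = impute_chained(screened, config.preprocess)
    plan = make_temporal_split(completed, config.train_frac, config.n_folds,
                               config.gap_steps, config.val_window, seed=config.seed)
    plan.to_json(out / "split_plan.json")
    manifest.outputs.append("split_plan.json")
    normalized, norm_params = normalize_features(completed, config.preprocess,
                                                 train_athletes=plan.train_athletes)
    engineered = engineer_features(
        normalized,
        interactions=[("protein_g_per_kg", "training_load"),
                      ("carb_pct_energy", "training_volume_h")],
        composites={"inflammation_index": ["il6", "tnf_alpha", "crp"]})
    tick("preprocess")

    # -- baseline table (group comparison) -----------------------------
    rows = []
    for f in PSYCH_BLOCK + IMMUNE_BLOCK + ["cortisol", "vo2max"]:
        base = completed.at_time(0)
        stats_row = {"feature": f}
        for g in GROUPS:
            vals = base[base["group"] == g][f]
            stats_row[f"{g}_mean"] = vals.mean()
            stats_row[f"{g}_sd"] = vals.std(ddof=1)
        stats_row["p_value"], stats_row["test"] = compare_groups(completed, f)
        rows.append(stats_row)
    save(pd.DataFrame(rows), "table_baseline.csv")

    r1, shared = first_canonical_correlation(
        completed.at_time(0)[PSYCH_BLOCK].to_numpy(),
        completed.at_time(0)[IMMUNE_BLOCK].to_numpy())
    tick("baseline_tables")

    # -- hybrid model --------------------------------------------------
    outcomes = ["fatigue", "stress", "resilience", "il6"]
    mcid = config.hybrid.responder_mcid
    # responder labels on the raw point scale; model trained on the
    # normalised/engineered panel
    raw_base_fat = completed.at_time(0).set_index("athlete_id")["fatigue"]
    raw_end_fat = completed.at_time(int(completed.time_indices.max())).set_index("athlete_id")["fatigue"]
    responders = (raw_base_fat - raw_end_fat) >= mcid
    model = train_hybrid(engineered, plan, config.hybrid, outcomes=outcomes,
                         primary="fatigue", responder_labels=responders)
    save(model.cv_report, "cv_report.csv")

    test_ids = sorted(plan.test_athletes)
    pred = model.predict(engineered, test_ids)
    truth = np.column_stack([
        engineered.data[engineered.data["athlete_id"].isin(test_ids)
                        & engineered.data["time_index"].between(model.target_range[0],
                                                                model.target_range[1] - 1)]
        .groupby("athlete_id", sort=True)[o].mean().to_numpy() for o in outcomes])
    base_fat = engineered.at_time(0).set_index("athlete_id")["fatigue"]
    score = -(base_fat.loc[test_ids].to_numpy() - pred["fatigue"].to_numpy())
    nonresp = (~responders.loc[test_ids]).to_numpy()
    report = evaluate(pred.to_numpy(), truth, outcomes=outcomes,
                      class_scores=score, class_labels=nonresp,
                      threshold=model.responder_threshold)
    save(pd.DataFrame({"outcome": outcomes,
                       "rmse": [report.rmse[o] for o in outcomes],
                       "r_squared": [report.r_squared[o] for o in outcomes],
                       "mape": [report.mape[o] for o in outcomes]}),
         "table_model_metrics.csv")
    tick("hybrid_model")

    # -- attribution ---------------------------------------------------
    # Fig-7-style question: which baseline characteristics predict the
    # 12-month response?  Attribute the early-identification view of the
    # hybrid (first assessments -> 12-month window), where the aggregates
    # cannot yet contain the realised response.
    from .hybrid.model import fit_window_model

    early_range = (0, max(plan.folds[0].train_times[1], 2))
    net_e, boost_e, fusion_e, static = fit_window_model(
        engineered, plan.train_athletes, early_range, model.target_range,
        config.hybrid, outcomes)
    _H1_MEAN = net_e.predict(
        _seq(engineered, sorted(plan.train_athletes), early_range,
             model.features)).mean(0)
    psych_targets = ["fatigue", "stress", "resilience"]
    sds = {o: float(engineered.at_time(0)[o].std(ddof=1)) or 1.0 for o in psych_targets}

    def predict_response(X):
        Xdf = pd.DataFrame(X, columns=static.columns)
        h2 = boost_predict(boost_e, Xdf)
        h1 = np.tile(_H1_MEAN, (len(Xdf), 1))
        yhat = fusion_e.predict(h1, h2)
        parts = []
        for o in psych_targets:
            j = outcomes.index(o)
            d = FEATURES_BY_NAME[o].direction
            parts.append(d * (yhat[:, j] - Xdf[f"base_{o}"].to_numpy()) / sds[o])
        return np.mean(parts, axis=0)

    groups_map = {f: [f"{v}_{f}" for v in ("base", "mean", "slope")]
                  for f in engineered.feature_names}
    table = shap_importance(predict_response, static, n_samples=64,
                            seed=config.seed, groups=groups_map)
    imp = table.importance.rename_axis("feature").reset_index(name="mean_abs_shap")
    save(imp, "shap_importance.csv")
    dep = pd.DataFrame({
        "feature_value": static["base_resilience"].to_numpy(),
        "shap_value": table.values["resilience"].to_numpy(),
        "colour_value": static["base_stress"].to_numpy(),
    })
    save(dep, "shap_dependency_resilience.csv")
    tick("attribution")

    # -- mediation -----------------------------------------------------
    med_result = None
    med_rows = []
    if completed.n_athletes >= 30:
        t_last = int(completed.time_indices.max())
        base = completed.at_time(0).set_index("athlete_id")
        end = completed.at_time(t_last).set_index("athlete_id")
        med = pd.DataFrame({
            "diet": base["group"].map(DIET_CODE),
            "psych_improvement": improvement_scores(completed, PSYCH_BLOCK),
            "cortisol_reduction": (base["cortisol"] - end["cortisol"]) / base["cortisol"].std(),
            "immune_improvement": improvement_scores(completed, IMMUNE_BLOCK),
        })
        med_result = fit_mediation_serial(
            med, "diet", ["psych_improvement", "cortisol_reduction"],
            "immune_improvement", n_boot=config.n_boot, seed=config.seed)
        for g in GROUPS:
            b = base[base["group"] == g]["cortisol"]
            e = end[end["group"] == g]["cortisol"]
            med_rows.append({"group": g, "cortisol_baseline": b.mean(),
                             "cortisol_12mo": e.mean(),
                             "cortisol_reduction_pct": 100.0 * (b.mean() - e.mean()) / b.mean()})
        med_tab = pd.DataFrame(med_rows)
        med_tab["a1"] = med_result.a1.coef
        med_tab["indirect_serial"] = med_result.indirect_serial
        med_tab["proportion_mediated_pct"] = proportion_mediated(med_result)
        save(med_tab, "table_mediation.csv")
    else:
        manifest.notes.append("mediation skipped: fewer than 30 athletes")
    tick("mediation")

    # -- lag scan ------------------------------------------------------
    lag_rows = []
    for a, b in (("fatigue", "il6"), ("stress", "tnf_alpha"), ("resilience", "iga")):
        scan = lag_correlation_scan(completed, a, b, max_lag=config.max_lag,
                                    n_boot=100, seed=config.seed)
        lag_rows.append({"pair": f"{a}->{b}", "peak_lag_steps": scan.peak_lag,
                         "peak_lag_months": round(scan.peak_lag_months, 2),
                         "peak_r": round(scan.peak_r, 3)})
    save(pd.DataFrame(lag_rows), "lag_scan.csv")

    months = np.array([month_of_index(t, completed.n_timepoints)
                       for t in completed.time_indices])
    psych_curve = _norm_improvement(completed, PSYCH_BLOCK)
    immune_curve = _norm_improvement(completed, IMMUNE_BLOCK)
    cross_lag = threshold_crossing_lag(months, psych_curve, immune_curve, 0.5)
    tick("lag_scan")

    # -- subgroup analysis --------------------------------------------
    change_rows = []
    for outcome in ("fatigue", "stress", "resilience"):
        for g in GROUPS:
            s = summarize_change(completed, g, outcome)
            change_rows.append(dataclasses.asdict(s))
    save(pd.DataFrame(change_rows), "table_changes.csv")

    df = completed.data.copy()
    df["psych_score"] = df[["fatigue", "stress"]].mean(axis=1)
    score_panel = AthletePanel(df)
    profiles = characterize_tertiles(score_panel, "psych_score", direction=-1)
    save(pd.DataFrame([dataclasses.asdict(p) for p in profiles]),
         "table_subgroups.csv")

    # random-intercept model: does the fatigue trajectory slope differ by
    # dietary group? (time x group interaction, within-athlete clustering)
    mixed_summary = None
    try:
        mm = fit_random_intercept(completed, "fatigue",
                                  ["time_index", "group"],
                                  interactions=[("time_index", "group")])
        inter_p = mm.pvalues[[ix for ix in mm.pvalues.index
                              if "time_index:" in ix]]
        mixed_summary = {
            "time_slope": float(mm.params["time_index"]),
            "interaction_p_min": float(inter_p.min()) if len(inter_p) else None,
            "random_intercept_var": mm.random_intercept_var,
        }
    except Exception as exc:  # degenerate smoke-scale panels may not converge
        manifest.notes.append(f"mixed model skipped: {exc}")
    tick("subgroups")

    # -- summary -------------------------------------------------------
    summary = {
        "n_athletes": completed.n_athletes,
        "n_timepoints": completed.n_timepoints,
        "group_sizes": {g: int((completed.at_time(0)["group"] == g).sum()) for g in GROUPS},
        "tertile_sizes": {t: int((completed.at_time(0)["tertile"] == t).sum())
                          for t in ("low", "moderate", "high")},
        "split": {"train": len(plan.train_athletes), "test": len(plan.test_athletes)},
        "outliers_flagged": len(flags),
        "first_canonical_correlation": round(r1, 3),
        "shared_variance_pct": round(shared, 1),
        "model": {"rmse": {k: round(v, 4) for k, v in report.rmse.items()},
                  "auc": None if report.auc is None else round(report.auc, 3),
                  "sensitivity": report.sensitivity,
                  "specificity": report.specificity},
        "lag_scan": lag_rows,
        "threshold_crossing_lag_months": None if cross_lag is None else round(cross_lag, 2),
        "top_predictors": imp["feature"].head(5).tolist(),
        "mixed_model": mixed_summary,
    }
    if med_result is not None:
        summary["mediation"] = {
            "indirect_serial": round(med_result.indirect_serial, 4),
            "indirect_simple": round(med_result.indirect_simple, 4),
            "total": round(med_result.total.coef, 4),
            "proportion_mediated_pct": round(proportion_mediated(med_result), 1),
        }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    manifest.outputs.append("summary.json")
    tick("total")
    manifest.to_json(out / "manifest.json")
    return manifest


def _seq(panel, athletes, t_range, features):
    from .hybrid.model import build_sequences
    return build_sequences(panel, athletes, t_range, features)


def _norm_improvement(panel: AthletePanel, features: list[str]) -> np.ndarray:
    """Cohort-mean improvement trajectory normalised to [0, 1]."""
    df = panel.data
    curves = []
    for f in features:
        d = FEATURES_BY_NAME[f].direction or 1
        traj = df.groupby("time_index")[f].mean().to_numpy()
        curves.append(d * (traj - traj[0]))
    curve = np.mean(curves, axis=0)
    span = curve.max() - curve.min()
    return (curve - curve.min()) / (span if span > 0 else 1.0)


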