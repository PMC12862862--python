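"""Resilience-subgroup stratification, mixed models and change summaries.

Covers the cohort-level descriptive machinery: tertile stratification by a
baseline score, random-intercept mixed-effects models for longitudinal
outcomes, baseline-to-endpoint change summaries with minimal clinically
important difference (MCID) rates, response-trajectory characterisation
(onset / improvement rate / plateau), and Bonferroni adjustment within
variable families.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import FEATURES_BY_NAME


class AnalysisError(ValueError):
    pass


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------

def stratify_tertiles(values: pd.Series, labels: tuple[str, str, str] = ("low", "moderate", "high")) -> pd.Series:
    """Split athletes into tertiles of a baseline score.

    Sizes differ by at most one; when n % 3 == 2 the extra members go to the
    outer tertiles (200 athletes -> 67 low / 66 moderate / 67 high).  Ties
    are broken deterministically by athlete id.
    """
    n = len(values)
    if n < 3:
        raise AnalysisError(f"need >= 3 athletes to form tertiles, got {n}")
    if values.nunique() == 1:
        warnings.warn("all stratification values tied; splitting by athlete id order")
    order = values.reset_index()
    id_col, val_col = order.columns[0], order.columns[1]
    order = order.sort_values([val_col, id_col], kind="mergesort")
    q, r = divmod(n, 3)
    sizes = [q + (1 if r >= 1 else 0), q, q + (1 if r >= 2 else 0)]
    out = np.empty(n, dtype=object)
    start = 0
    for lab, size in zip(labels, sizes):
        out[start:start + size] = lab
        start += size
    return pd.Series(out, index=order[id_col].to_numpy(), name="tertile").reindex(
        values.index)


# ---------------------------------------------------------------------------
# mixed-effects model
# ---------------------------------------------------------------------------

@dataclass
class MixedModelResult:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    random_intercept_var: float
    residual_var: float
    converged: bool
    model: object


def fit_random_intercept(panel, outcome: str, fixed_effects: list[str],
                         interactions: list[tuple[str, str]] | None = None) -> MixedModelResult:
    """REML random-intercept model ``outcome ~ fixed (+ interactions)``.

    Accounts for within-athlete clustering via athlete-specific intercepts;
    interaction Wald tests come with the fixed-effects table.
    """
    import statsmodels.formula.api as smf

    df = panel.data if hasattr(panel, "data") else panel
    counts = df.groupby("athlete_id")[outcome].count()
    if (counts < 2).any():
        raise AnalysisError("every athlete needs >= 2 observations for a mixed model")
    terms = list(fixed_effects)
    for a, b in interactions or []:
        terms.append(f"{a}:{b}")
    formula = f"{outcome} ~ " + " + ".join(terms)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df["athlete_id"])
        fit = model.fit(reml=True)
    if not fit.converged:
        raise AnalysisError(
            f"mixed model did not converge (gradient norm "
            f"{np.linalg.norm(fit.model.score(fit.params_object)):.3g})")
    return MixedModelResult(
        params=fit.fe_params, bse=fit.bse_fe, pvalues=fit.pvalues[fit.fe_params.index],
        random_intercept_var=float(fit.cov_re.iloc[0, 0]),
        residual_var=float(fit.scale), converged=bool(fit.converged), model=fit)


# ---------------------------------------------------------------------------
# change summaries
# ---------------------------------------------------------------------------

@dataclass
class GroupChangeSummary:
    group: str
    outcome: str
    n: int
    baseline_mean: float
    baseline_sd: float
    endpoint_mean: float
    endpoint_sd: float
    delta: float
    percent_change: float
    cohen_d: float
    clinical_improvement_pct: float
    p_value: float
    test: str


def _mcid_threshold(baseline_sd: float, floor: float = 1.0) -> float:
    """MCID: >= 1.0 point or 0.5 baseline SD, whichever is larger."""
    return max(floor, 0.5 * baseline_sd)


def summarize_change(panel, group: str, outcome: str, direction: int | None = None,
                     baseline_time: int | None = None, endpoint_time: int | None = None,
                     mcid_floor: float = 1.0, shapiro_alpha: float = 0.05) -> GroupChangeSummary:
    """Baseline-to-endpoint change summary for one group and outcome.

    ``direction`` is +1 when increases are beneficial, -1 when decreases are
    (defaults to the feature inventory's direction, else the sign of the
    observed change).  Clinical improvement counts athletes whose change in
    the beneficial direction meets the MCID, boundary included.  The
    within-group p-value uses a paired t-test, or Wilcoxon signed-rank when
    the differences fail a Shapiro-Wilk normality gate.
    """
    df = panel.data if hasattr(panel, "data") else panel
    sub = df[df["group"] == group] if group is not None else df
    times = np.sort(sub["time_index"].unique())
    t0 = times[0] if baseline_time is None else baseline_time
    t1 = times[-1] if endpoint_time is None else endpoint_time
    base = sub[sub["time_index"] == t0].set_index("athlete_id")[outcome]
    end = sub[sub["time_index"] == t1].set_index("athlete_id")[outcome]
    paired = pd.concat({"base": base, "end": end}, axis=1)
    n_excluded = int(paired.isna().any(axis=1).sum())
    if n_excluded:
        warnings.warn(f"{n_excluded} athletes excluded from {outcome!r} change "
                      "summary (missing baseline or endpoint)")
    paired = paired.dropna()
    if len(paired) < 3:
        raise AnalysisError(f"too few athletes with both time points for {outcome!r}")

    b, e = paired["base"].to_numpy(), paired["end"].to_numpy()
    delta = float(e.mean() - b.mean())
    if direction is None:
        feat = FEATURES_BY_NAME.get(outcome)
        direction = feat.direction if feat is not None and feat.direction else int(np.sign(delta) or 1)
    pooled_sd = float(np.sqrt((b.std(ddof=1) ** 2 + e.std(ddof=1) ** 2) / 2.0))
    mcid = _mcid_threshold(float(b.std(ddof=1)), mcid_floor)
    improvement = direction * (e - b)
    diffs = e - b
    if np.ptp(diffs) == 0:
        p, test = (1.0, "degenerate") if np.allclose(diffs, 0) else (0.0, "degenerate")
    elif stats.shapiro(diffs[:500]).pvalue > shapiro_alpha:
        p, test = float(stats.ttest_rel(e, b).pvalue), "paired t"
    else:
        p, test = float(stats.wilcoxon(e, b).pvalue), "wilcoxon"
    return GroupChangeSummary(
        group=group, outcome=outcome, n=len(paired),
        baseline_mean=float(b.mean()), baseline_sd=float(b.std(ddof=1)),
        endpoint_mean=float(e.mean()), endpoint_sd=float(e.std(ddof=1)),
        delta=delta,
        percent_change=100.0 * abs(delta) / abs(b.mean()),
        cohen_d=abs(delta) / pooled_sd if pooled_sd > 0 else float("nan"),
        clinical_improvement_pct=100.0 * float((improvement >= mcid).mean()),
        p_value=p, test=test)


# ---------------------------------------------------------------------------
# response trajectory characterisation
# ---------------------------------------------------------------------------

@dataclass
class SubgroupProfile:
    tertile: str
    baseline_score: float
    final_score: float
    improvement_rate: float  # points / month between onset and plateau
    onset_months: float | None
    plateau_months: float | None


def characterize_response(months: np.ndarray, values: np.ndarray, *,
                          direction: int = -1, baseline_sd: float = 1.0,
                          onset_frac: float = 0.5, plateau_slope: float = 0.05,
                          tertile: str = "") -> SubgroupProfile:
    """Onset / rate / plateau of one (group-mean) response trajectory.

    Onset is the earliest month at which cumulative improvement reaches
    ``onset_frac * baseline_sd`` and stays there for two consecutive
    assessments (linearly interpolated to 0.1-month resolution).  The plateau
    is the earliest post-onset month at which the rolling three-point slope
    falls below ``plateau_slope`` points/month; the rate is the least-squares
    slope of the improvement curve between onset and plateau.
    """
    months = np.asarray(months, float)
    values = np.asarray(values, float)
    if len(months) < 4:
        raise AnalysisError("trajectory too short to characterise")
    imp = direction * (values - values[0])
    thr = onset_frac * baseline_sd

    onset = None
    for i in range(1, len(imp) - 1):
        if imp[i] >= thr and imp[i + 1] >= thr:
            if imp[i - 1] < thr and imp[i] > imp[i - 1]:
                frac = (thr - imp[i - 1]) / (imp[i] - imp[i - 1])
                onset = months[i - 1] + frac * (months[i] - months[i - 1])
            else:
                onset = months[i]
            onset = round(onset * 10.0) / 10.0
            break
    if onset is None:
        return SubgroupProfile(tertile, float(values[0]), float(values[-1]),
                               0.0, None, None)

    plateau = None
    for i in range(len(imp) - 2):
        mid = months[i + 1]
        if mid <= onset:
            continue
        slope = np.polyfit(months[i:i + 3], imp[i:i + 3], 1)[0]
        if slope < plateau_slope:
            plateau = round(mid * 10.0) / 10.0
            break
    rate_end = plateau if plateau is not None else months[-1]
    sel = (months >= onset - 1e-9) & (months <= rate_end + 1e-9)
    if sel.sum() >= 2:
        rate = float(np.polyfit(months[sel], imp[sel], 1)[0])
    else:
        rate = float((imp[-1] - imp[0]) / (months[-1] - months[0]))
    return SubgroupProfile(tertile, float(values[0]), float(values[-1]),
                           max(rate, 0.0), onset, plateau)


def characterize_tertiles(panel, outcome: str, direction: int = -1) -> list[SubgroupProfile]:
    """Group-mean response profiles per resilience tertile."""
    df = panel.data if hasattr(panel, "data") else panel
    from .config import month_of_index
    t_count = df["time_index"].nunique()
    out = []
    for tert in ("high", "moderate", "low"):
        sub = df[df["tertile"] == tert]
        traj = sub.groupby("time_index")[outcome].mean()
        months = np.array([month_of_index(t, t_count) for t in traj.index])
        sd0 = float(sub[sub["time_index"] == traj.index[0]][outcome].std(ddof=1))
        out.append(characterize_response(months, traj.to_numpy(),
                                         direction=direction, baseline_sd=sd0,
                                         tertile=tert))
    return out


# ---------------------------------------------------------------------------
# multiplicity
# ---------------------------------------------------------------------------

def adjust_pvalues(pvals, family_size: int | None = None) -> np.ndarray:
    """Bonferroni adjustment within one variable family (p*m capped at 1)."""
    p = np.asarray(pvals, float)
    if np.any((p < 0) | (p > 1)):
        raise AnalysisError("p-values must lie in [0, 1]")
    m = family_size if family_size is not None else p.size
    return np.minimum(p * m, 1.0)


def compare_groups(panel, feature: str, shapiro_alpha: float = 0.05,
                   time_index: int = 0) -> tuple[float, str]:
    """Between-group comparison at one time point (ANOVA, or Kruskal-Wallis
    when any group fails the normality gate)."""
    df = panel.data if hasattr(panel, "data") else panel
    sub = df[df["time_index"] == time_index]
    samples = [g[feature].dropna().to_numpy() for _, g in sub.groupby("group")]
    normal = all(stats.shapiro(s[:500]).pvalue > shapiro_alpha for s in samples)
    if normal:
        return float(stats.f_oneway(*samples).pvalue), "anova"
    return float(stats.kruskal(*samples).pvalue), "kruskal"
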