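"""Synthetic longitudinal athlete cohort with planted psychoneuroimmune structure.

The generator emulates the study conditions of a 200-athlete, 12-month
observational cohort in three naturalistic dietary pattern groups.  It plants
four structures that the downstream analyses are designed to recover:

1. *Group calibration* — per-group baseline and 12-month endpoint means/SDs
   of every named marker match the configured profiles (``CohortSpec``).
2. *Temporal precedence* — within-athlete immune-marker deviations are driven
   by psychological deviations ``lag_steps`` bi-weekly points earlier (via a
   shared AR(1) latent), so a lag-correlation scan peaks at the planted lag.
3. *Serial mediation* — the latent chain runs diet -> psychology -> cortisol
   -> immunity with coefficients (a1, a2, b2) plus the direct paths b1 and
   c'.  Exact coefficient recovery is testable on the companion
   linear-Gaussian simulator :func:`simulate_serial_mediation`; the panel
   itself embeds the chain in its within-athlete noise and group profiles.
4. *Resilience subgroups* — response onset/plateau timing follows the
   configured per-tertile dynamics, and a response-propensity score loading
   on baseline resilience (strongest), fatigue, stress and sleep modulates
   each athlete's attained improvement.

Trajectories follow a saturating exponential from the athlete's baseline to
their endpoint: zero change before the onset month, then
``1 - exp(-r (m - onset))`` normalised to reach the endpoint at month 12,
with the rate ``r = 3 / (plateau - onset)`` so ~95% of the change is attained
at the tertile's plateau month.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import (
    DIET_RULES,
    GROUPS,
    PSYCH_CORE,
    CohortSpec,
    ConfigurationError,
    FeatureDef,
)
from .panel import AthletePanel, PanelError
from .subgroup_analysis import stratify_tertiles

__all__ = [
    "generate_baseline",
    "generate_trajectories",
    "degrade_panel",
    "generate_panel",
    "simulate_serial_mediation",
]


def _rng(spec: CohortSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, spec.seed])


def _group_arrays(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray]:
    ids, groups = [], []
    k = 0
    for g, n in zip(GROUPS, spec.n_per_group):
        for _ in range(n):
            ids.append(f"A{k:03d}")
            groups.append(g)
            k += 1
    return np.array(ids), np.array(groups)


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def _clip(values: np.ndarray, feat: FeatureDef) -> np.ndarray:
    lo = feat.lo if feat.lo > 0 else (1e-3 if feat.lo == 0.0 else feat.lo)
    return np.clip(values, lo, feat.hi)


# ---------------------------------------------------------------------------
# baseline
# ---------------------------------------------------------------------------

def generate_baseline(spec: CohortSpec) -> AthletePanel:
    """Generate the time-0 cross-section of the cohort.

    A single latent psychoneuroimmune axis (loading ``spec.axis_loading`` on
    every direction-carrying psychological, immune and performance marker)
    couples the baseline blocks, so athletes with poor psychological profiles
    also show elevated inflammation and suppressed mucosal immunity.
    Macronutrient intake is drawn inside each group's classification region,
    making the dietary labels consistent with the published rules.
    """
    spec.validate()
    rng = _rng(spec, 1)
    ids, groups = _group_arrays(spec)
    n = len(ids)
    gidx = np.array([GROUPS.index(g) for g in groups])

    lam = spec.axis_loading
    axis = rng.standard_normal(n)  # latent fitness/wellbeing axis

    data = {"athlete_id": ids, "group": groups}
    data["age"] = np.round(np.clip(
        np.array([28.3, 27.9, 28.6])[gidx]
        + np.array([5.2, 4.8, 5.5])[gidx] * rng.standard_normal(n), 18, 45), 1)
    data["time_index"] = np.zeros(n, dtype=int)

    for feat in spec.baseline_profiles.values():
        mu = np.array(feat.baseline)[gidx]
        sd = np.array(feat.sd)[gidx]
        if feat.name in ("carb_pct_energy", "protein_g_per_kg"):
            vals = np.empty(n)
            for gi, g in enumerate(GROUPS):
                sel = gidx == gi
                lo, hi = DIET_RULES[g][feat.name]
                vals[sel] = _truncnorm(rng, feat.baseline[gi], feat.sd[gi],
                                       lo, hi, int(sel.sum()))
        elif feat.direction != 0:
            eps = rng.standard_normal(n)
            vals = mu + sd * (lam * feat.direction * axis
                              + np.sqrt(1.0 - lam ** 2) * eps)
            vals = _clip(vals, feat)
        else:
            vals = _clip(mu + sd * rng.standard_normal(n), feat)
        data[feat.name] = vals

    df = pd.DataFrame(data)
    tert = stratify_tertiles(df.set_index("athlete_id")["resilience"])
    df.insert(2, "tertile", df["athlete_id"].map(tert).to_numpy())
    panel = AthletePanel(df, attrs={"seed": spec.seed, "stage": "baseline"})
    return panel


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def _response_shape(months: np.ndarray, onset: float, plateau: float,
                    horizon: float = 12.0) -> np.ndarray:
    """Saturating-exponential attainment fraction in [0, 1].

    Zero before ``onset``; reaches exactly 1 at ``horizon`` (month 12); ~95%
    of the change is attained at ``plateau``.
    """
    rate = 3.0 / max(plateau - onset, 0.5)
    span = max(horizon - onset, 0.5)
    raw = 1.0 - np.exp(-rate * np.clip(months - onset, 0.0, None))
    return raw / (1.0 - np.exp(-rate * span))


def _ar1(rng, n: int, t: int, rho: float) -> np.ndarray:
    w = rng.standard_normal((n, t))
    out = np.empty_like(w)
    out[:, 0] = w[:, 0]
    c = np.sqrt(1.0 - rho ** 2)
    for j in range(1, t):
        out[:, j] = rho * out[:, j - 1] + c * w[:, j]
    return out


def generate_trajectories(baseline: AthletePanel, spec: CohortSpec) -> AthletePanel:
    """Extend a baseline cross-section to the full bi-weekly panel.

    Implements the planted serial chain and temporal lag: cortisol deviations
    follow psychological deviations by ``spec.cortisol_lag_steps`` and immune
    deviations by ``spec.lag_steps`` (through the mediation coefficients),
    while mean trajectories of lagged markers are the psychological response
    curve shifted right by the same lag.
    """
    spec.validate()
    base0 = baseline.at_time(0)
    if len(base0) != baseline.n_athletes or len(base0) == 0:
        raise PanelError("baseline panel must cover time_index 0 for all athletes")
    base0 = base0.sort_values("athlete_id").reset_index(drop=True)
    missing_feats = [f for f in spec.feature_names if f not in base0.columns]
    if missing_feats:
        raise PanelError(f"baseline panel lacks features: {missing_feats[:5]}")

    rng = _rng(spec, 2)
    n, t_total = len(base0), spec.n_timepoints
    groups = base0["group"].to_numpy()
    gidx = np.array([GROUPS.index(g) for g in groups])
    a1, a2, b2, c_prime = spec.mediation_coeffs
    b1 = spec.b1

    # response propensity from group-centred core psychological baselines
    z_mod = np.zeros(n)
    for name, w in spec.propensity_loadings.items():
        col = base0[name].to_numpy()
        z = np.empty(n)
        for gi in range(len(GROUPS)):
            sel = gidx == gi
            mu, sd = col[sel].mean(), col[sel].std()
            z[sel] = (col[sel] - mu) / max(sd, 1e-9)
        z_mod += w * z
    z_mod /= max(z_mod.std(), 1e-9)

    # endpoint-level serial chain: athlete-specific change residuals follow
    # psych -> cortisol -> immunity, so change-score regressions recover a
    # serial indirect path.  Each latent is standardised.
    xi_c = rng.standard_normal(n)
    xi_i = rng.standard_normal(n)
    xi_p = rng.standard_normal(n)
    e_cort = a2 * z_mod + np.sqrt(max(1.0 - a2 ** 2, 0.05)) * xi_c
    sig2_imm = b2 ** 2 + b1 ** 2 + 2.0 * a2 * b1 * b2
    e_imm = (b2 * e_cort + b1 * z_mod
             + np.sqrt(max(1.0 - sig2_imm, 0.05)) * xi_i)
    e_imm /= max(e_imm.std(), 1e-9)
    e_perf = 0.4 * z_mod + np.sqrt(0.84) * xi_p
    endpoint_latent = {"psychological": z_mod, "immunological": e_imm,
                       "performance": e_perf, "cortisol": e_cort}

    # per-athlete response timing from the resilience tertile
    onset = np.empty(n)
    plateau = np.empty(n)
    no_response = np.zeros(n, bool)
    terts = base0["tertile"].to_numpy()
    for name, dyn in spec.subgroup_dynamics.items():
        sel = terts == name
        k = int(sel.sum())
        onset[sel] = np.clip(dyn.onset_months + dyn.onset_sd * rng.standard_normal(k),
                             0.2, 8.0)
        plateau[sel] = dyn.plateau_months + dyn.plateau_sd * rng.standard_normal(k)
        if dyn.rate_per_month == 0:
            no_response[sel] = True  # null dynamics: tertile stays at baseline
    plateau = np.maximum(plateau, onset + 1.5)

    # shared within-athlete latents on an extended grid (negative lags)
    lag = spec.lag_steps
    lag_c = spec.cortisol_lag_steps
    t_ext = t_total + lag
    rho = spec.ar_rho
    eta_psych = _ar1(rng, n, t_ext, rho)
    u_cort = _ar1(rng, n, t_ext, rho)
    u_imm = _ar1(rng, n, t_ext, rho)
    u_perf = _ar1(rng, n, t_ext, rho)
    eta_cort = a2 * np.roll(eta_psych, lag_c, axis=1) + np.sqrt(max(1 - a2 ** 2, 0.05)) * u_cort
    lag_ci = lag - lag_c
    sig2 = b2 ** 2 + b1 ** 2 + 2.0 * a2 * b1 * b2
    eta_imm = (b2 * np.roll(eta_cort, lag_ci, axis=1)
               + b1 * np.roll(eta_psych, lag, axis=1)
               + np.sqrt(max(1.0 - sig2, 0.05)) * u_imm)
    eta_perf = 0.3 * eta_psych + np.sqrt(0.91) * u_perf
    # rolled-in values from the future are invalid; the extended prefix
    # (first `lag` columns) absorbs them and is dropped below
    latents = {"psychological": eta_psych, "immunological": eta_imm,
               "performance": eta_perf}

    months = np.array([spec.month_of_index(t) for t in range(t_total)])
    w_dom = spec.domain_noise_share
    phi = spec.persistence
    c_mod = spec.propensity_effect

    frames = []
    values: dict[str, np.ndarray] = {}
    for feat in spec.baseline_profiles.values():
        mu_b = np.array(feat.baseline)[gidx]
        sd_b = np.array(feat.sd)[gidx]
        mu_e = np.array(feat.endpoint)[gidx]
        sd_e = np.array(feat.end_sd)[gidx]
        base = base0[feat.name].to_numpy()

        if feat.name == "cortisol":
            e_lat = endpoint_latent["cortisol"]
        else:
            e_lat = endpoint_latent.get(feat.domain, None)
        resid = np.sqrt(np.clip(1.0 - phi ** 2
                                - (c_mod ** 2 if feat.direction else 0.0),
                                0.05, None))
        latent_term = (feat.direction * sd_e * c_mod * e_lat
                       if (feat.direction != 0 and e_lat is not None) else 0.0)
        end = (mu_e + phi * (base - mu_b) * sd_e / np.maximum(sd_b, 1e-12)
               + latent_term
               + sd_e * resid * rng.standard_normal(n))

        if feat.direction != 0 and feat.domain == "immunological":
            lag_f = lag_c if feat.name == "cortisol" else lag
        else:
            lag_f = 0
        lag_months = spec.month_of_index(lag_f)

        shape = np.empty((n, t_total))
        for i in range(n):
            shape[i] = _response_shape(months - lag_months, onset[i], plateau[i])
        shape[no_response] = 0.0

        path = base[:, None] + (end - base)[:, None] * shape

        sigma_w = (spec.within_noise_frac * sd_b)[:, None]
        if feat.name == "cortisol":
            eta = eta_cort[:, lag:]
            noise = (w_dom * feat.direction * eta
                     + np.sqrt(1.0 - w_dom ** 2) * rng.standard_normal((n, t_total)))
        elif feat.domain in latents and feat.direction != 0:
            eta = latents[feat.domain][:, lag:]
            noise = (w_dom * feat.direction * eta
                     + np.sqrt(1.0 - w_dom ** 2) * rng.standard_normal((n, t_total)))
        else:
            noise = rng.standard_normal((n, t_total))
        vals = path + sigma_w * noise
        vals[:, 0] = base  # keep the generated baseline exactly
        values[feat.name] = _clip(vals, feat)

    for j in range(t_total):
        frame = base0[["athlete_id", "group", "tertile", "age"]].copy()
        frame["time_index"] = j
        for name in spec.feature_names:
            frame[name] = values[name][:, j]
        frames.append(frame)
    df = pd.concat(frames, ignore_index=True)
    attrs = dict(baseline.attrs)
    attrs.update({"stage": "trajectories", "lag_steps": lag,
                  "mediation_coeffs": list(spec.mediation_coeffs), "b1": b1})
    return AthletePanel(df, attrs=attrs)


# ---------------------------------------------------------------------------
# degradation
# ---------------------------------------------------------------------------

def degrade_panel(panel: AthletePanel, spec: CohortSpec) -> AthletePanel:
    """Inject MCAR missingness and gross outliers, recording ground truth.

    Injected outliers are displaced at least 4 pooled SDs from the feature
    mean so a downstream 3-SD screen flags every one of them.  Per-athlete
    observed fraction stays >= 0.8 (the cohort inclusion rule).
    """
    if not 0.0 <= spec.missing_rate < 0.2:
        raise ConfigurationError(
            f"missing_rate {spec.missing_rate} violates the <20% inclusion rule")
    out = panel.copy()
    if spec.missing_rate == 0.0 and spec.outlier_rate == 0.0:
        out.mask = pd.DataFrame(
            columns=["athlete_id", "time_index", "feature", "kind", "true_value"])
        return out

    rng = _rng(spec, 3)
    feats = out.feature_names
    df = out.data
    n_rows = len(df)
    records = []

    # outliers first (on observed values), then missingness
    if spec.outlier_rate > 0:
        means = df[feats].mean()
        sds = df[feats].std()
        hit = rng.random((n_rows, len(feats))) < spec.outlier_rate
        for j, f in enumerate(feats):
            rows = np.flatnonzero(hit[:, j])
            if rows.size == 0 or sds[f] == 0:
                continue
            signs = rng.choice([-1.0, 1.0], size=rows.size)
            disp = 4.2 + np.abs(rng.standard_normal(rows.size)) * 0.8
            new = means[f] + signs * disp * sds[f]
            for r, v in zip(rows, new):
                records.append((df.at[r, "athlete_id"], df.at[r, "time_index"],
                                f, "outlier", df.at[r, f]))
                df.at[r, f] = v

    if spec.missing_rate > 0:
        per_athlete_cap = 0.19
        for aid, g in df.groupby("athlete_id"):
            idx = g.index.to_numpy()
            cells = [(r, f) for r in idx for f in feats]
            m = rng.random(len(cells)) < spec.missing_rate
            max_missing = int(per_athlete_cap * len(cells))
            chosen = np.flatnonzero(m)
            if chosen.size > max_missing:
                chosen = rng.choice(chosen, size=max_missing, replace=False)
            for c in chosen:
                r, f = cells[c]
                if not np.isnan(df.at[r, f]):
                    records.append((df.at[r, "athlete_id"], df.at[r, "time_index"],
                                    f, "missing", df.at[r, f]))
                    df.at[r, f] = np.nan

    out.mask = pd.DataFrame(
        records, columns=["athlete_id", "time_index", "feature", "kind", "true_value"])
    out.attrs.update({"stage": "degraded", "missing_rate": spec.missing_rate,
                      "outlier_rate": spec.outlier_rate})
    return out


def generate_panel(spec: CohortSpec, degrade: bool = True) -> AthletePanel:
    """Full generation pipeline: baseline -> trajectories -> degradation."""
    panel = generate_trajectories(generate_baseline(spec), spec)
    return degrade_panel(panel, spec) if degrade else panel


# ---------------------------------------------------------------------------
# stand-alone serial-mediation simulator
# ---------------------------------------------------------------------------

def simulate_serial_mediation(a1: float, a2: float, b2: float, c_prime: float,
                              n: int, b1: float = 0.0, noise_sd: float = 1.0,
                              seed: int = 0) -> pd.DataFrame:
    """Linear-Gaussian draw from the serial chain x -> m1 -> m2 -> y.

    In the ``noise_sd -> 0`` limit, path regressions recover (a1, a2, b2,
    b1, c') exactly and the serial indirect effect equals ``a1 * a2 * b2``.
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    m1 = a1 * x + noise_sd * rng.standard_normal(n)
    m2 = a2 * m1 + noise_sd * rng.standard_normal(n)
    y = c_prime * x + b1 * m1 + b2 * m2 + noise_sd * rng.standard_normal(n)
    return pd.DataFrame({"exposure": x, "m1": m1, "m2": m2, "outcome": y})
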