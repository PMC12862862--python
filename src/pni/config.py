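"""Scenario configuration for the psychoneuroimmune athlete pipeline.

The central object is :class:`CohortSpec`, which fixes the study conditions a
synthetic longitudinal cohort is generated under: three naturalistic dietary
pattern groups (high-carbohydrate, high-protein, balanced micronutrient),
bi-weekly follow-up over twelve months, and 52 tracked features spanning
psychological state, nutrition, immune markers and performance.  Baseline and
endpoint means/SDs for the named markers are the published group profiles; the
remaining columns are documented fillers needed to honour the 52-dimensional
feature tensor the predictive model consumes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

GROUPS: tuple[str, str, str] = ("high_carb", "high_protein", "balanced")
TERTILES: tuple[str, str, str] = ("low", "moderate", "high")
DOMAINS: tuple[str, str, str, str] = (
    "psychological",
    "nutritional",
    "immunological",
    "performance",
)

#: bi-weekly index <-> month conversion; the panel's last index (T-1 = 23 by
#: default) corresponds to the 12-month endpoint assessment.
STEPS_PER_MONTH = 23.0 / 12.0


def month_of_index(t: float, n_timepoints: int = 24) -> float:
    """Calendar month of a bi-weekly ``time_index`` (0 -> 0.0, T-1 -> 12.0)."""
    return float(t) * 12.0 / (n_timepoints - 1)


def index_of_month(m: float, n_timepoints: int = 24) -> int:
    return int(round(float(m) * (n_timepoints - 1) / 12.0))


@dataclass(frozen=True)
class FeatureDef:
    """Static description of one tracked feature.

    ``baseline``/``endpoint`` are per-group means ordered as
    (high_carb, high_protein, balanced); ``direction`` is +1 when larger
    values are better, -1 when smaller values are better and 0 for features
    with no planted improvement axis (e.g. stable dietary intake).
    """

    name: str
    domain: str
    baseline: tuple[float, float, float]
    sd: tuple[float, float, float]
    endpoint: tuple[float, float, float]
    direction: int = 0
    endpoint_sd: tuple[float, float, float] | None = None
    lo: float = 0.0
    hi: float = float("inf")

    @property
    def end_sd(self) -> tuple[float, float, float]:
        return self.endpoint_sd if self.endpoint_sd is not None else self.sd


def _f(name, domain, base, sd, end, direction=0, end_sd=None, lo=0.0, hi=float("inf")):
    sd3 = (sd, sd, sd) if isinstance(sd, (int, float)) else tuple(sd)
    end_sd3 = None
    if end_sd is not None:
        end_sd3 = (end_sd, end_sd, end_sd) if isinstance(end_sd, (int, float)) else tuple(end_sd)
    return FeatureDef(name, domain, tuple(base), sd3, tuple(end), direction, end_sd3, lo, hi)


# Published group profiles for the named markers; psychological scales are
# 0-10, cytokines ng/L, CRP mg/L, IgA mg/dL, cortisol nmol/L, VO2max
# mL/kg/min.  Endpoints without a published value are plausible defaults with
# the balanced > high-protein > high-carb improvement ordering.
FEATURES: tuple[FeatureDef, ...] = (
    # -- psychological (12), 0-10 scales -----------------------------------
    _f("fatigue", "psychological", (5.8, 5.2, 4.6), 1.0, (5.0, 4.0, 2.8), -1,
       end_sd=(0.9, 0.9, 0.8), hi=10.0),
    _f("stress", "psychological", (6.2, 5.6, 5.0), 0.9, (5.3, 4.3, 3.3), -1,
       end_sd=(0.9, 0.8, 0.8), hi=10.0),
    _f("sleep_quality", "psychological", (6.2, 6.8, 7.4), 0.8, (6.6, 7.3, 8.0), 1, hi=10.0),
    _f("resilience", "psychological", (4.8, 5.4, 6.0), 0.9, (5.5, 6.5, 7.5), 1,
       end_sd=(0.9, 0.8, 0.8), hi=10.0),
    _f("mood", "psychological", (5.5, 5.9, 6.3), 1.0, (5.9, 6.5, 7.1), 1, hi=10.0),
    _f("motivation", "psychological", (6.0, 6.3, 6.6), 1.0, (6.3, 6.8, 7.3), 1, hi=10.0),
    _f("anxiety", "psychological", (4.9, 4.5, 4.1), 1.0, (4.4, 3.8, 3.2), -1, hi=10.0),
    _f("concentration", "psychological", (6.1, 6.4, 6.7), 0.9, (6.4, 6.9, 7.4), 1, hi=10.0),
    _f("vigor", "psychological", (5.6, 6.0, 6.4), 1.0, (6.0, 6.6, 7.2), 1, hi=10.0),
    _f("depression_index", "psychological", (3.4, 3.1, 2.8), 1.0, (3.0, 2.5, 2.0), -1, hi=10.0),
    _f("mental_toughness", "psychological", (5.7, 6.0, 6.3), 0.9, (6.0, 6.5, 7.0), 1, hi=10.0),
    _f("wellbeing", "psychological", (5.8, 6.2, 6.6), 0.9, (6.3, 6.9, 7.5), 1, hi=10.0),
    # -- nutritional (18), stable by design (naturalistic diet) ------------
    _f("energy_intake_kcal", "nutritional", (3420, 3180, 3260), 320, (3420, 3180, 3260)),
    _f("carb_pct_energy", "nutritional", (64.5, 50.0, 55.0), 2.5, (64.5, 50.0, 55.0), hi=100.0),
    _f("protein_g_per_kg", "nutritional", (1.00, 1.90, 1.40), (0.10, 0.15, 0.09),
       (1.00, 1.90, 1.40)),
    _f("fat_pct_energy", "nutritional", (22.0, 28.0, 27.0), 3.0, (22.0, 28.0, 27.0), hi=100.0),
    _f("vitamin_d_ug", "nutritional", (12.0, 15.0, 19.0), 4.0, (12.0, 15.0, 19.0)),
    _f("vitamin_b12_ug", "nutritional", (4.2, 5.8, 5.1), 1.2, (4.2, 5.8, 5.1)),
    _f("folate_ug", "nutritional", (380, 410, 450), 60, (380, 410, 450)),
    _f("iron_mg", "nutritional", (14.0, 18.0, 16.5), 3.0, (14.0, 18.0, 16.5)),
    _f("zinc_mg", "nutritional", (10.0, 13.0, 12.0), 2.2, (10.0, 13.0, 12.0)),
    _f("omega3_g", "nutritional", (1.1, 1.6, 2.0), 0.4, (1.1, 1.6, 2.0)),
    _f("fiber_g", "nutritional", (28.0, 24.0, 32.0), 5.0, (28.0, 24.0, 32.0)),
    _f("calcium_mg", "nutritional", (950, 1100, 1150), 180, (950, 1100, 1150)),
    _f("magnesium_mg", "nutritional", (340, 380, 410), 60, (340, 380, 410)),
    _f("vitamin_c_mg", "nutritional", (95, 110, 135), 28, (95, 110, 135)),
    _f("hydration_l", "nutritional", (3.2, 3.4, 3.3), 0.5, (3.2, 3.4, 3.3)),
    _f("caffeine_mg", "nutritional", (180, 160, 150), 60, (180, 160, 150)),
    _f("sugar_pct_energy", "nutritional", (18.0, 12.0, 13.0), 3.0, (18.0, 12.0, 13.0), hi=100.0),
    _f("micronutrient_diversity", "nutritional", (5.5, 6.5, 7.8), 1.0, (5.5, 6.5, 7.8), hi=10.0),
    # -- immunological (15) ------------------------------------------------
    _f("il6", "immunological", (3.24, 2.76, 2.31), (0.82, 0.75, 0.68),
       (3.02, 2.38, 1.82), -1, end_sd=(0.78, 0.70, 0.62)),
    _f("tnf_alpha", "immunological", (9.56, 8.84, 7.92), (1.23, 1.15, 1.08),
       (9.05, 7.95, 6.72), -1),
    _f("crp", "immunological", (3.85, 3.42, 2.98), (0.96, 0.88, 0.81),
       (3.55, 2.95, 2.35), -1),
    _f("iga", "immunological", (176.3, 185.7, 198.5), (19.2, 17.8, 18.6),
       (182.0, 197.5, 216.0), 1),
    _f("cortisol", "immunological", (458.3, 441.2, 436.8), (82.1, 79.5, 77.3),
       (398.7, 342.5, 298.4), -1, end_sd=(71.4, 68.2, 62.1)),
    _f("wbc_count", "immunological", (6.8, 6.5, 6.2), 1.2, (6.6, 6.2, 5.8), -1),
    _f("lymphocyte_pct", "immunological", (30.0, 31.5, 33.0), 4.0, (31.0, 33.0, 35.0), 1, hi=100.0),
    _f("neutrophil_pct", "immunological", (58.0, 56.5, 55.0), 5.0, (57.0, 55.0, 53.0), -1, hi=100.0),
    _f("monocyte_pct", "immunological", (7.2, 7.0, 6.8), 1.2, (7.1, 6.9, 6.7), -1, hi=100.0),
    _f("nk_cell_count", "immunological", (210, 225, 240), 45, (220, 245, 270), 1),
    _f("il10", "immunological", (4.1, 4.5, 5.0), 1.0, (4.4, 5.1, 5.8), 1),
    _f("il1b", "immunological", (2.9, 2.6, 2.3), 0.7, (2.7, 2.3, 1.9), -1),
    _f("igg", "immunological", (10.8, 11.2, 11.8), 1.6, (11.0, 11.6, 12.4), 1),
    _f("igm", "immunological", (1.15, 1.22, 1.30), 0.28, (1.18, 1.28, 1.38), 1),
    _f("eosinophil_pct", "immunological", (2.8, 2.7, 2.6), 0.9, (2.8, 2.7, 2.6), 0, hi=100.0),
    # -- performance (7) ---------------------------------------------------
    _f("vo2max", "performance", (58.2, 60.1, 62.4), (6.3, 5.8, 6.1),
       (59.5, 62.0, 64.8), 1),
    _f("training_volume_h", "performance", (12.5, 12.8, 12.3), (3.1, 2.9, 3.3),
       (12.5, 12.8, 12.3)),
    _f("training_load", "performance", (850, 880, 840), 160, (850, 880, 840)),
    _f("hrv_rmssd", "performance", (62, 66, 70), 14, (65, 70, 76), 1),
    _f("resting_hr", "performance", (52, 51, 50), 5, (51, 49.5, 48), -1),
    _f("competition_score", "performance", (71, 73, 75), 8, (73, 76, 79), 1, hi=100.0),
    _f("recovery_index", "performance", (6.2, 6.5, 6.8), 1.0, (6.5, 7.0, 7.5), 1, hi=10.0),
)

FEATURE_NAMES: tuple[str, ...] = tuple(f.name for f in FEATURES)
FEATURES_BY_NAME: Mapping[str, FeatureDef] = {f.name: f for f in FEATURES}
PSYCH_CORE: tuple[str, ...] = ("fatigue", "stress", "sleep_quality", "resilience")

assert len(FEATURES) == 52
assert tuple(sum(f.domain == d for f in FEATURES) for d in DOMAINS) == (12, 18, 15, 7)

#: truncation region of the macronutrient intake columns per dietary group,
#: chosen so the published classification rules reproduce the group labels:
#: high-carb >60% energy from carbohydrate and <1.2 g/kg protein; high-protein
#: >=1.6 g/kg with 45-55% carbohydrate; balanced 50-60% with 1.2-1.6 g/kg.
DIET_RULES: Mapping[str, Mapping[str, tuple[float, float]]] = {
    "high_carb": {"carb_pct_energy": (60.5, 72.0), "protein_g_per_kg": (0.60, 1.19)},
    "high_protein": {"carb_pct_energy": (45.2, 54.8), "protein_g_per_kg": (1.61, 2.60)},
    "balanced": {"carb_pct_energy": (50.2, 59.8), "protein_g_per_kg": (1.21, 1.59)},
}


def classify_diet(carb_pct_energy: float, protein_g_per_kg: float) -> str:
    """Dietary pattern label from macronutrient intake (published rules)."""
    if carb_pct_energy > 60.0 and protein_g_per_kg < 1.2:
        return "high_carb"
    if protein_g_per_kg >= 1.6 and 45.0 <= carb_pct_energy <= 55.0:
        return "high_protein"
    if 50.0 <= carb_pct_energy <= 60.0 and 1.2 <= protein_g_per_kg <= 1.6:
        return "balanced"
    return "unclassified"


@dataclass(frozen=True)
class TertileDynamics:
    """Response-trajectory timing of one resilience tertile (months)."""

    onset_months: float
    rate_per_month: float
    plateau_months: float
    onset_sd: float = 0.4
    plateau_sd: float = 1.2


class ConfigurationError(ValueError):
    """Raised when a scenario configuration violates its invariants."""


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Defaults reproduce the published cohort: 68/65/67 athletes across the
    three dietary groups, 24 bi-weekly assessments, a 3-step (~1.5 month)
    psychology-before-immunity lag, the diet -> psychology -> cortisol ->
    immunity serial chain, and resilience-tertile response dynamics.
    """

    n_per_group: tuple[int, int, int] = (68, 65, 67)
    n_timepoints: int = 24
    baseline_profiles: dict[str, FeatureDef] = field(
        default_factory=lambda: dict(FEATURES_BY_NAME)
    )
    lag_steps: int = 3
    #: (a1, a2, b2, c_prime) of the serial chain; b1 is the direct
    #: psychology -> immunity path.
    mediation_coeffs: tuple[float, float, float, float] = (0.5, 0.6, 0.4, 0.2)
    b1: float = 0.3
    subgroup_dynamics: dict[str, TertileDynamics] = field(
        default_factory=lambda: {
            "high": TertileDynamics(1.2, 0.43, 6.8, 0.3, 1.2),
            "moderate": TertileDynamics(2.1, 0.18, 9.5, 0.5, 1.8),
            "low": TertileDynamics(3.8, 0.10, 11.2, 0.9, 2.1),
        }
    )
    missing_rate: float = 0.05
    outlier_rate: float = 0.01
    seed: int = 0
    # -- secondary knobs (magnitudes the source leaves unstated) ----------
    #: within-athlete noise SD as a fraction of the cross-sectional SD
    within_noise_frac: float = 0.30
    #: AR(1) coefficient of within-athlete latent deviations
    ar_rho: float = 0.5
    #: share of within-athlete noise carried by the shared domain latent
    #: (sets the strength of the lagged psychology->immunity coupling)
    domain_noise_share: float = 0.75
    #: loading of the baseline psychoneuroimmune axis, calibrated so the
    #: first canonical correlation between the psychological and immune
    #: blocks matches the published r1 = 0.847
    axis_loading: float = 0.68
    #: baseline -> endpoint within-athlete tracking coefficient (strong
    #: trait stability; also keeps the attained change from being dominated
    #: by the athlete's own baseline)
    persistence: float = 0.72
    #: planted response-propensity loadings on centred baseline scores;
    #: resilience carries the dominant loading (the planted predictor
    #: hierarchy resilience > fatigue > stress > sleep quality)
    propensity_loadings: dict[str, float] = field(
        default_factory=lambda: {
            "resilience": 0.75, "fatigue": -0.18, "stress": -0.12,
            "sleep_quality": 0.08,
        }
    )
    #: endpoint shift (in endpoint SDs) per SD of response propensity
    propensity_effect: float = 0.50

    # ------------------------------------------------------------------
    @property
    def n_athletes(self) -> int:
        return int(sum(self.n_per_group))

    @property
    def cortisol_lag_steps(self) -> int:
        return max(self.lag_steps // 2, 1) if self.lag_steps > 0 else 0

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(self.baseline_profiles)

    def month_of_index(self, t: float) -> float:
        return month_of_index(t, self.n_timepoints)

    def validate(self) -> "CohortSpec":
        if any(n <= 0 for n in self.n_per_group):
            raise ConfigurationError(f"non-positive group size: {self.n_per_group}")
        if self.n_timepoints < 2:
            raise ConfigurationError("n_timepoints must be >= 2")
        if self.lag_steps < 0:
            raise ConfigurationError("lag_steps must be >= 0")
        if not 0.0 <= self.missing_rate < 0.2:
            raise ConfigurationError(
                f"missing_rate {self.missing_rate} outside [0, 0.2): cohort "
                "inclusion requires <20% missing values per athlete"
            )
        if not 0.0 <= self.outlier_rate < 0.5:
            raise ConfigurationError("outlier_rate outside [0, 0.5)")
        for feat in self.baseline_profiles.values():
            if any(s <= 0 for s in feat.sd) or any(s <= 0 for s in feat.end_sd):
                raise ConfigurationError(f"feature {feat.name!r} has SD <= 0")
            if feat.domain == "psychological" and not all(
                0.0 <= m <= 10.0 for m in feat.baseline + feat.endpoint
            ):
                raise ConfigurationError(
                    f"psychological scale {feat.name!r} mean outside [0, 10]"
                )
        for name, dyn in self.subgroup_dynamics.items():
            if dyn.onset_months > dyn.plateau_months:
                raise ConfigurationError(f"tertile {name!r}: onset after plateau")
        return self

    # -- (de)serialisation ---------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["baseline_profiles"] = {
            k: dataclasses.asdict(v) for k, v in self.baseline_profiles.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortSpec":
        d = dict(d)
        if "baseline_profiles" in d:
            profiles = {}
            for k, v in d["baseline_profiles"].items():
                v = dict(v)
                for key in ("baseline", "sd", "endpoint", "endpoint_sd"):
                    if v.get(key) is not None:
                        v[key] = tuple(v[key])
                profiles[k] = FeatureDef(**v)
            d["baseline_profiles"] = profiles
        if "subgroup_dynamics" in d:
            d["subgroup_dynamics"] = {
                k: v if isinstance(v, TertileDynamics) else TertileDynamics(**v)
                for k, v in d["subgroup_dynamics"].items()
            }
        for key in ("n_per_group", "mediation_coeffs"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d).validate()

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload.get("cohort", payload))


@dataclass
class PreprocessConfig:
    """Cleaning / normalisation pipeline thresholds."""

    outlier_k: float = 3.0
    shapiro_alpha: float = 0.05
    #: |skewness| required in addition to the Shapiro-Wilk gate before a log
    #: transform is applied (guards against trivially significant p at n=200)
    skew_gate: float = 1.0
    mice_iterations: int = 10
    mice_seed: int = 0
    #: features rescaled to the 0-10 scale instead of z-scored
    rescale_0_10: tuple[str, ...] = PSYCH_CORE + (
        "mood", "motivation", "anxiety", "concentration", "vigor",
        "depression_index", "mental_toughness", "wellbeing",
    )

    def validate(self) -> "PreprocessConfig":
        if self.outlier_k <= 0:
            raise ConfigurationError("outlier_k must be > 0")
        if not 0.0 < self.shapiro_alpha < 1.0:
            raise ConfigurationError("shapiro_alpha must be in (0, 1)")
        return self


@dataclass
class TemporalBranchConfig:
    """Stacked-recurrent branch hyperparameters.

    The full-size profile mirrors the published architecture: embedding
    52->128, LSTM(128), bidirectional LSTM(256 total), LSTM(64), dropout 0.3,
    Adam(lr=1e-3, betas=(0.9, 0.999)), batch 32, <=100 epochs, patience 10.
    """

    embed_dim: int = 128
    layer_sizes: tuple[int, ...] = (128, 256, 64)
    bidirectional: tuple[bool, ...] = (False, True, False)
    dropout: float = 0.3
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 100
    adam_betas: tuple[float, float] = (0.9, 0.999)
    early_stop_patience: int = 10
    seed: int = 0

    def validate(self) -> "TemporalBranchConfig":
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigurationError("dropout must be in [0, 1)")
        if self.early_stop_patience > self.max_epochs:
            raise ConfigurationError("patience must be <= max_epochs")
        if len(self.layer_sizes) != len(self.bidirectional):
            raise ConfigurationError("layer_sizes and bidirectional differ in length")
        if any(b and s % 2 for s, b in zip(self.layer_sizes, self.bidirectional)):
            raise ConfigurationError("bidirectional layer sizes must be even")
        return self

    @classmethod
    def desk_scale(cls, seed: int = 0) -> "TemporalBranchConfig":
        """Shrunken profile (same shape) used for tests and desk runs."""
        return cls(embed_dim=32, layer_sizes=(32, 64, 16),
                   bidirectional=(False, True, False), max_epochs=60, seed=seed)


@dataclass
class BoostBranchConfig:
    """Gradient-boosting branch hyperparameters (published defaults)."""

    n_estimators: int = 500
    max_depth: int = 6
    learning_rate: float = 0.1
    subsample: float = 0.8
    seed: int = 0

    def validate(self) -> "BoostBranchConfig":
        if self.n_estimators < 1:
            raise ConfigurationError("n_estimators must be >= 1")
        if not 0.0 < self.subsample <= 1.0:
            raise ConfigurationError("subsample must be in (0, 1]")
        return self

    @classmethod
    def desk_scale(cls, seed: int = 0) -> "BoostBranchConfig":
        return cls(n_estimators=100, max_depth=4, seed=seed)


@dataclass
class HybridConfig:
    """End-to-end hybrid model configuration."""

    temporal: TemporalBranchConfig = field(default_factory=TemporalBranchConfig)
    boost: BoostBranchConfig = field(default_factory=BoostBranchConfig)
    fusion_dim: int = 16
    fusion_epochs: int = 600
    fusion_lr: float = 0.01
    #: MCID on the primary psychological outcome defining a responder
    responder_mcid: float = 1.0
    seed: int = 0

    @classmethod
    def desk_scale(cls, seed: int = 0) -> "HybridConfig":
        return cls(temporal=TemporalBranchConfig.desk_scale(seed),
                   boost=BoostBranchConfig.desk_scale(seed),
                   fusion_dim=8, seed=seed)


@dataclass
class PipelineConfig:
    """Whole-run configuration (the YAML schema the CLI consumes)."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    hybrid: HybridConfig = field(default_factory=lambda: HybridConfig.desk_scale())
    train_frac: float = 0.8
    n_folds: int = 5
    gap_steps: int = 4
    val_window: int = 3
    n_boot: int = 1000
    max_lag: int = 8
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)

    @classmethod
    def from_dict(cls, payload: Mapping) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigurationError(
                f"unknown configuration keys: {sorted(unknown)}; expected a "
                f"subset of {sorted(known)}"
            )
        kw = dict(payload)
        if "cohort" in kw and not isinstance(kw["cohort"], CohortSpec):
            kw["cohort"] = CohortSpec.from_dict(kw["cohort"])
        if "preprocess" in kw and not isinstance(kw["preprocess"], PreprocessConfig):
            kw["preprocess"] = PreprocessConfig(**kw["preprocess"]).validate()
        if "hybrid" in kw and not isinstance(kw["hybrid"], HybridConfig):
            h = dict(kw["hybrid"])
            if "temporal" in h:
                h["temporal"] = TemporalBranchConfig(**{
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in h["temporal"].items()
                }).validate()
            if "boost" in h:
                h["boost"] = BoostBranchConfig(**h["boost"]).validate()
            kw["hybrid"] = HybridConfig(**h)
        cfg = cls(**kw)
        cfg.cohort.validate()
        cfg.preprocess.validate()
        return cfg
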