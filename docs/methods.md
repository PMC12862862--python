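# Methods

This note documents the models, generator, numerical choices and
limitations behind `pni`.  The package's purpose is twofold: to provide a
calibrated synthetic testbed for psychoneuroimmune (nutrition → psychology
→ immunity) analyses in longitudinal athlete cohorts, and to provide the
analyses themselves as tested, reusable operations.

## 1. Synthetic cohort model

### Design

Each cohort has `N = Σ n_per_group` athletes (default 68/65/67 across the
high-carbohydrate, high-protein and balanced dietary groups) observed at
`T` bi-weekly assessments (default 24).  Calendar time is mapped as
`month(t) = 12·t/(T−1)`, so index 0 is the baseline assessment and index
`T−1` the 12-month endpoint.  Every feature is defined by a
`FeatureDef` carrying per-group baseline mean/SD, 12-month endpoint
mean/SD, an improvement direction (+1 larger-is-better, −1
smaller-is-better, 0 no planted axis) and a support range.  The named
psychological scales live on 0–10; concentrations are positive.

### Baseline cross-section

A single latent psychoneuroimmune axis `q_i ~ N(0,1)` couples the baseline
blocks: every direction-carrying marker is drawn as
`μ + σ(λ·d·q_i + √(1−λ²)·ε)` with loading `λ = axis_loading = 0.68`,
calibrated once so that the first canonical correlation between the core
psychological block (fatigue, stress, sleep quality, resilience) and the
core immune block (IL-6, TNF-α, CRP, IgA) is ≈ 0.85 at n = 200.
Macronutrient intake (carbohydrate % energy, protein g/kg) is drawn from
truncated normals inside each group's classification region, so the
published labelling rules (high-carb > 60 % energy carbohydrate with
< 1.2 g/kg protein; high-protein ≥ 1.6 g/kg with 45–55 % carbohydrate;
balanced 50–60 % with 1.2–1.6 g/kg) reproduce the group labels exactly.

Resilience tertiles are assigned cohort-wide from baseline resilience,
ties broken by athlete id; with n = 200 the sizes are 67/66/67 (the
remainder goes to the outer tertiles).

### Trajectories

Each athlete follows a saturating-exponential response from their own
baseline to their own endpoint draw:

    s(m) = [1 − exp(−r·(m − onset)₊)] / [1 − exp(−r·(12 − onset))],
    r = 3 / (plateau − onset),

so the change is zero before the onset month, ~95 % complete at the
tertile's plateau month, and exactly complete at month 12 (anchoring the
endpoint calibration).  Onset/plateau are drawn per athlete around the
tertile dynamics (defaults: high 1.2 → 6.8 months, moderate 2.1 → 9.5,
low 3.8 → 11.2, jitter per the published SDs).  A tertile configured with
`rate_per_month = 0` is interpreted as a null-dynamics tertile and stays
at baseline.  Lagged markers (immune features; cortisol at half the lag)
use the same shape shifted right by `lag_steps` bi-weekly steps (default
3 ≈ 1.5 months), renormalised to still reach the endpoint at month 12 —
a deliberate compromise: the printed 12-month marker means are anchored
exactly, at the cost of slightly compressing the threshold-crossing lag
(measured ≈ 1.4 months for a planted 1.57).

Endpoint draws implement the planted structure on the change scale:

    end = μ_end + φ·(base − μ_base)·(σ_end/σ_base) + d·σ_end·c·η + residual

with persistence `φ = 0.72` (strong trait tracking; also prevents the
attained change from being dominated by the athlete's own baseline) and
propensity effect `c = 0.50`.  The response propensity is a weighted sum
of group-centred core psychological baselines (loadings: resilience 0.75,
fatigue −0.18, stress −0.12, sleep quality 0.08) — resilience is the
planted primary determinant of response.  The per-domain endpoint latents
chain serially: `η_cort = a₂·η_psych + …`, `η_imm = b₂·η_cort + b₁·η_psych
+ …`, so change-score regressions find a serial indirect path.  Group
means are unaffected (latents are centred), preserving calibration.

### Within-athlete noise

AR(1) latents (ρ = 0.5) per domain carry `domain_noise_share = 0.75` of
the within-athlete noise (SD = 0.30 of the cross-sectional SD); the
cortisol latent lags the psychological latent by `⌊lag/2⌋` steps and the
immune latent by the full lag, through the mediation coefficients.  This
makes the lag-correlation scan peak sharply at the planted lag (recovered
±1 step in ≥ 90 % of seeds).  The peak magnitude is bounded by the chain
strength (a₂·b₂ + b₁ = 0.54), giving peak r ≈ 0.5; stronger peaks would
require inflating the planted mediation coefficients, and pushing the
noise share higher turns the realised trajectories into such strong
latent proxies that the baseline-predictor hierarchy (below) degrades —
0.75 balances the two planted structures.

### Degradation

Missingness is MCAR at `missing_rate` (default 5 %), capped at 19 % per
athlete (the cohort inclusion rule is < 20 %).  Outliers (default 1 % of
cells) are displaced ≥ 4 pooled SDs from the feature mean, guaranteeing
detection by the 3-SD screen.  A sidecar mask records ground truth for
both, so imputation error and screen sensitivity are measurable.

### What the generator does *not* emulate

Real cohorts have non-Gaussian marginals, informative (MAR/MNAR) dropout,
measurement batch effects, seasonal confounding and inter-feature
correlation beyond the single axis + domain latents modelled here.
Passing tests demonstrate that the analysis operations recover structure
*of the planted kind at the planted strength*; they do not certify
performance on real data.

## 2. Preprocessing

Order: outlier screen → imputation → normalisation → feature engineering.
The screen flags cells strictly beyond `outlier_k = 3` pooled SDs
(a value at exactly 3 SD is retained; constant features produce no
flags) and converts them to missing.  Imputation is chained-equations
(IterativeImputer, Bayesian-ridge conditionals, 10 iterations, one
completed dataset, seeded); observed cells are never altered.  A feature
is log-transformed before z-scoring only if it fails Shapiro–Wilk at
α = 0.05 **and** |skewness| > 1 **and** is strictly positive — the extra
skewness gate exists because Shapiro–Wilk is trivially significant at
n = 4800 cells.  The 12 psychological scales are min-max rescaled to
0–10 instead.  All scaling parameters are estimated on training athletes
only.  Engineering adds nutrition × training-phase interaction products,
annual sine/cosine terms (period 26 bi-weekly steps), and composite
indices (means of z-scored members); a weekly-averaging helper collapses
finer-grained inputs.

The temporal split is an 80/20 athlete holdout stratified by dietary
group (160/40 at n = 200) plus forward-chaining folds over time:
validation windows of `val_window = 3` steps, contiguous, ending one step
before the series end (starts {8, 11, 14, 17, 20} at T = 24), each
trained on `[0, start − gap)` with `gap = 4` bi-weekly steps (two
months).  The gap inequality is re-validated before any model training.

## 3. Hybrid predictor

The temporal branch is a from-scratch numpy LSTM — embedding, stacked
layers (full profile 128 / bidirectional 256 / 64; desk profile
32 / 64 / 16), inverted dropout 0.3, linear head on the final hidden
state, Adam (lr 10⁻³, β = 0.9/0.999), batch 32, ≤ 100 epochs, early
stopping with patience 10.  Gradients are hand-derived BPTT and verified
against finite differences.  Targets are standardised internally.  The
boosting branch is one XGBoost regressor per outcome (full profile 500
trees, depth 6, lr 0.1, subsample 0.8) on a static table of baseline
values plus window means and slopes.

Fusion follows `z = α₁h₁ + α₂h₂`, `α = softmax(W[h₁;h₂])`, over the two
branches' per-outcome prediction vectors projected to a common dimension.
Prediction vectors (not hidden states) enter the fusion because the
fusion is trained on **cross-fitted** branch outputs (5-fold, stacking
hygiene) and hidden representations from independent refits live in
unaligned coordinate systems.  An internal 4-fold CV selects among four
fusion variants — boost passthrough, temporal passthrough,
constant-attention stack, trained gate — with complexity margins (the
stack must win by 20 %, the trained gate by 50 %); with the stacking
sample sizes typical here (tens of athletes) an input-dependent gate is
rarely supportable and the default keeps `W = 0` (α ≡ ½, ½).  This is
what makes the fused model provably no worse than its better branch up
to selection noise.

Per CV fold, branches fit on ~80 % of training athletes with features
from the fold's training window and targets from its validation window;
the held-out athletes give out-of-sample fold RMSEs for hybrid and both
single branches.  The final model refits on all training athletes with
the last fold's geometry.  The non-responder classifier scores athletes
by predicted primary-outcome improvement; its threshold is Youden-optimal
on out-of-fold scores from the late folds (whose windows match the
12-month responder label).  A non-responder fails the MCID
(≥ 1.0-point improvement, or 0.5 baseline SD if larger) on fatigue.

Evaluation: RMSE, R², MAPE (truth values with |y| < 0.1 excluded), AUC as
the normalised rank statistic, sensitivity/specificity at the stored
threshold.  Degenerate single-class labels yield NA with a warning.

## 4. Attribution

Shapley values are estimated by permutation sampling: each Monte-Carlo
draw pairs a background row with a random player ordering and telescopes
the prediction difference, so per-instance attributions sum *exactly* to
`f(x) − (mean background prediction over draws)`; Monte-Carlo error
affects only the background expectation (∝ 1/√n_samples).  Players may
be groups of columns — the pipeline attributes each underlying feature's
baseline/mean/slope views as one player.

The pipeline's attribution target is the predicted 12-month psychological
response (direction-aligned composite of fatigue, stress and resilience
improvements) from the hybrid's **early-identification view**: the same
architecture refitted with the first two months of data as input.  With
the full 8-month input window the static aggregates already contain the
realised response, and attribution degenerates to "each outcome's own
trajectory predicts itself"; the early window asks the scientifically
intended question — which baseline characteristics predict who will
respond — and under it the planted hierarchy (resilience > fatigue >
stress > sleep quality) is recovered.

## 5. Inference

- Lag scan: within-athlete correlation of a(t) with b(t+ℓ), Fisher-z
  averaged across athletes, bootstrap CIs over athletes; positive peak
  lag means series A leads.  With one athlete this reduces to the plain
  series correlation.
- First canonical correlation: whitening formulation
  (largest singular value of `Σxx^{-1/2} Σxy Σyy^{-1/2}`), ridge
  regularised with a warning if a within-block covariance is singular.
- Serial mediation: OLS path regressions (`m₁ ~ x`; `m₂ ~ m₁ + x`;
  `y ~ x + m₁ + m₂`; `y ~ x`), indirect effects as coefficient products
  (simple a₁b₁, serial a₁a₂b₂, plus the x→m₂ remainder d₂b₂), 5000-draw
  (desk: 1000) bias-corrected percentile bootstrap.  Designs with
  condition number > 10⁶ are rejected — note this means an *exactly*
  noise-free serial chain is unidentified (the mediators are collinear
  with the exposure); recovery properties are therefore stated in the
  small-noise large-n limit.
- ARIMA: maximum-likelihood fits over p, q ≤ 2, d ≤ 1; orders within 2
  AIC units of the minimum are treated as equivalent and the most
  parsimonious wins.  Plain minimum-AIC selection picks spuriously
  inflated orders on a true AR(1) in roughly half of simulated series;
  with the parsimony window the selected model is a stationary
  autoregression essentially always and exactly (1,0,0) in a majority of
  seeds, with φ̂ recovered.
- Multiplicity: Bonferroni within variable families (psychological,
  immune, performance), p·m capped at 1.

## 6. Subgroup analysis

Change summaries report Δ (endpoint − baseline means), percent change
(|Δ|/baseline mean), Cohen's d with pooled baseline/endpoint SD, and the
share of athletes meeting the MCID in the beneficial direction (boundary
counts); the within-group test is paired-t, or Wilcoxon when the
differences fail the normality gate.  Response characterisation
operationalises onset as the earliest month with cumulative improvement
≥ 0.5 baseline SD sustained for two consecutive assessments, plateau as
the earliest post-onset month where the rolling three-point slope drops
below 0.05 points/month, and rate as the least-squares slope between
them, all interpolated to 0.1-month resolution.  Published per-tertile
improvement *rates* are internally inconsistent with the printed
baselines/endpoints and are therefore not calibrated; only the ordering
(high onset < moderate < low; high plateau < low) is expected.

## 7. Problem sizes and profiles

Three bundled profiles set the compute scale: `smoke` (20 athletes, 12
time points, toy model — seconds), `desk_scale` (full cohort, model
32/64/16 with 100 boosting rounds, 1000 bootstrap draws — minutes on one
CPU; used by the test suite and the acceptance script) and `paper_scale`
(full-size architecture and 5000 bootstrap draws).  Profiles change
capacity and replication counts only, never the architecture shape or
the cohort conditions.  The full-size temporal branch has ~0.9 M
parameters with this head configuration; parameter counts depend on head
widths and are reported by `TemporalNet.n_parameters` rather than
asserted.

## 8. Known limitations

- All planted effects are linear-Gaussian on latent scales; the
  generator cannot produce qualitatively different mediation structures
  (e.g. suppression, exposure-dependent lags).
- The mediation proportion measured on the cohort (~10–30 %) is smaller
  than the published per-group decompositions: group-level differences
  in psychological and immune change are collinear with the diet
  exposure, so a pooled regression attributes them to the direct path.
  Exact coefficient recovery is demonstrated on the stand-alone
  simulator instead.
- Classification sensitivity/specificity at n_test = 40 carry wide
  sampling error; AUC is the stable metric.
- The numpy LSTM is CPU-only and single-threaded; it is sized for
  cohorts of hundreds, not tens of thousands.
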