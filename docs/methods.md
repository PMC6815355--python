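# Methods

This note documents the models implemented in `dceperf`, the defaults and
why they were chosen, what the synthetic data do and do not emulate, and the
numerical conventions a user relying on the outputs should know.

## 1. Heuristic DCE-MRI perfusion quantification

### Relative time–intensity curves

The input is a 4D signal series S(x, y, z, t) acquired at a fixed frame
spacing (default 9 s, 30 frames) with contrast injected after the
pre-contrast block. The baseline level of each voxel is the mean of its
`n_baseline_frames` pre-contrast frames (default 2, since injection during
the third repetition leaves two clean pre-contrast frames; the count is
configurable because acquisition protocols differ). The relative TIC is
s(t) = S(t)/baseline, so s ≡ 1 before contrast arrival. Voxels with a
nonpositive baseline mean cannot be normalised; they are excluded from all
VOI summaries and counted in `PerfusionQuantifier.n_invalid_`.

All metrics are invariant under any positive rescaling of the raw signal
(coil gain, units), which the test suite enforces to 1e-12.

### Enhancement-pattern classification

Each voxel is assigned one of four patterns from threshold rules on a linear
approximation of its TIC. The published classification scheme this emulates
is proprietary and its numeric thresholds unpublished, so the rules here are
an explicit, config-exposed heuristic (`ClassifierThresholds`):

| parameter | default | meaning |
|---|---|---|
| `theta_enh` | 0.10 | minimum relative enhancement for an onset (s ≥ 1.10) |
| `theta_wash` | 0.10 | late decline ≥ 10% of ME ⇒ washout |
| `theta_pers` | 0.05 | late rise ≥ 5% above ME ⇒ persistent |
| `min_late_frames` | 3 | minimum frames in the late least-squares window |
| `smooth_window` | 5 | moving-average window for the classification curve |

Rules, in order: (1) no frame of the smoothed curve reaches 1 + `theta_enh`
⇒ *no-enhancement*; (2) fit a least-squares line from the peak to the final
frame (at least `min_late_frames` frames); (3) fitted end ≤ ME·(1 −
`theta_wash`) ⇒ *washout*; (4) fitted end ≥ ME·(1 + `theta_pers`), or the
peak falls in the final two frames with positive late slope ⇒ *persistent*;
otherwise (5) *plateau*. Washout takes precedence over persistent.

The smoothing uses a **valid-region** moving average: every smoothed sample
averages exactly `smooth_window` raw frames. Replicate-edge filters inflate
noise variance at the series ends, which is precisely where the
peak-position rules look; valid-region averaging keeps the variance uniform
and was the difference between ~74% and ~94% recovery at SNR 20 during
development. TICs too short to smooth fall back to the raw curve. Reported
per-voxel metrics (ME, IRE, IRW, onset/peak frames) are always computed on
the **raw** TIC so that exact piecewise-linear inputs reproduce their closed
forms to 1e-9; only the class label uses the smoothed curve.

Conventions: indices are 0-based (x, y, z, frame); the peak is the first
frame attaining the maximum (tie-break); IRE is floored at 0 and uses the
single-step rise when onset and peak coincide; IRW needs at least two
post-peak frames, otherwise it is absent. "SNR 20" in the tests means
baseline signal ÷ noise SD = 1/0.05 on the relative-intensity scale.

### VOI aggregation

Nvoxel counts plateau ∪ washout voxels ("highly perfused"); Nvoxel% is its
percentage of all VOI voxels (0–100 scale). VOI-level IRE and ME are means
over **enhancing** voxels only — enhancement onset, and hence IRE, is
undefined for non-enhancing voxels (`enhancing_only=False` switches to
all-voxel means with zero imputation). The composites are literal products:
IRE×Nvoxel, IRE×Nvoxel%, ME×Nvoxel, ME×Nvoxel%; all four are 0 when
Nvoxel = 0, and IRE×Nvoxel% · n_total = 100 · IRE×Nvoxel holds identically.
The *total* VOI pools extensor and flexor voxels before averaging, so its
Nvoxel is exactly the sum of the parts. Excluding major vessels is the mask
author's responsibility, not the quantifier's.

## 2. Synthetic data

### 4D phantom

Canonical TICs are piecewise linear — flat baseline, linear upslope from 1.0
to the peak amplitude, then a class-specific late segment (flat for plateau,
positive slope for persistent, negative for washout) — matching the
linear-approximation classifier rather than smooth gamma-variate kinetics
(a deliberate non-goal, as are arterial input functions, pharmacokinetic
K^trans modelling, field effects and motion). Default shapes (peak
amplitude / onset / frames-to-peak / late slope per frame): persistent
1.4 / 3 / 7 / +0.02, plateau 1.8 / 3 / 7 / 0, washout 2.2 / 3 / 5 / −0.03 —
washout as the artery-like highest-and-fastest curve. Noise is additive
i.i.d. Gaussian on the relative scale, the simplest model that lets
classification accuracy be swept against SNR. Per-voxel baseline intensities
vary ±20% around 100 to exercise the normalisation. The VOI mask is two
rectangular blocks (extensor/flexor) inside a one-voxel border; only the
label bookkeeping matters downstream. Voxel classes are i.i.d. categorical
draws from `pattern_mix`; an `onset_jitter_frames` parameter (default 0)
desynchronises contrast arrival, since real arrival times are not
synchronous across tissue.

What passing tests show: the quantifier inverts exactly the data-generating
process it is given. What they do not show: robustness to motion, partial
volume, vessel contamination, or non-Gaussian scanner noise — real-data
performance claims need real data.

### Trial tables

Change scores follow two linear structural equations (treatment T, female
indicator g, baseline outcome Y₀ and baseline mediator M₀ centred at their
means):

ΔM = a·T + γ_mg·g + γ_mb·(Y₀−μ_Y) + γ_mm·(M₀−μ_M) + ε_M
ΔY = c′·T + b·ΔM + γ_yg·g + γ_yb·(Y₀−μ_Y) + ε_Y

so ACME = a·b, ADE = c′ and total = c′ + a·b exactly. Defaults emulate a
~33-person osteoarthritis exercise trial: 16 per arm (17 controls via
`n_control`), 80% female, baseline pain 57 ± 14 KOOS points, residual SDs
9–10 points, direct effect 7 points, mediator effect a = 8 units with
b = 0.4 points/unit, and mild regression to the mean (γ_mb = −0.1,
γ_mm = −0.2, γ_yb = −0.3). Follow-up = baseline + change without clipping to
the KOOS 0–100 range, keeping the linear structure exact. Attendance,
outside exercise and imaging completeness are generated so the per-protocol
filter has work to do when the corresponding fractions are nonzero (defaults
0: everyone adheres).

The γ_mm term matters: with both residual SDs zero and identical covariates
in both mediation models, ΔM would lie exactly in the span of the outcome
design and the decomposition would be unidentifiable. The mediator's
dependence on its own baseline supplies exogenous variation, so fitting the
mediator model with the mediator's baseline among its covariates makes the
noise-free fit exact (ACME = a·b to machine precision) — the package
exposes `mediator_covariates` for exactly this.

## 3. Trial statistics

**Per-protocol filter**: ET rows need attendance ≥ 24 of 36 sessions
(boundary inclusive — "12 or fewer non-attendances"), controls must not have
exercised, and imaging must be complete at both timepoints. The filter
emits a flow log counting exclusions by first failing rule.

**ANCOVA**: OLS of change on intercept, baseline, arm (ET = 1) and gender
(female = 1, the majority class; coding chosen so the arm coefficient is
the ET−CG difference as conventionally reported). Inference is normal-theory
t-based. Adjusted means are classic least-squares means: model predictions
per arm with every other covariate at its pooled sample mean, with SEs from
the coefficient covariance. The sensitivity variant adds age and weight
only — gender is already a covariate of the primary model, so "adding
age, weight and gender" reduces to adding the two. Missing data:
pairwise-complete per outcome, no imputation (a completers analysis).
Rank-deficient designs raise an error naming a removable covariate.

**Spearman**: `scipy.stats.spearmanr` per pair on pairwise-complete
observations (average-rank ties, two-sided t approximation with n−2 df,
appropriate at the n ≈ 33 scale); an exact permutation null is available for
n ≤ 9. Pairs with fewer than 4 complete observations are flagged absent.
No multiplicity correction is applied by default — these are exploratory
correlations; apply Holm externally if confirmatory use is intended.

**ICC**: two-way random-effects, absolute-agreement, single-measurement
ICC(A,1) from the mean-squares decomposition, with the F-distribution
confidence interval of McGraw & Wong; cross-checked against
`pingouin.intraclass_corr` in the tests. Zero between-subject variance
yields ICC 0 with a warning and an undefined interval.

## 4. Causal mediation

Point estimates come from the two OLS structural models with no
treatment×mediator interaction (a single ACME is reported, which is only
coherent in the no-interaction linear case; the product-of-coefficients and
difference-of-coefficients estimators then coincide, and
total = ACME + ADE holds to 1e-10 by construction). Both models adjust for
the primary-analysis covariates (baseline pain, gender) by default;
`mediator_covariates` can differ (see §2).

Uncertainty: seeded nonparametric bootstrap, case-resampling participants
(not residuals — the nonparametric default), refitting both models per
resample. Intervals are percentile (the simplest method consistent with
bootstrap variance estimation; BCa was considered and not implemented — a
deliberate scope cut, not an oversight). Bootstrap p = 2·min(Pr*(θ* ≤ 0),
Pr*(θ* ≥ 0)), capped at 1. The proportion mediated is the ratio of point
estimates; its CI is the percentile interval of the per-resample ratio with
|total| < 1e-8 resamples dropped and counted (`n_prop_dropped_`), since the
ratio is unstable near a null total effect. Resamples that lose an arm or
leave the mediator constant are redrawn and counted. `mediate_all` analyses
each mediator with seed = base + index of first occurrence, so rows are
independently reproducible and duplicate mediators give identical rows.
Published proportion-mediated intervals sometimes mix proportion and
effect scales; this implementation reports proportions strictly as
fractions of the total effect.

## 5. Pipeline and problem sizes

One global seed fans out by fixed offsets (trial +1, imaging +100 with
2 per participant×timepoint, mediation +3). The manifest written with every
run echoes the full config and suffices to reproduce any output. Control
follow-up volumes shift `cg_followup_decline` (default 15%) of the highly
perfused class mass to no-enhancement, emulating perfusion decline without
exercise while the exercise arm is maintained.

Default problem sizes were chosen so a full verification run completes in
well under a minute on one core while keeping Monte-Carlo error small:
2000-voxel phantoms for recovery rates, 1000 simulated 33-person trials for
the type-I error of ANCOVA, and 200 replicate trials (n = 200, 300 bootstrap
resamples each) for mediation recovery and coverage. Because the ACME
estimator at that size has sampling SD ≈ 0.23, recovery is asserted on the
replicate mean (MC se ≈ 0.016) rather than a single draw.

## Known limitations

- Classifier thresholds are heuristics labelled as such; they separate the
  canonical shapes, not any particular scanner's data.
- Whether IRE's %/s refers to the 0–1 or 0–100 relative scale is a
  convention; this package uses 100·Δs/Δt and keeps Nvoxel% on the 0–100
  scale throughout, so composite magnitudes follow that choice.
- The mediation model assumes sequential ignorability; no sensitivity
  analysis for unmeasured mediator–outcome confounding is provided.
- Smallest-detectable-change computations for the perfusion variables are
  out of scope.
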