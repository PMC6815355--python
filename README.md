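# dceperf

Quantification of skeletal-muscle perfusion from dynamic contrast-enhanced
MRI (DCE-MRI) and the statistical analysis of a two-arm exercise trial built
on top of it: baseline-adjusted ANCOVA of change scores, Spearman correlation
of changes, agreement ICC, and bootstrap causal mediation of the
treatment→pain effect through perfusion. The target use case is exercise
trials in knee osteoarthritis, where the question is whether the
pain-relieving effect of exercise therapy travels through changes in
peri-articular muscle perfusion.

No patient imaging or trial data ship with the package. A first-class
synthetic-data module generates 4D DCE phantoms with known voxel labels and
trial tables with a known treatment→mediator→outcome structure, so every
stage is testable end to end.

## The model

**Perfusion quantification.** Each voxel's signal S(t) over a 30-frame, 9 s
resolution series is normalised by its pre-contrast baseline (mean of the
first 2 frames) into a relative time–intensity curve s(t) with baseline 1.0.
A threshold rule on a moving-average linear approximation assigns each voxel
one of four enhancement patterns — *no-enhancement*, *persistent* (still
rising at series end), *plateau*, *washout* (rise then decline) — and the
per-voxel metrics

- ME = max_t s(t) (maximal enhancement),
- IRE = 100·(s(t_peak) − s(t_onset)) / ((t_peak − t_onset)·Δt) in %/s
  (initial rate of enhancement),
- IRW = least-squares post-peak slope in %/s (diagnostic),

are pooled over each volume of interest (extensor, flexor, total muscle)
into eight variables: Nvoxel and Nvoxel% (count/percentage of *highly
perfused* voxels, i.e. plateau ∪ washout), VOI-mean IRE and ME, and the
composites IRE×Nvoxel, IRE×Nvoxel%, ME×Nvoxel, ME×Nvoxel%.

**Trial statistics.** For each outcome Y, the change Δ = Y₁ − Y₀ is analysed
in the per-protocol population (≥ 24/36 exercise sessions in the exercise
arm; no exercise in controls; complete imaging at both timepoints) by OLS
ANCOVA

Δ = β₀ + β_b·Y₀ + β_T·T + β_g·female + ε,

where β_T is the adjusted ET−CG mean difference and least-squares means fix
covariates at their pooled averages. Mediation uses the two linear
structural models ΔM = α₀ + a·T + … and ΔY = γ₀ + c′·T + b·ΔM + …, giving
ACME = a·b, ADE = c′, total effect = c′ + a·b (exact decomposition), with
percentile CIs from a seeded nonparametric case-resampling bootstrap and
proportion mediated = ACME/total.

## Worked example

```python
from dceperf import (SynthImagingConfig, generate_dce_volume,
                     PerfusionQuantifier)

cfg = SynthImagingConfig(grid_dims=(12, 12, 2),
                         pattern_mix=(0.4, 0.2, 0.2, 0.2), seed=1)
series, mask, labels = generate_dce_volume(cfg)
quant = PerfusionQuantifier().fit(series, mask)
print(quant.summaries_[["voi_label", "nvoxel", "nvoxel_pct",
                        "ire", "me", "me_x_nvoxel_pct"]].to_string(index=False))
```

prints

```
voi_label  nvoxel  nvoxel_pct      ire       me  me_x_nvoxel_pct
    total      81        40.5 1.422917 1.926833        78.036750
 extensor      43        43.0 1.474511 1.939683        83.406349
   flexor      38        38.0 1.365892 1.912632        72.680000
```

40.5% of the 200 muscle voxels show a plateau or washout pattern (highly
perfused tissue); the VOI-mean upslope is ≈ 1.4%/s and peak enhancement
≈ 1.9× baseline, and ME×Nvoxel% combines degree and extent of perfusion.
With `noise_sd=0` the recovered per-voxel classes match the phantom's
ground-truth labels exactly.

The same pipeline runs from the shell:

```bash
dceperf run --seed 42 --out run1        # phantom -> quantification -> ANCOVA
                                        # -> correlations -> mediation
dceperf analyze --table trial.csv --outcomes koos_pain --out results/
```

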