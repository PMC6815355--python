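"""Synthetic two-arm exercise trial with a known mediation structure.

Emulates a randomised trial of exercise therapy (ET) versus a no-attention
control group (CG) in knee osteoarthritis, with a patient-reported pain
outcome (KOOS pain, 0-100, higher = better) and a muscle-perfusion mediator.
Change scores follow two linear structural equations:

    dM = a * T + g_m * female + bo_m * (Y0 - mean) + bm * (M0 - mean) + e_M
    dY = c' * T + b * dM + g_y * female + bo_y * (Y0 - mean) + e_Y

so the average causal mediation effect is ``a * b``, the direct effect is
``c'`` and the total effect ``c' + a * b`` -- the ground truth every
downstream mediation fit is checked against. Baselines are Gaussian;
follow-up = baseline + change (not clipped to the KOOS range, so the linear
structure stays exact). Default magnitudes are on the scale of a ~33-person
trial: arm effects of a few KOOS points, residual SDs of ~9-10 points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SynthTrialConfig", "MediationGroundTruth", "generate_trial"]


@dataclass
class SynthTrialConfig:
    """Structural parameters of the synthetic trial.

    a_path / b_path / c_prime are the treatment->mediator, mediator->outcome
    and direct treatment->outcome coefficients. ``mediator_baseline_effect``
    (regression to the mean of the mediator on its own baseline) gives the
    mediator exogenous variation beyond the adjustment covariates, which keeps
    the two structural fits identifiable even with zero residual noise.
    ``n_control`` defaults to ``n_per_arm`` (set 17 vs 16 to mirror an
    unbalanced per-protocol sample).
    """

    n_per_arm: int = 16
    n_control: int | None = None
    a_path: float = 8.0
    b_path: float = 0.4
    c_prime: float = 7.0
    baseline_effect_mediator: float = -0.1
    gender_effect_mediator: float = 1.0
    mediator_baseline_effect: float = -0.2
    baseline_effect_outcome: float = -0.3
    gender_effect_outcome: float = 1.0
    baseline_outcome_mean: float = 57.0
    baseline_outcome_sd: float = 14.0
    baseline_mediator_mean: float = 57.0
    baseline_mediator_sd: float = 15.0
    gender_fraction: float = 0.8
    noise_sd_mediator: float = 10.0
    noise_sd_outcome: float = 9.0
    age_mean: float = 64.0
    age_sd: float = 8.0
    weight_mean: float = 81.0
    weight_sd: float = 13.0
    nonadherent_fraction: float = 0.0
    exercised_outside_fraction: float = 0.0
    incomplete_dce_fraction: float = 0.0
    outcome_name: str = "koos_pain"
    mediator_name: str = "perfusion_index"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_arm < 2 or (self.n_control is not None and self.n_control < 2):
            raise ValueError("need at least 2 participants per arm")
        for name in ("baseline_outcome_sd", "baseline_mediator_sd",
                     "noise_sd_mediator", "noise_sd_outcome", "age_sd", "weight_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.gender_fraction <= 1.0:
            raise ValueError("gender_fraction must be in [0, 1]")
        for name in ("nonadherent_fraction", "exercised_outside_fraction",
                     "incomplete_dce_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class MediationGroundTruth:
    """True mediation estimands implied by the structural coefficients."""

    true_acme: float
    true_ade: float
    true_total: float


def generate_trial(config: SynthTrialConfig) -> tuple[pd.DataFrame, MediationGroundTruth]:
    """Simulate one trial table plus its mediation ground truth.

    Returns a per-participant DataFrame with columns: participant_id, arm
    (ET/CG), gender (F/M), age, weight, attendance (ET only, sessions of 36),
    exercised_outside (CG only), complete_dce, and
    ``<outcome>_baseline/_followup``, ``<mediator>_baseline/_followup``.
    Reproducible bit-for-bit under a fixed config.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_et = cfg.n_per_arm
    n_cg = cfg.n_control if cfg.n_control is not None else cfg.n_per_arm
    n = n_et + n_cg

    treat = np.concatenate([np.ones(n_et), np.zeros(n_cg)])
    female = (rng.random(n) < cfg.gender_fraction).astype(float)
    age = rng.normal(cfg.age_mean, cfg.age_sd, n)
    weight = rng.normal(cfg.weight_mean, cfg.weight_sd, n)

    y0 = rng.normal(cfg.baseline_outcome_mean, cfg.baseline_outcome_sd, n)
    m0 = rng.normal(cfg.baseline_mediator_mean, cfg.baseline_mediator_sd, n)
    e_m = rng.normal(0.0, cfg.noise_sd_mediator, n) if cfg.noise_sd_mediator > 0 else np.zeros(n)
    e_y = rng.normal(0.0, cfg.noise_sd_outcome, n) if cfg.noise_sd_outcome > 0 else np.zeros(n)

    dm = (
        cfg.a_path * treat
        + cfg.gender_effect_mediator * female
        + cfg.baseline_effect_mediator * (y0 - cfg.baseline_outcome_mean)
        + cfg.mediator_baseline_effect * (m0 - cfg.baseline_mediator_mean)
        + e_m
    )
    dy = (
        cfg.c_prime * treat
        + cfg.b_path * dm
        + cfg.gender_effect_outcome * female
        + cfg.baseline_effect_outcome * (y0 - cfg.baseline_outcome_mean)
        + e_y
    )

    attendance = np.full(n, np.nan)
    adherent = rng.random(n_et) >= cfg.nonadherent_fraction
    attendance[:n_et] = np.where(
        adherent, rng.integers(24, 37, n_et), rng.integers(0, 24, n_et)
    )
    exercised_outside = np.zeros(n, dtype=bool)
    exercised_outside[n_et:] = rng.random(n_cg) < cfg.exercised_outside_fraction
    complete_dce = rng.random(n) >= cfg.incomplete_dce_fraction

    table = pd.DataFrame(
        {
            "participant_id": [f"P{i + 1:03d}" for i in range(n)],
            "arm": np.where(treat == 1, "ET", "CG"),
            "gender": np.where(female == 1, "F", "M"),
            "age": age,
            "weight": weight,
            "attendance": attendance,
            "exercised_outside": exercised_outside,
            "complete_dce": complete_dce,
            f"{cfg.outcome_name}_baseline": y0,
            f"{cfg.outcome_name}_followup": y0 + dy,
            f"{cfg.mediator_name}_baseline": m0,
            f"{cfg.mediator_name}_followup": m0 + dm,
        }
    )
    truth = MediationGroundTruth(
        true_acme=cfg.a_path * cfg.b_path,
        true_ade=cfg.c_prime,
        true_total=cfg.c_prime + cfg.a_path * cfg.b_path,
    )
    return table, truth
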