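"""End-to-end pipeline: synthetic volumes -> perfusion variables -> trial stats.

Stages, in order:

1. ``trial``       simulate (or load) the two-arm trial table;
2. ``imaging``     simulate per-participant DCE volumes at baseline and
                   follow-up and quantify them into the eight VOI perfusion
                   variables (control follow-up volumes lose a configurable
                   fraction of highly perfused voxels, emulating declining
                   perfusion without exercise);
3. ``per_protocol`` apply the adherence / no-exercise / complete-imaging filter;
4. ``ancova``      baseline-adjusted group comparison per outcome
                   (+ sensitivity variant with age and weight);
5. ``correlations`` Spearman matrix of change scores;
6. ``mediation``   bootstrap mediation of the pain effect through each
                   perfusion variable;
7. ``maps``        parametric maps (pattern/IRE/ME) for one exemplar volume.

One global seed fans out to per-stage seeds by fixed offsets so any stage can
be re-run in isolation; a run manifest (config echo, versions, seeds,
exclusion counts) makes every output reproducible from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dpio
from .curves import EnhancementPattern
from .phantom import SynthImagingConfig, generate_dce_volume
from .quantify import ClassifierThresholds, PerfusionQuantifier
from .trialsim import SynthTrialConfig, generate_trial
from .trialstats import ancova_table, change_table, filter_per_protocol, spearman_matrix
from .mediation import mediate_all

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

PERFUSION_VARIABLES = (
    "nvoxel_pct",
    "ire_x_nvoxel",
    "ire_x_nvoxel_pct",
    "me_x_nvoxel",
    "me_x_nvoxel_pct",
)
VOI_ORDER = ("total", "extensor", "flexor")

# fixed per-stage seed offsets from the global seed
_TRIAL_OFFSET = 1
_IMAGING_OFFSET = 100
_MEDIATION_OFFSET = 3


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Configuration of one end-to-end run.

    ``trial_csv`` switches the trial stage from simulation to a file;
    ``imaging`` may be ``None`` to skip the imaging stages entirely (the
    analysis then uses only the tabular mediator).
    """

    trial: SynthTrialConfig = field(default_factory=SynthTrialConfig)
    trial_csv: str | None = None
    imaging: SynthImagingConfig | None = field(
        default_factory=lambda: SynthImagingConfig(grid_dims=(10, 10, 2), noise_sd=0.05)
    )
    thresholds: ClassifierThresholds = field(default_factory=ClassifierThresholds)
    outcomes: tuple[str, ...] = ("koos_pain", "perfusion_index")
    mediation_outcome: str = "koos_pain"
    run_sensitivity: bool = False
    run_mediation: bool = True
    run_correlations: bool = True
    cg_followup_decline: float = 0.15
    n_boot: int = 500
    seed: int = 42
    out_dir: str = "dceperf_run"
    log_level: str = "info"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.imaging is not None:
            d["imaging"]["pattern_params"] = {
                EnhancementPattern(k).name.lower(): list(dataclasses.astuple(v))
                for k, v in self.imaging.pattern_params.items()
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("trial") is not None and not isinstance(d["trial"], SynthTrialConfig):
            d["trial"] = SynthTrialConfig(**d["trial"])
        if d.get("imaging") is not None and not isinstance(d["imaging"], SynthImagingConfig):
            img = dict(d["imaging"])
            if "pattern_params" in img and isinstance(img["pattern_params"], dict):
                from .curves import CurveParams, coerce_pattern

                img["pattern_params"] = {
                    coerce_pattern(k): CurveParams(*v) for k, v in img["pattern_params"].items()
                }
            img["grid_dims"] = tuple(img["grid_dims"])
            img["pattern_mix"] = tuple(img["pattern_mix"])
            d["imaging"] = SynthImagingConfig(**img)
        if d.get("thresholds") is not None and not isinstance(d["thresholds"], ClassifierThresholds):
            d["thresholds"] = ClassifierThresholds(**d["thresholds"])
        d["outcomes"] = tuple(d.get("outcomes", ()))
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _shifted_mix(mix: tuple[float, ...], decline: float) -> tuple[float, ...]:
    """Move a fraction of the plateau+washout mass to no-enhancement."""
    ne, pers, plat, wash = mix
    moved = decline * (plat + wash)
    return (ne + moved, pers, plat * (1 - decline), wash * (1 - decline))


def _quantify_participants(cfg: PipelineConfig, table: pd.DataFrame):
    """Simulate + quantify one volume per participant x timepoint.

    Returns (long-format VOI summary frame, wide imaging columns keyed by
    participant_id, exemplar quantifier for map export).
    """
    assert cfg.imaging is not None
    rows = []
    wide: dict[str, dict[str, float]] = {}
    exemplar = None
    for i, rec in enumerate(table.itertuples(index=False)):
        wide_row: dict[str, float] = {}
        for t, timepoint in enumerate(("baseline", "followup")):
            mix = tuple(cfg.imaging.pattern_mix)
            if timepoint == "followup" and rec.arm == "CG":
                mix = _shifted_mix(mix, cfg.cg_followup_decline)
            img_cfg = dataclasses.replace(
                cfg.imaging,
                pattern_mix=mix,
                seed=cfg.seed + _IMAGING_OFFSET + 2 * i + t,
            )
            series, mask, _ = generate_dce_volume(img_cfg)
            quant = PerfusionQuantifier(
                theta_enh=cfg.thresholds.theta_enh,
                theta_wash=cfg.thresholds.theta_wash,
                theta_pers=cfg.thresholds.theta_pers,
                min_late_frames=cfg.thresholds.min_late_frames,
                smooth_window=cfg.thresholds.smooth_window,
            ).fit(series, mask)
            if exemplar is None:
                exemplar = quant
            for s in quant.summaries_.itertuples(index=False):
                rows.append(
                    {
                        "participant_id": rec.participant_id,
                        "timepoint": timepoint,
                        **s._asdict(),
                    }
                )
                for var in PERFUSION_VARIABLES:
                    wide_row[f"{s.voi_label}_{var}_{timepoint}"] = getattr(s, var)
        wide[rec.participant_id] = wide_row
    summaries = pd.DataFrame(rows)
    wide_df = pd.DataFrame.from_dict(wide, orient="index")
    wide_df.index.name = "participant_id"
    return summaries, wide_df.reset_index(), exemplar


@contextmanager
def _stage(name: str, out_dir: Path):
    try:
        yield
    except Exception as exc:
        (out_dir / "FAILED").write_text(f"stage={name}\nerror={exc}\n")
        raise PipelineError(name, exc) from exc


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run all configured stages; returns a name -> path map of outputs.

    Deterministic given the config (including the seed): two runs produce
    byte-identical tabular outputs. On failure, partial outputs are retained
    next to a ``FAILED`` marker naming the stage.
    """
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    outputs: dict[str, Path] = {}
    manifest: dict = {
        "config": cfg.to_dict(),
        "stage_seeds": {
            "trial": cfg.seed + _TRIAL_OFFSET,
            "imaging_base": cfg.seed + _IMAGING_OFFSET,
            "mediation": cfg.seed + _MEDIATION_OFFSET,
        },
        "versions": _versions(),
    }

    with _stage("trial", out):
        if cfg.trial_csv is not None:
            table = dpio.read_trial_table(cfg.trial_csv)
            truth = None
        else:
            trial_cfg = dataclasses.replace(cfg.trial, seed=cfg.seed + _TRIAL_OFFSET)
            table, truth = generate_trial(trial_cfg)
            pd.DataFrame([dataclasses.asdict(truth)]).to_csv(
                out / "ground_truth.csv", index=False
            )
            outputs["ground_truth"] = out / "ground_truth.csv"
        dpio.write_trial_table(table, out / "trial_table.csv")
        outputs["trial_table"] = out / "trial_table.csv"

    imaging_outcomes: list[str] = []
    exemplar = None
    if cfg.imaging is not None:
        with _stage("imaging", out):
            summaries, wide, exemplar = _quantify_participants(cfg, table)
            summaries.to_csv(out / "voi_summaries.csv", index=False)
            outputs["voi_summaries"] = out / "voi_summaries.csv"
            table = table.merge(wide, on="participant_id", how="left")
            imaging_outcomes = [f"{voi}_{var}" for voi in VOI_ORDER for var in PERFUSION_VARIABLES]

    with _stage("per_protocol", out):
        pp_table, flow = filter_per_protocol(table)
        manifest["per_protocol_flow"] = flow
        dpio.write_trial_table(pp_table, out / "per_protocol_table.csv")
        outputs["per_protocol_table"] = out / "per_protocol_table.csv"

    outcomes = list(cfg.outcomes) + imaging_outcomes

    with _stage("ancova", out):
        anc = ancova_table(pp_table, outcomes)
        anc.to_csv(out / "ancova.csv", index=False)
        outputs["ancova"] = out / "ancova.csv"
        if cfg.run_sensitivity:
            sens = ancova_table(pp_table, outcomes, extra_covariates=("age", "weight"))
            sens.to_csv(out / "ancova_sensitivity.csv", index=False)
            outputs["ancova_sensitivity"] = out / "ancova_sensitivity.csv"

    if cfg.run_correlations:
        with _stage("correlations", out):
            corr = spearman_matrix(change_table(pp_table, outcomes))
            corr.rho.to_csv(out / "correlations_rho.csv")
            corr.p_value.to_csv(out / "correlations_p.csv")
            outputs["correlations_rho"] = out / "correlations_rho.csv"
            outputs["correlations_p"] = out / "correlations_p.csv"

    if cfg.run_mediation:
        with _stage("mediation", out):
            mediators = [o for o in outcomes if o != cfg.mediation_outcome]
            med_table = pp_table.copy()
            changes = change_table(med_table, outcomes)
            for o in outcomes:
                med_table[f"{o}_change"] = changes[o]
            med = mediate_all(
                med_table,
                mediators=[f"{m}_change" for m in mediators],
                outcome=f"{cfg.mediation_outcome}_change",
                covariates=(f"{cfg.mediation_outcome}_baseline", "female"),
                n_boot=cfg.n_boot,
                random_state=cfg.seed + _MEDIATION_OFFSET,
            )
            med.to_csv(out / "mediation.csv", index=False)
            outputs["mediation"] = out / "mediation.csv"

    if exemplar is not None:
        with _stage("maps", out):
            maps_dir = out / "maps"
            maps_dir.mkdir(exist_ok=True)
            for which in ("pattern", "ire", "me"):
                p = maps_dir / f"{which}.nii"
                dpio.write_metric_volume(exemplar.parametric_map(which), p)
                outputs[f"map_{which}"] = p

    manifest["toggles"] = {
        "sensitivity": cfg.run_sensitivity,
        "mediation": cfg.run_mediation,
        "correlations": cfg.run_correlations,
    }
    manifest["outputs"] = {k: str(v) for k, v in sorted(outputs.items())}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    outputs["manifest"] = out / "manifest.json"
    return outputs


def _versions() -> dict[str, str]:
    import nibabel
    import scipy
    import sklearn
    import statsmodels

    from . import __version__

    return {
        "dceperf": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
        "scikit-learn": sklearn.__version__,
        "nibabel": nibabel.__version__,
    }
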