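"""Synthetic 4D DCE phantom with ground-truth enhancement labels.

The phantom emulates the temporal structure of a dynamic T1 acquisition
(default 30 frames at 9 s spacing, contrast arriving after 2 pre-contrast
frames) over a small voxel grid. Each in-mask voxel is assigned one of the
four canonical enhancement classes by a seeded categorical draw and given the
corresponding piecewise-linear TIC plus i.i.d. Gaussian noise on the relative
scale, multiplied by a per-voxel baseline intensity. The mask splits the
in-scope voxels into two rectangular blocks standing in for the extensor and
flexor muscle VOIs; only the label bookkeeping matters downstream.

Not modelled (out of scope): pharmacokinetics / arterial input functions,
field inhomogeneity, subject motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curves import (
    CANONICAL_PARAMS,
    CurveParams,
    EnhancementPattern,
    generate_canonical_tic,
)
from .quantify import EXTENSOR, FLEXOR, OUTSIDE, DceSeries, VoiMask

__all__ = ["SynthImagingConfig", "generate_dce_volume"]

LABEL_OUTSIDE = -1  # ground-truth label map sentinel for out-of-mask voxels


@dataclass
class SynthImagingConfig:
    """Configuration of the synthetic DCE phantom.

    ``pattern_mix`` gives the class fractions over (no-enhancement,
    persistent, plateau, washout) and must sum to 1. ``noise_sd`` is the SD of
    additive Gaussian noise on the relative-intensity scale. ``onset_jitter_frames``
    shifts each voxel's onset uniformly in ``[-j, +j]`` frames (contrast
    arrival is not synchronous across tissue in practice; default 0 keeps
    curves exactly canonical). ``baseline_variation`` is the +/- fractional
    spread of per-voxel raw baseline intensity around ``baseline_intensity``.
    """

    grid_dims: tuple[int, int, int] = (16, 16, 4)
    n_frames: int = 30
    frame_spacing_s: float = 9.0
    n_baseline_frames: int = 2
    pattern_mix: tuple[float, float, float, float] = (0.4, 0.2, 0.2, 0.2)
    pattern_params: dict = field(default_factory=lambda: dict(CANONICAL_PARAMS))
    noise_sd: float = 0.0
    onset_jitter_frames: int = 0
    baseline_intensity: float = 100.0
    baseline_variation: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_dims) != 3 or min(self.grid_dims) < 1:
            raise ValueError("grid_dims must be 3 positive integers")
        if self.n_frames <= self.n_baseline_frames:
            raise ValueError("n_baseline_frames must be < n_frames")
        if self.frame_spacing_s <= 0:
            raise ValueError("frame_spacing_s must be > 0")
        mix = np.asarray(self.pattern_mix, dtype=float)
        if mix.size != 4 or np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError("pattern_mix must be 4 nonnegative fractions summing to 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.onset_jitter_frames < 0:
            raise ValueError("onset_jitter_frames must be >= 0")


def _block_mask(grid_dims: tuple[int, int, int]) -> np.ndarray:
    """Two rectangular VOI blocks with a 1-voxel out-of-mask border."""
    nx, ny, nz = grid_dims
    if nx < 4 or ny < 3:
        raise ValueError(
            f"grid {grid_dims} too small to host extensor and flexor blocks "
            "(need nx >= 4 and ny >= 3)"
        )
    labels = np.full(grid_dims, OUTSIDE, dtype=np.int16)
    mid = 1 + (nx - 2) // 2
    labels[1:mid, 1 : ny - 1, :] = EXTENSOR
    labels[mid : nx - 1, 1 : ny - 1, :] = FLEXOR
    if not (labels == EXTENSOR).any() or not (labels == FLEXOR).any():
        raise ValueError(f"grid {grid_dims} too small to host both VOI labels")
    return labels


def _jittered_params(params: CurveParams, jitter: int, cfg: SynthImagingConfig,
                     rng: np.random.Generator) -> CurveParams:
    if jitter == 0:
        return params
    shift = int(rng.integers(-jitter, jitter + 1))
    onset = params.onset_frame + shift
    lo = cfg.n_baseline_frames
    hi = cfg.n_frames - 1 - params.time_to_peak_frames
    onset = int(np.clip(onset, lo, hi))
    return CurveParams(
        params.peak_amplitude, onset, params.time_to_peak_frames, params.late_slope_per_frame
    )


def generate_dce_volume(
    config: SynthImagingConfig,
) -> tuple[DceSeries, VoiMask, np.ndarray]:
    """Generate a phantom series, its VOI mask, and the ground-truth label map.

    Returns
    -------
    (series, mask, label_map)
        ``label_map`` is a 3D int array: enhancement-class code 0-3 for
        in-mask voxels, -1 outside. Identical configs (including seed) give
        bit-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    labels = _block_mask(tuple(config.grid_dims))
    mask = VoiMask(labels)
    in_mask = np.argwhere(labels != OUTSIDE)

    mix = np.asarray(config.pattern_mix, dtype=float)
    mix = mix / mix.sum()  # guard rounding at the 1e-9 tolerance
    classes = rng.choice(4, size=len(in_mask), p=mix)

    signal = np.empty(config.grid_dims + (config.n_frames,), dtype=float)
    # out-of-mask voxels: flat background at the baseline intensity
    flat = np.ones(config.n_frames)
    for x, y, z in np.argwhere(labels == OUTSIDE):
        s0 = config.baseline_intensity * (
            1.0 + rng.uniform(-config.baseline_variation, config.baseline_variation)
        )
        noise = rng.normal(0.0, config.noise_sd, config.n_frames) if config.noise_sd > 0 else 0.0
        signal[x, y, z, :] = s0 * (flat + noise)

    label_map = np.full(config.grid_dims, LABEL_OUTSIDE, dtype=np.int16)
    for (x, y, z), cls in zip(in_mask, classes):
        pattern = EnhancementPattern(int(cls))
        params = _jittered_params(
            config.pattern_params[pattern], config.onset_jitter_frames, config, rng
        )
        tic = generate_canonical_tic(
            pattern,
            params,
            n_frames=config.n_frames,
            frame_spacing_s=config.frame_spacing_s,
            n_baseline_frames=config.n_baseline_frames,
            noise_sd=config.noise_sd,
            rng=rng,
        )
        s0 = config.baseline_intensity * (
            1.0 + rng.uniform(-config.baseline_variation, config.baseline_variation)
        )
        signal[x, y, z, :] = s0 * tic
        label_map[x, y, z] = int(cls)

    signal = np.maximum(signal, 0.0)
    series = DceSeries(
        signal=signal,
        frame_spacing_s=config.frame_spacing_s,
        n_baseline_frames=config.n_baseline_frames,
    )
    return series, mask, label_map
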