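"""Canonical time-intensity curves (TICs) for the four enhancement patterns.

A TIC is a per-voxel relative signal-intensity series, normalised so that the
pre-contrast baseline sits at 1.0. Perfused tissue shows a rise after contrast
arrival; the late behaviour separates the patterns:

* ``NO_ENHANCEMENT`` -- flat at baseline,
* ``PERSISTENT``     -- still rising at the end of the series,
* ``PLATEAU``        -- rise, then stable at the peak,
* ``WASHOUT``        -- rise, then linear decline (high-perfusion signature,
  e.g. an arterial voxel).

Canonical curves are piecewise linear: baseline 1.0 up to an onset frame, a
linear upslope from 1.0 to the peak amplitude over ``time_to_peak_frames``
frames, then a class-specific linear late segment.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

__all__ = [
    "EnhancementPattern",
    "CurveParams",
    "CANONICAL_PARAMS",
    "generate_canonical_tic",
]


class EnhancementPattern(IntEnum):
    """Voxel enhancement-pattern classes (codes used in parametric maps)."""

    NO_ENHANCEMENT = 0
    PERSISTENT = 1
    PLATEAU = 2
    WASHOUT = 3


@dataclass(frozen=True)
class CurveParams:
    """Parameters of one canonical piecewise-linear TIC.

    Parameters
    ----------
    peak_amplitude
        Relative intensity reached at the end of the upslope (baseline = 1.0).
    onset_frame
        0-based frame at which enhancement starts (value still 1.0 there).
    time_to_peak_frames
        Number of frames from onset to peak.
    late_slope_per_frame
        Slope of the post-peak segment in relative-intensity units per frame.
        Negative for washout, positive for persistent, ignored (0) for plateau.
    """

    peak_amplitude: float = 2.0
    onset_frame: int = 3
    time_to_peak_frames: int = 6
    late_slope_per_frame: float = 0.0


#: Default per-class curve shapes used by the synthetic phantom. Amplitudes and
#: slopes are set so the three enhancing shapes are well separated on a
#: 30-frame, 9 s series: washout reaches the highest peak and declines fast
#: (artery-like), persistent keeps rising through the final frame.
CANONICAL_PARAMS: dict[EnhancementPattern, CurveParams] = {
    EnhancementPattern.NO_ENHANCEMENT: CurveParams(1.0, 3, 1, 0.0),
    EnhancementPattern.PERSISTENT: CurveParams(1.4, 3, 7, 0.02),
    EnhancementPattern.PLATEAU: CurveParams(1.8, 3, 7, 0.0),
    EnhancementPattern.WASHOUT: CurveParams(2.2, 3, 5, -0.03),
}

_NAME_TO_PATTERN = {
    "no-enhancement": EnhancementPattern.NO_ENHANCEMENT,
    "no_enhancement": EnhancementPattern.NO_ENHANCEMENT,
    "persistent": EnhancementPattern.PERSISTENT,
    "plateau": EnhancementPattern.PLATEAU,
    "washout": EnhancementPattern.WASHOUT,
}


def coerce_pattern(pattern: EnhancementPattern | str | int) -> EnhancementPattern:
    """Map a pattern name/code to the :class:`EnhancementPattern` enum."""
    if isinstance(pattern, EnhancementPattern):
        return pattern
    if isinstance(pattern, str):
        try:
            return _NAME_TO_PATTERN[pattern.strip().lower()]
        except KeyError:
            raise ValueError(f"unknown enhancement pattern name: {pattern!r}") from None
    try:
        return EnhancementPattern(pattern)
    except ValueError:
        raise ValueError(f"unknown enhancement pattern code: {pattern!r}") from None


def generate_canonical_tic(
    pattern: EnhancementPattern | str,
    params: CurveParams | None = None,
    *,
    n_frames: int = 30,
    frame_spacing_s: float = 9.0,
    n_baseline_frames: int = 2,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Generate one canonical relative-intensity TIC, optionally with noise.

    Pre-contrast frames have expectation 1.0. The noise model is additive
    Gaussian on the relative-intensity scale, i.i.d. across frames.

    Parameters
    ----------
    pattern
        Enhancement class (enum, code, or name such as ``"washout"``).
    params
        Curve shape; defaults to :data:`CANONICAL_PARAMS` for the class.
    n_frames, frame_spacing_s, n_baseline_frames
        Temporal grid. ``frame_spacing_s`` is carried as metadata only; the
        curve is defined on frame indices.
    noise_sd
        SD of the additive Gaussian noise (relative-intensity units).
    rng
        :class:`numpy.random.Generator`, integer seed, or ``None`` (no noise
        draw needed when ``noise_sd == 0``).

    Returns
    -------
    numpy.ndarray of shape ``(n_frames,)``
    """
    pattern = coerce_pattern(pattern)
    if params is None:
        params = CANONICAL_PARAMS[pattern]
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_frames <= n_baseline_frames:
        raise ValueError("n_frames must exceed n_baseline_frames")
    if frame_spacing_s <= 0:
        raise ValueError("frame_spacing_s must be > 0")
    if params.peak_amplitude < 0:
        raise ValueError("peak_amplitude must be >= 0")

    s = np.ones(n_frames, dtype=float)
    if pattern != EnhancementPattern.NO_ENHANCEMENT:
        onset = int(params.onset_frame)
        peak = onset + int(params.time_to_peak_frames)
        if not (n_baseline_frames <= onset < peak <= n_frames - 1):
            raise ValueError(
                "need n_baseline_frames <= onset_frame < peak frame <= n_frames-1 "
                f"(onset={onset}, peak={peak}, n_frames={n_frames})"
            )
        slope = float(params.late_slope_per_frame)
        if pattern == EnhancementPattern.WASHOUT and slope >= 0:
            raise ValueError("washout requires a negative late_slope_per_frame")
        if pattern == EnhancementPattern.PERSISTENT and slope <= 0:
            raise ValueError("persistent requires a positive late_slope_per_frame")
        t = np.arange(n_frames, dtype=float)
        rise = (t - onset) / (peak - onset)
        seg = 1.0 + (params.peak_amplitude - 1.0) * np.clip(rise, 0.0, 1.0)
        if pattern == EnhancementPattern.PLATEAU:
            s = seg
        else:
            late = params.peak_amplitude + slope * (t - peak)
            s = np.where(t <= peak, seg, late)
        s = np.maximum(s, 0.0)  # relative intensity cannot go negative

    if noise_sd > 0:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        s = s + gen.normal(0.0, noise_sd, size=n_frames)
    return s
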