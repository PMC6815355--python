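"""DCE-MRI heuristic perfusion quantification.

Converts a 4D dynamic contrast-enhanced series plus a labelled muscle mask
into per-voxel enhancement metrics and the eight per-VOI perfusion variables:

====================  =======================================================
Nvoxel                count of highly perfused voxels (plateau or washout)
Nvoxel%               Nvoxel as a percentage of all VOI voxels
IRE                   initial rate of enhancement, mean upslope onset->peak, %/s
ME                    maximal enhancement, peak relative intensity (unitless)
IRExNvoxel            IRE * Nvoxel   (composite: degree x volume of perfusion)
IRExNvoxel%           IRE * Nvoxel%
MExNvoxel             ME * Nvoxel
MExNvoxel%            ME * Nvoxel%
====================  =======================================================

The per-voxel classifier assigns each in-mask voxel to one of four
enhancement patterns (no-enhancement / persistent / plateau / washout) from
threshold rules on a linear approximation of its relative TIC; numeric
thresholds are heuristics exposed in :class:`ClassifierThresholds`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .curves import EnhancementPattern

logger = logging.getLogger(__name__)

__all__ = [
    "DceSeries",
    "VoiMask",
    "RelativeTic",
    "ClassifierThresholds",
    "VoxelMetrics",
    "VoiSummary",
    "InvalidVoxelError",
    "compute_relative_tic",
    "detect_onset",
    "compute_me",
    "compute_ire",
    "compute_irw",
    "classify_voxel",
    "compute_voxel_metrics",
    "summarize_voi",
    "make_parametric_map",
    "TicPatternClassifier",
    "PerfusionQuantifier",
]

# mask codes
OUTSIDE, EXTENSOR, FLEXOR = 0, 1, 2
VOI_LABELS = ("total", "extensor", "flexor")
MAP_SENTINEL = -1.0


class InvalidVoxelError(ValueError):
    """Raised when a voxel has a nonpositive pre-contrast baseline."""


@dataclass
class DceSeries:
    """A 4D signal-intensity series ``(x, y, z, frame)`` with temporal metadata."""

    signal: np.ndarray
    frame_spacing_s: float = 9.0
    n_baseline_frames: int = 2

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4D (x, y, z, frame)")
        if np.any(self.signal < 0):
            raise ValueError("signal intensities must be nonnegative")
        if self.frame_spacing_s <= 0:
            raise ValueError("frame_spacing_s must be > 0")
        if self.n_baseline_frames < 1:
            raise ValueError("n_baseline_frames must be >= 1")
        if self.signal.shape[3] < self.n_baseline_frames + 2:
            raise ValueError("need at least 2 frames after the baseline block")

    @property
    def n_frames(self) -> int:
        return self.signal.shape[3]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]


@dataclass
class VoiMask:
    """3D label map: 0 outside, 1 extensor VOI, 2 flexor VOI."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int16)
        if self.labels.ndim != 3:
            raise ValueError("mask labels must be 3D")
        bad = set(np.unique(self.labels)) - {OUTSIDE, EXTENSOR, FLEXOR}
        if bad:
            raise ValueError(f"unknown mask label codes: {sorted(bad)}")

    def voxels(self, voi_label: str = "total") -> np.ndarray:
        """Boolean 3D array selecting the voxels of one VOI."""
        if voi_label == "total":
            return self.labels != OUTSIDE
        if voi_label == "extensor":
            return self.labels == EXTENSOR
        if voi_label == "flexor":
            return self.labels == FLEXOR
        raise ValueError(f"unknown VOI label: {voi_label!r}")


@dataclass
class RelativeTic:
    """A relative time-intensity curve (pre-contrast baseline = 1.0)."""

    s: np.ndarray
    n_baseline_frames: int = 2
    frame_spacing_s: float = 9.0

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float).ravel()
        if self.s.size < self.n_baseline_frames + 1:
            raise ValueError("TIC too short for the baseline block")

    @property
    def n_frames(self) -> int:
        return self.s.size


@dataclass(frozen=True)
class ClassifierThresholds:
    """Heuristic thresholds of the enhancement-pattern classifier.

    theta_enh
        Minimum relative enhancement above baseline for a voxel to count as
        enhancing (onset rule: first frame with s >= 1 + theta_enh).
    theta_wash
        Minimum fractional late decline from ME to call WASHOUT.
    theta_pers
        Minimum fractional late rise above ME to call PERSISTENT.
    min_late_frames
        Minimum number of frames in the late least-squares fit window
        (peak frame to final frame, extended backwards when the peak is late).
    smooth_window
        Odd moving-average window (frames) applied to the TIC before the
        classification rules, approximating the curve piecewise-linearly and
        suppressing frame-to-frame noise. 1 disables smoothing. Reported
        voxel metrics (ME/IRE/IRW) always come from the raw TIC.
    """

    theta_enh: float = 0.10
    theta_wash: float = 0.10
    theta_pers: float = 0.05
    min_late_frames: int = 3
    smooth_window: int = 5

    def __post_init__(self) -> None:
        if min(self.theta_enh, self.theta_wash, self.theta_pers) <= 0:
            raise ValueError("all thetas must be > 0")
        if self.min_late_frames < 2:
            raise ValueError("min_late_frames must be >= 2")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be a positive odd integer")


@dataclass
class VoxelMetrics:
    """Per-voxel enhancement metrics; frame indices are 0-based."""

    pattern: EnhancementPattern
    me: float
    ire: float = np.nan
    irw: float = np.nan
    onset_frame: int | None = None
    peak_frame: int | None = None


@dataclass
class VoiSummary:
    """The eight per-VOI perfusion variables plus bookkeeping counts."""

    voi_label: str
    n_total_voxels: int
    nvoxel: int
    nvoxel_pct: float
    ire: float
    me: float
    ire_x_nvoxel: float
    ire_x_nvoxel_pct: float
    me_x_nvoxel: float
    me_x_nvoxel_pct: float


def _as_tic(tic, n_baseline_frames: int = 2, frame_spacing_s: float = 9.0) -> RelativeTic:
    if isinstance(tic, RelativeTic):
        return tic
    return RelativeTic(np.asarray(tic, float), n_baseline_frames, frame_spacing_s)


def compute_relative_tic(series: DceSeries, voxel: tuple[int, int, int]) -> RelativeTic:
    """Normalise one voxel's raw series by its pre-contrast baseline mean.

    Raises :class:`InvalidVoxelError` when the baseline mean is nonpositive;
    such voxels are excluded from all VOI summaries.
    """
    raw = np.asarray(series.signal[voxel[0], voxel[1], voxel[2], :], dtype=float)
    base = raw[: series.n_baseline_frames].mean()
    if base <= 0:
        raise InvalidVoxelError(
            f"voxel {voxel}: nonpositive baseline mean ({base:g}); excluded"
        )
    return RelativeTic(raw / base, series.n_baseline_frames, series.frame_spacing_s)


def detect_onset(tic, thresholds: ClassifierThresholds | None = None) -> int | None:
    """First post-baseline frame with ``s >= 1 + theta_enh`` (inclusive), or None."""
    thresholds = thresholds or ClassifierThresholds()
    tic = _as_tic(tic)
    post = tic.s[tic.n_baseline_frames :]
    hits = np.nonzero(post >= 1.0 + thresholds.theta_enh)[0]
    if hits.size == 0:
        return None
    return int(hits[0]) + tic.n_baseline_frames


def compute_me(tic) -> tuple[float, int]:
    """Maximal enhancement and its (first-attained) peak frame.

    ME is the maximum relative intensity over the post-baseline frames; ties
    break to the earliest frame.
    """
    tic = _as_tic(tic)
    post = tic.s[tic.n_baseline_frames :]
    peak = int(np.argmax(post)) + tic.n_baseline_frames
    return float(tic.s[peak]), peak


def compute_ire(tic, onset_frame: int, peak_frame: int) -> float:
    """Initial rate of enhancement in %/s.

    Mean relative increase per second from enhancement onset until ME:
    ``100 * (s(peak) - s(onset)) / ((peak - onset) * frame_spacing_s)``.
    When onset and peak coincide, the single-step rise into the onset frame is
    used. The result is floored at 0.
    """
    tic = _as_tic(tic)
    if onset_frame is None:
        raise ValueError("IRE is undefined without an enhancement onset")
    if onset_frame > peak_frame:
        raise ValueError("onset_frame must be <= peak_frame")
    if peak_frame > onset_frame:
        rate = (tic.s[peak_frame] - tic.s[onset_frame]) / (
            (peak_frame - onset_frame) * tic.frame_spacing_s
        )
    else:
        rate = (tic.s[onset_frame] - tic.s[onset_frame - 1]) / tic.frame_spacing_s
    return max(100.0 * float(rate), 0.0)


def compute_irw(tic, peak_frame: int, thresholds: ClassifierThresholds | None = None) -> float | None:
    """Initial rate of washout in %/s (diagnostic; not a Table-style outcome).

    Least-squares slope of the TIC over the window from the peak frame to the
    final frame. ``None`` when fewer than 2 frames remain.
    """
    tic = _as_tic(tic)
    idx = np.arange(peak_frame, tic.n_frames)
    if idx.size < 2:
        return None
    slope = np.polyfit(idx.astype(float), tic.s[idx], 1)[0]
    return 100.0 * float(slope) / tic.frame_spacing_s


def _smoothed_tic(tic: RelativeTic, window: int) -> RelativeTic:
    """Valid-region moving average of a TIC (the linear approximation the
    classification rules operate on).

    Every smoothed sample averages exactly ``window`` raw frames, so the
    noise variance is uniform along the curve (replicate-edge filters inflate
    variance at the series ends, right where the peak-position rules look).
    Smoothed frame ``i`` is centred on raw frame ``i + window//2``; TICs too
    short to smooth fall back to the raw curve.
    """
    if window <= 1:
        return tic
    half = window // 2
    n_base = max(1, tic.n_baseline_frames - half)
    if tic.n_frames - window + 1 < n_base + 2:
        return tic
    valid = np.convolve(tic.s, np.full(window, 1.0 / window), mode="valid")
    return RelativeTic(valid, n_base, tic.frame_spacing_s)


def _late_fit(s: np.ndarray, start: int) -> tuple[float, float]:
    """Least-squares line over frames ``start..end``; returns (slope, fitted end value)."""
    n = s.size
    idx = np.arange(start, n, dtype=float)
    if idx.size < 2:
        return 0.0, float(s[-1])
    slope, intercept = np.polyfit(idx, s[start:], 1)
    return float(slope), float(intercept + slope * (n - 1))


def classify_voxel(tic, thresholds: ClassifierThresholds | None = None) -> EnhancementPattern:
    """Assign one TIC to an enhancement pattern.

    Rules, applied to the (optionally smoothed) curve:

    1. no onset (never reaches ``1 + theta_enh``) -> NO_ENHANCEMENT;
    2. fit a least-squares line over the late window (peak to final frame,
       at least ``min_late_frames`` frames);
    3. fitted end-of-series value <= ``ME * (1 - theta_wash)`` -> WASHOUT;
    4. fitted end value >= ``ME * (1 + theta_pers)``, or the peak lies in the
       final two frames with a positive late slope -> PERSISTENT;
    5. otherwise PLATEAU.

    The washout test takes precedence over the persistent test.
    """
    thresholds = thresholds or ClassifierThresholds()
    tic = _as_tic(tic)
    work = _smoothed_tic(tic, thresholds.smooth_window)
    if detect_onset(work, thresholds) is None:
        return EnhancementPattern.NO_ENHANCEMENT
    me, peak = compute_me(work)
    n = work.n_frames
    start = max(work.n_baseline_frames, min(peak, n - thresholds.min_late_frames))
    slope, fitted_end = _late_fit(work.s, start)
    if fitted_end <= me * (1.0 - thresholds.theta_wash):
        return EnhancementPattern.WASHOUT
    if fitted_end >= me * (1.0 + thresholds.theta_pers) or (peak >= n - 2 and slope > 0):
        return EnhancementPattern.PERSISTENT
    return EnhancementPattern.PLATEAU


def compute_voxel_metrics(tic, thresholds: ClassifierThresholds | None = None) -> VoxelMetrics:
    """Classify one TIC and compute its raw-curve metrics.

    The pattern comes from :func:`classify_voxel` (smoothed rule); ME, IRE and
    IRW come from the raw curve so exact piecewise-linear inputs reproduce
    their closed forms. A voxel whose raw curve never crosses the onset
    threshold is reported as NO_ENHANCEMENT regardless of the smoothed class.
    """
    thresholds = thresholds or ClassifierThresholds()
    tic = _as_tic(tic)
    pattern = classify_voxel(tic, thresholds)
    me_raw, peak_raw = compute_me(tic)
    if pattern == EnhancementPattern.NO_ENHANCEMENT:
        return VoxelMetrics(pattern=pattern, me=me_raw)
    onset = detect_onset(tic, thresholds)
    if onset is None:  # smoothed curve enhanced but raw never crossed
        return VoxelMetrics(pattern=EnhancementPattern.NO_ENHANCEMENT, me=me_raw)
    peak = max(peak_raw, onset)
    ire = compute_ire(tic, onset, peak)
    irw = compute_irw(tic, peak, thresholds)
    return VoxelMetrics(
        pattern=pattern,
        me=me_raw,
        ire=ire,
        irw=np.nan if irw is None else irw,
        onset_frame=onset,
        peak_frame=peak,
    )


_HIGHLY_PERFUSED = (EnhancementPattern.PLATEAU, EnhancementPattern.WASHOUT)


def summarize_voi(
    metrics: pd.DataFrame,
    mask: VoiMask,
    voi_label: str,
    *,
    enhancing_only: bool = True,
) -> VoiSummary:
    """Aggregate per-voxel metrics into the eight VOI perfusion variables.

    ``metrics`` is the per-voxel frame produced by :class:`PerfusionQuantifier`
    (columns x, y, z, voi, pattern, me, ire, valid). Nvoxel counts plateau and
    washout voxels. IRE and ME are VOI means over enhancing voxels by default
    (enhancement onset is undefined elsewhere); with
    ``enhancing_only=False`` all valid voxels enter the means with
    IRE 0 / ME as observed. Composites follow the definitions in the table
    above; all are 0 when Nvoxel is 0.
    """
    if voi_label not in VOI_LABELS:
        raise ValueError(f"unknown VOI label: {voi_label!r}")
    sel = mask.voxels(voi_label)
    n_total = int(sel.sum())
    if n_total == 0:
        raise ValueError(f"VOI {voi_label!r} contains no voxels")
    sub = metrics if voi_label == "total" else metrics[metrics["voi"] == voi_label]
    sub = sub[sub["valid"]]
    patterns = sub["pattern"].to_numpy()
    nvoxel = int(np.isin(patterns, [int(p) for p in _HIGHLY_PERFUSED]).sum())
    nvoxel_pct = 100.0 * nvoxel / n_total
    if enhancing_only:
        enh = sub[sub["pattern"] != int(EnhancementPattern.NO_ENHANCEMENT)]
        ire = float(enh["ire"].mean()) if len(enh) else 0.0
        me = float(enh["me"].mean()) if len(enh) else 0.0
    else:
        ire = float(sub["ire"].fillna(0.0).mean()) if len(sub) else 0.0
        me = float(sub["me"].mean()) if len(sub) else 0.0
    if nvoxel == 0:
        composites = (0.0, 0.0, 0.0, 0.0)
    else:
        composites = (ire * nvoxel, ire * nvoxel_pct, me * nvoxel, me * nvoxel_pct)
    return VoiSummary(
        voi_label=voi_label,
        n_total_voxels=n_total,
        nvoxel=nvoxel,
        nvoxel_pct=nvoxel_pct,
        ire=ire,
        me=me,
        ire_x_nvoxel=composites[0],
        ire_x_nvoxel_pct=composites[1],
        me_x_nvoxel=composites[2],
        me_x_nvoxel_pct=composites[3],
    )


def make_parametric_map(metrics: pd.DataFrame, shape: tuple[int, int, int], which: str) -> np.ndarray:
    """Build a voxel-aligned 3D map of one metric.

    ``which`` is one of ``ire``, ``me``, ``irw`` or ``pattern`` (class codes
    0-3). Out-of-mask / invalid voxels carry the sentinel -1.
    """
    which = which.lower()
    if which not in ("ire", "me", "irw", "pattern"):
        raise ValueError(f"unknown parametric map: {which!r}")
    vol = np.full(shape, MAP_SENTINEL, dtype=float)
    sub = metrics[metrics["valid"]]
    vals = sub[which].to_numpy(dtype=float)
    vol[sub["x"].to_numpy(), sub["y"].to_numpy(), sub["z"].to_numpy()] = vals
    return vol


class TicPatternClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn style classifier of relative TICs into enhancement patterns.

    Stateless (threshold-rule based); ``fit`` only validates input and records
    ``classes_``. ``X`` is ``(n_voxels, n_frames)`` of relative intensities.
    """

    def __init__(
        self,
        theta_enh: float = 0.10,
        theta_wash: float = 0.10,
        theta_pers: float = 0.05,
        min_late_frames: int = 3,
        smooth_window: int = 5,
        n_baseline_frames: int = 2,
        frame_spacing_s: float = 9.0,
    ):
        self.theta_enh = theta_enh
        self.theta_wash = theta_wash
        self.theta_pers = theta_pers
        self.min_late_frames = min_late_frames
        self.smooth_window = smooth_window
        self.n_baseline_frames = n_baseline_frames
        self.frame_spacing_s = frame_spacing_s

    def _thresholds(self) -> ClassifierThresholds:
        return ClassifierThresholds(
            theta_enh=self.theta_enh,
            theta_wash=self.theta_wash,
            theta_pers=self.theta_pers,
            min_late_frames=self.min_late_frames,
            smooth_window=self.smooth_window,
        )

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < self.n_baseline_frames + 2:
            raise ValueError("X must be (n_voxels, n_frames) with frames after baseline")
        self._thresholds()  # validates parameters
        self.classes_ = np.array([int(p) for p in EnhancementPattern])
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        """Pattern codes (0-3) for each row of ``X``."""
        if not hasattr(self, "classes_"):
            self.fit(np.asarray(X, dtype=float))
        X = np.asarray(X, dtype=float)
        thr = self._thresholds()
        out = np.empty(X.shape[0], dtype=np.int8)
        for i, row in enumerate(X):
            tic = RelativeTic(row, self.n_baseline_frames, self.frame_spacing_s)
            out[i] = int(classify_voxel(tic, thr))
        return out

    def metrics_frame(self, X) -> pd.DataFrame:
        """Per-row :class:`VoxelMetrics` as a DataFrame."""
        X = np.asarray(X, dtype=float)
        thr = self._thresholds()
        rows = []
        for row in X:
            m = compute_voxel_metrics(
                RelativeTic(row, self.n_baseline_frames, self.frame_spacing_s), thr
            )
            rows.append(
                dict(
                    pattern=int(m.pattern),
                    me=m.me,
                    ire=m.ire,
                    irw=m.irw,
                    onset_frame=m.onset_frame,
                    peak_frame=m.peak_frame,
                )
            )
        return pd.DataFrame(rows)


class PerfusionQuantifier(BaseEstimator):
    """Fit-style quantifier: DCE series + VOI mask -> voxel metrics + VOI summaries.

    After ``fit(series, mask)``:

    ``voxel_metrics_``
        per-voxel DataFrame (x, y, z, voi, valid, pattern, me, ire, irw,
        onset_frame, peak_frame),
    ``summaries_``
        one row per VOI (total / extensor / flexor) with the eight variables,
    ``n_invalid_``
        voxels excluded for a nonpositive baseline.
    """

    def __init__(
        self,
        theta_enh: float = 0.10,
        theta_wash: float = 0.10,
        theta_pers: float = 0.05,
        min_late_frames: int = 3,
        smooth_window: int = 5,
        enhancing_only: bool = True,
    ):
        self.theta_enh = theta_enh
        self.theta_wash = theta_wash
        self.theta_pers = theta_pers
        self.min_late_frames = min_late_frames
        self.smooth_window = smooth_window
        self.enhancing_only = enhancing_only

    def fit(self, series: DceSeries, mask: VoiMask):
        if mask.labels.shape != series.spatial_shape:
            raise ValueError(
                f"mask dims {mask.labels.shape} != series dims {series.spatial_shape}"
            )
        thr = ClassifierThresholds(
            theta_enh=self.theta_enh,
            theta_wash=self.theta_wash,
            theta_pers=self.theta_pers,
            min_late_frames=self.min_late_frames,
            smooth_window=self.smooth_window,
        )
        rows = []
        n_invalid = 0
        for x, y, z in np.argwhere(mask.labels != OUTSIDE):
            voi = "extensor" if mask.labels[x, y, z] == EXTENSOR else "flexor"
            base = dict(x=int(x), y=int(y), z=int(z), voi=voi)
            try:
                tic = compute_relative_tic(series, (x, y, z))
            except InvalidVoxelError:
                n_invalid += 1
                logger.warning("excluding voxel (%d, %d, %d): nonpositive baseline", x, y, z)
                rows.append(
                    dict(
                        **base, valid=False, pattern=-1, me=np.nan, ire=np.nan,
                        irw=np.nan, onset_frame=None, peak_frame=None,
                    )
                )
                continue
            m = compute_voxel_metrics(tic, thr)
            rows.append(
                dict(
                    **base, valid=True, pattern=int(m.pattern), me=m.me, ire=m.ire,
                    irw=m.irw, onset_frame=m.onset_frame, peak_frame=m.peak_frame,
                )
            )
        if not rows:
            raise ValueError("mask selects no voxels")
        self.voxel_metrics_ = pd.DataFrame(rows)
        self.n_invalid_ = n_invalid
        summaries = []
        for voi in VOI_LABELS:
            if not mask.voxels(voi).any():
                continue
            summaries.append(
                vars(
                    summarize_voi(
                        self.voxel_metrics_, mask, voi, enhancing_only=self.enhancing_only
                    )
                )
            )
        self.summaries_ = pd.DataFrame(summaries)
        self._shape = series.spatial_shape
        return self

    def parametric_map(self, which: str) -> np.ndarray:
        """3D map of ``ire``/``me``/``irw``/``pattern`` (sentinel -1 outside)."""
        if not hasattr(self, "voxel_metrics_"):
            raise RuntimeError("call fit() first")
        return make_parametric_map(self.voxel_metrics_, self._shape, which)
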