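"""Spatially resolved tissue classification and boundary detection.

A 32-A-scan window slides along a long lateral scan; each window is
featurized and scored by the one-class SVM, producing a score trace.  The
trace is denoised by soft thresholding in the wavelet domain (Daubechies-4,
universal threshold sigma*sqrt(2 ln n) with sigma from the finest-scale
median absolute deviation), and normal/abnormal boundaries are located at
the large-magnitude local extrema of the first-order difference of the
filtered trace: the score changes abruptly where the tissue type changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from .exceptions import InputError, DegeneratePatchError
from .classifier import OneClassModel, predict_score
from .features import featurize_patch
from .phantom import OCTImage
from .segmentation import SegmenterModel

WAVELET = "db4"

# direction labels for a boundary crossing
NORMAL_TO_ABNORMAL = "normal->abnormal"
ABNORMAL_TO_NORMAL = "abnormal->normal"


@dataclass(frozen=True)
class Boundary:
    """A detected tissue transition along the lateral axis."""

    position: float       # A-scan coordinate of the transition
    direction: str        # NORMAL_TO_ABNORMAL or ABNORMAL_TO_NORMAL
    magnitude: float      # |first difference| at the transition


@dataclass
class ScoreTrace:
    """Lateral sequence of SVM scores with optional filtering/boundaries."""

    positions: np.ndarray           # A-scan index of each window centre
    scores: np.ndarray
    filtered: np.ndarray | None = None
    boundaries: list[Boundary] = field(default_factory=list)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.positions.size != self.scores.size:
            raise InputError("positions and scores must have equal length")
        if self.positions.size > 1 and not np.all(np.diff(self.positions) > 0):
            raise InputError("positions must be strictly increasing")


def score_trace(model: OneClassModel, segmenter: SegmenterModel,
                image: OCTImage, stride: int = 1,
                window: int = 32) -> ScoreTrace:
    """Score a sliding window along the scan.

    ``stride`` 1 gives per-lateral-coordinate scores; ``stride`` = window
    reduces to the non-overlapping patch workflow.  Position is the window
    centre in A-scan coordinates.  Degenerate windows are recorded as NaN
    and interpolated from neighbours (they are rare on skin data).
    """
    if image.width < window:
        raise InputError(f"image width {image.width} < window {window}")
    if not (1 <= stride <= window):
        raise InputError("stride must lie in [1, window]")
    starts = range(0, image.width - window + 1, stride)
    scores = np.empty(len(starts))
    positions = np.empty(len(starts))
    for k, s in enumerate(starts):
        patch = OCTImage(pixels=image.pixels[:, s:s + window],
                         axial_spacing=image.axial_spacing,
                         lateral_spacing=image.lateral_spacing,
                         lateral_offset=image.lateral_offset + s)
        positions[k] = s + (window - 1) / 2.0
        try:
            fv = featurize_patch(segmenter, patch, model.config.feature_group)
            scores[k] = predict_score(model, fv)
        except DegeneratePatchError:
            scores[k] = np.nan
    nan = np.isnan(scores)
    if nan.all():
        raise InputError("every window was degenerate; no trace")
    if nan.any():
        scores[nan] = np.interp(positions[nan], positions[~nan], scores[~nan])
    return ScoreTrace(positions=positions, scores=scores)


def denoise_scores(scores: np.ndarray, wavelet: str = WAVELET,
                   level: int | None = None) -> np.ndarray:
    """Wavelet soft-thresholding at the universal threshold.

    sigma is the median absolute deviation of the finest-scale detail
    coefficients divided by 0.6745; the threshold sigma*sqrt(2 ln n) is
    applied softly to all detail bands.  A constant input is returned
    unchanged (all detail coefficients are zero).
    """
    x = np.asarray(scores, dtype=np.float64).ravel()
    n = x.size
    if n < 8:
        raise InputError(f"need >= 8 samples to denoise, got {n}")
    max_level = pywt.dwt_max_level(n, pywt.Wavelet(wavelet).dec_len)
    if level is None:
        level = min(3, max(1, int(np.floor(np.log2(n))) - 2))
    level = min(level, max(1, max_level))
    coeffs = pywt.wavedec(x, wavelet, level=level, mode="periodization")
    detail_finest = coeffs[-1]
    sigma = float(np.median(np.abs(detail_finest))) / 0.6745
    thresh = sigma * np.sqrt(2.0 * np.log(n))
    coeffs = [coeffs[0]] + [pywt.threshold(c, thresh, mode="soft")
                            for c in coeffs[1:]]
    out = pywt.waverec(coeffs, wavelet, mode="periodization")
    return out[:n]


def detect_boundary(trace: ScoreTrace, min_jump: float) -> list[Boundary]:
    """Boundaries from the first-order difference of the filtered trace.

    ``d[n] = filtered[n+1] - filtered[n]``; local extrema of |d| exceeding
    ``min_jump`` are reported, position halfway between the two samples,
    direction from the sign of d (negative: score drops, normal tissue ends).
    An empty list (no extremum above threshold) is not an error.  The
    boundaries are also attached to ``trace.boundaries``, sorted by
    magnitude so the global peak — the single-boundary case — comes first.
    """
    if trace.filtered is None:
        raise InputError("trace has no filtered scores; run denoise_scores first")
    f = np.asarray(trace.filtered, dtype=np.float64)
    if f.size != trace.positions.size:
        raise InputError("filtered length does not match positions")
    d = np.diff(f)
    mag = np.abs(d)
    out: list[Boundary] = []
    for n in range(mag.size):
        left = mag[n - 1] if n > 0 else -np.inf
        right = mag[n + 1] if n < mag.size - 1 else -np.inf
        # strict-left / non-strict-right comparison keeps one sample per plateau
        if mag[n] > min_jump and mag[n] > left and mag[n] >= right:
            pos = 0.5 * (trace.positions[n] + trace.positions[n + 1])
            direction = NORMAL_TO_ABNORMAL if d[n] < 0 else ABNORMAL_TO_NORMAL
            out.append(Boundary(position=float(pos), direction=direction,
                                magnitude=float(mag[n])))
    out.sort(key=lambda b: -b.magnitude)
    trace.boundaries = out
    return out


def default_min_jump(normal_traces: list[np.ndarray],
                     fraction: float = 0.5) -> float:
    """Data-driven jump threshold from normal-only traces.

    Half the 95th percentile of |first difference| over filtered traces of
    purely normal tissue: transitions must stand clearly above the residual
    score wiggle seen when no transition exists.
    """
    diffs = np.concatenate([np.abs(np.diff(np.asarray(t, dtype=np.float64)))
                            for t in normal_traces])
    if diffs.size == 0:
        raise InputError("need at least one trace with >= 2 samples")
    return float(fraction * np.percentile(diffs, 95))


def analyze_trace(model: OneClassModel, segmenter: SegmenterModel,
                  image: OCTImage, stride: int = 1,
                  min_jump: float | None = None) -> ScoreTrace:
    """score_trace + denoise + boundary detection in one call."""
    trace = score_trace(model, segmenter, image, stride=stride)
    trace.filtered = denoise_scores(trace.scores)
    if min_jump is None:
        min_jump = 0.5 * float(np.percentile(np.abs(np.diff(trace.filtered)), 95))
    detect_boundary(trace, min_jump)
    return trace
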