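"""Candidate detection: local maxima of the smoothed synapse-marker channel.

The marker raster is smoothed with an isotropic Gaussian kernel (default
sigma 480 nm) to suppress pixel noise, then all strict local maxima above an
intensity threshold are collected as synapse candidates.  The threshold is
deliberately permissive — false positives are removed later by the
goodness-of-fit filter — and defaults to a robust ``median + k * MAD`` rule
so runs are reproducible without a hand-picked value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List

import numpy as np
from scipy import ndimage

from .config import PipelineConfig
from .types import DomainError, ImageField, MARKER, SpotCandidate

log = logging.getLogger("cosiquant.detection")


@dataclass(frozen=True)
class DetectionResult:
    candidates: List[SpotCandidate]
    threshold_used: float
    sigma_px: float
    n_rejected_by_threshold: int


def smooth(raster: np.ndarray, sigma_px: float) -> np.ndarray:
    """Gaussian smoothing with reflective boundaries.

    Reflection preserves constant images and avoids the edge dimming that a
    zero-padded convolution would introduce into threshold decisions.
    """
    if sigma_px <= 0:
        raise DomainError("sigma_px must be positive")
    return ndimage.gaussian_filter(
        np.asarray(raster, dtype=float), sigma=sigma_px, mode="reflect"
    )


def robust_threshold(raster: np.ndarray, k: float) -> float:
    """Outlier-robust intensity threshold: median + k * 1.4826 * MAD.

    The 1.4826 factor makes the median absolute deviation a consistent
    estimator of the standard deviation under Gaussian noise.
    """
    raster = np.asarray(raster, dtype=float)
    if raster.size == 0:
        raise DomainError("empty raster")
    med = float(np.median(raster))
    mad = float(np.median(np.abs(raster - med)))
    return med + k * 1.4826 * mad


def _local_maxima(smoothed: np.ndarray, sep_px: int, margin: int):
    """Row-major list of (y, x, value) neighbourhood maxima inside margins.

    A pixel qualifies when it equals the maximum of its (2*sep+1)^2
    neighbourhood and exceeds its minimum (a perfectly flat patch is not a
    maximum); ties and dimmer maxima within the separation radius of a
    brighter one are resolved afterwards by the caller.
    """
    size = 2 * sep_px + 1
    footprint_max = ndimage.maximum_filter(smoothed, size=size, mode="reflect")
    footprint_min = ndimage.minimum_filter(smoothed, size=size, mode="reflect")
    mask = (smoothed >= footprint_max) & (smoothed > footprint_min)
    h, w = smoothed.shape
    mask[:margin, :] = False
    mask[:, :margin] = False
    if margin > 0:
        mask[h - margin :, :] = False
        mask[:, w - margin :] = False
    ys, xs = np.nonzero(mask)
    return [(int(y), int(x), float(smoothed[y, x])) for y, x in zip(ys, xs)]


def find_candidates(field: ImageField, config: PipelineConfig) -> DetectionResult:
    """Detect synapse candidates on the marker channel of one field.

    Maxima closer to the border than the fitting-ROI half-width are excluded
    so every candidate can later be fitted; maxima within the minimum
    separation of a brighter (or equal, earlier in row-major order) maximum
    are suppressed.
    """
    marker = field.channel(MARKER)
    sigma_px = config.sigma_px(field.pixel_size_nm)
    half = config.roi_half_px(field.pixel_size_nm)
    h, w = marker.shape
    if h < 2 * half + 1 or w < 2 * half + 1:
        log.warning(
            "field %s (%dx%d px) smaller than the %d px ROI; no candidates",
            field.field_id, h, w, 2 * half + 1,
        )
        return DetectionResult([], threshold_used=np.inf, sigma_px=sigma_px,
                               n_rejected_by_threshold=0)

    smoothed = smooth(marker, sigma_px)
    if config.detect_threshold_mode == "absolute":
        threshold = float(config.detect_threshold_value)
    else:
        threshold = robust_threshold(smoothed, config.detect_threshold_value)

    sep = config.separation_px(field.pixel_size_nm)
    peaks = _local_maxima(smoothed, sep, margin=half)

    # Greedy suppression: brightest first, ties broken by row-major order,
    # so of two equal plateau pixels the earlier one survives.
    peaks.sort(key=lambda p: (-p[2], p[0], p[1]))
    kept: list = []
    for y, x, v in peaks:
        if any(abs(y - ky) <= sep and abs(x - kx) <= sep for ky, kx, _ in kept):
            continue
        kept.append((y, x, v))

    n_below = sum(v < threshold for _, _, v in kept)
    kept = [(y, x, v) for y, x, v in kept if v >= threshold]
    kept.sort(key=lambda p: (p[0], p[1]))
    candidates = [
        SpotCandidate(x_px=x, y_px=y, smoothed_peak=v,
                      field_id=field.field_id, candidate_id=i)
        for i, (y, x, v) in enumerate(kept)
    ]
    log.info(
        "detect %s: %d candidates (threshold %.4g, %d maxima below threshold)",
        field.field_id, len(candidates), threshold, n_below,
    )
    return DetectionResult(
        candidates=candidates,
        threshold_used=threshold,
        sigma_px=sigma_px,
        n_rejected_by_threshold=n_below,
    )
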