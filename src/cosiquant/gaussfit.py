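"""Rotated elliptical 2D Gaussian fitting of puncta in raw-image ROIs.

Each synapse candidate is fitted independently in every channel on the raw
(unsmoothed) image, inside a square region of interest centred on the
candidate.  The model is

    f(x, y) = offset + A * exp(-(a dx^2 + 2 b dx dy + c dy^2))

with dx = x - x0, dy = y - y0 and

    a = cos^2(t)/(2 s1^2) + sin^2(t)/(2 s2^2)
    b = sin(2t)/(4 s1^2) - sin(2t)/(4 s2^2)
    c = sin^2(t)/(2 s1^2) + cos^2(t)/(2 s2^2),

i.e. variable position, size, orientation, amplitude and offset, with the
major axis along (cos t, sin t) so that the point one major sigma along it
evaluates to offset + A*exp(-1/2).  The
integrated (volume) intensity above offset is 2*pi*A*s1*s2, and the quality
of each fit is summarised by R^2 over the ROI pixels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Dict, List, Optional

import numpy as np
from scipy.optimize import curve_fit

from .config import PipelineConfig
from .detection import DetectionResult
from .types import DomainError, ImageField, SpotCandidate

log = logging.getLogger("cosiquant.gaussfit")

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class GaussianFit:
    """Converged (or failed) 2D Gaussian fit for one candidate in one channel.

    Continuous coordinates follow the package convention (pixel centers at
    integer values, ``x`` = column, ``y`` = row).  ``sigma_major_px >=
    sigma_minor_px`` and ``theta_rad`` lies in [0, pi) for converged fits; a
    failed fit carries ``converged=False`` and ``r2=-inf`` so it can never
    pass a goodness-of-fit threshold.
    """

    x0_px: float
    y0_px: float
    sigma_major_px: float
    sigma_minor_px: float
    theta_rad: float
    amplitude: float
    offset: float
    integrated_intensity: float
    r2: float
    converged: bool
    channel_role: str = ""

    @classmethod
    def failed(cls, role: str = "") -> "GaussianFit":
        return cls(
            x0_px=math.nan, y0_px=math.nan, sigma_major_px=math.nan,
            sigma_minor_px=math.nan, theta_rad=math.nan, amplitude=math.nan,
            offset=math.nan, integrated_intensity=math.nan, r2=-math.inf,
            converged=False, channel_role=role,
        )


@dataclass(frozen=True)
class SynapseRecord:
    """Per-candidate bundle: the three channel fits plus accept status."""

    candidate: SpotCandidate
    fits: Dict[str, GaussianFit]
    accepted: Optional[bool] = None
    reject_reason: Optional[str] = None


def gaussian2d_model(x, y, x0, y0, sigma_major, sigma_minor, theta, amplitude, offset):
    """Evaluate the rotated elliptical Gaussian at (x, y); vectorised."""
    if np.any(np.asarray(sigma_major) <= 0) or np.any(np.asarray(sigma_minor) <= 0):
        raise DomainError("gaussian2d_model requires positive sigmas")
    ct, st = math.cos(theta), math.sin(theta)
    s2t = math.sin(2.0 * theta)
    a = ct * ct / (2 * sigma_major**2) + st * st / (2 * sigma_minor**2)
    b = s2t / (4 * sigma_major**2) - s2t / (4 * sigma_minor**2)
    c = st * st / (2 * sigma_major**2) + ct * ct / (2 * sigma_minor**2)
    dx = np.asarray(x, dtype=float) - x0
    dy = np.asarray(y, dtype=float) - y0
    return offset + amplitude * np.exp(-(a * dx * dx + 2 * b * dx * dy + c * dy * dy))


def r_squared(data: np.ndarray, model: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot over ROI pixels.

    Zero-variance data makes R^2 undefined; NaN is returned and treated as a
    failed fit downstream.
    """
    data = np.asarray(data, dtype=float)
    model = np.asarray(model, dtype=float)
    if data.shape != model.shape:
        raise DomainError("data and model shapes differ")
    ss_tot = float(np.sum((data - data.mean()) ** 2))
    if ss_tot == 0.0:
        return math.nan
    ss_res = float(np.sum((data - model) ** 2))
    return 1.0 - ss_res / ss_tot


def canonical_orientation(sigma_major, sigma_minor, theta):
    """Map equivalent parameterisations to sigma_major >= sigma_minor,
    theta in [0, pi)."""
    if sigma_minor > sigma_major:
        sigma_major, sigma_minor = sigma_minor, sigma_major
        theta += math.pi / 2.0
    return sigma_major, sigma_minor, theta % math.pi


def extract_roi(raster: np.ndarray, x_px: int, y_px: int, half: int) -> np.ndarray:
    """Square (2*half+1)^2 view centred on the candidate; must fit inside."""
    h, w = raster.shape
    if not (half <= y_px < h - half and half <= x_px < w - half):
        raise DomainError(
            f"ROI of half-width {half} around ({x_px}, {y_px}) exceeds image bounds"
        )
    return raster[y_px - half : y_px + half + 1, x_px - half : x_px + half + 1]


def _moment_start(roi, xx, yy, lo, sig0, sig_hi):
    """Moment-based initial guess: intensity-weighted centroid and principal
    axes of the offset-subtracted ROI.  Returns None when degenerate."""
    w = roi - lo
    total = float(w.sum())
    if total <= 0:
        return None
    xb = float((w * xx).sum() / total)
    yb = float((w * yy).sum() / total)
    cxx = float((w * (xx - xb) ** 2).sum() / total)
    cyy = float((w * (yy - yb) ** 2).sum() / total)
    cxy = float((w * (xx - xb) * (yy - yb)).sum() / total)
    cov = np.array([[cxx, cxy], [cxy, cyy]])
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 0:
        return None
    s_minor, s_major = np.sqrt(evals)
    theta = math.atan2(evecs[1, 1], evecs[0, 1])  # major-axis eigenvector
    theta = ((theta + math.pi / 2) % math.pi) - math.pi / 2
    ny, nx = roi.shape
    clip = lambda s: float(np.clip(s, 0.55, sig_hi - 1e-6))
    x0 = float(np.clip(xb, 0.0, nx - 1.0))
    y0 = float(np.clip(yb, 0.0, ny - 1.0))
    amp0 = max(float(roi.max()) - lo, 1e-9)
    return [x0, y0, clip(s_major), clip(s_minor), theta, amp0, lo]


def fit_gaussian2d(
    roi: np.ndarray,
    init_sigma_px: float,
    role: str = "",
    x_offset: float = 0.0,
    y_offset: float = 0.0,
    max_nfev: int = 2000,
) -> GaussianFit:
    """Least-squares fit of the 2D Gaussian to one ROI.

    ``x_offset``/``y_offset`` shift the reported center into full-image
    coordinates.  Initialisation: center at the ROI center, offset at the ROI
    minimum, amplitude at max - min, isotropic sigma at ``init_sigma_px``.
    Bounds keep the center inside the ROI, sigmas in [0.5 px, ROI side / 2]
    and the amplitude non-negative, which prevents degenerate noise "fits"
    from producing runaway integrated intensities.
    """
    roi = np.asarray(roi, dtype=float)
    ny, nx = roi.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    lo = float(roi.min())
    hi = float(roi.max())
    sig_hi = max(nx, ny) / 2.0
    sig0 = float(np.clip(init_sigma_px, 0.6, sig_hi - 1e-6))
    amp0 = max(hi - lo, 1e-9)
    starts = [_moment_start(roi, xx, yy, lo, sig0, sig_hi)]
    starts.append([(nx - 1) / 2.0, (ny - 1) / 2.0, sig0, sig0, 0.0, amp0, lo])
    bounds = (
        [0.0, 0.0, 0.5, 0.5, -math.pi, 0.0, -np.inf],
        [nx - 1.0, ny - 1.0, sig_hi, sig_hi, math.pi, np.inf, np.inf],
    )

    def model_flat(coords, x0, y0, s1, s2, th, amp, off):
        x, y = coords
        return gaussian2d_model(x, y, x0, y0, s1, s2, th, amp, off)

    popt = None
    best_cost = np.inf
    for p0 in starts:
        if p0 is None:
            continue
        try:
            sol, _ = curve_fit(
                model_flat,
                (xx.ravel(), yy.ravel()),
                roi.ravel(),
                p0=p0,
                bounds=bounds,
                max_nfev=max_nfev,
            )
        except (RuntimeError, ValueError):
            continue
        cost = float(np.sum((model_flat((xx.ravel(), yy.ravel()), *sol) - roi.ravel()) ** 2))
        if cost < best_cost:
            best_cost, popt = cost, sol
    if popt is None:
        return GaussianFit.failed(role)

    x0, y0, s1, s2, th, amp, off = popt
    s1, s2, th = canonical_orientation(s1, s2, th)
    model = gaussian2d_model(xx, yy, x0, y0, s1, s2, th, amp, off)
    r2 = r_squared(roi, model)
    if math.isnan(r2):
        return GaussianFit.failed(role)
    return GaussianFit(
        x0_px=float(x0 + x_offset),
        y0_px=float(y0 + y_offset),
        sigma_major_px=float(s1),
        sigma_minor_px=float(s2),
        theta_rad=float(th),
        amplitude=float(amp),
        offset=float(off),
        integrated_intensity=float(TWO_PI * amp * s1 * s2),
        r2=float(r2),
        converged=True,
        channel_role=role,
    )


def fit_roi(
    field: ImageField,
    candidate: SpotCandidate,
    role: str,
    config: PipelineConfig,
) -> GaussianFit:
    """Fit one channel of one candidate on the raw image ROI."""
    raster = field.channel(role)
    half = config.roi_half_px(field.pixel_size_nm)
    roi = extract_roi(raster, candidate.x_px, candidate.y_px, half)
    return fit_gaussian2d(
        roi,
        init_sigma_px=config.sigma_px(field.pixel_size_nm),
        role=role,
        x_offset=candidate.x_px - half,
        y_offset=candidate.y_px - half,
    )


def fit_all_channels(
    field: ImageField,
    detection: DetectionResult,
    config: PipelineConfig,
) -> List[SynapseRecord]:
    """Fit every candidate in every channel; acceptance is decided later."""
    records = []
    for cand in detection.candidates:
        fits = {
            role: fit_roi(field, cand, role, config)
            for role in field.channel_roles
        }
        records.append(SynapseRecord(candidate=cand, fits=fits))
    n_conv = sum(all(f.converged for f in r.fits.values()) for r in records)
    log.info(
        "fit %s: %d candidates, %d fully converged", field.field_id, len(records), n_conv
    )
    return records
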