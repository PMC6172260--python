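"""Single-antibody intensity calibration.

Individual immunostained primary antibodies adsorbed to a coverslip are
detected with a difference-of-Gaussians bandpass filter, Gaussian-fitted on
the raw image, and their integrated-intensity population is fitted with a
single 1D Gaussian.  The peak of that population Gaussian is the mean
single-antibody intensity, the divisor that turns any structure's intensity
into an antibody count.

With super-resolution data (pixel size <= 25 nm here) spots with a fitted
FWHM above 50 nm are discarded as dirt or antibody clusters; at conventional
pixel sizes that cutoff is unresolvable and an adaptive sanity bound of twice
the population's median FWHM is applied instead.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .config import PipelineConfig
from .detection import robust_threshold, smooth, _local_maxima
from .gaussfit import GaussianFit, extract_roi, fit_gaussian2d, r_squared
from .types import (
    CALIBRATION,
    DomainError,
    ImageField,
    InsufficientDataError,
)

log = logging.getLogger("cosiquant.calibration")

FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))  # sigma -> FWHM, ~2.3548

#: Pixel size below which the absolute FWHM cutoff is considered resolvable.
SUPER_RESOLUTION_PIXEL_NM = 25.0


@dataclass(frozen=True)
class CalibrationResult:
    spot_intensities: tuple
    n_rejected_fwhm: int
    population_mu: float
    population_sigma: float
    population_fit_r2: float
    fwhm_cutoff_nm: float
    population_median: float
    population_fit_warning: bool

    @property
    def n_spots(self) -> int:
        return len(self.spot_intensities)


def bandpass(raster: np.ndarray, sigma_small_px: float, sigma_large_px: float) -> np.ndarray:
    """Difference-of-Gaussians bandpass: passes structures around the small
    scale while rejecting the DC level and slow background gradients."""
    if not 0 < sigma_small_px < sigma_large_px:
        raise DomainError("require 0 < sigma_small_px < sigma_large_px")
    return smooth(raster, sigma_small_px) - smooth(raster, sigma_large_px)


def fwhm_of_fit(fit: GaussianFit, pixel_size_nm: float) -> float:
    """FWHM in nm of a fitted spot, using the geometric-mean sigma so an
    elliptical fit maps to the isotropic spot of equal area."""
    sigma_mean = math.sqrt(fit.sigma_major_px * fit.sigma_minor_px)
    return FWHM_FACTOR * sigma_mean * pixel_size_nm


def _gauss1d(x, a, mu, sigma):
    return a * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def fit_intensity_population(intensities: np.ndarray):
    """Least-squares single-Gaussian fit to the Freedman-Diaconis histogram
    of spot intensities; returns (mu, sigma, r2)."""
    counts, edges = np.histogram(intensities, bins="fd")
    if len(counts) < 4:
        counts, edges = np.histogram(intensities, bins=max(4, intensities.size // 5))
    centers = 0.5 * (edges[:-1] + edges[1:])
    p0 = [float(counts.max()), float(np.median(intensities)), float(intensities.std() or 1.0)]
    try:
        popt, _ = curve_fit(_gauss1d, centers, counts, p0=p0, maxfev=5000)
        a, mu, sigma = popt
        sigma = abs(float(sigma))
        r2 = r_squared(counts, _gauss1d(centers, a, mu, sigma))
    except (RuntimeError, ValueError):
        mu, sigma, r2 = float(np.median(intensities)), float(intensities.std()), 0.0
    return float(mu), sigma, float(r2)


def detect_calibration_spots(
    field: ImageField,
    config: PipelineConfig,
    psf_sigma_nm: float,
    roi_half_px: int,
) -> List[GaussianFit]:
    """Bandpass-detect antibody spots on one field and fit each on the raw
    image.  The bandpass scales default to the PSF sigma and 3x the PSF
    sigma."""
    raster = field.channels[0]
    px = field.pixel_size_nm
    s_small = psf_sigma_nm / px
    bp = bandpass(raster, s_small, 3.0 * s_small)
    thr = robust_threshold(bp, config.detect_threshold_value)
    sep = max(1, int(round(2.0 * s_small)))
    peaks = _local_maxima(bp, sep, margin=roi_half_px)
    peaks.sort(key=lambda p: (-p[2], p[0], p[1]))
    kept = []
    for y, x, v in peaks:
        if v < thr:
            continue
        if any(abs(y - ky) <= sep and abs(x - kx) <= sep for ky, kx in kept):
            continue
        kept.append((y, x))
    fits = []
    for y, x in kept:
        roi = extract_roi(raster, x, y, roi_half_px)
        fit = fit_gaussian2d(
            roi, init_sigma_px=s_small, role=CALIBRATION,
            x_offset=x - roi_half_px, y_offset=y - roi_half_px,
        )
        if fit.converged and fit.amplitude > 0:
            fits.append(fit)
    return fits


def calibrate(
    fields: Sequence[ImageField],
    config: PipelineConfig,
    psf_sigma_nm: Optional[float] = None,
    fwhm_cutoff_nm: float = 50.0,
    roi_side_nm: Optional[float] = None,
) -> CalibrationResult:
    """Measure the mean single-antibody intensity from calibration fields.

    Parameters
    ----------
    fields
        One or more single-channel calibration acquisitions (crops of sample
        fields next to cells work equally well).
    psf_sigma_nm
        Expected spot sigma, used for the bandpass scales and fit
        initialisation; defaults to the pipeline smoothing sigma.
    fwhm_cutoff_nm
        Spots wider than this are discounted as dirt — but only when the
        pixel size resolves the cutoff (super-resolution data); otherwise
        spots wider than twice the population median FWHM are dropped.
    roi_side_nm
        Side of the per-spot fitting ROI; defaults to the pipeline ROI.
    """
    if len(fields) == 0:
        raise InsufficientDataError("calibrate needs at least one field")
    psf = psf_sigma_nm if psf_sigma_nm is not None else config.smoothing_sigma_nm
    fits: List[GaussianFit] = []
    for field in fields:
        px = field.pixel_size_nm
        side = roi_side_nm if roi_side_nm is not None else config.roi_side_nm
        half = max(2, int(round(side / px)) // 2)
        fits.extend(detect_calibration_spots(field, config, psf, half))
    if not fits:
        raise InsufficientDataError("no antibody spots detected")

    px = fields[0].pixel_size_nm
    fwhms = np.array([fwhm_of_fit(f, px) for f in fits])
    if px <= SUPER_RESOLUTION_PIXEL_NM:
        keep = fwhms <= fwhm_cutoff_nm
        cutoff_used = fwhm_cutoff_nm
    else:
        cutoff_used = 2.0 * float(np.median(fwhms))
        keep = fwhms <= cutoff_used
    n_rejected = int((~keep).sum())
    retained = [f for f, k in zip(fits, keep) if k]
    if len(retained) < 10:
        raise InsufficientDataError(
            f"only {len(retained)} antibody spots retained (< 10)"
        )

    intensities = np.array([f.integrated_intensity for f in retained])
    mu, sigma, r2 = fit_intensity_population(intensities)
    warning = r2 < 0.5
    if warning:
        log.warning(
            "intensity population poorly fit by a single Gaussian (R^2=%.2f); "
            "possible antibody clusters or multimodal population", r2,
        )
    if mu <= 0:
        mu = float(np.median(intensities))
    log.info(
        "calibrate: %d spots retained, %d rejected by size, mu=%.4g",
        len(retained), n_rejected, mu,
    )
    return CalibrationResult(
        spot_intensities=tuple(float(v) for v in intensities),
        n_rejected_fwhm=n_rejected,
        population_mu=mu,
        population_sigma=sigma,
        population_fit_r2=r2,
        fwhm_cutoff_nm=float(cutoff_used),
        population_median=float(np.median(intensities)),
        population_fit_warning=warning,
    )
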