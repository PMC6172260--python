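"""Filtering of fitted candidates and conversion of intensities into
per-synapse protein copy numbers.

The copy-number interpolation is the heart of the comparative approach: each
accepted culture-synapse intensity is divided by the mean intensity of the
biochemically characterised synaptosomes stained in parallel, and multiplied
by the published mean copies per synaptosome.  Intensities here are the
fitted integrated (volume) intensities, 2*pi*A*sigma1*sigma2; amplitude-based
summaries are available for sensitivity analysis via ``measure="amplitude"``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, List, Sequence, Tuple

import numpy as np
from scipy import stats

from .config import PipelineConfig
from .gaussfit import SynapseRecord
from .types import DomainError, SYNAPSE_ROLES

log = logging.getLogger("cosiquant.quantify")


@dataclass(frozen=True)
class IntensitySummary:
    sample_kind: str
    role: str
    n: int
    mean_intensity: float
    sem_intensity: float


@dataclass(frozen=True)
class CopyNumberEstimate:
    """Per-synapse copy numbers for one target protein.

    ``per_synapse_copies[i] = synapse_intensity[i] / reference_mean_intensity
    * reference_copies``.  The headline mean and SEM summarise the
    per-synapse values; the reference table's own SEM is reported separately
    and not propagated.
    """

    target: str
    per_synapse_copies: Tuple[float, ...]
    mean_copies: float
    sem_copies: float
    reference_copies: float
    reference_mean_intensity: float


def mean_sem(values: Sequence[float]) -> Tuple[float, float]:
    """Arithmetic mean and standard error of the mean (n-1 denominator).

    SEM is 0.0 for a single value.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise DomainError("mean_sem of an empty list")
    mean = float(arr.mean())
    if arr.size < 2:
        return mean, 0.0
    return mean, float(arr.std(ddof=1) / math.sqrt(arr.size))


def filter_records(
    records: Iterable[SynapseRecord], config: PipelineConfig
) -> List[SynapseRecord]:
    """Set the accept flag on each record from the per-channel R^2 thresholds.

    Thresholds are inclusive (a fit exactly at the threshold passes); a
    non-converged or R^2-undefined fit always fails.  Rejected records name
    the failing channel(s) in ``reject_reason``.
    """
    out = []
    for rec in records:
        failing = []
        for role, thr in config.r2_thresholds.items():
            fit = rec.fits.get(role)
            if fit is None or not fit.converged or math.isnan(fit.r2) or fit.r2 < thr:
                failing.append(role)
        if failing:
            out.append(replace(rec, accepted=False, reject_reason=",".join(failing)))
        else:
            out.append(replace(rec, accepted=True, reject_reason=None))
    n_acc = sum(r.accepted for r in out)
    log.info("filter: %d/%d records accepted", n_acc, len(out))
    return out


def accepted_intensities(
    records: Iterable[SynapseRecord], role: str, measure: str = "integrated"
) -> np.ndarray:
    """Intensities of the given channel over accepted records."""
    if measure not in ("integrated", "amplitude"):
        raise DomainError(f"unknown intensity measure {measure!r}")
    vals = [
        rec.fits[role].integrated_intensity
        if measure == "integrated"
        else rec.fits[role].amplitude
        for rec in records
        if rec.accepted and role in rec.fits
    ]
    return np.asarray(vals, dtype=float)


def summarize_intensities(
    records: Sequence[SynapseRecord],
    sample_kind: str,
    roles: Sequence[str] = SYNAPSE_ROLES,
    measure: str = "integrated",
) -> List[IntensitySummary]:
    summaries = []
    for role in roles:
        vals = accepted_intensities(records, role, measure)
        if vals.size == 0:
            continue
        mean, sem = mean_sem(vals)
        summaries.append(IntensitySummary(sample_kind, role, int(vals.size), mean, sem))
    return summaries


def estimate_copy_numbers(
    synapse_intensities: Sequence[float],
    synaptosome_intensities: Sequence[float],
    reference_copies: float,
    target: str = "",
) -> CopyNumberEstimate:
    """Interpolate per-synapse copy numbers against the synaptosome standard.

    Each synapse intensity is divided by the *mean* synaptosome intensity and
    multiplied by the published copies per synaptosome; the estimate is
    invariant under any common rescaling of both intensity sets.
    """
    syn = np.asarray(synapse_intensities, dtype=float)
    ref = np.asarray(synaptosome_intensities, dtype=float)
    if syn.size == 0 or ref.size == 0:
        raise DomainError("both intensity lists must be non-empty")
    ref_mean = float(ref.mean())
    if ref_mean <= 0:
        raise DomainError("mean synaptosome intensity must be positive")
    if reference_copies <= 0:
        raise DomainError("reference_copies must be positive")
    copies = syn / ref_mean * reference_copies
    mean, sem = mean_sem(copies)
    return CopyNumberEstimate(
        target=target,
        per_synapse_copies=tuple(float(c) for c in copies),
        mean_copies=mean,
        sem_copies=sem,
        reference_copies=float(reference_copies),
        reference_mean_intensity=ref_mean,
    )


def antibodies_per_structure(
    structure_intensities: Sequence[float], single_ab_mean_intensity: float
) -> np.ndarray:
    """Express structure intensities as numbers of primary antibodies.

    Assumes antibody signals sum linearly, so dividing by the mean intensity
    of a single immunostained antibody yields an antibody count.
    """
    if single_ab_mean_intensity <= 0:
        raise DomainError("single-antibody mean intensity must be positive")
    return np.asarray(structure_intensities, dtype=float) / single_ab_mean_intensity


def compare_measured_vs_estimated(
    measured: Sequence[float], estimated: Sequence[float]
) -> Tuple[float, float]:
    """Ordinary least-squares line y = a*x + b between two copy/antibody-number
    sets; returns (slope, R^2).  Utility for cross-dataset validation."""
    x = np.asarray(estimated, dtype=float)
    y = np.asarray(measured, dtype=float)
    if x.size != y.size:
        raise DomainError("length mismatch")
    if x.size < 2:
        raise DomainError("need at least two points")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.rvalue**2)
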