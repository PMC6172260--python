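"""End-to-end orchestration: detect -> fit -> filter -> quantify on a
synaptosome/culture sample pair processed with one shared configuration.

The method's validity rests on identical processing of the reference and the
sample of interest; the only per-sample override permitted is the detection
threshold, because background levels differ between a synaptosome lawn and a
neuron culture.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import __version__
from .config import PipelineConfig
from .detection import find_candidates
from .gaussfit import SynapseRecord, fit_all_channels
from .quantify import (
    CopyNumberEstimate,
    IntensitySummary,
    accepted_intensities,
    estimate_copy_numbers,
    filter_records,
    mean_sem,
    summarize_intensities,
)
from .reference import ReferenceEntry, lookup
from .types import (
    ConfigurationError,
    EmptyResultError,
    ImageField,
    POI,
)

log = logging.getLogger("cosiquant.pipeline")


@dataclass(frozen=True)
class StageCounts:
    field_id: str
    n_candidates: int
    n_fitted: int
    n_accepted: int


@dataclass(frozen=True)
class RunReport:
    """Summary of one comparative run; reproducible from config + inputs."""

    config: dict
    counts: Dict[str, List[StageCounts]]  # sample kind -> per-field counts
    intensity_summaries: Dict[str, List[IntensitySummary]]
    copy_numbers: Optional[CopyNumberEstimate]
    antibodies_per_synapse_mean: Optional[float]
    antibodies_per_synapse_sem: Optional[float]
    calibration_mu: Optional[float]
    reference_target: Optional[str]
    version: str
    seed: int

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        return enc(dataclasses.asdict(self))

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def process_sample(
    fields: Sequence[ImageField],
    config: PipelineConfig,
) -> tuple:
    """Run detect -> fit -> filter on every field of one sample.

    Returns (records, per-field StageCounts).  The stage bookkeeping
    invariant n(candidates) >= n(fitted) >= n(accepted) holds per field.
    """
    all_records: List[SynapseRecord] = []
    counts: List[StageCounts] = []
    for field in fields:
        det = find_candidates(field, config)
        records = fit_all_channels(field, det, config)
        records = filter_records(records, config)
        n_fit = sum(all(f.converged for f in r.fits.values()) for r in records)
        counts.append(StageCounts(
            field_id=field.field_id,
            n_candidates=len(det.candidates),
            n_fitted=n_fit,
            n_accepted=sum(bool(r.accepted) for r in records),
        ))
        all_records.extend(records)
    return all_records, counts


def run_pipeline(
    synaptosome_fields: Sequence[ImageField],
    culture_fields: Sequence[ImageField],
    config: PipelineConfig,
    reference_target: Optional[str] = None,
    reference_entry: Optional[ReferenceEntry] = None,
    reference_copies: Optional[float] = None,
    calibration_mu: Optional[float] = None,
    culture_threshold_override: Optional[float] = None,
    measure: str = "integrated",
) -> RunReport:
    """Execute the full comparative analysis on a sample pair.

    Copy numbers for the protein of interest are computed when a reference
    is given — either a target name resolved against the packaged table, an
    explicit :class:`ReferenceEntry`, or a raw ``reference_copies`` value.
    ``calibration_mu`` (mean single-antibody intensity) additionally converts
    culture-synapse intensities into antibodies per synapse.
    """
    if len(synaptosome_fields) == 0 or len(culture_fields) == 0:
        raise ConfigurationError("both synaptosome and culture fields are required")

    syn_records, syn_counts = process_sample(synaptosome_fields, config)
    cul_config = config
    if culture_threshold_override is not None:
        cul_config = dataclasses.replace(
            config, detect_threshold_value=culture_threshold_override
        )
    cul_records, cul_counts = process_sample(culture_fields, cul_config)

    for kind, recs in (("synaptosome", syn_records), ("culture", cul_records)):
        if not any(r.accepted for r in recs):
            raise EmptyResultError(
                f"no accepted synapses in the {kind} sample after R^2 filtering"
            )

    summaries = {
        "synaptosome": summarize_intensities(syn_records, "synaptosome", measure=measure),
        "culture": summarize_intensities(cul_records, "culture", measure=measure),
    }

    copies = None
    target_name = reference_target
    if reference_entry is None and reference_target is not None:
        reference_entry = lookup(reference_target)
    if reference_entry is not None:
        if reference_entry.copies_per_synaptosome is None:
            raise ConfigurationError(
                f"reference entry {reference_entry.target!r} has no measured "
                f"copy number ({reference_entry.copies_provenance})"
            )
        reference_copies = reference_entry.copies_per_synaptosome
        target_name = reference_entry.target
    if reference_copies is not None:
        copies = estimate_copy_numbers(
            accepted_intensities(cul_records, POI, measure),
            accepted_intensities(syn_records, POI, measure),
            reference_copies,
            target=target_name or "",
        )

    ab_mean = ab_sem = None
    if calibration_mu is not None:
        from .quantify import antibodies_per_structure

        counts_per_synapse = antibodies_per_structure(
            accepted_intensities(cul_records, POI, measure), calibration_mu
        )
        ab_mean, ab_sem = mean_sem(counts_per_synapse)

    report = RunReport(
        config=config.to_dict(),
        counts={"synaptosome": syn_counts, "culture": cul_counts},
        intensity_summaries=summaries,
        copy_numbers=copies,
        antibodies_per_synapse_mean=ab_mean,
        antibodies_per_synapse_sem=ab_sem,
        calibration_mu=calibration_mu,
        reference_target=target_name,
        version=__version__,
        seed=config.seed,
    )
    log.info(
        "run complete: %d/%d synaptosome and %d/%d culture records accepted",
        sum(c.n_accepted for c in syn_counts), sum(c.n_candidates for c in syn_counts),
        sum(c.n_accepted for c in cul_counts), sum(c.n_candidates for c in cul_counts),
    )
    return report
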