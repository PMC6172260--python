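"""Image and tabular input/output.

TIFF stacks are read page-per-channel and promoted to float64 without any
rescaling — cross-sample intensity comparison requires raw units.  Tabular
outputs are plain CSV with fixed, documented headers; floats are written in
shortest-exact ``repr`` form so a read-back reproduces them bit-for-bit.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import tifffile

from .gaussfit import GaussianFit, SynapseRecord
from .types import (
    ConfigurationError,
    CosiQuantError,
    FormatError,
    ImageField,
    SpotCandidate,
)

log = logging.getLogger("cosiquant.io")

#: Fixed header of the per-(record, channel) fit table.  ``x0_nm``/``y0_nm``
#: duplicate the continuous center in physical units.
RECORD_COLUMNS = [
    "field_id", "candidate_id", "cand_x_px", "cand_y_px", "smoothed_peak",
    "channel_role", "x0_px", "y0_px", "x0_nm", "y0_nm",
    "sigma_major_px", "sigma_minor_px", "theta_rad", "amplitude", "offset",
    "integrated_intensity", "r2", "converged", "accepted", "reject_reason",
]

CANDIDATE_COLUMNS = ["field_id", "candidate_id", "x_px", "y_px", "smoothed_peak"]


def read_field(
    path,
    pixel_size_nm: float,
    channel_roles: Sequence[str],
    field_id: Optional[str] = None,
    sample_kind: str = "synaptosome",
) -> ImageField:
    """Read a single- or multi-page grayscale TIFF as one ImageField.

    The page count must equal the number of roles; page shapes must agree.
    """
    path = Path(path)
    try:
        arr = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise CosiQuantError(f"cannot read TIFF {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3:
        raise FormatError(f"{path}: expected 2D pages, got array of ndim {arr.ndim}")
    if arr.shape[0] != len(channel_roles):
        raise ConfigurationError(
            f"{path}: {arr.shape[0]} pages but {len(channel_roles)} channel roles"
        )
    return ImageField(
        channels=tuple(arr.astype(np.float64)),
        channel_roles=tuple(channel_roles),
        pixel_size_nm=pixel_size_nm,
        field_id=field_id or path.stem,
        sample_kind=sample_kind,
    )


def write_field(field: ImageField, path) -> None:
    """Write the channels of a field as a multi-page float32 TIFF."""
    stack = np.stack(field.channels).astype(np.float32)
    tifffile.imwrite(path, stack, photometric="minisblack")


def write_candidates(candidates: Sequence[SpotCandidate], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(CANDIDATE_COLUMNS)
        for c in candidates:
            w.writerow([c.field_id, c.candidate_id, c.x_px, c.y_px, repr(c.smoothed_peak)])


def read_candidates(path) -> List[SpotCandidate]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(SpotCandidate(
                x_px=int(row["x_px"]), y_px=int(row["y_px"]),
                smoothed_peak=float(row["smoothed_peak"]),
                field_id=row["field_id"], candidate_id=int(row["candidate_id"]),
            ))
    return out


def write_records(
    records: Sequence[SynapseRecord], path, pixel_size_nm: Optional[float] = None
) -> None:
    """Write one CSV row per (record, channel) with all fit parameters.

    ``x0_nm``/``y0_nm`` are filled when ``pixel_size_nm`` is given, else
    left empty.  An empty record list writes the header only.
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(RECORD_COLUMNS)
        for rec in records:
            c = rec.candidate
            for role, fit in rec.fits.items():
                x_nm = repr(fit.x0_px * pixel_size_nm) if pixel_size_nm else ""
                y_nm = repr(fit.y0_px * pixel_size_nm) if pixel_size_nm else ""
                w.writerow([
                    c.field_id, c.candidate_id, c.x_px, c.y_px, repr(c.smoothed_peak),
                    role, repr(fit.x0_px), repr(fit.y0_px), x_nm, y_nm,
                    repr(fit.sigma_major_px), repr(fit.sigma_minor_px),
                    repr(fit.theta_rad), repr(fit.amplitude), repr(fit.offset),
                    repr(fit.integrated_intensity), repr(fit.r2),
                    int(fit.converged),
                    "" if rec.accepted is None else int(rec.accepted),
                    rec.reject_reason or "",
                ])
    log.info("wrote %d records to %s", len(records), path)


def read_records(path) -> List[SynapseRecord]:
    """Reconstruct SynapseRecords from a CSV written by :func:`write_records`."""
    groups: dict = {}
    order: list = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            key = (row["field_id"], int(row["candidate_id"]))
            if key not in groups:
                groups[key] = {"rows": [], "accepted": row["accepted"],
                               "reason": row["reject_reason"]}
                order.append(key)
            groups[key]["rows"].append(row)
    records = []
    for key in order:
        g = groups[key]
        first = g["rows"][0]
        cand = SpotCandidate(
            x_px=int(first["cand_x_px"]), y_px=int(first["cand_y_px"]),
            smoothed_peak=float(first["smoothed_peak"]),
            field_id=first["field_id"], candidate_id=int(first["candidate_id"]),
        )
        fits = {}
        for row in g["rows"]:
            fits[row["channel_role"]] = GaussianFit(
                x0_px=float(row["x0_px"]), y0_px=float(row["y0_px"]),
                sigma_major_px=float(row["sigma_major_px"]),
                sigma_minor_px=float(row["sigma_minor_px"]),
                theta_rad=float(row["theta_rad"]),
                amplitude=float(row["amplitude"]), offset=float(row["offset"]),
                integrated_intensity=float(row["integrated_intensity"]),
                r2=float(row["r2"]), converged=bool(int(row["converged"])),
                channel_role=row["channel_role"],
            )
        accepted = None if g["accepted"] == "" else bool(int(g["accepted"]))
        records.append(SynapseRecord(
            candidate=cand, fits=fits, accepted=accepted,
            reject_reason=g["reason"] or None,
        ))
    return records
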