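"""Packaged synaptosome reference: antibodies and protein copies per
synaptosome for 120 antibody/target combinations, with the staining
conditions under which each number was obtained.

The table is the transferable currency of the comparative approach: a lab
that measures "antibodies per structure" for its own sample under the same
staining conditions can convert to protein copy numbers via these entries
without ever handling the characterised synaptosome preparation.

Copy-number provenance per entry:

* ``measured`` — biochemically determined in the source synaptosome
  characterisation; carries a numeric value and SEM.
* ``estimated_by_authors`` — only a textual estimate exists (e.g. "~100-200",
  "<100", or "similar to ChromograninB"); stored as a structured range plus
  qualifier, never collapsed to a single float.
* ``not_determined`` — no copy number available.
"""

from __future__ import annotations

import csv
import difflib
import logging
from dataclasses import dataclass, fields as dc_fields
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import List, Optional

from .types import AmbiguousLookupError, DomainError, FormatError, NotFoundError

log = logging.getLogger("cosiquant.reference")

DISPERSION_KINDS = ("SEM", "ROV")
PROVENANCES = ("measured", "estimated_by_authors", "not_determined")

#: Synaptic-vesicle counts from 30 electron-microscopy 3D reconstructions of
#: cultured hippocampal synapses.  Their mean +/- SEM (250 +/- 26) anchors the
#: expectation that cultured synapses hold ~35% fewer vesicles than the
#: synaptosome standard (~380 vesicles on average).
CULTURE_VESICLE_COUNTS = (
    36, 86, 89, 95, 119, 124, 128, 136, 137, 173, 185, 191, 197, 197, 212,
    224, 233, 248, 249, 252, 257, 302, 315, 377, 403, 450, 509, 516, 526, 544,
)

#: Mean synaptic-vesicle count per synaptosome in the reference preparation.
SYNAPTOSOME_MEAN_VESICLES = 380.0


@dataclass(frozen=True)
class ReferenceEntry:
    """One row of the synaptosome reference table."""

    target: str
    mean_antibodies_per_synaptosome: float
    dispersion_value: float
    dispersion_kind: str
    copies_per_synaptosome: Optional[float]
    copies_sem: Optional[float]
    copies_range_low: Optional[float]
    copies_range_high: Optional[float]
    copies_qualifier: str
    copies_provenance: str
    company: str
    catalog_number: str
    species_clonality: str
    dilution: str
    fixation: str
    blocking: str
    permeabilization: str
    note: str = ""

    def __post_init__(self):
        if self.mean_antibodies_per_synaptosome <= 0:
            raise DomainError(f"{self.target}: antibodies/synaptosome must be > 0")
        if self.dispersion_value < 0:
            raise DomainError(f"{self.target}: dispersion must be >= 0")
        if self.dispersion_kind not in DISPERSION_KINDS:
            raise FormatError(f"{self.target}: bad dispersion kind {self.dispersion_kind!r}")
        if self.copies_provenance not in PROVENANCES:
            raise FormatError(f"{self.target}: bad provenance {self.copies_provenance!r}")
        has_info = (
            self.copies_per_synaptosome is not None
            or self.copies_range_low is not None
            or self.copies_range_high is not None
            or bool(self.copies_qualifier)
        )
        if (self.copies_provenance != "not_determined") != has_info:
            raise FormatError(
                f"{self.target}: copy-number info inconsistent with provenance "
                f"{self.copies_provenance!r}"
            )

    def describe(self) -> str:
        return (
            f"{self.target} [{self.company} {self.catalog_number or '-'} "
            f"{self.dilution}, {self.dispersion_kind}]"
        )


def _opt_float(s: str) -> Optional[float]:
    return float(s) if s not in ("", None) else None


def _data_path() -> Path:
    return resources.files("cosiquant.data") / "reference_table.csv"


@lru_cache(maxsize=1)
def load_reference() -> List[ReferenceEntry]:
    """Load and validate the packaged reference table (>= 100 entries)."""
    entries = []
    with _data_path().open(newline="") as fh:
        for row in csv.DictReader(fh):
            entries.append(
                ReferenceEntry(
                    target=row["target"],
                    mean_antibodies_per_synaptosome=float(row["antibodies_per_synaptosome"]),
                    dispersion_value=float(row["dispersion_value"]),
                    dispersion_kind=row["dispersion_kind"],
                    copies_per_synaptosome=_opt_float(row["copies_per_synaptosome"]),
                    copies_sem=_opt_float(row["copies_sem"]),
                    copies_range_low=_opt_float(row["copies_range_low"]),
                    copies_range_high=_opt_float(row["copies_range_high"]),
                    copies_qualifier=row["copies_qualifier"],
                    copies_provenance=row["copies_provenance"],
                    company=row["company"],
                    catalog_number=row["catalog_number"],
                    species_clonality=row["species_clonality"],
                    dilution=row["dilution"],
                    fixation=row["fixation"],
                    blocking=row["blocking"],
                    permeabilization=row["permeabilization"],
                    note=row.get("note", ""),
                )
            )
    if len(entries) < 100:
        raise FormatError(
            f"packaged reference table has only {len(entries)} entries; corrupted?"
        )
    return entries


def lookup(
    target: str,
    catalog_number: Optional[str] = None,
    dilution: Optional[str] = None,
    dispersion_kind: Optional[str] = None,
) -> ReferenceEntry:
    """Case-insensitive exact lookup of one reference entry.

    Several antibodies exist for some targets (different vendors or
    dilutions); ``catalog_number``, ``dilution`` and/or ``dispersion_kind``
    narrow the match.  An ambiguous query raises with the candidate rows
    enumerated; a miss raises with near-name suggestions.
    """
    entries = load_reference()
    hits = [e for e in entries if e.target.lower() == target.lower()]
    if not hits:
        names = sorted({e.target for e in entries})
        suggestions = difflib.get_close_matches(target, names, n=3, cutoff=0.5)
        hint = f"; did you mean {', '.join(suggestions)}?" if suggestions else ""
        raise NotFoundError(f"no reference entry for {target!r}{hint}")
    if catalog_number is not None:
        hits = [e for e in hits if e.catalog_number.replace(" ", "")
                == catalog_number.replace(" ", "")]
    if dilution is not None:
        hits = [e for e in hits if e.dilution == dilution]
    if dispersion_kind is not None:
        hits = [e for e in hits if e.dispersion_kind == dispersion_kind.upper()]
    if not hits:
        raise NotFoundError(
            f"no reference entry for {target!r} matching the given qualifiers"
        )
    if len(hits) > 1:
        listing = "; ".join(e.describe() for e in hits)
        raise AmbiguousLookupError(
            f"{len(hits)} reference entries match {target!r}: {listing} "
            f"(disambiguate by catalog_number, dilution or dispersion_kind)",
            candidates=hits,
        )
    return hits[0]


def export_csv(path) -> None:
    """Write the full reference table to a CSV file (lossless round-trip)."""
    entries = load_reference()
    cols = [f.name for f in dc_fields(ReferenceEntry)]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(cols)
        for e in entries:
            w.writerow(["" if getattr(e, c) is None else getattr(e, c) for c in cols])
    log.info("exported %d reference entries to %s", len(entries), path)
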