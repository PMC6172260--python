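"""Shared domain types for the comparative synaptosome imaging pipeline.

Coordinate convention used throughout the package: rasters are indexed
``array[y, x]`` (row, column), pixel indices are 0-based, and continuous
(sub-pixel) fit coordinates place pixel centers at integer values.  Physical
lengths are carried in nanometres and converted with :func:`nm_to_px` /
:func:`px_to_nm`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

# Channel roles.  A synapse field carries exactly one synaptic-vesicle marker
# channel (synaptophysin), one active-zone channel (bassoon) and one channel
# for the protein of interest; calibration fields carry a single channel of
# surface-adsorbed single antibodies.
MARKER = "marker"
ACTIVE_ZONE = "active_zone"
POI = "poi"
CALIBRATION = "calibration"

SYNAPSE_ROLES = (MARKER, ACTIVE_ZONE, POI)
ALL_ROLES = SYNAPSE_ROLES + (CALIBRATION,)

SAMPLE_KINDS = ("synaptosome", "culture", "calibration")


class CosiQuantError(Exception):
    """Base class for package errors."""


class ConfigurationError(CosiQuantError):
    """Inconsistent configuration or mismatched inputs."""


class FormatError(CosiQuantError):
    """Malformed input file."""


class DomainError(CosiQuantError, ValueError):
    """Argument outside its mathematical domain."""


class NotFoundError(CosiQuantError, KeyError):
    """Reference-table lookup found no matching entry."""


class AmbiguousLookupError(CosiQuantError):
    """Reference-table lookup matched several entries."""

    def __init__(self, message: str, candidates: Sequence[object] = ()):
        super().__init__(message)
        self.candidates = list(candidates)


class InsufficientDataError(CosiQuantError):
    """Too few data points to produce a meaningful estimate."""


class PackingError(CosiQuantError):
    """Simulated spots could not be placed at the requested separation."""


class EmptyResultError(CosiQuantError):
    """A pipeline stage produced no usable output."""


def nm_to_px(value_nm: float, pixel_size_nm: float) -> float:
    """Convert a physical length in nm to pixels.

    Both arguments must be positive; e.g. an 800 nm scale bar at a 160 nm
    pixel size spans 5 pixels.
    """
    if value_nm <= 0 or pixel_size_nm <= 0:
        raise DomainError(
            f"nm_to_px requires positive arguments, got ({value_nm}, {pixel_size_nm})"
        )
    return value_nm / pixel_size_nm


def px_to_nm(value_px: float, pixel_size_nm: float) -> float:
    """Inverse of :func:`nm_to_px`."""
    if value_px <= 0 or pixel_size_nm <= 0:
        raise DomainError(
            f"px_to_nm requires positive arguments, got ({value_px}, {pixel_size_nm})"
        )
    return value_px * pixel_size_nm


@dataclass(frozen=True)
class ImageField:
    """One registered multi-channel acquisition (a single field of view).

    Parameters
    ----------
    channels
        2D non-negative intensity rasters, all with identical shape.  They
        are promoted to float64 on construction; intensities stay in raw
        (arbitrary) fluorescence units.
    channel_roles
        One role per channel, drawn from ``{marker, active_zone, poi}`` for
        synapse samples or ``{calibration}`` for single-antibody fields.
    pixel_size_nm
        Physical pixel size; must be positive.
    field_id
        Identifier used in all tabular outputs.
    sample_kind
        ``synaptosome``, ``culture`` or ``calibration``.
    """

    channels: tuple
    channel_roles: tuple
    pixel_size_nm: float
    field_id: str = "field"
    sample_kind: str = "synaptosome"

    def __post_init__(self):
        chans = tuple(np.asarray(c, dtype=np.float64) for c in self.channels)
        object.__setattr__(self, "channels", chans)
        object.__setattr__(self, "channel_roles", tuple(self.channel_roles))
        if len(chans) == 0:
            raise ConfigurationError("ImageField needs at least one channel")
        if len(chans) != len(self.channel_roles):
            raise ConfigurationError(
                f"{len(chans)} channels but {len(self.channel_roles)} roles"
            )
        shape = chans[0].shape
        if any(c.shape != shape for c in chans) or len(shape) != 2:
            raise FormatError("all channels must be 2D rasters of identical shape")
        if self.pixel_size_nm <= 0:
            raise DomainError("pixel_size_nm must be positive")
        for role in self.channel_roles:
            if role not in ALL_ROLES:
                raise ConfigurationError(f"unknown channel role {role!r}")
        if self.sample_kind not in SAMPLE_KINDS:
            raise ConfigurationError(f"unknown sample_kind {self.sample_kind!r}")
        if self.sample_kind in ("synaptosome", "culture"):
            n_marker = sum(r == MARKER for r in self.channel_roles)
            if n_marker != 1:
                raise ConfigurationError(
                    f"{self.sample_kind} field must have exactly one marker "
                    f"channel, found {n_marker}"
                )

    @property
    def shape(self):
        return self.channels[0].shape

    def channel(self, role: str) -> np.ndarray:
        """Return the raster with the given role."""
        try:
            idx = self.channel_roles.index(role)
        except ValueError:
            raise ConfigurationError(
                f"field {self.field_id!r} has no channel with role {role!r}"
            ) from None
        return self.channels[idx]


@dataclass(frozen=True)
class SpotCandidate:
    """An initial synapse guess: the pixel position of a local maximum of the
    smoothed marker channel, plus its smoothed peak intensity."""

    x_px: int
    y_px: int
    smoothed_peak: float
    field_id: str = "field"
    candidate_id: int = 0
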