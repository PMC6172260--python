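"""Pipeline configuration: one flat, versioned key-value document (JSON)."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .types import ACTIVE_ZONE, MARKER, POI, ConfigurationError, DomainError, nm_to_px

CONFIG_VERSION = 1

#: Per-channel goodness-of-fit acceptance thresholds.  A candidate is kept
#: only when the synaptic-vesicle marker fit reaches R^2 >= 0.85, the
#: active-zone fit >= 0.70 and the protein-of-interest fit >= 0.60.
DEFAULT_R2_THRESHOLDS = {MARKER: 0.85, ACTIVE_ZONE: 0.70, POI: 0.60}


@dataclass(frozen=True)
class PipelineConfig:
    """Parameters governing detection, fitting and filtering.

    Attributes
    ----------
    smoothing_sigma_nm
        Standard deviation of the Gaussian kernel applied to the marker
        channel before maxima search (default 480 nm).
    roi_side_nm
        Side of the square fitting region of interest (default 2200 nm,
        i.e. 2.2 um x 2.2 um).
    r2_thresholds
        Role -> minimum R^2 for a fit to be accepted (inclusive).
    detect_threshold_mode
        ``robust`` (default): threshold = median + k * 1.4826 * MAD of the
        smoothed marker raster with k = ``detect_threshold_value``;
        ``absolute``: threshold = ``detect_threshold_value`` directly.
    detect_threshold_value
        k for robust mode (default 5.0) or the absolute intensity cut.
    maxima_min_separation_nm
        Minimum separation between candidate maxima; dimmer maxima within
        this radius of a brighter one are suppressed (default 480 nm).
    seed
        Seed recorded alongside results for provenance.
    """

    smoothing_sigma_nm: float = 480.0
    roi_side_nm: float = 2200.0
    r2_thresholds: dict = field(
        default_factory=lambda: dict(DEFAULT_R2_THRESHOLDS)
    )
    detect_threshold_mode: str = "robust"
    detect_threshold_value: float = 5.0
    maxima_min_separation_nm: float = 480.0
    seed: int = 0

    def __post_init__(self):
        for name in ("smoothing_sigma_nm", "roi_side_nm", "maxima_min_separation_nm"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")
        if self.detect_threshold_mode not in ("robust", "absolute"):
            raise ConfigurationError(
                f"unknown detect_threshold_mode {self.detect_threshold_mode!r}"
            )
        for role, thr in self.r2_thresholds.items():
            if not 0.0 <= thr <= 1.0:
                raise DomainError(f"r2 threshold for {role!r} outside [0, 1]")

    # -- pixel-space helpers -------------------------------------------------
    def sigma_px(self, pixel_size_nm: float) -> float:
        return nm_to_px(self.smoothing_sigma_nm, pixel_size_nm)

    def roi_half_px(self, pixel_size_nm: float) -> int:
        """Half-width of the (odd-sided) fitting ROI in whole pixels."""
        side = nm_to_px(self.roi_side_nm, pixel_size_nm)
        return max(1, int(round(side)) // 2)

    def separation_px(self, pixel_size_nm: float) -> int:
        return max(1, int(round(nm_to_px(self.maxima_min_separation_nm, pixel_size_nm))))

    # -- (de)serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["config_version"] = CONFIG_VERSION
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        version = d.pop("config_version", CONFIG_VERSION)
        if version != CONFIG_VERSION:
            raise ConfigurationError(f"unsupported config_version {version}")
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
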