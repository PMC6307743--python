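"""Core domain types shared across the snow-detection pipeline.

The pipeline reasons about one midday image per camera site per day.  Each
image carries crowd votes on a five-way label (bad image / no snow / three
snow sub-categories), an optional feature vector extracted from the image,
and an optional pair of satellite fractional-snow-cover readings.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


class SnowLabel(str, enum.Enum):
    """Five-way per-image label used by annotators and the gold standard."""

    BAD_IMAGE = "bad_image"
    NO_SNOW = "no_snow"
    SNOW_TREELESS = "snow_treeless"
    SNOW_ON_TREES = "snow_on_trees"
    SNOW_GROUND_ONLY = "snow_ground_only"

    @property
    def is_snow(self) -> bool:
        return self in SNOW_SUBLABELS

    @property
    def binary(self) -> Optional[bool]:
        """Binary snow projection; None for BAD_IMAGE."""
        if self is SnowLabel.BAD_IMAGE:
            return None
        return self.is_snow


SNOW_SUBLABELS = frozenset(
    {SnowLabel.SNOW_TREELESS, SnowLabel.SNOW_ON_TREES, SnowLabel.SNOW_GROUND_ONLY}
)


class TopLevel(str, enum.Enum):
    """Consensus top-level class: binary projection plus BAD and UNRESOLVED."""

    BAD = "bad"
    NO_SNOW = "no_snow"
    SNOW = "snow"
    UNRESOLVED = "unresolved"


class BinaryOutcome(str, enum.Enum):
    """Binarized satellite observation for one image."""

    SNOW = "snow"
    NO_SNOW = "no_snow"
    MISSING = "missing"


class SiteType(str, enum.Enum):
    """Camera-protocol adherence tiers of the network.

    Type I sites use the standard camera and protocol, Type II only the
    protocol, Type III neither necessarily.
    """

    I = "I"
    II = "II"
    III = "III"


class Canopy(str, enum.Enum):
    NONE = "none"
    OPEN = "open"
    DENSE = "dense"


@dataclass(frozen=True)
class ConsensusResult:
    """Aggregated crowd label for one image.

    ``sub_label`` is only present when ``top_level`` is SNOW and the snow
    votes have a majority sub-category.  ``unanimous`` refers to the binary
    snow/no-snow projection and is defined only when no vote was BAD_IMAGE.
    """

    image_id: str
    top_level: TopLevel
    sub_label: Optional[SnowLabel] = None
    unanimous: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.sub_label is not None and self.top_level is not TopLevel.SNOW:
            raise ValueError("sub_label only meaningful for SNOW consensus")


@dataclass(frozen=True)
class SiteConfig:
    """Static description of one camera site in a synthetic network."""

    site_id: str
    site_type: SiteType = SiteType.I
    winter_severity: float = 0.5
    latitude_proxy: float = 45.0
    canopy: Canopy = Canopy.NONE
    white_object: bool = False
    site_offset_scale: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.winter_severity <= 1.0:
            raise ValueError("winter_severity must be in [0, 1]")
        if self.site_offset_scale < 0:
            raise ValueError("site_offset_scale must be >= 0")


@dataclass(frozen=True)
class TrueState:
    """Ground truth for one image in the synthetic network.

    ``patchiness`` (fraction of ground covered, in (0, 1]) is defined only
    when snow is present.  ``snow_on_trees`` is defined only when snow is
    present at a site with canopy; ``None`` otherwise (treeless scenes).
    ``bad`` marks an unusable image (lens obstruction, camera fault).
    """

    image_id: str
    snow: bool
    patchiness: Optional[float] = None
    snow_on_trees: Optional[bool] = None
    bad: bool = False

    def __post_init__(self) -> None:
        if self.snow:
            if self.patchiness is None or not 0.0 < self.patchiness <= 1.0:
                raise ValueError("snow images need patchiness in (0, 1]")
        else:
            if self.patchiness is not None:
                raise ValueError("patchiness defined only for snow images")
            if self.snow_on_trees is not None:
                raise ValueError("snow_on_trees defined only for snow images")

    @property
    def true_label(self) -> SnowLabel:
        """Five-way label implied by the true state (ignores ``bad``)."""
        if not self.snow:
            return SnowLabel.NO_SNOW
        if self.snow_on_trees is None:
            return SnowLabel.SNOW_TREELESS
        return (
            SnowLabel.SNOW_ON_TREES if self.snow_on_trees else SnowLabel.SNOW_GROUND_ONLY
        )


@dataclass(frozen=True)
class ModisObservation:
    """Paired daily fractional-snow-cover readings for one image.

    ``terra_fraction`` / ``aqua_fraction`` play the roles of the morning and
    afternoon 500 m products; values are percent cover in [0, 100] or None
    when the product reported nothing usable (cloud, fill).
    """

    image_id: str
    terra_fraction: Optional[float] = None
    aqua_fraction: Optional[float] = None


@dataclass
class SimulationConfig:
    """Knobs of the synthetic camera network.

    Defaults are calibrated to the marginal rates of the full-scale
    deployment the pipeline mirrors: ~21% of images with snow, ~6.2% bad
    images, ~56% of images with at least one satellite reading.
    """

    n_sites: int = 133
    years: int = 2
    seed: int = 42
    # crowd model
    annotator_error_base: float = 0.01
    annotator_error_patchy: float = 0.18
    bad_image_prob: float = 0.062
    bad_vote_prob: float = 0.95  # P(vote BAD | image is bad)
    spurious_bad_prob: float = 0.0  # P(vote BAD | image is good)
    # satellite model
    modis_missing_prob: float = 0.44
    modis_miss_base: float = 0.11
    modis_miss_canopy_penalty: float = 0.21
    modis_miss_patchy: float = 0.45
    modis_false_pos_prob: float = 0.029
    # feature model
    feature_dim: int = 16
    class_separation: float = 6.0
    site_offset_scale: float = 1.5
    white_object_shift: float = 0.25  # fraction of class_separation
    # seasonal truth model
    target_snow_prevalence: float = 0.21

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.years < 1:
            raise ValueError("years must be >= 1")
        if self.feature_dim < 2:
            raise ValueError("feature_dim must be >= 2")
        for name in (
            "annotator_error_base",
            "annotator_error_patchy",
            "bad_image_prob",
            "bad_vote_prob",
            "spurious_bad_prob",
            "modis_missing_prob",
            "modis_miss_base",
            "modis_miss_canopy_penalty",
            "modis_miss_patchy",
            "modis_false_pos_prob",
            "target_snow_prevalence",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        if self.class_separation < 0 or self.site_offset_scale < 0:
            raise ValueError("separation and offset scales must be >= 0")
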