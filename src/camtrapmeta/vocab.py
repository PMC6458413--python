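"""Controlled vocabularies: effectiveness metrics, survey-method classes,
and the ordinal author-recommendation scale.

Every comparison in the meta-analysis pairs a camera-trap measurement with a
measurement from one alternative survey method, under one of nine
effectiveness metrics.  Each metric has a known "better" direction: for
species richness, detection rate, detection probability and the number of
individuals detected, higher values mean better performance; for latency to
detection, percentage bias, coefficient of variation, implementation effort
and cost, lower values do.
"""

from __future__ import annotations

import enum
from collections.abc import Iterable

import yaml


class Direction(str, enum.Enum):
    HIGHER_BETTER = "higher_better"
    LOWER_BETTER = "lower_better"


class MetricKind(str, enum.Enum):
    """The nine effectiveness metrics extracted from method-comparison studies."""

    SPECIES_RICHNESS = "species_richness"
    DETECTION_RATE = "detection_rate"
    LATENCY_TO_DETECTION = "latency_to_detection"
    DETECTION_PROBABILITY = "detection_probability"
    INDIVIDUALS_DETECTED = "individuals_detected"
    ACCURACY_PCT_BIAS = "accuracy_pct_bias"
    PRECISION_CV = "precision_cv"
    IMPLEMENTATION_EFFORT = "implementation_effort"
    COST = "cost"

    @property
    def direction(self) -> Direction:
        if self in _LOWER_BETTER:
            return Direction.LOWER_BETTER
        return Direction.HIGHER_BETTER


_LOWER_BETTER = frozenset(
    {
        MetricKind.LATENCY_TO_DETECTION,
        MetricKind.ACCURACY_PCT_BIAS,
        MetricKind.PRECISION_CV,
        MetricKind.IMPLEMENTATION_EFFORT,
        MetricKind.COST,
    }
)


#: Ordered levels of the author-recommendation response.  Larger latent values
#: are more camera-favourable: other_method < ambiguous < camera_trap.
RECOMMENDATION_LEVELS: tuple[str, ...] = ("other_method", "ambiguous", "camera_trap")

CAMERA_TYPES: tuple[str, ...] = ("film", "digital")
ATTRACTANT_LEVELS: tuple[str, ...] = ("used", "not_used")
HABITAT_LEVELS: tuple[str, ...] = ("closed", "open")


#: Default 22 alternative survey-method classes.  The classes named in the
#: primary literature are included verbatim; the remainder are common field
#: methods, and the vocabulary is extensible via config for datasets that use
#: a different classing.
DEFAULT_METHOD_CLASSES: tuple[str, ...] = (
    "live_trap",
    "hair_trap",
    "detector_dog",
    "acoustic_recording",
    "edna",
    "radio_tracking",
    "local_ecological_knowledge",
    "line_transect",
    "plot_survey",
    "sign_survey",
    "spotlighting",
    "track_plate",
    "scat_survey",
    "point_count",
    "aerial_survey",
    "drone_survey",
    "direct_observation",
    "hunter_survey",
    "pitfall_trap",
    "mist_net",
    "dung_count",
    "burrow_count",
)


class MethodVocabulary:
    """Controlled vocabulary of comparison survey-method classes.

    Unknown method names in input data are rejected unless the vocabulary is
    extended, either programmatically or from a YAML config with an
    ``extra_methods`` list.
    """

    def __init__(self, names: Iterable[str] = DEFAULT_METHOD_CLASSES):
        names = tuple(names)
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if list(names).count(n) > 1})
            raise ValueError(f"duplicate method class names: {dupes}")
        self.names = names
        self._set = frozenset(names)

    def __contains__(self, name: str) -> bool:
        return name in self._set

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def extended(self, extra: Iterable[str]) -> "MethodVocabulary":
        """Return a new vocabulary with ``extra`` classes appended."""
        extra = [e for e in extra if e not in self._set]
        return MethodVocabulary(self.names + tuple(extra))

    @classmethod
    def from_yaml(cls, path) -> "MethodVocabulary":
        """Load a vocabulary extension: YAML mapping with ``extra_methods``
        (appended to the defaults) or ``methods`` (full replacement)."""
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if "methods" in doc:
            return cls(tuple(doc["methods"]))
        return cls().extended(doc.get("extra_methods", []))


DEFAULT_VOCABULARY = MethodVocabulary()
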