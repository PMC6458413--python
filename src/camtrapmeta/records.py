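"""Record types for the study and comparison tables, with validation.

A :class:`StudyRecord` is one primary study: covariates describing the
equipment (film vs digital camera, attractant use), the setting (habitat
openness, absolute latitude), the smallest-bodied focal species, and the
study authors' overall ordinal recommendation.  A :class:`ComparisonRecord`
is one paired quantitative measurement from such a study: the same metric
measured with camera traps and with one alternative method.
"""

from __future__ import annotations

from dataclasses import dataclass

from .vocab import (
    ATTRACTANT_LEVELS,
    CAMERA_TYPES,
    DEFAULT_VOCABULARY,
    HABITAT_LEVELS,
    MethodVocabulary,
    MetricKind,
    RECOMMENDATION_LEVELS,
)


class SchemaError(ValueError):
    """A required column is missing or the file shape is wrong."""


class ValidationError(ValueError):
    """A field value violates the controlled vocabulary or a range constraint."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class IntegrityError(ValueError):
    """A foreign-key reference (comparison -> study) cannot be resolved."""


@dataclass(frozen=True)
class StudyRecord:
    study_id: str
    camera_type: str          # film | digital
    attractant: str           # used | not_used
    habitat: str              # closed | open
    abs_latitude: float       # degrees, 0..90
    min_weight_g: float       # body mass of smallest focal species, grams, > 0
    recommendation: str       # other_method < ambiguous < camera_trap

    def validate(self, row: int | None = None) -> "StudyRecord":
        if self.camera_type not in CAMERA_TYPES:
            raise ValidationError(
                f"camera_type {self.camera_type!r} not in {CAMERA_TYPES}", row)
        if self.attractant not in ATTRACTANT_LEVELS:
            raise ValidationError(
                f"attractant {self.attractant!r} not in {ATTRACTANT_LEVELS}", row)
        if self.habitat not in HABITAT_LEVELS:
            raise ValidationError(
                f"habitat {self.habitat!r} not in {HABITAT_LEVELS}", row)
        if not 0.0 <= float(self.abs_latitude) <= 90.0:
            raise ValidationError(
                f"abs_latitude {self.abs_latitude} outside [0, 90]", row)
        if not float(self.min_weight_g) > 0.0:
            raise ValidationError(
                f"min_weight_g {self.min_weight_g} must be > 0", row)
        if self.recommendation not in RECOMMENDATION_LEVELS:
            raise ValidationError(
                f"recommendation {self.recommendation!r} not in {RECOMMENDATION_LEVELS}",
                row)
        return self


@dataclass(frozen=True)
class ComparisonRecord:
    study_id: str
    metric: MetricKind
    method: str               # a MethodVocabulary class name
    value_camera: float       # nonnegative, metric units
    value_other: float        # nonnegative, same units as value_camera

    def validate(
        self,
        row: int | None = None,
        vocabulary: MethodVocabulary = DEFAULT_VOCABULARY,
        study_ids: set[str] | None = None,
    ) -> "ComparisonRecord":
        if not isinstance(self.metric, MetricKind):
            raise ValidationError(f"unknown metric {self.metric!r}", row)
        if self.method not in vocabulary:
            raise ValidationError(f"unknown method class {self.method!r}", row)
        if not float(self.value_camera) >= 0.0:
            raise ValidationError(
                f"value_camera {self.value_camera} must be nonnegative", row)
        if not float(self.value_other) >= 0.0:
            raise ValidationError(
                f"value_other {self.value_other} must be nonnegative", row)
        if study_ids is not None and self.study_id not in study_ids:
            raise IntegrityError(
                f"row {row}: study_id {self.study_id!r} not present in the study table"
                if row is not None
                else f"study_id {self.study_id!r} not present in the study table")
        return self
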