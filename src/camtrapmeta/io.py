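"""CSV readers/writers for the study and comparison tables.

Dialect: UTF-8, comma-separated, "." decimal, header row required.  Lines
beginning with ``#`` are metadata comments (every file the pipeline writes
carries a small metadata header) and are ignored on read.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

import pandas as pd

from .records import (
    ComparisonRecord,
    IntegrityError,
    SchemaError,
    StudyRecord,
    ValidationError,
)
from .vocab import DEFAULT_VOCABULARY, MethodVocabulary, MetricKind

STUDY_COLUMNS = (
    "study_id", "camera_type", "attractant", "habitat",
    "abs_latitude", "min_weight_g", "recommendation",
)
COMPARISON_COLUMNS = ("study_id", "metric", "method", "value_camera", "value_other")


def _read_csv(path, required: Sequence[str], kind: str) -> pd.DataFrame:
    frame = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{kind} table {path}: missing column(s) {missing}")
    return frame


def read_studies(path) -> list[StudyRecord]:
    """Read and validate the study table.  Row order is preserved;
    duplicate ``study_id`` values are rejected."""
    frame = _read_csv(path, STUDY_COLUMNS, "study")
    records: list[StudyRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        sid = str(row.study_id)
        if sid in seen:
            raise ValidationError(f"duplicate study_id {sid!r}", row=i)
        seen.add(sid)
        try:
            lat = float(row.abs_latitude)
            wt = float(row.min_weight_g)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-numeric covariate: {exc}", row=i) from exc
        rec = StudyRecord(
            study_id=sid,
            camera_type=str(row.camera_type),
            attractant=str(row.attractant),
            habitat=str(row.habitat),
            abs_latitude=lat,
            min_weight_g=wt,
            recommendation=str(row.recommendation),
        )
        records.append(rec.validate(row=i))
    return records


def read_comparisons(
    path,
    studies: Iterable[StudyRecord],
    vocabulary: MethodVocabulary = DEFAULT_VOCABULARY,
) -> list[ComparisonRecord]:
    """Read and validate the comparison table, enforcing referential
    integrity against ``studies``."""
    frame = _read_csv(path, COMPARISON_COLUMNS, "comparison")
    study_ids = {s.study_id for s in studies}
    records: list[ComparisonRecord] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        try:
            metric = MetricKind(str(row.metric))
        except ValueError as exc:
            raise ValidationError(f"unknown metric {row.metric!r}", row=i) from exc
        try:
            vc = float(row.value_camera)
            vo = float(row.value_other)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-numeric value: {exc}", row=i) from exc
        rec = ComparisonRecord(
            study_id=str(row.study_id),
            metric=metric,
            method=str(row.method),
            value_camera=vc,
            value_other=vo,
        )
        records.append(rec.validate(row=i, vocabulary=vocabulary, study_ids=study_ids))
    return records


def studies_to_frame(records: Iterable[StudyRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "study_id": r.study_id,
                "camera_type": r.camera_type,
                "attractant": r.attractant,
                "habitat": r.habitat,
                "abs_latitude": r.abs_latitude,
                "min_weight_g": r.min_weight_g,
                "recommendation": r.recommendation,
            }
            for r in records
        ],
        columns=list(STUDY_COLUMNS),
    )


def comparisons_to_frame(records: Iterable[ComparisonRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "study_id": r.study_id,
                "metric": r.metric.value,
                "method": r.method,
                "value_camera": r.value_camera,
                "value_other": r.value_other,
            }
            for r in records
        ],
        columns=list(COMPARISON_COLUMNS),
    )


def write_table(records, path, metadata: dict | None = None) -> None:
    """Write a record collection (or a DataFrame) to CSV.

    Floats are written with 17 significant digits so that read(write(x))
    round-trips losslessly.  ``metadata`` key/value pairs are emitted as
    ``# key=value`` comment lines before the header.
    """
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        records = list(records)
        if records and isinstance(records[0], StudyRecord):
            frame = studies_to_frame(records)
        elif records and isinstance(records[0], ComparisonRecord):
            frame = comparisons_to_frame(records)
        elif not records:
            raise ValueError(
                "cannot infer columns for an empty record list; "
                "pass an empty DataFrame with the desired columns instead")
        else:
            frame = pd.DataFrame([vars(r) if not hasattr(r, "__dataclass_fields__")
                                  else {f: getattr(r, f) for f in r.__dataclass_fields__}
                                  for r in records])
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}={value}\n")
        frame.to_csv(fh, index=False, float_format="%.17g")


def write_studies(records: Iterable[StudyRecord], path, metadata=None) -> None:
    write_table(studies_to_frame(records), path, metadata)


def write_comparisons(records: Iterable[ComparisonRecord], path, metadata=None) -> None:
    write_table(comparisons_to_frame(records), path, metadata)


__all__ = [
    "read_studies", "read_comparisons", "write_table", "write_studies",
    "write_comparisons", "studies_to_frame", "comparisons_to_frame",
    "SchemaError", "ValidationError", "IntegrityError",
]
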