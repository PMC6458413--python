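"""Direction-aware log response ratio effect sizes.

The effect size for one paired comparison is the log response ratio
ln(camera / other) for metrics where higher values mean better performance,
and ln(other / camera) for metrics where lower values do (latency to
detection, percentage bias, coefficient of variation, implementation effort,
cost).  With this orientation a positive effect size always means camera
traps outperformed the method they were compared with.  Pairs with a zero on
either side are excluded (a log ratio is undefined there) and counted; no
continuity correction is applied.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable
from dataclasses import dataclass

import pandas as pd

from .records import ComparisonRecord, StudyRecord
from .vocab import Direction, MetricKind

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EffectSize:
    """One oriented log response ratio (natural-log units)."""

    study_id: str
    metric: MetricKind
    method: str
    value: float


@dataclass(frozen=True)
class ExcludedComparison:
    """A comparison that produced no effect size, with the reason."""

    study_id: str
    metric: MetricKind
    method: str
    reason: str


def log_response_ratio(record: ComparisonRecord) -> EffectSize | ExcludedComparison:
    """Compute the direction-aware log response ratio for one comparison.

    Returns an :class:`ExcludedComparison` if either value is zero.
    Negative inputs raise (they should have been rejected by validation).
    """
    vc, vo = float(record.value_camera), float(record.value_other)
    if vc < 0 or vo < 0:
        raise ValueError(
            f"negative measurement in {record.study_id}: ({vc}, {vo})")
    if vc == 0.0 or vo == 0.0:
        return ExcludedComparison(
            record.study_id, record.metric, record.method,
            reason="zero value: log ratio undefined")
    if record.metric.direction is Direction.HIGHER_BETTER:
        value = math.log(vc / vo)
    else:
        value = math.log(vo / vc)
    return EffectSize(record.study_id, record.metric, record.method, value)


def percent_effectiveness(es_value: float) -> float:
    """Convert a log response ratio to a percent difference in effectiveness,
    100 * (exp(value) - 1).  A value of 0.33 corresponds to ~39%."""
    return 100.0 * math.expm1(es_value)


def compute_effects(
    comparisons: Iterable[ComparisonRecord],
) -> tuple[list[EffectSize], list[ExcludedComparison]]:
    """Compute effect sizes for all comparisons, separating exclusions."""
    effects: list[EffectSize] = []
    excluded: list[ExcludedComparison] = []
    for rec in comparisons:
        out = log_response_ratio(rec)
        if isinstance(out, EffectSize):
            effects.append(out)
        else:
            excluded.append(out)
    return effects, excluded


def effect_table(
    comparisons: Iterable[ComparisonRecord],
    studies: Iterable[StudyRecord],
) -> pd.DataFrame:
    """Effect sizes joined with study-level covariates, one row per
    non-excluded comparison.  The exclusion count is reported in the log."""
    effects, excluded = compute_effects(comparisons)
    logger.info(
        "computed %d effect sizes; excluded %d comparison(s) with zero values",
        len(effects), len(excluded))
    eff = pd.DataFrame(
        [
            {
                "study_id": e.study_id,
                "metric": e.metric.value,
                "method": e.method,
                "effect_size": e.value,
            }
            for e in effects
        ],
        columns=["study_id", "metric", "method", "effect_size"],
    )
    cov = pd.DataFrame(
        [
            {
                "study_id": s.study_id,
                "camera_type": s.camera_type,
                "attractant": s.attractant,
                "habitat": s.habitat,
                "abs_latitude": s.abs_latitude,
                "min_weight_g": s.min_weight_g,
            }
            for s in studies
        ],
        columns=["study_id", "camera_type", "attractant", "habitat",
                 "abs_latitude", "min_weight_g"],
    )
    if eff.empty:
        return eff.assign(**{c: pd.Series(dtype=cov[c].dtype)
                             for c in cov.columns if c != "study_id"})
    return eff.merge(cov, on="study_id", how="left", validate="many_to_one")


__all__ = [
    "EffectSize", "ExcludedComparison", "log_response_ratio",
    "percent_effectiveness", "compute_effects", "effect_table",
]
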