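"""Study-stratified bootstrap of median effect sizes, with quantile
confidence intervals and post hoc pairwise Wald tests.

Multiple comparisons extracted from the same primary study are not
independent, so the study is treated as the exchangeable unit.  In each
bootstrap replicate for a group (a metric, a survey method, or a factor
level) the default *cluster* scheme (a) resamples the group's distinct
studies with replacement and (b) draws a single comparison uniformly at
random from each sampled study, then records the median of the drawn
values.  A study contributing one comparison therefore has the same
per-replicate influence as a study contributing one hundred.

An alternative *fixed-studies* scheme keeps the study set fixed and only
randomizes the within-study draw; it is available via ``scheme``.

Groups with at most ``min_comparisons`` effect sizes (strictly more are
required) are reported as skipped.  Significance of a group is judged by
whether its 95% quantile interval excludes zero; pairs of groups are
compared with Wald tests using the bootstrap standard deviation as the
standard error.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

SCHEMES = ("cluster", "fixed_studies")


@dataclass
class BootstrapResult:
    group: str
    n_comparisons: int
    n_studies: int
    skipped: bool = False
    point_estimate: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    se: float = float("nan")
    n_boot: int = 0
    significant: bool = False
    replicates: np.ndarray | None = field(default=None, repr=False)


@dataclass(frozen=True)
class WaldComparison:
    group_a: str
    group_b: str
    z: float
    p: float


def child_rng(seed: int, label: str) -> np.random.Generator:
    """Per-group generator derived deterministically from the root seed and
    the group label, so adding or reordering groups never perturbs others."""
    digest = hashlib.sha256(label.encode("utf-8")).digest()
    return np.random.default_rng(
        [int(seed), int.from_bytes(digest[:8], "little")])


def replicate_medians(
    values: np.ndarray,
    study_ids: np.ndarray,
    n_boot: int,
    rng: np.random.Generator,
    scheme: str = "cluster",
) -> np.ndarray:
    """Bootstrap replicate medians for one group (vectorized).

    Each replicate draws one value per (re)sampled study and takes the
    median; ties over even-sized draws use the midpoint convention of
    ``numpy.median``.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown bootstrap scheme {scheme!r}; use one of {SCHEMES}")
    values = np.asarray(values, dtype=float)
    codes, _ = pd.factorize(np.asarray(study_ids), sort=True)
    order = np.argsort(codes, kind="stable")
    sorted_vals = values[order]
    sorted_codes = codes[order]
    counts = np.bincount(sorted_codes)
    offsets = np.concatenate([[0], np.cumsum(counts)[:-1]])
    n_studies = len(counts)

    if scheme == "cluster":
        study_idx = rng.integers(0, n_studies, size=(n_boot, n_studies))
    else:
        study_idx = np.broadcast_to(
            np.arange(n_studies), (n_boot, n_studies))
    # one uniform comparison from each sampled study
    u = rng.random((n_boot, n_studies))
    pick = np.minimum((u * counts[study_idx]).astype(np.int64),
                      counts[study_idx] - 1)
    drawn = sorted_vals[offsets[study_idx] + pick]
    return np.median(drawn, axis=1)


def _summarize(group: str, reps: np.ndarray, n_comp: int, n_stud: int,
               keep_replicates: bool) -> BootstrapResult:
    ci_low, ci_high = np.quantile(reps, [0.025, 0.975])
    point = float(np.median(reps))
    se = float(np.std(reps, ddof=1))
    return BootstrapResult(
        group=group,
        n_comparisons=n_comp,
        n_studies=n_stud,
        point_estimate=point,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        se=se,
        n_boot=len(reps),
        significant=bool(ci_low > 0.0 or ci_high < 0.0),
        replicates=reps if keep_replicates else None,
    )


def stratified_bootstrap(
    effects: pd.DataFrame,
    group_col: str,
    value_col: str = "effect_size",
    study_col: str = "study_id",
    n_boot: int = 10_000,
    min_comparisons: int = 15,
    seed: int = 0,
    scheme: str = "cluster",
    keep_replicates: bool = True,
) -> list[BootstrapResult]:
    """Run the stratified bootstrap separately for every group level.

    Groups with ``n_comparisons <= min_comparisons`` are returned with
    ``skipped=True`` (the threshold is strict: exactly 15 comparisons is
    skipped under the default).  Results are ordered by group label.
    """
    if effects.empty:
        warnings.warn("no effect sizes: empty bootstrap result", stacklevel=2)
        return []
    results: list[BootstrapResult] = []
    for label, sub in sorted(effects.groupby(group_col, observed=True),
                             key=lambda kv: str(kv[0])):
        label = str(label)
        n_comp = len(sub)
        n_stud = sub[study_col].nunique()
        if n_comp <= min_comparisons:
            logger.info("group %s skipped (%d comparisons <= %d)",
                        label, n_comp, min_comparisons)
            results.append(BootstrapResult(
                group=label, n_comparisons=n_comp, n_studies=n_stud,
                skipped=True))
            continue
        rng = child_rng(seed, f"{group_col}={label}")
        reps = replicate_medians(
            sub[value_col].to_numpy(), sub[study_col].to_numpy(),
            n_boot, rng, scheme=scheme)
        results.append(_summarize(label, reps, n_comp, n_stud, keep_replicates))
    return results


def overall_bootstrap(effects: pd.DataFrame, **kwargs) -> BootstrapResult:
    """Bootstrap over all effect sizes pooled as a single group."""
    frame = effects.assign(_overall="overall")
    (result,) = stratified_bootstrap(frame, "_overall", **kwargs)
    result.group = "overall"
    return result


def subgroup_bootstrap(
    effects: pd.DataFrame,
    factor: str,
    **kwargs,
) -> list[BootstrapResult]:
    """Bootstrap per level of a study-level factor (camera_type,
    attractant, or habitat), exactly as for metrics and methods."""
    if factor not in effects.columns:
        raise KeyError(f"factor column {factor!r} not in effect table")
    return stratified_bootstrap(effects, factor, **kwargs)


def wald_test(a: BootstrapResult, b: BootstrapResult) -> WaldComparison:
    """Two-sided Wald test of the difference between two bootstrapped
    medians, using the bootstrap SDs as standard errors."""
    pooled = float(np.hypot(a.se, b.se))
    if not pooled > 0.0:
        raise ValueError(
            f"zero pooled SE for ({a.group}, {b.group}): degenerate bootstrap "
            "distributions cannot be compared")
    z = (a.point_estimate - b.point_estimate) / pooled
    p = 2.0 * stats.norm.sf(abs(z))
    return WaldComparison(a.group, b.group, float(z), float(p))


def pairwise_wald(results: list[BootstrapResult]) -> list[WaldComparison]:
    """All pairwise Wald tests among non-skipped groups (plain alpha,
    no multiplicity correction)."""
    live = [r for r in results if not r.skipped]
    out = []
    for i in range(len(live)):
        for j in range(i + 1, len(live)):
            out.append(wald_test(live[i], live[j]))
    return out


def results_to_frame(results: list[BootstrapResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": r.group,
                "point_estimate": r.point_estimate,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "se": r.se,
                "n_comparisons": r.n_comparisons,
                "n_studies": r.n_studies,
                "n_boot": r.n_boot,
                "significant": r.significant,
                "skipped": r.skipped,
            }
            for r in results
        ],
        columns=["group", "point_estimate", "ci_low", "ci_high", "se",
                 "n_comparisons", "n_studies", "n_boot", "significant",
                 "skipped"],
    )


__all__ = [
    "BootstrapResult", "WaldComparison", "stratified_bootstrap",
    "overall_bootstrap", "subgroup_bootstrap", "wald_test", "pairwise_wald",
    "replicate_medians", "results_to_frame", "child_rng",
]
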