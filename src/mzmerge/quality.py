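"""Replicate-based reproducibility metrics and quality filters.

Sample quality is the mean pairwise Pearson correlation among a biological
sample's analytical replicates, computed over features with no missing value
in any profile of the table.  Feature quality is the percent intensity
difference (PID) between duplicate injections, or the coefficient of
variation (CV) when each sample has three or more replicates:

* ``PID(a, b) = 100 * |a - b| / mean(a, b)``, bounded by [0, 200];
* ``CV(x)    = 100 * sd(x) / mean(x)`` with the n-1 standard deviation.

Both are summarised per feature over biological samples with a six-number
summary (min, Q1, median, mean, Q3, max); quartiles use linear interpolation
between order statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .errors import ComputationError, ConfigurationError
from .feature_table import FeatureTable, ReplicateDesign

__all__ = [
    "pid",
    "cv",
    "SampleQuality",
    "FeatureQuality",
    "evaluate_samples",
    "evaluate_features",
    "filter_samples",
    "filter_features",
    "write_sample_quality",
    "write_feature_quality",
]

logger = logging.getLogger(__name__)


def pid(a: float, b: float) -> float:
    """Percent intensity difference between two replicate intensities.

    Returns ``NaN`` (metric undefined) when both intensities are zero.
    """
    if a < 0 or b < 0:
        raise ValueError("intensities must be nonnegative")
    m = (a + b) / 2.0
    if m == 0:
        return math.nan
    return 100.0 * abs(a - b) / m


def cv(values) -> float:
    """Percent coefficient of variation (sample sd / mean) of >= 2 values.

    Returns ``NaN`` when the mean is zero.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError(f"cv requires >= 2 values, got {x.size}")
    m = x.mean()
    if m == 0:
        return math.nan
    return 100.0 * x.std(ddof=1) / m


@dataclass
class SampleQuality:
    sample_id: str
    n_replicates: int
    mean_pairwise_correlation: float | None
    n_complete_features: int
    n_undefined_pairs: int = 0
    reason: str | None = None


@dataclass
class FeatureQuality:
    """Per-feature reproducibility summary across biological samples."""

    index: int
    metric_kind: str  # "PID" or "CV"
    per_sample: dict[str, float]
    summary: tuple[float, float, float, float, float, float] | None

    @property
    def median(self) -> float | None:
        return self.summary[2] if self.summary is not None else None


def _six_number(values: np.ndarray) -> tuple[float, ...]:
    q = np.quantile(values, [0.0, 0.25, 0.5, 0.75, 1.0])  # linear interpolation
    return (float(q[0]), float(q[1]), float(q[2]),
            float(values.mean()), float(q[3]), float(q[4]))


def _replicate_columns(
    table: FeatureTable, design: ReplicateDesign
) -> dict[str, list[int]]:
    design.validate_against(table)
    col = {pid: j for j, pid in enumerate(table.profile_ids)}
    return {
        sid: [col[p] for p in design.replicates_of(sid)]
        for sid in design.samples()
    }


def evaluate_features(
    table: FeatureTable,
    design: ReplicateDesign,
    *,
    allow_mixed_replicates: bool = False,
) -> list[FeatureQuality]:
    """PID (duplicates) or CV (>= 3 replicates) per feature per sample.

    A sample contributes to a feature only if every one of its replicate
    intensities is observed.  With a uniform replicate count ``r`` the metric
    is PID iff ``r == 2``, CV otherwise.  ``allow_mixed_replicates`` relaxes
    the uniform-design requirement: PID is used for 2-replicate samples and
    CV for larger ones, feature by feature.
    """
    cols = _replicate_columns(table, design)
    counts = {s: len(c) for s, c in cols.items()}
    small = sorted(s for s, n in counts.items() if n < 2)
    if small:
        raise ConfigurationError(
            f"samples with fewer than 2 replicates: {small}"
        )
    distinct = set(counts.values())
    if len(distinct) > 1 and not allow_mixed_replicates:
        offenders = {s: n for s, n in sorted(counts.items())}
        raise ConfigurationError(
            f"replicate count varies across samples: {offenders}; "
            "pass allow_mixed_replicates=True to evaluate anyway"
        )
    uniform_r = distinct.pop() if len(distinct) == 1 else None
    kind = "PID" if uniform_r == 2 else "CV"

    obs = table.observed()
    out: list[FeatureQuality] = []
    for i in range(table.n_features):
        per_sample: dict[str, float] = {}
        for sid, cc in cols.items():
            if not obs[i, cc].all():
                continue  # sample skipped: missing replicate intensity
            vals = table.intensities[i, cc]
            v = pid(vals[0], vals[1]) if len(cc) == 2 else cv(vals)
            if not math.isnan(v):
                per_sample[sid] = v
        summary = (
            _six_number(np.array(list(per_sample.values())))
            if per_sample else None
        )
        out.append(FeatureQuality(i, kind, per_sample, summary))
    return out


def evaluate_samples(
    table: FeatureTable,
    design: ReplicateDesign,
    *,
    log2: bool = False,
    min_complete_features: int = 3,
) -> list[SampleQuality]:
    """Mean pairwise Pearson r among each sample's replicates.

    Only features observed in *every* profile of the table enter the
    correlation.  Replicate pairs with a zero-variance vector have undefined
    r; they are excluded from the mean and counted.
    """
    cols = _replicate_columns(table, design)
    complete = table.complete_rows()
    n_complete = len(complete)
    out: list[SampleQuality] = []
    for sid, cc in cols.items():
        if len(cc) < 2:
            out.append(SampleQuality(sid, len(cc), None, n_complete,
                                     reason="fewer than 2 replicates"))
            continue
        if n_complete < min_complete_features:
            out.append(SampleQuality(
                sid, len(cc), None, n_complete,
                reason=f"only {n_complete} complete features "
                       f"(need >= {min_complete_features})"))
            continue
        mat = table.intensities[np.ix_(complete, cc)]
        if log2:
            mat = np.log2(mat)
        rs, undefined = [], 0
        for a, b in combinations(range(len(cc)), 2):
            x, y = mat[:, a], mat[:, b]
            if x.std() == 0 or y.std() == 0:
                undefined += 1
                continue
            rs.append(float(np.corrcoef(x, y)[0, 1]))
        if rs:
            out.append(SampleQuality(sid, len(cc), float(np.mean(rs)),
                                     n_complete, n_undefined_pairs=undefined))
        else:
            out.append(SampleQuality(sid, len(cc), None, n_complete,
                                     n_undefined_pairs=undefined,
                                     reason="no replicate pair with defined r"))
    return out


def filter_samples(
    table: FeatureTable,
    design: ReplicateDesign,
    qualities: list[SampleQuality],
    samp_filt_thresh: float | None,
) -> tuple[FeatureTable, ReplicateDesign]:
    """Drop every profile of biological samples whose mean r is below threshold.

    ``samp_filt_thresh=None`` disables the filter.  Samples whose quality is
    unavailable are retained (and logged).
    """
    if samp_filt_thresh is None:
        return table, design
    dropped = []
    for q in qualities:
        if q.mean_pairwise_correlation is None:
            logger.warning("sample %s: quality unavailable (%s); retained",
                           q.sample_id, q.reason)
        elif q.mean_pairwise_correlation < samp_filt_thresh:
            dropped.append(q.sample_id)
    if not dropped:
        return table, design
    if len(dropped) == len({q.sample_id for q in qualities}):
        raise ComputationError(
            f"sample filter at {samp_filt_thresh} removed every sample"
        )
    logger.info("sample filter %.3g dropped: %s", samp_filt_thresh, dropped)
    drop_profiles = [p for p, s in design.assignments.items() if s in dropped]
    return (table.drop_profiles(drop_profiles), design.drop_samples(dropped))


def filter_features(
    table: FeatureTable,
    qualities: list[FeatureQuality],
    feat_filt_thresh: float | None,
) -> FeatureTable:
    """Retain features whose median metric is strictly below the threshold.

    Features with no evaluable sample (median unavailable) are dropped when
    the filter is enabled.  ``None`` disables the filter.
    """
    if feat_filt_thresh is None:
        return table
    if len(qualities) != table.n_features:
        raise ConfigurationError(
            "feature qualities were not computed on this table"
        )
    keep = [q.index for q in qualities
            if q.median is not None and q.median < feat_filt_thresh]
    if not keep:
        logger.warning("feature filter at %.3g retained no feature",
                       feat_filt_thresh)
    return table.take(keep)


def write_sample_quality(qualities, path, *, delimiter="\t") -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(delimiter.join(
            ["sample_id", "n_replicates", "mean_r",
             "n_complete_features", "n_undefined_pairs", "note"]) + "\n")
        for q in qualities:
            r = "" if q.mean_pairwise_correlation is None \
                else f"{q.mean_pairwise_correlation:.6f}"
            fh.write(delimiter.join(
                [q.sample_id, str(q.n_replicates), r,
                 str(q.n_complete_features), str(q.n_undefined_pairs),
                 q.reason or ""]) + "\n")


def write_feature_quality(table, qualities, path, *, delimiter="\t") -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(delimiter.join(
            ["mz", "time", "metric_kind",
             "min", "q1", "median", "mean", "q3", "max"]) + "\n")
        for q in qualities:
            row = [f"{table.mz[q.index]:.5f}", f"{table.rt[q.index]:.3f}",
                   q.metric_kind]
            row += ([f"{v:.4f}" for v in q.summary] if q.summary is not None
                    else [""] * 6)
            fh.write(delimiter.join(row) + "\n")
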