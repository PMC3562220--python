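"""Merge feature tables extracted at different parameter settings.

The merge is a four-step reduction of the union of two (or more) feature
tables that share the same profile columns:

1. concatenate the tables into one feature list;
2. group features by a ppm m/z tolerance (sorted single-linkage chaining:
   after sorting by m/z, a new group starts whenever the ppm gap to the
   previous feature — referenced to the lower m/z — exceeds the tolerance);
3. sub-group each m/z group by a retention-time tolerance in seconds, with
   the same chaining rule;
4. within each multi-member sub-group, report a paired t-test on intensities
   and keep the member with the smallest median replicate metric (PID for
   duplicate designs, CV otherwise) as the representative.

Singleton sub-groups pass through unchanged.  When ``t_test_alpha`` is set,
a two-member sub-group whose paired t-test p-value is below alpha is treated
as two genuinely distinct features and both members are kept.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ConfigurationError, ValidationError
from .feature_table import FeatureTable, ReplicateDesign
from .quality import FeatureQuality, evaluate_features

__all__ = [
    "MergeConfig",
    "MergeReport",
    "CollapseRecord",
    "group_by_mz",
    "subgroup_by_rt",
    "paired_t",
    "select_representative",
    "merge_results",
]

logger = logging.getLogger(__name__)


@dataclass
class MergeConfig:
    mz_tolerance_ppm: float = 5.0
    rt_tolerance_seconds: float = 30.0
    t_test_alpha: float | None = None
    tie_break: str = "intensity"  # "intensity" or "first"

    def __post_init__(self) -> None:
        if self.mz_tolerance_ppm <= 0 or self.rt_tolerance_seconds <= 0:
            raise ConfigurationError("merge tolerances must be positive")
        if self.t_test_alpha is not None and not 0 < self.t_test_alpha < 1:
            raise ConfigurationError("t_test_alpha must be in (0, 1)")
        if self.tie_break not in ("intensity", "first"):
            raise ConfigurationError(f"unknown tie_break {self.tie_break!r}")


@dataclass
class CollapseRecord:
    """One multi-member sub-group and the choice made for it."""

    members: list[tuple[int, int]]            # (table index, row index)
    representative: tuple[int, int]
    member_medians: list[float | None]
    t_statistic: float | None = None
    p_value: float | None = None
    kept_distinct: bool = False


@dataclass
class MergeReport:
    n_input_features: list[int]
    n_groups: int = 0
    n_subgroups: int = 0
    n_unique_passthrough: int = 0
    n_redundant_collapsed: int = 0
    n_kept_distinct_by_t_test: int = 0
    collapses: list[CollapseRecord] = field(default_factory=list)

    @property
    def n_output(self) -> int:
        return (self.n_unique_passthrough + self.n_redundant_collapsed
                + self.n_kept_distinct_by_t_test)


def group_by_mz(mz_values, tol_ppm: float) -> list[list[int]]:
    """Single-linkage grouping of indices by ppm gaps in sorted m/z order.

    The gap between consecutive sorted values is referenced to the lower of
    the two m/z; this equals the transitive closure of the pairwise relation
    ``|mz_i - mz_j| / min(mz_i, mz_j) * 1e6 <= tol_ppm``.
    """
    mz = np.asarray(mz_values, dtype=float)
    if mz.size == 0:
        return []
    order = np.argsort(mz, kind="stable")
    groups: list[list[int]] = [[int(order[0])]]
    for prev, cur in zip(order[:-1], order[1:]):
        gap_ppm = (mz[cur] - mz[prev]) / mz[prev] * 1e6
        if gap_ppm > tol_ppm:
            groups.append([])
        groups[-1].append(int(cur))
    return groups


def subgroup_by_rt(rt_values, members: list[int], tol_seconds: float) -> list[list[int]]:
    """Chain ``members`` (indices into rt_values) by RT gaps <= tol_seconds."""
    if not members:
        return []
    rt = np.asarray(rt_values, dtype=float)
    ordered = sorted(members, key=lambda i: (rt[i], i))
    subs: list[list[int]] = [[ordered[0]]]
    for prev, cur in zip(ordered[:-1], ordered[1:]):
        if rt[cur] - rt[prev] > tol_seconds:
            subs.append([])
        subs[-1].append(cur)
    return subs


def paired_t(x, y) -> tuple[float, float]:
    """Two-sided paired t-test over profiles observed in both vectors.

    Returns ``(nan, nan)`` with fewer than two complete pairs, ``(0, 1)``
    when all differences are zero, and a signed-infinity sentinel with p=0
    for nonzero constant differences (zero variance).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    d = x[ok] - y[ok]
    n = d.size
    if n < 2:
        return (math.nan, math.nan)
    if np.all(d == 0):
        return (0.0, 1.0)
    sd = d.std(ddof=1)
    if sd == 0:
        return (math.copysign(math.inf, d.mean()), 0.0)
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return (float(t), float(p))


def select_representative(
    members: list[int],
    medians: dict[int, float | None],
    mean_intensity: dict[int, float],
    tie_break: str = "intensity",
) -> int:
    """Member with the minimum median metric; ties broken per policy.

    With no evaluable metric anywhere in the sub-group, falls back to the
    highest mean intensity (logged).
    """
    if not members:
        raise ValueError("empty sub-group")
    scored = [m for m in members if medians.get(m) is not None]
    if not scored:
        logger.warning("sub-group %s has no evaluable metric; "
                       "falling back to highest mean intensity", members)
        return max(members, key=lambda m: (mean_intensity.get(m, -math.inf), -m))
    best = min(medians[m] for m in scored)
    tied = [m for m in scored if medians[m] == best]
    if len(tied) == 1 or tie_break == "first":
        return tied[0]
    return max(tied, key=lambda m: (mean_intensity.get(m, -math.inf), -m))


def _merge_two(
    tables: list[FeatureTable],
    design: ReplicateDesign,
    config: MergeConfig,
    qualities: list[list[FeatureQuality]],
) -> tuple[FeatureTable, MergeReport]:
    ref = tables[0].profile_ids
    for t in tables[1:]:
        if t.profile_ids != ref:
            raise ConfigurationError(
                "tables to merge must share identical profile columns "
                f"(and order): {ref} vs {t.profile_ids}"
            )

    # flatten: combined index -> (table, row)
    origin: list[tuple[int, int]] = [
        (ti, ri) for ti, t in enumerate(tables) for ri in range(t.n_features)
    ]
    mz = np.concatenate([t.mz for t in tables]) if origin else np.empty(0)
    rt = np.concatenate([t.rt for t in tables]) if origin else np.empty(0)
    inten = (np.vstack([t.intensities for t in tables]) if origin
             else np.empty((0, len(ref))))

    medians: dict[int, float | None] = {
        k: qualities[ti][ri].median for k, (ti, ri) in enumerate(origin)
    }
    with np.errstate(invalid="ignore"):
        mean_int = {k: float(np.nanmean(inten[k])) if np.any(~np.isnan(inten[k]))
                    else -math.inf for k in range(len(origin))}

    report = MergeReport(n_input_features=[t.n_features for t in tables])
    kept: list[int] = []
    groups = group_by_mz(mz, config.mz_tolerance_ppm)
    report.n_groups = len(groups)
    for group in groups:
        for sub in subgroup_by_rt(rt, group, config.rt_tolerance_seconds):
            report.n_subgroups += 1
            if len(sub) == 1:
                kept.append(sub[0])
                report.n_unique_passthrough += 1
                continue
            t_stat = p_val = None
            if len(sub) == 2:
                t_stat, p_val = paired_t(inten[sub[0]], inten[sub[1]])
                if math.isnan(t_stat):
                    t_stat = p_val = None
            rep = select_representative(sub, medians, mean_int, config.tie_break)
            record = CollapseRecord(
                members=[origin[m] for m in sub],
                representative=origin[rep],
                member_medians=[medians[m] for m in sub],
                t_statistic=t_stat,
                p_value=p_val,
            )
            if (config.t_test_alpha is not None and len(sub) == 2
                    and p_val is not None and p_val < config.t_test_alpha):
                record.kept_distinct = True
                kept.extend(sub)
                report.n_kept_distinct_by_t_test += 2
            else:
                kept.append(rep)
                report.n_redundant_collapsed += 1
            report.collapses.append(record)

    kept_arr = np.array(sorted(kept, key=lambda k: (mz[k], rt[k], k)), dtype=int)
    merged = FeatureTable(
        mz=mz[kept_arr] if kept_arr.size else np.empty(0),
        rt=rt[kept_arr] if kept_arr.size else np.empty(0),
        intensities=inten[kept_arr] if kept_arr.size else np.empty((0, len(ref))),
        profile_ids=list(ref),
        setting_label=" u ".join(t.setting_label or f"T{i}"
                                 for i, t in enumerate(tables)),
    )
    return merged, report


def merge_results(
    tables: list[FeatureTable],
    design: ReplicateDesign,
    config: MergeConfig | None = None,
    *,
    allow_mixed_replicates: bool = False,
) -> tuple[FeatureTable, MergeReport]:
    """Merge >= 2 feature tables into one table of unique representatives.

    Per-input-table feature qualities (median PID/CV) are computed before
    merging and drive representative selection.  More than two tables are
    folded pairwise in input order (logged; the two-setting case is the
    canonical one).
    """
    if len(tables) < 2:
        raise ValidationError("merge requires at least two feature tables")
    config = config or MergeConfig()

    def quals(t: FeatureTable) -> list[FeatureQuality]:
        return evaluate_features(
            t, design, allow_mixed_replicates=allow_mixed_replicates
        )

    if len(tables) > 2:
        logger.warning("merging %d tables by pairwise folding in input order",
                       len(tables))
    merged, report = _merge_two(tables[:2], design, config,
                                [quals(tables[0]), quals(tables[1])])
    for extra in tables[2:]:
        merged, rep2 = _merge_two([merged, extra], design, config,
                                  [quals(merged), quals(extra)])
        rep2.n_input_features = report.n_input_features + [extra.n_features]
        rep2.collapses = report.collapses + rep2.collapses
        report = rep2
    return merged, report


def write_merge_report(report: MergeReport, path, *, delimiter="\t") -> None:
    """Flat per-collapse table plus summary counters as comment lines."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# inputs: {report.n_input_features}\n")
        fh.write(f"# groups: {report.n_groups}  subgroups: {report.n_subgroups}\n")
        fh.write(f"# passthrough: {report.n_unique_passthrough}  "
                 f"collapsed: {report.n_redundant_collapsed}  "
                 f"kept_distinct: {report.n_kept_distinct_by_t_test}\n")
        fh.write(delimiter.join(
            ["members", "representative", "member_medians",
             "t_statistic", "p_value", "kept_distinct"]) + "\n")
        for c in report.collapses:
            fmt = lambda v: "" if v is None else f"{v:.6g}"
            fh.write(delimiter.join([
                ";".join(f"{t}:{r}" for t, r in c.members),
                f"{c.representative[0]}:{c.representative[1]}",
                ";".join("" if m is None else f"{m:.4f}"
                         for m in c.member_medians),
                fmt(c.t_statistic), fmt(c.p_value),
                str(c.kept_distinct).lower(),
            ]) + "\n")
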