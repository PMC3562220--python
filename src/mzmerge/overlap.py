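"""Cross-dataset feature matching, Venn region counts and rare features.

Two features match when their m/z values differ by at most a ppm threshold
(referenced to the lower of the two m/z, which makes matching symmetric) and,
when a retention-time threshold is enabled, their RTs differ by at most that
many seconds.  Matching is many-to-many; every qualifying pair is reported.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .errors import ConfigurationError, ValidationError
from .feature_table import FeatureTable, ReplicateDesign

__all__ = [
    "MatchConfig",
    "MatchResult",
    "RareFeatureConfig",
    "find_overlapping_mzs",
    "find_unique_mzs",
    "venn_counts",
    "VennCounts",
    "check_mz_in_replicates",
    "write_match_result",
]


@dataclass
class MatchConfig:
    mz_thresh_ppm: float = 5.0
    time_thresh_seconds: float | None = None  # None: match on m/z alone

    def __post_init__(self) -> None:
        if self.mz_thresh_ppm <= 0:
            raise ConfigurationError("mz_thresh_ppm must be positive")
        if self.time_thresh_seconds is not None and self.time_thresh_seconds <= 0:
            raise ConfigurationError("time_thresh_seconds must be positive")


@dataclass
class MatchResult:
    """All qualifying (i, j) pairs plus the unmatched remainder of each list."""

    pairs: list[tuple[int, int, float, float]]  # (i, j, ppm error, rt diff)
    unique_l1: list[int]
    unique_l2: list[int]
    n_l1: int
    n_l2: int

    @property
    def matched_l1(self) -> list[int]:
        return sorted({i for i, *_ in self.pairs})

    @property
    def matched_l2(self) -> list[int]:
        return sorted({j for _, j, *_ in self.pairs})


def find_overlapping_mzs(
    l1: FeatureTable, l2: FeatureTable, config: MatchConfig | None = None
) -> MatchResult:
    """All feature pairs of ``l1`` x ``l2`` within the m/z (and RT) thresholds."""
    config = config or MatchConfig()
    tol = config.mz_thresh_ppm * 1e-6
    mz2 = np.asarray(l2.mz, dtype=float)
    order = np.argsort(mz2, kind="stable")
    sorted_mz2 = mz2[order]
    pairs: list[tuple[int, int, float, float]] = []
    for i in range(l1.n_features):
        m1 = float(l1.mz[i])
        # |dm| / min(m1, m2) <= tol  <=>  m2 in [m1/(1+tol), m1*(1+tol)]
        lo = np.searchsorted(sorted_mz2, m1 / (1.0 + tol), side="left")
        hi = np.searchsorted(sorted_mz2, m1 * (1.0 + tol), side="right")
        for k in range(lo, hi):
            j = int(order[k])
            rt_diff = float(l1.rt[i] - l2.rt[j])
            if (config.time_thresh_seconds is not None
                    and abs(rt_diff) > config.time_thresh_seconds):
                continue
            m2 = float(mz2[j])
            ppm = (m2 - m1) / min(m1, m2) * 1e6
            pairs.append((i, j, ppm, rt_diff))
    matched1 = {i for i, *_ in pairs}
    matched2 = {j for _, j, *_ in pairs}
    return MatchResult(
        pairs=pairs,
        unique_l1=[i for i in range(l1.n_features) if i not in matched1],
        unique_l2=[j for j in range(l2.n_features) if j not in matched2],
        n_l1=l1.n_features,
        n_l2=l2.n_features,
    )


def find_unique_mzs(
    l1: FeatureTable, l2: FeatureTable, config: MatchConfig | None = None
) -> tuple[list[int], list[int]]:
    """Indices of features with no match in the other list (per list)."""
    res = find_overlapping_mzs(l1, l2, config)
    return res.unique_l1, res.unique_l2


@dataclass
class VennCounts:
    """Region counts for 2-3 datasets.

    ``per_dataset[label][region]`` counts the features of that dataset
    assigned to ``region`` (the sorted tuple of labels of every dataset the
    feature matches, itself included) — so each dataset's regions sum to its
    feature count.  ``regions`` collapses this to one number per region,
    taken from the region's first-listed dataset; for many-to-many matches
    the per-dataset counts of a shared region may differ and are the
    authoritative numbers.
    """

    labels: list[str]
    per_dataset: dict[str, dict[tuple[str, ...], int]]
    regions: dict[tuple[str, ...], int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "labels": self.labels,
            "regions": {"&".join(k): v for k, v in sorted(self.regions.items())},
            "per_dataset": {
                lab: {"&".join(k): v for k, v in sorted(d.items())}
                for lab, d in self.per_dataset.items()
            },
        }, indent=2)


def venn_counts(
    datasets: list[FeatureTable],
    config: MatchConfig | None = None,
    labels: list[str] | None = None,
) -> VennCounts:
    """Venn region counts for 2 or 3 feature lists.

    A feature belongs to the intersection region of every dataset in which
    it has at least one match.
    """
    if not 2 <= len(datasets) <= 3:
        raise ValidationError(
            f"venn_counts supports 2 or 3 datasets, got {len(datasets)}"
        )
    if labels is None:
        labels = [d.setting_label or chr(ord("A") + k)
                  for k, d in enumerate(datasets)]
    if len(set(labels)) != len(labels):
        labels = [chr(ord("A") + k) for k in range(len(datasets))]

    membership = [
        [{labels[k]} for _ in range(d.n_features)]
        for k, d in enumerate(datasets)
    ]
    for a, b in combinations(range(len(datasets)), 2):
        res = find_overlapping_mzs(datasets[a], datasets[b], config)
        for i in res.matched_l1:
            membership[a][i].add(labels[b])
        for j in res.matched_l2:
            membership[b][j].add(labels[a])

    order = {lab: k for k, lab in enumerate(labels)}
    per_dataset: dict[str, dict[tuple[str, ...], int]] = {}
    for k, lab in enumerate(labels):
        counts: dict[tuple[str, ...], int] = {}
        for ms in membership[k]:
            region = tuple(sorted(ms, key=order.get))
            counts[region] = counts.get(region, 0) + 1
        per_dataset[lab] = counts

    regions: dict[tuple[str, ...], int] = {}
    for lab in labels:  # earliest dataset holding the region provides the count
        for region, n in per_dataset[lab].items():
            regions.setdefault(region, n)
    return VennCounts(labels=labels, per_dataset=per_dataset, regions=regions)


@dataclass
class RareFeatureConfig:
    min_samps: int = 1
    min_reps: float = 100.0  # percent of a sample's replicates

    def __post_init__(self) -> None:
        if self.min_samps < 1:
            raise ConfigurationError("min_samps must be >= 1")
        if not 0 < self.min_reps <= 100:
            raise ConfigurationError("min_reps must be in (0, 100]")


def check_mz_in_replicates(
    table: FeatureTable,
    design: ReplicateDesign,
    config: RareFeatureConfig,
) -> list[int]:
    """Features observed in >= min_reps % of replicates of >= min_samps samples.

    The per-sample requirement is ``observed >= ceil(min_reps/100 * r)`` for a
    sample with ``r`` replicates (percentage rounded up to whole replicates).
    """
    design.validate_against(table)
    col = {pid: j for j, pid in enumerate(table.profile_ids)}
    obs = table.observed()
    sample_cols = [
        [col[p] for p in design.replicates_of(s)] for s in design.samples()
    ]
    required = [math.ceil(config.min_reps / 100.0 * len(cc))
                for cc in sample_cols]
    kept = []
    for i in range(table.n_features):
        n_ok = sum(
            1 for cc, need in zip(sample_cols, required)
            if int(obs[i, cc].sum()) >= need
        )
        if n_ok >= config.min_samps:
            kept.append(i)
    return kept


def write_match_result(
    l1: FeatureTable, l2: FeatureTable, result: MatchResult, path,
    *, delimiter="\t",
) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(delimiter.join(
            ["index_1", "mz_1", "time_1", "index_2", "mz_2", "time_2",
             "ppm_error", "rt_diff"]) + "\n")
        for i, j, ppm, dt in result.pairs:
            fh.write(delimiter.join([
                str(i), f"{l1.mz[i]:.5f}", f"{l1.rt[i]:.3f}",
                str(j), f"{l2.mz[j]:.5f}", f"{l2.rt[j]:.3f}",
                f"{ppm:.3f}", f"{dt:.3f}"]) + "\n")
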