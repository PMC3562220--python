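"""Score extraction settings and setting-pairs, and pick the best pair.

A candidate (a single setting or the merge of a pair of settings) is scored

    S = N - w * medianPID

where ``N`` is the candidate's feature count, ``medianPID`` the median over
features of each feature's median replicate metric (percent), and ``w`` a
weighting constant trading feature yield against reproducibility (typical
values 30 and 100).  The candidate maximising S wins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .errors import ConfigurationError
from .feature_table import FeatureTable, ReplicateDesign
from .merge import MergeConfig, merge_results
from .quality import evaluate_features

__all__ = [
    "SettingScore",
    "OptimizationConfig",
    "score_setting",
    "rank_settings",
    "median_metric",
    "optimize_pair",
    "write_scores",
]


@dataclass
class SettingScore:
    labels: tuple[str, ...]          # 1 label (single) or 2 (merged pair)
    n_features: int
    median_pid: float
    w: float
    score: float
    is_best: bool = False
    available: bool = True
    note: str = ""

    @property
    def label(self) -> str:
        return " u ".join(self.labels)


@dataclass
class OptimizationConfig:
    candidates: list[tuple[str, FeatureTable]]
    w_values: tuple[float, ...] = (30.0, 100.0)
    merge_config: MergeConfig = field(default_factory=MergeConfig)
    pair_summary: str = "median"       # median of per-feature medians, or "mean"
    include_singles: bool = True

    def __post_init__(self) -> None:
        if len(self.candidates) < 2:
            raise ConfigurationError("optimization needs >= 2 candidate settings")
        if any(w <= 0 for w in self.w_values):
            raise ConfigurationError("w values must be positive")
        if self.pair_summary not in ("median", "mean"):
            raise ConfigurationError(f"unknown pair_summary {self.pair_summary!r}")


def score_setting(
    n_features: int, median_pid: float, w: float, labels: tuple[str, ...] = ("?",)
) -> SettingScore:
    """S = N - w * medianPID, exact arithmetic."""
    if n_features < 0:
        raise ValueError("feature count must be nonnegative")
    if w <= 0:
        raise ValueError("w must be positive")
    return SettingScore(
        labels=tuple(labels),
        n_features=int(n_features),
        median_pid=float(median_pid),
        w=float(w),
        score=n_features - w * median_pid,
    )


def rank_settings(
    entries: list[tuple[tuple[str, ...], int, float]], w: float
) -> list[SettingScore]:
    """Score (labels, N, medianPID) entries and sort descending; argmax flagged."""
    scores = [score_setting(n, mpid, w, labels) for labels, n, mpid in entries]
    scores.sort(key=lambda s: -s.score)
    if scores:
        scores[0].is_best = True
    return scores


def median_metric(
    table: FeatureTable,
    design: ReplicateDesign,
    *,
    summary: str = "median",
    allow_mixed_replicates: bool = False,
) -> float:
    """Dataset-level percent metric: median (or mean) of per-feature medians."""
    quals = evaluate_features(
        table, design, allow_mixed_replicates=allow_mixed_replicates
    )
    meds = [q.median for q in quals if q.median is not None]
    if not meds:
        return math.nan
    agg = np.median if summary == "median" else np.mean
    return float(agg(meds))


def optimize_pair(
    config: OptimizationConfig, design: ReplicateDesign
) -> dict[float, list[SettingScore]]:
    """Evaluate every single setting and unordered pair; rank per w value.

    Pairs are scored on the output of the merge (N = merged feature count,
    medianPID recomputed on the merged table).  A pair whose merge fails is
    reported unavailable and the rest are still ranked.
    """
    evaluated: list[tuple[tuple[str, ...], int, float, str]] = []
    if config.include_singles:
        for label, table in config.candidates:
            evaluated.append((
                (label,), table.n_features,
                median_metric(table, design, summary=config.pair_summary), ""
            ))
    for (la, ta), (lb, tb) in combinations(config.candidates, 2):
        try:
            merged, _ = merge_results([ta, tb], design, config.merge_config)
            mpid = median_metric(merged, design, summary=config.pair_summary)
            evaluated.append(((la, lb), merged.n_features, mpid, ""))
        except Exception as exc:  # pragma: no cover - defensive
            evaluated.append(((la, lb), 0, math.nan, f"merge failed: {exc}"))

    out: dict[float, list[SettingScore]] = {}
    for w in config.w_values:
        scores = []
        for labels, n, mpid, note in evaluated:
            if note or math.isnan(mpid):
                s = SettingScore(labels, n, mpid, w, -math.inf,
                                 available=False, note=note or "metric undefined")
            else:
                s = score_setting(n, mpid, w, labels)
            scores.append(s)
        scores.sort(key=lambda s: -s.score)
        for s in scores:
            if s.available:
                s.is_best = True
                break
        out[w] = scores
    return out


def write_scores(ranked: dict[float, list[SettingScore]], path, *, delimiter="\t"):
    """Ranked scores as delimited text (one block of rows across all w)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(delimiter.join(
            ["setting", "n_features", "median_pid", "w", "score",
             "is_best", "note"]) + "\n")
        for w in sorted(ranked):
            for s in ranked[w]:
                fh.write(delimiter.join([
                    s.label, str(s.n_features),
                    "" if math.isnan(s.median_pid) else f"{s.median_pid:.4f}",
                    f"{w:g}",
                    "-inf" if s.score == -math.inf else f"{s.score:.4f}",
                    str(s.is_best).lower(), s.note]) + "\n")
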