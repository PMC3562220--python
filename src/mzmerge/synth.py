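"""Synthetic two-setting extraction pairs with known ground truth.

Emulates re-extracting the same LC/MS runs at two parameter settings: a set
of shared ground-truth compounds appears in both output tables (with small
m/z / RT jitter between settings and setting-specific replicate noise), and
each setting additionally detects its own unique compounds.  Distinct
compounds are kept separated in m/z by more than three times the merge
tolerance, so the expected merged feature count is exactly
``n_shared + 2 * n_unique_per_setting``.

Intensities are log-normal (per-compound base level x per-sample biological
factor), replicate noise is multiplicative log-normal, and missingness is
applied independently per cell.  Everything is driven by one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .feature_table import FeatureTable, ReplicateDesign

__all__ = ["SynthConfig", "GroundTruth", "generate_extraction_pair",
           "make_design", "write_ground_truth"]


@dataclass
class SynthConfig:
    n_shared_compounds: int = 30
    n_unique_per_setting: int = 10
    n_samples: int = 6
    replicates_per_sample: int = 2
    mz_range: tuple[float, float] = (85.0, 850.0)
    rt_range: tuple[float, float] = (10.0, 600.0)
    # replicate noise: per feature-copy log-normal sigma drawn from this range;
    # the second copy of a shared compound gets its sigma scaled up by a factor
    # drawn from noise_sd_ratio so one copy is reliably the "cleaner" member.
    noise_sd_range: tuple[float, float] = (0.02, 0.10)
    noise_sd_ratio: tuple[float, float] = (3.0, 5.0)
    jitter_ppm_sd: float = 0.5
    jitter_rt_sd: float = 1.0
    missing_prob: float = 0.0
    base_log_intensity: float = np.log(1e5)
    base_log_sd: float = 1.0
    sample_log_sd: float = 0.5
    mz_tolerance_ppm: float = 5.0   # merge tolerance the layout must respect
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates_per_sample not in (2, 3):
            raise ConfigurationError("replicates_per_sample must be 2 or 3")
        if self.n_samples < 1 or self.n_shared_compounds < 0 \
                or self.n_unique_per_setting < 0:
            raise ConfigurationError("counts must be nonnegative")
        if not 0 <= self.missing_prob < 1:
            raise ConfigurationError("missing_prob must be in [0, 1)")
        if self.jitter_ppm_sd * 6 > self.mz_tolerance_ppm:
            raise ConfigurationError(
                "jitter_ppm_sd too large relative to the merge tolerance"
            )


@dataclass
class GroundTruth:
    """Row-level provenance for a generated extraction pair."""

    compound_mz: np.ndarray
    compound_rt: np.ndarray
    # per table: compound index of each feature row
    rows: tuple[list[int], list[int]] = field(default_factory=lambda: ([], []))
    # shared compounds: (compound idx, row in t1, row in t2,
    #                    lower-noise table (0/1), sd table0, sd table1)
    shared: list[tuple[int, int, int, int, float, float]] = field(
        default_factory=list
    )

    @property
    def n_expected_merged(self) -> int:
        return len(set(self.rows[0]) | set(self.rows[1]))


def make_design(n_samples: int, replicates: int) -> ReplicateDesign:
    return ReplicateDesign({
        f"S{s + 1}_r{r + 1}": f"S{s + 1}"
        for s in range(n_samples) for r in range(replicates)
    })


def _spaced_mz(rng: np.random.Generator, n: int, cfg: SynthConfig) -> np.ndarray:
    """n sorted m/z values with pairwise ppm separation > 3x merge tolerance."""
    lo, hi = cfg.mz_range
    min_gap_rel = 3.0 * cfg.mz_tolerance_ppm * 1e-6
    if n == 0:
        return np.empty(0)
    # feasibility: worst case all mass sits near the top of the range
    if lo * (1 + min_gap_rel * 4) ** n > hi:
        raise ConfigurationError(
            f"cannot place {n} compounds in {cfg.mz_range} with separation "
            f"> 3x {cfg.mz_tolerance_ppm} ppm"
        )
    for _ in range(1000):
        mz = np.sort(rng.uniform(lo, hi, size=n))
        rel_gaps = np.diff(mz) / mz[:-1]
        if n == 1 or rel_gaps.min() > min_gap_rel:
            return mz
    raise ConfigurationError("failed to satisfy m/z separation invariant")


def generate_extraction_pair(
    config: SynthConfig,
) -> tuple[FeatureTable, FeatureTable, GroundTruth]:
    """Two feature tables sharing profile columns, plus their ground truth."""
    rng = np.random.default_rng(config.seed)
    n_total = config.n_shared_compounds + 2 * config.n_unique_per_setting
    mz = _spaced_mz(rng, n_total, config)
    rt = rng.uniform(*config.rt_range, size=n_total)

    n_prof = config.n_samples * config.replicates_per_sample
    design = make_design(config.n_samples, config.replicates_per_sample)
    profile_ids = list(design.assignments)

    # true per-compound per-sample intensity, shared between settings
    base = np.exp(rng.normal(config.base_log_intensity, config.base_log_sd,
                             size=n_total))
    sample_factor = np.exp(rng.normal(0.0, config.sample_log_sd,
                                      size=(n_total, config.n_samples)))
    true_sample = base[:, None] * sample_factor  # (compound, sample)

    shared_idx = list(range(config.n_shared_compounds))
    uniq1 = list(range(config.n_shared_compounds,
                       config.n_shared_compounds + config.n_unique_per_setting))
    uniq2 = list(range(config.n_shared_compounds + config.n_unique_per_setting,
                       n_total))

    truth = GroundTruth(compound_mz=mz, compound_rt=rt)
    tables: list[FeatureTable] = []
    # noise sigma per (compound, table-copy)
    sd_low = rng.uniform(*config.noise_sd_range, size=n_total)
    ratio = rng.uniform(*config.noise_sd_ratio, size=n_total)
    low_noise_table = rng.integers(0, 2, size=n_total)

    for ti in (0, 1):
        compounds = shared_idx + (uniq1 if ti == 0 else uniq2)
        rows_mz, rows_rt, rows_int = [], [], []
        for c in compounds:
            sd = sd_low[c] if low_noise_table[c] == ti else sd_low[c] * ratio[c]
            jit_mz = mz[c] * (1 + rng.normal(0.0, config.jitter_ppm_sd) * 1e-6)
            jit_rt = max(0.0, rt[c] + rng.normal(0.0, config.jitter_rt_sd))
            reps = np.repeat(true_sample[c], config.replicates_per_sample)
            noise = np.exp(rng.normal(0.0, sd, size=n_prof)) if sd > 0 else 1.0
            inten = reps * noise
            if config.missing_prob > 0:
                miss = rng.random(n_prof) < config.missing_prob
                inten = np.where(miss, np.nan, inten)
            rows_mz.append(jit_mz)
            rows_rt.append(jit_rt)
            rows_int.append(inten)
        order = np.argsort(rows_mz, kind="stable")
        tables.append(FeatureTable(
            mz=np.array(rows_mz)[order],
            rt=np.array(rows_rt)[order],
            intensities=np.array(rows_int)[order],
            profile_ids=profile_ids,
            setting_label=f"synthetic-P{ti + 1}",
        ))
        truth.rows[ti].extend(int(compounds[k]) for k in order)

    row_of = [
        {c: r for r, c in enumerate(truth.rows[ti])} for ti in (0, 1)
    ]
    for c in shared_idx:
        sd0 = sd_low[c] if low_noise_table[c] == 0 else sd_low[c] * ratio[c]
        sd1 = sd_low[c] if low_noise_table[c] == 1 else sd_low[c] * ratio[c]
        truth.shared.append((c, row_of[0][c], row_of[1][c],
                             int(low_noise_table[c]), float(sd0), float(sd1)))
    return tables[0], tables[1], truth


def write_ground_truth(truth: GroundTruth, path, *, delimiter="\t") -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(delimiter.join(
            ["compound", "mz", "rt", "row_t1", "row_t2",
             "lower_noise_table", "sd_t1", "sd_t2"]) + "\n")
        in_shared = {c: rec for rec in truth.shared for c in [rec[0]]}
        r1 = {c: r for r, c in enumerate(truth.rows[0])}
        r2 = {c: r for r, c in enumerate(truth.rows[1])}
        for c in range(len(truth.compound_mz)):
            rec = in_shared.get(c)
            fh.write(delimiter.join([
                str(c), f"{truth.compound_mz[c]:.5f}",
                f"{truth.compound_rt[c]:.3f}",
                str(r1.get(c, "")), str(r2.get(c, "")),
                str(rec[3]) if rec else "",
                f"{rec[4]:.4f}" if rec else "",
                f"{rec[5]:.4f}" if rec else "",
            ]) + "\n")
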