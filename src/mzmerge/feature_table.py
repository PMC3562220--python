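"""Feature-table and replicate-design containers with delimited-text I/O.

A feature table is a delimited text file with a header row ``mz``, ``time``
followed by one column per LC/MS profile.  Retention time is always in
seconds.  Intensities are nonnegative; by default a stored ``0`` is read as
*missing* (the convention of upstream peak extractors that emit 0 for absent
features) and missing values are written back as ``0``.  Pass
``zero_as_missing=False`` to treat zeros as observed.

Internally missing intensities are ``NaN`` in a dense ``(features, profiles)``
float array.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import TableFormatError, ValidationError

__all__ = [
    "FeatureTable",
    "ReplicateDesign",
    "read_feature_table",
    "write_feature_table",
    "read_replicate_design",
    "write_replicate_design",
]

#: decimal places used when writing m/z (sub-ppm over the 85-850 range)
MZ_DECIMALS = 5
RT_DECIMALS = 3
#: significant digits for intensities (scientific notation)
INTENSITY_SIGFIGS = 6

_MZ_NAMES = {"mz", "m/z", "m.z", "mz_value"}
_RT_NAMES = {"time", "rt", "retention_time", "time.s", "rtime"}


@dataclass
class FeatureTable:
    """Dense features x profiles intensity matrix keyed by (m/z, RT)."""

    mz: np.ndarray
    rt: np.ndarray
    intensities: np.ndarray
    profile_ids: list[str]
    setting_label: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim == 1:
            self.intensities = self.intensities.reshape(len(self.mz), -1)
        self.profile_ids = list(self.profile_ids)
        self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def n_features(self) -> int:
        return len(self.mz)

    @property
    def n_profiles(self) -> int:
        return len(self.profile_ids)

    def validate(self) -> None:
        n, p = self.n_features, self.n_profiles
        if self.rt.shape != (n,):
            raise ValidationError(
                f"rt length {self.rt.shape} does not match {n} features"
            )
        if self.intensities.shape != (n, p):
            raise ValidationError(
                f"intensity matrix shape {self.intensities.shape} does not match "
                f"({n} features, {p} profiles)"
            )
        if len(set(self.profile_ids)) != p:
            dupes = sorted(
                {x for x in self.profile_ids if self.profile_ids.count(x) > 1}
            )
            raise ValidationError(f"duplicate profile column names: {dupes}")
        if n:
            bad = np.flatnonzero(~(self.mz > 0))
            if bad.size:
                raise ValidationError(f"non-positive m/z at feature row {bad[0]}")
            bad = np.flatnonzero(~(self.rt >= 0))
            if bad.size:
                raise ValidationError(
                    f"negative retention time at feature row {bad[0]}"
                )
            with np.errstate(invalid="ignore"):
                neg = np.argwhere(self.intensities < 0)
            if neg.size:
                r, c = neg[0]
                raise ValidationError(
                    f"negative intensity at feature row {r}, "
                    f"column {self.profile_ids[c]!r}"
                )

    # -- views -------------------------------------------------------------

    def observed(self) -> np.ndarray:
        """Boolean mask of observed (non-missing) cells."""
        return ~np.isnan(self.intensities)

    def complete_rows(self) -> np.ndarray:
        """Indices of features observed in every profile."""
        return np.flatnonzero(self.observed().all(axis=1))

    def take(self, rows) -> "FeatureTable":
        rows = np.asarray(rows, dtype=int)
        return replace(
            self,
            mz=self.mz[rows],
            rt=self.rt[rows],
            intensities=self.intensities[rows],
            profile_ids=list(self.profile_ids),
        )

    def drop_profiles(self, profile_ids) -> "FeatureTable":
        drop = set(profile_ids)
        keep = [i for i, pid in enumerate(self.profile_ids) if pid not in drop]
        if not keep:
            raise ValidationError("dropping requested profiles leaves no column")
        return replace(
            self,
            intensities=self.intensities[:, keep],
            profile_ids=[self.profile_ids[i] for i in keep],
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.intensities, columns=self.profile_ids)
        df.insert(0, "time", self.rt)
        df.insert(0, "mz", self.mz)
        return df

    def __eq__(self, other) -> bool:  # value equality, NaN == NaN
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (
            self.profile_ids == other.profile_ids
            and self.mz.shape == other.mz.shape
            and np.array_equal(self.mz, other.mz)
            and np.array_equal(self.rt, other.rt)
            and np.array_equal(self.intensities, other.intensities, equal_nan=True)
        )


@dataclass
class ReplicateDesign:
    """Mapping of profile column -> biological sample."""

    assignments: dict[str, str] = field(default_factory=dict)

    def samples(self) -> list[str]:
        seen: dict[str, None] = {}
        for sid in self.assignments.values():
            seen.setdefault(sid, None)
        return list(seen)

    def replicates_of(self, sample_id: str) -> list[str]:
        return [p for p, s in self.assignments.items() if s == sample_id]

    def replicate_counts(self) -> dict[str, int]:
        return {s: len(self.replicates_of(s)) for s in self.samples()}

    def validate_against(self, table: FeatureTable) -> None:
        missing = [p for p in table.profile_ids if p not in self.assignments]
        if missing:
            raise ValidationError(
                f"profiles without a sample assignment: {missing}"
            )
        extra = [p for p in self.assignments if p not in table.profile_ids]
        if extra:
            raise ValidationError(
                f"design references unknown profile columns: {extra}"
            )

    def restrict_to(self, profile_ids) -> "ReplicateDesign":
        keep = set(profile_ids)
        return ReplicateDesign(
            {p: s for p, s in self.assignments.items() if p in keep}
        )

    def drop_samples(self, sample_ids) -> "ReplicateDesign":
        drop = set(sample_ids)
        return ReplicateDesign(
            {p: s for p, s in self.assignments.items() if s not in drop}
        )


# ---------------------------------------------------------------------------
# I/O


def _sniff_delimiter(first_line: str) -> str:
    return "\t" if "\t" in first_line else ","


def read_feature_table(
    path,
    *,
    delimiter: str | None = None,
    zero_as_missing: bool = True,
    setting_label: str | None = None,
) -> FeatureTable:
    """Read a delimited feature table (columns mz, time, then profiles)."""
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    if not text.strip():
        raise TableFormatError(f"{path}: empty file")
    if delimiter is None:
        delimiter = _sniff_delimiter(text.splitlines()[0])
    header = [c.strip() for c in text.splitlines()[0].split(delimiter)]
    if len(set(header)) != len(header):  # pandas would mangle duplicates
        dupes = sorted({c for c in header if header.count(c) > 1})
        raise ValidationError(f"{path}: duplicate profile column names: {dupes}")
    try:
        df = pd.read_csv(io.StringIO(text), sep=delimiter, dtype=str)
    except pd.errors.ParserError as exc:
        raise TableFormatError(f"{path}: {exc}") from exc
    if df.shape[1] < 2:
        raise TableFormatError(
            f"{path}: expected at least columns 'mz' and 'time', "
            f"got {list(df.columns)}"
        )
    cols = [str(c) for c in df.columns]
    if cols[0].strip().lower() not in _MZ_NAMES:
        raise TableFormatError(
            f"{path}: first column must be 'mz', got {cols[0]!r}"
        )
    if cols[1].strip().lower() not in _RT_NAMES:
        raise TableFormatError(
            f"{path}: second column must be 'time', got {cols[1]!r}"
        )
    profile_ids = cols[2:]
    if len(set(profile_ids)) != len(profile_ids):
        raise ValidationError(f"{path}: duplicate profile column names")

    def _numeric(col: pd.Series, what: str) -> np.ndarray:
        out = pd.to_numeric(col, errors="coerce")
        bad = out.isna() & col.notna() & (col.astype(str).str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise TableFormatError(
                f"{path}: non-numeric {what} {col.iloc[row]!r} at data row {row}"
            )
        return out.to_numpy(dtype=float)

    mz = _numeric(df.iloc[:, 0], "m/z")
    rt = _numeric(df.iloc[:, 1], "retention time")
    if np.isnan(mz).any() or np.isnan(rt).any():
        row = int(np.flatnonzero(np.isnan(mz) | np.isnan(rt))[0])
        raise TableFormatError(f"{path}: missing m/z or time at data row {row}")
    inten = np.column_stack(
        [_numeric(df.iloc[:, 2 + j], f"intensity ({pid})")
         for j, pid in enumerate(profile_ids)]
    ) if profile_ids else np.empty((len(mz), 0))
    if zero_as_missing and inten.size:
        inten = np.where(inten == 0, np.nan, inten)
    return FeatureTable(
        mz=mz,
        rt=rt,
        intensities=inten,
        profile_ids=profile_ids,
        setting_label=(
            setting_label
            if setting_label is not None
            else os.path.splitext(os.path.basename(str(path)))[0]
        ),
    )


def write_feature_table(
    table: FeatureTable,
    path,
    *,
    delimiter: str = "\t",
    missing_marker: str = "0",
) -> None:
    """Write ``table`` as delimited text (mz, time, one column per profile)."""
    table.validate()
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(delimiter.join(["mz", "time", *table.profile_ids]) + "\n")
        for i in range(table.n_features):
            cells = [
                f"{table.mz[i]:.{MZ_DECIMALS}f}",
                f"{table.rt[i]:.{RT_DECIMALS}f}",
            ]
            for v in table.intensities[i]:
                cells.append(
                    missing_marker if np.isnan(v)
                    else f"{v:.{INTENSITY_SIGFIGS - 1}e}"
                )
            fh.write(delimiter.join(cells) + "\n")


_DESIGN_HEADERS = {"profile_id", "profile", "sample_id", "sample"}


def read_replicate_design(path, *, delimiter: str | None = None) -> ReplicateDesign:
    """Read a two-column (profile_id, sample_id) design file."""
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise TableFormatError(f"{path}: empty design file")
    if delimiter is None:
        delimiter = _sniff_delimiter(lines[0])
    rows = [ln.split(delimiter) for ln in lines]
    if any(len(r) != 2 for r in rows):
        bad = next(i for i, r in enumerate(rows) if len(r) != 2)
        raise TableFormatError(f"{path}: row {bad} does not have 2 columns")
    if rows[0][0].strip().lower() in _DESIGN_HEADERS:
        rows = rows[1:]
    assignments: dict[str, str] = {}
    for i, (pid, sid) in enumerate(rows):
        pid, sid = pid.strip(), sid.strip()
        if pid in assignments:
            raise ValidationError(f"{path}: profile {pid!r} listed twice (row {i})")
        assignments[pid] = sid
    return ReplicateDesign(assignments)


def write_replicate_design(design: ReplicateDesign, path, *, delimiter="\t") -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(delimiter.join(["profile_id", "sample_id"]) + "\n")
        for pid, sid in design.assignments.items():
            fh.write(f"{pid}{delimiter}{sid}\n")
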