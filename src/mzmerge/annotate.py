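"""Adduct-based m/z annotation against a local compound database.

Each query m/z is compared with the theoretical m/z of every
(compound, adduct) combination, ``(M + offset) / charge`` for neutral
monoisotopic mass ``M``; hits are those within a ppm window referenced to
the query m/z.  Reports are written as delimited text and standalone HTML
with hyperlinks to external database identifiers carried in the compound
table.

The compound database is a TSV with columns ``id``, ``name``,
``monoisotopic_mass`` and optional identifier columns (``kegg_id``,
``hmdb_id``, ``pubchem_cid``, ``chebi_id``, ``cas``, ``lipidmaps_id``).
A small demo database ships with the package (:func:`demo_database_path`).
"""

from __future__ import annotations

import html
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

__all__ = [
    "PROTON_MASS",
    "WATER_MASS",
    "Adduct",
    "DEFAULT_ADDUCTS",
    "CompoundRecord",
    "AnnotationHit",
    "adduct_mz",
    "read_compound_db",
    "demo_database_path",
    "batch_annotate",
    "unannotated_queries",
    "write_annotation_report",
]

#: proton and water monoisotopic masses, unified atomic mass units
PROTON_MASS = 1.00727646677
WATER_MASS = 18.0105646863
ELECTRON_MASS = 0.00054857991
_NA = 22.9897692809
_K = 38.9637064864
_NH4 = 18.0343741331  # N + 4H, neutral


@dataclass(frozen=True)
class Adduct:
    name: str
    offset: float  # mass added to the neutral monoisotopic mass, u
    charge: int = 1


DEFAULT_ADDUCTS: dict[str, Adduct] = {
    a.name: a for a in [
        Adduct("M", 0.0),
        Adduct("M+H", PROTON_MASS),
        Adduct("M+H-H2O", PROTON_MASS - WATER_MASS),
        Adduct("M+Na", _NA - ELECTRON_MASS),
        Adduct("M+K", _K - ELECTRON_MASS),
        Adduct("M+NH4", _NH4 - ELECTRON_MASS),
        Adduct("M-H", -PROTON_MASS),
    ]
}


def resolve_adducts(names) -> list[Adduct]:
    out = []
    for n in names:
        if isinstance(n, Adduct):
            out.append(n)
        elif n in DEFAULT_ADDUCTS:
            out.append(DEFAULT_ADDUCTS[n])
        else:
            raise ConfigurationError(
                f"unknown adduct {n!r}; known: {sorted(DEFAULT_ADDUCTS)}"
            )
    return out


_LINK_COLUMNS = ("kegg_id", "hmdb_id", "pubchem_cid", "chebi_id", "cas",
                 "lipidmaps_id")


@dataclass
class CompoundRecord:
    compound_id: str
    name: str
    monoisotopic_mass: float
    links: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.monoisotopic_mass > 0:
            raise ValidationError(
                f"compound {self.compound_id!r}: mass must be positive"
            )


@dataclass
class AnnotationHit:
    query_mz: float
    adduct: str
    compound_id: str
    compound_name: str
    theoretical_mz: float
    ppm_error: float  # (query - theoretical) / query * 1e6
    links: dict[str, str] = field(default_factory=dict)


def adduct_mz(neutral_mass: float, adduct: Adduct | str) -> float:
    """Theoretical m/z of ``adduct`` for a neutral monoisotopic mass."""
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    if isinstance(adduct, str):
        (adduct,) = resolve_adducts([adduct])
    return (neutral_mass + adduct.offset) / adduct.charge


def read_compound_db(path) -> list[CompoundRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"id", "name", "monoisotopic_mass"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(
            f"{path}: compound database missing columns {sorted(missing)}"
        )
    records = []
    for _, row in df.iterrows():
        links = {c: str(row[c]) for c in _LINK_COLUMNS
                 if c in df.columns and pd.notna(row[c]) and str(row[c]).strip()}
        records.append(CompoundRecord(
            compound_id=str(row["id"]),
            name=str(row["name"]),
            monoisotopic_mass=float(row["monoisotopic_mass"]),
            links=links,
        ))
    if not records:
        raise ValidationError(f"{path}: compound database is empty")
    return records


def demo_database_path():
    """Path to the bundled ~50-compound demo database."""
    return resources.files("mzmerge").joinpath("data/demo_compounds.tsv")


def batch_annotate(
    query_mzs,
    db: list[CompoundRecord],
    adducts=("M+H", "M+H-H2O"),
    ppm_thresh: float = 5.0,
) -> list[AnnotationHit]:
    """All (compound, adduct) hits within ``ppm_thresh`` of each query m/z.

    The window is referenced to the query: a theoretical m/z ``t`` is a hit
    for query ``q`` when ``|q - t| / q * 1e6 <= ppm_thresh``.
    """
    if not db:
        raise ValidationError("compound database is empty")
    if ppm_thresh <= 0:
        raise ConfigurationError("ppm_thresh must be positive")
    adducts = resolve_adducts(adducts)
    theo = []
    for rec in db:
        for add in adducts:
            theo.append((adduct_mz(rec.monoisotopic_mass, add), rec, add))
    theo.sort(key=lambda t: t[0])
    theo_mz = np.array([t[0] for t in theo])

    hits: list[AnnotationHit] = []
    for q in np.asarray(query_mzs, dtype=float):
        half = ppm_thresh * 1e-6 * q
        lo = np.searchsorted(theo_mz, q - half, side="left")
        hi = np.searchsorted(theo_mz, q + half, side="right")
        for k in range(lo, hi):
            t, rec, add = theo[k]
            hits.append(AnnotationHit(
                query_mz=float(q),
                adduct=add.name,
                compound_id=rec.compound_id,
                compound_name=rec.name,
                theoretical_mz=t,
                ppm_error=(q - t) / q * 1e6,
                links=dict(rec.links),
            ))
    return hits


def unannotated_queries(query_mzs, hits: list[AnnotationHit]) -> list[float]:
    annotated = {h.query_mz for h in hits}
    return [float(q) for q in query_mzs if float(q) not in annotated]


_LINK_URLS = {
    "kegg_id": "https://www.genome.jp/dbget-bin/www_bget?cpd:{0}",
    "hmdb_id": "https://hmdb.ca/metabolites/{0}",
    "pubchem_cid": "https://pubchem.ncbi.nlm.nih.gov/compound/{0}",
    "chebi_id": "https://www.ebi.ac.uk/chebi/searchId.do?chebiId={0}",
    "lipidmaps_id": "https://www.lipidmaps.org/databases/lmsd/{0}",
}

_TEXT_COLUMNS = ["query_mz", "adduct", "compound_id", "compound_name",
                 "theoretical_mz", "ppm_error", *_LINK_COLUMNS]


def write_annotation_report(
    query_mzs, hits: list[AnnotationHit], path, fmt: str = "text"
) -> None:
    """Deterministic text or HTML report; unmatched queries listed too."""
    if fmt not in ("text", "html"):
        raise ConfigurationError(f"unknown report format {fmt!r}")
    rows = sorted(hits, key=lambda h: (h.query_mz, h.adduct, h.compound_id))
    missed = unannotated_queries(query_mzs, hits)
    if fmt == "text":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("\t".join(_TEXT_COLUMNS) + "\n")
            for h in rows:
                fh.write("\t".join([
                    f"{h.query_mz:.5f}", h.adduct, h.compound_id,
                    h.compound_name, f"{h.theoretical_mz:.5f}",
                    f"{h.ppm_error:.3f}",
                    *[h.links.get(c, "") for c in _LINK_COLUMNS]]) + "\n")
            for q in missed:
                fh.write("\t".join([f"{q:.5f}", "", "no_match", "", "", "",
                                    *[""] * len(_LINK_COLUMNS)]) + "\n")
        return

    def link_cell(h: AnnotationHit, col: str) -> str:
        v = h.links.get(col, "")
        if not v:
            return ""
        url = _LINK_URLS.get(col)
        esc = html.escape(v)
        return f'<a href="{url.format(esc)}">{esc}</a>' if url else esc

    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        "<title>m/z annotation report</title>",
        "<style>table{border-collapse:collapse}"
        "td,th{border:1px solid #999;padding:2px 6px}</style></head><body>",
        "<h1>m/z annotation report</h1>",
        f"<p>{len(rows)} hits; {len(missed)} unannotated queries.</p>",
        "<table><tr>" + "".join(f"<th>{c}</th>" for c in _TEXT_COLUMNS) + "</tr>",
    ]
    for h in rows:
        cells = [f"{h.query_mz:.5f}", h.adduct, html.escape(h.compound_id),
                 html.escape(h.compound_name), f"{h.theoretical_mz:.5f}",
                 f"{h.ppm_error:.3f}",
                 *[link_cell(h, c) for c in _LINK_COLUMNS]]
        parts.append("<tr>" + "".join(f"<td>{c}</td>" for c in cells) + "</tr>")
    for q in missed:
        cells = [f"{q:.5f}", "", "no_match", "", "", "",
                 *[""] * len(_LINK_COLUMNS)]
        parts.append("<tr>" + "".join(f"<td>{c}</td>" for c in cells) + "</tr>")
    parts.append("</table></body></html>")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(parts) + "\n")
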