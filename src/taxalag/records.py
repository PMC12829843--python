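"""Reading, validation, filtering and serialization of type-series metadata.

A record describes one species: its describing publication (date, identifier,
author count, species-per-paper count), the region and genus it belongs to,
the collection events of its type series (holotype + paratypes) as verbatim
date strings, and the covariates used by the mixed models.

Every input row is either retained or logged with a single exclusion reason,
so |input species| == |retained| + |excluded| for every ingest.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .dates import CollectionDate, DateParseError, parse_date_text

#: canonical CSV column order
CANONICAL_COLUMNS = [
    "species", "genus", "region", "publication_date", "publication_id",
    "collection_date_raw", "n_authors", "n_types", "n_species_in_paper",
    "genetics", "genus_richness",
]

_COVARIATE_COLUMNS = [
    "genus", "region", "publication_date", "publication_id", "n_authors",
    "n_types", "n_species_in_paper", "genetics", "genus_richness",
]

EXCLUSION_REASONS = (
    "missing_publication_date",
    "missing_collection_dates",
    "unparseable_date",
    "out_of_window",
    "pub_before_collection",
)


@dataclass(frozen=True)
class TypeSeriesRecord:
    species: str
    genus: str
    region: str
    publication_date: dt.date
    publication_id: str
    collection_events: tuple[CollectionDate, ...]
    n_authors: int
    n_types: int
    n_species_in_paper: int
    genetics: bool
    genus_richness: int

    def __post_init__(self):
        if not self.collection_events:
            raise ValueError(f"{self.species}: no collection events")
        for name in ("n_authors", "n_types", "n_species_in_paper",
                     "genus_richness"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{self.species}: {name} must be >= 1")


@dataclass(frozen=True)
class ExclusionEntry:
    species: str
    reason: str

    def __post_init__(self):
        if self.reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion reason {self.reason!r}")


@dataclass
class ExclusionLog:
    entries: list[ExclusionEntry] = field(default_factory=list)

    def add(self, species: str, reason: str) -> None:
        self.entries.append(ExclusionEntry(species, reason))

    def extend(self, other: "ExclusionLog") -> None:
        self.entries.extend(other.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def species(self) -> set[str]:
        return {e.species for e in self.entries}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.species, e.reason) for e in self.entries],
            columns=["species", "reason"],
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


class SchemaError(ValueError):
    """A mandatory column is missing from the input table."""


class ValidationError(ValueError):
    """Per-species covariates disagree across rows of the same species."""


def _parse_publication_date(value) -> dt.date | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    text = str(value).strip()
    if not text or text.lower() in {"nan", "na", "none"}:
        return None
    cd = parse_date_text(text)
    return cd.resolved


def _as_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in {"true", "yes", "1", "1.0", "y"}:
        return True
    if text in {"false", "no", "0", "0.0", "n"}:
        return False
    raise ValueError(f"cannot interpret {value!r} as boolean")


def _load_table(path: str | Path, fmt: str | None,
                column_map: dict[str, str] | None,
                sheet: int | str = 0) -> pd.DataFrame:
    path = Path(path)
    if fmt is None:
        fmt = "xlsx" if path.suffix.lower() in {".xlsx", ".xls"} else "csv"
    if fmt == "xlsx":
        df = pd.read_excel(path, sheet_name=sheet)
    elif fmt == "csv":
        df = pd.read_csv(path, dtype={"species": str})
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if column_map:
        df = df.rename(columns=column_map)
    df.columns = [str(c).strip() for c in df.columns]
    return df


def _date_columns(df: pd.DataFrame) -> list[str]:
    """Collection-date columns: the canonical one plus any wide variants."""
    cols = [c for c in df.columns if c == "collection_date_raw"
            or c.startswith("collection_date_raw_")]
    return cols


def read_records(
    path: str | Path,
    fmt: str | None = None,
    column_map: dict[str, str] | None = None,
    sheet: int | str = 0,
) -> tuple[list[TypeSeriesRecord], ExclusionLog]:
    """Ingest a type-series table (CSV or XLSX) into validated records.

    Accepts either the long layout (one row per species x date string) or a
    wide layout with ``collection_date_raw_1..k`` columns.  ``column_map``
    renames input columns to the canonical schema before validation, which
    is how differently-headed supplementary tables are ingested.

    Returns the retained records and an :class:`ExclusionLog`; every input
    species appears in exactly one of the two.
    """
    df = _load_table(path, fmt, column_map, sheet)
    required = {"species", "genus", "region", "publication_date",
                "publication_id", "n_authors", "n_types",
                "n_species_in_paper", "genetics", "genus_richness"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"missing mandatory columns: {sorted(missing)}")
    date_cols = _date_columns(df)
    if not date_cols:
        raise SchemaError("no collection_date_raw column(s) found")
    return records_from_frame(df, date_cols)


def records_from_frame(
    df: pd.DataFrame, date_cols: Sequence[str] = ("collection_date_raw",),
) -> tuple[list[TypeSeriesRecord], ExclusionLog]:
    records: list[TypeSeriesRecord] = []
    log = ExclusionLog()
    for species, group in df.groupby("species", sort=True):
        for col in _COVARIATE_COLUMNS:
            vals = group[col].dropna().astype(str).str.strip().unique() \
                if group[col].dtype == object else group[col].dropna().unique()
            if len(vals) > 1:
                raise ValidationError(
                    f"{species}: inconsistent {col!r} across rows: {vals}")
        row = group.iloc[0]
        try:
            pub = _parse_publication_date(row["publication_date"])
        except DateParseError:
            pub = None
        if pub is None:
            log.add(str(species), "missing_publication_date")
            continue

        raw_dates: list[str] = []
        for col in date_cols:
            for v in group[col].tolist():
                if v is None or (isinstance(v, float) and pd.isna(v)):
                    continue
                text = str(v).strip()
                if text and text.lower() not in {"nan", "na"}:
                    raw_dates.append(text)
        if not raw_dates:
            log.add(str(species), "missing_collection_dates")
            continue
        try:
            events = tuple(parse_date_text(t) for t in raw_dates)
        except DateParseError:
            log.add(str(species), "unparseable_date")
            continue

        if max(e.resolved for e in events) >= pub:
            log.add(str(species), "pub_before_collection")
            continue

        records.append(TypeSeriesRecord(
            species=str(species),
            genus=str(row["genus"]).strip(),
            region=str(row["region"]).strip(),
            publication_date=pub,
            publication_id=str(row["publication_id"]).strip(),
            collection_events=events,
            n_authors=int(row["n_authors"]),
            n_types=int(row["n_types"]),
            n_species_in_paper=int(row["n_species_in_paper"]),
            genetics=_as_bool(row["genetics"]),
            genus_richness=int(row["genus_richness"]),
        ))
    return records, log


def filter_window(
    records: Iterable[TypeSeriesRecord],
    first_year: int = 2000,
    last_year: int = 2023,
) -> tuple[list[TypeSeriesRecord], ExclusionLog]:
    """Retain records whose publication year lies in [first_year, last_year]."""
    if first_year > last_year:
        raise ValueError("first_year must be <= last_year")
    kept: list[TypeSeriesRecord] = []
    log = ExclusionLog()
    for rec in records:
        if first_year <= rec.publication_date.year <= last_year:
            kept.append(rec)
        else:
            log.add(rec.species, "out_of_window")
    return kept, log


def records_to_frame(records: Iterable[TypeSeriesRecord]) -> pd.DataFrame:
    """Long-format canonical table, one row per (species, collection event)."""
    rows = []
    for rec in records:
        for ev in rec.collection_events:
            rows.append({
                "species": rec.species,
                "genus": rec.genus,
                "region": rec.region,
                "publication_date": rec.publication_date.isoformat(),
                "publication_id": rec.publication_id,
                "collection_date_raw": ev.raw_text,
                "n_authors": rec.n_authors,
                "n_types": rec.n_types,
                "n_species_in_paper": rec.n_species_in_paper,
                "genetics": rec.genetics,
                "genus_richness": rec.genus_richness,
            })
    return pd.DataFrame(rows, columns=CANONICAL_COLUMNS)


def write_records(records: Iterable[TypeSeriesRecord],
                  path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def covariate_frame(records: Iterable[TypeSeriesRecord]) -> pd.DataFrame:
    """One row per species with the model covariates (no dates)."""
    rows = [{
        "species": r.species,
        "genus": r.genus,
        "region": r.region,
        "publication_year": r.publication_date.year,
        "publication_id": r.publication_id,
        "n_authors": r.n_authors,
        "n_types": r.n_types,
        "n_species_in_paper": r.n_species_in_paper,
        "genetics": r.genetics,
        "genus_richness": r.genus_richness,
    } for r in records]
    return pd.DataFrame(rows)
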