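"""Readers and writers for the five Snapshot Serengeti table schemas.

The toolkit exchanges data through plain CSV files mirroring the survey's
public data release: raw volunteer classifications (``raw_data.csv``), aggregated
consensus records (``consensus_data.csv``), expert gold-standard labels
(``gold_standard_data.csv``), camera operation dates (``search_effort.csv``)
and the image URL index (``all_images.csv``). Column names and order follow
the published field listings exactly; behaviour flags are written 0/1 and
``Y``/``N`` is accepted on input.

All readers skip ``#``-prefixed provenance comment lines that the CLI may
write atop output tables.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import warnings
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import pandas as pd

from .counts import CountBin
from .vocabulary import BLANK, IMPOSSIBLE, canonical_species

__all__ = [
    "SchemaError",
    "SpeciesAnnotation",
    "ClassificationEvent",
    "ConsensusRecord",
    "GoldRecord",
    "OperationInterval",
    "CaptureMetadata",
    "RAW_COLUMNS",
    "CONSENSUS_COLUMNS",
    "GOLD_COLUMNS",
    "EFFORT_COLUMNS",
    "IMAGE_COLUMNS",
    "read_raw_classifications",
    "write_raw_classifications",
    "read_consensus",
    "write_consensus",
    "read_gold",
    "write_gold",
    "read_effort",
    "write_effort",
    "read_image_index",
    "write_image_index",
]

BEHAVIOURS = ("standing", "resting", "moving", "eating", "interacting")

RAW_COLUMNS = (
    "CaptureEventID",
    "ClassificationID",
    "UserID",
    "Species",
    "Count",
    "Standing",
    "Resting",
    "Moving",
    "Eating",
    "Interacting",
    "Babies",
)

CONSENSUS_COLUMNS = (
    "CaptureEventID",
    "NumImages",
    "DateTime",
    "SiteID",
    "LocationX",
    "LocationY",
    "NumSpecies",
    "Species",
    "Count",
    "Standing",
    "Resting",
    "Moving",
    "Eating",
    "Interacting",
    "Babies",
    "NumClassifications",
    "NumVotes",
    "NumBlanks",
    "Evenness",
)

GOLD_COLUMNS = ("CaptureEventID", "NumSpecies", "Species", "Count")

EFFORT_COLUMNS = ("Site ID", "Start date", "End date")

IMAGE_COLUMNS = ("CaptureEventID", "URL_Info")

DATETIME_FORMAT = "%Y-%m-%d %H:%M:%S"  # local camera time, UTC+3, no DST


class SchemaError(ValueError):
    """A table does not conform to its published schema."""


@dataclasses.dataclass(frozen=True)
class SpeciesAnnotation:
    """One (species, count, behaviours, young) entry within a classification."""

    species: str
    count: CountBin
    standing: bool = False
    resting: bool = False
    moving: bool = False
    eating: bool = False
    interacting: bool = False
    babies: bool = False

    def behaviour(self, name: str) -> bool:
        if name not in BEHAVIOURS:
            raise ValueError(f"unknown behaviour: {name}")
        return getattr(self, name)


@dataclasses.dataclass(frozen=True)
class ClassificationEvent:
    """One volunteer's complete answer for one capture event.

    ``annotations`` is empty exactly when the answer was 'nothing here';
    a non-blank answer may name multiple species (same ClassificationID)
    and may repeat a species before normalization.
    """

    capture_event_id: str
    classification_id: str
    user_id: str
    annotations: tuple[SpeciesAnnotation, ...] = ()

    @property
    def is_blank(self) -> bool:
        return not self.annotations

    @property
    def species_set(self) -> frozenset[str]:
        return frozenset(a.species for a in self.annotations)


@dataclasses.dataclass(frozen=True)
class CaptureMetadata:
    """Site/time metadata carried on every consensus row."""

    capture_event_id: str
    num_images: int = 1
    datetime: _dt.datetime = _dt.datetime(2010, 1, 1)
    site_id: str = ""
    location_x: float = 0.0
    location_y: float = 0.0


@dataclasses.dataclass(frozen=True)
class ConsensusRecord:
    """One aggregated species row of the consensus table.

    Behaviour fields hold the proportion of classifications naming this
    species that flagged the behaviour; ``evenness`` is shared by every
    species row of the same capture event. ``tie`` and ``percent_support``
    are diagnostics outside the published schema and are only written when
    explicitly requested.
    """

    metadata: CaptureMetadata
    num_species: int
    species: str
    count: CountBin
    standing: float
    resting: float
    moving: float
    eating: float
    interacting: float
    babies: float
    num_classifications: int
    num_votes: int
    num_blanks: int
    evenness: float
    tie: bool = False
    percent_support: float = 0.0

    @property
    def capture_event_id(self) -> str:
        return self.metadata.capture_event_id


@dataclasses.dataclass(frozen=True)
class GoldRecord:
    """One expert-adjudicated species row; ``impossible`` has no count."""

    capture_event_id: str
    num_species: int
    species: str
    count: CountBin | None

    @property
    def is_impossible(self) -> bool:
        return self.species == IMPOSSIBLE


@dataclasses.dataclass(frozen=True)
class OperationInterval:
    """Dates a camera was active on one SD card (both ends inclusive)."""

    site_id: str
    start_date: _dt.date
    end_date: _dt.date

    def __post_init__(self) -> None:
        if self.start_date > self.end_date:
            raise SchemaError(
                f"operation interval for site {self.site_id} ends "
                f"({self.end_date}) before it starts ({self.start_date})"
            )


# ---------------------------------------------------------------------------
# parsing helpers

_TRUE = {"1", "y", "yes", "true"}
_FALSE = {"0", "n", "no", "false", ""}


def _parse_flag(value: object, row: int, column: str) -> bool:
    s = str(value).strip().lower()
    if s.endswith(".0"):
        s = s[:-2]
    if s in _TRUE:
        return True
    if s in _FALSE or s == "nan":
        return False
    raise SchemaError(f"row {row}: {column} is not a 0/1 or Y/N flag: {value!r}")


def _read_table(path: str | Path | IO[str], columns: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str, comment="#", keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file, expected header {list(columns)}")
    # Tolerate spacing variants in headers ("SiteID" vs "Site ID").
    wanted = {c.lower().replace(" ", "").replace("_", ""): c for c in columns}
    rename = {}
    for col in df.columns:
        key = col.strip().lower().replace(" ", "").replace("_", "")
        if key in wanted:
            rename[col] = wanted[key]
    df = df.rename(columns=rename)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    return df


def _format_flag(value: bool) -> str:
    return "1" if value else "0"


# ---------------------------------------------------------------------------
# raw classifications

def read_raw_classifications(
    path: str | Path | IO[str],
) -> Iterator[ClassificationEvent]:
    """Stream ClassificationEvents from a raw classification table.

    Rows sharing (CaptureEventID, ClassificationID) are grouped into one
    event, preserving file order; a ``blank`` species row yields a blank
    event. Unknown species labels and malformed counts raise
    :class:`SchemaError` naming the offending row.
    """
    df = _read_table(path, RAW_COLUMNS)
    current_key: tuple[str, str] | None = None
    current_rows: list[tuple[int, pd.Series]] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        key = (row.CaptureEventID, row.ClassificationID)
        if key != current_key:
            if current_key is not None:
                yield _build_event(current_key, current_rows)
            current_key = key
            current_rows = []
        current_rows.append((idx, row))
    if current_key is not None:
        yield _build_event(current_key, current_rows)


def _build_event(
    key: tuple[str, str], rows: list[tuple[int, object]]
) -> ClassificationEvent:
    capture_event_id, classification_id = key
    user_id = rows[0][1].UserID
    annotations: list[SpeciesAnnotation] = []
    saw_blank = False
    for idx, row in rows:
        try:
            species = canonical_species(row.Species, allow_blank=True)
        except ValueError as exc:
            raise SchemaError(f"row {idx}: {exc}") from exc
        if species == BLANK:
            saw_blank = True
            # A 'nothing here' answer carries no count or behaviours.
            stray = [
                col
                for col, val in zip(RAW_COLUMNS[4:], row[4:])
                if str(val).strip() not in ("", "0", "nan", "N", "n")
            ]
            if stray:
                warnings.warn(
                    f"row {idx}: blank classification carries values in "
                    f"{stray}; ignored",
                    stacklevel=3,
                )
            continue
        try:
            count = CountBin.parse(row.Count)
        except ValueError as exc:
            raise SchemaError(f"row {idx}: {exc}") from exc
        annotations.append(
            SpeciesAnnotation(
                species=species,
                count=count,
                standing=_parse_flag(row.Standing, idx, "Standing"),
                resting=_parse_flag(row.Resting, idx, "Resting"),
                moving=_parse_flag(row.Moving, idx, "Moving"),
                eating=_parse_flag(row.Eating, idx, "Eating"),
                interacting=_parse_flag(row.Interacting, idx, "Interacting"),
                babies=_parse_flag(row.Babies, idx, "Babies"),
            )
        )
    if saw_blank and annotations:
        raise SchemaError(
            f"classification {classification_id}: mixes 'blank' with species rows"
        )
    return ClassificationEvent(
        capture_event_id=capture_event_id,
        classification_id=classification_id,
        user_id=user_id,
        annotations=tuple(annotations),
    )


def write_raw_classifications(
    events: Iterable[ClassificationEvent], path: str | Path | IO[str]
) -> None:
    """Write events in the raw table schema (one row per species, blank
    events as a single ``blank`` row with empty payload columns)."""
    rows = []
    for ev in events:
        if ev.is_blank:
            rows.append(
                (ev.capture_event_id, ev.classification_id, ev.user_id, BLANK)
                + ("",) * 7
            )
        else:
            for a in ev.annotations:
                rows.append(
                    (
                        ev.capture_event_id,
                        ev.classification_id,
                        ev.user_id,
                        a.species,
                        a.count.label,
                        _format_flag(a.standing),
                        _format_flag(a.resting),
                        _format_flag(a.moving),
                        _format_flag(a.eating),
                        _format_flag(a.interacting),
                        _format_flag(a.babies),
                    )
                )
    pd.DataFrame(rows, columns=list(RAW_COLUMNS)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# consensus table

def write_consensus(
    records: Iterable[ConsensusRecord],
    path: str | Path | IO[str],
    *,
    diagnostics: bool = False,
) -> None:
    """Write consensus records, one row per (capture event, species).

    With ``diagnostics=True`` two extra columns (``Tie``,
    ``PercentSupport``) are appended after the published schema.
    """
    rows = []
    for r in records:
        m = r.metadata
        row = [
            m.capture_event_id,
            m.num_images,
            m.datetime.strftime(DATETIME_FORMAT),
            m.site_id,
            repr(m.location_x),
            repr(m.location_y),
            r.num_species,
            r.species,
            r.count.label,
            repr(r.standing),
            repr(r.resting),
            repr(r.moving),
            repr(r.eating),
            repr(r.interacting),
            repr(r.babies),
            r.num_classifications,
            r.num_votes,
            r.num_blanks,
            repr(r.evenness),
        ]
        if diagnostics:
            row += [_format_flag(r.tie), repr(r.percent_support)]
        rows.append(row)
    columns = list(CONSENSUS_COLUMNS)
    if diagnostics:
        columns += ["Tie", "PercentSupport"]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def read_consensus(path: str | Path | IO[str]) -> list[ConsensusRecord]:
    """Read a consensus table back into records (diagnostic columns, if
    present, are restored; otherwise they default)."""
    df = _read_table(path, CONSENSUS_COLUMNS)
    records: list[ConsensusRecord] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        try:
            species = canonical_species(row.Species)
            meta = CaptureMetadata(
                capture_event_id=row.CaptureEventID,
                num_images=int(row.NumImages),
                datetime=_dt.datetime.strptime(row.DateTime, DATETIME_FORMAT),
                site_id=row.SiteID,
                location_x=float(row.LocationX),
                location_y=float(row.LocationY),
            )
            records.append(
                ConsensusRecord(
                    metadata=meta,
                    num_species=int(row.NumSpecies),
                    species=species,
                    count=CountBin.parse(row.Count),
                    standing=float(row.Standing),
                    resting=float(row.Resting),
                    moving=float(row.Moving),
                    eating=float(row.Eating),
                    interacting=float(row.Interacting),
                    babies=float(row.Babies),
                    num_classifications=int(row.NumClassifications),
                    num_votes=int(row.NumVotes),
                    num_blanks=int(row.NumBlanks),
                    evenness=float(row.Evenness),
                    tie=_parse_flag(getattr(row, "Tie", "0"), idx, "Tie"),
                    percent_support=float(getattr(row, "PercentSupport", 0.0)),
                )
            )
        except (ValueError, SchemaError) as exc:
            raise SchemaError(f"row {idx}: {exc}") from exc
    return records


# ---------------------------------------------------------------------------
# gold standard

def read_gold(path: str | Path | IO[str]) -> list[GoldRecord]:
    """Read expert gold-standard labels.

    ``impossible`` rows have no count and must be the only row for their
    capture event.
    """
    df = _read_table(path, GOLD_COLUMNS)
    records: list[GoldRecord] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        try:
            species = canonical_species(row.Species, allow_impossible=True)
        except ValueError as exc:
            raise SchemaError(f"row {idx}: {exc}") from exc
        if species == IMPOSSIBLE:
            count = None
        else:
            try:
                count = CountBin.parse(row.Count)
            except ValueError as exc:
                raise SchemaError(f"row {idx}: {exc}") from exc
        records.append(
            GoldRecord(
                capture_event_id=row.CaptureEventID,
                num_species=int(row.NumSpecies),
                species=species,
                count=count,
            )
        )
    by_event: dict[str, list[GoldRecord]] = {}
    for r in records:
        by_event.setdefault(r.capture_event_id, []).append(r)
    for event_id, rows in by_event.items():
        if any(r.is_impossible for r in rows) and len(rows) > 1:
            raise SchemaError(
                f"event {event_id}: 'impossible' must be its only gold row"
            )
    return records


def write_gold(records: Iterable[GoldRecord], path: str | Path | IO[str]) -> None:
    rows = [
        (
            r.capture_event_id,
            r.num_species,
            r.species,
            "" if r.count is None else r.count.label,
        )
        for r in records
    ]
    pd.DataFrame(rows, columns=list(GOLD_COLUMNS)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# search effort

def read_effort(path: str | Path | IO[str]) -> list[OperationInterval]:
    df = _read_table(path, EFFORT_COLUMNS)
    intervals = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        site, start, end = row
        try:
            intervals.append(
                OperationInterval(
                    site_id=site,
                    start_date=_dt.date.fromisoformat(start.strip()),
                    end_date=_dt.date.fromisoformat(end.strip()),
                )
            )
        except (ValueError, SchemaError) as exc:
            raise SchemaError(f"row {idx}: {exc}") from exc
    return intervals


def write_effort(
    intervals: Iterable[OperationInterval], path: str | Path | IO[str]
) -> None:
    rows = [
        (i.site_id, i.start_date.isoformat(), i.end_date.isoformat())
        for i in intervals
    ]
    pd.DataFrame(rows, columns=list(EFFORT_COLUMNS)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# image index

def read_image_index(path: str | Path | IO[str]) -> list[tuple[str, str]]:
    """(capture_event_id, URL suffix) pairs; suffixes are kept verbatim for
    appending to a configured base URL."""
    df = _read_table(path, IMAGE_COLUMNS)
    return [(row.CaptureEventID, row.URL_Info) for row in df.itertuples(index=False)]


def write_image_index(
    pairs: Iterable[tuple[str, str]], path: str | Path | IO[str]
) -> None:
    pd.DataFrame(list(pairs), columns=list(IMAGE_COLUMNS)).to_csv(path, index=False)
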