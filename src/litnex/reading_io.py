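"""Ingest machine-reading output into an extracted event set (EES).

Reading engines emit one row per extracted event: a directed, signed
interaction between a regulator entity and a regulated entity, together with
the source paper and the evidence sentence. The same interaction is typically
extracted from many papers (and sometimes several times from one paper), so
the tabular output is grouped here into *distinct events*, each carrying its
occurrence count ``f_i`` and the set of supporting papers. The grouped
collection — the extracted event set — is the unit every downstream stage
(collaboration graph, clustering, selection) consumes.

Event identity is the triple (regulator key, regulated key, sign). The
interaction subtype reported by the reader (phosphorylation, transcription,
amount/activity change, ...) is deliberately *not* part of identity: the
downstream graph semantics only use signed influence.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from ._canon import NEGATIVE, POSITIVE, EventKey, canonical_key, normalize_name

__all__ = [
    "EntityRef",
    "EventRecord",
    "Event",
    "EES",
    "ParseReport",
    "ReadingConfigError",
    "DEFAULT_READING_COLUMNS",
    "parse_reading_table",
    "build_ees",
    "write_ees",
    "write_parse_report",
    "flag_model_overlap",
]

#: Logical field -> default column header (tabular reader-output layout).
DEFAULT_READING_COLUMNS: dict[str, str] = {
    "regulator_name": "Regulator Name",
    "regulator_type": "Regulator Type",
    "regulator_id": "Regulator ID",
    "regulated_name": "Regulated Name",
    "regulated_type": "Regulated Type",
    "regulated_id": "Regulated ID",
    "sign": "Interaction",
    "paper_id": "Paper ID",
    "evidence": "Evidence",
}

#: Columns that must be present in the input table.
MANDATORY_FIELDS = ("regulator_name", "regulated_name", "sign", "paper_id")

#: Sign lexicon: the readers' interaction vocabulary mapped onto {+, -}.
SIGN_LEXICON: dict[str, str] = {
    "increases": POSITIVE,
    "activates": POSITIVE,
    "positive": POSITIVE,
    "+": POSITIVE,
    "decreases": NEGATIVE,
    "inhibits": NEGATIVE,
    "negative": NEGATIVE,
    "-": NEGATIVE,
}


class ReadingConfigError(ValueError):
    """A required column is missing from the reading table."""


@dataclass(frozen=True)
class EntityRef:
    """A participant of an extracted event (protein, gene, chemical, ...)."""

    name: str
    type: str = "other"
    db_id: str = ""

    @property
    def key(self) -> str:
        return canonical_key(self.name, self.db_id)


@dataclass(frozen=True)
class EventRecord:
    """One reading-table row: a single extraction of a signed interaction."""

    regulator: EntityRef
    regulated: EntityRef
    sign: str
    paper_id: str
    evidence: str = ""

    @property
    def key(self) -> EventKey:
        return (self.regulator.key, self.regulated.key, self.sign)


@dataclass(frozen=True)
class Event:
    """A distinct interaction with its literature support.

    ``f_i`` counts occurrences (rows), while ``papers`` is a set: duplicate
    sentences within one paper raise ``f_i`` but not the paper count, so
    co-occurrence statistics downstream stay per-paper.
    """

    key: EventKey
    records: tuple[EventRecord, ...]

    @property
    def f_i(self) -> int:
        return len(self.records)

    @property
    def papers(self) -> frozenset[str]:
        return frozenset(r.paper_id for r in self.records)

    @property
    def regulator(self) -> EntityRef:
        return self.records[0].regulator

    @property
    def regulated(self) -> EntityRef:
        return self.records[0].regulated


@dataclass
class EES:
    """Extracted event set: all distinct events with occurrence counts."""

    events: dict[EventKey, Event] = field(default_factory=dict)

    @property
    def N(self) -> int:
        """Total number of event occurrences."""
        return sum(e.f_i for e in self.events.values())

    @property
    def M(self) -> int:
        """Number of distinct events."""
        return len(self.events)

    @property
    def f_max(self) -> int:
        if not self.events:
            return 0
        return max(e.f_i for e in self.events.values())

    def entity_name(self, key: str) -> str:
        """Display name for a canonical entity key (first occurrence wins)."""
        return self._entity_names().get(key, key)

    def entity_type(self, key: str) -> str:
        return self._entity_types().get(key, "other")

    def entity_keys(self) -> set[str]:
        ks: set[str] = set()
        for reg_key, tgt_key, _ in self.events:
            ks.add(reg_key)
            ks.add(tgt_key)
        return ks

    def _entity_names(self) -> dict[str, str]:
        names: dict[str, str] = {}
        for ev in self.events.values():
            for ent in (ev.regulator, ev.regulated):
                names.setdefault(ent.key, normalize_name(ent.name))
        return names

    def _entity_types(self) -> dict[str, str]:
        types: dict[str, str] = {}
        for ev in self.events.values():
            for ent in (ev.regulator, ev.regulated):
                types.setdefault(ent.key, ent.type)
        return types


@dataclass
class ParseReport:
    rows_read: int = 0
    records_kept: int = 0
    rows_dropped: int = 0
    drop_reasons: Counter = field(default_factory=Counter)
    flagged_model_edges: list[EventKey] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "rows_read": self.rows_read,
            "records_kept": self.records_kept,
            "rows_dropped": self.rows_dropped,
            "drop_reasons": dict(self.drop_reasons),
            "flagged_model_edges": [list(k) for k in self.flagged_model_edges],
        }


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".xlsx", ".xls"}:
        return pd.read_excel(path, dtype=str, keep_default_na=False)
    sep = "," if suffix == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def parse_reading_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> tuple[list[EventRecord], ParseReport]:
    """Parse a reading-output table into event records.

    Parameters
    ----------
    path
        TSV/CSV/XLSX file with one extracted event per row.
    column_map
        Logical field -> column header, overriding ``DEFAULT_READING_COLUMNS``
        entry-wise.

    Returns
    -------
    records, report
        Normalized records, and a report counting dropped rows by reason
        (missing entity name, unknown sign token, missing paper id).
    """
    cols = dict(DEFAULT_READING_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = _read_table(path)
    for fld in MANDATORY_FIELDS:
        if cols[fld] not in df.columns:
            raise ReadingConfigError(
                f"reading table is missing mandatory column {cols[fld]!r} "
                f"(logical field {fld!r})"
            )

    def get(row, fld: str) -> str:
        col = cols[fld]
        return str(row[col]).strip() if col in df.columns else ""

    report = ParseReport(rows_read=len(df))
    records: list[EventRecord] = []
    for _, row in df.iterrows():
        reg_name = normalize_name(get(row, "regulator_name"))
        tgt_name = normalize_name(get(row, "regulated_name"))
        if not reg_name or not tgt_name:
            report.drop_reasons["empty entity name"] += 1
            continue
        paper = get(row, "paper_id")
        if not paper:
            report.drop_reasons["empty paper id"] += 1
            continue
        sign_tok = get(row, "sign").casefold()
        sign = SIGN_LEXICON.get(sign_tok)
        if sign is None:
            report.drop_reasons[f"unknown sign token: {sign_tok!r}"] += 1
            continue
        records.append(
            EventRecord(
                regulator=EntityRef(reg_name, get(row, "regulator_type") or "other",
                                    get(row, "regulator_id")),
                regulated=EntityRef(tgt_name, get(row, "regulated_type") or "other",
                                    get(row, "regulated_id")),
                sign=sign,
                paper_id=paper,
                evidence=get(row, "evidence"),
            )
        )
    report.records_kept = len(records)
    report.rows_dropped = report.rows_read - report.records_kept
    return records, report


def build_ees(records: Iterable[EventRecord]) -> EES:
    """Group records by event identity into an extracted event set.

    Order-independent: records are grouped by key and stored in a canonical
    (key-sorted, then paper/evidence-sorted) order.
    """
    grouped: dict[EventKey, list[EventRecord]] = {}
    for rec in records:
        grouped.setdefault(rec.key, []).append(rec)
    events = {
        key: Event(key=key, records=tuple(
            sorted(rs, key=lambda r: (r.paper_id, r.evidence))))
        for key, rs in sorted(grouped.items())
    }
    return EES(events=events)


def write_ees(ees: EES, path: str | Path) -> None:
    """Write the normalized EES back out in the reading-table layout."""
    rows = []
    for ev in ees.events.values():
        for rec in ev.records:
            rows.append({
                "Regulator Name": rec.regulator.name,
                "Regulator Type": rec.regulator.type,
                "Regulator ID": rec.regulator.db_id,
                "Regulated Name": rec.regulated.name,
                "Regulated Type": rec.regulated.type,
                "Regulated ID": rec.regulated.db_id,
                "Interaction": "increases" if rec.sign == POSITIVE else "decreases",
                "Paper ID": rec.paper_id,
                "Evidence": rec.evidence,
            })
    df = pd.DataFrame(rows, columns=list(DEFAULT_READING_COLUMNS.values()))
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df.to_csv(path, sep=sep, index=False)


def write_parse_report(report: ParseReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2))


def flag_model_overlap(ees: EES, model_edges: set[EventKey]) -> list[EventKey]:
    """Events identical to an existing model edge (flagged, never removed)."""
    return sorted(k for k in ees.events if k in model_edges)
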