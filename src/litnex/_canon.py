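"""Canonical entity keys shared by the reading-table and model parsers.

Entities coming from machine readers and from hand-built model tables must be
compared with one key convention, otherwise node overlap and evaluation compare
apples with oranges. The rule: the database identifier wins when present
(names are unstable across readers); otherwise the case-folded,
whitespace-collapsed name.
"""

from __future__ import annotations

POSITIVE = "+"
NEGATIVE = "-"
SIGNS = (POSITIVE, NEGATIVE)

#: Event key: (regulator canonical key, regulated canonical key, sign).
EventKey = tuple[str, str, str]


def normalize_name(name: str) -> str:
    """Collapse internal whitespace and strip the ends of a label."""
    return " ".join(str(name).split())


def fold_name(name: str) -> str:
    return normalize_name(name).casefold()


def canonical_key(name: str, db_id: str = "") -> str:
    """Canonical key for an entity: db_id if non-empty, else the folded name."""
    db_id = str(db_id).strip()
    if db_id:
        return db_id
    return fold_name(name)
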