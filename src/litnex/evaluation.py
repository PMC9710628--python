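"""Precision/recall of a selected extension against a gold-standard model.

Scores answer two questions: of the events (entities) the pipeline selected,
how many are in the gold model (precision); and of the gold events (entities)
the pipeline *could possibly have found* — those present in the extracted
event set and absent from the baseline — how many were selected (recall).
Gold content that never appeared in the reading output is excluded from the
recall denominator: a reader-miss is not a selection-miss.

Events are matched as (regulator key, regulated key, sign) triples; a
sign-agnostic mode is available for readers with unreliable polarity.
Baseline edges and elements are excluded from the selected sets, since they
are not extensions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from ._canon import EventKey
from .model_io import ModelGraph
from .reading_io import EES

__all__ = ["EvalReport", "evaluate"]


@dataclass
class EvalReport:
    entity_precision: float | None
    event_precision: float | None
    entity_recall: float
    event_recall: float
    tp_events: set = field(default_factory=set)
    fp_events: set = field(default_factory=set)
    fn_events: set = field(default_factory=set)
    tp_entities: set = field(default_factory=set)
    fp_entities: set = field(default_factory=set)
    fn_entities: set = field(default_factory=set)

    def to_dict(self) -> dict:
        return {
            "entity_precision": self.entity_precision,
            "event_precision": self.event_precision,
            "entity_recall": self.entity_recall,
            "event_recall": self.event_recall,
            "tp_events": sorted(map(list, self.tp_events)),
            "fp_events": sorted(map(list, self.fp_events)),
            "fn_events": sorted(map(list, self.fn_events)),
            "tp_entities": sorted(self.tp_entities),
            "fp_entities": sorted(self.fp_entities),
            "fn_entities": sorted(self.fn_entities),
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def summary(self) -> str:
        def fmt(x):
            return "n/a" if x is None else f"{x:.3f}"
        return (
            f"entity precision {fmt(self.entity_precision)}  "
            f"event precision {fmt(self.event_precision)}  "
            f"entity recall {fmt(self.entity_recall)}  "
            f"event recall {fmt(self.event_recall)}"
        )


def _unsigned(keys: set[EventKey]) -> set[tuple[str, str]]:
    return {(s, d) for s, d, _ in keys}


def evaluate(
    selected_events: set[EventKey],
    gold: ModelGraph,
    baseline: ModelGraph,
    ees: EES,
    sign_sensitive: bool = True,
) -> EvalReport:
    """Score selected extension events against the gold model.

    ``selected_events`` is typically ``ExtensionResult.merged_events``.
    """
    ees_events = set(ees.events)
    ees_entities = ees.entity_keys()

    sel_events = {k for k in selected_events if k not in baseline.E_BM}
    gold_events = set(gold.E_BM)
    recoverable_events = {
        k for k in gold_events if k in ees_events and k not in baseline.E_BM}
    if sign_sensitive:
        tp_events = sel_events & gold_events
    else:
        gold_u = _unsigned(gold_events)
        tp_events = {k for k in sel_events if (k[0], k[1]) in gold_u}
        recoverable_events = {
            k for k in gold_events
            if (k[0], k[1]) in _unsigned(ees_events) and k not in baseline.E_BM}
    fp_events = sel_events - tp_events
    if sign_sensitive:
        fn_events = recoverable_events - sel_events
    else:
        sel_u = _unsigned(sel_events)
        fn_events = {k for k in recoverable_events if (k[0], k[1]) not in sel_u}

    sel_entities = ({s for s, _, _ in sel_events} | {d for _, d, _ in sel_events}) \
        - baseline.V_BM
    recoverable_entities = (gold.V_BM & ees_entities) - baseline.V_BM
    tp_entities = sel_entities & gold.V_BM
    fp_entities = sel_entities - gold.V_BM
    fn_entities = recoverable_entities - sel_entities

    def precision(tp: set, sel: set) -> float | None:
        return len(tp) / len(sel) if sel else None

    def recall(tp_count: int, denom: set) -> float:
        # vacuous case: nothing was recoverable, so nothing was missed
        if not denom:
            return 1.0 if (sel_events or sel_entities) else 0.0
        return tp_count / len(denom)

    return EvalReport(
        entity_precision=precision(tp_entities, sel_entities),
        event_precision=precision(tp_events, sel_events),
        entity_recall=recall(len(recoverable_entities - fn_entities), recoverable_entities),
        event_recall=recall(len(recoverable_events - fn_events), recoverable_events),
        tp_events=tp_events, fp_events=fp_events, fn_events=fn_events,
        tp_entities=tp_entities, fp_entities=fp_entities, fn_entities=fn_entities,
    )
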