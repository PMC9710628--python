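"""Element-table model I/O and the directed signed graph view.

Models are stored one element per row with its positive and negative
regulator expressions (influence sets). The expression grammar uses '!' for
logical NOT, '()' for AND grouping and ',' for OR. Only the *influence
structure* is needed here — which regulator influences which element with
which sign — so expressions are tokenized on the operator characters and
otherwise preserved verbatim for round-tripping. A '!'-prefixed token inside
a positive-regulator expression contributes a negative edge (and vice versa).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from ._canon import NEGATIVE, POSITIVE, EventKey, canonical_key, fold_name, normalize_name

__all__ = [
    "ModelElement",
    "ModelGraph",
    "ModelParseError",
    "DEFAULT_MODEL_COLUMNS",
    "tokenize_influence",
    "parse_model",
    "write_model",
    "write_model_graphml",
    "model_from_edges",
]

DEFAULT_MODEL_COLUMNS: dict[str, str] = {
    "name": "Element Name",
    "type": "Element Type",
    "db_id": "Element IDs",
    "variable": "Variable",
    "pos_expr": "Positive Regulators",
    "neg_expr": "Negative Regulators",
    "evidence": "Evidence",
}

_OPERATORS = set("!(),")


class ModelParseError(ValueError):
    """Malformed element table or influence expression."""


@dataclass
class ModelElement:
    name: str
    type: str = "other"
    db_id: str = ""
    variable: str = ""
    pos_expr: str = ""
    neg_expr: str = ""
    evidence: str = ""

    @property
    def key(self) -> str:
        return canonical_key(self.name, self.db_id)


def tokenize_influence(expr: str, row_id: str = "?") -> list[tuple[str, bool]]:
    """Split an influence expression into (token, negated) pairs.

    The grammar's operators { '!', '(', ')', ',' } delimit tokens; '!'
    negates the token it prefixes. Raises on unbalanced parentheses.
    """
    tokens: list[tuple[str, bool]] = []
    buf: list[str] = []
    negate = False
    depth = 0

    def flush() -> None:
        nonlocal negate
        tok = normalize_name("".join(buf))
        buf.clear()
        if tok:
            tokens.append((tok, negate))
        negate = False

    for ch in str(expr):
        if ch == "!":
            flush()
            negate = True
        elif ch == "(":
            flush()
            depth += 1
        elif ch == ")":
            flush()
            depth -= 1
            if depth < 0:
                raise ModelParseError(f"unbalanced parentheses in row {row_id!r}: {expr!r}")
        elif ch == ",":
            flush()
        else:
            buf.append(ch)
    flush()
    if depth != 0:
        raise ModelParseError(f"unbalanced parentheses in row {row_id!r}: {expr!r}")
    return tokens


class ModelGraph:
    """A model as elements plus the directed signed edges they imply.

    Edges are derived from the regulator expressions: token T in the positive
    expression of element v gives edge (T, v, '+'), in the negative expression
    (T, v, '-'), with '!' flipping the sign in either. Regulator names with no
    element row of their own become implicit elements so every edge endpoint
    is a model node.
    """

    def __init__(self, elements: Iterable[ModelElement]):
        self.elements: dict[str, ModelElement] = {}
        seen_vars: set[str] = set()
        for el in elements:
            if not normalize_name(el.name):
                raise ModelParseError("model element with empty name")
            var = el.variable.strip()
            if var:
                if var in seen_vars:
                    raise ModelParseError(f"duplicate variable {var!r}")
                seen_vars.add(var)
            key = el.key
            if key in self.elements:
                raise ModelParseError(f"duplicate element key {key!r} ({el.name!r})")
            self.elements[key] = el
        self._name_to_key = {fold_name(el.name): k for k, el in self.elements.items()}
        for k, el in self.elements.items():
            if el.variable.strip():
                self._name_to_key.setdefault(fold_name(el.variable), k)
        self.E_BM: set[EventKey] = set()
        self._derive_edges()

    # -- construction helpers -------------------------------------------------

    def _resolve(self, token: str) -> str:
        key = self._name_to_key.get(fold_name(token))
        if key is None:
            el = ModelElement(name=normalize_name(token))
            key = el.key
            self.elements[key] = el
            self._name_to_key[fold_name(token)] = key
        return key

    def _derive_edges(self) -> None:
        for key, el in list(self.elements.items()):
            for expr, base in ((el.pos_expr, POSITIVE), (el.neg_expr, NEGATIVE)):
                for tok, negated in tokenize_influence(expr, row_id=el.name):
                    sign = base
                    if negated:
                        sign = NEGATIVE if base == POSITIVE else POSITIVE
                    self.E_BM.add((self._resolve(tok), key, sign))

    # -- public surface -------------------------------------------------------

    @property
    def V_BM(self) -> set[str]:
        return set(self.elements)

    def element_name(self, key: str) -> str:
        return self.elements[key].name

    def copy(self) -> "ModelGraph":
        return copy.deepcopy(self)

    def add_element(self, el: ModelElement, key: str | None = None) -> str:
        """Register an element, optionally under an explicit canonical key
        (used when a renamed extension element must keep the entity's key)."""
        key = key or el.key
        if key not in self.elements:
            self.elements[key] = replace(el)
            self._name_to_key[fold_name(el.name)] = key
        return key

    def add_edge(self, src_key: str, dst_key: str, sign: str) -> bool:
        """Add a signed influence edge, appending the regulator name to the
        matching expression of the target element. Returns False if already
        present."""
        if (src_key, dst_key, sign) in self.E_BM:
            return False
        if src_key not in self.elements or dst_key not in self.elements:
            raise KeyError("both endpoints must be model elements before adding an edge")
        dst = self.elements[dst_key]
        token = self.elements[src_key].name
        if sign == POSITIVE:
            dst.pos_expr = f"{dst.pos_expr}, {token}" if dst.pos_expr.strip() else token
        else:
            dst.neg_expr = f"{dst.neg_expr}, {token}" if dst.neg_expr.strip() else token
        self.E_BM.add((src_key, dst_key, sign))
        return True

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for key, el in self.elements.items():
            g.add_node(key, name=el.name, type=el.type)
        for src, dst, sign in self.E_BM:
            g.add_edge(src, dst, sign=sign)
        return g


def parse_model(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> ModelGraph:
    """Read an element table (TSV/CSV/XLSX) into a ModelGraph."""
    cols = dict(DEFAULT_MODEL_COLUMNS)
    if column_map:
        cols.update(column_map)
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".xlsx", ".xls"}:
        df = pd.read_excel(path, dtype=str, keep_default_na=False)
    else:
        df = pd.read_csv(path, sep="," if suffix == ".csv" else "\t",
                         dtype=str, keep_default_na=False)
    if cols["name"] not in df.columns:
        raise ModelParseError(f"model table is missing column {cols['name']!r}")
    elements = []
    for _, row in df.iterrows():
        def get(fld: str) -> str:
            col = cols[fld]
            return str(row[col]).strip() if col in df.columns else ""
        if not get("name"):
            continue
        elements.append(ModelElement(
            name=normalize_name(get("name")),
            type=get("type") or "other",
            db_id=get("db_id"),
            variable=get("variable"),
            pos_expr=get("pos_expr"),
            neg_expr=get("neg_expr"),
            evidence=get("evidence"),
        ))
    if not elements:
        raise ModelParseError("model has no elements")
    return ModelGraph(elements)


def write_model(model: ModelGraph, path: str | Path) -> None:
    """Write the element table back out (expressions verbatim)."""
    rows = [{
        "Element Name": el.name,
        "Element Type": el.type,
        "Element IDs": el.db_id,
        "Variable": el.variable,
        "Positive Regulators": el.pos_expr,
        "Negative Regulators": el.neg_expr,
        "Evidence": el.evidence,
    } for el in model.elements.values()]
    df = pd.DataFrame(rows, columns=list(DEFAULT_MODEL_COLUMNS.values()))
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        df.to_excel(path, index=False)
    else:
        df.to_csv(path, sep="," if path.suffix.lower() == ".csv" else "\t", index=False)


def write_model_graphml(model: ModelGraph, path: str | Path) -> None:
    nx.write_graphml(model.to_digraph(), str(path))


def model_from_edges(
    edges: Iterable[tuple[str, str, str]],
    types: Mapping[str, str] | None = None,
) -> ModelGraph:
    """Build a ModelGraph from (regulator name, regulated name, sign) triples.

    Convenience for synthetic models and tests; expressions are flat
    OR-lists of the regulators.
    """
    types = dict(types or {})
    pos: dict[str, list[str]] = {}
    neg: dict[str, list[str]] = {}
    names: dict[str, None] = {}
    for src, dst, sign in edges:
        names.setdefault(src)
        names.setdefault(dst)
        (pos if sign == POSITIVE else neg).setdefault(dst, []).append(src)
    elements = [
        ModelElement(
            name=n,
            type=types.get(n, "protein"),
            variable=n,
            pos_expr=", ".join(pos.get(n, [])),
            neg_expr=", ".join(neg.get(n, [])),
        )
        for n in names
    ]
    return ModelGraph(elements)
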