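"""A small, total selection language over site-table fields.

Expressions combine field comparisons with boolean operators, e.g.::

    polarity_class == phosphate
    residue_name == RHL and chain_label in {guest_chain1, guest_chain2}
    not (site_name == W) or molecule_id == 3

Supported fields: ``site_name``, ``residue_name``, ``polarity_class``,
``chain_label``, ``molecule_id``, ``chain_position``.  The literals
``all`` and ``none`` select everything / nothing.  Parsing is total:
every string either yields an index set or raises
:class:`SelectionSyntaxError` with the offending position.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Union

import numpy as np

from .core import BilayerError, SiteTable

STRING_FIELDS = {"site_name", "residue_name", "polarity_class", "chain_label"}
INT_FIELDS = {"molecule_id", "chain_position"}
FIELDS = STRING_FIELDS | INT_FIELDS


class SelectionSyntaxError(BilayerError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


_TOKEN_RE = re.compile(
    r"\s*(?:(?P<op>==|!=|\(|\)|\{|\}|,)|(?P<word>[A-Za-z0-9_.\-]+))"
)


def _tokenize(text: str):
    tokens = []  # (kind, value, position)
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == pos:
            stripped = text[pos:].lstrip()
            if not stripped:
                break
            raise SelectionSyntaxError(
                f"unexpected character {stripped[0]!r}", len(text) - len(stripped)
            )
        if m.group("op"):
            tokens.append(("op", m.group("op"), m.start("op")))
        else:
            tokens.append(("word", m.group("word"), m.start("word")))
        pos = m.end()
    tokens.append(("end", "", len(text)))
    return tokens


# --- AST -------------------------------------------------------------------

@dataclass(frozen=True)
class _Cmp:
    field: str
    op: str  # "==", "!=", "in"
    values: tuple

    def evaluate(self, table: SiteTable) -> np.ndarray:
        col = table.df[self.field]
        if self.field in INT_FIELDS:
            arr = np.asarray(col.astype("float"))
            vals = np.array([float(v) for v in self.values])
        else:
            arr = np.asarray(col.astype("object").where(col.notna(), "").astype(str))
            vals = np.array([str(v) for v in self.values], dtype=object)
        mask = np.isin(arr, vals)
        if self.op == "!=":
            mask = ~mask
        return mask


@dataclass(frozen=True)
class _Bool:
    op: str  # "and", "or", "not", "all", "none"
    args: tuple

    def evaluate(self, table: SiteTable) -> np.ndarray:
        n = len(table)
        if self.op == "all":
            return np.ones(n, dtype=bool)
        if self.op == "none":
            return np.zeros(n, dtype=bool)
        masks = [a.evaluate(table) for a in self.args]
        if self.op == "not":
            return ~masks[0]
        out = masks[0]
        for m in masks[1:]:
            out = (out & m) if self.op == "and" else (out | m)
        return out


_Node = Union[_Cmp, _Bool]


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self):
        return self.tokens[self.i]

    def advance(self):
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect(self, kind, value=None):
        k, v, p = self.peek()
        if k != kind or (value is not None and v != value):
            want = value if value is not None else kind
            raise SelectionSyntaxError(f"expected {want!r}, found {v or 'end'!r}", p)
        return self.advance()

    def parse(self) -> _Node:
        node = self.parse_or()
        k, v, p = self.peek()
        if k != "end":
            raise SelectionSyntaxError(f"unexpected trailing input {v!r}", p)
        return node

    def parse_or(self) -> _Node:
        args = [self.parse_and()]
        while self.peek()[:2] == ("word", "or"):
            self.advance()
            args.append(self.parse_and())
        return args[0] if len(args) == 1 else _Bool("or", tuple(args))

    def parse_and(self) -> _Node:
        args = [self.parse_unary()]
        while self.peek()[:2] == ("word", "and"):
            self.advance()
            args.append(self.parse_unary())
        return args[0] if len(args) == 1 else _Bool("and", tuple(args))

    def parse_unary(self) -> _Node:
        k, v, p = self.peek()
        if (k, v) == ("word", "not"):
            self.advance()
            return _Bool("not", (self.parse_unary(),))
        if (k, v) == ("op", "("):
            self.advance()
            node = self.parse_or()
            self.expect("op", ")")
            return node
        return self.parse_comparison()

    def parse_comparison(self) -> _Node:
        k, v, p = self.peek()
        if k != "word":
            raise SelectionSyntaxError(f"expected a field name, found {v or 'end'!r}", p)
        if v in ("all", "none"):
            self.advance()
            return _Bool(v, ())
        if v not in FIELDS:
            raise SelectionSyntaxError(
                f"unknown field {v!r} (known: {', '.join(sorted(FIELDS))})", p
            )
        self.advance()
        k2, op, p2 = self.advance()
        if (k2, op) == ("word", "in"):
            self.expect("op", "{")
            values = [self._value_token(v)]
            while self.peek()[:2] == ("op", ","):
                self.advance()
                values.append(self._value_token(v))
            self.expect("op", "}")
            return _Cmp(v, "in", tuple(values))
        if k2 == "op" and op in ("==", "!="):
            return _Cmp(v, op, (self._value_token(v),))
        raise SelectionSyntaxError(f"expected '==', '!=' or 'in' after {v!r}", p2)

    def _value_token(self, fieldname: str):
        k, v, p = self.advance()
        if k != "word":
            raise SelectionSyntaxError(f"expected a value, found {v or 'end'!r}", p)
        if fieldname in INT_FIELDS:
            try:
                return int(v)
            except ValueError:
                raise SelectionSyntaxError(
                    f"field {fieldname!r} takes integer values, got {v!r}", p
                ) from None
        return v


@dataclass(frozen=True)
class SelectionExpr:
    """A parsed selection expression; hashable and reusable across tables."""

    source: str
    _ast: _Node

    @classmethod
    def parse(cls, text: str) -> "SelectionExpr":
        return cls(text, _Parser(text).parse())

    def mask(self, table: SiteTable) -> np.ndarray:
        return self._ast.evaluate(table)


def parse_selection(text: str) -> SelectionExpr:
    return SelectionExpr.parse(text)


def select(table: SiteTable, expr: "SelectionExpr | str") -> np.ndarray:
    """Evaluate a selection, returning site indices in ascending order."""
    if isinstance(expr, str):
        expr = SelectionExpr.parse(expr)
    return np.flatnonzero(expr.mask(table))
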