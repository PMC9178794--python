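"""A small selection-expression language over topologies.

Grammar (MDAnalysis-flavoured)::

    expr     := or_expr
    or_expr  := and_expr ('or' and_expr)*
    and_expr := unary ('and' unary)*
    unary    := 'not' unary | '(' expr ')' | primary
    primary  := 'all'
              | 'name'    WORD+
              | 'resname' WORD+
              | 'resid'   RANGE+          (1-based, '4' or '2:17')
              | 'index'   RANGE+          (1-based atom serials)
              | 'segid'   WORD+           (protomer / chain label)
              | 'class'   WORD+           (residue chemical class)
              | 'group'   WORD            (named group on the topology)

Selections return 0-based atom indices in topology order, so they are
deterministic and idempotent. Keywords that match nothing produce an empty
selection with a warning by default; pass ``strict=True`` to raise instead.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import Topology

__all__ = ["select", "SelectionError"]


class SelectionError(ValueError):
    """Raised for unparseable expressions or (in strict mode) empty matches."""


_KEYWORDS = {"name", "resname", "resid", "index", "segid", "class", "group",
             "and", "or", "not", "all", "(", ")"}


def _tokenize(expression: str) -> list[str]:
    out: list[str] = []
    for raw in expression.replace("(", " ( ").replace(")", " ) ").split():
        out.append(raw)
    return out


class _Parser:
    def __init__(self, tokens: list[str], topo: Topology, strict: bool):
        self.tokens = tokens
        self.pos = 0
        self.topo = topo
        self.strict = strict
        self.n = len(topo)

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.or_expr()
        if self.peek() is not None:
            raise SelectionError(f"trailing tokens at {self.peek()!r}")
        return mask

    def or_expr(self) -> np.ndarray:
        mask = self.and_expr()
        while self.peek() == "or":
            self.take()
            mask = mask | self.and_expr()
        return mask

    def and_expr(self) -> np.ndarray:
        mask = self.unary()
        while self.peek() == "and":
            self.take()
            mask = mask & self.unary()
        return mask

    def unary(self) -> np.ndarray:
        tok = self.peek()
        if tok == "not":
            self.take()
            return ~self.unary()
        if tok == "(":
            self.take()
            mask = self.or_expr()
            if self.take() != ")":
                raise SelectionError("unbalanced parentheses")
            return mask
        return self.primary()

    def _values(self) -> list[str]:
        vals = []
        while self.peek() is not None and self.peek() not in _KEYWORDS:
            vals.append(self.take())
        if not vals:
            raise SelectionError("keyword needs at least one value")
        return vals

    def _warn_or_raise(self, what: str) -> None:
        if self.strict:
            raise SelectionError(f"selection matched no atoms: {what}")
        warnings.warn(f"selection matched no atoms: {what}", stacklevel=4)

    def _match_field(self, field: np.ndarray, values: list[str], what: str) -> np.ndarray:
        mask = np.isin(field, values)
        for v in values:
            if not np.any(field == v):
                self._warn_or_raise(f"{what} {v}")
        return mask

    def _match_ranges(self, field: np.ndarray, values: list[str]) -> np.ndarray:
        mask = np.zeros(self.n, dtype=bool)
        for v in values:
            if ":" in v:
                lo_s, hi_s = v.split(":", 1)
                try:
                    lo, hi = int(lo_s), int(hi_s)
                except ValueError as exc:
                    raise SelectionError(f"bad range {v!r}") from exc
                mask |= (field >= lo) & (field <= hi)
            else:
                try:
                    mask |= field == int(v)
                except ValueError as exc:
                    raise SelectionError(f"bad integer {v!r}") from exc
        return mask

    def primary(self) -> np.ndarray:
        tok = self.take()
        topo = self.topo
        if tok == "all":
            return np.ones(self.n, dtype=bool)
        if tok == "name":
            return self._match_field(topo.names, self._values(), "name")
        if tok == "resname":
            return self._match_field(topo.residue_names, self._values(), "resname")
        if tok == "segid":
            return self._match_field(topo.protomer_ids, self._values(), "segid")
        if tok == "class":
            return self._match_field(topo.residue_classes, self._values(), "class")
        if tok == "resid":
            return self._match_ranges(topo.residue_indices, self._values())
        if tok == "index":
            serials = np.array([a.atom_index for a in topo.atoms])
            return self._match_ranges(serials, self._values())
        if tok == "group":
            gname = self.take()
            if gname not in topo.groups:
                self._warn_or_raise(f"group {gname}")
                return np.zeros(self.n, dtype=bool)
            mask = np.zeros(self.n, dtype=bool)
            mask[topo.groups[gname]] = True
            return mask
        raise SelectionError(f"unknown selection keyword {tok!r}")


def select(topology: Topology, expression: str, strict: bool = False) -> np.ndarray:
    """Evaluate a selection expression, returning sorted 0-based atom indices."""
    tokens = _tokenize(expression)
    if not tokens:
        raise SelectionError("empty selection expression")
    mask = _Parser(tokens, topology, strict).parse()
    return np.flatnonzero(mask)
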