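"""Gene-protein-reaction (GPR) boolean rules.

A GPR rule ties a reaction's availability to gene presence: ``OR`` encodes
isozymes (any gene suffices), ``AND`` encodes enzyme complexes (all subunits
required). An empty rule means the reaction is gene-independent (transport,
exchange, spontaneous) and can never be disabled by a gene deletion.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import FrozenSet, Iterator, Optional, Tuple, Union

__all__ = ["GPRRule", "GPRParseError", "parse_gpr"]

# Expression tree: a gene id (str), or ("and"|"or", (child, child, ...)).
Expr = Union[str, Tuple[str, Tuple["Expr", ...]]]


class GPRParseError(ValueError):
    """Malformed GPR expression; carries the offending token position."""

    def __init__(self, message: str, position: int) -> None:
        super().__init__(f"{message} (at position {position})")
        self.position = position


_TOKEN = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize(text: str) -> Iterator[Tuple[str, int]]:
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:  # only trailing whitespace remains
            break
        yield m.group(1), m.start(1)
        pos = m.end()


@dataclass(frozen=True)
class GPRRule:
    """Immutable boolean tree over gene identifiers.

    ``expr`` is ``None`` for the empty rule, a gene id string for a leaf, or
    an ``(op, children)`` tuple with ``op`` in ``{"and", "or"}``.
    """

    expr: Optional[Expr] = None

    @property
    def is_empty(self) -> bool:
        return self.expr is None

    @property
    def genes(self) -> FrozenSet[str]:
        """Set of gene ids appearing as leaves."""

        out = set()

        def walk(node: Expr) -> None:
            if isinstance(node, str):
                out.add(node)
            else:
                for child in node[1]:
                    walk(child)

        if self.expr is not None:
            walk(self.expr)
        return frozenset(out)

    def evaluate(self, active_genes) -> bool:
        """Truth value given a set of present/active genes.

        The empty rule is always true: a reaction with no gene requirement
        stays available under any deletion.
        """

        active = set(active_genes)

        def walk(node: Expr) -> bool:
            if isinstance(node, str):
                return node in active
            op, children = node
            if op == "and":
                return all(walk(c) for c in children)
            return any(walk(c) for c in children)

        return True if self.expr is None else walk(self.expr)

    def to_string(self) -> str:
        """Serialize back to ``and``/``or`` text; parses to an equivalent rule."""

        def walk(node: Expr, parent_op: Optional[str]) -> str:
            if isinstance(node, str):
                return node
            op, children = node
            inner = f" {op} ".join(walk(c, op) for c in children)
            # parenthesize whenever nested under a different operator
            if parent_op is not None and parent_op != op:
                return f"({inner})"
            return inner

        return "" if self.expr is None else walk(self.expr, None)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


def parse_gpr(text: str) -> GPRRule:
    """Parse a GPR string (``and``/``or``/parentheses, case-insensitive).

    Raises
    ------
    GPRParseError
        On malformed input, naming the offending token position.
    """

    tokens = list(_tokenize(text))
    if not tokens:
        return GPRRule(None)

    index = 0

    def peek() -> Optional[Tuple[str, int]]:
        return tokens[index] if index < len(tokens) else None

    def advance() -> Tuple[str, int]:
        nonlocal index
        tok = tokens[index]
        index += 1
        return tok

    def parse_or() -> Expr:
        parts = [parse_and()]
        while peek() is not None and peek()[0].lower() == "or":
            advance()
            parts.append(parse_and())
        return parts[0] if len(parts) == 1 else ("or", tuple(parts))

    def parse_and() -> Expr:
        parts = [parse_atom()]
        while peek() is not None and peek()[0].lower() == "and":
            advance()
            parts.append(parse_atom())
        return parts[0] if len(parts) == 1 else ("and", tuple(parts))

    def parse_atom() -> Expr:
        tok = peek()
        if tok is None:
            raise GPRParseError("unexpected end of expression", len(text))
        word, pos = advance()
        if word == "(":
            node = parse_or()
            closing = peek()
            if closing is None or closing[0] != ")":
                raise GPRParseError("unbalanced parenthesis", pos)
            advance()
            return node
        if word == ")" or word.lower() in ("and", "or"):
            raise GPRParseError(f"unexpected token {word!r}", pos)
        return word

    expr = parse_or()
    if peek() is not None:
        word, pos = peek()
        raise GPRParseError(f"unexpected token {word!r}", pos)
    return GPRRule(expr)
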