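"""Boolean gene-protein-reaction (GPR) rules.

A GPR is a boolean expression over gene identifiers attached to a reaction.
``AND`` joins subunits of an obligate complex (every gene required), ``OR``
joins isozymes (any one suffices).  An empty rule marks a spontaneous or
non-gene-associated reaction, which is always considered active.

Gene identifiers are taken verbatim (``42197.4.peg.3610``-style ids with dots
are valid tokens); no case folding is applied to gene ids, while the
``and``/``or`` keywords are case-insensitive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Tuple, Union

__all__ = ["Gpr", "GprError"]


class GprError(ValueError):
    """Raised when a GPR string cannot be parsed."""


# AST node: ("gene", id) | ("and", (children...)) | ("or", (children...))
Node = Tuple[str, Union[str, Tuple["Node", ...]]]

_KEYWORDS = {"and", "or"}


def _tokenize(text: str) -> list[str]:
    tokens: list[str] = []
    buf = ""
    for ch in text:
        if ch in "()":
            if buf:
                tokens.append(buf)
                buf = ""
            tokens.append(ch)
        elif ch.isspace():
            if buf:
                tokens.append(buf)
                buf = ""
        else:
            buf += ch
    if buf:
        tokens.append(buf)
    return tokens


class _Parser:
    def __init__(self, tokens: list[str], source: str):
        self.tokens = tokens
        self.pos = 0
        self.source = source

    def peek(self) -> Optional[str]:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise GprError(f"unexpected end of GPR expression: {self.source!r}")
        self.pos += 1
        return tok

    # grammar: expr := term ("or" term)* ; term := factor ("and" factor)*
    def expr(self) -> Node:
        children = [self.term()]
        while (tok := self.peek()) is not None and tok.lower() == "or":
            self.next()
            children.append(self.term())
        return children[0] if len(children) == 1 else _flatten("or", children)

    def term(self) -> Node:
        children = [self.factor()]
        while (tok := self.peek()) is not None and tok.lower() == "and":
            self.next()
            children.append(self.factor())
        return children[0] if len(children) == 1 else _flatten("and", children)

    def factor(self) -> Node:
        tok = self.next()
        if tok == "(":
            node = self.expr()
            closing = self.next()
            if closing != ")":
                raise GprError(f"expected ')' in GPR {self.source!r}, got {closing!r}")
            return node
        if tok == ")" or tok.lower() in _KEYWORDS:
            raise GprError(f"unexpected token {tok!r} in GPR {self.source!r}")
        return ("gene", tok)


def _flatten(op: str, children: list[Node]) -> Node:
    flat: list[Node] = []
    for child in children:
        if child[0] == op:
            flat.extend(child[1])  # type: ignore[arg-type]
        else:
            flat.append(child)
    return (op, tuple(flat))


@dataclass(frozen=True)
class Gpr:
    """Parsed GPR rule; ``node is None`` means the empty (always-true) rule."""

    node: Optional[Node] = None

    @classmethod
    def parse(cls, text: Optional[str]) -> "Gpr":
        if text is None or not text.strip():
            return cls(None)
        tokens = _tokenize(text)
        parser = _Parser(tokens, text)
        node = parser.expr()
        if parser.peek() is not None:
            raise GprError(f"trailing tokens in GPR {text!r}")
        return cls(node)

    @property
    def is_empty(self) -> bool:
        return self.node is None

    @property
    def genes(self) -> frozenset[str]:
        if self.node is None:
            return frozenset()
        out: set[str] = set()
        stack = [self.node]
        while stack:
            kind, payload = stack.pop()
            if kind == "gene":
                out.add(payload)  # type: ignore[arg-type]
            else:
                stack.extend(payload)  # type: ignore[arg-type]
        return frozenset(out)

    def evaluate(self, deleted: Iterable[str] = ()) -> bool:
        """True if the reaction retains catalysis with ``deleted`` genes removed.

        AND nodes fail if any child fails; OR nodes fail only if all children
        fail; the empty rule is always true.
        """
        deleted = set(deleted)

        def rec(node: Node) -> bool:
            kind, payload = node
            if kind == "gene":
                return payload not in deleted
            if kind == "and":
                return all(rec(c) for c in payload)  # type: ignore[union-attr]
            return any(rec(c) for c in payload)  # type: ignore[union-attr]

        return True if self.node is None else rec(self.node)

    def to_string(self) -> str:
        """Canonical infix form; ``and`` binds tighter than ``or``."""

        def rec(node: Node, parent: str) -> str:
            kind, payload = node
            if kind == "gene":
                return payload  # type: ignore[return-value]
            sep = f" {kind} "
            text = sep.join(rec(c, kind) for c in payload)  # type: ignore[union-attr]
            # an or-node nested under an and-node needs explicit grouping
            if kind == "or" and parent == "and":
                return f"({text})"
            return text

        return "" if self.node is None else rec(self.node, "")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()
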