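"""Gene-protein-reaction (GPR) boolean rules.

A GPR links gene presence to enzyme availability: AND joins subunits of a
complex (all required), OR joins isoenzymes (any suffices). Rules are stored
as an expression tree whose leaves are gene identifiers; the empty rule means
"no gene association" and always evaluates to functional.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Union

# Tree nodes: a gene id (str) is a leaf; internal nodes are ("and"|"or", [children]).
Node = Union[str, tuple]

_TOKEN = re.compile(r"\(|\)|\band\b|\bor\b|[^\s()]+", re.IGNORECASE)


class GPRSyntaxError(ValueError):
    """Raised when a GPR string cannot be parsed into a well-formed tree."""


def _parse_tokens(tokens: list[str], pos: int) -> tuple[Node, int]:
    """Recursive-descent parse: or-expr := and-expr ('or' and-expr)*."""

    def parse_or(pos: int) -> tuple[Node, int]:
        node, pos = parse_and(pos)
        children = [node]
        while pos < len(tokens) and tokens[pos].lower() == "or":
            child, pos = parse_and(pos + 1)
            children.append(child)
        return (("or", children) if len(children) > 1 else children[0]), pos

    def parse_and(pos: int) -> tuple[Node, int]:
        node, pos = parse_atom(pos)
        children = [node]
        while pos < len(tokens) and tokens[pos].lower() == "and":
            child, pos = parse_atom(pos + 1)
            children.append(child)
        return (("and", children) if len(children) > 1 else children[0]), pos

    def parse_atom(pos: int) -> tuple[Node, int]:
        if pos >= len(tokens):
            raise GPRSyntaxError("unexpected end of GPR expression")
        tok = tokens[pos]
        if tok == "(":
            node, pos = parse_or(pos + 1)
            if pos >= len(tokens) or tokens[pos] != ")":
                raise GPRSyntaxError("unbalanced parenthesis in GPR expression")
            return node, pos + 1
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRSyntaxError(f"unexpected token {tok!r} in GPR expression")
        return tok, pos + 1

    return parse_or(pos)


@dataclass(frozen=True)
class GPR:
    """A gene-protein-reaction rule as an AND/OR tree over gene ids."""

    root: Node | None = None

    @classmethod
    def from_string(cls, rule: str) -> "GPR":
        rule = rule.strip()
        if not rule:
            return cls(None)
        tokens = _TOKEN.findall(rule)
        node, pos = _parse_tokens(tokens, 0)
        if pos != len(tokens):
            raise GPRSyntaxError(f"trailing tokens in GPR expression: {rule!r}")
        return cls(node)

    @property
    def is_empty(self) -> bool:
        return self.root is None

    def genes(self) -> frozenset[str]:
        out: set[str] = set()

        def walk(node: Node) -> None:
            if isinstance(node, str):
                out.add(node)
            else:
                for child in node[1]:
                    walk(child)

        if self.root is not None:
            walk(self.root)
        return frozenset(out)

    def evaluate(self, knocked: Iterable[str] = ()) -> bool:
        """True iff the enzyme is still functional with ``knocked`` genes removed."""
        knocked = frozenset(knocked)
        if self.root is None:
            return True

        def walk(node: Node) -> bool:
            if isinstance(node, str):
                return node not in knocked
            op, children = node
            if op == "and":
                return all(walk(c) for c in children)
            return any(walk(c) for c in children)

        return walk(self.root)

    def minimal_knockout_sets(self) -> list[frozenset[str]]:
        """All inclusion-minimal gene sets whose removal falsifies the rule.

        For a leaf this is the gene itself; for an AND it suffices to break any
        one child; for an OR every child must be broken simultaneously.
        """
        if self.root is None:
            return []

        def walk(node: Node) -> list[frozenset[str]]:
            if isinstance(node, str):
                return [frozenset([node])]
            op, children = node
            if op == "and":
                sets: list[frozenset[str]] = []
                for c in children:
                    sets.extend(walk(c))
            else:  # or: cartesian union over children
                sets = [frozenset()]
                for c in children:
                    sets = [s | t for s in sets for t in walk(c)]
            # prune non-minimal / duplicate combinations
            uniq = sorted(set(sets), key=lambda s: (len(s), sorted(s)))
            minimal: list[frozenset[str]] = []
            for s in uniq:
                if not any(m <= s for m in minimal):
                    minimal.append(s)
            return minimal

        return walk(self.root)

    def to_string(self) -> str:
        def walk(node: Node, parent_op: str | None = None) -> str:
            if isinstance(node, str):
                return node
            op, children = node
            body = f" {op} ".join(walk(c, op) for c in children)
            if parent_op is not None and parent_op != op:
                return f"({body})"
            return body

        return "" if self.root is None else walk(self.root)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


EMPTY_GPR = GPR(None)


def evaluate_gpr(rule: GPR | str, knocked: Iterable[str] = ()) -> bool:
    """Evaluate a GPR (object or string) against a set of knocked-out genes."""
    if isinstance(rule, str):
        rule = GPR.from_string(rule)
    return rule.evaluate(knocked)
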