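"""Gene-protein-reaction (GPR) boolean rules: parsing, rendering, evaluation.

A GPR rule links a reaction to the genes encoding its enzyme(s): ``and``
joins subunits of a complex (all required), ``or`` joins isozymes (any
suffices).  When quantitative gene data are pushed onto reactions, ``and``
maps to the minimum of the child values and ``or`` to the maximum — a
complex is only as available as its scarcest subunit, while isozymes are as
available as the most abundant one.

Genes without a measured value are simply skipped at their parent node; a
rule in which no gene at all is measured (or an empty rule) yields the
:data:`UNMAPPED` marker rather than an error, so partial gene coverage of a
model is a defined, non-exceptional state.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Optional

from .errors import GprParseError

#: Marker for "no data maps onto this reaction".
UNMAPPED = None


class GprExpression:
    """Base class of the boolean GPR tree."""

    def genes(self) -> frozenset[str]:
        raise NotImplementedError

    def evaluate(self, gene_values: Mapping[str, float]) -> Optional[float]:
        raise NotImplementedError

    def render(self) -> str:
        raise NotImplementedError

    @property
    def is_empty(self) -> bool:
        return isinstance(self, GprEmpty)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"{type(self).__name__}({self.render()!r})"


@dataclass(frozen=True)
class GprEmpty(GprExpression):
    """No gene association."""

    def genes(self) -> frozenset[str]:
        return frozenset()

    def evaluate(self, gene_values: Mapping[str, float]) -> Optional[float]:
        return UNMAPPED

    def render(self) -> str:
        return ""


@dataclass(frozen=True)
class GprGene(GprExpression):
    gene: str

    def genes(self) -> frozenset[str]:
        return frozenset({self.gene})

    def evaluate(self, gene_values: Mapping[str, float]) -> Optional[float]:
        value = gene_values.get(self.gene)
        return None if value is None else float(value)

    def render(self) -> str:
        return self.gene


@dataclass(frozen=True)
class _GprJunction(GprExpression):
    children: tuple[GprExpression, ...] = field(default_factory=tuple)

    _reduce = staticmethod(min)
    _keyword = ""

    def genes(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for child in self.children:
            out = out | child.genes()
        return out

    def evaluate(self, gene_values: Mapping[str, float]) -> Optional[float]:
        values = [v for v in (c.evaluate(gene_values) for c in self.children) if v is not None]
        if not values:
            return UNMAPPED
        return self._reduce(values)

    def render(self) -> str:
        parts = []
        for child in self.children:
            text = child.render()
            if self._needs_parens(child):
                text = f"({text})"
            parts.append(text)
        return f" {self._keyword} ".join(parts)

    def _needs_parens(self, child: GprExpression) -> bool:
        raise NotImplementedError


@dataclass(frozen=True)
class GprAnd(_GprJunction):
    """Enzyme complex: value is the minimum over measured children."""

    _reduce = staticmethod(min)
    _keyword = "and"

    def _needs_parens(self, child: GprExpression) -> bool:
        # "and" binds tighter than "or", so an "or" child must be bracketed.
        return isinstance(child, GprOr)


@dataclass(frozen=True)
class GprOr(_GprJunction):
    """Isozymes: value is the maximum over measured children."""

    _reduce = staticmethod(max)
    _keyword = "or"

    def _needs_parens(self, child: GprExpression) -> bool:
        return False


_TOKEN_RE = re.compile(r"\s*(?:(?P<lpar>\()|(?P<rpar>\))|(?P<word>[^\s()]+))")


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    pos = 0
    while pos < len(text):
        match = _TOKEN_RE.match(text, pos)
        if match is None:
            break
        pos = match.end()
        if match.group("lpar"):
            tokens.append(("(", "(", match.start("lpar")))
        elif match.group("rpar"):
            tokens.append((")", ")", match.start("rpar")))
        else:
            word = match.group("word")
            kind = word.lower() if word.lower() in ("and", "or") else "gene"
            tokens.append((kind, word, match.start("word")))
    return tokens


class _Parser:
    """Recursive-descent parser; ``and`` binds tighter than ``or``."""

    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.index = 0

    def peek(self) -> Optional[tuple[str, str, int]]:
        return self.tokens[self.index] if self.index < len(self.tokens) else None

    def advance(self) -> tuple[str, str, int]:
        token = self.tokens[self.index]
        self.index += 1
        return token

    def fail(self, message: str, position: int) -> GprParseError:
        return GprParseError(f"{message} at position {position} in {self.text!r}")

    def parse(self) -> GprExpression:
        if not self.tokens:
            return GprEmpty()
        expr = self.parse_or()
        trailing = self.peek()
        if trailing is not None:
            raise self.fail(f"unexpected {trailing[1]!r}", trailing[2])
        return expr

    def parse_or(self) -> GprExpression:
        children = [self.parse_and()]
        while (token := self.peek()) is not None and token[0] == "or":
            self.advance()
            children.append(self.parse_and())
        return children[0] if len(children) == 1 else GprOr(tuple(children))

    def parse_and(self) -> GprExpression:
        children = [self.parse_atom()]
        while (token := self.peek()) is not None and token[0] == "and":
            self.advance()
            children.append(self.parse_atom())
        return children[0] if len(children) == 1 else GprAnd(tuple(children))

    def parse_atom(self) -> GprExpression:
        token = self.peek()
        if token is None:
            raise self.fail("dangling operator (expected gene or '(')", len(self.text))
        kind, word, position = token
        if kind == "gene":
            self.advance()
            return GprGene(word)
        if kind == "(":
            self.advance()
            inner = self.parse_or()
            closing = self.peek()
            if closing is None or closing[0] != ")":
                raise self.fail("unbalanced parentheses (missing ')')", position)
            self.advance()
            return inner
        raise self.fail(f"unexpected {word!r} (expected gene or '(')", position)


def parse_gpr(rule_text: str) -> GprExpression:
    """Parse a GPR rule string into a boolean expression tree.

    Keywords ``and``/``or`` are case-insensitive, ``and`` binds tighter than
    ``or``, parentheses override precedence, and the empty string denotes no
    gene association.  Raises :class:`GprParseError` naming the offending
    position for unbalanced parentheses or dangling operators.
    """
    return _Parser(rule_text).parse()


def evaluate_gpr(gpr: GprExpression, gene_values: Mapping[str, float]) -> Optional[float]:
    """Map gene values onto a reaction through its GPR rule.

    ``and`` nodes take the minimum of their measured children, ``or`` nodes
    the maximum; unmeasured genes are skipped.  Returns :data:`UNMAPPED`
    (``None``) when no gene in the rule has a value or the rule is empty.
    """
    return gpr.evaluate(gene_values)
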