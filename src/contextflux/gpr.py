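"""Boolean gene-protein-reaction (GPR) rules.

A GPR is a boolean tree of AND/OR nodes over gene-id leaves describing which
gene products enable a reaction (isozymes combine with OR, enzyme-complex
subunits with AND).  The empty rule — exchange, demand and spontaneous
reactions — always evaluates *present*, so that expression-based model
extraction never penalises reactions that no gene encodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Union

from .errors import MalformedGprError

__all__ = ["Gpr", "GprLeaf", "GprAnd", "GprOr", "parse_gpr"]


@dataclass(frozen=True)
class GprLeaf:
    gene: str

    def __post_init__(self) -> None:
        if not self.gene or not isinstance(self.gene, str):
            raise MalformedGprError("GPR leaf must be a nonempty gene id")


@dataclass(frozen=True)
class GprAnd:
    children: tuple["GprNode", ...]

    def __post_init__(self) -> None:
        if len(self.children) < 1:
            raise MalformedGprError("AND node needs at least one child")


@dataclass(frozen=True)
class GprOr:
    children: tuple["GprNode", ...]

    def __post_init__(self) -> None:
        if len(self.children) < 1:
            raise MalformedGprError("OR node needs at least one child")


GprNode = Union[GprLeaf, GprAnd, GprOr]


@dataclass(frozen=True)
class Gpr:
    """A gene-protein-reaction rule; ``root is None`` means the empty rule."""

    root: GprNode | None = None

    @property
    def is_empty(self) -> bool:
        return self.root is None

    def evaluate(self, present_genes: Iterable[str]) -> bool:
        """True iff the rule is satisfied by the set of present genes.

        The empty rule evaluates True: non-gene-associated reactions are
        never switched off by expression data.
        """
        present = set(present_genes)

        def ev(node: GprNode) -> bool:
            if isinstance(node, GprLeaf):
                return node.gene in present
            if isinstance(node, GprAnd):
                return all(ev(c) for c in node.children)
            if isinstance(node, GprOr):
                return any(ev(c) for c in node.children)
            raise MalformedGprError(f"unknown GPR node type {type(node)!r}")

        return True if self.root is None else ev(self.root)

    def genes(self) -> frozenset[str]:
        """All leaf gene ids, ignoring the AND/OR structure."""
        out: set[str] = set()

        def walk(node: GprNode) -> None:
            if isinstance(node, GprLeaf):
                out.add(node.gene)
            elif isinstance(node, (GprAnd, GprOr)):
                for c in node.children:
                    walk(c)
            else:
                raise MalformedGprError(f"unknown GPR node type {type(node)!r}")

        if self.root is not None:
            walk(self.root)
        return frozenset(out)

    def to_string(self) -> str:
        def fmt(node: GprNode, parent: str) -> str:
            if isinstance(node, GprLeaf):
                return node.gene
            op = " and " if isinstance(node, GprAnd) else " or "
            kind = "and" if isinstance(node, GprAnd) else "or"
            inner = op.join(fmt(c, kind) for c in node.children)
            # parenthesise only when nested under the other operator
            if parent not in ("", kind):
                return f"({inner})"
            return inner

        return "" if self.root is None else fmt(self.root, "")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


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


def parse_gpr(text: str) -> Gpr:
    """Parse a rule string like ``"g1 and (g2 or g3)"`` into a :class:`Gpr`.

    Grammar (case-insensitive keywords)::

        expr   := term ("or" term)*
        term   := factor ("and" factor)*
        factor := "(" expr ")" | GENE_ID

    An empty or all-whitespace string yields the empty rule.
    """
    tokens = _tokenize(text or "")
    if not tokens:
        return Gpr(None)
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def advance() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_expr() -> GprNode:
        terms = [parse_term()]
        while peek() is not None and peek().lower() == "or":
            advance()
            terms.append(parse_term())
        return terms[0] if len(terms) == 1 else GprOr(tuple(terms))

    def parse_term() -> GprNode:
        factors = [parse_factor()]
        while peek() is not None and peek().lower() == "and":
            advance()
            factors.append(parse_factor())
        return factors[0] if len(factors) == 1 else GprAnd(tuple(factors))

    def parse_factor() -> GprNode:
        tok = peek()
        if tok is None:
            raise MalformedGprError(f"unexpected end of GPR string: {text!r}")
        if tok == "(":
            advance()
            node = parse_expr()
            if peek() != ")":
                raise MalformedGprError(f"unbalanced parentheses in {text!r}")
            advance()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise MalformedGprError(f"unexpected token {tok!r} in {text!r}")
        return GprLeaf(advance())

    root = parse_expr()
    if pos != len(tokens):
        raise MalformedGprError(f"trailing tokens in GPR string {text!r}")
    return Gpr(root)
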