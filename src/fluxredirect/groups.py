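"""Enzyme groups: the unit of targeting.

Reactions that share one catalyzing gene association form a single enzyme
group, and every engineering instruction applies to the whole group — all
member reactions receive the same redirection coefficient.  Grouping is by
*canonicalized association string*, not by boolean semantics: the isozyme
pair ``"fabB or fabF"`` and the lone gene ``"fabB"`` are distinct enzymes
with distinct reaction sets, exactly as a metabolic reconstruction lists
them.  Canonicalization lowercases gene ids and sorts the operands of the
commutative ``and``/``or`` operators while preserving nesting, so that
``"fabF or fabB"`` and ``"fabB or fabF"`` name the same group.  No boolean
minimization is performed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .network import MetabolicNetwork


class AssociationParseError(ValueError):
    """Raised when a gene-association string cannot be parsed."""


_TOKEN = re.compile(r"\(|\)|\band\b|\bor\b|[^\s()]+", re.IGNORECASE)


def _tokenize(text: str) -> list[str]:
    tokens = _TOKEN.findall(text)
    if "".join(tokens).replace("(", "").replace(")", "") == "" and text.strip():
        raise AssociationParseError(f"no tokens in association {text!r}")
    return tokens


class _Parser:
    """Recursive-descent parser for gene-association boolean expressions.

    Grammar:  expr := term ('or' term)* ;  term := atom ('and' atom)* ;
    atom := gene | '(' expr ')'.  Returns a nested tuple AST
    ('or'|'and', [children...]) with gene-id strings at the leaves.
    """

    def __init__(self, tokens: list[str], source: str):
        self.tokens = tokens
        self.pos = 0
        self.source = source

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise AssociationParseError(f"unexpected end of association {self.source!r}")
        self.pos += 1
        return tok

    def parse(self):
        node = self.expr()
        if self.peek() is not None:
            raise AssociationParseError(
                f"trailing token {self.peek()!r} in association {self.source!r}"
            )
        return node

    def expr(self):
        children = [self.term()]
        while self.peek() is not None and self.peek().lower() == "or":
            self.take()
            children.append(self.term())
        return children[0] if len(children) == 1 else ("or", children)

    def term(self):
        children = [self.atom()]
        while self.peek() is not None and self.peek().lower() == "and":
            self.take()
            children.append(self.atom())
        return children[0] if len(children) == 1 else ("and", children)

    def atom(self):
        tok = self.take()
        if tok == "(":
            node = self.expr()
            if self.take() != ")":
                raise AssociationParseError(f"unbalanced parentheses in {self.source!r}")
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise AssociationParseError(
                f"unexpected token {tok!r} in association {self.source!r}"
            )
        return tok.lower()


def parse_association(text: str):
    """Parse a gene-association string into an AST; ``None`` for empty."""
    if not text or not text.strip():
        return None
    return _Parser(_tokenize(text), text).parse()


def _operands(node, op) -> list[str]:
    """Canonical operand strings of ``node`` under ``op``, flattening
    associative repeats of the same operator at any depth."""
    if isinstance(node, tuple) and node[0] == op:
        out: list[str] = []
        for child in node[1]:
            out.extend(_operands(child, op))
        return out
    return [_canonical(node)]


def _canonical(node) -> str:
    if isinstance(node, str):
        return node
    op, children = node
    # flatten same-operator nesting ("a or (b or c)" == "a or b or c")
    # into individual operands, then sort; different operators keep their
    # nesting.
    flat: list[str] = []
    for child in children:
        flat.extend(_operands(child, op))
    return "(" + f" {op} ".join(sorted(flat)) + ")"


def canonicalize_association(text: str) -> str:
    """Canonical form of a gene-association string ("" for empty).

    Lowercases gene ids, sorts ``and``/``or`` operands, flattens
    associative repeats of the same operator and drops the outermost
    parentheses.  Purely textual: no logic minimization, so
    ``"fabB or fabF"`` stays distinct from ``"fabB"``.
    """
    node = parse_association(text)
    if node is None:
        return ""
    out = _canonical(node)
    if out.startswith("("):
        out = out[1:-1]
    return out


def association_genes(text: str) -> frozenset[str]:
    """Set of (lowercased) gene ids appearing in an association string."""
    node = parse_association(text)
    genes: set[str] = set()

    def walk(n):
        if n is None:
            return
        if isinstance(n, str):
            genes.add(n)
        else:
            for child in n[1]:
                walk(child)

    walk(node)
    return frozenset(genes)


@dataclass(frozen=True)
class EnzymeGroup:
    """Set of reactions sharing one canonical gene association."""

    group_id: str
    reactions: tuple[str, ...]
    genes: frozenset[str] = field(default_factory=frozenset)

    def __len__(self) -> int:
        return len(self.reactions)


def derive_enzyme_groups(network: MetabolicNetwork) -> list[EnzymeGroup]:
    """Partition reactions with nonempty gene associations into enzyme groups.

    Reactions with an empty association (spontaneous, exchange, biomass)
    belong to no group and are never targetable.  Group order follows the
    first appearance of each canonical association in reaction order, so
    output is deterministic for a fixed model file; the partition itself is
    invariant under reaction reordering.
    """
    buckets: dict[str, list[str]] = {}
    for rxn in network.reactions:
        raw = network.gene_association.get(rxn, "")
        try:
            canon = canonicalize_association(raw)
        except AssociationParseError as exc:
            raise AssociationParseError(f"reaction {rxn!r}: {exc}") from exc
        if not canon:
            continue
        buckets.setdefault(canon, []).append(rxn)
    groups = []
    for canon, rxns in buckets.items():
        genes = association_genes(network.gene_association[rxns[0]])
        groups.append(EnzymeGroup(group_id=canon, reactions=tuple(rxns), genes=genes))
    return groups
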