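"""Gene-protein-reaction (GPR) boolean logic.

A GPR rule states which genes must be present for a reaction to carry flux:
``sucC and sucD`` (an enzyme complex — both subunits required), ``gA or gB``
(isozymes — either suffices), or the empty rule (spontaneous / orphan
reactions, which no gene deletion can block).

This module owns parsing, evaluation under a set of deleted genes,
propagation of deletions to blocked reactions, and single-deletion gene
equivalence classes used for reporting and search-space pruning.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Dict, FrozenSet, Iterable, List, Set, Tuple

if TYPE_CHECKING:  # pragma: no cover
    from .model import GEMModel


class GprParseError(ValueError):
    """Raised on a malformed GPR string; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class GprExpr:
    """Immutable boolean tree over gene identifiers.

    ``kind`` is one of ``"true"`` (the empty rule), ``"gene"``, ``"and"``,
    ``"or"``. AND/OR nodes are flattened (associativity normalized), so
    re-serialization is idempotent.
    """

    kind: str
    gene: str = ""
    children: Tuple["GprExpr", ...] = ()

    # -- constructors ---------------------------------------------------
    @staticmethod
    def true() -> "GprExpr":
        return _TRUE

    @staticmethod
    def of_gene(gene: str) -> "GprExpr":
        return GprExpr("gene", gene=gene)

    @staticmethod
    def join(kind: str, parts: Iterable["GprExpr"]) -> "GprExpr":
        flat: List[GprExpr] = []
        for p in parts:
            if p.kind == kind:
                flat.extend(p.children)
            else:
                flat.append(p)
        if len(flat) == 1:
            return flat[0]
        return GprExpr(kind, children=tuple(flat))

    # -- queries --------------------------------------------------------
    def genes(self) -> FrozenSet[str]:
        if self.kind == "gene":
            return frozenset((self.gene,))
        out: Set[str] = set()
        for c in self.children:
            out |= c.genes()
        return frozenset(out)

    def evaluate(self, deleted: FrozenSet[str] | Set[str]) -> bool:
        """True iff the reaction stays active when ``deleted`` genes are off."""
        if self.kind == "true":
            return True
        if self.kind == "gene":
            return self.gene not in deleted
        if self.kind == "and":
            return all(c.evaluate(deleted) for c in self.children)
        return any(c.evaluate(deleted) for c in self.children)

    def serialize(self) -> str:
        if self.kind == "true":
            return ""
        if self.kind == "gene":
            return self.gene
        sep = " and " if self.kind == "and" else " or "
        parts = []
        for c in self.children:
            s = c.serialize()
            if c.kind in ("and", "or"):
                s = f"({s})"
            parts.append(s)
        return sep.join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.serialize() or "TRUE"


_TRUE = GprExpr("true")

_TOKEN_RE = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize(text: str) -> List[Tuple[str, int]]:
    tokens: List[Tuple[str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


def parse_gpr(text: str) -> GprExpr:
    """Parse a GPR string into a :class:`GprExpr`.

    Grammar: gene identifiers, ``and`` / ``or`` (case-insensitive),
    parentheses. ``or`` binds looser than ``and``. The empty string is the
    distinguished TRUE rule.
    """
    if text is None or not text.strip():
        return GprExpr.true()
    tokens = _tokenize(text)
    expr, idx = _parse_or(tokens, 0, text)
    if idx != len(tokens):
        raise GprParseError("unexpected token %r" % tokens[idx][0], tokens[idx][1])
    return expr


def _parse_or(tokens, idx, text):
    parts = []
    part, idx = _parse_and(tokens, idx, text)
    parts.append(part)
    while idx < len(tokens) and tokens[idx][0].lower() == "or":
        part, idx = _parse_and(tokens, idx + 1, text)
        parts.append(part)
    return GprExpr.join("or", parts), idx


def _parse_and(tokens, idx, text):
    parts = []
    part, idx = _parse_atom(tokens, idx, text)
    parts.append(part)
    while idx < len(tokens) and tokens[idx][0].lower() == "and":
        part, idx = _parse_atom(tokens, idx + 1, text)
        parts.append(part)
    return GprExpr.join("and", parts), idx


def _parse_atom(tokens, idx, text):
    if idx >= len(tokens):
        raise GprParseError("empty operand", len(text))
    tok, pos = tokens[idx]
    if tok == "(":
        expr, idx = _parse_or(tokens, idx + 1, text)
        if idx >= len(tokens) or tokens[idx][0] != ")":
            raise GprParseError("unbalanced parentheses", pos)
        return expr, idx + 1
    if tok == ")":
        raise GprParseError("unbalanced parentheses", pos)
    if tok.lower() in ("and", "or"):
        raise GprParseError("empty operand before %r" % tok, pos)
    return GprExpr.of_gene(tok), idx + 1


# ---------------------------------------------------------------------------
# Knockout propagation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KnockoutEffect:
    """Reactions blocked by a set of gene deletions.

    Monotone in the deleted set: a superset of deletions blocks a superset
    of reactions. Reactions with the TRUE rule are never blocked.
    """

    deleted_genes: FrozenSet[str]
    blocked_reactions: FrozenSet[str]


def blocked_reactions(model: "GEMModel", genes: Iterable[str]) -> FrozenSet[str]:
    """Reaction ids whose GPR evaluates false once ``genes`` are deleted."""
    deleted = frozenset(genes)
    unknown = deleted - model.genes
    if unknown:
        raise KeyError(f"unknown gene id(s): {sorted(unknown)}")
    blocked = set()
    for rxn in model.reactions.values():
        if rxn.gpr.kind != "true" and not rxn.gpr.evaluate(deleted):
            blocked.add(rxn.id)
    return frozenset(blocked)


def knockout_propagate(
    model: "GEMModel", genes: Iterable[str]
) -> Tuple[KnockoutEffect, "GEMModel"]:
    """Apply gene deletions: block all reactions whose GPR turns false.

    Returns the effect and a derived mutant model with lb = ub = 0 on every
    blocked reaction. The input model is not modified.
    """
    deleted = frozenset(genes)
    blocked = blocked_reactions(model, deleted)
    mutant = model.copy()
    for rid in blocked:
        rxn = mutant.reactions[rid]
        rxn.lb = 0.0
        rxn.ub = 0.0
    return KnockoutEffect(deleted, blocked), mutant


# ---------------------------------------------------------------------------
# Gene equivalence classes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneClass:
    """Genes with identical single-deletion blocked-reaction sets.

    ``cuttable`` is False for genes that occur in no GPR at all — deleting
    such a gene can never change any rule at any order, so the search may
    skip them entirely. Genes whose single deletion blocks nothing but that
    do occur in GPRs (isozyme members) remain cuttable: they matter in
    combination.
    """

    representative: str
    members: FrozenSet[str]
    blocked: FrozenSet[str]
    cuttable: bool


def gene_equivalence_classes(model: "GEMModel") -> List[GeneClass]:
    """Partition the gene set by single-deletion blocked-reaction sets."""
    occurring: Set[str] = set()
    for rxn in model.reactions.values():
        occurring |= rxn.gpr.genes()
    groups: Dict[tuple, List[str]] = {}
    singles: Dict[str, FrozenSet[str]] = {}
    for g in sorted(model.genes):
        eff = blocked_reactions(model, (g,)) if g in occurring else frozenset()
        singles[g] = eff
    for g, eff in singles.items():
        # genes absent from all GPRs share one non-cuttable bucket, kept
        # apart from occurring genes that merely have an empty single effect
        groups.setdefault((eff, g in occurring), []).append(g)
    classes = []
    for members in groups.values():
        rep = min(members)
        classes.append(
            GeneClass(
                representative=rep,
                members=frozenset(members),
                blocked=singles[rep],
                cuttable=rep in occurring,
            )
        )
    classes.sort(key=lambda c: c.representative)
    return classes
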