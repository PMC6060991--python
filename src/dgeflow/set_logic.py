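"""Combine DE gene sets from the three pairwise comparisons.

The study design has three libraries — V1 and V2 (vegetative stage, single-
and double-flowering sub-groups) and F2 (flowering stage, double-flowering
sub-group) — giving three pairwise comparisons labelled V1F2, V1V2 and V2F2.
Genes DE against the flowering-stage material in both vegetative baselines
but not between the vegetative samples themselves are taken as the
"flowering-exclusive" set: (V1F2 & V2F2) - V1V2. The expression is
user-configurable because the published figure never states its formula.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Iterable, Mapping

from .errors import SetExpressionError, ValidationError

#: The three pairwise comparison labels (reference library first).
LABELS = ("V1F2", "V1V2", "V2F2")

DEFAULT_FLOWERING_EXPRESSION = "(V1F2 & V2F2) - V1V2"


@dataclass
class ComparisonSets:
    """Gene-id sets for the three pairwise comparisons."""

    sets: Mapping[str, set]

    def __post_init__(self) -> None:
        if set(self.sets) != set(LABELS):
            raise ValidationError(
                f"comparison sets must be labelled exactly {LABELS}, got {sorted(self.sets)}"
            )
        self.sets = {k: set(v) for k, v in self.sets.items()}

    def __getitem__(self, label: str) -> set:
        if label not in self.sets:
            raise KeyError(f"unknown comparison label {label!r}")
        return self.sets[label]


def venn_counts(sets: ComparisonSets) -> dict[str, int]:
    """Sizes of the 7 disjoint regions of the three-set Venn diagram.

    Keys are '&'-joined sorted label subsets (e.g. 'V1F2', 'V1F2&V1V2',
    'V1F2&V1V2&V2F2'); values sum to the size of the union.
    """
    regions: dict[str, int] = {}
    for r in (1, 2, 3):
        for combo in itertools.combinations(LABELS, r):
            inside = set.intersection(*(sets[l] for l in combo))
            outside = set.union(set(), *(sets[l] for l in LABELS if l not in combo))
            regions["&".join(combo)] = len(inside - outside)
    return regions


# ---------------------------------------------------------------------------
# Set-expression parser (identifiers, & | -, parentheses)
# ---------------------------------------------------------------------------

_TOKEN = re.compile(r"\s*(?:(?P<name>[A-Za-z_][A-Za-z0-9_]*)|(?P<op>[&|()\-]))")


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            if text[pos:].strip() == "":
                break
            raise SetExpressionError(f"unexpected character {text[pos:].strip()[0]!r}", pos)
        kind = "name" if m.group("name") else "op"
        tokens.append((kind, m.group(kind), m.start(kind)))
        pos = m.end()
    return tokens


class _Parser:
    """Recursive descent: union binds loosest; '&' and '-' bind equally, left-assoc."""

    def __init__(self, text: str, sets: ComparisonSets):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0
        self.sets = sets

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self):
        tok = self.peek()
        if tok is None:
            raise SetExpressionError("unexpected end of expression", len(self.text))
        self.i += 1
        return tok

    def parse(self) -> set:
        value = self.union()
        if self.peek() is not None:
            kind, val, pos = self.peek()
            raise SetExpressionError(f"unexpected token {val!r}", pos)
        return value

    def union(self) -> set:
        value = self.term()
        while self.peek() and self.peek()[1] == "|":
            self.next()
            value = value | self.term()
        return value

    def term(self) -> set:
        value = self.atom()
        while self.peek() and self.peek()[1] in ("&", "-"):
            op = self.next()[1]
            rhs = self.atom()
            value = value & rhs if op == "&" else value - rhs
        return value

    def atom(self) -> set:
        kind, val, pos = self.next()
        if kind == "name":
            if val not in LABELS:
                raise SetExpressionError(f"unknown comparison label {val!r}", pos)
            return set(self.sets[val])
        if val == "(":
            inner = self.union()
            tok = self.peek()
            if tok is None or tok[1] != ")":
                raise SetExpressionError("missing closing parenthesis", pos)
            self.next()
            return inner
        raise SetExpressionError(f"unexpected token {val!r}", pos)


def evaluate_set_expression(expression: str, sets: ComparisonSets) -> set:
    """Evaluate a boolean combination of the three comparison labels."""
    return _Parser(expression, sets).parse()


def flowering_exclusive_genes(
    sets: ComparisonSets,
    expression: str = DEFAULT_FLOWERING_EXPRESSION,
) -> set:
    """Genes selected by the configured set expression (default: DE against
    the flowering material in both vegetative baselines, minus the genes DE
    between the vegetative samples)."""
    return evaluate_set_expression(expression, sets)


def comparison_sets_from_screens(screens: Mapping[str, "object"]) -> ComparisonSets:
    """Build ComparisonSets from three DE screen tables.

    Direction is ignored: any gene called up or down is in the comparison's
    set, matching the aggregate counts of the published Venn figure.
    """
    sets = {}
    for label, table in screens.items():
        called = table[table["direction"].isin(("up", "down"))]
        sets[label] = set(called["gene_id"])
    return ComparisonSets(sets)
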