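"""KEGG module DEFINITION parsing and completeness evaluation.

A DEFINITION string is compiled to a boolean expression tree over KO
leaves.  Grammar (precedence ``+`` > ``,`` > space):

* space separates AND-ed steps,
* ``,`` separates OR alternatives,
* ``+`` joins complex subunits (all required),
* ``-`` prefixes an optional component (ignored for completeness),
* ``--`` is a wildcard step (satisfied by default; configurable),
* parentheses group.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .io_formats import ModuleFlatRecord
from .quantify import TpmMatrix, present_kos
from .taxonomy import Lineage

#: Nitrogenase structural subunit KOs: nifH, nifD, nifK.
NITROGENASE_KOS = ("K02588", "K02586", "K02591")

_TOKEN_RE = re.compile(r"K\d{5}|--|[(),+\-]|\s+")


class DefinitionParseError(ValueError):
    """Raised for unbalanced parentheses or illegal tokens (with position)."""


# --- expression tree -------------------------------------------------------


@dataclass(frozen=True)
class Leaf:
    ko: str


@dataclass(frozen=True)
class Wildcard:
    pass


@dataclass(frozen=True)
class Optional_:
    child: "Node"


@dataclass(frozen=True)
class And:
    children: tuple["Node", ...]


@dataclass(frozen=True)
class Or:
    children: tuple["Node", ...]


@dataclass(frozen=True)
class Complex:
    children: tuple["Node", ...]


Node = Leaf | Wildcard | Optional_ | And | Or | Complex


def parse_definition(definition: str) -> Node:
    """Parse a DEFINITION string into an expression tree."""
    tokens: list[tuple[str, int]] = []
    pos = 0
    while pos < len(definition):
        m = _TOKEN_RE.match(definition, pos)
        if m is None:
            raise DefinitionParseError(f"illegal token at position {pos}: {definition[pos:pos+8]!r}")
        text = m.group(0)
        tokens.append((" " if text.isspace() else text, pos))
        pos = m.end()
    parser = _Parser(tokens, definition)
    node = parser.parse_expr()
    parser.expect_end()
    return node


class _Parser:
    def __init__(self, tokens: list[tuple[str, int]], source: str):
        self.tokens = [t for t in tokens]
        self.i = 0
        self.source = source

    def peek(self) -> str | None:
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def pos(self) -> int:
        return self.tokens[self.i][1] if self.i < len(self.tokens) else len(self.source)

    def advance(self) -> str:
        tok = self.tokens[self.i][0]
        self.i += 1
        return tok

    def skip_space(self) -> None:
        while self.peek() == " ":
            self.advance()

    def expect_end(self) -> None:
        self.skip_space()
        if self.peek() is not None:
            raise DefinitionParseError(f"unexpected {self.peek()!r} at position {self.pos()}")

    def parse_expr(self) -> Node:
        """Space-separated steps -> And."""
        self.skip_space()
        steps = [self.parse_step()]
        while True:
            if self.peek() == " ":
                self.skip_space()
                if self.peek() in (None, ")"):
                    break
                steps.append(self.parse_step())
            else:
                break
        return steps[0] if len(steps) == 1 else And(tuple(steps))

    def parse_step(self) -> Node:
        """Comma-separated alternatives -> Or."""
        alts = [self.parse_alt()]
        while self.peek() == ",":
            self.advance()
            alts.append(self.parse_alt())
        return alts[0] if len(alts) == 1 else Or(tuple(alts))

    def parse_alt(self) -> Node:
        """'+'/'-' joined complex members; '-' marks the member optional."""
        members: list[Node] = []
        optional_first = False
        if self.peek() == "-":
            self.advance()
            optional_first = True
        first = self.parse_unit()
        members.append(Optional_(first) if optional_first else first)
        while self.peek() in ("+", "-"):
            op = self.advance()
            unit = self.parse_unit()
            members.append(Optional_(unit) if op == "-" else unit)
        if len(members) == 1:
            return members[0]
        return Complex(tuple(members))

    def parse_unit(self) -> Node:
        tok = self.peek()
        if tok is None:
            raise DefinitionParseError(f"unexpected end of definition at position {self.pos()}")
        if tok == "--":
            self.advance()
            return Wildcard()
        if tok == "(":
            self.advance()
            inner = self.parse_expr()
            if self.peek() != ")":
                raise DefinitionParseError(f"unbalanced parentheses at position {self.pos()}")
            self.advance()
            return inner
        if re.fullmatch(r"K\d{5}", tok):
            self.advance()
            return Leaf(tok)
        raise DefinitionParseError(f"unexpected {tok!r} at position {self.pos()}")


def serialize(node: Node) -> str:
    """Canonical string form; ``parse(serialize(x))`` is a fixed point."""
    return _ser(node, "top")


def _ser(node: Node, ctx: str) -> str:
    if isinstance(node, Leaf):
        return node.ko
    if isinstance(node, Wildcard):
        return "--"
    if isinstance(node, Optional_):
        return "-" + _optional_body(node.child)
    if isinstance(node, Complex):
        parts = []
        for i, child in enumerate(node.children):
            if isinstance(child, Optional_):
                parts.append("-" + _optional_body(child.child))
            else:
                body = _ser(child, "complex")
                if isinstance(child, Complex):
                    body = f"({body})"  # keep nesting; bare '+' would flatten
                parts.append(("+" if i > 0 else "") + body)
        return "".join(parts)
    if isinstance(node, Or):
        body = ",".join(_ser(c, "or") for c in node.children)
        return f"({body})"
    if isinstance(node, And):
        body = " ".join(_ser(c, "step") for c in node.children)
        return f"({body})" if ctx != "top" else body
    raise TypeError(type(node))


def _optional_body(child: Node) -> str:
    # only a bare KO can follow '-' unambiguously; everything else needs parens
    if isinstance(child, Leaf):
        return child.ko
    return f"({_ser(child, 'top')})"


def expression_kos(node: Node) -> set[str]:
    """All KO ids appearing in the expression, optional ones included."""
    if isinstance(node, Leaf):
        return {node.ko}
    if isinstance(node, Wildcard):
        return set()
    if isinstance(node, Optional_):
        return expression_kos(node.child)
    return set().union(*(expression_kos(c) for c in node.children)) if node.children else set()


def required_kos(node: Node) -> set[str]:
    """A KO set sufficient to satisfy the expression (cheapest completion)."""
    missing = _min_missing(node, frozenset(), True)
    return set(missing) if missing is not None else set()


# --- evaluation ------------------------------------------------------------


@dataclass
class CompletenessResult:
    """Completeness verdict for one module in one scope."""

    module_id: str
    scope: str
    complete: bool
    satisfied_fraction: float
    missing_kos: tuple[str, ...]
    feasible: bool = True


def _truth(node: Node, present: frozenset[str], wildcard: bool) -> bool:
    if isinstance(node, Leaf):
        return node.ko in present
    if isinstance(node, Wildcard):
        return wildcard
    if isinstance(node, Optional_):
        return True
    if isinstance(node, (And, Complex)):
        return all(_truth(c, present, wildcard) for c in node.children)
    if isinstance(node, Or):
        return any(_truth(c, present, wildcard) for c in node.children)
    raise TypeError(type(node))


def _min_missing(
    node: Node, present: frozenset[str], wildcard: bool
) -> tuple[str, ...] | None:
    """Minimal-cardinality KO set completing ``node``; None if infeasible.

    Ties between OR branches break lexicographically on the sorted KO tuple.
    """
    if isinstance(node, Leaf):
        return () if node.ko in present else (node.ko,)
    if isinstance(node, Wildcard):
        return () if wildcard else None
    if isinstance(node, Optional_):
        return ()
    if isinstance(node, (And, Complex)):
        union: set[str] = set()
        for child in node.children:
            sub = _min_missing(child, present, wildcard)
            if sub is None:
                return None
            union.update(sub)
        return tuple(sorted(union))
    if isinstance(node, Or):
        best: tuple[str, ...] | None = None
        for child in node.children:
            sub = _min_missing(child, present, wildcard)
            if sub is None:
                continue
            if best is None or (len(sub), sub) < (len(best), best):
                best = sub
        return best
    raise TypeError(type(node))


def evaluate(
    expr: Node,
    present: set[str],
    wildcard_satisfied: bool = True,
    module_id: str = "",
    scope: str = "community",
) -> CompletenessResult:
    """Evaluate completeness of ``expr`` against a KO presence set.

    ``satisfied_fraction`` is the fraction of satisfied top-level AND steps,
    optional steps excluded from the denominator.  ``missing_kos`` is the
    minimal KO set completing the cheapest unsatisfied alternative.
    """
    frozen = frozenset(present)
    steps = list(expr.children) if isinstance(expr, And) else [expr]
    scored = [s for s in steps if not isinstance(s, Optional_)]
    if scored:
        satisfied = sum(_truth(s, frozen, wildcard_satisfied) for s in scored)
        fraction = satisfied / len(scored)
    else:
        fraction = 1.0
    missing = _min_missing(expr, frozen, wildcard_satisfied)
    complete = _truth(expr, frozen, wildcard_satisfied)
    return CompletenessResult(
        module_id=module_id,
        scope=scope,
        complete=complete,
        satisfied_fraction=fraction,
        missing_kos=missing if missing is not None else (),
        feasible=missing is not None,
    )


# --- community / per-family screening --------------------------------------


def screen_modules(
    modules: Sequence[ModuleFlatRecord],
    tpm: TpmMatrix | pd.DataFrame,
    annotations: Mapping[str, str],
    lineages: Mapping[str, Lineage],
    groups: Mapping[str, str] | None = None,
    per_family: bool = True,
    min_family_share: float = 0.01,
    wildcard_satisfied: bool = True,
    superkingdom: str = "Bacteria",
) -> pd.DataFrame:
    """Evaluate module completeness on bacterial genes, per sample group.

    For each group, the community scope pools the KOs of all genes of the
    requested superkingdom with TPM > 0 in any of its samples.  Per-family
    scopes are restricted to families contributing more than
    ``min_family_share`` of the group's bacterial TPM.
    """
    data = getattr(tpm, "data", tpm)
    if groups is None:
        groups = {s: "all" for s in data.index}
    exprs = {m.module_id: parse_definition(m.definition) for m in modules}

    bact_genes = [
        g for g in data.columns if g in lineages and lineages[g].superkingdom == superkingdom
    ]
    gene_family = {
        g: (lineages[g].family if lineages[g].family is not None else None) for g in bact_genes
    }

    rows = []
    for group in sorted(set(groups.values())):
        samples = [s for s in data.index if groups.get(s) == group]
        sub = data.loc[samples, bact_genes]
        active = sub.columns[(sub > 0).any(axis=0)]
        community_present = {annotations[g] for g in active if g in annotations}
        for mid, expr in exprs.items():
            res = evaluate(expr, community_present, wildcard_satisfied, mid, "community")
            rows.append(_result_row(res, group))
        if per_family:
            fam_mass = sub.sum(axis=0).groupby(
                pd.Index([gene_family[g] for g in sub.columns], name="family")
            ).sum()
            fam_mass = fam_mass[fam_mass.index.notna()]
            total = fam_mass.sum()
            if total > 0:
                abundant = fam_mass.index[(fam_mass / total) > min_family_share]
                for family in sorted(abundant):
                    fam_genes = [g for g in active if gene_family[g] == family]
                    present = {annotations[g] for g in fam_genes if g in annotations}
                    for mid, expr in exprs.items():
                        res = evaluate(expr, present, wildcard_satisfied, mid, family)
                        rows.append(_result_row(res, group))
    return pd.DataFrame(
        rows,
        columns=[
            "module_id",
            "group",
            "scope",
            "complete",
            "satisfied_fraction",
            "missing_kos",
            "feasible",
        ],
    )


def _result_row(res: CompletenessResult, group: str) -> tuple:
    return (
        res.module_id,
        group,
        res.scope,
        res.complete,
        res.satisfied_fraction,
        ";".join(res.missing_kos),
        res.feasible,
    )


def nitrogenase_screen(
    annotations: Mapping[str, str],
    tpm_by_layer: Mapping[str, TpmMatrix | pd.DataFrame],
) -> pd.DataFrame:
    """Per-sample, per-layer presence of the nitrogenase subunit KOs.

    A subunit is present when any gene carrying it has TPM > 0 in that
    sample and layer.
    """
    rows = []
    for layer, tpm in tpm_by_layer.items():
        per_sample = present_kos(tpm, annotations)
        for sample, kos in per_sample.items():
            for ko in NITROGENASE_KOS:
                rows.append((sample, layer, ko, ko in kos))
    return pd.DataFrame(rows, columns=["sample", "layer", "ko", "present"])
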