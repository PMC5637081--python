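"""Ovid-MEDLINE Boolean filter expressions: parse, serialize, evaluate.

A filter is a Boolean tree whose leaves are field-tagged terms in the Ovid
dialect used by published search hedges:

* ``term.tw`` — text word: the term's token sequence must occur contiguously
  in the tokenised title or the tokenised abstract;
* ``Term Phrase.sh`` — subject heading: the phrase must equal an assigned
  MeSH heading (case-insensitive, ``/qualifier`` suffixes stripped,
  unexploded);
* a trailing ``*`` truncates the final token: any document token with that
  token as a prefix matches (``paramedic*`` matches "paramedics",
  "paramedicine").

Tokenisation case-folds and splits on every non-alphanumeric character, so
hyphenated spellings are distinct from closed-up ones ("pre-hospital" vs
"prehospital") — which is why published filters carry both.

Operators are OR, AND and unary NOT (precedence NOT > AND > OR, left
associative).  OR/AND nodes are n-ary and self-flattening, so the canonical
serialisation round-trips to a structurally identical tree.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterator, TYPE_CHECKING

import pyparsing as pp

if TYPE_CHECKING:  # pragma: no cover
    from .records import BibRecord, Corpus

SUPPORTED_FIELDS = ("tw", "sh")

_TOKEN_RE = re.compile(r"[0-9a-z]+")


class FilterParseError(ValueError):
    """Invalid Ovid filter text; carries the offending position."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


def tokenize(text: str) -> tuple[str, ...]:
    """Case-fold and split on non-alphanumeric runs (hyphens split, digits kept)."""
    return tuple(_TOKEN_RE.findall(text.casefold()))


class FilterExpr:
    """Base of the Boolean expression tree."""

    def evaluate(self, record: "BibRecord") -> bool:
        raise NotImplementedError

    def terms(self) -> Iterator["FilterTerm"]:
        raise NotImplementedError

    def serialize(self) -> str:
        return serialize_filter(self)

    def __or__(self, other: "FilterExpr") -> "Or":
        return Or(self, other)

    def __and__(self, other: "FilterExpr") -> "And":
        return And(self, other)

    def __invert__(self) -> "Not":
        return Not(self)


@dataclass(frozen=True)
class FilterTerm(FilterExpr):
    """A field-tagged, optionally truncated term or phrase (a tree leaf)."""

    text: str
    field: str
    truncated: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "text", self.text.strip().casefold())
        if not self.text:
            raise ValueError("term text must be non-empty")
        if self.field not in SUPPORTED_FIELDS:
            raise ValueError(
                f"unsupported field tag {self.field!r}; expected one of "
                f"{SUPPORTED_FIELDS}"
            )
        if not tokenize(self.text):
            raise ValueError(f"term {self.text!r} has no alphanumeric tokens")

    @property
    def tokens(self) -> tuple[str, ...]:
        return tokenize(self.text)

    def evaluate(self, record: "BibRecord") -> bool:
        return match_term(self, record)

    def terms(self) -> Iterator["FilterTerm"]:
        yield self

    def __str__(self) -> str:
        return serialize_filter(self)


def _flatten(cls: type, children: tuple[FilterExpr, ...]) -> tuple[FilterExpr, ...]:
    out: list[FilterExpr] = []
    for child in children:
        if isinstance(child, cls):
            out.extend(child.children)  # type: ignore[attr-defined]
        else:
            out.append(child)
    return tuple(out)


@dataclass(frozen=True)
class Or(FilterExpr):
    children: tuple[FilterExpr, ...]

    def __init__(self, *children: FilterExpr):
        object.__setattr__(self, "children", _flatten(Or, tuple(children)))
        if len(self.children) < 2:
            raise ValueError("OR requires at least 2 children")

    def evaluate(self, record: "BibRecord") -> bool:
        return any(c.evaluate(record) for c in self.children)

    def terms(self) -> Iterator[FilterTerm]:
        for c in self.children:
            yield from c.terms()


@dataclass(frozen=True)
class And(FilterExpr):
    children: tuple[FilterExpr, ...]

    def __init__(self, *children: FilterExpr):
        object.__setattr__(self, "children", _flatten(And, tuple(children)))
        if len(self.children) < 2:
            raise ValueError("AND requires at least 2 children")

    def evaluate(self, record: "BibRecord") -> bool:
        return all(c.evaluate(record) for c in self.children)

    def terms(self) -> Iterator[FilterTerm]:
        for c in self.children:
            yield from c.terms()


@dataclass(frozen=True)
class Not(FilterExpr):
    child: FilterExpr

    def evaluate(self, record: "BibRecord") -> bool:
        return not self.child.evaluate(record)

    def terms(self) -> Iterator[FilterTerm]:
        yield from self.child.terms()


# --- matching ---------------------------------------------------------------


def _phrase_in(needle: tuple[str, ...], haystack: tuple[str, ...], truncated: bool) -> bool:
    n = len(needle)
    if n == 0 or n > len(haystack):
        return False
    head, last = needle[:-1], needle[-1]
    for i in range(len(haystack) - n + 1):
        if tuple(haystack[i : i + n - 1]) != head:
            continue
        doc_tok = haystack[i + n - 1]
        if doc_tok == last or (truncated and doc_tok.startswith(last)):
            return True
    return False


def _strip_qualifier(heading: str) -> str:
    return heading.split("/", 1)[0].strip()


def match_term(term: FilterTerm, record: "BibRecord") -> bool:
    """Does a single field-tagged term match a record?

    ``tw`` terms are matched as contiguous token sequences against title and
    abstract separately; ``sh`` terms against each MeSH heading with its
    ``/qualifier`` suffix stripped.  Truncation allows the final term token to
    be a prefix (zero or more extra characters) of the matched document token;
    non-truncated tokens match whole tokens only.
    """
    needle = term.tokens
    if term.field == "tw":
        return _phrase_in(needle, tokenize(record.title), term.truncated) or _phrase_in(
            needle, tokenize(record.abstract), term.truncated
        )
    # sh: whole-heading equality (punctuation-insensitive via tokenisation)
    for heading in record.mesh_headings:
        h_tokens = tokenize(_strip_qualifier(heading))
        if len(h_tokens) != len(needle):
            continue
        if _phrase_in(needle, h_tokens, term.truncated):
            return True
    return False


def evaluate_filter(expr: FilterExpr, record: "BibRecord") -> bool:
    """Standard Boolean semantics over the leaf matches."""
    return expr.evaluate(record)


def retrieve(expr: FilterExpr, corpus: "Corpus") -> set[str]:
    """The set of record ids the filter retrieves from a corpus."""
    return {rec.record_id for rec in corpus if expr.evaluate(rec)}


# --- parsing ----------------------------------------------------------------

# An atom is one or more dot-free words, the last carrying a .tag suffix.
# Reserved operator words never start a word of an atom.
_ATOM_WORD = r"(?!(?i:OR|AND|NOT)[\s()])[^\s().]+"
_ATOM_RE = rf"(?:{_ATOM_WORD}\s+)*(?:{_ATOM_WORD})?\.[A-Za-z][A-Za-z0-9]*"


def _make_term(source: str, loc: int, tokens: pp.ParseResults) -> FilterTerm:
    atom = re.sub(r"\s+", " ", tokens[0].strip())
    body, _, tag = atom.rpartition(".")
    tag = tag.casefold()
    if tag not in SUPPORTED_FIELDS:
        raise FilterParseError(f"unknown field tag {tag!r} in {atom!r}", loc)
    if not body:
        raise FilterParseError(f"empty term before field tag in {atom!r}", loc)
    truncated = body.endswith("*")
    if truncated:
        body = body[:-1]
    if "*" in body:
        raise FilterParseError(
            f"truncation '*' is only allowed at the end of the final token: {atom!r}",
            loc,
        )
    try:
        return FilterTerm(text=body, field=tag, truncated=truncated)
    except ValueError as exc:
        raise FilterParseError(str(exc), loc) from exc


@lru_cache(maxsize=1)
def _grammar() -> pp.ParserElement:
    atom = pp.Regex(_ATOM_RE).set_parse_action(_make_term)

    def unary(tokens: pp.ParseResults) -> FilterExpr:
        parts = tokens[0]
        expr = parts[-1]
        for _ in parts[:-1]:
            expr = Not(expr)
        return expr

    def nary(cls):
        def action(tokens: pp.ParseResults) -> FilterExpr:
            operands = tokens[0][0::2]
            return cls(*operands)

        return action

    expr = pp.infix_notation(
        atom,
        [
            (pp.CaselessKeyword("NOT"), 1, pp.OpAssoc.RIGHT, unary),
            (pp.CaselessKeyword("AND"), 2, pp.OpAssoc.LEFT, nary(And)),
            (pp.CaselessKeyword("OR"), 2, pp.OpAssoc.LEFT, nary(Or)),
        ],
    )
    return expr


def parse_filter(text: str) -> FilterExpr:
    """Parse Ovid-syntax filter text into an expression tree.

    Atom text is case-folded; precedence is NOT > AND > OR with left
    association; OR/AND chains become single n-ary nodes.  Empty input,
    unknown field tags, dangling operators and unbalanced parentheses raise
    :class:`FilterParseError` with the offending position.
    """
    if not text or not text.strip():
        raise FilterParseError("empty filter text")
    try:
        result = _grammar().parse_string(text, parse_all=True)
    except FilterParseError:
        raise
    except pp.ParseBaseException as exc:
        raise FilterParseError(exc.msg, exc.loc) from exc
    return result[0]


def parse_term(text: str) -> FilterTerm:
    """Parse a single field-tagged atom like ``paramedic*.tw``."""
    expr = parse_filter(text)
    if not isinstance(expr, FilterTerm):
        raise FilterParseError(f"expected a single term, got an expression: {text!r}")
    return expr


_PRECEDENCE = {Or: 1, And: 2, Not: 3, FilterTerm: 4}


def _prec(expr: FilterExpr) -> int:
    return _PRECEDENCE[type(expr)]


def _serialize(expr: FilterExpr, parent_prec: int) -> str:
    p = _prec(expr)
    if isinstance(expr, FilterTerm):
        out = f"{expr.text}{'*' if expr.truncated else ''}.{expr.field}"
    elif isinstance(expr, Or):
        out = " OR ".join(_serialize(c, p) for c in expr.children)
    elif isinstance(expr, And):
        out = " AND ".join(_serialize(c, p) for c in expr.children)
    elif isinstance(expr, Not):
        out = f"NOT {_serialize(expr.child, p)}"
    else:  # pragma: no cover
        raise TypeError(f"not a FilterExpr: {expr!r}")
    if p < parent_prec:
        out = f"({out})"
    return out


def serialize_filter(expr: FilterExpr) -> str:
    """Canonical Ovid text; ``parse_filter(serialize_filter(e))`` equals ``e``."""
    return _serialize(expr, 0)
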